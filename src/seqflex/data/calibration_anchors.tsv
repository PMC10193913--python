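# Segment mean-flexibility (mBf) anchors used to pin the packaged scale.
# role "calibration" anchors enter the affine fit; role "heldout" anchors are
# reserved for validation.  target_mbf values are the printed segment indices
# the calibration is anchored to.
protein_id	segment_name	start	end	helix_class	target_mbf	role
TRPV1_rat_S4	S4b	546	558	three10	1.6	calibration
hERG_human_S5PH	S5-PH	574	586	three10	2.08	calibration
TRPA1_human_PH2	PH2	917	924	pi	2.4	heldout
TRPV3_human_S45L	S4-S5L	573	579	pi	1.4	heldout
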