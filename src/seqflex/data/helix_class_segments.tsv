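protein_id	segment_name	start	end	helix_class
TRPV3_mouse_S6pi	S6	663	673	pi
TRPV6_human_S6pi	S6	564	574	pi
TRPM4_human_S6pi	S6	1029	1039	pi
TRPM8_mouse_S6pi	S6	965	975	pi
TRPC3_human_S6pi	S6	729	739	pi
TRPA1_human_S6pi	S6	946	956	pi
TRPV1_rat_S4	S4b	546	558	three10
hERG_human_S5PH	S5-PH	574	586	three10
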