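"""Compare mean flexibility of pi- versus 3(10)-transition segments.

Uses the packaged fixture set: six S6 pi-region 11-mers from the TRP
superfamily and two 3(10)-class segments (TRPV1 S4b, hERG S5-PH).  The pi
group is expected to be the more rigid.
"""

from seqflex import compare_helix_classes, flex_profile, group_segments, load_flex_scale
from seqflex.datasets import channel_segments, helix_class_annotations

scale = load_flex_scale("default")
profiles = [flex_profile(rec, scale) for rec in channel_segments()]
groups = group_segments(profiles, list(helix_class_annotations()))

for cls in ("pi", "three10"):
    for m in groups.groups[cls]:
        print(f"{cls:8s} {m.protein_id:20s} {m.segment_name:6s} "
              f"mBf={m.mean_flexibility.mbf:.3f}")

rep = compare_helix_classes(groups, "pi", "three10")
print(f"\nmean mBf: pi={rep.mean_a:.3f} (n={rep.n_a})  "
      f"three10={rep.mean_b:.3f} (n={rep.n_b})")
print(f"difference (three10 - pi) = {rep.difference:.3f}")
print(f"rank-sum U={rep.statistic:.1f}, two-sided p={rep.p_value:.3f}")
print("\nA positive difference reproduces the ordering: segments undergoing")
print("alpha->3(10) transitions are intrinsically more flexible than the")
print("rigid pi-transition regions of the S6 inner gate.")
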