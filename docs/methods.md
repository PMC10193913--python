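# Methods

## Flexibility model

The package treats per-residue flexibility as a compositional property of the
primary sequence.  Its empirical basis is the per-structure standardized
B-factor, `nBf = (B − Bm)/Bσ`, computed with the sample (n−1) standard
deviation; standardization is exact (output mean 0, sample SD 1) and a
constant B-factor series is rejected as degenerate rather than silently
producing zeros.  Averaging standardized B-factors over large structure sets
yields a 20-value propensity scale; the packaged base table is the
Vihinen-type "average normalized B-value" scale, chosen because it is the
standard literature representative of this family and satisfies the ordering
constraints the analysis relies on (Leu more flexible than Phe, Lys more
flexible than Arg).

A profile smooths the per-residue scale values over a symmetric window.  The
default window is width 3 with weights (¼, ½, ¼): each residue is read in
the context of its immediate N- and C-terminal neighbours, with the central
residue dominating.  At the termini the window is truncated and the
remaining weights renormalized to sum 1.  This keeps every profile value a
convex combination of scale values, which in turn gives the invariants the
test-bench checks: profile values bounded by the scale extrema, reversal
symmetry, and monotonicity under substitution by a more flexible residue.
Unknown residues (`X`) contribute the unweighted mean of the 20 scale
values; other ambiguity codes are rejected at parse time so the arithmetic
never sees them.

The segment index `mBf` is the arithmetic mean of the profile over an
inclusive 1-based residue range and is reported as a positive number, with
larger meaning more flexible.  The reciprocal `1/mBf` ("relative
flexibility") and the negated literal mean are exposed as separate fields
because both sign conventions circulate; only the positive index is used in
comparisons.

## Scale calibration

Published flexibility scales agree well in ranking but differ in location
and spread, roughly an affine change of units.  `calibrate_scale` therefore
re-anchors a scale with a single gain/offset pair, least-squares fitted so
that anchor segments' predicted `mBf` match externally given target indices.
Because the profile and segment mean are linear in the scale values, the fit
reduces to simple linear regression of targets on predicted means.  A
positive-gain affine map cannot reorder residues, so calibration can never
distort the scale's scientific content; a fit demanding non-positive gain is
refused.  With no anchors the scale is returned unchanged; with one anchor
(or no prediction spread) an offset-only adjustment is applied with a
warning.

The packaged default is calibrated against two published ion-channel segment
indices: rat TRPV1 S4b (residues 546–558) → 1.6 and human hERG S5-PH
(574–586) → 2.08.  The anchor spread (0.48 index units) is roughly 25×
larger than the spread the raw base scale produces between those segments,
so the unconstrained fit drives the gain to ~20 and would push the stiffest
residues (Trp, Cys, Phe) to non-positive values — invalid for a flexibility
scale and fatal for the downstream pD/nBf quotient.  The fit is therefore
solved under the constraint that the smallest calibrated value stays at or
above a small positive floor (default 0.05); when the unconstrained optimum
is feasible it is returned exactly, and in the constrained case the optimum
lies on the boundary and is obtained in closed form.  With the packaged
anchors the constrained fit still reproduces the calibration targets to
within ~0.05 (1.617 vs 1.6; 2.067 vs 2.08).

Two further published indices — TRPA1 PH2 (917–924) → 2.4 and TRPV3 S4–S5
linker (573–579) → 1.4 — are packaged as held-out validation anchors.  Their
residuals (~0.3–0.5) measure the joint error of (a) the stand-in base
scale's residue spacing relative to the unpublished scale behind the
reference values, amplified by the ~20× calibration gain, and (b) the
held-out fixture sequences themselves, which are partial reconstructions
with unknown interior positions stored as `X` (full-length accession
sequences cannot be redistributed with the package; the fixture FASTA marks
these entries as synthetic stand-ins).  The held-out residual is reported
honestly rather than absorbed into the fit.

## Disorder tracks and the naive stand-in

Disorder probabilities `pD ∈ [0,1]` come from external predictors; the
package parses a generic tab-separated dialect and a PrDOS-style CSV export,
validating bounds and strict residue-number monotonicity, and refusing
length or residue-letter mismatches when pairing with a sequence (silent
truncation would misalign every downstream quotient).  Binary verdicts use a
default threshold of 0.5, the probability midpoint.

`naive_disorder_score` is an offline stand-in: a packaged heuristic
disorder-propensity table (ordering consistent with published
order/disorder propensity rankings — aromatics strongly order-promoting,
Pro/Glu/Lys strongly disorder-promoting), smoothed with the profile window
and min–max rescaled to [0,1] using the *table's* extrema.  Anchoring the
rescale at the table rather than the sequence keeps scores comparable across
proteins.  The stand-in is deterministic, permutation-equivariant under
sequence reversal, and monotone under substitution toward higher propensity.
It is emphatically not a re-implementation of any machine-learning
predictor: being purely compositional it is strongly rank-correlated with
the flexibility scale, so discrepancies computed against it reflect
table-shape disagreements (e.g. proline), not the contextual effects a
template-based predictor would reveal.  Tests passing with the stand-in
validate the pipeline's arithmetic, not predictor fidelity.

## Discrepancy statistics

Flexibility and disorder tracks are paired residue by residue with `pD`
clamped to `[ε, 1]`, ε = 0.01 — below typical predictor reporting
resolution, and necessary because `pD = 0` is legitimate while the quotients
are not defined there.  The white quotient `nBf/pD` and black quotient
`pD/nBf` are exact reciprocals (their product is 1 at every residue, a
tested identity).  Dispersion is summarized on the raw white quotient as the
sample SD with standard error `sd/√n` — the identity `sem·√n = sd` holds
exactly by construction.

Flagging operates on log-quotients: a residue is flagged when its
log-white value deviates more than `k` sample SDs from the track mean
(default `k = 2`, a conventional outlier cut).  The log scale is the only
one on which the two discrepancy directions are symmetric: inverting every
quotient flags the same positions with directions swapped.  A track whose
log-quotient variance is zero up to floating-point rounding yields no flags
(with a warning) — the relative tolerance matters because a nominally
constant quotient track carries ~1e-16 arithmetic noise that would otherwise
be standardized into apparent outliers.  Under a Gaussian log-quotient null
the expected flag fraction at `k = 2` is ~4.6%, verified by simulation.

## Synthetic data

The generator produces the data structure the analysis assumes.  Sequences
are uniform over the 20 residues, drawn from the stiff/flexible scale
quartile pools, or greedily adjusted toward a target `mBf` (each step makes
the single substitution that most reduces the gap, ties broken leftmost;
the segment mean is linear in the per-position scale values, so each
candidate swap is evaluated in closed form).  Targets must lie strictly
inside the scale range.

Disorder tracks follow a logistic link to the standardized, re-smoothed
profile: `pd = expit(a·z + e + logit(0.3))` with Gaussian noise
`e ~ N(0, noise_sd²)` and gain `a = ρ·noise_sd/√(1−ρ²)`, which makes the
latent correlation with the smoothed profile equal ρ exactly; the logistic
transform distorts this only mildly at moderate spreads (realized Pearson
correlation within 0.1 of ρ = 0.8 at length 300).  The baseline disorder
level 0.3 reflects mostly ordered transmembrane domains.  Larger `noise_sd`
both weakens the per-residue information and saturates the logistic, so
flag recovery degrades as noise grows.  Discrepancy sites are injected by
displacing `pd` multiplicatively so the log-white quotient moves by
`effect` pre-injection SDs, in a random recorded direction per site (clipped
at `pd = 1`).  All generators are seed-deterministic, with independent
substreams for sequence, track, and replicate derived from the configured
seed.

Reference simulation conditions: length 300, ρ = 0.8, `noise_sd` 0.5
(moderate link noise; `pd` spans roughly 0.1–0.6), 5 injected sites of
3-SD effect, 100 replicates.  At these conditions the measured recovery is
sensitivity ≈ 0.76 and precision ≈ 0.24, with a null false-positive rate
≈ 0.05 and sensitivity monotone in effect size.  The precision value is a
structural consequence of the 2-sigma cut, not an implementation artifact:
with Gaussian link noise the baseline log-quotient is Gaussian-tailed, so
~4.6% of the ~295 uninjected residues (≈ 9–13 positions) are flagged per
track against at most 5 true sites, bounding precision near 0.3 no matter
how large the effect.  High precision at this design point would require
either a stricter cut (k ≈ 3), more injected sites, or a sub-Gaussian
link — the flag threshold `k` is configurable for exactly this reason.

## Helix-class comparison and pipeline

Annotated segments are grouped by helix class (`alpha`, `pi`, `three10`,
`loop`, `unknown`) and summarized by their `mBf`.  The default comparison is
π versus 3₁₀, reported as group means/SDs, the difference
mean(3₁₀) − mean(π), and a two-sided Mann–Whitney rank-sum helper; it is
descriptive, not an inferential claim about gating, and a single default
comparison carries no multiplicity adjustment.  The all-pairwise mode
adjusts p-values with Benjamini–Hochberg.  On the packaged fixture set (six
S6 π-region 11-mers; TRPV1 S4b and hERG S5-PH as the 3₁₀ class) the π group
mean is 1.19 versus 1.84 — the expected rigidity ordering — though with
n = 6 vs 2 the rank-sum p-value (0.071) is unsurprisingly above 0.05.

`run_full_analysis` composes the stages into an on-disk bundle (profile
tables, per-segment indices, comparison table, discrepancy tables and
dispersion summary when tracks are supplied) plus the resolved configuration
as YAML.  Outputs carry no timestamps, so identical inputs and configuration
give byte-identical bundles; every number in the bundle equals the
corresponding single-operation result, and any stage failure is re-raised
with the stage named.  Supplying no disorder tracks skips the discrepancy
stage with a logged notice.

## Numbering and degenerate inputs

Coordinates are 1-based and inclusive at both ends throughout.  Records
carry an explicit `numbering_offset` so fixtures may store fragments of
full-length proteins without renumbering annotations; FASTA round trips
preserve the offset via a header token.  Degenerate inputs fail loudly:
empty sequences, inverted ranges, out-of-range annotations (reporting the
valid span), constant B-factor series, incomplete or non-positive scales,
and mismatched track lengths are all errors, never silent coercions.

## Known limitations

- The per-residue scale is a calibrated literature stand-in; absolute `mBf`
  values inherit its residue spacing, and held-out published indices are
  reproduced only to ~0.3–0.5 under the ~20× calibration gain.
- Two packaged fixture segments are partial reconstructions (`X`-filled);
  results on them pin the protocol, not the underlying proteins.
- The naive disorder scorer shares its compositional basis with the
  flexibility scale; realistic discrepancy detection requires an external
  predictor's track.
- No structure-based flexibility (ENM/GNM), no PDB/mmCIF parsing, no
  multiple sequence alignment, and no re-implementation of disorder
  predictors: sequences, pre-extracted B-factor tables and predictor exports
  are the only inputs.
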