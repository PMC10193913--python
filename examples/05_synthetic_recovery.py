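"""Validate the discrepancy-flagging stage on synthetic ground truth.

Generates sequences whose disorder tracks follow a noisy logistic link to
the smoothed flexibility profile (target correlation 0.8), injects five
discrepancy sites of 3-SD effect per 300-residue sequence, and scores how
well the 2-sigma log-quotient flagging recovers them.
"""

from seqflex import SyntheticConfig, recovery_experiment

config = SyntheticConfig(length=300, rho=0.8, noise_sd=0.5, n_sites=5,
                         effect=3.0, seed=1)
report = recovery_experiment(config, n_seeds=50)
print(f"sensitivity          = {report.sensitivity:.3f}")
print(f"precision            = {report.precision:.3f}")

null = recovery_experiment(
    SyntheticConfig(length=300, rho=0.8, n_sites=0, seed=1), n_seeds=50
)
print(f"false-positive rate  = {null.false_positive_rate:.4f} (no injection)")

print("\nSensitivity is the fraction of injected sites flagged; precision the")
print("fraction of flags that were injected.  With a ~2-sigma cut the null")
print("flag rate stays near the Gaussian expectation (~4.6%), which bounds")
print("the attainable precision when only a handful of true sites exist.")
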