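"""Minimal plotting helpers: profile / disorder overlay."""

from __future__ import annotations

from typing import Optional

from .disorder import DisorderProfile
from .flexprofile import FlexProfile


def plot_profile_overlay(
    flex: FlexProfile,
    disorder: Optional[DisorderProfile] = None,
    ax=None,
):
    """Plot a flexibility profile (thick line), optionally overlaid with a
    disorder track (thin line, right axis).  Returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(flex.positions, flex.nbf, lw=2, color="tab:blue", label="nBf")
    ax.set_xlabel("residue number")
    ax.set_ylabel("nBf (flexibility)")
    ax.set_title(flex.record_id)
    if disorder is not None:
        ax2 = ax.twinx()
        ax2.plot(disorder.positions, disorder.pd, lw=0.8, color="tab:red", label="pD")
        ax2.set_ylabel("pD (disorder)")
        ax2.set_ylim(0, 1)
    return ax
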