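"""Matplotlib rendering of SAI curves (headless-safe)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .surrogacy import RELIABILITY_THRESHOLD, SAICurve

__all__ = ["plot_sai_curves"]


def plot_sai_curves(curves: dict[str, SAICurve], path: str | Path, title: str | None = None) -> None:
    """Plot SAI vs q with 95% intervals for each surrogate set, plus the 0.2 reliability line."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for i, (name, curve) in enumerate(curves.items()):
        q = list(curve.q_values)
        mean = curve.sai_mean.to_numpy()
        err_lo = mean - curve.ci_low.to_numpy()
        err_hi = curve.ci_high.to_numpy() - mean
        offset = (i - (len(curves) - 1) / 2) * 0.4
        ax.errorbar(
            [x + offset for x in q], mean, yerr=[err_lo, err_hi],
            marker="o", linestyle="-", capsize=3, label=name,
        )
    ax.axhline(RELIABILITY_THRESHOLD, color="grey", linestyle="--", linewidth=1,
               label=f"reliability threshold ({RELIABILITY_THRESHOLD})")
    ax.set_xlabel("q (% of plots with species data)")
    ax.set_ylabel("Species Accumulation Index")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
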