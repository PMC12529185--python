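"""Cumulative incidence curve plots (one panel per contrast)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .config import INTERVAL_DAYS  # noqa: E402


def plot_curves(curves: dict, out_path, title: str | None = None) -> None:
    """Plot per-arm cumulative incidence with pointwise 95% bands.

    ``curves`` maps an arm label to a CumulativeIncidenceCurve.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    for arm, curve in curves.items():
        months = [(k + 1) * INTERVAL_DAYS / 30.0 for k in range(curve.horizon)]
        ax.step(months, curve.F, where="post", label=str(arm))
        lo = curve.F - 1.96 * curve.se
        hi = curve.F + 1.96 * curve.se
        ax.fill_between(months, lo, hi, step="post", alpha=0.2)
    ax.set_xlabel("months of follow-up")
    ax.set_ylabel("cumulative incidence")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
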