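"""Static figures: per-class site-fraction bars and CDF-shift step plots."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .enrichment import CumulativeCurve, EnrichmentResult
from .omics_io import CLASSES

__all__ = ["plot_enrichment_bars", "plot_cumulative_curves"]


def plot_enrichment_bars(result: EnrichmentResult, path: Union[str, Path], title: str = "") -> None:
    """Bar chart of the site-containing fraction per regulation class."""
    fracs = [result.fractions[c] for c in CLASSES]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(CLASSES, fracs, color=["#c0392b", "#2980b9", "#7f8c8d"])
    ax.set_ylabel("fraction with seed site")
    label = "p = {:.2g} (chi-squared, {})".format(result.p_value, result.comparison)
    ax.set_title(f"{title}\n{label}".strip())
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_cumulative_curves(curve: CumulativeCurve, path: Union[str, Path], title: str = "") -> None:
    """Step plot of the set vs control cumulative fold-change fractions."""
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.step(curve.x, curve.y_in_set, where="post", label=f"{curve.set_label} (n={curve.n_set})")
    ax.step(
        curve.x,
        curve.y_out_set,
        where="post",
        label=f"{curve.control_label} (n={curve.n_control})",
    )
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("cumulative fraction")
    ax.set_title(f"{title} (D = {curve.max_vertical_gap:.3f})".strip())
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
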