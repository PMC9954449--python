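"""ONEST plot rendering.

Two styles: the *full* plot draws every sampled OPA curve (one line per
permutation); the *simplified* plot draws only the pointwise minimum,
median and maximum curves.  Optional annotations mark the ONEST value
(vertical segment down to the minimum curve) and the bandwidth (bracket
between the extreme curves at k = 2).  The plotted series are exported as
CSV straight from the result object — the plotting layer never recomputes
numbers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .core import OnestResult

__all__ = ["render_onest_plot", "render_overlay_plot"]

_SUMMARY_STYLE = {"min": "tab:red", "median": "tab:gray", "max": "tab:blue"}


def _export_series(result: OnestResult, mode: str, csv_path: Path) -> None:
    frame = result.curves_frame() if mode == "full" else result.summary_frame()
    frame.to_csv(csv_path)


def render_onest_plot(
    result: OnestResult,
    path: str | Path,
    mode: str = "simplified",
    annotate_onest: bool = True,
    annotate_bandwidth: bool = True,
    y_range: tuple[float, float] = (0.0, 1.0),
    csv_path: str | Path | None = None,
) -> Path:
    """Render one ONEST plot (PNG or SVG by file suffix) plus a series CSV.

    ``mode="full"`` draws all sampled permutation curves; ``"simplified"``
    draws the min/median/max summary.  The companion CSV (default: the
    plot path with a ``.csv`` suffix) contains exactly the plotted series.
    """
    if mode not in {"full", "simplified"}:
        raise ValueError(f"mode must be 'full' or 'simplified', got {mode!r}")
    lo, hi = y_range
    if not lo < hi:
        raise ValueError(f"y_range must satisfy lo < hi, got {y_range}")
    path = Path(path)
    csv_path = Path(csv_path) if csv_path is not None else path.with_suffix(".csv")

    fig, ax = plt.subplots(figsize=(7, 5))
    ks = result.ks
    if mode == "full":
        for row in result.curves:
            ax.plot(ks, row, color="tab:blue", alpha=0.25, lw=0.8)
    else:
        ax.plot(ks, result.max_curve, color=_SUMMARY_STYLE["max"], lw=1.8, label="MAX")
        ax.plot(ks, result.median_curve, color=_SUMMARY_STYLE["median"], lw=1.8, label="MED")
        ax.plot(ks, result.min_curve, color=_SUMMARY_STYLE["min"], lw=1.8, label="MIN")
        ax.legend(loc="upper right", frameon=False)
    if annotate_onest:
        k_star = result.onest_value
        y_star = result.min_curve[k_star - 2]
        ax.vlines(k_star, lo, y_star, color="black", ls="--", lw=1.0)
        ax.annotate(f"ONEST = {k_star}", (k_star, lo), xytext=(4, 6),
                    textcoords="offset points", fontsize=9)
    if annotate_bandwidth:
        ax.annotate(
            "", (2, result.max_curve[0]), (2, result.min_curve[0]),
            arrowprops={"arrowstyle": "<->", "color": "black", "lw": 1.0},
        )
        ax.annotate(f"bandwidth = {result.bandwidth:.3f}",
                    (2, (result.max_curve[0] + result.min_curve[0]) / 2),
                    xytext=(6, 0), textcoords="offset points", fontsize=9)
    ax.set_xlabel("number of observers (k)")
    ax.set_ylabel("overall percent agreement")
    if len(ks) <= 25:
        ax.set_xticks(ks)
    ax.set_ylim(lo, hi)
    ax.set_title(f"ONEST ({result.curves.shape[0]} permutations"
                 f"{', exhaustive' if result.exhaustive else ''})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)

    _export_series(result, mode, csv_path)
    return path


def render_overlay_plot(
    results: Sequence[OnestResult],
    path: str | Path,
    labels: Sequence[str] | None = None,
    y_range: tuple[float, float] = (0.5, 1.0),
    csv_path: str | Path | None = None,
) -> Path:
    """Overlay the simplified summaries of several runs (3 series each).

    Mirrors the repeated-run comparison figure: every run contributes its
    min/median/max curves, and the exported CSV holds all of them.
    """
    if not results:
        raise ValueError("need at least one result to overlay")
    labels = list(labels) if labels is not None else [chr(ord("A") + i) for i in range(len(results))]
    path = Path(path)
    csv_path = Path(csv_path) if csv_path is not None else path.with_suffix(".csv")

    import pandas as pd

    fig, ax = plt.subplots(figsize=(7, 5))
    cmap = plt.get_cmap("tab10")
    frames = []
    for i, (res, label) in enumerate(zip(results, labels)):
        color = cmap(i % 10)
        for which, curve, ls in (
            ("max", res.max_curve, ":"),
            ("median", res.median_curve, "--"),
            ("min", res.min_curve, "-"),
        ):
            ax.plot(res.ks, curve, color=color, ls=ls,
                    label=f"{label} {which.upper()}" if which == "min" else None)
        summary = res.summary_frame().add_prefix(f"{label}_")
        frames.append(summary)
    ax.legend(loc="lower left", frameon=False, fontsize=8)
    ax.set_xlabel("number of observers (k)")
    ax.set_ylabel("overall percent agreement")
    ax.set_ylim(*y_range)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)

    pd.concat(frames, axis=1).to_csv(csv_path)
    return path
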