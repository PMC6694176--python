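"""EED plots: fitted CDF with bootstrap band, empirical points, benchmarks."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first
import matplotlib.pyplot as plt
import numpy as np

from .eed import CensoredSample, EEDFit, _dist, empirical_points


def plot_eed(
    fit: EEDFit,
    data: Sequence[CensoredSample],
    benchmarks: Mapping[str, float] | None = None,
    title: str = "",
    ax=None,
):
    """Draw one environmental exposure distribution.

    Quantified observations are filled dots at their Hazen plotting position;
    censored observations are horizontal interval marks spanning their
    censoring interval.  The fitted CDF is drawn with a pointwise 95%
    percentile band across the bootstrap replicates, and each benchmark is a
    vertical line labelled with its endpoint kind.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    pts = empirical_points(data)
    lo = min(pts["lo"][pts["lo"] > 0].min(), pts["midpoint"].min()) / 5
    hi = max(pts["hi"].max(), fit.dist.ppf(0.995)) * 5
    if benchmarks:
        hi = max(hi, max(benchmarks.values()) * 2)
        lo = min(lo, min(benchmarks.values()) / 2)
    grid = np.geomspace(max(lo, 1e-12), hi, 300)

    ax.plot(grid, fit.cdf(grid), color="black", lw=1.5, label=f"{fit.family} fit (MLE)")
    if fit.bootstrap_reps is not None and len(fit.bootstrap_reps) > 0:
        curves = np.array([_dist(fit.family, p).cdf(grid) for p in fit.bootstrap_reps])
        band = np.percentile(curves, [2.5, 97.5], axis=0)
        ax.fill_between(grid, band[0], band[1], color="grey", alpha=0.35,
                        label="95% bootstrap band")

    exact = pts[pts["kind"] == "exact"]
    cens = pts[pts["kind"] != "exact"]
    ax.plot(exact["midpoint"], exact["prob"], "ko", ms=4, label="quantified samples")
    for _, row in cens.iterrows():
        ax.hlines(row["prob"], max(row["lo"], lo), row["hi"],
                  color="grey", lw=1.0)
    if len(cens):
        ax.hlines([], [], [], color="grey", lw=1.0, label="censored samples")

    colors = ["tab:red", "tab:blue", "tab:green", "tab:purple"]
    for (label, bench), color in zip((benchmarks or {}).items(), colors):
        ax.axvline(bench, color=color, ls="--", lw=1.2, label=f"{label} benchmark")

    ax.set_xscale("log")
    ax.set_xlabel("concentration (ng a.i./g)")
    ax.set_ylabel("cumulative probability")
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8, loc="lower right")
    return ax
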