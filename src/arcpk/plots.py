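"""Static figures: Bland-Altman agreement and hematocrit time-course plots."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .agreement import AgreementResult

__all__ = ["bland_altman_plot", "hematocrit_plot"]


def bland_altman_plot(pairs, result: AgreementResult, title: str = "",
                      out: str | Path | None = None, ax=None):
    """Scatter of per-pair differences vs pair means with bias and 95 % LoA."""
    import matplotlib
    if out is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pairs = list(pairs)
    means = np.array([(a + b) / 2.0 for a, b in pairs])
    diffs = np.asarray(result.per_pair_diffs)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, color="k", s=24)
    ax.axhline(result.bias, ls="--", color="k", label=f"bias {result.bias:.2f}")
    for y, lab in ((result.loa_lower, "LLA"), (result.loa_upper, "ULA")):
        ax.axhline(y, ls=":", color="k")
        ax.annotate(f"{lab} {y:.2f}", (means.max(), y), fontsize=8,
                    ha="right", va="bottom")
    unit = "%" if result.mode == "percent" else ""
    ax.set_xlabel("Mean of measurements")
    ax.set_ylabel(f"Difference {unit}")
    ax.set_title(title)
    if out is not None:
        ax.figure.savefig(out, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def hematocrit_plot(dataset, out: str | Path | None = None, ax=None):
    """Group mean +- SD hematocrit vs time since fluid start."""
    import matplotlib
    if out is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for group, marker in (("control", "o"), ("treatment", "s")):
        by_time: dict[float, list[float]] = {}
        for aid in dataset.animal_ids(group):
            for t, v in dataset.animals[aid].hematocrit:
                by_time.setdefault(t, []).append(v)
        if not by_time:
            continue
        times = sorted(by_time)
        means = [float(np.mean(by_time[t])) for t in times]
        sds = [float(np.std(by_time[t], ddof=1)) if len(by_time[t]) > 1 else 0.0
               for t in times]
        ax.errorbar(times, means, yerr=sds, marker=marker, capsize=3, label=group)
    ax.set_xlabel("Time since fluid start (h)")
    ax.set_ylabel("Hematocrit (%)")
    ax.legend()
    if out is not None:
        ax.figure.savefig(out, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
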