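"""Per-mouse aggregation and cohort-level reporting statistics.

Several SHG fields are imaged per mouse; image summaries are averaged
per animal (equal weights) before any group test, so the animal — not
the image — is the statistical unit.  Group comparisons use Welch's
unequal-variance two-sided t-test; associations with tumor burden use
the two-sided Pearson correlation.  Suspect values (e.g. one animal's
11,000 µm² mean crypt size against a group of hundreds) are *flagged*
by an iterative Grubbs test; exclusion is always an explicit user
action, never silent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from cryptscape.spatial import ImageSummary

#: metrics carried from ImageSummary into per-mouse means
AGGREGATED_METRICS = (
    "interior_count",
    "mean_area_um2",
    "mean_nn_distance_um",
    "mean_neighbor_count",
)


@dataclass
class MouseSummary:
    """One animal: image summaries and their unweighted means."""

    mouse_id: str
    genotype: str = ""
    timepoint: str = ""
    image_summaries: list[ImageSummary] = field(default_factory=list)
    tumor_burden: float | None = None
    means: dict[str, float] = field(default_factory=dict)
    n_defined: dict[str, int] = field(default_factory=dict)


def aggregate_per_mouse(
    image_summaries: list[ImageSummary],
    mouse_id: str,
    genotype: str = "",
    timepoint: str = "",
    tumor_burden: float | None = None,
) -> MouseSummary:
    """Unweighted per-metric mean over a mouse's images.

    Images where a metric is undefined (NaN — e.g. no interior crypt
    had a nearest neighbor) are excluded from that metric's mean; the
    count of contributing images is reported alongside.
    """
    if not image_summaries:
        raise ValueError("need >= 1 image summary per mouse")
    means: dict[str, float] = {}
    n_defined: dict[str, int] = {}
    for metric in AGGREGATED_METRICS:
        vals = [
            float(getattr(s, metric))
            for s in image_summaries
            if np.isfinite(getattr(s, metric))
        ]
        n_defined[metric] = len(vals)
        means[metric] = float(np.mean(vals)) if vals else float("nan")
    return MouseSummary(
        mouse_id=mouse_id,
        genotype=genotype,
        timepoint=timepoint,
        image_summaries=list(image_summaries),
        tumor_burden=tumor_burden,
        means=means,
        n_defined=n_defined,
    )


@dataclass
class GroupComparison:
    """A two-group comparison reported as mean ± SEM plus the test."""

    metric: str
    group_names: tuple[str, str]
    means: tuple[float, float]
    sems: tuple[float, float]
    statistic: float
    p_value: float
    df: float
    degenerate: bool = False


def _sem(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / math.sqrt(len(x)))


def welch_t(
    group1: np.ndarray,
    group2: np.ndarray,
    metric: str = "",
    group_names: tuple[str, str] = ("group1", "group2"),
) -> GroupComparison:
    """Welch's unequal-variance two-sided t with Welch–Satterthwaite df."""
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        equal = x.mean() == y.mean()
        return GroupComparison(
            metric=metric,
            group_names=group_names,
            means=(float(x.mean()), float(y.mean())),
            sems=(0.0, 0.0),
            statistic=0.0 if equal else math.inf,
            p_value=1.0 if equal else 0.0,
            df=float(len(x) + len(y) - 2),
            degenerate=True,
        )
    res = stats.ttest_ind(x, y, equal_var=False)
    sx, sy = vx / len(x), vy / len(y)
    df = (sx + sy) ** 2 / (
        sx**2 / (len(x) - 1) + sy**2 / (len(y) - 1)
    )
    return GroupComparison(
        metric=metric,
        group_names=group_names,
        means=(float(x.mean()), float(y.mean())),
        sems=(_sem(x), _sem(y)),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(df),
    )


def pearson_with_burden(
    metric_values: np.ndarray, tumor_burden: np.ndarray
) -> tuple[float, float]:
    """Sample Pearson r and two-sided p (via the t transform)."""
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(tumor_burden, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if len(x) < 3:
        raise ValueError("correlation needs n >= 3")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _grubbs_critical(n: int, alpha: float) -> float:
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))


def flag_outliers(values: np.ndarray, alpha: float = 0.05) -> list[int]:
    """Iterative two-sided Grubbs test; returns indices, flags only.

    Each round tests the most extreme remaining value against the
    Grubbs critical value at ``alpha`` and stops at the first
    non-significant candidate (or when fewer than 3 values remain).
    Flagged values are never removed here — exclusion is an explicit,
    recorded user decision.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("outlier test needs n >= 3")
    remaining = list(range(len(x)))
    flagged: list[int] = []
    while len(remaining) >= 3:
        sub = x[remaining]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        i_max = int(dev.argmax())
        g = dev[i_max] / sd
        if g <= _grubbs_critical(len(sub), alpha):
            break
        flagged.append(remaining.pop(i_max))
    return flagged
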