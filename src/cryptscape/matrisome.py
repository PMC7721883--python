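"""Matrisome set-overlap analysis of protein lists.

The matrisome is the ensemble of ECM and ECM-associated proteins (core
matrisome: collagens, ECM glycoproteins, proteoglycans; associated:
regulators, secreted factors, ECM-affiliated).  This module compares
detected or differentially expressed protein lists against reference
matrisome lists by exact set algebra on normalized gene symbols, applies
the differential-expression cutoffs (fold change > 1.5 in either
direction, step-up FDR <= 0.1), and provides the simple per-protein
tests: two-way ANOVA with Benjamini–Hochberg step-up adjustment for the
two-factor design, an unpaired two-sided t-test for single-factor
designs, and the paired two-sided t-test for matched abundances.

Symbol matching is case-insensitive string equality after uppercasing;
no ortholog mapping is attempted for cross-species comparisons, and
non-matching symbols remain listed in the difference sets for audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MATRISOME_DIVISIONS = ("core", "associated")
MATRISOME_CATEGORIES = (
    "collagens",
    "ECM glycoproteins",
    "proteoglycans",
    "ECM regulators",
    "secreted factors",
    "ECM-affiliated",
)


@dataclass
class ProteinList:
    """A named, normalized (uppercased, deduplicated) gene-symbol set."""

    name: str
    symbols: frozenset[str]
    annotations: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(not s for s in self.symbols):
            raise ValueError("empty symbols are not allowed")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class OverlapResult:
    """Venn-style overlap between two protein lists."""

    name_a: str
    name_b: str
    only_a: frozenset[str]
    only_b: frozenset[str]
    intersection: frozenset[str]

    @property
    def n_a(self) -> int:
        return len(self.only_a) + len(self.intersection)

    @property
    def n_b(self) -> int:
        return len(self.only_b) + len(self.intersection)

    @property
    def n_intersection(self) -> int:
        return len(self.intersection)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"symbol": s, "membership": m}
            for part, m in [
                (self.intersection, "both"),
                (self.only_a, f"only_{self.name_a}"),
                (self.only_b, f"only_{self.name_b}"),
            ]
            for s in sorted(part)
        ]
        return pd.DataFrame(rows, columns=["symbol", "membership"])


def normalize_symbols(raw: "pd.Series | list[str]") -> list[str]:
    """Uppercase, strip, drop empties; preserves order, keeps duplicates."""
    out = []
    for s in raw:
        if pd.isna(s):
            continue
        s = str(s).strip().upper()
        if s:
            out.append(s)
    return out


def load_protein_list(
    path: str | Path, symbol_column: str, name: str | None = None
) -> ProteinList:
    """Read a CSV/TSV protein table into a normalized symbol set.

    The separator is inferred from the extension (``.tsv``/``.txt`` →
    tab).  Duplicates after normalization are dropped and counted in
    the log; an empty result is an error.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    table = pd.read_csv(path, sep=sep)
    if symbol_column not in table.columns:
        raise ValueError(
            f"{path}: no column {symbol_column!r}; has {list(table.columns)}"
        )
    symbols = normalize_symbols(table[symbol_column])
    unique = frozenset(symbols)
    n_dropped = len(symbols) - len(unique)
    if n_dropped:
        logger.info(
            "%s: dropped %d duplicate symbol(s) after normalization",
            path.name,
            n_dropped,
        )
    if not unique:
        raise ValueError(f"{path}: no usable symbols in {symbol_column!r}")
    return ProteinList(name=name or path.stem, symbols=unique)


def intersect_counts(a: ProteinList, b: ProteinList) -> OverlapResult:
    """Exact set algebra between two normalized symbol sets."""
    inter = a.symbols & b.symbols
    return OverlapResult(
        name_a=a.name,
        name_b=b.name,
        only_a=frozenset(a.symbols - b.symbols),
        only_b=frozenset(b.symbols - a.symbols),
        intersection=frozenset(inter),
    )


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def de_filter(
    de_table: pd.DataFrame,
    fc_cutoff: float = 1.5,
    fdr_cutoff: float = 0.1,
    symbol_column: str = "symbol",
    fc_column: str = "fold_change",
    fdr_column: str = "fdr",
    name: str = "differential",
) -> ProteinList:
    """Keep proteins changing > ``fc_cutoff``-fold (either direction)
    at step-up FDR <= ``fdr_cutoff``.

    Fold changes are ratios (> 0); a ratio r passes when
    ``max(r, 1/r) > fc_cutoff``, so 2.0 and 0.5 are treated alike.
    The FDR bound is inclusive, the fold-change bound exclusive.
    """
    for col in (symbol_column, fc_column, fdr_column):
        if col not in de_table.columns:
            raise ValueError(f"DE table lacks column {col!r}")
    fc = de_table[fc_column].astype(float)
    if (fc <= 0).any():
        raise ValueError("fold changes must be positive ratios")
    fdr = de_table[fdr_column].astype(float)
    keep = (np.maximum(fc, 1.0 / fc) > fc_cutoff) & (fdr <= fdr_cutoff)
    symbols = frozenset(normalize_symbols(de_table.loc[keep, symbol_column]))
    return ProteinList(name=name, symbols=symbols)


def step_up_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment (NaNs pass through)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    valid = np.isfinite(p)
    if valid.any():
        out[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return out


def two_way_anova_stepup(
    values: pd.DataFrame,
    factor_a: "pd.Series | list",
    factor_b: "pd.Series | list",
) -> pd.DataFrame:
    """Per-protein two-way ANOVA with step-up FDR across proteins.

    ``values`` is proteins x samples; ``factor_a`` is the factor of
    interest (e.g. genotype), ``factor_b`` the second factor (e.g.
    timepoint).  Each protein's p-value is the type-II main effect of
    ``factor_a``.  When ``factor_b`` has a single level the design
    degenerates and the unpaired two-sided Student's t-test on
    ``factor_a`` is used instead.  Proteins with zero variance in
    every cell are flagged and get an undefined p-value.
    """
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if a.shape[0] != values.shape[1] or b.shape[0] != values.shape[1]:
        raise ValueError("factor length must match the number of samples")
    if len(np.unique(a)) < 2:
        raise ValueError("factor_a must have at least two levels")
    single_factor = len(np.unique(b)) < 2
    cells = pd.Series(zip(a, b))
    p_values = np.full(values.shape[0], np.nan)
    degenerate = np.zeros(values.shape[0], dtype=bool)
    for i in range(values.shape[0]):
        y = values.iloc[i].to_numpy(dtype=float)
        within_var = sum(
            np.var(y[cells == cell]) for cell in cells.unique()
        )
        if within_var == 0:
            degenerate[i] = True
            continue
        if single_factor:
            groups = np.unique(a)
            res = stats.ttest_ind(y[a == groups[0]], y[a == groups[1]])
            p_values[i] = res.pvalue
        else:
            frame = pd.DataFrame({"y": y, "a": a, "b": b})
            fit = ols("y ~ C(a) * C(b)", data=frame).fit()
            table = anova_lm(fit, typ=2)
            p_values[i] = table.loc["C(a)", "PR(>F)"]
    return pd.DataFrame(
        {
            "protein": values.index,
            "p_value": p_values,
            "fdr": step_up_adjust(p_values),
            "degenerate": degenerate,
        }
    ).set_index("protein")


@dataclass
class PairedTestResult:
    t: float
    p: float
    n: int
    mean_difference: float
    degenerate: bool = False


def paired_abundance_test(
    values_a: np.ndarray, values_b: np.ndarray
) -> PairedTestResult:
    """Classical paired two-sided t-test on matched abundance vectors.

    All-zero differences give t = 0, p = 1; nonzero constant
    differences (zero variance) are flagged degenerate.
    """
    x = np.asarray(values_a, dtype=float)
    y = np.asarray(values_b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    n = x.shape[0]
    if n < 2:
        raise ValueError("paired test needs n >= 2")
    diff = y - x
    mean_diff = float(diff.mean())
    if diff.std(ddof=1) == 0:
        if mean_diff == 0:
            return PairedTestResult(t=0.0, p=1.0, n=n, mean_difference=0.0)
        return PairedTestResult(
            t=float(np.inf) if mean_diff > 0 else float(-np.inf),
            p=0.0,
            n=n,
            mean_difference=mean_diff,
            degenerate=True,
        )
    res = stats.ttest_rel(y, x)
    return PairedTestResult(
        t=float(res.statistic), p=float(res.pvalue), n=n, mean_difference=mean_diff
    )
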