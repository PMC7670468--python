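"""Feature-repeatability filtering by intraclass correlation.

Intra-observer agreement uses ICC(3,1) (two-way mixed, consistency not
required — see below), inter-observer agreement uses ICC(2,1) (two-way
random, absolute agreement, single rater), both from the classical
mean-square decomposition of the cases x raters table. A feature is kept
when BOTH ICCs exceed the threshold (default 0.75, the usual "good
agreement" cut).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["ICCReport", "icc", "filter_repeatable", "bh_adjust"]


def icc(ratings: np.ndarray, kind: str = "icc2") -> float:
    """Single-rater ICC from a cases x raters matrix.

    kind="icc2": two-way random effects, absolute agreement — ICC(2,1).
    kind="icc3": two-way mixed effects, consistency — ICC(3,1).

    A table whose rater columns are all identical has perfect agreement by
    definition (ICC = 1) even when the case variance is zero; zero total
    variance with unequal columns is an error.
    """
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a cases x raters matrix with >=2 cases and >=2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings must be finite")
    n, k = x.shape
    if np.all(x == x[:, [0]]):
        return 1.0
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("zero total variance with non-identical raters")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    if kind == "icc2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif kind == "icc3":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC kind {kind!r}")
    if denom == 0:
        return 1.0
    return float((msr - mse) / denom)


@dataclass
class ICCReport:
    """Per-feature ICC values and the kept/dropped verdict."""

    table: pd.DataFrame  # columns: icc_intra, icc_inter, kept
    threshold: float

    @property
    def kept_ids(self) -> list[str]:
        return list(self.table.index[self.table["kept"]])


def filter_repeatable(
    fv_rater1: pd.DataFrame,
    fv_rater1_repeat: pd.DataFrame,
    fv_rater2: pd.DataFrame,
    threshold: float = 0.75,
) -> ICCReport:
    """Keep features whose intra- AND inter-observer ICC exceed threshold.

    Inputs are aligned cases x features tables from the original
    delineation, its repeat by the same rater, and a second rater.
    Features whose ICC is undefined (non-finite values or degenerate
    variance with disagreeing raters) are dropped and reported as NaN.
    """
    for other in (fv_rater1_repeat, fv_rater2):
        if not fv_rater1.index.equals(other.index) or not fv_rater1.columns.equals(other.columns):
            raise ValueError("rating tables must share identical case and feature indexes")
    rows = {}
    for feat in fv_rater1.columns:
        a = fv_rater1[feat].to_numpy()
        rows[feat] = {
            "icc_intra": _safe_icc(np.column_stack([a, fv_rater1_repeat[feat]]), "icc3"),
            "icc_inter": _safe_icc(np.column_stack([a, fv_rater2[feat]]), "icc2"),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table["kept"] = (table["icc_intra"] > threshold) & (table["icc_inter"] > threshold)
    table["kept"] = table["kept"].fillna(False)
    return ICCReport(table, threshold)


def _safe_icc(ratings: np.ndarray, kind: str) -> float:
    try:
        return icc(ratings, kind)
    except ValueError:
        return float("nan")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, in [0,1])."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
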