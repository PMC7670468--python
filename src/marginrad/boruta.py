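"""Boruta all-relevant feature selection.

Each iteration appends a shuffled "shadow" copy of every surviving
feature, fits a random forest on the augmented design, and scores a hit
for every real feature whose importance exceeds the maximum shadow
importance. Features are confirmed or rejected by two-sided binomial
tests on their hit counts (chance level 1/2), with Benjamini–Hochberg FDR
correction across the still-undecided features; whatever is undecided
after ``n_iter`` iterations stays tentative. Confirmed features keep
competing (all-relevant semantics: duplicated informative features are
both confirmed), rejected features are removed from subsequent forests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .reliability import bh_adjust

__all__ = ["BorutaConfig", "BorutaResult", "boruta_select"]


@dataclass
class BorutaConfig:
    n_iter: int = 100
    alpha: float = 0.01
    #: "impurity" (Gini, fast) or "permutation"
    importance: str = "impurity"
    n_estimators: int = 100
    max_depth: int | None = 5
    seed: int = 0
    #: tests start once a feature could possibly reach significance
    min_iterations: int = 5


@dataclass
class BorutaResult:
    """Per-feature status plus the importance history."""

    status: pd.Series  # values in {"confirmed", "tentative", "rejected"}
    hits: pd.Series
    n_iterations: int
    importance_history: pd.DataFrame = field(repr=False, default=None)

    @property
    def confirmed(self) -> list[str]:
        return list(self.status.index[self.status == "confirmed"])

    @property
    def rejected(self) -> list[str]:
        return list(self.status.index[self.status == "rejected"])

    @property
    def tentative(self) -> list[str]:
        return list(self.status.index[self.status == "tentative"])


def _importances(X: np.ndarray, y: np.ndarray, cfg: BorutaConfig, rng: np.random.Generator) -> np.ndarray:
    rf = RandomForestClassifier(
        n_estimators=cfg.n_estimators,
        max_features="sqrt",
        max_depth=cfg.max_depth,
        random_state=int(rng.integers(2**31 - 1)),
        n_jobs=1,
    )
    rf.fit(X, y)
    if cfg.importance == "impurity":
        return rf.feature_importances_
    if cfg.importance == "permutation":
        res = permutation_importance(
            rf, X, y, n_repeats=3, random_state=int(rng.integers(2**31 - 1)), n_jobs=1
        )
        return res.importances_mean
    raise ValueError(f"unknown importance {cfg.importance!r}")


def boruta_select(X: pd.DataFrame, y, config: BorutaConfig | None = None) -> BorutaResult:
    """Run Boruta on a cases x features table against binary labels."""
    cfg = config or BorutaConfig()
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=np.float64)
    else:
        Xv = np.asarray(X, dtype=np.float64)
        names = [f"f{i}" for i in range(Xv.shape[1])]
    yv = np.asarray(y)
    if np.unique(yv).size < 2:
        raise ValueError("labels must contain at least two classes")
    if not np.all(np.isfinite(Xv)):
        raise ValueError("feature matrix contains missing or non-finite values")

    rng = np.random.default_rng(cfg.seed)
    n, p = Xv.shape
    status = np.array(["tentative"] * p, dtype=object)
    hits = np.zeros(p, dtype=int)
    trials = np.zeros(p, dtype=int)
    history = []

    it = 0
    for it in range(1, cfg.n_iter + 1):
        active = status != "rejected"
        if not active.any():
            break
        Xa = Xv[:, active]
        # shadows of ALL original features, reshuffled every iteration: the
        # max-shadow bar must not collapse as rejected features drop out of
        # the forest, or surviving spurious features get confirmed on null
        # data
        shadows = Xv.copy()
        for j in range(shadows.shape[1]):
            rng.shuffle(shadows[:, j])
        imp = _importances(np.hstack([Xa, shadows]), yv, cfg, rng)
        real_imp = imp[: Xa.shape[1]]
        shadow_max = imp[Xa.shape[1]:].max()
        hit_now = real_imp > shadow_max
        hits[active] += hit_now
        trials[active] += 1
        row = np.full(p, np.nan)
        row[active] = real_imp
        history.append(row)

        if it >= cfg.min_iterations:
            undecided = status == "tentative"
            if undecided.any():
                h = hits[undecided]
                t = trials[undecided]
                p_conf = stats.binom.sf(h - 1, t, 0.5)   # P(X >= h): evidence for relevance
                p_rej = stats.binom.cdf(h, t, 0.5)       # P(X <= h): evidence for irrelevance
                conf = bh_adjust(p_conf) < cfg.alpha
                rej = bh_adjust(p_rej) < cfg.alpha
                ids = np.flatnonzero(undecided)
                status[ids[conf & ~rej]] = "confirmed"
                status[ids[rej & ~conf]] = "rejected"
            if not (status == "tentative").any():
                break

    return BorutaResult(
        status=pd.Series(status, index=names),
        hits=pd.Series(hits, index=names),
        n_iterations=it,
        importance_history=pd.DataFrame(history, columns=names),
    )
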