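"""Sense-of-direction scoring and the sex-adjusted partial correlation.

The behavioral stage sums 16 five-point Likert items (reverse-keyed items
mapped v -> 6 - v) into a sense-of-direction score and correlates it with
a single nine-point circadian-regularity rating, partialling out sex by
least-squares residualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BehaviorTable",
    "PartialCorrelationResult",
    "score_sbsod",
    "partial_correlation",
    "DEFAULT_REVERSE_ITEMS",
]

#: 1-based positions of reverse-keyed items in the standard 16-item scale.
DEFAULT_REVERSE_ITEMS: tuple[int, ...] = (1, 3, 4, 5, 7, 9, 14)

ITEM_COLS = [f"item{j:02d}" for j in range(1, 17)]


class BehaviorTable:
    """Validated wrapper around the behavioral DataFrame.

    Columns: participant_id, sex in {F, M}, item01..item16 in 1..5,
    circadian in 1..9.
    """

    def __init__(self, df: pd.DataFrame):
        required = ["participant_id", "sex", *ITEM_COLS, "circadian"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"behavior table missing columns: {missing}")
        if df["participant_id"].duplicated().any():
            raise ValueError("duplicate participant_id")
        if not df["sex"].isin(["F", "M"]).all():
            raise ValueError("sex must be 'F' or 'M'")
        items = df[ITEM_COLS].to_numpy(int)
        if items.min() < 1 or items.max() > 5:
            raise ValueError("item responses must lie in 1..5")
        circ = df["circadian"].to_numpy(int)
        if circ.min() < 1 or circ.max() > 9:
            raise ValueError("circadian ratings must lie in 1..9")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_female(self) -> int:
        return int((self.df["sex"] == "F").sum())

    def sbsod_scores(self, reverse_items=DEFAULT_REVERSE_ITEMS) -> np.ndarray:
        items = self.df[ITEM_COLS].to_numpy(int)
        return np.array(
            [score_sbsod(row, reverse_items) for row in items], dtype=int
        )

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BehaviorTable":
        return cls(pd.read_csv(path, dtype={"participant_id": str, "sex": str}))


def score_sbsod(items, reverse_items=DEFAULT_REVERSE_ITEMS) -> int:
    """Sum score over 16 Likert items, reverse-keying the given positions.

    Reverse-keyed items are mapped v -> 6 - v before summing, so a higher
    total always means a better reported sense of direction; the score
    ranges over [16, 80].
    """
    vals = np.asarray(items, dtype=int).ravel()
    if vals.size != 16:
        raise ValueError(f"expected 16 items, got {vals.size}")
    if vals.min() < 1 or vals.max() > 5:
        raise ValueError(f"item response out of 1..5: {vals.tolist()}")
    rev = set(int(i) for i in reverse_items)
    if rev and (min(rev) < 1 or max(rev) > 16):
        raise ValueError("reverse item positions must be 1-based in 1..16")
    total = 0
    for pos, v in enumerate(vals, start=1):
        total += (6 - v) if pos in rev else v
    return int(total)


@dataclass(frozen=True)
class PartialCorrelationResult:
    r_partial: float
    p_two_tailed: float
    n: int
    df: int  # n - n_covariates - 2
    covariates: tuple = ()


def partial_correlation(
    x, y, covariates=None, covariate_names: tuple = ()
) -> PartialCorrelationResult:
    """Pearson correlation of x and y after residualizing on covariates.

    Both variables are regressed (with intercept) on the covariate columns;
    the partial r is the Pearson correlation of the residuals, with the
    two-tailed p from t = r sqrt(df) / sqrt(1 - r^2), df = n - k - 2 for k
    covariates.  With no covariates this reduces to the plain Pearson r.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariate rows must match n")
    k = cov.shape[1]
    if n <= k + 2:
        raise ValueError("need n > n_covariates + 2")
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix (with intercept)")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    sx, sy = rx.std(ddof=1), ry.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero residual variance")
    r = float(np.dot(rx - rx.mean(), ry - ry.mean()) / ((n - 1) * sx * sy))
    r = min(max(r, -1.0), 1.0)
    dof = n - k - 2
    if abs(r) >= 1.0:
        p = np.nextafter(0.0, 1.0)
    else:
        t = r * np.sqrt(dof) / np.sqrt(1.0 - r * r)
        p = float(2.0 * stats.t.sf(abs(t), dof))
    return PartialCorrelationResult(
        r_partial=r,
        p_two_tailed=p,
        n=n,
        df=dof,
        covariates=tuple(covariate_names) or tuple(f"c{i}" for i in range(k)),
    )
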