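"""Per-donor expression-activation correlation and random-effects pooling.

The core statistic of the pipeline: within each donor, the activation
likelihood at the donor's sampling sites is regressed on the donor's
standardized gene expression (slope = Pearson r on standardized data);
the donor-level slopes are then pooled with a one-sample t-test — the
"approximate random-effects" analysis that lets the correlation generalize
beyond the sampled donors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .expression import GeneExpressionVector, standardize
from .meta_map import ActivationMap

__all__ = [
    "DonorCorrelation",
    "RandomEffectsResult",
    "sample_map_at_sites",
    "donor_correlation",
    "random_effects_test",
    "count_repetitions",
]


@dataclass(frozen=True)
class DonorCorrelation:
    donor_id: str
    n_sites: int
    slope: float  # OLS slope on standardized variables (= pearson_r)
    pearson_r: float
    p_two_tailed: float


@dataclass(frozen=True)
class RandomEffectsResult:
    n_donors: int
    mean_slope: float
    sd_slope: float
    t_stat: float
    df: int
    p_two_tailed: float


def sample_map_at_sites(
    amap: ActivationMap, sites_mm: np.ndarray, site_ids=None
) -> np.ndarray:
    """Nearest-voxel map values at MNI mm sites.

    Sites are snapped to the nearest voxel center through the inverse
    affine; sites outside the grid bounding box raise, naming the
    offenders.
    """
    sites = np.atleast_2d(np.asarray(sites_mm, dtype=float))
    inside = amap.grid.contains(sites)
    if not np.all(inside):
        bad = np.flatnonzero(~inside)
        names = (
            [site_ids[i] for i in bad] if site_ids is not None else bad.tolist()
        )
        raise ValueError(f"sites outside grid bounding box: {names[:10]}")
    return amap.values.ravel()[amap.grid.flat_index(sites)]


def _pearson_t_p(r: float, n: int) -> float:
    """Two-tailed p of Pearson r from the t distribution with n-2 df."""
    r = min(max(r, -1.0), 1.0)
    if abs(r) >= 1.0:
        return np.nextafter(0.0, 1.0)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def donor_correlation(
    expr: GeneExpressionVector | np.ndarray,
    map_values: np.ndarray,
    donor_id: str | None = None,
) -> DonorCorrelation:
    """Correlate one donor's gene expression with map values at its sites.

    Both vectors are standardized, so the OLS slope equals the Pearson r;
    p is two-tailed from the t distribution with n-2 df.
    """
    if isinstance(expr, GeneExpressionVector):
        donor_id = donor_id if donor_id is not None else expr.donor_id
        x = expr.values
    else:
        x = np.asarray(expr, dtype=float).ravel()
        donor_id = donor_id if donor_id is not None else "?"
    y = np.asarray(map_values, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} expression vs {y.size} map values")
    if x.size < 4:
        raise ValueError("donor correlation needs at least 4 sites")
    xs, ys = standardize(x), standardize(y)  # raises on zero variance
    n = x.size
    r = float(np.dot(xs, ys) / (n - 1))
    return DonorCorrelation(
        donor_id=donor_id,
        n_sites=n,
        slope=r,
        pearson_r=r,
        p_two_tailed=_pearson_t_p(r, n),
    )


def random_effects_test(fits: list[DonorCorrelation]) -> RandomEffectsResult:
    """One-sample t-test of the per-donor slopes against zero."""
    slopes = np.array([f.slope for f in fits], dtype=float)
    return _one_sample_t(slopes)


def _one_sample_t(values: np.ndarray) -> RandomEffectsResult:
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("random-effects test needs >= 2 donors")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate slopes: zero variance across donors")
    mean = values.mean()
    t = mean / (sd / np.sqrt(n))
    return RandomEffectsResult(
        n_donors=n,
        mean_slope=float(mean),
        sd_slope=float(sd),
        t_stat=float(t),
        df=n - 1,
        p_two_tailed=float(2.0 * stats.t.sf(abs(t), n - 1)),
    )


def count_repetitions(
    fits: list[DonorCorrelation], alpha: float = 0.05, sign: int | None = None
) -> int:
    """Number of donors individually significant at ``alpha`` (two-tailed).

    ``sign=+1``/``-1`` restricts the count to slopes of that sign;
    the default is sign-agnostic, matching the uncorrected two-tailed
    repetition statistic used against the resampling null.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    hits = 0
    for f in fits:
        if f.p_two_tailed < alpha and (sign is None or np.sign(f.slope) == sign):
            hits += 1
    return hits
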