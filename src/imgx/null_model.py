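"""Study-resampling null for inter-donor repeatability.

How surprising is it that all (or most) donors individually show a
significant expression-activation correlation?  The null redraws, B times,
a random set of studies of the same size as the target-term set from the
rest of the database (excluding the term's own studies), rebuilds the
activation map, recomputes every donor's correlation, and counts how many
donors are individually significant.  The empirical p of the observed
repetition count is the fraction of resamples reaching a count at least
as large.

Because each donor's correlation depends on the map only through its
values at that donor's sampling sites, the resampled maps are evaluated
directly at the site voxels (see
:func:`imgx.meta_map.study_site_activation_matrix`), which is exactly
equivalent to building the full map and sampling it, and orders of
magnitude faster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .expression import ExpressionAtlas, average_probes, standardize
from .meta_map import (
    StudyDatabase,
    StudyRecord,
    VoxelGrid,
    build_activation_map,
    select_studies,
    study_site_activation_matrix,
)
from .similarity import (
    count_repetitions,
    donor_correlation,
    sample_map_at_sites,
)

__all__ = ["RepeatabilityNull", "resample_study_set", "repeatability_test"]


@dataclass
class RepeatabilityNull:
    B: int
    n_studies_resampled: int
    alpha: float
    null_counts: np.ndarray  # B integers in [0, n_donors]
    observed_count: int
    empirical_p: float
    estimator: str = "plain"  # or "add-one"
    n_donors: int = 0
    failures: list = field(default_factory=list)  # (iteration, donor_id) pairs

    def summary(self) -> dict:
        counts = np.asarray(self.null_counts)
        return {
            "B": self.B,
            "n_studies_resampled": self.n_studies_resampled,
            "alpha": self.alpha,
            "observed_count": self.observed_count,
            "empirical_p": self.empirical_p,
            "estimator": self.estimator,
            "null_mean": float(counts.mean()),
            "null_sd": float(counts.std(ddof=1)) if self.B > 1 else 0.0,
            "n_failures": len(self.failures),
        }


def _exclusion_pool(db: StudyDatabase, term_expr) -> tuple[list[StudyRecord], int]:
    term_studies = select_studies(db, term_expr)
    term_ids = {s.study_id for s in term_studies}
    pool = [s for s in db.studies if s.study_id not in term_ids]
    if len(pool) < len(term_studies):
        raise ValueError(
            f"insufficient non-term studies: pool {len(pool)} < "
            f"term count {len(term_studies)}"
        )
    return pool, len(term_studies)


def resample_study_set(
    db: StudyDatabase, term_expr, rng: np.random.Generator
) -> list[StudyRecord]:
    """Uniform sample, without replacement, of non-term studies.

    The sample has the same size as the term's study set and is drawn only
    from studies *not* carrying the term (exclusion by study identity).
    """
    pool, n_term = _exclusion_pool(db, term_expr)
    idx = rng.choice(len(pool), size=n_term, replace=False)
    return [pool[i] for i in idx]


def _fast_pearson_p(z_x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-tailed p given a pre-standardized x."""
    n = y.size
    sy = y.std(ddof=1)
    if sy == 0:
        raise ValueError("zero variance")
    r = float(np.dot(z_x, (y - y.mean()) / sy) / (n - 1))
    r = min(max(r, -1.0), 1.0)
    if abs(r) >= 1.0:
        return r, float(np.nextafter(0.0, 1.0))
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), n - 2))


def repeatability_test(
    db: StudyDatabase,
    term_expr,
    gene: str,
    atlases: list[ExpressionAtlas],
    grid: VoxelGrid | None = None,
    radius: float = 10.0,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    estimator: str = "plain",
    max_failure_frac: float = 0.01,
) -> RepeatabilityNull:
    """Empirical p of the observed inter-donor repetition count.

    Per-iteration RNG streams are spawned from ``seed``, so results are
    reproducible and independent of iteration order.  Donor-level failures
    (e.g. a resampled map constant at a donor's sites) are recorded, not
    silently dropped; more than ``max_failure_frac`` failed donor
    evaluations aborts the run.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    grid = grid if grid is not None else VoxelGrid.mni()
    term_studies = select_studies(db, term_expr)
    if not term_studies:
        raise ValueError(f"no studies for term {term_expr!r}")
    term_name = term_expr if isinstance(term_expr, str) else " ".join(term_expr)
    term_map = build_activation_map(term_studies, grid, radius, term=term_name)

    gene_z = []
    observed_fits = []
    site_flat = []
    for a in atlases:
        vec = average_probes(a, gene)
        gene_z.append(standardize(vec.values))
        site_flat.append(grid.flat_index(a.site_coords))
        observed_fits.append(
            donor_correlation(
                vec, sample_map_at_sites(term_map, a.site_coords, a.site_ids)
            )
        )
    observed = count_repetitions(observed_fits, alpha)

    pool, n_term = _exclusion_pool(db, term_expr)
    all_flat = np.concatenate(site_flat)
    uniq, inv = np.unique(all_flat, return_inverse=True)
    donor_cols = []
    start = 0
    for f in site_flat:
        donor_cols.append(inv[start : start + len(f)])
        start += len(f)
    M = study_site_activation_matrix(pool, grid, radius, uniq).astype(np.float64)

    counts = np.zeros(B, dtype=int)
    failures: list[tuple[int, str]] = []
    children = np.random.SeedSequence(seed).spawn(B)
    for b, child in enumerate(children):
        rng = np.random.default_rng(child)
        idx = rng.choice(len(pool), size=n_term, replace=False)
        vals_u = M[idx].mean(axis=0)
        c = 0
        for d, a in enumerate(atlases):
            y = vals_u[donor_cols[d]]
            try:
                _, p = _fast_pearson_p(gene_z[d], y)
            except ValueError:
                failures.append((b, a.donor_id))
                continue
            if p < alpha:
                c += 1
        counts[b] = c
    if len(failures) > max_failure_frac * B * len(atlases):
        raise RuntimeError(
            f"{len(failures)} failed donor evaluations out of "
            f"{B * len(atlases)} exceed the {max_failure_frac:.0%} budget"
        )

    n_extreme = int(np.sum(counts >= observed))
    if estimator == "plain":
        emp_p = n_extreme / B
    elif estimator == "add-one":
        emp_p = (1 + n_extreme) / (B + 1)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return RepeatabilityNull(
        B=B,
        n_studies_resampled=n_term,
        alpha=alpha,
        null_counts=counts,
        observed_count=observed,
        empirical_p=float(emp_p),
        estimator=estimator,
        n_donors=len(atlases),
        failures=failures,
    )
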