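"""Gene-set and cognitive-domain screens over the similarity pipeline.

Runs the per-donor correlation + random-effects chain over a list of genes
against one term map (with Benjamini-Hochberg FDR across the gene set and
a repetition-count robustness label), or over one gene against a battery
of cognitive-domain terms (nine domains x three sub-domains by default,
reported uncorrected as an exploratory profile).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionAtlas, average_probes
from .meta_map import StudyDatabase, VoxelGrid, build_activation_map, select_studies
from .similarity import (
    DonorCorrelation,
    RandomEffectsResult,
    count_repetitions,
    donor_correlation,
    random_effects_test,
    sample_map_at_sites,
)

__all__ = [
    "ScreenConfig",
    "GeneScreenResult",
    "DomainProfile",
    "screen_genes",
    "bh_fdr",
    "classify_robustness",
    "domain_profile",
    "DEFAULT_DOMAINS",
]

#: Default cognitive-domain battery: nine broad domains, three sub-domain
#: term expressions each, mixing spatial and non-spatial processes.  An
#: entry is a single term label or a two-label conjunction.
DEFAULT_DOMAINS: dict[str, list] = {
    "perception": ["object perception", "scene perception", "face perception"],
    "memory": ["spatial memory", "semantic memory", "episodic memory"],
    "social cognition": ["self-referential", "social interaction", "empathy"],
    "intelligence": ["reasoning", "decision making", "problem solving"],
    "language": ["speech understanding", "phonetic", "reading"],
    "attention": ["spatial attention", "attention shift", "sustained attention"],
    "executive function": ["response selection", "inhibition", "task switching"],
    "motor": ["eye movement", "motor control", "grasping"],
    "learning": [["spatial", "learning"], "reward learning", "skill learning"],
}


@dataclass
class ScreenConfig:
    radius: float = 10.0
    alpha: float = 0.05  # per-donor repetition level, uncorrected two-tailed
    fdr_q: float = 0.05
    robust_min: int | None = None  # default: repetitions == n_donors
    marginal_min: int | None = None  # default: n_donors - 1


@dataclass
class GeneScreenResult:
    gene: str
    result: RandomEffectsResult | None
    fits: list[DonorCorrelation] = field(default_factory=list)
    repetitions: int = 0
    q_value: float | None = None
    rejected: bool = False
    robustness: str = "none"
    note: str = ""


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection flags, adjusted p-values)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def classify_robustness(
    repetitions: int,
    n_donors: int,
    robust_min: int | None = None,
    marginal_min: int | None = None,
) -> str:
    """Label a repetition count: full house is robust, one short marginal."""
    if not 0 <= repetitions <= n_donors:
        raise ValueError("repetitions must lie in [0, n_donors]")
    robust_min = n_donors if robust_min is None else robust_min
    marginal_min = n_donors - 1 if marginal_min is None else marginal_min
    if repetitions >= robust_min:
        return "robust"
    if repetitions >= marginal_min:
        return "marginal"
    return "none"


def _gene_fits(gene, amap, atlases):
    fits = []
    for a in atlases:
        vec = average_probes(a, gene)
        fits.append(
            donor_correlation(vec, sample_map_at_sites(amap, a.site_coords, a.site_ids))
        )
    return fits


def screen_genes(
    genes: list[str],
    db: StudyDatabase,
    term_expr,
    atlases: list[ExpressionAtlas],
    grid: VoxelGrid | None = None,
    config: ScreenConfig | None = None,
) -> list[GeneScreenResult]:
    """Similarity pipeline per gene, BH-corrected across the screened set.

    Genes missing from any atlas yield a null result row with a warning
    instead of aborting the screen; FDR is applied to the random-effects
    p-values of the successfully screened genes only.
    """
    config = config or ScreenConfig()
    grid = grid if grid is not None else VoxelGrid.mni()
    studies = select_studies(db, term_expr)
    if not studies:
        raise ValueError(f"no studies for term {term_expr!r}")
    term_name = term_expr if isinstance(term_expr, str) else " ".join(term_expr)
    amap = build_activation_map(studies, grid, config.radius, term=term_name)

    results = []
    for gene in genes:
        try:
            fits = _gene_fits(gene, amap, atlases)
        except KeyError as e:
            warnings.warn(f"skipping gene {gene!r}: {e}", stacklevel=2)
            results.append(
                GeneScreenResult(gene=gene, result=None, note="missing from atlas")
            )
            continue
        results.append(
            GeneScreenResult(
                gene=gene,
                result=random_effects_test(fits),
                fits=fits,
                repetitions=count_repetitions(fits, config.alpha),
                robustness=classify_robustness(
                    count_repetitions(fits, config.alpha),
                    len(atlases),
                    config.robust_min,
                    config.marginal_min,
                ),
            )
        )
    tested = [r for r in results if r.result is not None]
    if tested:
        reject, p_adj = bh_fdr([r.result.p_two_tailed for r in tested], config.fdr_q)
        for r, rej, q in zip(tested, reject, p_adj):
            r.q_value, r.rejected = float(q), bool(rej)
    return results


@dataclass
class DomainProfile:
    """Per sub-domain donor betas and random-effects summaries (one gene)."""

    gene: str
    rows: list[dict]  # domain, subdomain, term_expr, n_studies, betas, result, flagged

    def beta_matrix(self) -> np.ndarray:
        """(n_subdomains, n_donors) betas; flagged rows are NaN."""
        usable = [r for r in self.rows if not r["flagged"]]
        n_donors = len(usable[0]["betas"]) if usable else 0
        out = np.full((len(self.rows), n_donors), np.nan)
        for i, r in enumerate(self.rows):
            if not r["flagged"]:
                out[i] = r["betas"]
        return out

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "domain": r["domain"],
                    "subdomain": r["subdomain"],
                    "n_studies": r["n_studies"],
                    "flagged": r["flagged"],
                    "mean_beta": (
                        r["result"].mean_slope if r["result"] is not None else np.nan
                    ),
                    "p": (
                        r["result"].p_two_tailed if r["result"] is not None else np.nan
                    ),
                }
            )
        return pd.DataFrame(recs)


def _subdomain_name(term_expr) -> str:
    return term_expr if isinstance(term_expr, str) else " ".join(term_expr)


def domain_profile(
    gene: str,
    domain_terms: dict[str, list],
    db: StudyDatabase,
    atlases: list[ExpressionAtlas],
    grid: VoxelGrid | None = None,
    config: ScreenConfig | None = None,
) -> DomainProfile:
    """Correlation profile of one gene across cognitive-domain term maps.

    Each sub-domain term expression (single label or two-label
    conjunction) is resolved to a study set and an activation map;
    sub-domains with no matching studies are flagged, not fatal.
    Results are reported uncorrected — an exploratory profile, not a
    hypothesis test battery.
    """
    config = config or ScreenConfig()
    grid = grid if grid is not None else VoxelGrid.mni()
    rows = []
    for domain, subterms in domain_terms.items():
        for term_expr in subterms:
            name = _subdomain_name(term_expr)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                studies = select_studies(db, term_expr)
            row = {
                "domain": domain,
                "subdomain": name,
                "term_expr": term_expr,
                "n_studies": len(studies),
                "betas": None,
                "result": None,
                "flagged": True,
            }
            if studies:
                amap = build_activation_map(studies, grid, config.radius, term=name)
                try:
                    fits = _gene_fits(gene, amap, atlases)
                    row.update(
                        betas=[f.slope for f in fits],
                        result=random_effects_test(fits),
                        flagged=False,
                    )
                except (KeyError, ValueError) as e:
                    row["note"] = str(e)
            rows.append(row)
    return DomainProfile(gene=gene, rows=rows)
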