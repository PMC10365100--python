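"""Synthetic worlds with planted effects for ground-truth recovery tests.

Three generators share one :class:`SimulationConfig`:

* a study database in which a target term's studies concentrate their foci
  around configurable hotspot centers while background studies scatter
  foci uniformly over the brain bounding box;
* donor expression atlases whose gene signals carry a planted spatial
  correlation with a target activation map, degraded by i.i.d. probe
  noise;
* a behavioral table (16 Likert sense-of-direction items + one circadian
  regularity item) with a planted sex-adjusted correlation.

Defaults mirror the scale of the real resources the pipeline emulates:
six donors with ~500 sampling sites each, a 61-study target term averaging
49 foci per study (~3,000 foci), and a behavioral sample of 292
participants (155 female).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import BehaviorTable
from .expression import ExpressionAtlas, standardize
from .meta_map import ActivationMap, StudyDatabase, StudyRecord, VoxelGrid

__all__ = [
    "SimulationConfig",
    "generate_study_database",
    "generate_expression_atlases",
    "generate_behavior",
    "DEFAULT_PROBE_COUNTS",
    "DEFAULT_PLANTED_RHO",
    "DEFAULT_HOTSPOTS",
    "CLOCK_PATHWAY_GENES",
]

#: Probe multiplicities typical of microarray atlases (the focal gene CRY2
#: has three probes; counts for the rest follow the pathway gene panel).
DEFAULT_PROBE_COUNTS: dict[str, int] = {
    "CRY2": 3,
    "S100B": 2,
    "ISCA1": 5,
    "CLOCK": 3,
    "PER1": 2,
    "PER2": 2,
    "PER3": 3,
    "ARNTL": 2,
    "CSNK1D": 1,
    "CSNK1E": 3,
    "ARNT2": 2,
    "NPAS2": 2,
    "TIMELESS": 2,
}

#: Core circadian ("clock") pathway panel screened against the target map.
CLOCK_PATHWAY_GENES = [
    "CLOCK",
    "PER1",
    "PER2",
    "PER3",
    "ARNTL",
    "CSNK1D",
    "CSNK1E",
    "ARNT2",
    "NPAS2",
    "TIMELESS",
]

#: Default planted expression-activation correlations: a clear focal-gene
#: signal, a weaker negative co-regressor, a marginal clock-gene signal,
#: and a null comparator; unlisted genes are pure noise.
DEFAULT_PLANTED_RHO: dict[str, float] = {
    "CRY2": 0.3,
    "S100B": -0.2,
    "CLOCK": 0.15,
    "ISCA1": 0.0,
}

#: Medial-temporal / retrosplenial-like hotspot centers (MNI mm).
DEFAULT_HOTSPOTS: tuple[tuple[float, float, float], ...] = (
    (-24.0, -30.0, -12.0),
    (26.0, -32.0, -10.0),
    (-2.0, -52.0, 14.0),
)


@dataclass
class SimulationConfig:
    """Stated world for the synthetic study; all randomness flows from ``seed``."""

    seed: int = 0
    n_donors: int = 6
    n_sites_per_donor: int = 500
    n_studies_total: int = 400
    n_term_studies: int = 61
    foci_per_study_mean: float = 49.0
    focus_scatter_sd: float = 8.0  # mm
    hotspot_centers: tuple = DEFAULT_HOTSPOTS
    planted_rho: dict = field(default_factory=lambda: dict(DEFAULT_PLANTED_RHO))
    n_probes: dict = field(default_factory=lambda: dict(DEFAULT_PROBE_COUNTS))
    probe_noise_sd: float = 0.3
    term: str = "navigation"
    #: extra term labels assigned to background studies, each with its own
    #: hotspot centers (for cognitive-domain planted contrasts)
    extra_terms: dict = field(default_factory=dict)
    n_extra_term_studies: int = 30
    site_support_frac: float = 0.5  # fraction of sites inside map support
    behavior_n: int = 292
    behavior_n_female: int = 155
    behavior_partial_rho: float = 0.15
    behavior_sex_effect_sod: float = 0.8  # latent-SD shift (males minus females)
    behavior_sex_effect_circadian: float = 0.8
    item_noise_sd: float = 0.7
    reverse_items: tuple = (1, 3, 4, 5, 7, 9, 14)  # 1-based positions
    grid_spacing: float = 4.0

    def __post_init__(self) -> None:
        if self.n_term_studies > self.n_studies_total:
            raise ValueError("n_term_studies must not exceed n_studies_total")
        for g, r in self.planted_rho.items():
            if not abs(r) < 1:
                raise ValueError(f"planted rho for {g} must satisfy |rho| < 1")
        for g, k in self.n_probes.items():
            if k < 1:
                raise ValueError(f"probe count for {g} must be >= 1")
        if not 0 <= self.behavior_n_female <= self.behavior_n:
            raise ValueError("behavior_n_female must be in [0, behavior_n]")
        if not abs(self.behavior_partial_rho) < 1:
            raise ValueError("behavior_partial_rho must satisfy |rho| < 1")
        if not 0 <= self.site_support_frac <= 1:
            raise ValueError("site_support_frac must be in [0, 1]")

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid.mni(self.grid_spacing)

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.planted_rho) | set(self.n_probes))

    def rng(self, *stream: int) -> np.random.Generator:
        """Named substream of the master seed; streams never interact."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, *stream]))


def _truncated_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    counts = rng.poisson(mean, size=size)
    return np.maximum(counts, 1)


def _hotspot_foci(
    rng: np.random.Generator, centers: np.ndarray, n: int, sd: float, grid: VoxelGrid
) -> np.ndarray:
    which = rng.integers(0, len(centers), size=n)
    foci = centers[which] + rng.normal(0.0, sd, size=(n, 3))
    box = grid.bounding_box
    return np.clip(foci, box[:, 0], box[:, 1])


def generate_study_database(cfg: SimulationConfig) -> StudyDatabase:
    """Synthetic study database with one hotspot-concentrated target term.

    Exactly ``n_term_studies`` studies carry the target term and draw their
    foci from isotropic Gaussians (sd = ``focus_scatter_sd``) around the
    hotspot centers; the remaining studies scatter foci uniformly over the
    brain bounding box, giving the resampling null genuine spatial
    heterogeneity.  Optional ``extra_terms`` relabel background studies
    with their own hotspots.
    """
    grid = cfg.grid
    centers = np.asarray(cfg.hotspot_centers, dtype=float).reshape(-1, 3)
    if centers.shape[0] == 0:
        raise ValueError("hotspot_centers must be non-empty")
    if not np.all(grid.contains(centers)):
        raise ValueError("hotspot center outside the grid bounding box")
    for t, c in cfg.extra_terms.items():
        c = np.asarray(c, dtype=float).reshape(-1, 3)
        if not np.all(grid.contains(c)):
            raise ValueError(f"extra term {t!r} hotspot outside the bounding box")

    rng = cfg.rng(0)
    n_bg = cfg.n_studies_total - cfg.n_term_studies
    counts = _truncated_poisson(rng, cfg.foci_per_study_mean, cfg.n_studies_total)
    box = grid.bounding_box

    # background studies claimed by extra terms, round-robin, never the target
    extra_names = sorted(cfg.extra_terms)
    if len(extra_names) * cfg.n_extra_term_studies > n_bg:
        raise ValueError("not enough background studies for extra_terms")
    extra_assignment: dict[int, str] = {}
    pos = 0
    for name in extra_names:
        for _ in range(cfg.n_extra_term_studies):
            extra_assignment[pos] = name
            pos += 1

    studies = []
    width = len(str(cfg.n_studies_total))
    for i in range(cfg.n_studies_total):
        sid = f"study{i:0{width}d}"
        n_foci = int(counts[i])
        if i < cfg.n_term_studies:
            terms = frozenset({cfg.term})
            foci = _hotspot_foci(rng, centers, n_foci, cfg.focus_scatter_sd, grid)
        else:
            bg_pos = i - cfg.n_term_studies
            if bg_pos in extra_assignment:
                name = extra_assignment[bg_pos]
                terms = frozenset(name.split() + [name] if " " in name else [name])
                c = np.asarray(cfg.extra_terms[name], dtype=float).reshape(-1, 3)
                foci = _hotspot_foci(rng, c, n_foci, cfg.focus_scatter_sd, grid)
            else:
                terms = frozenset({"background"})
                foci = rng.uniform(box[:, 0], box[:, 1], size=(n_foci, 3))
        studies.append(StudyRecord(study_id=sid, terms=terms, foci=foci))
    return StudyDatabase(studies)


def generate_expression_atlases(
    cfg: SimulationConfig, target_map: ActivationMap
) -> list[ExpressionAtlas]:
    """Per-donor atlases whose gene signals carry planted map correlations.

    Sites sit at voxel centers: a ``site_support_frac`` share drawn
    uniformly from voxels with nonzero map support, the rest uniformly
    over the whole grid.  For a gene with planted correlation rho the
    latent site signal is ``rho * z + sqrt(1 - rho^2) * eps`` where ``z``
    is the donor's standardized map value profile; every probe adds
    independent Gaussian noise of SD ``probe_noise_sd``.
    """
    grid = target_map.grid
    if grid.shape != cfg.grid.shape or grid.spacing != cfg.grid.spacing:
        raise ValueError("target_map grid does not match the configured grid")
    support = np.flatnonzero(target_map.values.ravel() > 0)
    if support.size == 0:
        raise ValueError("target map has no nonzero support")
    genes = cfg.genes
    atlases = []
    for d in range(cfg.n_donors):
        rng = cfg.rng(1, d)
        n_sup = int(round(cfg.site_support_frac * cfg.n_sites_per_donor))
        sup_flat = rng.choice(support, size=n_sup, replace=True)
        bg_flat = rng.integers(0, grid.n_voxels, size=cfg.n_sites_per_donor - n_sup)
        flat = np.concatenate([sup_flat, bg_flat])
        coords = grid.flat_to_mm(flat)
        map_vals = target_map.values.ravel()[flat]
        z = standardize(map_vals)
        probe_ids, probe_genes, rows = [], [], []
        for g in genes:
            rho = float(cfg.planted_rho.get(g, 0.0))
            k = int(cfg.n_probes.get(g, 2))
            eps = rng.standard_normal(cfg.n_sites_per_donor)
            latent = rho * z + np.sqrt(1.0 - rho * rho) * eps
            for j in range(k):
                probe_ids.append(f"{g}_probe{j + 1}")
                probe_genes.append(g)
                rows.append(
                    latent
                    + rng.normal(0.0, cfg.probe_noise_sd, cfg.n_sites_per_donor)
                )
        atlases.append(
            ExpressionAtlas(
                donor_id=f"donor{d + 1}",
                site_ids=[f"donor{d + 1}_s{i:04d}" for i in range(len(flat))],
                site_coords=coords,
                probe_ids=probe_ids,
                probe_genes=probe_genes,
                values=np.vstack(rows),
            )
        )
    return atlases


def _likert(latent: np.ndarray, k: int, half_range: float = 2.5) -> np.ndarray:
    """Equal-width binning of a standardized score onto 1..k."""
    z = standardize(latent)
    bins = np.floor((z + half_range) / (2 * half_range) * k).astype(int) + 1
    return np.clip(bins, 1, k)


def generate_behavior(cfg: SimulationConfig) -> BehaviorTable:
    """Behavioral table with a planted sex-adjusted latent correlation.

    Latent sense-of-direction and circadian-regularity scores are drawn
    bivariate normal with correlation ``behavior_partial_rho``; additive
    sex effects confound the marginal association.  The latent
    sense-of-direction score is expressed through 16 noisy Likert items
    (1-5, reverse-keyed per config) and the circadian score through one
    1-9 item.
    """
    rng = cfg.rng(2)
    n, n_f = cfg.behavior_n, cfg.behavior_n_female
    sex = np.array(["F"] * n_f + ["M"] * (n - n_f))
    rng.shuffle(sex)
    is_m = (sex == "M").astype(float)
    rho = cfg.behavior_partial_rho
    cov = np.array([[1.0, rho], [rho, 1.0]])
    latent = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    sod = latent[:, 0] + cfg.behavior_sex_effect_sod * is_m
    circ = latent[:, 1] + cfg.behavior_sex_effect_circadian * is_m

    items = {}
    for j in range(16):
        noisy = sod + rng.normal(0.0, cfg.item_noise_sd, n)
        vals = _likert(noisy, 5)
        if (j + 1) in cfg.reverse_items:
            vals = 6 - vals  # stored reverse-keyed; scoring re-reverses
        items[f"item{j + 1:02d}"] = vals
    df = pd.DataFrame(
        {
            "participant_id": [f"p{i + 1:04d}" for i in range(n)],
            "sex": sex,
            **items,
            "circadian": _likert(circ, 9),
        }
    )
    return BehaviorTable(df)
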