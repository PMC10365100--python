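"""Gene screens, BH-FDR, robustness labels and domain profiles."""

import dataclasses
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imgx.expression import average_probes
from imgx.meta_map import build_activation_map, select_studies
from imgx.screening import (
    DEFAULT_DOMAINS,
    ScreenConfig,
    bh_fdr,
    classify_robustness,
    domain_profile,
    screen_genes,
)
from imgx.similarity import donor_correlation, random_effects_test, sample_map_at_sites
from imgx.synthetic import (
    SimulationConfig,
    generate_expression_atlases,
    generate_study_database,
)


def brute_force_bh(p, q):
    """Step-up by hand: largest k with p_(k) <= k q / m; reject smallest k."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, bool)
    reject[order[:k_star]] = True
    adj = np.empty(m)
    running = 1.0
    for k in range(m, 0, -1):
        running = min(running, m * p[order[k - 1]] / k)
        adj[order[k - 1]] = running
    return reject, adj


class TestBH:
    def test_worked_example(self):
        reject, _ = bh_fdr([0.001, 0.02, 0.04, 0.8], q=0.05)
        assert reject.tolist() == [True, True, False, False]

    def test_all_ones_none_rejected(self):
        reject, adj = bh_fdr([1.0] * 5, q=0.05)
        assert not reject.any() and np.all(adj == 1.0)

    def test_all_zeros_all_rejected(self):
        reject, adj = bh_fdr([0.0] * 5, q=0.05)
        assert reject.all() and np.all(adj == 0.0)

    def test_empty_input(self):
        reject, adj = bh_fdr([], q=0.05)
        assert reject.size == 0 and adj.size == 0

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            m = rng.integers(1, 9)
            p = np.round(rng.random(m), 3)
            reject, adj = bh_fdr(p, q=0.05)
            bf_reject, bf_adj = brute_force_bh(p, 0.05)
            assert np.array_equal(reject, bf_reject)
            assert np.allclose(adj, bf_adj, atol=1e-12)

    def test_adjusted_monotone_in_p(self, rng):
        p = rng.random(8)
        _, adj = bh_fdr(p, q=0.05)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestRobustness:
    @pytest.mark.parametrize(
        "reps,label", [(6, "robust"), (5, "marginal"), (4, "none"), (0, "none")]
    )
    def test_default_thresholds(self, reps, label):
        assert classify_robustness(reps, 6) == label

    def test_custom_thresholds(self):
        assert classify_robustness(4, 6, robust_min=4, marginal_min=3) == "robust"

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_robustness(7, 6)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(n=st.integers(2, 8), data=st.data())
    def test_monotone_in_repetitions(self, n, data):
        rank = {"none": 0, "marginal": 1, "robust": 2}
        r1 = data.draw(st.integers(0, n))
        r2 = data.draw(st.integers(r1, n))
        assert rank[classify_robustness(r1, n)] <= rank[classify_robustness(r2, n)]


class TestScreenGenes:
    def test_clock_panel_row_count(self, world):
        cfg, db, _, atlases = world
        genes = ["CLOCK", "PER1", "PER2", "PER3", "ARNTL", "CSNK1D",
                 "CSNK1E", "ARNT2", "NPAS2", "TIMELESS", "ISCA1"]
        results = screen_genes(genes, db, cfg.term, atlases, grid=cfg.grid)
        assert [r.gene for r in results] == genes
        assert all(r.result is not None for r in results)

    def test_single_gene_q_equals_p(self, world):
        cfg, db, _, atlases = world
        (res,) = screen_genes(["CRY2"], db, cfg.term, atlases, grid=cfg.grid)
        assert res.q_value == pytest.approx(res.result.p_two_tailed)

    def test_q_never_below_p(self, world):
        cfg, db, _, atlases = world
        results = screen_genes(
            ["CRY2", "CLOCK", "PER1", "ISCA1"], db, cfg.term, atlases, grid=cfg.grid
        )
        for r in results:
            assert r.q_value >= r.result.p_two_tailed - 1e-12

    def test_missing_gene_warns_with_null_row(self, world):
        cfg, db, _, atlases = world
        with pytest.warns(UserWarning, match="NOTAGENE"):
            results = screen_genes(
                ["CRY2", "NOTAGENE"], db, cfg.term, atlases, grid=cfg.grid
            )
        assert results[1].result is None and results[1].note

    def test_focal_gene_reproduces_similarity_module(self, world):
        """The screen's per-gene chain is bit-identical to the direct one."""
        cfg, db, amap, atlases = world
        (res,) = screen_genes(["CRY2"], db, cfg.term, atlases, grid=cfg.grid)
        fits = [
            donor_correlation(
                average_probes(a, "CRY2"),
                sample_map_at_sites(amap, a.site_coords, a.site_ids),
            )
            for a in atlases
        ]
        direct = random_effects_test(fits)
        assert res.result == direct
        assert [f.slope for f in res.fits] == [f.slope for f in fits]


@pytest.fixture(scope="module")
def planted_world():
    """'spatial memory' shares the target hotspots; 'face perception' not."""
    cfg = SimulationConfig(
        seed=13,
        n_sites_per_donor=250,
        n_studies_total=250,
        planted_rho={"CRY2": 0.4},
        n_probes={"CRY2": 3},
        extra_terms={
            "spatial memory": list(SimulationConfig().hotspot_centers),
            "face perception": [(-40.0, -52.0, -20.0), (42.0, -50.0, -20.0)],
        },
    )
    db = generate_study_database(cfg)
    amap = build_activation_map(
        select_studies(db, cfg.term), cfg.grid, 10.0, term=cfg.term
    )
    atlases = generate_expression_atlases(cfg, amap)
    return cfg, db, atlases


class TestDomainProfile:
    def test_full_battery_shape(self, planted_world):
        cfg, db, atlases = planted_world
        prof = domain_profile("CRY2", DEFAULT_DOMAINS, db, atlases, grid=cfg.grid)
        assert len(prof.rows) == 27  # nine domains x three sub-domains
        mat = prof.beta_matrix()
        assert mat.shape == (27, cfg.n_donors)

    def test_empty_subdomains_flagged_not_fatal(self, planted_world):
        cfg, db, atlases = planted_world
        prof = domain_profile(
            "CRY2", {"memory": ["episodic memory"]}, db, atlases, grid=cfg.grid
        )
        row = prof.rows[0]
        assert row["flagged"] and row["n_studies"] == 0 and row["betas"] is None

    def test_planted_contrast(self, planted_world):
        """Sub-domain co-located with the planted gene beats an unrelated one."""
        cfg, db, atlases = planted_world
        prof = domain_profile(
            "CRY2",
            {"memory": ["spatial memory"], "perception": ["face perception"]},
            db,
            atlases,
            grid=cfg.grid,
        )
        by_name = {r["subdomain"]: r for r in prof.rows}
        assert not by_name["spatial memory"]["flagged"]
        assert (
            by_name["spatial memory"]["result"].mean_slope
            > by_name["face perception"]["result"].mean_slope + 0.1
        )

    def test_conjunction_expression_resolves(self, planted_world):
        cfg, db, atlases = planted_world
        prof = domain_profile(
            "CRY2", {"memory": [("spatial", "memory")]}, db, atlases, grid=cfg.grid
        )
        assert not prof.rows[0]["flagged"]
        assert prof.rows[0]["n_studies"] == cfg.n_extra_term_studies
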