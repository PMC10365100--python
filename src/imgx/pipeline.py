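"""One-command orchestration of the full synthetic study.

``run_full_study`` executes simulate -> meta-map -> per-donor correlation
-> resampling null -> two-gene stepwise -> gene screen -> cognitive-domain
profile -> behavioral partial correlation, and emits a machine-readable
JSON report plus a human-readable markdown summary.  Every random draw
flows from the single master seed through named substreams, and every
report embeds the hash of the configuration that produced it, so a run is
reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import behavior as beh
from . import null_model, screening, stepwise
from .expression import average_probes, standardize
from .meta_map import build_activation_map, build_association_map, select_studies
from .similarity import (
    count_repetitions,
    donor_correlation,
    random_effects_test,
    sample_map_at_sites,
)
from .synthetic import (
    CLOCK_PATHWAY_GENES,
    SimulationConfig,
    generate_behavior,
    generate_expression_atlases,
    generate_study_database,
)

__all__ = ["PipelineConfig", "run_full_study"]

log = logging.getLogger("imgx")

#: extra hotspot terms planted by default so the domain battery has
#: non-empty rows; their hotspots are disjoint from the target term's so
#: the resampling null pool stays unconfounded
_DEFAULT_EXTRA_TERMS = {
    "spatial memory": [(-28.0, -60.0, 46.0), (30.0, -58.0, 48.0)],
    "face perception": [(-40.0, -52.0, -20.0), (42.0, -50.0, -20.0)],
}


@dataclass
class PipelineConfig:
    seed: int = 0
    sim: SimulationConfig | None = None
    radius: float = 10.0
    map_mode: str = "likelihood"  # or "association" for the main term map
    alpha: float = 0.05
    B: int = 1000
    null_estimator: str = "plain"
    p_enter: float = 0.05
    p_remove: float = 0.10
    fdr_q: float = 0.05
    robust_min: int | None = None
    marginal_min: int | None = None
    focal_gene: str = "CRY2"
    co_gene: str = "S100B"
    screen_gene_list: tuple = tuple(CLOCK_PATHWAY_GENES) + ("ISCA1",)
    domains: dict = field(default_factory=lambda: dict(screening.DEFAULT_DOMAINS))

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = SimulationConfig(
                seed=self.seed, extra_terms=dict(_DEFAULT_EXTRA_TERMS)
            )
        elif self.sim.seed != self.seed:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["hotspot_centers"] = [list(c) for c in d["sim"]["hotspot_centers"]]
        d["sim"]["extra_terms"] = {
            k: [list(c) for c in v] for k, v in d["sim"]["extra_terms"].items()
        }
        d["screen_gene_list"] = list(self.screen_gene_list)
        d["sim"]["reverse_items"] = list(self.sim.reverse_items)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", None)
        if sim is not None:
            sim = SimulationConfig(
                **{
                    **sim,
                    "hotspot_centers": tuple(tuple(c) for c in sim["hotspot_centers"]),
                    "reverse_items": tuple(sim["reverse_items"]),
                }
            )
        d["screen_gene_list"] = tuple(d.get("screen_gene_list", ()))
        return cls(sim=sim, **d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _fit_dict(f) -> dict:
    return {
        "donor_id": f.donor_id,
        "n_sites": f.n_sites,
        "slope": f.slope,
        "r": f.pearson_r,
        "p": f.p_two_tailed,
    }


def _re_dict(r) -> dict | None:
    if r is None:
        return None
    return {
        "n_donors": r.n_donors,
        "mean_slope": r.mean_slope,
        "sd_slope": r.sd_slope,
        "t": r.t_stat,
        "df": r.df,
        "p": r.p_two_tailed,
    }


def run_full_study(config: PipelineConfig, out_dir=None) -> dict:
    """Execute every stage on one synthetic world; return the report dict.

    With ``out_dir`` the report (JSON), a markdown summary, the config and
    the simulated CSV exports are written there; any stage failure aborts
    with the stage name after persisting what completed.
    """
    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    stage = "init"
    t0 = time.time()
    try:
        stage = "simulate"
        log.info("stage=%s seed=%d", stage, config.seed)
        sim = config.sim
        grid = sim.grid
        db = generate_study_database(sim)
        term_studies = select_studies(db, sim.term)
        term_map = build_activation_map(
            term_studies, grid, config.radius, term=sim.term
        )
        atlases = generate_expression_atlases(sim, term_map)
        table = generate_behavior(sim)
        report["simulate"] = {
            "n_studies": len(db),
            "n_term_studies": len(term_studies),
            "total_term_foci": int(sum(s.n_foci for s in term_studies)),
            "n_donors": len(atlases),
            "n_sites_per_donor": atlases[0].n_sites,
            "behavior_n": len(table),
            "behavior_n_female": table.n_female,
        }

        stage = "metamap"
        log.info("stage=%s", stage)
        if config.map_mode == "association":
            term_ids = {s.study_id for s in term_studies}
            background = [s for s in db.studies if s.study_id not in term_ids]
            main_map = build_association_map(
                term_studies, background, grid, config.radius, term=sim.term
            )
        else:
            main_map = term_map
        report["metamap"] = {
            "term": sim.term,
            "mode": config.map_mode,
            "radius_mm": config.radius,
            "spacing_mm": grid.spacing,
            "n_studies": main_map.n_studies,
            "n_active_voxels": int(np.count_nonzero(main_map.values)),
            "max_value": float(main_map.values.max()),
        }

        stage = "correlate"
        log.info("stage=%s gene=%s", stage, config.focal_gene)
        fits = [
            donor_correlation(
                average_probes(a, config.focal_gene),
                sample_map_at_sites(main_map, a.site_coords, a.site_ids),
            )
            for a in atlases
        ]
        re_res = random_effects_test(fits)
        report["correlate"] = {
            "gene": config.focal_gene,
            "map_mode": config.map_mode,
            "fits": [_fit_dict(f) for f in fits],
            "random_effects": _re_dict(re_res),
            "repetitions": count_repetitions(fits, config.alpha),
            "alpha": config.alpha,
        }

        stage = "gene_gene"
        gg_fits = [
            donor_correlation(
                standardize(average_probes(a, config.focal_gene).values),
                average_probes(a, config.co_gene).values,
                donor_id=a.donor_id,
            )
            for a in atlases
        ]
        report["gene_gene"] = {
            "genes": [config.focal_gene, config.co_gene],
            "fits": [_fit_dict(f) for f in gg_fits],
            "random_effects": _re_dict(random_effects_test(gg_fits)),
        }

        stage = "nulltest"
        log.info("stage=%s B=%d", stage, config.B)
        null = null_model.repeatability_test(
            db,
            sim.term,
            config.focal_gene,
            atlases,
            grid=grid,
            radius=config.radius,
            B=config.B,
            alpha=config.alpha,
            seed=config.seed,
            estimator=config.null_estimator,
        )
        report["nulltest"] = null.summary()

        stage = "stepwise"
        log.info("stage=%s", stage)
        sw_fits = []
        for a in atlases:
            g1 = standardize(average_probes(a, config.focal_gene).values)
            g2 = standardize(average_probes(a, config.co_gene).values)
            y = sample_map_at_sites(term_map, a.site_coords, a.site_ids)
            sw_fits.append(
                stepwise.stepwise_fit(
                    y,
                    {
                        config.focal_gene: g1,
                        config.co_gene: g2,
                        "interaction": stepwise.interaction_term(g1, g2),
                    },
                    config.p_enter,
                    config.p_remove,
                    donor_id=a.donor_id,
                )
            )
        re_betas = stepwise.random_effects_on_betas(sw_fits)
        report["stepwise"] = {
            "p_enter": config.p_enter,
            "p_remove": config.p_remove,
            "fits": [
                {
                    "donor_id": f.donor_id,
                    "selected": list(f.selected),
                    "betas": f.betas,
                    "adj_r2": f.adj_r2,
                    "model_p": f.model_p,
                }
                for f in sw_fits
            ],
            "random_effects": {t: _re_dict(r) for t, r in re_betas.items()},
        }

        stage = "screen"
        log.info("stage=%s genes=%d", stage, len(config.screen_gene_list))
        scr = screening.screen_genes(
            list(config.screen_gene_list),
            db,
            sim.term,
            atlases,
            grid=grid,
            config=screening.ScreenConfig(
                radius=config.radius,
                alpha=config.alpha,
                fdr_q=config.fdr_q,
                robust_min=config.robust_min,
                marginal_min=config.marginal_min,
            ),
        )
        report["screen"] = [
            {
                "gene": r.gene,
                "random_effects": _re_dict(r.result),
                "repetitions": r.repetitions,
                "q_value": r.q_value,
                "rejected": r.rejected,
                "robustness": r.robustness,
                "note": r.note,
            }
            for r in scr
        ]

        stage = "domains"
        log.info("stage=%s", stage)
        prof = screening.domain_profile(
            config.focal_gene,
            config.domains,
            db,
            atlases,
            grid=grid,
            config=screening.ScreenConfig(radius=config.radius, alpha=config.alpha),
        )
        report["domains"] = [
            {
                "domain": r["domain"],
                "subdomain": r["subdomain"],
                "n_studies": r["n_studies"],
                "flagged": r["flagged"],
                "betas": r["betas"],
                "random_effects": _re_dict(r["result"]),
            }
            for r in prof.rows
        ]

        stage = "behavior"
        log.info("stage=%s", stage)
        scores = table.sbsod_scores(sim.reverse_items)
        circ = table.df["circadian"].to_numpy(float)
        sex01 = (table.df["sex"] == "M").to_numpy(float)
        part = beh.partial_correlation(
            scores, circ, sex01, covariate_names=("sex",)
        )
        marginal = beh.partial_correlation(scores, circ)
        report["behavior"] = {
            "n": part.n,
            "df": part.df,
            "covariates": list(part.covariates),
            "r_partial": part.r_partial,
            "p_partial": part.p_two_tailed,
            "r_marginal": marginal.r_partial,
            "sbsod_mean": float(scores.mean()),
        }
    except Exception:
        log.error("pipeline failed at stage=%s", stage)
        if out_dir is not None:
            _write_outputs(report, config, out_dir, failed_stage=stage)
        raise

    log.info("pipeline complete in %.1fs", time.time() - t0)
    if out_dir is not None:
        _write_outputs(report, config, out_dir)
    return report


def report_json(report: dict) -> str:
    return json.dumps(report, sort_keys=True, indent=2)


def _write_outputs(report, config, out_dir, failed_stage=None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if failed_stage is not None:
        report = {**report, "failed_stage": failed_stage}
    (out / "report.json").write_text(report_json(report) + "\n")
    config.save(out / "config.yaml")
    (out / "summary.md").write_text(markdown_summary(report))


def markdown_summary(report: dict) -> str:
    lines = [
        "# Synthetic study report",
        "",
        f"- config hash: `{report['config_hash']}` (seed {report['seed']})",
    ]
    if "correlate" in report:
        c = report["correlate"]
        re_ = c["random_effects"]
        lines += [
            f"- {c['gene']} vs term map ({c['map_mode']}): "
            f"mean slope {re_['mean_slope']:.3f} (SD {re_['sd_slope']:.3f}), "
            f"t({re_['df']}) = {re_['t']:.2f}, p = {re_['p']:.4g}; "
            f"{c['repetitions']}/{re_['n_donors']} donors significant "
            f"at alpha = {c['alpha']}",
        ]
    if "nulltest" in report:
        n = report["nulltest"]
        lines += [
            f"- resampling null (B = {n['B']}): observed repetitions "
            f"{n['observed_count']}, null mean {n['null_mean']:.2f} "
            f"(SD {n['null_sd']:.2f}), empirical p = {n['empirical_p']:.3f} "
            f"({n['estimator']} estimator)",
        ]
    if "stepwise" in report:
        re_b = report["stepwise"]["random_effects"]
        parts = []
        for t, r in re_b.items():
            parts.append(
                f"{t}: not testable" if r is None
                else f"{t}: mean beta {r['mean_slope']:.3f} (p = {r['p']:.3g})"
            )
        lines += ["- stepwise random effects — " + "; ".join(parts)]
    if "screen" in report:
        sig = [r["gene"] for r in report["screen"] if r["rejected"]]
        lines += [f"- gene screen: FDR-significant genes: {sig or 'none'}"]
    if "behavior" in report:
        b = report["behavior"]
        lines += [
            f"- behavior: partial r = {b['r_partial']:.3f} "
            f"(p = {b['p_partial']:.4g}, n = {b['n']}), "
            f"marginal r = {b['r_marginal']:.3f}",
        ]
    if "failed_stage" in report:
        lines += [f"- **FAILED at stage {report['failed_stage']}**"]
    return "\n".join(lines) + "\n"
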