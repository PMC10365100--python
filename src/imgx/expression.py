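"""Donor expression atlases: probe-to-gene collapsing and standardization.

An atlas holds one donor's sampling sites (MNI mm) and a probe x site
matrix of normalized microarray expression; multiple probes may map to the
same gene and are collapsed by an unweighted per-site mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionAtlas",
    "GeneExpressionVector",
    "average_probes",
    "standardize",
    "write_expression_csv",
    "load_expression_csv",
]


@dataclass
class ExpressionAtlas:
    donor_id: str
    site_ids: list[str]
    site_coords: np.ndarray  # (n_sites, 3) MNI mm
    probe_ids: list[str]
    probe_genes: list[str]  # gene symbol per probe, parallel to probe_ids
    values: np.ndarray  # (n_probes, n_sites)

    def __post_init__(self) -> None:
        self.site_coords = np.asarray(self.site_coords, dtype=float).reshape(-1, 3)
        self.values = np.asarray(self.values, dtype=float)
        n_sites, n_probes = len(self.site_ids), len(self.probe_ids)
        if len(set(self.site_ids)) != n_sites:
            raise ValueError(f"donor {self.donor_id}: duplicate site_ids")
        if len(set(self.probe_ids)) != n_probes:
            raise ValueError(f"donor {self.donor_id}: duplicate probe_ids")
        if len(self.probe_genes) != n_probes:
            raise ValueError("probe_genes must parallel probe_ids")
        if self.site_coords.shape[0] != n_sites:
            raise ValueError("site_coords/site_ids length mismatch")
        if self.values.shape != (n_probes, n_sites):
            raise ValueError(
                f"values shape {self.values.shape} != (n_probes={n_probes}, "
                f"n_sites={n_sites})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"donor {self.donor_id}: non-finite expression values")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.probe_genes))

    def probe_rows(self, gene: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.probe_genes) if g == gene])


@dataclass
class GeneExpressionVector:
    donor_id: str
    gene: str
    values: np.ndarray  # per-site, probe-averaged; order matches the atlas

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")


def average_probes(atlas: ExpressionAtlas, gene: str) -> GeneExpressionVector:
    """Collapse a gene's probes to one per-site value by unweighted mean."""
    rows = atlas.probe_rows(gene)
    if rows.size == 0:
        raise KeyError(
            f"gene {gene!r} not in atlas {atlas.donor_id}; "
            f"available: {', '.join(atlas.genes)}"
        )
    return GeneExpressionVector(
        donor_id=atlas.donor_id,
        gene=gene,
        values=atlas.values[rows].mean(axis=0),
    )


def standardize(values: np.ndarray) -> np.ndarray:
    """Center to mean 0 and scale to sample SD 1 (n-1 denominator)."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("standardize needs at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: cannot standardize a constant vector")
    return (x - x.mean()) / sd


_CSV_COLS = ["donor_id", "site_id", "x_mm", "y_mm", "z_mm", "probe_id", "gene", "value"]


def write_expression_csv(atlases: list[ExpressionAtlas], path) -> None:
    """Long-format export: one row per (donor, site, probe)."""
    frames = []
    for a in atlases:
        n_p, n_s = a.values.shape
        frames.append(
            pd.DataFrame(
                {
                    "donor_id": np.repeat(a.donor_id, n_p * n_s),
                    "site_id": np.tile(a.site_ids, n_p),
                    "x_mm": np.tile(a.site_coords[:, 0], n_p),
                    "y_mm": np.tile(a.site_coords[:, 1], n_p),
                    "z_mm": np.tile(a.site_coords[:, 2], n_p),
                    "probe_id": np.repeat(a.probe_ids, n_s),
                    "gene": np.repeat(a.probe_genes, n_s),
                    "value": a.values.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_expression_csv(path) -> list[ExpressionAtlas]:
    df = pd.read_csv(path, dtype={"donor_id": str, "site_id": str, "probe_id": str})
    missing = [c for c in _CSV_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"expression csv missing columns: {missing}")
    if not np.all(np.isfinite(df["value"].to_numpy(float))):
        raise ValueError("expression csv contains non-numeric or non-finite values")
    dup = df.duplicated(subset=["donor_id", "site_id", "probe_id"])
    if dup.any():
        key = df.loc[dup.idxmax(), ["donor_id", "site_id", "probe_id"]].tolist()
        raise ValueError(f"duplicated (donor, site, probe) key: {tuple(key)}")
    atlases = []
    for donor_id, g in df.groupby("donor_id", sort=True):
        site_first = g.drop_duplicates("site_id")
        site_ids = site_first["site_id"].tolist()
        coords = site_first[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
        probe_first = g.drop_duplicates("probe_id")
        probe_ids = probe_first["probe_id"].tolist()
        probe_genes = probe_first["gene"].tolist()
        gene_of = dict(zip(probe_first["probe_id"], probe_first["gene"]))
        bad = g[[gene_of[p] != gg for p, gg in zip(g["probe_id"], g["gene"])]]
        if len(bad):
            raise ValueError(
                f"probe {bad.iloc[0]['probe_id']!r} maps to more than one gene"
            )
        wide = g.pivot(index="probe_id", columns="site_id", values="value")
        if wide.isna().any().any():
            raise ValueError(f"donor {donor_id}: missing probe/site values")
        values = wide.loc[probe_ids, site_ids].to_numpy(float)
        atlases.append(
            ExpressionAtlas(
                donor_id=donor_id,
                site_ids=site_ids,
                site_coords=coords,
                probe_ids=probe_ids,
                probe_genes=probe_genes,
                values=values,
            )
        )
    return atlases
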