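"""Coordinate-based meta-analytic activation maps.

A study database pairs each fMRI study with a set of term labels and its
reported activation foci (MNI mm).  A term's activation-likelihood map is
the per-voxel fraction of that term's studies reporting a focus within a
sphere radius of the voxel center — the classic automated-meta-analysis
convention.  An association-test variant (two-proportion z of term vs.
non-term studies) is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "VoxelGrid",
    "StudyRecord",
    "StudyDatabase",
    "ActivationMap",
    "select_studies",
    "study_activation_mask",
    "build_activation_map",
    "build_association_map",
    "study_site_activation_matrix",
    "write_study_database",
    "load_study_database",
]

#: MNI-like bounding box (mm): x -90..90, y -126..90, z -72..108.
MNI_BOX = ((-90.0, 90.0), (-126.0, 90.0), (-72.0, 108.0))

DEFAULT_RADIUS_MM = 10.0


@dataclass(frozen=True)
class VoxelGrid:
    """Isotropic voxel grid in MNI millimetre space.

    ``origin`` is the mm coordinate of the *center* of voxel (0, 0, 0);
    the voxel->mm map is ``mm = origin + index * spacing`` and its inverse
    round-trips exactly at voxel centers.
    """

    shape: tuple[int, int, int]
    spacing: float = 4.0
    origin: tuple[float, float, float] = (-90.0, -126.0, -72.0)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("voxel spacing must be positive")
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"invalid grid shape {self.shape!r}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @classmethod
    def mni(cls, spacing: float = 4.0) -> "VoxelGrid":
        """Grid covering the standard MNI bounding box at ``spacing`` mm."""
        shape = tuple(
            int(round((hi - lo) / spacing)) + 1 for lo, hi in MNI_BOX
        )
        origin = tuple(lo for lo, _ in MNI_BOX)
        return cls(shape=shape, spacing=float(spacing), origin=origin)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.spacing] * 3 + [1.0])
        aff[:3, 3] = self.origin
        return aff

    @property
    def bounding_box(self) -> np.ndarray:
        """(3, 2) mm bounds: voxel-center extremes padded by half a voxel."""
        lo = np.asarray(self.origin) - self.spacing / 2.0
        hi = (
            np.asarray(self.origin)
            + (np.asarray(self.shape) - 1) * self.spacing
            + self.spacing / 2.0
        )
        return np.column_stack([lo, hi])

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        box = self.bounding_box
        return np.all((pts >= box[:, 0]) & (pts <= box[:, 1]), axis=1)

    def mm_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Nearest voxel index for each mm point (no bounds check)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return np.round((pts - np.asarray(self.origin)) / self.spacing).astype(int)

    def voxel_to_mm(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices))
        return np.asarray(self.origin) + idx * self.spacing

    def flat_index(self, points_mm: np.ndarray) -> np.ndarray:
        idx = self.mm_to_voxel(points_mm)
        idx = np.clip(idx, 0, np.asarray(self.shape) - 1)
        return np.ravel_multi_index(tuple(idx.T), self.shape)

    def flat_to_mm(self, flat: np.ndarray) -> np.ndarray:
        idx = np.column_stack(np.unravel_index(np.asarray(flat), self.shape))
        return self.voxel_to_mm(idx)


@dataclass(frozen=True)
class StudyRecord:
    """One study: identifier, lowercase term labels, activation foci (mm)."""

    study_id: str
    terms: frozenset[str]
    foci: np.ndarray

    def __post_init__(self) -> None:
        foci = np.asarray(self.foci, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(foci)):
            raise ValueError(f"study {self.study_id}: non-finite focus coordinates")
        object.__setattr__(self, "foci", foci)
        object.__setattr__(self, "terms", frozenset(self.terms))

    @property
    def n_foci(self) -> int:
        return self.foci.shape[0]


class StudyDatabase:
    """Collection of :class:`StudyRecord` with a term -> study-id index."""

    def __init__(self, studies: list[StudyRecord]):
        ids = [s.study_id for s in studies]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate study_id in database")
        self.studies = list(studies)
        self._by_id = {s.study_id: s for s in self.studies}
        index: dict[str, set[str]] = {}
        for s in self.studies:
            for t in s.terms:
                index.setdefault(t, set()).add(s.study_id)
        self.term_index = index

    def __len__(self) -> int:
        return len(self.studies)

    def __getitem__(self, study_id: str) -> StudyRecord:
        return self._by_id[study_id]

    @property
    def terms(self) -> set[str]:
        return set(self.term_index)

    def study_ids_for(self, term: str) -> set[str]:
        return set(self.term_index.get(term, set()))


def _check_label(label: str) -> str:
    if not isinstance(label, str) or not label:
        raise ValueError("term labels must be non-empty strings")
    if label != label.lower():
        raise ValueError(f"term label {label!r} must be lowercase")
    return label


def select_studies(db: StudyDatabase, term_expr) -> list[StudyRecord]:
    """Studies carrying a term, or the intersection of a pair of terms.

    ``term_expr`` is a single label or a pair of labels; a pair selects
    studies labeled by *both* (the two-word-term conjunction rule).  Unknown
    labels yield an empty selection with a warning so large term screens
    can proceed.
    """
    if isinstance(term_expr, str):
        labels = [_check_label(term_expr)]
    else:
        labels = [_check_label(t) for t in term_expr]
        if len(labels) != 2:
            raise ValueError("term_expr must be a single label or a pair")
    id_sets = []
    for lab in labels:
        if lab not in db.term_index:
            warnings.warn(f"term {lab!r} not found in study database", stacklevel=2)
            id_sets.append(set())
        else:
            id_sets.append(db.study_ids_for(lab))
    ids = set.intersection(*id_sets)
    return [db[i] for i in sorted(ids)]


def _candidate_offsets(grid: VoxelGrid, radius: float) -> np.ndarray:
    w = int(np.ceil(radius / grid.spacing)) + 1
    rng = np.arange(-w, w + 1)
    return (
        np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)
    )


def _active_flat_voxels(foci: np.ndarray, grid: VoxelGrid, radius: float) -> np.ndarray:
    """Flat indices of voxels whose center is within ``radius`` of any focus."""
    foci = np.asarray(foci, dtype=float).reshape(-1, 3)
    if foci.shape[0] == 0:
        return np.empty(0, dtype=np.intp)
    offs = _candidate_offsets(grid, radius)
    base = np.round((foci - np.asarray(grid.origin)) / grid.spacing).astype(int)
    cand = base[:, None, :] + offs[None, :, :]  # (F, K, 3)
    centers = np.asarray(grid.origin) + cand * grid.spacing
    d2 = np.sum((centers - foci[:, None, :]) ** 2, axis=-1)
    inb = np.all((cand >= 0) & (cand < np.asarray(grid.shape)), axis=-1)
    sel = (d2 <= radius**2) & inb
    if not np.any(sel):
        return np.empty(0, dtype=np.intp)
    flat = np.ravel_multi_index(tuple(cand[sel].T), grid.shape)
    return np.unique(flat)


def study_activation_mask(
    study: StudyRecord, grid: VoxelGrid, radius: float = DEFAULT_RADIUS_MM
) -> np.ndarray:
    """Binary voxel mask: active iff within ``radius`` mm of >=1 focus.

    Foci outside the grid contribute only to in-grid voxels; overlapping
    foci never double-count.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    mask = np.zeros(grid.shape, dtype=bool)
    flat = _active_flat_voxels(study.foci, grid, radius)
    mask.ravel()[flat] = True
    return mask


@dataclass
class ActivationMap:
    """Per-voxel activation statistic on a grid.

    In ``likelihood`` mode each value is exactly
    (number of active studies at the voxel) / n_studies, so it lies in
    [0, 1]; ``association`` mode holds a two-proportion z statistic.
    """

    grid: VoxelGrid
    values: np.ndarray
    n_studies: int
    term: str = "random-sample"
    mode: str = "likelihood"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("map values do not match grid shape")
        if self.mode == "likelihood" and (
            self.values.min() < 0 or self.values.max() > 1
        ):
            raise ValueError("likelihood values must lie in [0, 1]")

    def to_nifti(self):
        import nibabel as nib

        img = nib.Nifti1Image(self.values.astype(np.float32), self.grid.affine)
        img.header["descrip"] = f"{self.mode}:{self.term}:n={self.n_studies}"[:79]
        return img

    def save(self, path) -> None:
        import nibabel as nib

        nib.save(self.to_nifti(), str(path))


def _count_map(studies, grid: VoxelGrid, radius: float) -> np.ndarray:
    counts = np.zeros(grid.n_voxels, dtype=np.int64)
    for s in studies:
        counts[_active_flat_voxels(s.foci, grid, radius)] += 1
    return counts.reshape(grid.shape)


def build_activation_map(
    studies: list[StudyRecord],
    grid: VoxelGrid,
    radius: float = DEFAULT_RADIUS_MM,
    term: str = "random-sample",
) -> ActivationMap:
    """Activation-likelihood map: per-voxel fraction of active studies."""
    if len(studies) == 0:
        raise ValueError("no studies for term")
    counts = _count_map(studies, grid, radius)
    return ActivationMap(
        grid=grid,
        values=counts / float(len(studies)),
        n_studies=len(studies),
        term=term,
        mode="likelihood",
    )


def build_association_map(
    term_studies: list[StudyRecord],
    background_studies: list[StudyRecord],
    grid: VoxelGrid,
    radius: float = DEFAULT_RADIUS_MM,
    term: str = "random-sample",
) -> ActivationMap:
    """Two-proportion z map of term vs. non-term activation rates.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with the pooled proportion p;
    voxels active in no or all studies get z = 0.
    """
    if len(term_studies) == 0 or len(background_studies) == 0:
        raise ValueError("association map needs both term and background studies")
    n1, n2 = len(term_studies), len(background_studies)
    c1 = _count_map(term_studies, grid, radius).astype(float)
    c2 = _count_map(background_studies, grid, radius).astype(float)
    pooled = (c1 + c2) / (n1 + n2)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = np.zeros_like(c1)
    ok = se > 0
    z[ok] = (c1[ok] / n1 - c2[ok] / n2) / se[ok]
    return ActivationMap(
        grid=grid, values=z, n_studies=n1, term=term, mode="association"
    )


def study_site_activation_matrix(
    studies: list[StudyRecord],
    grid: VoxelGrid,
    radius: float,
    flat_voxels: np.ndarray,
) -> np.ndarray:
    """Boolean (n_studies, n_voxels) activation restricted to given voxels.

    Column means over a subset of rows reproduce exactly the likelihood-map
    values those studies would yield at those voxels — the workhorse of the
    resampling null, which only ever needs map values at sampling sites.
    """
    centers = grid.flat_to_mm(np.asarray(flat_voxels))
    out = np.zeros((len(studies), centers.shape[0]), dtype=bool)
    r2 = radius**2
    for i, s in enumerate(studies):
        if s.n_foci == 0:
            continue
        d2 = np.sum((centers[None, :, :] - s.foci[:, None, :]) ** 2, axis=-1)
        out[i] = np.any(d2 <= r2, axis=0)
    return out


def write_study_database(db: StudyDatabase, studies_path, foci_path) -> None:
    """Write studies.csv (study_id, terms pipe-delimited) and foci.csv."""
    pd.DataFrame(
        {
            "study_id": [s.study_id for s in db.studies],
            "terms": ["|".join(sorted(s.terms)) for s in db.studies],
        }
    ).to_csv(studies_path, index=False)
    rows = []
    for s in db.studies:
        for x, y, z in s.foci:
            rows.append((s.study_id, x, y, z))
    pd.DataFrame(rows, columns=["study_id", "x_mm", "y_mm", "z_mm"]).to_csv(
        foci_path, index=False
    )


def load_study_database(studies_path, foci_path) -> StudyDatabase:
    studies = pd.read_csv(studies_path, dtype={"study_id": str})
    foci = pd.read_csv(foci_path, dtype={"study_id": str})
    grouped = {
        sid: g[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
        for sid, g in foci.groupby("study_id")
    }
    records = []
    for _, row in studies.iterrows():
        terms = frozenset(t for t in str(row["terms"]).split("|") if t)
        records.append(
            StudyRecord(
                study_id=row["study_id"],
                terms=terms,
                foci=grouped.get(row["study_id"], np.empty((0, 3))),
            )
        )
    return StudyDatabase(records)
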