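"""Seed-based and ROI-based functional connectivity.

Seed maps correlate the mean time course of a spherical seed (defined in mm
via the image affine) with every in-mask voxel; correlations are Fisher
r-to-z transformed (``z = atanh(r)`` with |r| clamped to ``1 - 1e-7``).
The subject-level DMN map is the voxelwise mean of the three seed z-maps
(transform first, then average).  ROI matrices are pairwise Pearson
correlations between mean ROI time courses from an integer-labelled atlas,
with optional exclusion of labels and removal of seed voxels from their
host ROIs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .rest_extraction import RestSeries

logger = logging.getLogger(__name__)

__all__ = [
    "R_CLAMP",
    "SeedSpec",
    "ConnectivityMap",
    "ConnectivityMatrix",
    "default_seeds",
    "fisher_z",
    "sphere_mask",
    "seed_timecourse",
    "seed_map",
    "average_dmn_map",
    "apply_roi_exclusion",
    "matrix_from_timecourses",
    "roi_matrix",
    "roi_timecourses",
    "seed_to_roi_vector",
    "upper_triangle_features",
]

R_CLAMP = 1.0 - 1e-7


@dataclass(frozen=True)
class SeedSpec:
    """A spherical seed region in mm space."""

    name: str
    center_mni: tuple[float, float, float]
    radius: float = 6.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"seed radius must be > 0, got {self.radius}")


def default_seeds(radius: float = 6.0) -> tuple[SeedSpec, SeedSpec, SeedSpec]:
    """The three task-induced-deactivation seeds (MPFC, PCC/PrC, left AG)."""
    return (
        SeedSpec("MPFC", (-1.0, 47.0, -4.0), radius),
        SeedSpec("PCC", (-5.0, -49.0, 40.0), radius),
        SeedSpec("AG", (-45.0, -67.0, 36.0), radius),
    )


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher r-to-z with |r| clamped to ``R_CLAMP`` before atanh."""
    r = np.clip(r, -R_CLAMP, R_CLAMP)
    return np.arctanh(r)


@dataclass
class ConnectivityMap:
    """Voxelwise seed correlation (r) and Fisher-z maps."""

    r_map: np.ndarray
    z_map: np.ndarray
    seed: SeedSpec | None
    n_timepoints: int
    affine: np.ndarray | None = None
    mask: np.ndarray | None = None
    zero_variance: np.ndarray | None = None


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI Fisher-z matrix; diagonal is NaN."""

    roi_ids: tuple[int, ...]
    z_values: np.ndarray
    excluded: tuple[int, ...] = field(default_factory=tuple)
    seed_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        n = len(self.roi_ids)
        if self.z_values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.z_values.shape} does not match "
                f"{n} ROI ids"
            )
        off = ~np.eye(n, dtype=bool)
        if not np.all(np.isfinite(self.z_values[off])):
            raise ValueError("non-finite off-diagonal connectivity value")
        if not np.allclose(self.z_values, self.z_values.T, atol=1e-12, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    def value(self, id_a: int, id_b: int) -> float:
        i, j = self.roi_ids.index(id_a), self.roi_ids.index(id_b)
        return float(self.z_values[i, j])


def upper_triangle_features(
    matrix: ConnectivityMatrix,
) -> tuple[np.ndarray, list[str]]:
    """Flatten the strict upper triangle into (values, connection names)."""
    n = matrix.n_rois
    iu, ju = np.triu_indices(n, k=1)
    values = matrix.z_values[iu, ju]
    names = [f"{matrix.roi_ids[i]}~{matrix.roi_ids[j]}" for i, j in zip(iu, ju)]
    return values, names


# ---------------------------------------------------------------------------
# voxel-space operations
# ---------------------------------------------------------------------------

def sphere_mask(
    shape: tuple[int, int, int],
    affine: np.ndarray,
    center_mm: tuple[float, float, float],
    radius: float,
) -> np.ndarray:
    """Boolean mask of voxels whose mm center lies within ``radius`` of a point."""
    idx = np.indices(shape).reshape(3, -1)
    hom = np.vstack([idx, np.ones(idx.shape[1])])
    mm = (affine @ hom)[:3]
    d2 = ((mm - np.asarray(center_mm)[:, None]) ** 2).sum(axis=0)
    return (d2 <= radius**2).reshape(shape)


def seed_timecourse(series: RestSeries, seed: SeedSpec) -> np.ndarray:
    """Unweighted mean series over in-mask voxels inside the seed sphere."""
    if series.affine is None:
        raise ValueError("seed extraction requires an affine (voxel-mode series)")
    mask = sphere_mask(series.spatial_shape, series.affine, seed.center_mni,
                       seed.radius)
    if series.brain_mask is not None:
        mask &= series.brain_mask.astype(bool)
    if not mask.any():
        raise ValueError(
            f"seed {seed.name!r} at {seed.center_mni} does not intersect the "
            "brain mask"
        )
    return series.data[mask].mean(axis=0)


def _correlate_with(data2d: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each row of ``data2d`` with ``reference``.

    Zero-variance rows (or reference) get r = 0 and are flagged.
    """
    x = data2d - data2d.mean(axis=1, keepdims=True)
    y = reference - reference.mean()
    sx = np.sqrt((x**2).sum(axis=1))
    sy = float(np.sqrt((y**2).sum()))
    flagged = (sx <= 1e-12) | (sy <= 1e-12)
    denom = np.where(flagged, 1.0, sx * max(sy, 1e-300))
    r = np.where(flagged, 0.0, (x @ y) / denom)
    return np.clip(r, -1.0, 1.0), flagged


def seed_map(series: RestSeries, seed: SeedSpec, min_timepoints: int = 10) -> ConnectivityMap:
    """Voxelwise correlation of the seed mean time course with the brain."""
    if series.n_volumes < min_timepoints:
        raise ValueError(
            f"need >= {min_timepoints} timepoints, got {series.n_volumes}"
        )
    tc = seed_timecourse(series, seed)
    flat = series.data.reshape(-1, series.n_volumes)
    r, flagged = _correlate_with(flat, tc)
    shape = series.spatial_shape
    return ConnectivityMap(
        r_map=r.reshape(shape),
        z_map=np.asarray(fisher_z(r)).reshape(shape),
        seed=seed,
        n_timepoints=series.n_volumes,
        affine=series.affine,
        mask=series.brain_mask,
        zero_variance=flagged.reshape(shape),
    )


def average_dmn_map(maps: list[ConnectivityMap]) -> ConnectivityMap:
    """Voxelwise arithmetic mean of seed z-maps (per subject, before any
    group statistics)."""
    if not maps:
        raise ValueError("no maps to average")
    shape = maps[0].z_map.shape
    for m in maps[1:]:
        if m.z_map.shape != shape:
            raise ValueError("seed maps live on different grids")
    z = np.mean([m.z_map for m in maps], axis=0)
    return ConnectivityMap(
        r_map=np.tanh(z),
        z_map=z,
        seed=None,
        n_timepoints=maps[0].n_timepoints,
        affine=maps[0].affine,
        mask=maps[0].mask,
    )


# ---------------------------------------------------------------------------
# ROI-space operations
# ---------------------------------------------------------------------------

def apply_roi_exclusion(
    label_ids: list[int] | tuple[int, ...],
    exclude: set[int] | list[int] | tuple[int, ...],
) -> tuple[int, ...]:
    """Retained ROI ids (sorted) after dropping the exclusion list."""
    exclude = set(exclude)
    missing = exclude - set(label_ids)
    if missing:
        logger.warning("exclusion ids not in atlas: %s", sorted(missing))
    return tuple(sorted(set(label_ids) - exclude))


def roi_timecourses(
    series: RestSeries,
    atlas: np.ndarray,
    exclude: set[int] | tuple[int, ...] = (),
    seeds: list[SeedSpec] | None = None,
) -> tuple[np.ndarray, tuple[int, ...]]:
    """Mean time course per retained atlas label.

    Label 0 is background.  When seeds are given, voxels inside any seed
    sphere are removed from their host ROIs first; an ROI emptied by the
    removal is excluded (logged).
    """
    atlas = np.asarray(atlas)
    if atlas.shape != series.spatial_shape:
        raise ValueError(
            f"atlas shape {atlas.shape} != series spatial shape "
            f"{series.spatial_shape}"
        )
    labels = [int(v) for v in np.unique(atlas) if v != 0]
    keep = apply_roi_exclusion(labels, exclude)

    seed_vox = np.zeros(series.spatial_shape, dtype=bool)
    if seeds:
        if series.affine is None:
            raise ValueError("seed removal requires an affine")
        for s in seeds:
            seed_vox |= sphere_mask(series.spatial_shape, series.affine,
                                    s.center_mni, s.radius)

    tcs, kept = [], []
    for lab in keep:
        m = (atlas == lab) & ~seed_vox
        if not m.any():
            logger.warning("ROI %d emptied by seed removal; excluded", lab)
            continue
        tcs.append(series.data[m].mean(axis=0))
        kept.append(lab)
    return np.asarray(tcs), tuple(kept)


def matrix_from_timecourses(
    timecourses: np.ndarray,
    roi_ids: tuple[int, ...],
    excluded: tuple[int, ...] = (),
) -> ConnectivityMatrix:
    """Pairwise Pearson r between rows, Fisher-z transformed; diagonal NaN."""
    tc = np.asarray(timecourses, dtype=float)
    if tc.ndim != 2 or tc.shape[0] != len(roi_ids):
        raise ValueError("timecourses must be (n_roi, t) matching roi_ids")
    centered = tc - tc.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    flagged = norms <= 1e-12
    if flagged.any():
        logger.warning("%d zero-variance ROI(s); their correlations set to 0",
                       int(flagged.sum()))
    safe_norms = np.where(flagged, 1.0, norms)
    unit = centered / safe_norms[:, None]
    r = np.clip(unit @ unit.T, -1.0, 1.0)
    r[flagged, :] = 0.0
    r[:, flagged] = 0.0
    z = np.asarray(fisher_z(r), dtype=float)
    np.fill_diagonal(z, np.nan)
    z = (z + z.T) / 2.0  # exact symmetry despite fp rounding
    return ConnectivityMatrix(roi_ids=tuple(roi_ids), z_values=z,
                              excluded=tuple(excluded))


def roi_matrix(
    series: RestSeries,
    atlas: np.ndarray,
    exclude: set[int] | tuple[int, ...] = (),
    seeds: list[SeedSpec] | None = None,
) -> ConnectivityMatrix:
    """Full ROI x ROI Fisher-z connectivity matrix from a labelled atlas."""
    tcs, kept = roi_timecourses(series, atlas, exclude=exclude, seeds=seeds)
    return matrix_from_timecourses(tcs, kept, excluded=tuple(sorted(set(exclude))))


def seed_to_roi_vector(
    series: RestSeries,
    seed: SeedSpec,
    atlas: np.ndarray,
    exclude: set[int] | tuple[int, ...] = (),
) -> tuple[np.ndarray, tuple[int, ...]]:
    """Fisher-z connectivity of one seed with every retained ROI.

    Seed voxels are removed from their host ROIs before computing ROI mean
    time courses.  Returns ``(z_vector, roi_ids)``.
    """
    tc = seed_timecourse(series, seed)
    tcs, kept = roi_timecourses(series, atlas, exclude=exclude, seeds=[seed])
    r, flagged = _correlate_with(tcs, tc)
    if flagged.any():
        logger.warning("%d zero-variance ROI(s) in seed vector", int(flagged.sum()))
    return np.asarray(fisher_z(r), dtype=float), kept
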