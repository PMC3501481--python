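"""Task GLM, group inference, FDR and Monte-Carlo cluster-extent thresholds.

Subject-level model: one boxcar per condition group convolved with the
canonical double-gamma HRF (response peak 6 s, undershoot peak 16 s, ratio
1/6 — the SPM default kernel), sampled at the TR, plus an intercept.
Contrast t-maps feed a summary-statistics random-effects group test
(one- or two-sample t on subject-level maps, pooled variance).

Cluster-extent thresholds are calibrated by simulating Gaussian noise in
the analysis mask, smoothing to the stated FWHM, thresholding voxelwise
and recording the maximum cluster size; the minimum extent is the smallest
k whose null exceedance probability is <= alpha.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .study_design import SessionDesign
from .signal_cleaning import smooth_gaussian

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "StatMap",
    "Cluster",
    "ClusterTable",
    "ClusterExtentNull",
    "double_gamma_hrf",
    "build_design_matrix",
    "fit_glm",
    "group_ttest",
    "fdr_threshold",
    "cluster_extent_threshold",
    "extract_clusters",
    "connectivity_structure",
]

_HRF_DT = 0.1  # s, oversampling grid for boxcar convolution


def double_gamma_hrf(t: np.ndarray, peak: float = 6.0, undershoot: float = 16.0,
                     ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma HRF evaluated at times ``t`` (seconds).

    Normalized to unit integral so that a convolved boxcar plateaus at 1.
    """
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, peak, scale=1.0) - ratio * stats.gamma.pdf(
        t, undershoot, scale=1.0
    )
    h[t < 0] = 0.0
    area = np.trapezoid(h, t) if len(t) > 1 else 1.0
    if abs(area) > 1e-12:
        h = h / area
    return h


@dataclass
class DesignMatrix:
    """Volumes x (conditions + nuisance) matrix for the task GLM."""

    matrix: np.ndarray
    condition_names: tuple[str, ...]
    column_names: tuple[str, ...]
    hrf_model: str = "double_gamma"

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.column_names):
            raise ValueError("one name per column required")
        rank = np.linalg.matrix_rank(self.matrix)
        self.full_rank = bool(rank == self.matrix.shape[1])
        if not self.full_rank:
            logger.warning(
                "design matrix rank %d < %d columns", rank, self.matrix.shape[1]
            )

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def contrast_vector(self, weights: dict[str, float]) -> np.ndarray:
        """Expand ``{condition: weight}`` into a full column-weight vector."""
        c = np.zeros(self.matrix.shape[1])
        for name, w in weights.items():
            if name not in self.column_names:
                raise KeyError(f"unknown design column {name!r}")
            c[self.column_names.index(name)] = w
        return c


def build_design_matrix(
    design: SessionDesign,
    hrf: str = "double_gamma",
    include_rest_regressor: bool = True,
) -> DesignMatrix:
    """HRF-convolved boxcar regressors for one run, one per condition group.

    Conditions are collapsed to their regressor group via the design's
    ``condition_groups`` mapping (e.g. pun + literal -> language).  Rest
    blocks get their own regressor by default, matching a model in which
    rest-vs-task contrasts are formed between explicit regressors.  An
    intercept column is always appended.
    """
    if hrf != "double_gamma":
        raise ValueError(f"unknown HRF model {hrf!r}")
    acq = design.acquisition
    groups: list[str] = []
    for b in design.blocks:
        g = design.group_of(b.condition)
        if g not in groups:
            groups.append(g)
    if not include_rest_regressor and "rest" in groups:
        groups.remove("rest")

    duration = acq.duration
    hi_t = np.arange(0.0, duration + 32.0, _HRF_DT)
    kernel = double_gamma_hrf(np.arange(0.0, 32.0, _HRF_DT)) * _HRF_DT

    vol_times = np.arange(acq.n_volumes) * acq.tr
    cols = []
    for g in groups:
        boxcar = np.zeros_like(hi_t)
        for b in design.blocks:
            if design.group_of(b.condition) != g:
                continue
            boxcar[(hi_t >= b.onset) & (hi_t < b.end)] = 1.0
        conv = np.convolve(boxcar, kernel)[: len(hi_t)]
        cols.append(np.interp(vol_times, hi_t, conv))
    cols.append(np.ones(acq.n_volumes))
    X = np.column_stack(cols)
    return DesignMatrix(
        matrix=X,
        condition_names=tuple(groups),
        column_names=tuple(groups) + ("intercept",),
        hrf_model=hrf,
    )


@dataclass
class StatMap:
    """Per-voxel (or per-ROI) statistic values with degrees of freedom."""

    values: np.ndarray
    df: float
    contrast: str = ""
    affine: np.ndarray | None = None
    mask: np.ndarray | None = None
    betas: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError(f"df must be > 0, got {self.df}")
        check = self.values if self.mask is None else self.values[self.mask]
        if not np.all(np.isfinite(check)):
            raise ValueError("non-finite statistic inside mask")


def fit_glm(
    data: np.ndarray,
    X: DesignMatrix,
    contrast: dict[str, float] | np.ndarray,
    affine: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> StatMap:
    """Per-voxel OLS fit and contrast t-map.

    ``data`` is ``(..., t)``; ``contrast`` is either a column-weight vector
    or a ``{column_name: weight}`` mapping.  ``df = volumes - rank(X)``.
    Rank-deficient designs are solved with the pseudo-inverse (logged).
    """
    data = np.asarray(data, dtype=float)
    if data.shape[-1] != X.n_volumes:
        raise ValueError(
            f"data has {data.shape[-1]} volumes, design expects {X.n_volumes}"
        )
    c = X.contrast_vector(contrast) if isinstance(contrast, dict) else np.asarray(contrast, float)
    M = X.matrix
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        logger.warning("rank-deficient design (%d < %d); pseudo-inverse fit",
                       rank, M.shape[1])
    df = X.n_volumes - rank
    if df <= 0:
        raise ValueError("no residual degrees of freedom")

    spatial_shape = data.shape[:-1]
    Y = data.reshape(-1, X.n_volumes).T      # (t, v)
    pinv = np.linalg.pinv(M)
    beta = pinv @ Y                           # (k, v)
    resid = Y - M @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    cvar = float(c @ pinv @ pinv.T @ c)       # c' (X'X)^+ c
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 * cvar)
        t = np.where(se > 0, (c @ beta) / np.where(se > 0, se, 1.0), 0.0)
    return StatMap(
        values=t.reshape(spatial_shape),
        df=float(df),
        contrast=str(contrast),
        affine=affine,
        mask=mask,
        betas=(c @ beta).reshape(spatial_shape),
    )


def group_ttest(
    maps_a: list[np.ndarray] | np.ndarray,
    maps_b: list[np.ndarray] | np.ndarray | None = None,
    affine: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> StatMap:
    """Voxelwise random-effects t on subject-level maps.

    One-sample against zero when ``maps_b`` is None; otherwise a pooled-
    variance two-sample t (group a minus group b), df = n1 + n2 - 2.
    """
    A = np.asarray(maps_a, dtype=float)
    if maps_b is None:
        n = A.shape[0]
        if n < 2:
            raise ValueError("need >= 2 subjects")
        mean = A.mean(axis=0)
        sd = A.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sd > 0, mean / (np.where(sd > 0, sd, 1.0) / np.sqrt(n)), 0.0)
        return StatMap(values=t, df=float(n - 1), contrast="one-sample",
                       affine=affine, mask=mask)
    B = np.asarray(maps_b, dtype=float)
    n1, n2 = A.shape[0], B.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >= 2 subjects per group, got {n1} and {n2}")
    v1 = A.var(axis=0, ddof=1)
    v2 = B.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        t = np.where(se > 0, (A.mean(axis=0) - B.mean(axis=0))
                     / np.where(se > 0, se, 1.0), 0.0)
    return StatMap(values=t, df=float(n1 + n2 - 2), contrast="two-sample",
                   affine=affine, mask=mask)


def fdr_threshold(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up: boolean rejection set at level ``q``."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= (np.arange(1, m + 1) / m) * q
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.nonzero(below)[0]))  # largest i with p_(i) <= i/m q
        reject[order[: k + 1]] = True
    return reject.reshape(np.asarray(p_values).shape)


def connectivity_structure(connectivity: int = 18) -> np.ndarray:
    """3D binary structure for cluster labelling (6, 18 or 26 neighbors)."""
    rank = {6: 1, 18: 2, 26: 3}
    if connectivity not in rank:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, rank[connectivity])


@dataclass
class ClusterExtentNull:
    """Null distribution of the maximum suprathreshold cluster size."""

    k_min: int
    max_sizes: np.ndarray
    alpha: float
    voxel_p: float

    def fwe_rate(self, k: int) -> float:
        """Fraction of null simulations whose max cluster size is >= k."""
        return float(np.mean(self.max_sizes >= k))

    def corrected_p(self, k: int) -> float:
        return self.fwe_rate(k)


def cluster_extent_threshold(
    mask: np.ndarray,
    smoothness_fwhm: float = 0.0,
    voxel_p: float = 0.001,
    n_sim: int = 10_000,
    alpha: float = 0.05,
    connectivity: int = 18,
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0),
    two_sided: bool = True,
    seed: int | np.random.Generator | None = 0,
) -> ClusterExtentNull:
    """Monte-Carlo minimum cluster extent controlling FWE at ``alpha``.

    Each simulation draws white Gaussian noise on the mask grid, smooths to
    ``smoothness_fwhm`` mm, re-standardizes within the mask, thresholds at
    the (two-sided by default) ``voxel_p`` quantile and records the largest
    connected suprathreshold component.  ``k_min`` is the smallest size
    whose null exceedance probability is <= alpha.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3 or not mask.any():
        raise ValueError("mask must be a nonempty 3D boolean array")
    if not (0 < voxel_p < 1):
        raise ValueError(f"voxel_p must be in (0, 1), got {voxel_p}")
    if alpha >= 1:
        return ClusterExtentNull(k_min=1, max_sizes=np.ones(0), alpha=alpha,
                                 voxel_p=voxel_p)
    if n_sim < 100:
        warnings.warn(f"n_sim={n_sim} is too small for a stable threshold")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z_thr = stats.norm.isf(voxel_p / 2 if two_sided else voxel_p)
    structure = connectivity_structure(connectivity)

    max_sizes = np.zeros(n_sim, dtype=int)
    for i in range(n_sim):
        noise = rng.standard_normal(mask.shape)
        if smoothness_fwhm > 0:
            noise = smooth_gaussian(noise, smoothness_fwhm, voxel_size)
            inside = noise[mask]
            noise = (noise - inside.mean()) / inside.std()
        supra = np.abs(noise) > z_thr if two_sided else noise > z_thr
        supra &= mask
        if not supra.any():
            continue
        labels, n_lab = ndimage.label(supra, structure=structure)
        if n_lab:
            sizes = np.bincount(labels.ravel())[1:]
            max_sizes[i] = int(sizes.max())

    # smallest k with P(max >= k) <= alpha
    k = 1
    while np.mean(max_sizes >= k) > alpha:
        k += 1
    return ClusterExtentNull(k_min=k, max_sizes=max_sizes, alpha=alpha,
                             voxel_p=voxel_p)


@dataclass(frozen=True)
class Cluster:
    size: int
    peak_index: tuple[int, int, int]
    peak_mm: tuple[float, float, float]
    peak_stat: float
    corrected_p: float = float("nan")


@dataclass
class ClusterTable:
    clusters: tuple[Cluster, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def to_rows(self) -> list[dict]:
        return [
            {
                "k": c.size, "x": c.peak_mm[0], "y": c.peak_mm[1],
                "z": c.peak_mm[2], "stat": c.peak_stat, "p_fwe": c.corrected_p,
            }
            for c in self.clusters
        ]


def extract_clusters(
    stat_map: StatMap,
    stat_threshold: float,
    k_min: int = 1,
    connectivity: int = 18,
    two_sided: bool = False,
    null: ClusterExtentNull | None = None,
) -> ClusterTable:
    """Connected suprathreshold components of size >= ``k_min``.

    Peak coordinates are reported in mm via the map affine when available,
    otherwise as voxel indices.  If a :class:`ClusterExtentNull` is given,
    each cluster gets a corrected p from the null max-size distribution.
    """
    if stat_threshold <= 0 or k_min < 1:
        raise ValueError("thresholds must be positive")
    values = np.asarray(stat_map.values, dtype=float)
    if values.ndim != 3:
        raise ValueError("cluster extraction needs a 3D map")
    supra = np.abs(values) > stat_threshold if two_sided else values > stat_threshold
    if stat_map.mask is not None:
        supra &= stat_map.mask
    if not supra.any():
        return ClusterTable()
    labels, n_lab = ndimage.label(supra, structure=connectivity_structure(connectivity))
    clusters: list[Cluster] = []
    magnitude = np.abs(values) if two_sided else values
    for lab in range(1, n_lab + 1):
        where = labels == lab
        size = int(where.sum())
        if size < k_min:
            continue
        idx_flat = np.flatnonzero(where.ravel())
        peak_flat = idx_flat[np.argmax(magnitude.ravel()[idx_flat])]
        peak_idx = np.unravel_index(peak_flat, values.shape)
        if stat_map.affine is not None:
            mm = stat_map.affine @ np.array([*peak_idx, 1.0])
            peak_mm = tuple(float(v) for v in mm[:3])
        else:
            peak_mm = tuple(float(v) for v in peak_idx)
        clusters.append(
            Cluster(
                size=size,
                peak_index=tuple(int(v) for v in peak_idx),
                peak_mm=peak_mm,
                peak_stat=float(values[peak_idx]),
                corrected_p=null.corrected_p(size) if null is not None else float("nan"),
            )
        )
    clusters.sort(key=lambda c: (-c.size, c.peak_index))
    return ClusterTable(clusters=tuple(clusters))
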