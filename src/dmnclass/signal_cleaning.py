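"""Nuisance regression and spatial smoothing for pseudo-resting-state data.

The nuisance model follows the stated recipe: six rigid-body motion
parameters plus a mean-motion column, the mean signal in gray matter, white
matter, CSF and the whole brain, and a per-session linear trend and
intercept.  ``regress_out`` projects every voxel/ROI series onto the
orthogonal complement of the nuisance space.

The "mean head motion parameter" is implemented as one column: per-volume
root-mean-square of the six parameters, mean-centered (the source method is
ambiguous on this point; the choice is recorded in the NuisanceSet labels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .rest_extraction import RestSeries

logger = logging.getLogger(__name__)

__all__ = ["NuisanceSet", "build_nuisance", "regress_out", "smooth_gaussian"]

TISSUE_NAMES = ("gm", "wm", "csf", "brain")


@dataclass
class NuisanceSet:
    """Volumes x k regressor matrix with per-column labels."""

    regressors: np.ndarray
    labels: tuple[str, ...]
    constant_flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        if self.regressors.ndim != 2:
            raise ValueError("regressors must be 2D (volumes x k)")
        if self.regressors.shape[1] != len(self.labels):
            raise ValueError("one label per column required")

    @property
    def n_volumes(self) -> int:
        return self.regressors.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.regressors.shape[1]


def _mean_over_mask(data: np.ndarray, mask: np.ndarray, name: str) -> np.ndarray:
    if mask.shape != data.shape[:-1]:
        raise ValueError(
            f"mask {name!r} shape {mask.shape} does not match data "
            f"spatial shape {data.shape[:-1]}"
        )
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError(f"mask {name!r} is empty")
    return data[mask].mean(axis=0)


def build_nuisance(
    series: RestSeries,
    motion: np.ndarray,
    masks: dict[str, np.ndarray],
) -> NuisanceSet:
    """Assemble the nuisance regressor matrix for one subject series.

    ``motion`` must already be aligned to the retained volumes (rows =
    series volumes, columns = 6 rigid-body parameters).  ``masks`` maps
    ``gm``/``wm``/``csf``/``brain`` to boolean arrays over the spatial
    dims.  Trend and intercept columns are built per source session (run),
    not per concatenated whole.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape != (series.n_volumes, 6):
        raise ValueError(
            f"motion table must be ({series.n_volumes}, 6), got {motion.shape}"
        )
    for name in TISSUE_NAMES:
        if name not in masks:
            raise ValueError(f"missing tissue mask {name!r}")

    cols: list[np.ndarray] = []
    labels: list[str] = []

    for i in range(6):
        cols.append(motion[:, i])
        labels.append(f"motion_{i}")
    rms = np.sqrt(np.mean(motion**2, axis=1))
    cols.append(rms - rms.mean())
    labels.append("motion_rms_centered")

    data = np.asarray(series.data, dtype=float)
    for name in TISSUE_NAMES:
        cols.append(_mean_over_mask(data, masks[name], name))
        labels.append(f"mean_{name}")

    run_of_vol = series.run_index_per_volume()
    for run in series.run_indices:
        rows = run_of_vol == run
        n = int(rows.sum())
        intercept = np.zeros(series.n_volumes)
        intercept[rows] = 1.0
        trend = np.zeros(series.n_volumes)
        trend[rows] = np.linspace(-1.0, 1.0, n) if n > 1 else 0.0
        cols.append(intercept)
        labels.append(f"session{run}_intercept")
        cols.append(trend)
        labels.append(f"session{run}_trend")

    X = np.column_stack(cols)
    flags = []
    for j, label in enumerate(labels):
        constant = bool(np.ptp(X[:, j]) < 1e-12)
        flags.append(constant)
        if constant and not label.endswith("intercept"):
            logger.info("nuisance column %r is constant; retained, flagged", label)
    return NuisanceSet(regressors=X, labels=tuple(labels),
                       constant_flags=tuple(flags))


def regress_out(series: RestSeries, nuisance: NuisanceSet) -> RestSeries:
    """Residualize the series against the nuisance set (per voxel/ROI OLS).

    Uses a pseudo-inverse solve, so rank-deficient nuisance matrices are
    handled (logged).  The result is a projection: applying it twice gives
    the same residuals.
    """
    if nuisance.n_volumes != series.n_volumes:
        raise ValueError(
            f"nuisance has {nuisance.n_volumes} rows, series has "
            f"{series.n_volumes} volumes"
        )
    X = nuisance.regressors
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning(
            "nuisance matrix rank-deficient (rank %d < %d columns); "
            "pseudo-inverse solution used", rank, X.shape[1],
        )
    data = np.asarray(series.data, dtype=float)
    flat = data.reshape(-1, series.n_volumes)  # (space, t)
    beta = np.linalg.pinv(X) @ flat.T          # (k, space)
    resid = flat.T - X @ beta                  # (t, space)
    cleaned = resid.T.reshape(data.shape)
    return RestSeries(
        data=cleaned,
        segments=series.segments,
        tr=series.tr,
        affine=series.affine,
        brain_mask=series.brain_mask,
    )


def smooth_gaussian(
    data: np.ndarray,
    fwhm: float,
    voxel_size: tuple[float, float, float],
) -> np.ndarray:
    """Per-volume 3D Gaussian smoothing of a 4D series (or single volume).

    ``sigma = fwhm / (2 * sqrt(2 * ln 2))`` per axis in mm, converted to
    voxels by the (possibly anisotropic) voxel size.  Boundary mode is
    'reflect'.  ``fwhm = 0`` is the identity.
    """
    if fwhm < 0:
        raise ValueError(f"fwhm must be >= 0, got {fwhm}")
    data = np.asarray(data, dtype=float)
    if data.ndim not in (3, 4):
        raise ValueError("expected a 3D volume or 4D series")
    if fwhm == 0:
        return data.copy()
    sigma_mm = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = [sigma_mm / v for v in voxel_size]
    if data.ndim == 3:
        return ndimage.gaussian_filter(data, sigma=sigma_vox, mode="reflect")
    out = np.empty_like(data)
    for t in range(data.shape[-1]):
        out[..., t] = ndimage.gaussian_filter(
            data[..., t], sigma=sigma_vox, mode="reflect"
        )
    return out
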