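"""Excision of rest blocks from blocked-design runs.

Converts a run with interleaved task and fixation blocks into a
concatenated pseudo-resting-state series: the first ``lag`` seconds of each
rest block are dropped (hemodynamic return to baseline), and for designs
whose rest blocks are shorter than ``short_rest_threshold`` seconds the
first ``lag`` seconds of the immediately following task block are appended
to each rest segment (hemodynamic delay carries rest-like signal into the
task block).  Segments are concatenated in temporal order and their
provenance — source run, source block, source volume range — is retained so
that downstream detrending can still operate within each original session.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .study_design import SessionDesign, Block

logger = logging.getLogger(__name__)

__all__ = [
    "BoldRun",
    "RestSegment",
    "RestSeries",
    "excise_rest_blocks",
    "concatenate_runs",
]


@dataclass
class BoldRun:
    """One run of BOLD data: 4D ``(x, y, z, t)`` or 2D ``(roi, t)``.

    ``affine`` maps voxel indices to mm coordinates (None in ROI mode);
    ``brain_mask`` is a boolean array over the spatial dims (None = all).
    """

    data: np.ndarray
    design: SessionDesign
    affine: np.ndarray | None = None
    brain_mask: np.ndarray | None = None
    run_index: int = 0

    def __post_init__(self) -> None:
        if self.data.ndim not in (2, 4):
            raise ValueError(f"data must be 2D or 4D, got ndim={self.data.ndim}")
        n_vol = self.data.shape[-1]
        if n_vol != self.design.acquisition.n_volumes:
            raise ValueError(
                f"run has {n_vol} volumes but design expects "
                f"{self.design.acquisition.n_volumes}"
            )
        if self.brain_mask is not None and self.brain_mask.shape != self.spatial_shape:
            raise ValueError(
                f"mask shape {self.brain_mask.shape} != spatial shape "
                f"{self.spatial_shape}"
            )

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.data.shape[:-1]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]


@dataclass(frozen=True)
class RestSegment:
    """Provenance of one retained chunk of volumes."""

    run_index: int
    block_index: int
    src_start: int  # volume range in the source run (half-open)
    src_stop: int
    dst_start: int  # volume range in the concatenated series (half-open)
    dst_stop: int

    @property
    def n_volumes(self) -> int:
        return self.src_stop - self.src_start


@dataclass
class RestSeries:
    """Concatenated retained rest volumes with segment provenance."""

    data: np.ndarray
    segments: tuple[RestSegment, ...]
    tr: float
    affine: np.ndarray | None = None
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        total = sum(s.n_volumes for s in self.segments)
        if total != self.data.shape[-1]:
            raise ValueError(
                f"segments cover {total} volumes but data has "
                f"{self.data.shape[-1]}"
            )

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.data.shape[:-1]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    @property
    def run_indices(self) -> tuple[int, ...]:
        return tuple(sorted({s.run_index for s in self.segments}))

    def source_volume_indices(self) -> np.ndarray:
        """Per retained volume, the index it had in its source run."""
        out = np.empty(self.n_volumes, dtype=int)
        for seg in self.segments:
            out[seg.dst_start:seg.dst_stop] = np.arange(seg.src_start, seg.src_stop)
        return out

    def run_index_per_volume(self) -> np.ndarray:
        out = np.empty(self.n_volumes, dtype=int)
        for seg in self.segments:
            out[seg.dst_start:seg.dst_stop] = seg.run_index
        return out


def _volume_range(design: SessionDesign, start_s: float, stop_s: float) -> tuple[int, int]:
    """Half-open volume range fully inside [start_s, stop_s).

    Conservative conversion: a volume is retained only if it starts at or
    after ``start_s`` and ends by ``stop_s`` (exact when timings are TR
    multiples, as here).
    """
    tr = design.acquisition.tr
    start = math.ceil(start_s / tr - 1e-9)
    stop = math.floor(stop_s / tr + 1e-9)
    stop = min(stop, design.acquisition.n_volumes)
    return start, max(stop, start)


def excise_rest_blocks(
    run: BoldRun,
    lag: float = 6.0,
    short_rest_threshold: float = 20.0,
) -> RestSeries:
    """Extract the pseudo-resting-state series from one blocked run.

    For each rest block, volumes in ``[onset + lag, onset + duration)`` are
    retained.  If the run's rest blocks are shorter than
    ``short_rest_threshold`` seconds, the first ``lag`` seconds of the task
    block immediately following each rest block are appended to that
    segment; a trailing rest block with no following task block is kept
    without the appendage (logged).
    """
    design = run.design
    rest_blocks = design.rest_blocks
    for b in rest_blocks:
        if b.duration <= lag:
            raise ValueError(
                f"rest block at {b.onset} s lasts {b.duration} s <= lag {lag} s"
            )
    append_task = all(b.duration < short_rest_threshold for b in rest_blocks)

    chunks: list[np.ndarray] = []
    segments: list[RestSegment] = []
    dst = 0
    for block_index, block in enumerate(design.blocks):
        if not block.is_rest:
            continue
        stop_s = block.end
        if append_task:
            nxt = design.block_after(block)
            if nxt is not None and not nxt.is_rest and nxt.onset <= block.end + 1e-9:
                stop_s = nxt.onset + min(lag, nxt.duration)
            else:
                logger.warning(
                    "rest block at %.1f s in %r has no following task block; "
                    "kept without task appendage", block.onset, design.study_id,
                )
        start, stop = _volume_range(design, block.onset + lag, stop_s)
        if stop <= start:
            continue
        chunks.append(run.data[..., start:stop])
        segments.append(
            RestSegment(
                run_index=run.run_index,
                block_index=block_index,
                src_start=start,
                src_stop=stop,
                dst_start=dst,
                dst_stop=dst + (stop - start),
            )
        )
        dst += stop - start
    return RestSeries(
        data=np.concatenate(chunks, axis=-1),
        segments=tuple(segments),
        tr=design.acquisition.tr,
        affine=None if run.affine is None else run.affine.copy(),
        brain_mask=run.brain_mask,
    )


def concatenate_runs(series: Sequence[RestSeries]) -> RestSeries:
    """Collate per-run rest series into one subject-level series.

    Segment provenance is preserved across run boundaries; no temporal
    operation crosses a boundary here.
    """
    if not series:
        raise ValueError("no series to concatenate")
    first = series[0]
    for s in series[1:]:
        if s.spatial_shape != first.spatial_shape:
            raise ValueError(
                f"spatial shape mismatch: {s.spatial_shape} != {first.spatial_shape}"
            )
        if abs(s.tr - first.tr) > 1e-9:
            raise ValueError(f"TR mismatch: {s.tr} != {first.tr}")
    segments: list[RestSegment] = []
    offset = 0
    for s in series:
        for seg in s.segments:
            segments.append(
                RestSegment(
                    run_index=seg.run_index,
                    block_index=seg.block_index,
                    src_start=seg.src_start,
                    src_stop=seg.src_stop,
                    dst_start=seg.dst_start + offset,
                    dst_stop=seg.dst_stop + offset,
                )
            )
        offset += s.n_volumes
    return RestSeries(
        data=np.concatenate([s.data for s in series], axis=-1),
        segments=tuple(segments),
        tr=first.tr,
        affine=first.affine,
        brain_mask=first.brain_mask,
    )
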