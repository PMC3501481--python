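"""Data model and I/O for blocked fMRI experimental designs.

A :class:`SessionDesign` describes one scanning run as an ordered list of
non-overlapping condition blocks (task conditions plus ``"rest"`` fixation
blocks) together with the acquisition metadata needed to map block timing
onto volume indices.

Timing is expressed in seconds (floats) everywhere; volume indices are
derived quantities, 0-based, half-open ``[onset_vol, end_vol)``.  Gaps
between blocks (cue screens, un-modelled time) are permitted and simply
belong to no condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml

REST = "rest"

__all__ = [
    "REST",
    "AcquisitionParams",
    "Block",
    "SessionDesign",
    "DesignParseError",
    "DesignValidationError",
    "load_design",
    "write_design",
    "canonical_designs",
]


class DesignParseError(ValueError):
    """A design file could not be parsed."""


class DesignValidationError(ValueError):
    """A parsed design violates a structural invariant."""


@dataclass(frozen=True)
class AcquisitionParams:
    """Scanner-side metadata for one run."""

    tr: float
    n_volumes: int
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    fwhm_smooth: float = 8.0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise DesignValidationError(f"tr must be > 0, got {self.tr}")
        if self.n_volumes < 1:
            raise DesignValidationError(
                f"n_volumes must be >= 1, got {self.n_volumes}"
            )
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise DesignValidationError(
                f"voxel_size must be three positive values, got {self.voxel_size}"
            )
        if self.fwhm_smooth < 0:
            raise DesignValidationError("fwhm_smooth must be >= 0")

    @property
    def duration(self) -> float:
        return self.tr * self.n_volumes


@dataclass(frozen=True)
class Block:
    """One condition block: a label plus an interval in run time."""

    condition: str
    onset: float
    duration: float

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise DesignValidationError(f"onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise DesignValidationError(
                f"duration must be > 0, got {self.duration}"
            )

    @property
    def end(self) -> float:
        return self.onset + self.duration

    @property
    def is_rest(self) -> bool:
        return self.condition == REST


@dataclass(frozen=True)
class SessionDesign:
    """Validated block layout for one run."""

    study_id: str
    blocks: tuple[Block, ...]
    acquisition: AcquisitionParams
    condition_groups: dict[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        blocks = tuple(sorted(self.blocks, key=lambda b: b.onset))
        object.__setattr__(self, "blocks", blocks)
        _check_non_overlapping(blocks)
        if not any(b.is_rest for b in blocks):
            raise DesignValidationError(
                f"design {self.study_id!r} contains no rest block"
            )
        total = sum(b.duration for b in blocks)
        if total > self.acquisition.duration + 1e-9:
            raise DesignValidationError(
                f"blocks span {total} s but run lasts "
                f"{self.acquisition.duration} s"
            )

    @property
    def rest_blocks(self) -> tuple[Block, ...]:
        return tuple(b for b in self.blocks if b.is_rest)

    @property
    def task_blocks(self) -> tuple[Block, ...]:
        return tuple(b for b in self.blocks if not b.is_rest)

    def group_of(self, condition: str) -> str:
        """Regressor group a condition belongs to (defaults to itself)."""
        return self.condition_groups.get(condition, condition)

    def block_after(self, block: Block) -> Block | None:
        """The next block in temporal order, or None."""
        for b in self.blocks:
            if b.onset >= block.end - 1e-9 and b is not block:
                return b
        return None


def _check_non_overlapping(blocks: Sequence[Block]) -> None:
    for prev, nxt in zip(blocks, blocks[1:]):
        if nxt.onset < prev.end - 1e-9:
            raise DesignValidationError(
                f"blocks overlap: {prev.condition!r} [{prev.onset}, {prev.end}) "
                f"and {nxt.condition!r} at onset {nxt.onset}"
            )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ("onset", "duration", "condition")


def _load_sidecar(path: Path) -> AcquisitionParams:
    with open(path) as fh:
        meta = yaml.safe_load(fh) if path.suffix in {".yml", ".yaml"} else json.load(fh)
    if not isinstance(meta, dict):
        raise DesignParseError(f"{path}: sidecar must be a mapping")
    try:
        return AcquisitionParams(
            tr=float(meta["tr"]),
            n_volumes=int(meta["n_volumes"]),
            voxel_size=tuple(meta.get("voxel_size", (3.0, 3.0, 3.0))),
            fwhm_smooth=float(meta.get("fwhm", 8.0)),
        )
    except KeyError as exc:
        raise DesignParseError(f"{path}: missing sidecar key {exc}") from exc


def load_design(
    path: str | Path,
    acquisition: AcquisitionParams | None = None,
    sidecar: str | Path | None = None,
    study_id: str | None = None,
) -> SessionDesign:
    """Read a block table (TSV or JSON) into a validated :class:`SessionDesign`.

    TSV files need the header ``onset<TAB>duration<TAB>condition``; JSON files
    hold a list of ``{"onset": ..., "duration": ..., "condition": ...}``
    records, optionally wrapped in ``{"blocks": [...], "acquisition": {...}}``.
    Acquisition metadata comes from (in order of precedence) the
    ``acquisition`` argument, a YAML/JSON ``sidecar`` file, or the JSON
    wrapper.  Overlapping blocks are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sidecar is not None:
        acquisition = _load_sidecar(Path(sidecar))

    if path.suffix == ".json":
        blocks, acq_inline = _parse_json(path)
    else:
        blocks, acq_inline = _parse_tsv(path), None
    if acquisition is None:
        acquisition = acq_inline
    if acquisition is None:
        # fall back: enough volumes to cover the blocks at TR = 1 s
        end = max(b.end for b in blocks)
        acquisition = AcquisitionParams(tr=1.0, n_volumes=int(-(-end // 1)))
    return SessionDesign(
        study_id=study_id or path.stem,
        blocks=tuple(blocks),
        acquisition=acquisition,
    )


def _parse_tsv(path: Path) -> list[Block]:
    lines = path.read_text().splitlines()
    if not lines:
        raise DesignParseError(f"{path}: empty design file")
    header = tuple(h.strip() for h in lines[0].split("\t"))
    if header[: len(_TSV_COLUMNS)] != _TSV_COLUMNS:
        raise DesignParseError(
            f"{path}:1: expected header {'	'.join(_TSV_COLUMNS)!r}, got {lines[0]!r}"
        )
    blocks: list[Block] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise DesignParseError(f"{path}:{lineno}: expected 3 columns")
        try:
            blocks.append(
                Block(
                    condition=parts[2].strip(),
                    onset=float(parts[0]),
                    duration=float(parts[1]),
                )
            )
        except ValueError as exc:
            raise DesignParseError(f"{path}:{lineno}: {exc}") from exc
    if not blocks:
        raise DesignParseError(f"{path}: no block rows")
    return blocks


def _parse_json(path: Path) -> tuple[list[Block], AcquisitionParams | None]:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise DesignParseError(f"{path}:{exc.lineno}: {exc.msg}") from exc
    acq = None
    if isinstance(payload, dict):
        if "acquisition" in payload:
            a = payload["acquisition"]
            acq = AcquisitionParams(
                tr=float(a["tr"]),
                n_volumes=int(a["n_volumes"]),
                voxel_size=tuple(a.get("voxel_size", (3.0, 3.0, 3.0))),
                fwhm_smooth=float(a.get("fwhm", 8.0)),
            )
        payload = payload.get("blocks", [])
    if not isinstance(payload, list) or not payload:
        raise DesignParseError(f"{path}: no block records")
    blocks = [
        Block(condition=str(r["condition"]), onset=float(r["onset"]),
              duration=float(r["duration"]))
        for r in payload
    ]
    return blocks, acq


def write_design(design: SessionDesign, path: str | Path) -> Path:
    """Write the block table as TSV (round-trips with :func:`load_design`)."""
    path = Path(path)
    rows = ["\t".join(_TSV_COLUMNS)]
    for b in design.blocks:
        rows.append(f"{b.onset:g}\t{b.duration:g}\t{b.condition}")
    path.write_text("\n".join(rows) + "\n")
    return path


# ---------------------------------------------------------------------------
# canonical designs
# ---------------------------------------------------------------------------

def _layout(study_id: str, pattern: Iterable[tuple[str, float]],
            acquisition: AcquisitionParams,
            condition_groups: dict[str, str]) -> SessionDesign:
    blocks, t = [], 0.0
    for condition, duration in pattern:
        blocks.append(Block(condition=condition, onset=t, duration=duration))
        t += duration
    return SessionDesign(
        study_id=study_id,
        blocks=tuple(blocks),
        acquisition=acquisition,
        condition_groups=condition_groups,
    )


def canonical_designs(tr: float = 1.0) -> tuple[SessionDesign, SessionDesign, SessionDesign]:
    """The three built-in blocked designs (sentence, word, theory-of-mind).

    * ``sentence`` — 8 task blocks of six 6-s trials (36 s each; four
      pun-sentence and four literal-sentence blocks) interleaved with five
      24-s fixation blocks.
    * ``word`` — nine 30-s judgment blocks (three each of self / other /
      case judgments) interleaved with seven 15-s fixation blocks, every
      fixation block followed by a task block.
    * ``tom`` — four cartoon-vignette blocks built from 11-s trials
      (11 physical + 11 intentional attributions) interleaved with five
      24-s fixation epochs.

    Together the three designs contain 17 rest blocks (120 + 105 + 120
    rest seconds).  Exact block orderings are not part of the published
    timing and are fixed here arbitrarily but deterministically.
    """
    trial = 5.0 + 1.0  # 5000 ms sentence + 1000 ms inter-trial interval
    sentence_task = 6 * trial  # 36 s
    sentence_pattern: list[tuple[str, float]] = []
    order = ["pun", "literal", "pun", "literal", "pun", "literal", "pun", "literal"]
    for i in range(4):
        sentence_pattern.append((REST, 24.0))
        sentence_pattern.append((order[2 * i], sentence_task))
        sentence_pattern.append((order[2 * i + 1], sentence_task))
    sentence_pattern.append((REST, 24.0))
    sentence = _layout(
        "sentence",
        sentence_pattern,
        AcquisitionParams(tr=tr, n_volumes=int(round(408 / tr))),
        {"pun": "language", "literal": "language"},
    )

    word_conditions = ["self", "other", "case"] * 3
    word_pattern = []
    for cond in word_conditions[:7]:
        word_pattern.append((REST, 15.0))
        word_pattern.append((cond, 30.0))
    for cond in word_conditions[7:]:
        word_pattern.append((cond, 30.0))
    word = _layout(
        "word",
        word_pattern,
        AcquisitionParams(tr=tr, n_volumes=int(round(375 / tr))),
        {"self": "self_other", "other": "self_other", "case": "self_other"},
    )

    vignette = 11.0
    tom_pattern = [
        (REST, 24.0), ("physical", 6 * vignette),
        (REST, 24.0), ("intentional", 5 * vignette),
        (REST, 24.0), ("physical", 5 * vignette),
        (REST, 24.0), ("intentional", 6 * vignette),
        (REST, 24.0),
    ]
    tom = _layout(
        "tom",
        tom_pattern,
        AcquisitionParams(tr=tr, n_volumes=int(round(362 / tr))),
        {"physical": "tom", "intentional": "tom"},
    )
    return sentence, word, tom


def with_acquisition(design: SessionDesign, acquisition: AcquisitionParams) -> SessionDesign:
    return replace(design, acquisition=acquisition)
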