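"""Synthetic two-group cohort generator with planted DMN effects.

Builds a fully synthetic stand-in for a 13 + 14 subject blocked-design
study: for each subject and each of the three canonical runs, DMN node
signals are drawn from a zero-mean Gaussian process with the group's
target correlation matrix; task blocks add an HRF-convolved boxcar scaled
by per-node deactivation amplitudes (negative during task for DMN nodes,
less negative in the "asd" group); linear drift, motion-coupled, global
and white-noise components are added on top.

Two output modes:

* ``roi`` — each run is a 2D ``(roi, t)`` array: node ROIs first, then
  independent pseudo-ROIs, 116 rows total so that the 116 -> 102 exclusion
  bookkeeping can be exercised without the real anatomical atlas.
* ``voxel`` — node signals are painted into spherical regions of a small
  MNI-like labelled grid (default 30 x 36 x 30 voxels at 6 mm isotropic),
  with an affine chosen so the printed seed coordinates fall inside their
  node spheres.

Identical specs and seeds reproduce bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .study_design import SessionDesign, write_design
from .rest_extraction import BoldRun
from .deactivation_glm import build_design_matrix

__all__ = [
    "SyntheticGrid",
    "NodeSpec",
    "CohortSpec",
    "SyntheticSubject",
    "default_nodes",
    "nearest_correlation_psd",
    "make_dmn_cohort_spec",
    "generate_cohort",
    "default_exclusion",
    "GROUP_A",
    "GROUP_B",
    "voxel_atlas",
    "roi_atlas_ids",
    "tissue_masks",
    "write_cohort",
]

N_ATLAS_LABELS = 116
N_EXCLUDED_LABELS = 14

GROUP_A = "asd"      # reduced MPFC coupling, weaker deactivation
GROUP_B = "control"


@dataclass(frozen=True)
class SyntheticGrid:
    """MNI-like voxel grid for the synthetic brain."""

    shape: tuple[int, int, int] = (30, 36, 30)
    voxel_size: float = 6.0
    origin: tuple[float, float, float] = (-90.0, -126.0, -72.0)

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        aff[:3, 3] = self.origin
        return aff

    @classmethod
    def coarse(cls) -> "SyntheticGrid":
        """Quarter-resolution grid for replicate-heavy simulation tests."""
        return cls(shape=(15, 18, 15), voxel_size=12.0)

    def voxel_centers_mm(self) -> np.ndarray:
        idx = np.indices(self.shape).reshape(3, -1)
        return (idx * self.voxel_size + np.asarray(self.origin)[:, None])

    def brain_mask(self) -> np.ndarray:
        """Ellipsoid inscribed in the grid bounding box."""
        idx = np.indices(self.shape).astype(float)
        half = (np.asarray(self.shape) - 1) / 2.0
        d2 = sum(((idx[i] - half[i]) / (half[i] + 0.5)) ** 2 for i in range(3))
        return d2 <= 1.0


@dataclass(frozen=True)
class NodeSpec:
    """A DMN node: labelled sphere in mm space."""

    name: str
    center_mni: tuple[float, float, float]
    radius: float = 9.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"node radius must be > 0, got {self.radius}")


def default_nodes(radius: float = 9.0) -> tuple[NodeSpec, ...]:
    """Four DMN nodes: the three seed locations plus a right STG node."""
    return (
        NodeSpec("MPFC", (-1.0, 47.0, -4.0), radius),
        NodeSpec("PCC", (-5.0, -49.0, 40.0), radius),
        NodeSpec("AG", (-45.0, -67.0, 36.0), radius),
        NodeSpec("STG_R", (66.0, -24.0, 6.0), radius),
    )


@dataclass
class CohortSpec:
    """Everything the generator needs, retained as ground truth."""

    n_group_a: int
    n_group_b: int
    node_set: tuple[NodeSpec, ...]
    corr_a: np.ndarray
    corr_b: np.ndarray
    deact_amp_a: np.ndarray
    deact_amp_b: np.ndarray
    noise_sd: float
    drift_slope: float
    global_amp: float
    motion_coupling: float
    rng_seed: int
    effect_size: float = 0.0
    n_pseudo_rois: int = N_ATLAS_LABELS - 4
    # a subset of pseudo-ROIs loads weakly on the node GP signals so that
    # planted coupling deficits propagate into many matrix entries, as a
    # real network effect would
    n_loaded_pseudo: int = 40
    pseudo_node_loading: float = 0.5

    def __post_init__(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ValueError("need >= 2 subjects per group")
        k = len(self.node_set)
        for name, m in (("corr_a", self.corr_a), ("corr_b", self.corr_b)):
            m = np.asarray(m, dtype=float)
            if m.shape != (k, k):
                raise ValueError(f"{name} must be {k}x{k}")
            if not np.allclose(m, m.T, atol=1e-12):
                raise ValueError(f"{name} must be symmetric")
            if not np.allclose(np.diag(m), 1.0, atol=1e-12):
                raise ValueError(f"{name} must have unit diagonal")
            if np.linalg.eigvalsh(m).min() < -1e-10:
                raise ValueError(f"{name} is not positive semi-definite")
        for name, a in (("deact_amp_a", self.deact_amp_a),
                        ("deact_amp_b", self.deact_amp_b)):
            if np.asarray(a).shape != (k,):
                raise ValueError(f"{name} must have one amplitude per node")
        names = [n.name for n in self.node_set]
        if len(set(names)) != k:
            raise ValueError("node names must be unique")
        for i in range(k):
            for j in range(i + 1, k):
                d = np.linalg.norm(
                    np.asarray(self.node_set[i].center_mni)
                    - np.asarray(self.node_set[j].center_mni)
                )
                if d <= self.node_set[i].radius + self.node_set[j].radius:
                    raise ValueError(
                        f"nodes {names[i]} and {names[j]} overlap "
                        f"(centers {d:.1f} mm apart)"
                    )

    @property
    def n_nodes(self) -> int:
        return len(self.node_set)

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.node_set)

    def group_params(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        if group == GROUP_A:
            return np.asarray(self.corr_a, float), np.asarray(self.deact_amp_a, float)
        if group == GROUP_B:
            return np.asarray(self.corr_b, float), np.asarray(self.deact_amp_b, float)
        raise ValueError(f"unknown group {group!r}")


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    runs: list[BoldRun]
    motion: list[np.ndarray]  # per run, (n_volumes, 6)
    truth: dict


def nearest_correlation_psd(matrix: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Eigenvalue-clip projection to the PSD cone, re-normalized to unit
    diagonal."""
    m = np.asarray(matrix, dtype=float)
    w, v = np.linalg.eigh((m + m.T) / 2.0)
    w = np.clip(w, eps, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(out), 1e-12, None))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


_BASE_COUPLING = {
    ("MPFC", "PCC"): 0.6,
    ("MPFC", "AG"): 0.5,
    ("MPFC", "STG_R"): 0.4,
    ("PCC", "AG"): 0.6,
    ("PCC", "STG_R"): 0.4,
    ("AG", "STG_R"): 0.4,
}


def make_dmn_cohort_spec(
    effect_size: float,
    seed: int,
    n_group_a: int = 13,
    n_group_b: int = 14,
    node_radius: float = 9.0,
    deact_amp_a: float = -0.4,
    deact_amp_b: float = -1.0,
    noise_sd: float = 0.3,
    drift_slope: float = 0.002,
    global_amp: float = 0.2,
    motion_coupling: float = 0.2,
    n_pseudo_rois: int = N_ATLAS_LABELS - 4,
) -> CohortSpec:
    """Cohort spec with a planted MPFC-coupling deficit of ``effect_size``.

    The control-like group (``corr_b``) has strong anterior-posterior
    coupling; ``corr_a`` equals ``corr_b`` with every MPFC-row coupling
    reduced by ``effect_size`` and the result projected back to the
    nearest PSD correlation matrix.
    """
    if not 0 <= effect_size < 1:
        raise ValueError(f"effect_size must be in [0, 1), got {effect_size}")
    nodes = default_nodes(radius=node_radius)
    names = [n.name for n in nodes]
    k = len(nodes)
    corr_b = np.eye(k)
    for (a, b), rho in _BASE_COUPLING.items():
        i, j = names.index(a), names.index(b)
        corr_b[i, j] = corr_b[j, i] = rho
    corr_a = corr_b.copy()
    mpfc = names.index("MPFC")
    for j in range(k):
        if j != mpfc:
            corr_a[mpfc, j] -= effect_size
            corr_a[j, mpfc] -= effect_size
    corr_a = nearest_correlation_psd(corr_a)
    if np.linalg.eigvalsh(corr_a).min() < -1e-10:
        raise ValueError(
            f"effect_size {effect_size} leaves corr_a non-PSD after projection"
        )
    return CohortSpec(
        n_group_a=n_group_a,
        n_group_b=n_group_b,
        node_set=nodes,
        corr_a=corr_a,
        corr_b=corr_b,
        deact_amp_a=np.full(k, float(deact_amp_a)),
        deact_amp_b=np.full(k, float(deact_amp_b)),
        noise_sd=float(noise_sd),
        drift_slope=float(drift_slope),
        global_amp=float(global_amp),
        motion_coupling=float(motion_coupling),
        rng_seed=int(seed),
        effect_size=float(effect_size),
        n_pseudo_rois=int(n_pseudo_rois),
    )


# ---------------------------------------------------------------------------
# signal generation
# ---------------------------------------------------------------------------

def _gp_factor(corr: np.ndarray) -> np.ndarray:
    """Factor L with L L' = corr (eigendecomposition; works for PSD)."""
    w, v = np.linalg.eigh(corr)
    return v * np.sqrt(np.clip(w, 0.0, None))


def _task_regressor(design: SessionDesign) -> np.ndarray:
    """Sum of HRF-convolved task (non-rest) boxcars, plateau ~1."""
    X = build_design_matrix(design)
    total = np.zeros(design.acquisition.n_volumes)
    for name in X.condition_names:
        if name != "rest":
            total += X.matrix[:, X.column_names.index(name)]
    return total


def _motion_params(rng: np.random.Generator, n_volumes: int) -> np.ndarray:
    """Slow random-walk rigid-body parameters, (t, 6)."""
    steps = rng.standard_normal((n_volumes, 6)) * 0.02
    return np.cumsum(steps, axis=0)


def _run_components(
    rng: np.random.Generator,
    spec: CohortSpec,
    design: SessionDesign,
    corr: np.ndarray,
    amps: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Node signals (k, t), shared additive series (t,), motion (t, 6),
    pseudo-ROI base signals (n_pseudo, t)."""
    T = design.acquisition.n_volumes
    k = spec.n_nodes
    L = _gp_factor(corr)
    node_base = L @ rng.standard_normal((k, T))
    task = _task_regressor(design)
    nodes = node_base + amps[:, None] * task[None, :]

    motion = _motion_params(rng, T)
    rms = np.sqrt(np.mean(motion**2, axis=1))
    rms_sd = rms.std()
    motion_component = spec.motion_coupling * (
        (rms - rms.mean()) / rms_sd if rms_sd > 0 else np.zeros(T)
    )
    drift = spec.drift_slope * (np.arange(T) - T / 2.0)
    global_sig = spec.global_amp * rng.standard_normal(T)
    shared = drift + motion_component + global_sig

    pseudo = rng.standard_normal((spec.n_pseudo_rois, T))
    n_loaded = min(spec.n_loaded_pseudo, spec.n_pseudo_rois)
    w = spec.pseudo_node_loading
    if n_loaded and abs(w) > 0:
        hosts = np.arange(n_loaded) % k  # cycle pseudo-ROIs over nodes
        pseudo[:n_loaded] = (
            np.sqrt(1.0 - w**2) * pseudo[:n_loaded] + w * node_base[hosts]
        )
    return nodes, shared, motion, pseudo


def roi_atlas_ids(spec: CohortSpec) -> tuple[int, ...]:
    """ROI-mode label ids: nodes 1..k, pseudo-ROIs k+1..k+n_pseudo."""
    return tuple(range(1, spec.n_nodes + spec.n_pseudo_rois + 1))


def default_exclusion(spec: CohortSpec) -> tuple[int, ...]:
    """The last 14 pseudo-ROI labels, mimicking the 116 -> 102 exclusion."""
    ids = roi_atlas_ids(spec)
    return ids[-N_EXCLUDED_LABELS:]


def voxel_atlas(spec: CohortSpec, grid: SyntheticGrid) -> np.ndarray:
    """Integer-labelled synthetic atlas: node spheres 1..k, remaining brain
    voxels tiled into pseudo-ROI labels."""
    atlas = np.zeros(grid.shape, dtype=np.int32)
    centers = grid.voxel_centers_mm()
    brain = grid.brain_mask()
    for i, node in enumerate(spec.node_set, start=1):
        d2 = ((centers - np.asarray(node.center_mni)[:, None]) ** 2).sum(axis=0)
        sphere = (d2 <= node.radius**2).reshape(grid.shape)
        if not sphere.any():
            raise ValueError(
                f"node {node.name!r} at {node.center_mni} contains no voxel "
                f"center on grid {grid.shape} at {grid.voxel_size} mm"
            )
        atlas[sphere] = i
        brain &= ~sphere
    rest_idx = np.flatnonzero(brain.ravel())
    tiles = np.array_split(rest_idx, spec.n_pseudo_rois)
    flat = atlas.ravel()
    for j, tile in enumerate(tiles, start=spec.n_nodes + 1):
        flat[tile] = j
    return atlas


def tissue_masks(spec_or_n, grid: SyntheticGrid | None = None) -> dict[str, np.ndarray]:
    """Deterministic gm/wm/csf/brain masks.

    Voxel mode (grid given): partition the brain ellipsoid by distance from
    the grid center — inner core = csf, middle shell = wm, outer shell = gm.
    ROI mode (int given): partition the feature axis into contiguous runs.
    """
    if grid is not None:
        brain = grid.brain_mask()
        idx = np.indices(grid.shape).astype(float)
        half = (np.asarray(grid.shape) - 1) / 2.0
        d2 = sum(((idx[i] - half[i]) / (half[i] + 0.5)) ** 2 for i in range(3))
        # partitions deliberately leave gaps so the brain mean is not an
        # exact linear combination of the tissue means
        csf = brain & (d2 <= 0.04)
        wm = brain & (d2 > 0.08) & (d2 <= 0.4)
        gm = brain & (d2 > 0.45)
        return {"gm": gm, "wm": wm, "csf": csf, "brain": brain}
    n = int(spec_or_n)
    brain = np.ones(n, dtype=bool)
    gm = np.zeros(n, dtype=bool)
    wm = np.zeros(n, dtype=bool)
    csf = np.zeros(n, dtype=bool)
    gm[: int(0.55 * n)] = True
    wm[int(0.6 * n): int(0.85 * n)] = True
    csf[int(0.9 * n):] = True
    return {"gm": gm, "wm": wm, "csf": csf, "brain": brain}


def generate_cohort(
    spec: CohortSpec,
    designs: tuple[SessionDesign, ...],
    mode: str = "roi",
    grid: SyntheticGrid | None = None,
) -> list[SyntheticSubject]:
    """Generate all subjects for the cohort.

    ``mode='roi'`` yields 2D ``(116, t)`` runs (nodes first); ``'voxel'``
    paints node signals into spheres of a labelled grid and returns 4D
    runs with affine, brain mask and float32 data.  Per-subject RNG streams
    are derived from ``spec.rng_seed`` so outputs are reproducible and
    independent of generation order.
    """
    if mode not in ("roi", "voxel"):
        raise ValueError(f"mode must be 'roi' or 'voxel', got {mode!r}")
    if mode == "voxel":
        grid = grid or SyntheticGrid()
        atlas = voxel_atlas(spec, grid)  # validates node placement
        brain = grid.brain_mask() | (atlas > 0)

    groups = [GROUP_A] * spec.n_group_a + [GROUP_B] * spec.n_group_b
    subjects: list[SyntheticSubject] = []
    for s_idx, group in enumerate(groups):
        rng = np.random.default_rng(np.random.SeedSequence(spec.rng_seed).spawn(
            spec.n_group_a + spec.n_group_b)[s_idx])
        corr, amps = spec.group_params(group)
        runs: list[BoldRun] = []
        motions: list[np.ndarray] = []
        for r_idx, design in enumerate(designs):
            nodes, shared, motion, pseudo = _run_components(
                rng, spec, design, corr, amps
            )
            T = design.acquisition.n_volumes
            if mode == "roi":
                data = np.empty((spec.n_nodes + spec.n_pseudo_rois, T))
                data[: spec.n_nodes] = nodes
                data[spec.n_nodes:] = pseudo
                data += shared[None, :]
                data += spec.noise_sd * rng.standard_normal(data.shape)
                run = BoldRun(data=data, design=design, run_index=r_idx)
            else:
                vol = rng.standard_normal((*grid.shape, T)).astype(np.float32)
                vol *= spec.noise_sd if spec.noise_sd > 0 else 1e-6
                for i in range(spec.n_nodes):
                    vol[atlas == i + 1] += nodes[i].astype(np.float32)
                bg = brain & (atlas > spec.n_nodes)
                vol[bg] += rng.standard_normal((int(bg.sum()), T)).astype(np.float32)
                vol[brain] += shared.astype(np.float32)[None, :]
                run = BoldRun(
                    data=vol, design=design, affine=grid.affine,
                    brain_mask=brain, run_index=r_idx,
                )
            runs.append(run)
            motions.append(motion)
        subjects.append(
            SyntheticSubject(
                subject_id=f"sub-{s_idx + 1:02d}",
                group=group,
                runs=runs,
                motion=motions,
                truth={
                    "group": group,
                    "corr": corr.tolist(),
                    "deact_amp": amps.tolist(),
                    "effect_size": spec.effect_size,
                    "rng_seed": spec.rng_seed,
                    "subject_index": s_idx,
                },
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# on-disk artifacts
# ---------------------------------------------------------------------------

def write_cohort(
    subjects: list[SyntheticSubject],
    out_dir: str | Path,
    spec: CohortSpec,
    grid: SyntheticGrid | None = None,
) -> Path:
    """Write per-subject runs (NIfTI for voxel mode, TSV for ROI mode),
    motion TSVs, design files and a JSON manifest with ground truth."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "n_group_a": spec.n_group_a,
        "n_group_b": spec.n_group_b,
        "effect_size": spec.effect_size,
        "rng_seed": spec.rng_seed,
        "nodes": [asdict(n) for n in spec.node_set],
        "corr_a": np.asarray(spec.corr_a).tolist(),
        "corr_b": np.asarray(spec.corr_b).tolist(),
        "subjects": [],
    }
    for sub in subjects:
        sdir = out_dir / sub.subject_id
        sdir.mkdir(exist_ok=True)
        entry = {"subject_id": sub.subject_id, "group": sub.group, "runs": []}
        for run, motion in zip(sub.runs, sub.motion):
            stem = f"run-{run.run_index + 1}"
            if run.data.ndim == 4:
                img = nib.Nifti1Image(np.asarray(run.data, dtype=np.float32),
                                      run.affine)
                data_path = sdir / f"{stem}_bold.nii"
                nib.save(img, data_path)
            else:
                data_path = sdir / f"{stem}_roi.tsv"
                np.savetxt(data_path, run.data, delimiter="\t", fmt="%.6g")
            np.savetxt(sdir / f"{stem}_motion.tsv", motion, delimiter="\t",
                       fmt="%.6g")
            write_design(run.design, sdir / f"{stem}_design.tsv")
            with open(sdir / f"{stem}_acq.json", "w") as fh:
                json.dump(
                    {
                        "tr": run.design.acquisition.tr,
                        "n_volumes": run.design.acquisition.n_volumes,
                        "voxel_size": list(run.design.acquisition.voxel_size),
                        "fwhm": run.design.acquisition.fwhm_smooth,
                    },
                    fh, indent=1,
                )
            entry["runs"].append({"data": data_path.name,
                                  "design": f"{stem}_design.tsv",
                                  "motion": f"{stem}_motion.tsv"})
        manifest["subjects"].append(entry)
    with open(out_dir / "cohort.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out_dir / "cohort.json"
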