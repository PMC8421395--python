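"""Trajectory handling: runs, timelines, superposition, equilibration trim."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .structure import Structure
from .topology import NucleosomeTopology

log = logging.getLogger(__name__)


@dataclass
class FrameTimeline:
    """Analysis sampling parameters (ns)."""

    analysis_stride: float = 1.0
    equilibration_fraction: float = 0.0625

    def __post_init__(self) -> None:
        if self.analysis_stride <= 0:
            raise ValueError("analysis_stride must be positive")
        if not 0 <= self.equilibration_fraction < 1:
            raise ValueError("equilibration_fraction must be in [0, 1)")


@dataclass
class Run:
    """One simulation run: shared structure + per-frame coordinates.

    ``times`` are absolute (ns), strictly increasing and uniformly spaced;
    they are kept absolute through equilibration trimming.
    """

    structure: Structure
    coords: np.ndarray
    times: np.ndarray
    label: str = ""
    run_length_ns: float | None = None
    equilibration_trimmed: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.structure.n_atoms:
            raise ValueError("coords must be (n_frames, n_atoms, 3) matching the structure")
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times length must match frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if self.run_length_ns is None:
            dt = self.times[1] - self.times[0] if len(self.times) > 1 else 0.0
            self.run_length_ns = float(self.times[-1] - self.times[0] + dt)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


@dataclass
class TrajectoryEnsemble:
    """A set of independent runs sharing one topology."""

    runs: list[Run]
    topology: NucleosomeTopology
    label: str = ""

    def __iter__(self):
        return iter(self.runs)

    def __len__(self) -> int:
        return len(self.runs)


def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares proper rotation R and translation t mapping mobile→ref."""
    cm = mobile.mean(axis=0)
    cr = ref.mean(axis=0)
    h = (mobile - cm).T @ (ref - cr)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d < 0:
        log.info("superposition: reflection optimum rejected, proper-rotation branch used")
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cr - rot @ cm
    return rot, t


def superpose(
    frame: np.ndarray, reference: np.ndarray, selection: np.ndarray
) -> tuple[np.ndarray, float]:
    """Rigid-body fit of ``frame`` onto ``reference`` over ``selection``.

    Least-squares rotation + translation (no reflection) minimising the
    RMSD of the selected atoms; all atoms are transformed, the returned
    RMSD is over the selection only.
    """
    selection = np.asarray(selection, dtype=int)
    if len(selection) < 3:
        raise ValueError("superposition needs at least 3 selection atoms")
    mob_sel = frame[selection]
    ref_sel = reference[selection]
    centered = mob_sel - mob_sel.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("selection atoms are collinear")
    rot, t = _kabsch(mob_sel, ref_sel)
    out = frame @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((out[selection] - ref_sel) ** 2, axis=1))))
    return out, rmsd


def superpose_run(run: Run, reference: np.ndarray, selection: np.ndarray) -> tuple[Run, np.ndarray]:
    """Superpose every frame of a run onto a reference coordinate set."""
    fitted = np.empty_like(run.coords)
    rmsds = np.empty(run.n_frames)
    for i in range(run.n_frames):
        fitted[i], rmsds[i] = superpose(run.coords[i], reference, selection)
    return replace(run, coords=fitted), rmsds


def core_calpha_selection(structure: Structure, topology: NucleosomeTopology) -> np.ndarray:
    """Atom indices of the core Cα atoms named by the topology."""
    keys = set(map(tuple, topology.core_calpha))
    tab = structure.atoms
    mask = (tab["name"] == "CA").to_numpy()
    pair = list(zip(tab["chain"], tab["resnum"]))
    mask &= np.fromiter(((c, r) in keys for c, r in pair), dtype=bool, count=len(tab))
    return np.flatnonzero(mask)


def equilibration_cut_ns(run_length_ns: float, fraction: float = 0.0625) -> float:
    """Equilibration period to discard for a run of the given length.

    200 ns for long (≥4000 ns) runs, 50 ns for ≥800 ns runs, otherwise
    ``floor(fraction × length)`` ns for short toy runs.
    """
    if run_length_ns >= 4000.0:
        return 200.0
    if run_length_ns >= 800.0:
        return 50.0
    return float(np.floor(fraction * run_length_ns))


def trim_equilibration(run: Run, fraction: float = 0.0625) -> Run:
    """Drop the initial conformational-equilibration period of a run.

    Idempotent: a run already trimmed is returned unchanged.  Absolute
    frame times are kept (no re-offsetting).
    """
    if run.equilibration_trimmed:
        return run
    cut = equilibration_cut_ns(run.run_length_ns, fraction)
    if cut >= run.run_length_ns:
        raise ValueError("equilibration cut would remove the whole run")
    t0 = run.times[0]
    keep = run.times >= t0 + cut
    if not keep.any():
        raise ValueError("equilibration cut removed all frames")
    return replace(
        run,
        coords=run.coords[keep],
        times=run.times[keep],
        equilibration_trimmed=True,
        run_length_ns=run.run_length_ns,
    )
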