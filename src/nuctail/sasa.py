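"""Solvent-accessible surface area and tail-imposed DNA occlusion.

Shrake–Rupley SASA: each heavy atom's sphere is inflated by the probe
radius (1.4 Å, a water molecule) and sampled with a deterministic
Fibonacci lattice (960 points by default); a point is accessible when it
lies outside every neighbour's inflated sphere, and the atom's SASA is
the accessible fraction of its inflated-sphere area.

DNA occlusion by histone tails is the per-base-pair difference between
the DNA SASA computed in the full system (DNA + histone cores + tails)
and with the tail atoms deleted (cores retained, so only the tails'
shadow is measured).  The percentage change uses the tail-free SASA as
the denominator, and the occlusion-fraction track counts frames whose
decrease exceeds 20%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import Structure
from .topology import NucleosomeTopology, shl_of
from .trajectory import Run
from .contacts import build_atom_index

log = logging.getLogger(__name__)

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960
OCCLUSION_PCT_THRESHOLD = 0.20
DEFAULT_SASA_STRIDE_NS = 5.0


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (Fibonacci lattice)."""
    if n < 32:
        raise ValueError("need at least 32 sphere points")
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²)."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if len(coords) == 0:
        return np.zeros(0)
    if np.any(radii <= 0):
        raise ValueError("all radii must be positive")
    pts = sphere_points(n_points)
    ext = radii + probe

    # exact duplicates (same centre and radius) are degenerate: the first
    # carries the shared surface, later copies get zero
    _, first_of, inverse = np.unique(
        np.round(np.column_stack([coords, radii[:, None]]), 6),
        axis=0, return_index=True, return_inverse=True,
    )
    canonical = first_of[inverse]
    unique_idx = np.flatnonzero(canonical == np.arange(len(coords)))

    tree = cKDTree(coords[unique_idx])
    sasa = np.zeros(len(coords))
    for i in unique_idx:
        nbrs = [
            unique_idx[j]
            for j in tree.query_ball_point(coords[i], r=ext[i] + ext.max())
            if unique_idx[j] != i
        ]
        surface = coords[i] + ext[i] * pts
        if nbrs:
            nb = np.asarray(nbrs, dtype=int)
            d2 = ((surface[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (ext[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        sasa[i] = frac * 4.0 * np.pi * ext[i] ** 2
    return sasa


@dataclass
class SasaFrameRecord:
    """Per-bp DNA SASA of one frame, with and without tail atoms."""

    time: float
    sasa_with_tails: np.ndarray
    sasa_without_tails: np.ndarray
    probe_radius: float = DEFAULT_PROBE_RADIUS
    sphere_points: int = DEFAULT_N_POINTS

    @property
    def delta(self) -> np.ndarray:
        return self.sasa_without_tails - self.sasa_with_tails


def dna_sasa_with_without_tails(
    structure: Structure,
    coords: np.ndarray,
    topology: NucleosomeTopology,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    time: float = 0.0,
) -> SasaFrameRecord:
    """Per-bp DNA SASA of a frame in the full system vs. tails deleted.

    The tail-free reference retains the histone cores; deleting whole
    histones would inflate ΔSASA wherever DNA wraps the octamer.
    """
    idx = build_atom_index(structure, topology)
    if len(idx.tail_atom_idx) == 0:
        raise ValueError("structure contains no tail atoms for this topology")
    heavy = np.flatnonzero(structure.heavy_mask())
    radii_all = structure.atoms["vdw_radius"].to_numpy()

    def per_bp(atom_subset: np.ndarray) -> np.ndarray:
        sasa = shrake_rupley_sasa(coords[atom_subset], radii_all[atom_subset], probe, n_points)
        pos_of = {a: k for k, a in enumerate(atom_subset)}
        out = np.zeros(topology.n_bp)
        for a, b in zip(idx.dna_atom_idx, idx.dna_atom_bp):
            out[b] += sasa[pos_of[a]]
        return out

    tail_set = set(idx.tail_atom_idx.tolist())
    without_subset = np.array([a for a in heavy if a not in tail_set], dtype=int)
    return SasaFrameRecord(
        time=time,
        sasa_with_tails=per_bp(heavy),
        sasa_without_tails=per_bp(without_subset),
        probe_radius=probe,
        sphere_points=n_points,
    )


def sasa_profile(
    runs: list[Run] | Run,
    topology: NucleosomeTopology,
    stride_ns: float = DEFAULT_SASA_STRIDE_NS,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    pct_threshold: float = OCCLUSION_PCT_THRESHOLD,
) -> pd.DataFrame:
    """Tail-imposed DNA occlusion profile over an ensemble.

    Per frame and bp: ΔSASA = SASA(without tails) − SASA(with tails) and
    %change = ΔSASA / SASA(without tails); frames with %change above the
    threshold feed the occlusion-fraction track.  Per-run means are
    averaged with SEM across runs.  Base pairs with a zero tail-free
    SASA in a frame are excluded from the percentage statistics (logged).
    """
    if isinstance(runs, Run):
        runs = [runs]
    per_run_dsasa, per_run_pct, per_run_occl = [], [], []
    for run in runs:
        dt = run.times[1] - run.times[0] if run.n_frames > 1 else stride_ns
        step = max(1, int(round(stride_ns / dt)))
        frames = np.arange(0, run.n_frames, step)
        if len(frames) == 0:
            raise ValueError("run has no frames at the requested stride")
        ds, pc, oc = [], [], []
        for f in frames:
            rec = dna_sasa_with_without_tails(
                run.structure, run.coords[f], topology, probe, n_points, time=run.times[f]
            )
            delta = rec.delta
            denom = rec.sasa_without_tails
            with np.errstate(invalid="ignore", divide="ignore"):
                pct = np.where(denom > 0, delta / denom, np.nan)
            if np.any(denom == 0):
                log.info("frame %.1f ns: %d bp with zero tail-free SASA excluded",
                         rec.time, int((denom == 0).sum()))
            ds.append(delta)
            pc.append(pct)
            oc.append(pct > pct_threshold)
        per_run_dsasa.append(np.mean(ds, axis=0))
        per_run_pct.append(np.nanmean(pc, axis=0))
        per_run_occl.append(np.mean(oc, axis=0))
    d = np.asarray(per_run_dsasa)
    n = d.shape[0]
    off = topology.bp_offsets
    return pd.DataFrame(
        {
            "bp_offset": off,
            "shl": shl_of(off),
            "mean_dsasa": d.mean(axis=0),
            "sem_dsasa": d.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            "mean_pct_change": np.asarray(per_run_pct).mean(axis=0),
            "occlusion_fraction": np.asarray(per_run_occl).mean(axis=0),
            "n": n,
        }
    )
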