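"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators:

* two-state binding/unbinding kinetics per tail residue (exact
  continuous-time Gillespie, optional shared tail-level latent state that
  modulates residue on-rates to mimic cooperative full-tail binding);
* toy nucleosome trajectories — a 187-bp superhelical DNA path (147-bp
  core + 2×20-bp linkers), core histone Cα beads, and one-bead-per-residue
  tail chains whose frame-by-frame placement realises a prescribed
  bound/unbound state matrix exactly (bound beads sit 3.5 Å from their
  target base pair, unbound beads ≥ 8 Å from all DNA);
* MNase-seq fragment sets with planted dyads and uniform background;
* toy nucleosome–partner complexes with pseudo-atom footprints on chosen
  base pairs and, optionally, on tail or core residues.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure import Structure
from .topology import NucleosomeTopology, TailDefinition, DEFAULT_TAIL_RANGES
from .trajectory import Run, TrajectoryEnsemble

# ---------------------------------------------------------------------------
# two-state kinetics


@dataclass
class TwoStateKineticsSpec:
    """Per-residue two-state binding kinetics parameters.

    Rates are ns⁻¹.  With ``coupling="shared-latent"`` a tail-level
    two-state chain gates the residues: while the latent state is
    unbound, residue on-rates are multiplied by ``latent_off_factor``.
    """

    n_residues: int
    k_on: float
    k_off: float
    total_time: float
    dt: float = 1.0
    seed: int = 0
    coupling: str | None = None
    latent_k_on: float = 0.01
    latent_k_off: float = 0.002
    latent_off_factor: float = 0.02

    def __post_init__(self) -> None:
        rates = [self.k_on, self.k_off]
        if self.coupling == "shared-latent":
            rates += [self.latent_k_on, self.latent_k_off]
        elif self.coupling is not None:
            raise ValueError(f"unknown coupling {self.coupling!r}")
        if any(r <= 0 for r in rates):
            raise ValueError("all rates must be positive")
        if self.total_time <= 0 or self.dt <= 0:
            raise ValueError("total_time and dt must be positive")
        if self.dt > 1.0 / (10.0 * max(rates)):
            raise ValueError("dt too coarse for the fastest rate (need dt <= 1/(10 max(k)))")


@dataclass
class TwoStateSimResult:
    """Discretised states plus the exact continuous-time ground truth."""

    times: np.ndarray                 # (n_frames,) ns
    states: np.ndarray                # (n_frames, n_residues) bool
    true_bound_intervals: list[np.ndarray]  # per residue, (k, 2) start/end ns
    latent_states: np.ndarray | None  # (n_frames,) bool when coupled
    spec: TwoStateKineticsSpec


def _gillespie_two_state(
    rng: np.random.Generator,
    k_on: float,
    k_off: float,
    total: float,
    latent: list[tuple[float, float, bool]] | None = None,
    off_factor: float = 1.0,
) -> tuple[bool, np.ndarray]:
    """Exact two-state chain with piecewise-constant on-rate modulation.

    Returns the initial state and the sorted transition times.  Crossing
    a latent-interval boundary resamples the exponential waiting time at
    the new rate, which is exact by memorylessness.
    """
    k_on0 = k_on * (1.0 if (latent is None or latent[0][2]) else off_factor)
    p_bound = k_on0 / (k_on0 + k_off)
    state = bool(rng.random() < p_bound)
    intervals = latent if latent is not None else [(0.0, total, True)]
    transitions = []
    t = 0.0
    li = 0
    while t < total:
        t_hi = min(intervals[li][1], total)
        rate = k_off if state else k_on * (1.0 if intervals[li][2] else off_factor)
        dwell = rng.exponential(1.0 / rate)
        if t + dwell < t_hi:
            t += dwell
            transitions.append(t)
            state = not state
        else:
            t = t_hi
            if li + 1 < len(intervals):
                li += 1
            elif t >= total:
                break
    init = state if len(transitions) % 2 == 0 else not state
    return init, np.asarray(transitions)


def _discretize(init: bool, transitions: np.ndarray, times: np.ndarray) -> np.ndarray:
    flips = np.searchsorted(transitions, times, side="right")
    return (flips % 2 == 1) != init  # init XOR odd-number-of-flips


def _bound_intervals(init: bool, transitions: np.ndarray, total: float) -> np.ndarray:
    edges = np.concatenate([[0.0], transitions, [total]])
    out = []
    state = init
    for a, b in zip(edges[:-1], edges[1:]):
        if state:
            out.append((a, b))
        state = not state
    return np.asarray(out).reshape(-1, 2)


def simulate_two_state_series(spec: TwoStateKineticsSpec) -> TwoStateSimResult:
    """Simulate per-residue bound/unbound series on the analysis grid.

    Initial states are drawn from the stationary distribution of the
    rates at t = 0.  The exact event list (continuous-time bound
    intervals, trajectory-truncated at both ends) is returned alongside
    the discretised matrix.
    """
    rng = np.random.default_rng(spec.seed)
    n_frames = int(np.floor(spec.total_time / spec.dt))
    times = spec.dt * np.arange(n_frames)

    latent_intervals = None
    latent_disc = None
    if spec.coupling == "shared-latent":
        init_l, trans_l = _gillespie_two_state(
            rng, spec.latent_k_on, spec.latent_k_off, spec.total_time
        )
        iv = _bound_intervals(init_l, trans_l, spec.total_time)
        edges = np.concatenate([[0.0], trans_l, [spec.total_time]])
        state = init_l
        latent_intervals = []
        for a, b in zip(edges[:-1], edges[1:]):
            latent_intervals.append((a, b, state))
            state = not state
        latent_disc = _discretize(init_l, trans_l, times)

    states = np.zeros((n_frames, spec.n_residues), dtype=bool)
    events = []
    for r in range(spec.n_residues):
        init, trans = _gillespie_two_state(
            rng, spec.k_on, spec.k_off, spec.total_time,
            latent=latent_intervals, off_factor=spec.latent_off_factor,
        )
        states[:, r] = _discretize(init, trans, times)
        events.append(_bound_intervals(init, trans, spec.total_time))
    return TwoStateSimResult(
        times=times, states=states, true_bound_intervals=events,
        latent_states=latent_disc, spec=spec,
    )


# ---------------------------------------------------------------------------
# toy nucleosome geometry

#: Default tail target centres (bp_offset) for copy 1; copy 2 is mirrored.
DEFAULT_TAIL_TARGETS = {
    "H3": -70,      # linker / SHL −7 entry
    "H4": 21,       # SHL +2
    "H2A_N": -42,   # SHL −4
    "H2A_C": 73,    # SHL +7
    "H2B": -21,     # SHL −2
}

_TAIL_CHAINS = {"H3": ("A", "E"), "H4": ("B", "F"), "H2A_N": ("C", "G"),
                "H2A_C": ("C", "G"), "H2B": ("D", "H")}
_CORE_RANGES = {"A": (40, 44), "E": (40, 44), "B": (20, 24), "F": (20, 24),
                "C": (50, 54), "G": (50, 54), "D": (30, 34), "H": (30, 34)}


@dataclass
class ToyNucleosomeSpec:
    """Geometry of the bead-model nucleosome.

    DNA follows a superhelical path (radius, pitch, turns over the core);
    one pseudo-atom per strand per bp.  Tails are one-bead-per-residue
    chains at the canonical clip-site lengths; each residue has a target
    base pair spread around the tail's target centre.
    """

    n_core_bp: int = 147
    linker_bp: int = 20
    superhelix_radius: float = 41.9
    superhelix_pitch: float = 25.9
    core_turns: float = 1.65
    strand_offset: float = 1.0
    bound_distance: float = 3.5
    unbound_distance: float = 30.0
    tail_targets: dict = field(default_factory=lambda: dict(DEFAULT_TAIL_TARGETS))
    tail_ranges: dict = field(default_factory=lambda: dict(DEFAULT_TAIL_RANGES))
    mirror_copy2_targets: bool = True  # copy 2 binds the dyad-mirrored region

    @property
    def n_bp(self) -> int:
        return self.n_core_bp + 2 * self.linker_bp

    @property
    def half(self) -> int:
        return (self.n_core_bp - 1) // 2 + self.linker_bp


@dataclass
class ToyNucleosome:
    """Built toy nucleosome: structure, topology and placement tables."""

    structure: Structure
    topology: NucleosomeTopology
    spec: ToyNucleosomeSpec
    tail_atom_indices: np.ndarray     # structure atom index per tail residue (topology order)
    bound_positions: np.ndarray       # (n_tail_res, 3)
    unbound_positions: np.ndarray     # (n_tail_res, 3)
    residue_target_bp: np.ndarray     # bp_offset per tail residue


def _bp_frame(spec: ToyNucleosomeSpec, offset: int) -> tuple[np.ndarray, np.ndarray]:
    """Path point and outward radial unit vector of a bp offset."""
    theta_bp = spec.core_turns * 2.0 * np.pi / (spec.n_core_bp - 1)
    ang = offset * theta_bp
    z = spec.superhelix_pitch * ang / (2.0 * np.pi)
    radial = np.array([np.cos(ang), np.sin(ang), 0.0])
    centre = spec.superhelix_radius * radial + np.array([0.0, 0.0, z])
    return centre, radial


def build_toy_nucleosome(spec: ToyNucleosomeSpec | None = None) -> ToyNucleosome:
    """Construct the bead nucleosome (all tails in unbound positions)."""
    spec = spec or ToyNucleosomeSpec()
    half = spec.half
    offsets = np.arange(-half, half + 1)

    rows, xyz = [], []
    aid = 0

    def add(name, elem, chain, resnum, resname, pos, radius):
        nonlocal aid
        rows.append((aid, name, elem, chain, resnum, resname, True, radius))
        xyz.append(pos)
        aid += 1

    # DNA strands I / J (chains contiguous, as in a real PDB file)
    bp_records = []
    for off in offsets:
        centre, radial = _bp_frame(spec, int(off))
        res_i = int(off) + half + 1
        res_j = 2 * (half + 1) - res_i  # antiparallel numbering
        add("P", "P", "I", res_i, "DA", centre + [0, 0, spec.strand_offset], 1.80)
        bp_records.append((int(off), res_i, res_j))
    for off in offsets:
        centre, _ = _bp_frame(spec, int(off))
        res_j = half + 1 - int(off)
        add("P", "P", "J", res_j, "DT", centre - [0, 0, spec.strand_offset], 1.80)

    # plan tail placements (topology order); a per-tail z offset keeps
    # unbound beads of different tail instances apart even when their
    # target regions coincide (mirrored copies)
    tails = []
    placements = []  # per tail: list of (resnum, bound, unbound, tgt)
    tail_counter = 0
    for tail_id, (c1, c2) in _TAIL_CHAINS.items():
        lo, hi = spec.tail_ranges[tail_id]
        n_res = hi - lo + 1
        for copy, chain in ((1, c1), (2, c2)):
            tails.append(TailDefinition(tail_id=tail_id, copy=copy, chain=chain, start=lo, end=hi))
            sign = 1 if (copy == 1 or not spec.mirror_copy2_targets) else -1
            centre_bp = spec.tail_targets[tail_id] * sign
            z_shift = np.array([0.0, 0.0, (tail_counter - 4.5) * 6.0])
            tail_counter += 1
            beads = []
            for i, resnum in enumerate(range(lo, hi + 1)):
                delta = i - (n_res - 1) // 2
                tgt = int(np.clip(centre_bp + delta * sign, -half, half))
                centre, radial = _bp_frame(spec, tgt)
                strand_i_pos = centre + [0, 0, spec.strand_offset]
                b = strand_i_pos + spec.bound_distance * radial
                u = strand_i_pos + spec.unbound_distance * radial + z_shift
                beads.append((resnum, b, u, tgt))
            placements.append(beads)

    # core bead positions on an inner circle
    core_pos: dict[str, list] = {c: [] for c in _CORE_RANGES}
    n_core_beads = sum(hi - lo + 1 for lo, hi in _CORE_RANGES.values())
    k = 0
    for chain, (lo, hi) in _CORE_RANGES.items():
        for r in range(lo, hi + 1):
            ang = 2.0 * np.pi * k / n_core_beads
            core_pos[chain].append(
                (r, np.array([12.0 * np.cos(ang), 12.0 * np.sin(ang), 10.0 * np.sin(3 * ang)]))
            )
            k += 1

    # emit histone chains contiguously (tail beads, then core beads) so a
    # PDB round trip preserves atom order
    core_calpha = []
    atom_of_bead: dict[tuple[int, int], int] = {}  # (tail idx, bead idx) -> aid
    for chain in sorted(_CORE_RANGES):
        for t_idx, t in enumerate(tails):
            if t.chain != chain:
                continue
            for b_idx, (resnum, b, u, tgt) in enumerate(placements[t_idx]):
                atom_of_bead[(t_idx, b_idx)] = aid
                add("CB", "C", chain, resnum, "ALA", u, 1.70)
        for r, pos in core_pos[chain]:
            add("CA", "C", chain, r, "GLY", pos, 1.70)
            core_calpha.append((chain, r))

    tail_atom_idx, bound_pos, unbound_pos, target_bp = [], [], [], []
    for t_idx, beads in enumerate(placements):
        for b_idx, (resnum, b, u, tgt) in enumerate(beads):
            tail_atom_idx.append(atom_of_bead[(t_idx, b_idx)])
            bound_pos.append(b)
            unbound_pos.append(u)
            target_bp.append(tgt)

    atoms = pd.DataFrame(
        rows,
        columns=["atom_id", "name", "element", "chain", "resnum", "resname", "is_heavy", "vdw_radius"],
    )
    structure = Structure(atoms=atoms, coords=np.asarray(xyz), name="toy-nucleosome")
    topology = NucleosomeTopology(
        dna_chains=("I", "J"),
        base_pairs=pd.DataFrame(bp_records, columns=["bp_offset", "res_i", "res_j"]),
        tails=tails,
        core_calpha=core_calpha,
        n_core_bp=spec.n_core_bp,
        linker_bp=spec.linker_bp,
    )
    toy = ToyNucleosome(
        structure=structure,
        topology=topology,
        spec=spec,
        tail_atom_indices=np.asarray(tail_atom_idx),
        bound_positions=np.asarray(bound_pos),
        unbound_positions=np.asarray(unbound_pos),
        residue_target_bp=np.asarray(target_bp),
    )
    _validate_geometry(toy)
    return toy


def _validate_geometry(toy: ToyNucleosome) -> None:
    """Bound beads must touch their target bp; unbound beads touch nothing."""
    st = toy.structure
    dna_mask = st.atoms["chain"].isin(toy.topology.dna_chains).to_numpy()
    dna_xyz = st.coords[dna_mask]
    # bound check: distance to target bp strand-I atom
    for k, tgt in enumerate(toy.residue_target_bp):
        centre, _ = _bp_frame(toy.spec, int(tgt))
        d = np.linalg.norm(toy.bound_positions[k] - (centre + [0, 0, toy.spec.strand_offset]))
        if d > 4.0:
            raise ValueError("toy geometry infeasible: bound bead misses its target bp")
        dmin = np.linalg.norm(dna_xyz - toy.unbound_positions[k], axis=1).min()
        if dmin < 8.0:
            raise ValueError("toy geometry infeasible: unbound bead within 8 Å of DNA")


def generate_toy_trajectory(
    toy: ToyNucleosome,
    states: np.ndarray,
    stride_ns: float = 1.0,
    t0_ns: float = 0.0,
    label: str = "toy",
    run_length_ns: float | None = None,
) -> Run:
    """Realise a bound/unbound state matrix as a coordinate trajectory.

    ``states`` is (n_frames, n_tail_residues) in topology tail order;
    the resulting run reproduces it exactly under the 4 Å contact rule.
    """
    states = np.asarray(states, dtype=bool)
    n_tail = len(toy.tail_atom_indices)
    if states.ndim != 2 or states.shape[1] != n_tail:
        raise ValueError(f"states must be (n_frames, {n_tail})")
    n_frames = states.shape[0]
    coords = np.repeat(toy.structure.coords[None, :, :], n_frames, axis=0)
    pos = np.where(states[:, :, None], toy.bound_positions[None], toy.unbound_positions[None])
    coords[:, toy.tail_atom_indices, :] = pos
    times = t0_ns + stride_ns * np.arange(n_frames)
    return Run(
        structure=toy.structure, coords=coords, times=times, label=label,
        run_length_ns=run_length_ns,
    )


def toy_kinetic_ensemble(
    toy: ToyNucleosome,
    n_runs: int,
    total_time: float,
    k_on: float,
    k_off: float,
    stride_ns: float = 1.0,
    seed: int = 0,
    coupling: str | None = "shared-latent",
    latent_k_on: float = 0.01,
    latent_k_off: float = 0.002,
    copy_symmetric_states: bool = False,
    label: str = "toy-ensemble",
) -> tuple[TrajectoryEnsemble, list[TwoStateSimResult]]:
    """Ensemble of runs whose tail-bead placement follows two-state kinetics.

    Each tail copy gets an independent shared-latent chain (unless
    ``coupling=None``), so full tails show cooperative binding events.
    With ``copy_symmetric_states`` the second copy replays the first
    copy's state series on its mirrored target region — an idealised,
    perfectly converged two-fold pseudo-symmetric ensemble.
    """
    runs, sims = [], []
    for r in range(n_runs):
        cols, tail_sims = [], []
        copy1_sim: dict[str, TwoStateSimResult] = {}
        for ti, tail in enumerate(toy.topology.tails):
            if copy_symmetric_states and tail.copy == 2:
                sim = copy1_sim[tail.tail_id]
            else:
                spec = TwoStateKineticsSpec(
                    n_residues=tail.n_residues, k_on=k_on, k_off=k_off,
                    total_time=total_time, dt=stride_ns,
                    seed=seed + 1000 * r + ti, coupling=coupling,
                    latent_k_on=latent_k_on, latent_k_off=latent_k_off,
                )
                sim = simulate_two_state_series(spec)
                copy1_sim[tail.tail_id] = sim
            cols.append(sim.states)
            tail_sims.append(sim)
        states = np.hstack(cols)
        runs.append(
            generate_toy_trajectory(
                toy, states, stride_ns=stride_ns, label=f"{label}-{r}",
                run_length_ns=total_time,
            )
        )
        sims.extend(tail_sims)
    return TrajectoryEnsemble(runs=runs, topology=toy.topology, label=label), sims


# ---------------------------------------------------------------------------
# MNase fragments


@dataclass
class MNaseSimSpec:
    """Planted-dyad MNase fragment generator parameters.

    ``dyads`` maps genomic position → intensity weight; midpoint offsets
    around a planted dyad follow a discretised normal (sd
    ``spread_sd`` bp, truncated at ``max_offset``); a ``background``
    fraction of fragments has uniform midpoints over the region.
    """

    chrom: str = "chrS"
    region_start: int = 0
    region_end: int = 2000
    dyads: dict[int, float] = field(default_factory=lambda: {600: 1.0, 1400: 1.0})
    n_fragments: int = 200
    spread_sd: float = 4.0
    max_offset: int = 12
    background: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dyads:
            if self.background < 1.0:
                raise ValueError("need planted dyads unless background-only")
        if any(i <= 0 for i in self.dyads.values()):
            raise ValueError("dyad intensities must be positive")
        if not 0.0 <= self.background <= 1.0:
            raise ValueError("background must be a fraction")


def simulate_mnase_fragments(spec: MNaseSimSpec) -> pd.DataFrame:
    """147-bp fragments whose midpoints mix planted dyads and background."""
    rng = np.random.default_rng(spec.seed)
    half = 147 // 2
    lo, hi = spec.region_start + half, spec.region_end - half - 1
    mids = np.empty(spec.n_fragments, dtype=int)
    is_bg = rng.random(spec.n_fragments) < spec.background
    mids[is_bg] = rng.integers(lo, hi + 1, size=int(is_bg.sum()))
    n_sig = int((~is_bg).sum())
    if n_sig:
        positions = np.array(list(spec.dyads), dtype=int)
        weights = np.array([spec.dyads[p] for p in positions], dtype=float)
        weights /= weights.sum()
        which = rng.choice(len(positions), size=n_sig, p=weights)
        off = np.rint(rng.normal(0.0, spec.spread_sd, size=n_sig)).astype(int)
        off = np.clip(off, -spec.max_offset, spec.max_offset)
        mids[~is_bg] = np.clip(positions[which] + off, lo, hi)
    starts = mids - half
    return pd.DataFrame({"chrom": spec.chrom, "start": starts, "end": starts + 147})


def write_bed(fragments: pd.DataFrame, path) -> None:
    fragments.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# toy complexes


def generate_toy_complex(
    toy: ToyNucleosome,
    footprint_bps: list[int],
    tail_contacts: list[tuple[str, int]] = (),
    core_contact: bool = False,
    partner_chain: str = "Z",
    complex_id: str = "toy-complex",
) -> Structure:
    """Nucleosome + pseudo-atom partner touching the requested entities.

    Partner beads are placed 3.5 Å from the strand-I atom of each
    footprint bp, from the first residue bead of each flagged tail
    (tails sit in their unbound positions), and from one core Cα when
    ``core_contact`` is set.
    """
    half = toy.spec.half
    for b in footprint_bps:
        if not -half <= b <= half:
            raise ValueError(f"footprint bp {b} outside topology range ±{half}")
    st = toy.structure
    rows = st.atoms.copy()
    xyz = [st.coords]
    extra_rows, extra_xyz = [], []
    aid = len(rows)
    resnum = 1

    def add(pos):
        nonlocal aid, resnum
        extra_rows.append((aid, "X1", "C", partner_chain, resnum, "UNK", True, 1.70))
        extra_xyz.append(pos)
        aid += 1
        resnum += 1

    for b in footprint_bps:
        centre, radial = _bp_frame(toy.spec, int(b))
        add(centre + [0, 0, toy.spec.strand_offset] + 3.5 * radial)
    for tail_id, copy in tail_contacts:
        t = toy.topology.tail(tail_id, copy)
        order = [k for k, td in enumerate(toy.topology.tails) if td is t]
        start = sum(td.n_residues for td in toy.topology.tails[: order[0]])
        bead = toy.unbound_positions[start]
        direction = np.array([bead[0], bead[1], 0.0])
        direction /= np.linalg.norm(direction)
        add(bead + 3.5 * direction)
    if core_contact:
        chain, r = toy.topology.core_calpha[0]
        i = st.select(chain=chain, resnums=[r], names="CA")[0]
        pos = st.coords[i]
        add(pos - 3.5 * pos / np.linalg.norm(pos))

    atoms = pd.concat(
        [rows, pd.DataFrame(extra_rows, columns=rows.columns)], ignore_index=True
    )
    coords = np.vstack([st.coords, np.asarray(extra_xyz).reshape(-1, 3)])
    return Structure(atoms=atoms, coords=coords, name=complex_id)
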