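"""Tail–DNA heavy-atom contact analysis.

A contact is a pair of non-hydrogen atoms within the cutoff distance
(4 Å by default, inclusive).  Two aggregation views are maintained:

* per base pair — the number of *distinct tail heavy atoms* within the
  cutoff of any heavy atom of the base pair (either strand);
* per tail residue — the number of *distinct DNA heavy atoms* contacted
  by any heavy atom of the residue; a residue is *bound* in a frame iff
  this number is nonzero.

Profiles average over frames within each run first; run×copy units then
provide the mean ± SEM.  The second histone copy is mapped through the
nucleosome's pseudo-two-fold dyad symmetry (bp_offset → −bp_offset)
before pooling, unless disabled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .structure import Structure
from .topology import NucleosomeTopology, shl_of
from .trajectory import Run, TrajectoryEnsemble

DEFAULT_CUTOFF = 4.0
PREFERRED_REGION_THRESHOLD = 5.0


def atomic_contacts(
    coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float = DEFAULT_CUTOFF
) -> np.ndarray:
    """All (i, j) index pairs with ``|a_i − b_j| ≤ cutoff``.

    Spatial indexing via a k-d tree; matches the all-pairs definition
    exactly (inclusive at the cutoff).  Empty groups yield an empty
    (0, 2) array.
    """
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    if len(coords_a) == 0 or len(coords_b) == 0:
        return np.empty((0, 2), dtype=int)
    tree_b = cKDTree(coords_b)
    lists = cKDTree(coords_a).query_ball_tree(tree_b, r=cutoff)
    counts = [len(l) for l in lists]
    rows = np.repeat(np.arange(len(coords_a)), counts)
    cols = np.concatenate([np.asarray(l, dtype=int) for l in lists if l] or [np.empty(0, dtype=int)])
    return np.column_stack([rows, cols])


@dataclass
class _AtomIndex:
    """Precomputed atom-index maps tying a structure to its topology."""

    dna_atom_idx: np.ndarray          # heavy DNA atoms
    dna_atom_bp: np.ndarray           # bp index per DNA heavy atom
    tail_atom_idx: np.ndarray         # heavy tail atoms
    tail_atom_res: np.ndarray         # global tail-residue index per atom
    tail_atom_tail: np.ndarray        # tail-instance index per atom
    residue_index: pd.DataFrame       # tail_id, copy, chain, resnum, tail_idx


def build_atom_index(structure: Structure, topology: NucleosomeTopology) -> _AtomIndex:
    tab = structure.atoms
    heavy = tab["is_heavy"].to_numpy()
    chain = tab["chain"].to_numpy()
    resnum = tab["resnum"].to_numpy()

    ci, cj = topology.dna_chains
    bp_of: dict[tuple[str, int], int] = {}
    for b, row in enumerate(topology.base_pairs.itertuples(index=False)):
        bp_of[(ci, int(row.res_i))] = b
        bp_of[(cj, int(row.res_j))] = b
    dna_idx, dna_bp = [], []
    for i in range(len(tab)):
        if heavy[i]:
            b = bp_of.get((chain[i], int(resnum[i])))
            if b is not None:
                dna_idx.append(i)
                dna_bp.append(b)

    res_rows = []
    res_of: dict[tuple[str, int], int] = {}
    tail_of_res: list[int] = []
    for t_idx, t in enumerate(topology.tails):
        for r in t.residues:
            res_of[(t.chain, r)] = len(res_rows)
            tail_of_res.append(t_idx)
            res_rows.append((t.tail_id, t.copy, t.chain, r, t_idx))
    tail_idx, tail_res, tail_tail = [], [], []
    for i in range(len(tab)):
        if heavy[i]:
            g = res_of.get((chain[i], int(resnum[i])))
            if g is not None:
                tail_idx.append(i)
                tail_res.append(g)
                tail_tail.append(tail_of_res[g])

    residue_index = pd.DataFrame(
        res_rows, columns=["tail_id", "copy", "chain", "resnum", "tail_idx"]
    )
    return _AtomIndex(
        dna_atom_idx=np.asarray(dna_idx, dtype=int),
        dna_atom_bp=np.asarray(dna_bp, dtype=int),
        tail_atom_idx=np.asarray(tail_idx, dtype=int),
        tail_atom_res=np.asarray(tail_res, dtype=int),
        tail_atom_tail=np.asarray(tail_tail, dtype=int),
        residue_index=residue_index,
    )


@dataclass
class ContactSeries:
    """Per-frame contact state for one run.

    ``residue_ncontacts[f, r]`` — distinct DNA heavy atoms contacted by
    tail residue r in frame f; ``bp_tail_counts[f, t, b]`` — distinct
    heavy atoms of tail instance t within the cutoff of bp b.
    """

    times: np.ndarray
    cutoff: float
    residue_index: pd.DataFrame
    bp_offsets: np.ndarray
    tails: list
    residue_ncontacts: np.ndarray
    bp_tail_counts: np.ndarray
    run_label: str = ""
    run_length_ns: float | None = None

    @property
    def residue_bound(self) -> np.ndarray:
        return self.residue_ncontacts > 0

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def bp_counts(self, copy: int | None = None, tail_id: str | None = None) -> np.ndarray:
        """(n_frames, n_bp) distinct-tail-atom counts, optionally restricted."""
        sel = np.ones(len(self.tails), dtype=bool)
        if copy is not None:
            sel &= np.array([t.copy == copy for t in self.tails])
        if tail_id is not None:
            sel &= np.array([t.tail_id == tail_id for t in self.tails])
        return self.bp_tail_counts[:, sel, :].sum(axis=1)


def compute_contacts(
    run: Run,
    topology: NucleosomeTopology,
    cutoff: float = DEFAULT_CUTOFF,
    stride_ns: float = 1.0,
) -> ContactSeries:
    """Compute the tail–DNA contact time series of one run.

    Frames are sampled every ``stride_ns`` on the run's uniform time
    grid.  Heavy atoms only.
    """
    idx = build_atom_index(run.structure, topology)
    if len(idx.dna_atom_idx) == 0 or len(idx.tail_atom_idx) == 0:
        raise ValueError("topology selects no DNA or no tail heavy atoms")
    dt = run.times[1] - run.times[0] if run.n_frames > 1 else stride_ns
    step = max(1, int(round(stride_ns / dt)))
    frames = np.arange(0, run.n_frames, step)

    n_res = len(idx.residue_index)
    n_tails = len(topology.tails)
    n_bp = topology.n_bp
    residue_nc = np.zeros((len(frames), n_res), dtype=np.int16)
    bp_counts = np.zeros((len(frames), n_tails, n_bp), dtype=np.int16)

    for k, f in enumerate(frames):
        xyz = run.coords[f]
        pairs = atomic_contacts(xyz[idx.tail_atom_idx], xyz[idx.dna_atom_idx], cutoff)
        if len(pairs) == 0:
            continue
        ta, da = pairs[:, 0], pairs[:, 1]
        # distinct DNA atoms per residue
        rb = np.unique(idx.tail_atom_res[ta] * len(idx.dna_atom_idx) + da)
        np.add.at(residue_nc[k], rb // len(idx.dna_atom_idx), 1)
        # distinct tail atoms per (tail instance, bp)
        tb = np.unique(ta * n_bp + idx.dna_atom_bp[da])
        np.add.at(bp_counts[k], (idx.tail_atom_tail[tb // n_bp], tb % n_bp), 1)

    return ContactSeries(
        times=run.times[frames],
        cutoff=cutoff,
        residue_index=idx.residue_index,
        bp_offsets=topology.bp_offsets,
        tails=list(topology.tails),
        residue_ncontacts=residue_nc,
        bp_tail_counts=bp_counts,
        run_label=run.label,
        run_length_ns=run.run_length_ns,
    )


def compute_contacts_ensemble(
    ensemble: TrajectoryEnsemble, cutoff: float = DEFAULT_CUTOFF, stride_ns: float = 1.0
) -> list[ContactSeries]:
    return [compute_contacts(r, ensemble.topology, cutoff, stride_ns) for r in ensemble.runs]


# ---------------------------------------------------------------------------
# profiles


def _unit_profiles(
    series_list: list[ContactSeries],
    tail_id: str | None,
    mirror_copy2: bool,
    copies=(1, 2),
) -> np.ndarray:
    """Per-(run, copy) frame-averaged bp profiles, copy 2 optionally mirrored."""
    units = []
    for s in series_list:
        if s.n_frames == 0:
            raise ValueError("contact series with zero frames")
        for copy in copies:
            prof = s.bp_counts(copy=copy, tail_id=tail_id).mean(axis=0)
            if copy == 2 and mirror_copy2:
                prof = prof[::-1]
            units.append(prof)
    return np.asarray(units)


def _profile_frame(units: np.ndarray, bp_offsets: np.ndarray) -> pd.DataFrame:
    n = units.shape[0]
    mean = units.mean(axis=0)
    sem = units.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full(units.shape[1], np.nan)
    return pd.DataFrame(
        {
            "bp_offset": bp_offsets,
            "shl": shl_of(bp_offsets),
            "mean": mean,
            "sem": sem,
            "n": n,
        }
    )


def per_bp_contact_profile(
    series_list: list[ContactSeries] | ContactSeries,
    tail_id: str | None = None,
    mirror_copy2: bool = True,
) -> pd.DataFrame:
    """Mean tail heavy-atom contacts per base pair, ± SEM over run×copy units.

    Averaging is per run first; the run×copy units are then pooled (copy 2
    mirrored through the dyad unless ``mirror_copy2=False``).  SEM is NaN
    when only one unit is available.
    """
    if isinstance(series_list, ContactSeries):
        series_list = [series_list]
    units = _unit_profiles(series_list, tail_id, mirror_copy2)
    return _profile_frame(units, series_list[0].bp_offsets)


def per_bp_profile_by_tail(
    series_list: list[ContactSeries], mirror_copy2: bool = True
) -> dict[str, pd.DataFrame]:
    """Per-tail-type decomposition of :func:`per_bp_contact_profile`."""
    tail_ids = list(dict.fromkeys(t.tail_id for t in series_list[0].tails))
    return {
        tid: per_bp_contact_profile(series_list, tail_id=tid, mirror_copy2=mirror_copy2)
        for tid in tail_ids
    }


def copy_profile(
    series_list: list[ContactSeries], copy: int, tail_id: str | None = None, mirror: bool = False
) -> np.ndarray:
    """Mean bp profile of a single histone copy (averaged over runs)."""
    units = _unit_profiles(series_list, tail_id, mirror_copy2=mirror, copies=(copy,))
    return units.mean(axis=0)


def preferred_binding_regions(
    profile: pd.DataFrame | dict[str, pd.DataFrame],
    threshold: float = PREFERRED_REGION_THRESHOLD,
) -> set[int] | dict[str, set[int]]:
    """Base pairs with mean tail contacts strictly above the threshold."""
    if isinstance(profile, dict):
        return {k: preferred_binding_regions(v, threshold) for k, v in profile.items()}
    sel = profile["mean"].to_numpy() > threshold
    return set(int(x) for x in profile["bp_offset"].to_numpy()[sel])


def copy_symmetry_correlation(
    profile_copy1: np.ndarray, profile_copy2: np.ndarray, mirror: bool = True
) -> tuple[float, float]:
    """Pearson correlation between the two copies' bp profiles.

    Copy 2 is mirrored through the dyad before comparison (pass
    ``mirror=False`` if already mirrored).  Zero-variance profiles give
    ``(nan, nan)`` with a warning.
    """
    a = np.asarray(profile_copy1, dtype=float)
    b = np.asarray(profile_copy2, dtype=float)[::-1] if mirror else np.asarray(profile_copy2, dtype=float)
    if a.std() == 0 or b.std() == 0:
        warnings.warn("copy-symmetry correlation undefined: zero-variance profile")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def residue_contact_profile(series_list: list[ContactSeries]) -> pd.DataFrame:
    """Mean DNA heavy atoms contacted per tail residue ± SEM over runs.

    Copies are separate rows (``tail_id``, ``copy``, ``resnum``); the
    statistical unit is the run.
    """
    if isinstance(series_list, ContactSeries):
        series_list = [series_list]
    per_run = np.stack([s.residue_ncontacts.mean(axis=0) for s in series_list])
    n = per_run.shape[0]
    out = series_list[0].residue_index[["tail_id", "copy", "resnum"]].copy()
    out["mean"] = per_run.mean(axis=0)
    out["sem"] = per_run.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.nan
    out["n"] = n
    return out


# ---------------------------------------------------------------------------
# ensemble comparison


def _run_level_means(series_list: list[ContactSeries], level: str) -> pd.DataFrame:
    """One row per run, one column per item at the requested level."""
    rows = []
    for s in series_list:
        ri = s.residue_index
        if level == "residue":
            per_res = s.residue_ncontacts.mean(axis=0)
            df = pd.DataFrame({"item": list(zip(ri["tail_id"], ri["resnum"])), "value": per_res})
            row = df.groupby("item", sort=False)["value"].mean()  # pool the two copies
        elif level == "full_tail":
            totals = {}
            for tid in dict.fromkeys(ri["tail_id"]):
                cols = (ri["tail_id"] == tid).to_numpy()
                per_copy = []
                for copy in (1, 2):
                    sel = cols & (ri["copy"] == copy).to_numpy()
                    if sel.any():
                        per_copy.append(s.residue_ncontacts[:, sel].sum(axis=1).mean())
                totals[tid] = float(np.mean(per_copy))
            row = pd.Series(totals)
        elif level == "bp":
            row = pd.Series(s.bp_counts().mean(axis=0), index=s.bp_offsets)
        else:
            raise ValueError(f"unknown comparison level {level!r}")
        rows.append(row)
    return pd.DataFrame(rows)


def compare_contact_profiles(
    series_a: list[ContactSeries],
    series_b: list[ContactSeries],
    level: str = "full_tail",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare contact levels between two ensembles (e.g. wild type vs PTM).

    Independent runs are the statistical units; a Welch two-sample t test
    is applied per item and Benjamini–Hochberg adjusted across items.
    With fewer than two runs on either side, differences are reported and
    the tests are skipped with a warning.
    """
    a = _run_level_means(series_a, level)
    b = _run_level_means(series_b, level)
    items = a.columns
    out = pd.DataFrame(
        {
            "item": items,
            "mean_a": a.mean(axis=0).to_numpy(),
            "mean_b": b.reindex(columns=items).mean(axis=0).to_numpy(),
        }
    )
    out["delta"] = out["mean_b"] - out["mean_a"]
    na, nb = len(a), len(b)
    out["sem_a"] = a.std(axis=0, ddof=1).to_numpy() / np.sqrt(na) if na > 1 else np.nan
    out["sem_b"] = b.std(axis=0, ddof=1).to_numpy() / np.sqrt(nb) if nb > 1 else np.nan
    if na < 2 or nb < 2:
        warnings.warn("fewer than two runs per ensemble: significance test skipped")
        out["p"] = np.nan
        out["p_adj"] = np.nan
        out["significant"] = False
        return out
    pvals = np.array(
        [
            stats.ttest_ind(a[c].to_numpy(), b[c].to_numpy(), equal_var=False).pvalue
            for c in items
        ]
    )
    pvals = np.where(np.isnan(pvals), 1.0, pvals)  # zero-variance ties
    rej, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    out["p"] = pvals
    out["p_adj"] = p_adj
    out["significant"] = rej
    return out


def write_profile_tsv(profile: pd.DataFrame, path) -> None:
    profile.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_profile_bedgraph(profile: pd.DataFrame, path, chrom: str, anchor: int) -> None:
    """Write a bp profile as bedGraph; ``anchor`` is the genomic position of bp 0."""
    with open(path, "w") as fh:
        for row in profile.itertuples(index=False):
            start = anchor + int(row.bp_offset)
            fh.write(f"{chrom}\t{start}\t{start + 1}\t{row.mean:.6g}\n")
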