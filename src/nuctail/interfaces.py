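"""Nucleosome–partner interfaces and tail-footprint overlap.

A partner contacts a base pair or histone residue when at least one
heavy-atom pair lies within the 4 Å cutoff.  Partners are classified by
what they touch (DNA only, histones only, or multivalent with/without
tails), and their DNA footprint is compared with the histone-tail
preferred binding regions: the overlap fraction is the number of shared
base pairs divided by the partner's footprint size, and a single shared
base pair makes the two binding modes mutually exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure import Structure
from .topology import NucleosomeTopology, shl_of
from .contacts import atomic_contacts, DEFAULT_CUTOFF


class StructureRejected(ValueError):
    """Complex structure unusable for interface analysis (with reason)."""


@dataclass
class PartnerInterface:
    """Contacts of one nucleosome-binding partner."""

    complex_id: str
    partner_chains: tuple[str, ...]
    contacted_bps: set[int]                      # bp_offsets
    bp_contact_counts: dict[int, int]            # bp_offset -> partner heavy atoms
    tail_residues: set[tuple[str, int, int]]     # (tail_id, copy, resnum)
    core_residues: set[tuple[str, int]]          # (chain, resnum)

    @property
    def binds_dna(self) -> bool:
        return len(self.contacted_bps) > 0

    @property
    def binds_tails(self) -> bool:
        return len(self.tail_residues) > 0

    @property
    def binds_histone_core(self) -> bool:
        return len(self.core_residues) > 0

    @property
    def tail_ids(self) -> set[str]:
        return {t for t, _, _ in self.tail_residues}


@dataclass
class BindingModeClass:
    """Binding-mode category of a partner."""

    binds_dna: bool
    binds_histone_core: bool
    binds_tails: bool
    tail_ids: frozenset[str]
    category: str


@dataclass
class OverlapResult:
    """Overlap of a partner's DNA footprint with tail preferred regions."""

    fraction_overlap: float
    shared_bp_count: int
    partner_bp_count: int
    mutually_exclusive: bool


def extract_partner_contacts(
    structure: Structure,
    topology: NucleosomeTopology,
    partner_chains: list[str] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    complex_id: str = "",
) -> PartnerInterface:
    """Heavy-atom contact sets between a partner and the nucleosome.

    Partner chains may be declared explicitly; otherwise every chain that
    is neither a DNA strand nor an octamer chain named by the topology is
    taken as partner.  Structures missing any octamer or DNA chain are
    rejected with a reason (incomplete complexes are not comparable in
    the common bp frame).
    """
    chains_present = set(structure.chains)
    octamer_chains = {t.chain for t in topology.tails}
    octamer_chains |= {c for c, _ in topology.core_calpha}
    required = set(topology.dna_chains) | octamer_chains
    missing = required - chains_present
    if missing:
        raise StructureRejected(
            f"{complex_id or structure.name}: missing nucleosome chains {sorted(missing)}"
        )
    if partner_chains is None:
        partner_chains = sorted(chains_present - required)
    if not partner_chains:
        raise StructureRejected(f"{complex_id or structure.name}: no partner chains found")

    tab = structure.atoms
    heavy = tab["is_heavy"].to_numpy()
    is_partner = tab["chain"].isin(partner_chains).to_numpy() & heavy
    nuc_mask = heavy & ~is_partner
    partner_idx = np.flatnonzero(is_partner)
    nuc_idx = np.flatnonzero(nuc_mask)
    pairs = atomic_contacts(structure.coords[partner_idx], structure.coords[nuc_idx], cutoff)

    ci, cj = topology.dna_chains
    bp_of: dict[tuple[str, int], int] = {}
    for b, row in enumerate(topology.base_pairs.itertuples(index=False)):
        bp_of[(ci, int(row.res_i))] = b
        bp_of[(cj, int(row.res_j))] = b
    tail_of: dict[tuple[str, int], tuple[str, int, int]] = {}
    for t in topology.tails:
        for r in t.residues:
            tail_of[(t.chain, r)] = (t.tail_id, t.copy, r)

    offsets = topology.bp_offsets
    chain_arr = tab["chain"].to_numpy()
    res_arr = tab["resnum"].to_numpy()
    contacted_bps: set[int] = set()
    bp_atoms: dict[int, set[int]] = {}
    tail_residues: set[tuple[str, int, int]] = set()
    core_residues: set[tuple[str, int]] = set()
    for p, q in pairs:
        pa = partner_idx[p]
        na = nuc_idx[q]
        key = (chain_arr[na], int(res_arr[na]))
        b = bp_of.get(key)
        if b is not None:
            off = int(offsets[b])
            contacted_bps.add(off)
            bp_atoms.setdefault(off, set()).add(int(pa))
        elif key in tail_of:
            tail_residues.add(tail_of[key])
        else:
            core_residues.add(key)
    return PartnerInterface(
        complex_id=complex_id or structure.name,
        partner_chains=tuple(partner_chains),
        contacted_bps=contacted_bps,
        bp_contact_counts={b: len(a) for b, a in bp_atoms.items()},
        tail_residues=tail_residues,
        core_residues=core_residues,
    )


def classify_binding_mode(iface: PartnerInterface) -> BindingModeClass:
    """Assign the binding-mode category from the contact flags.

    multivalent-tail: DNA and at least one histone tail (ISWI-like);
    multivalent-core: DNA and core histones but no tail; DNA-only and
    histone-only otherwise.
    """
    dna, core, tails = iface.binds_dna, iface.binds_histone_core, iface.binds_tails
    if dna and tails:
        cat = "multivalent-tail"
    elif dna and core:
        cat = "multivalent-core"
    elif dna:
        cat = "DNA-only"
    else:
        cat = "histone-only"
    return BindingModeClass(
        binds_dna=dna,
        binds_histone_core=core,
        binds_tails=tails,
        tail_ids=frozenset(iface.tail_ids),
        category=cat,
    )


def interface_overlap_fraction(
    iface: PartnerInterface, preferred_regions: set[int]
) -> OverlapResult:
    """Fraction of the partner's DNA footprint inside tail preferred regions.

    fraction = |footprint ∩ preferred| / |footprint|; at least one shared
    base pair marks the partner and the tails as mutually exclusive
    binders.  Partners without DNA contacts are undefined here and raise.
    """
    if not iface.binds_dna:
        raise ValueError(f"{iface.complex_id}: partner has no DNA footprint")
    shared = iface.contacted_bps & set(preferred_regions)
    n = len(iface.contacted_bps)
    return OverlapResult(
        fraction_overlap=len(shared) / n,
        shared_bp_count=len(shared),
        partner_bp_count=n,
        mutually_exclusive=len(shared) >= 1,
    )


def aggregate_partner_profile(
    ifaces: list[PartnerInterface],
    topology: NucleosomeTopology,
    preferred_regions: set[int] | None = None,
) -> pd.DataFrame:
    """Mean partner heavy-atom contacts per bp across complexes (± SE).

    The statistical unit is the complex; a companion boolean track marks
    the tail preferred binding regions when supplied.
    """
    if not ifaces:
        raise ValueError("no interfaces to aggregate")
    off = topology.bp_offsets
    counts = np.zeros((len(ifaces), len(off)))
    pos = {int(o): k for k, o in enumerate(off)}
    for i, f in enumerate(ifaces):
        for b, c in f.bp_contact_counts.items():
            counts[i, pos[b]] = c
    n = len(ifaces)
    out = pd.DataFrame(
        {
            "bp_offset": off,
            "shl": shl_of(off),
            "mean_contacts": counts.mean(axis=0),
            "se": counts.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            "n": n,
        }
    )
    if preferred_regions is not None:
        out["tail_region"] = [int(o) in preferred_regions for o in off]
    return out
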