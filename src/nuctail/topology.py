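"""Nucleosome topology: DNA base pairing, histone tails, core Cα selection.

The topology is the frame of reference of every downstream profile: base
pairs are indexed by ``bp_offset`` (0 at the dyad, negative upstream),
and the superhelical location (SHL) of a base pair is
``round(bp_offset / 10.4)`` using the canonical 10.4 bp helical repeat.
The default model is a 147-bp core flanked by 20-bp linkers, i.e. offsets
−93 … +93.

Base pairing between the two DNA strands is declared explicitly in the
topology (one record per bp naming the residue on each strand); it is
never inferred geometrically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

HELICAL_REPEAT_BP = 10.4

#: Default tail residue ranges at the canonical proteolytic clip sites.
DEFAULT_TAIL_RANGES = {
    "H3": (1, 36),
    "H4": (1, 15),
    "H2A_N": (1, 11),
    "H2A_C": (119, 128),
    "H2B": (1, 23),
}

TAIL_IDS = tuple(DEFAULT_TAIL_RANGES)


def shl_of(bp_offset) -> np.ndarray:
    """Superhelical location label of a base-pair offset from the dyad."""
    return np.round(np.asarray(bp_offset) / HELICAL_REPEAT_BP).astype(int)


@dataclass(frozen=True)
class TailDefinition:
    """One histone tail instance (type, copy, chain, inclusive residue range)."""

    tail_id: str
    copy: int
    chain: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.tail_id not in TAIL_IDS:
            raise ValueError(f"unknown tail_id {self.tail_id!r}")
        if self.copy not in (1, 2):
            raise ValueError("copy must be 1 or 2")
        if self.end < self.start:
            raise ValueError("empty residue range")

    @property
    def residues(self) -> range:
        return range(self.start, self.end + 1)

    @property
    def n_residues(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> tuple[str, int]:
        return (self.tail_id, self.copy)


@dataclass
class NucleosomeTopology:
    """Chains, base pairing and tail/core partition of one nucleosome model.

    Parameters
    ----------
    dna_chains : (str, str)
        Chain ids of strand I and strand J.
    base_pairs : pandas.DataFrame
        Columns ``bp_offset`` (int, 0 at dyad), ``res_i``, ``res_j``
        (author residue numbers on each strand), ordered by offset.
    tails : list of TailDefinition
    core_calpha : list of (chain, resnum)
        Residues whose Cα atoms define the superposition selection.
    """

    dna_chains: tuple[str, str]
    base_pairs: pd.DataFrame
    tails: list[TailDefinition]
    core_calpha: list[tuple[str, int]]
    n_core_bp: int = 147
    linker_bp: int = 20

    def __post_init__(self) -> None:
        self.dna_chains = tuple(self.dna_chains)
        self.base_pairs = self.base_pairs.sort_values("bp_offset").reset_index(drop=True)
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if len(self.dna_chains) != 2:
            raise ValueError("exactly two DNA chains required")
        off = self.base_pairs["bp_offset"].to_numpy()
        half = (self.n_core_bp - 1) // 2 + self.linker_bp
        expected = np.arange(-half, half + 1)
        if not np.array_equal(off, expected):
            raise ValueError(
                f"bp_offset must be consecutive integers in [{-half}, {half}]"
            )
        seen: dict[tuple[str, int], tuple[str, int]] = {}
        for t in self.tails:
            for r in t.residues:
                key = (t.chain, r)
                if key in seen and seen[key] != t.key:
                    raise ValueError(f"residue {key} assigned to two tails")
                seen[key] = t.key
        tail_set = set(seen)
        for cr in self.core_calpha:
            if tuple(cr) in tail_set:
                raise ValueError(f"core Cα residue {cr} overlaps a tail")
        by_key: dict[tuple[str, int], int] = {}
        for t in self.tails:
            by_key[t.key] = by_key.get(t.key, 0) + 1
        for key, n in by_key.items():
            if n != 1:
                raise ValueError(f"tail {key} defined {n} times")

    # -- convenience ---------------------------------------------------
    @property
    def bp_offsets(self) -> np.ndarray:
        return self.base_pairs["bp_offset"].to_numpy()

    @property
    def n_bp(self) -> int:
        return len(self.base_pairs)

    def tails_by_copy(self, copy: int) -> list[TailDefinition]:
        return [t for t in self.tails if t.copy == copy]

    def tail(self, tail_id: str, copy: int) -> TailDefinition:
        for t in self.tails:
            if t.tail_id == tail_id and t.copy == copy:
                return t
        raise KeyError((tail_id, copy))

    def tail_residue_keys(self) -> set[tuple[str, int]]:
        return {(t.chain, r) for t in self.tails for r in t.residues}

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "dna_chains": list(self.dna_chains),
            "n_core_bp": self.n_core_bp,
            "linker_bp": self.linker_bp,
            "base_pairs": self.base_pairs[["bp_offset", "res_i", "res_j"]].to_numpy().tolist(),
            "tails": [
                {"tail_id": t.tail_id, "copy": t.copy, "chain": t.chain,
                 "start": t.start, "end": t.end}
                for t in self.tails
            ],
            "core_calpha": [[c, int(r)] for c, r in self.core_calpha],
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "NucleosomeTopology":
        bp = pd.DataFrame(d["base_pairs"], columns=["bp_offset", "res_i", "res_j"])
        tails = [TailDefinition(**t) for t in d["tails"]]
        return cls(
            dna_chains=tuple(d["dna_chains"]),
            base_pairs=bp,
            tails=tails,
            core_calpha=[tuple(x) for x in d["core_calpha"]],
            n_core_bp=int(d.get("n_core_bp", 147)),
            linker_bp=int(d.get("linker_bp", 20)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NucleosomeTopology":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
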