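"""Structure containers and readers (PDB / mmCIF, multi-model trajectories).

Atoms live in a pandas table paired with an ``(n_atoms, 3)`` coordinate
array; a multi-model file yields one shared atom table plus an
``(n_frames, n_atoms, 3)`` stack.  Parsing is delegated to gemmi; element
symbols are taken from the file when present and inferred from the atom
name otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

# Published van der Waals radii (Å) for the elements that occur in
# nucleic-acid / protein heavy atoms; used for contacts and SASA.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
    "H": 1.20,
}
DEFAULT_VDW_RADIUS = 1.70

_TWO_LETTER = {"CL", "BR", "FE", "MG", "ZN", "MN", "NA", "SE", "CU", "NI", "CO"}


def infer_element(name: str) -> str:
    """Guess the element from a PDB atom name.

    First alphabetic character, with a lookup for common two-letter
    elements (CL, FE, MG, ...).  Primes and digits are ignored.
    """
    stripped = "".join(c for c in name if c.isalpha()).upper()
    if not stripped:
        return ""
    if stripped[:2] in _TWO_LETTER:
        return stripped[:2].capitalize()
    return stripped[0]


def vdw_radius(element: str) -> float:
    r = VDW_RADII.get(element.upper()[:1] if len(element) == 1 else element.capitalize())
    if r is None:
        r = VDW_RADII.get(element.upper(), None)
    return r if r is not None else DEFAULT_VDW_RADIUS


@dataclass
class AtomRecord:
    """One atom: identity, coordinates and contact/SASA attributes."""

    atom_id: int
    name: str
    element: str
    chain: str
    resnum: int
    resname: str
    coords: np.ndarray
    is_heavy: bool
    vdw_radius: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.atom_id}: non-finite coordinates")
        if self.is_heavy and self.vdw_radius <= 0:
            raise ValueError(f"atom {self.atom_id}: heavy atom needs positive vdW radius")
        if self.is_heavy != (self.element.upper() != "H"):
            raise ValueError(f"atom {self.atom_id}: is_heavy inconsistent with element")


@dataclass
class Structure:
    """Atom table + one coordinate set.

    ``atoms`` columns: atom_id, name, element, chain, resnum, resname,
    is_heavy, vdw_radius.  Row order defines atom indexing everywhere.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError("coords shape does not match atom table")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        return list(dict.fromkeys(self.atoms["chain"]))

    def heavy_mask(self) -> np.ndarray:
        return self.atoms["is_heavy"].to_numpy()

    def select(self, chain=None, resnums=None, names=None) -> np.ndarray:
        """Return integer atom indices matching the given criteria."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            chains = {chain} if isinstance(chain, str) else set(chain)
            mask &= self.atoms["chain"].isin(chains).to_numpy()
        if resnums is not None:
            mask &= self.atoms["resnum"].isin(set(resnums)).to_numpy()
        if names is not None:
            names = {names} if isinstance(names, str) else set(names)
            mask &= self.atoms["name"].isin(names).to_numpy()
        return np.flatnonzero(mask)

    def records(self):
        """Yield AtomRecord views (convenience; the table is the container)."""
        for i, row in enumerate(self.atoms.itertuples(index=False)):
            yield AtomRecord(
                atom_id=row.atom_id,
                name=row.name,
                element=row.element,
                chain=row.chain,
                resnum=row.resnum,
                resname=row.resname,
                coords=self.coords[i],
                is_heavy=row.is_heavy,
                vdw_radius=row.vdw_radius,
            )


def _model_to_tables(model: gemmi.Model) -> tuple[pd.DataFrame, np.ndarray]:
    rows = []
    xyz = []
    atom_id = 0
    for chain in model:
        for residue in chain:
            for atom in residue:
                elem = atom.element.name
                if not elem or elem == "X":
                    elem = infer_element(atom.name)
                    if not elem:
                        warnings.warn(f"atom {atom.name}: element unknown, default radius used")
                        elem = "C"
                is_heavy = elem.upper() != "H" and elem.upper() != "D"
                rows.append(
                    (atom_id, atom.name, elem, chain.name, residue.seqid.num, residue.name,
                     is_heavy, vdw_radius(elem))
                )
                xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
                atom_id += 1
    atoms = pd.DataFrame(
        rows,
        columns=["atom_id", "name", "element", "chain", "resnum", "resname", "is_heavy", "vdw_radius"],
    )
    return atoms, np.asarray(xyz, dtype=float)


def _read_gemmi(path: str | Path, fmt: str | None) -> gemmi.Structure:
    path = str(path)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(path)
        elif fmt == "mmcif":
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(path)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"structure file {path} contains no models")
    return st


def _completeness_check(atoms: pd.DataFrame) -> None:
    heavy = atoms[atoms["is_heavy"]]
    if len(heavy) == 0:
        warnings.warn("structure contains no heavy atoms")
        return
    per_res = heavy.groupby(["chain", "resnum"]).size()
    # amino-acid / nucleotide residues have >= 4 heavy atoms; a mean below 2
    # signals a reduced representation (e.g. Cα-only model)
    if per_res.mean() < 2.0:
        warnings.warn(
            "heavy-atom completeness is low "
            f"(mean {per_res.mean():.2f} heavy atoms/residue); model may be Cα-only"
        )


def read_structure(path: str | Path, fmt: str | None = None) -> Structure:
    """Read the first model of a PDB or mmCIF file into a Structure."""
    st = _read_gemmi(path, fmt)
    atoms, coords = _model_to_tables(st[0])
    _completeness_check(atoms)
    return Structure(atoms=atoms, coords=coords, name=st.name or Path(path).stem)


def read_trajectory(
    path: str | Path,
    fmt: str | None = None,
    frame_interval_ns: float = 1.0,
    t0_ns: float = 0.0,
) -> tuple[Structure, np.ndarray, np.ndarray]:
    """Read a multi-model PDB/mmCIF as a trajectory.

    Returns ``(structure, coords, times)`` where coords has shape
    ``(n_models, n_atoms, 3)`` and ``times`` is a uniform grid starting at
    ``t0_ns`` with spacing ``frame_interval_ns``.  All models must share
    the first model's atom set.
    """
    st = _read_gemmi(path, fmt)
    atoms, first = _model_to_tables(st[0])
    _completeness_check(atoms)
    frames = [first]
    for model in list(st)[1:]:
        tab, xyz = _model_to_tables(model)
        if len(tab) != len(atoms) or not (tab["name"].to_numpy() == atoms["name"].to_numpy()).all():
            raise ValueError("trajectory models do not share a common atom set")
        frames.append(xyz)
    coords = np.stack(frames)
    times = t0_ns + frame_interval_ns * np.arange(len(frames))
    return Structure(atoms=atoms, coords=first, name=st.name or Path(path).stem), coords, times


def write_pdb(structure: Structure, path: str | Path, coords_frames: np.ndarray | None = None) -> None:
    """Write a (multi-model) PDB file.

    ``coords_frames`` of shape (n_frames, n_atoms, 3) produces MODEL /
    ENDMDL blocks; ``None`` writes the structure's own coordinates.
    """
    if coords_frames is None:
        coords_frames = structure.coords[None, :, :]
    coords_frames = np.asarray(coords_frames, dtype=float)
    multi = coords_frames.shape[0] > 1
    tab = structure.atoms
    with open(path, "w") as fh:
        for m, xyz in enumerate(coords_frames, start=1):
            if multi:
                fh.write(f"MODEL     {m:4d}\n")
            for i, row in enumerate(tab.itertuples(index=False)):
                name = row.name if len(row.name) >= 4 else f" {row.name:<3s}"
                fh.write(
                    "ATOM  {serial:5d} {name:<4s} {res:<3s} {chain:1s}{resnum:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}\n".format(
                        serial=(i % 99999) + 1,
                        name=name,
                        res=row.resname[:3],
                        chain=str(row.chain)[:1],
                        resnum=int(row.resnum),
                        x=xyz[i, 0],
                        y=xyz[i, 1],
                        z=xyz[i, 2],
                        occ=1.0,
                        b=0.0,
                        elem=row.element[:2].upper(),
                    )
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")
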