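"""Structure I/O, atom selection, superposition and RMSD utilities.

Coordinates are in Ångström throughout.  A :class:`Structure` holds one or
more models over a single shared atom roster, mirroring a multi-model PDB
file.  Models are 0-based in the API and written 1-based to file, as PDB
``MODEL`` records require.

Residue numbering is taken verbatim from the input file (author numbering);
nothing here ever renumbers.  Insertion codes are folded into the residue
key so that the per-model uniqueness invariant survives real PDB files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

import biotite.structure as bts
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Structure",
    "Selection",
    "StructureError",
    "MissingFileError",
    "EmptyStructureError",
    "RosterMismatchError",
    "SelectionError",
    "read_structure",
    "write_ensemble",
    "superpose",
    "apply_transform",
    "superposed_rmsd",
    "rmsd_profile",
]


class StructureError(Exception):
    """Base class for structure handling errors."""


class MissingFileError(StructureError):
    """The requested structure file does not exist."""


class EmptyStructureError(StructureError):
    """The file or structure contains no atoms (or no conformers)."""


class RosterMismatchError(StructureError):
    """Models (or conformers) do not share one atom roster."""


class SelectionError(StructureError):
    """A selection resolved to no atoms or is otherwise invalid."""


@dataclass
class Structure:
    """One atom roster with one or more coordinate models.

    Attributes
    ----------
    atom_name, element, res_name, chain_id : arrays of str, length n_atoms
    res_id : int array, author residue numbers
    ins_code : str array, insertion codes ('' when absent)
    coords : float array of shape (n_models, n_atoms, 3), Å
    provenance : source path or generator tag
    """

    atom_name: np.ndarray
    element: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    chain_id: np.ndarray
    coords: np.ndarray
    ins_code: np.ndarray | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.atom_name = np.asarray(self.atom_name, dtype="U6")
        self.element = np.asarray(self.element, dtype="U2")
        self.res_id = np.asarray(self.res_id, dtype=int)
        self.res_name = np.asarray(self.res_name, dtype="U5")
        self.chain_id = np.asarray(self.chain_id, dtype="U4")
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None, :, :]
        self.coords = coords
        if self.ins_code is None:
            self.ins_code = np.full(self.n_atoms, "", dtype="U2")
        else:
            self.ins_code = np.asarray(self.ins_code, dtype="U2")
        self.validate()

    # -- basic queries ---------------------------------------------------

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def validate(self) -> None:
        if self.n_atoms == 0:
            raise EmptyStructureError("structure has no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        for arr, name in [
            (self.atom_name, "atom_name"),
            (self.element, "element"),
            (self.res_id, "res_id"),
            (self.res_name, "res_name"),
            (self.chain_id, "chain_id"),
        ]:
            if len(arr) != self.n_atoms:
                raise StructureError(f"{name} length != n_atoms")
        keys = list(zip(self.chain_id, self.res_id,
                        self.ins_code if self.ins_code is not None else [""] * self.n_atoms,
                        self.atom_name))
        if len(set(keys)) != len(keys):
            raise StructureError("(chain, residue, insertion, atom name) not unique")

    def atom_keys(self) -> list[tuple]:
        """Roster identity: (chain, res_id, ins_code, atom_name) per atom."""
        return list(zip(self.chain_id, self.res_id, self.ins_code, self.atom_name))

    def residue_keys(self) -> list[tuple]:
        """Unique (chain, res_id, ins_code) keys in atom order."""
        seen: dict[tuple, None] = {}
        for c, r, i in zip(self.chain_id, self.res_id, self.ins_code):
            seen.setdefault((c, r, i), None)
        return list(seen)

    def residue_atom_indices(self) -> dict[tuple, np.ndarray]:
        """Map (chain, res_id, ins_code) -> atom index array, in atom order."""
        groups: dict[tuple, list[int]] = {}
        for i, key in enumerate(zip(self.chain_id, self.res_id, self.ins_code)):
            groups.setdefault(key, []).append(i)
        return {k: np.asarray(v, dtype=int) for k, v in groups.items()}

    def calpha_indices(self) -> np.ndarray:
        return np.flatnonzero(self.atom_name == "CA")

    def model(self, i: int) -> "Structure":
        """Single-model view (copy) of model i (0-based)."""
        return replace(self, coords=self.coords[i].copy())

    def with_coords(self, coords: np.ndarray, provenance: str | None = None) -> "Structure":
        return replace(
            self,
            coords=np.asarray(coords, dtype=float),
            provenance=self.provenance if provenance is None else provenance,
        )

    def same_roster(self, other: "Structure") -> bool:
        return self.atom_keys() == other.atom_keys()

    def subset(self, indices: np.ndarray) -> "Structure":
        """New Structure restricted to the given atom indices (all models)."""
        indices = np.asarray(indices, dtype=int)
        return replace(
            self,
            atom_name=self.atom_name[indices],
            element=self.element[indices],
            res_id=self.res_id[indices],
            res_name=self.res_name[indices],
            chain_id=self.chain_id[indices],
            ins_code=self.ins_code[indices],
            coords=self.coords[:, indices, :].copy(),
        )

    def restrict(self, chain: str | None = None,
                 residue_range: tuple[int, int] | None = None) -> "Structure":
        """Restrict to one chain and/or an inclusive residue-number range.

        Real structure files often contain fusion partners or extra
        chains; the modeled region is a user input, never hard-coded.
        """
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            mask &= self.chain_id == chain
        if residue_range is not None:
            lo, hi = residue_range
            mask &= (self.res_id >= lo) & (self.res_id <= hi)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise SelectionError(
                f"restriction chain={chain!r} range={residue_range} "
                "matched no atoms")
        return self.subset(idx)


@dataclass(frozen=True)
class Selection:
    """Atom predicate expressed as (chain, residue-number set, atom-name set).

    Each triple component may be ``None`` meaning "any".  A selection
    resolves against a Structure to a deterministic, ordered, non-empty
    atom index list (order = atom order in the structure).
    """

    parts: tuple[tuple[str | None, frozenset | None, frozenset | None], ...]

    @classmethod
    def of(cls, chain: str | None = None,
           residues: Iterable[int] | None = None,
           atom_names: Iterable[str] | None = None) -> "Selection":
        return cls(parts=((
            chain,
            None if residues is None else frozenset(int(r) for r in residues),
            None if atom_names is None else frozenset(atom_names),
        ),))

    @classmethod
    def calpha(cls, chain: str | None = None,
               residues: Iterable[int] | None = None) -> "Selection":
        return cls.of(chain=chain, residues=residues, atom_names=["CA"])

    def __or__(self, other: "Selection") -> "Selection":
        return Selection(parts=self.parts + other.parts)

    def mask(self, structure: Structure) -> np.ndarray:
        m = np.zeros(structure.n_atoms, dtype=bool)
        for chain, residues, names in self.parts:
            part = np.ones(structure.n_atoms, dtype=bool)
            if chain is not None:
                part &= structure.chain_id == chain
            if residues is not None:
                part &= np.isin(structure.res_id, list(residues))
            if names is not None:
                part &= np.isin(structure.atom_name, list(names))
            m |= part
        return m

    def resolve(self, structure: Structure) -> np.ndarray:
        idx = np.flatnonzero(self.mask(structure))
        if idx.size == 0:
            raise SelectionError(f"selection matched no atoms: {self.parts}")
        return idx


# -- file I/O ------------------------------------------------------------


def read_structure(path: str | os.PathLike) -> Structure:
    """Read a single- or multi-model PDB file.

    Altloc policy: the highest-occupancy alternate location is kept
    (ties resolve to 'A').  Raises :class:`MissingFileError`,
    :class:`EmptyStructureError` or :class:`RosterMismatchError`.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise MissingFileError(path)
    pdb = PDBFile.read(path)
    if not any(ln.startswith(("ATOM", "HETATM")) for ln in pdb.lines):
        raise EmptyStructureError(f"{path}: no ATOM/HETATM records")
    try:
        stack = pdb.get_structure(altloc="occupancy", extra_fields=[])
    except Exception as exc:  # biotite raises on inconsistent models
        raise RosterMismatchError(
            f"{path}: models do not share one atom roster ({exc})"
        ) from exc
    if stack.array_length() == 0:
        raise EmptyStructureError(f"{path}: no ATOM/HETATM records")
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    return Structure(
        atom_name=stack.atom_name,
        element=stack.element,
        res_id=stack.res_id,
        res_name=stack.res_name,
        chain_id=stack.chain_id,
        ins_code=stack.ins_code,
        coords=coords,
        provenance=path,
    )


def _to_atom_array_stack(structure: Structure) -> bts.AtomArrayStack:
    n = structure.n_atoms
    stack = bts.AtomArrayStack(structure.n_models, n)
    stack.coord[:] = structure.coords
    stack.atom_name = structure.atom_name.astype("U6")
    stack.element = structure.element.astype("U2")
    stack.res_id = structure.res_id.astype(int)
    stack.res_name = structure.res_name.astype("U5")
    stack.chain_id = structure.chain_id.astype("U4")
    stack.ins_code = structure.ins_code.astype("U1")
    stack.hetero = np.zeros(n, dtype=bool)
    return stack


def write_ensemble(conformers: Sequence[Structure] | Structure,
                   path: str | os.PathLike) -> None:
    """Write conformers as a multi-model PDB file.

    All conformers must share one atom roster.  Coordinates round-trip to
    PDB fixed-width precision (3 decimals, i.e. 5e-4 Å).
    """
    if isinstance(conformers, Structure):
        merged = conformers
    else:
        conformers = list(conformers)
        if len(conformers) == 0:
            raise EmptyStructureError("no conformers to write")
        first = conformers[0]
        coords = []
        for c in conformers:
            if not c.same_roster(first):
                raise RosterMismatchError("conformers do not share one atom roster")
            coords.append(c.coords.reshape(-1, first.n_atoms, 3))
        merged = first.with_coords(np.concatenate(coords, axis=0))
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array_stack(merged))
    pdb.write(os.fspath(path))


# -- superposition and RMSD ----------------------------------------------


def superpose(mobile: np.ndarray, reference: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch-optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation 3x3 with det +1, translation 3-vector, rmsd in Å)
    such that ``mobile @ R.T + t`` best fits ``reference`` in the
    least-squares sense.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"atom count mismatch: {mobile.shape} vs {reference.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atoms for superposition")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, rssd = Rotation.align_vectors(reference - rc, mobile - mc)
    R = rot.as_matrix()
    t = rc - R @ mc
    rmsd = float(rssd / np.sqrt(n))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ np.asarray(rotation).T + translation


def plain_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD without superposition."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two coordinate sets over rigid motions."""
    return superpose(a, b)[2]


def rmsd_profile(conf_a: Structure, conf_b: Structure,
                 selection: Selection | None = None) -> pd.DataFrame:
    """Per-residue Cα deviation after whole-selection Cα superposition.

    Both conformers must share the atom roster over the selection.  The
    selected Cα atoms are superposed as one rigid body, then each
    residue's Cα deviation is reported.  Columns: residue_number, chain,
    deviation_A.
    """
    if selection is None:
        selection = Selection.calpha()
    mask = selection.mask(conf_a) & (conf_a.atom_name == "CA")
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError("selection contains no Cα atoms")
    a = conf_a.coords[0][idx]
    b = conf_b.coords[0][idx]
    R, t, _ = superpose(b, a)
    b_fit = apply_transform(b, R, t)
    dev = np.linalg.norm(b_fit - a, axis=1)
    return pd.DataFrame({
        "residue_number": conf_a.res_id[idx],
        "chain": conf_a.chain_id[idx],
        "deviation_A": dev,
    })
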