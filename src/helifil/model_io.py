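"""Minimal atomic structure model with PDB/mmCIF readers and writers.

The in-memory model is a column-store :class:`Structure` (numpy coordinate
array plus parallel name/element/residue/chain columns); :class:`Atom` is a
per-row record view.  File I/O is delegated to gemmi, with a validation pass
on PDB input so that malformed coordinate records produce line-numbered
:class:`~helifil.errors.ParseError` instead of being silently skipped.

Conventions
-----------
* Coordinates are ångström throughout, right-handed frame, filament axis +z.
* Residue indices are 1-based (PDB convention).
* Altloc policy: keep the highest-occupancy location, ties broken by first
  occurrence; the choice is recorded in ``Structure.metadata['altloc']``.
* Hydrogens are optional and all downstream metrics are defined on heavy
  atoms only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import gemmi
import numpy as np

from .errors import FormatCapacityError, ParseError, ValidationError

__all__ = ["Atom", "Structure", "read_structure", "write_structure", "extract_chain"]

# Maximum magnitude representable in the fixed %8.3f PDB coordinate field.
_PDB_COORD_MAX = 9999.999
_PDB_MAX_ATOMS = 99_999


@dataclass(frozen=True)
class Atom:
    """One heavy (or hydrogen) atom: label, element, position and residue context."""

    name: str
    element: str
    coords: tuple[float, float, float]
    residue_index: int
    residue_name: str
    chain_id: str

    def __post_init__(self) -> None:
        if not self.element:
            raise ValidationError("Atom.element must be non-empty")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"Atom {self.name}: coordinates must be finite")


class Structure:
    """Ordered collection of atoms partitioned into chains.

    Invariants (checked by :meth:`validate`): ``(chain_id, residue_index,
    name)`` is unique per atom, and residue indices within a chain are
    non-decreasing in atom order.
    """

    def __init__(self, atoms: Iterable[Atom] = (), metadata: Mapping[str, str] | None = None):
        atoms = list(atoms)
        self.names: list[str] = [a.name for a in atoms]
        self.elements: list[str] = [a.element for a in atoms]
        self.residue_indices: np.ndarray = np.array(
            [a.residue_index for a in atoms], dtype=int
        )
        self.residue_names: list[str] = [a.residue_name for a in atoms]
        self.chain_ids: list[str] = [a.chain_id for a in atoms]
        self._coords: np.ndarray = (
            np.array([a.coords for a in atoms], dtype=float).reshape(len(atoms), 3)
        )
        self.metadata: dict[str, str] = dict(metadata or {})

    # ------------------------------------------------------------------ core

    @classmethod
    def from_arrays(
        cls,
        names: Iterable[str],
        elements: Iterable[str],
        coords: np.ndarray,
        residue_indices: Iterable[int],
        residue_names: Iterable[str],
        chain_ids: Iterable[str],
        metadata: Mapping[str, str] | None = None,
    ) -> "Structure":
        s = cls()
        s.names = list(names)
        s.elements = list(elements)
        s._coords = np.asarray(coords, dtype=float).reshape(len(s.names), 3)
        s.residue_indices = np.asarray(list(residue_indices), dtype=int)
        s.residue_names = list(residue_names)
        s.chain_ids = list(chain_ids)
        s.metadata = dict(metadata or {})
        if not (
            len(s.elements)
            == len(s.residue_indices)
            == len(s.residue_names)
            == len(s.chain_ids)
            == len(s.names)
        ):
            raise ValidationError("from_arrays: column lengths differ")
        if len(s.names) and not np.all(np.isfinite(s._coords)):
            raise ValidationError("from_arrays: coordinates must be finite")
        return s

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in Å.  A view — copy before mutating."""
        return self._coords

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms())

    def atoms(self) -> list[Atom]:
        return [
            Atom(
                self.names[i],
                self.elements[i],
                tuple(self._coords[i]),
                int(self.residue_indices[i]),
                self.residue_names[i],
                self.chain_ids[i],
            )
            for i in range(len(self))
        ]

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Same topology, new coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self._coords.shape:
            raise ValidationError(
                f"with_coords: expected shape {self._coords.shape}, got {coords.shape}"
            )
        out = self.from_arrays(
            self.names,
            self.elements,
            coords,
            self.residue_indices,
            self.residue_names,
            self.chain_ids,
            self.metadata,
        )
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Apply x -> R @ x + t to every atom."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return self.with_coords(self._coords @ R.T + t)

    # ---------------------------------------------------------------- chains

    def chain_order(self) -> list[str]:
        """Distinct chain ids in first-occurrence order."""
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c)
        return list(seen)

    @property
    def chains(self) -> dict[str, "Structure"]:
        return {c: extract_chain(self, c) for c in self.chain_order()}

    def select(self, mask: np.ndarray) -> "Structure":
        idx = np.flatnonzero(np.asarray(mask))
        return Structure.from_arrays(
            [self.names[i] for i in idx],
            [self.elements[i] for i in idx],
            self._coords[idx],
            self.residue_indices[idx],
            [self.residue_names[i] for i in idx],
            [self.chain_ids[i] for i in idx],
            self.metadata,
        )

    def heavy(self) -> "Structure":
        """Drop hydrogens (element H/D)."""
        mask = np.array([e.upper() not in ("H", "D") for e in self.elements])
        return self.select(mask)

    # ------------------------------------------------------------- integrity

    def validate(self) -> None:
        keys = list(zip(self.chain_ids, self.residue_indices.tolist(), self.names))
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (chain_id, residue_index, name) atom key")
        last: dict[str, int] = {}
        for c, r in zip(self.chain_ids, self.residue_indices.tolist()):
            if c in last and r < last[c]:
                raise ValidationError(
                    f"residue indices in chain {c!r} decrease in atom order"
                )
            last[c] = r

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<Structure {len(self)} atoms, "
            f"{len(self.chain_order())} chain(s)>"
        )


# ---------------------------------------------------------------------- I/O


def _guess_format(path: str | os.PathLike) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".pdb", ".ent"):
        return "pdb"
    if ext in (".cif", ".mmcif"):
        return "mmcif"
    raise ValidationError(f"cannot guess format from extension {ext!r}; pass format=")


def _validate_pdb_lines(path: str) -> None:
    """Pre-scan fixed-column PDB coordinate records so malformed fields raise
    a line-numbered ParseError (gemmi silently drops bad records)."""
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"{path}:{lineno}: coordinate record too short")
            for lo, hi, label in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                fragment = line[lo:hi]
                try:
                    float(fragment)
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric {label} coordinate field "
                        f"{fragment.strip()!r}"
                    ) from None


def read_structure(path: str | os.PathLike, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    All ATOM/HETATM coordinate records of the first model are kept, with the
    documented altloc policy (highest occupancy, first on ties).
    """
    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = _guess_format(path) if format == "auto" else format
    if fmt not in ("pdb", "mmcif"):
        raise ValidationError(f"unknown format {fmt!r}")
    if fmt == "pdb":
        _validate_pdb_lines(path)
    try:
        st = gemmi.read_structure(
            path,
            format=gemmi.CoorFormat.Pdb if fmt == "pdb" else gemmi.CoorFormat.Mmcif,
        )
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        return Structure(metadata={"source": path})

    names: list[str] = []
    elements: list[str] = []
    coords: list[tuple[float, float, float]] = []
    resids: list[int] = []
    resnames: list[str] = []
    chains: list[str] = []
    altloc_dropped = False
    model = st[0]
    for chain in model:
        for res in chain:
            # altloc policy: group by atom name, keep max occupancy / first.
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for atom in res:
                if atom.name not in best:
                    best[atom.name] = atom
                    order.append(atom.name)
                else:
                    altloc_dropped = True
                    if atom.occ > best[atom.name].occ:
                        best[atom.name] = atom
            for name in order:
                atom = best[name]
                names.append(name)
                elements.append(atom.element.name)
                coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
                resids.append(res.seqid.num)
                resnames.append(res.name)
                chains.append(chain.name)
    meta = {"source": path, "format": fmt}
    if altloc_dropped:
        meta["altloc"] = "kept highest occupancy, ties by first occurrence"
    return Structure.from_arrays(
        names, elements, np.array(coords, dtype=float).reshape(len(names), 3),
        resids, resnames, chains, meta,
    )


def _to_gemmi(s: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "helifil"
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    res_map: dict[tuple[str, int], gemmi.Residue] = {}
    for i in range(len(s)):
        cid = s.chain_ids[i]
        if cid not in chain_map:
            chain_map[cid] = gemmi.Chain(cid)
            model.add_chain(chain_map[cid])
            chain_map[cid] = model[len(model) - 1]
        chain = chain_map[cid]
        rkey = (cid, int(s.residue_indices[i]))
        if rkey not in res_map:
            res = gemmi.Residue()
            res.name = s.residue_names[i]
            res.seqid = gemmi.SeqId(int(s.residue_indices[i]), " ")
            chain.add_residue(res)
            res_map[rkey] = chain[len(chain) - 1]
        res = res_map[rkey]
        atom = gemmi.Atom()
        atom.name = s.names[i]
        atom.element = gemmi.Element(s.elements[i])
        x, y, z = s.coords[i]
        atom.pos = gemmi.Position(x, y, z)
        atom.occ = 1.0
        atom.b_iso = 0.0
        res.add_atom(atom)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(s: Structure, path: str | os.PathLike, format: str = "auto") -> None:
    """Write ``s`` to PDB or mmCIF; ``read_structure(write_structure(s))``
    preserves atom order, names and coordinates to format precision."""
    path = str(path)
    fmt = _guess_format(path) if format == "auto" else format
    if fmt == "pdb":
        if len(s) > _PDB_MAX_ATOMS:
            raise FormatCapacityError(
                f"{len(s)} atoms exceed the PDB serial field ({_PDB_MAX_ATOMS}); "
                "write mmCIF instead"
            )
        if any(len(c) > 1 for c in s.chain_ids):
            raise FormatCapacityError(
                "multi-character chain ids are not representable in PDB; "
                "write mmCIF instead"
            )
        if len(s) and np.abs(s.coords).max() > _PDB_COORD_MAX:
            raise FormatCapacityError(
                "coordinate exceeds the fixed PDB %8.3f field; write mmCIF instead"
            )
    elif fmt != "mmcif":
        raise ValidationError(f"unknown format {fmt!r}")
    st = _to_gemmi(s)
    if fmt == "pdb":
        st.write_pdb(path)
    else:
        st.make_mmcif_document().write_file(path)


def extract_chain(s: Structure, chain_id: str) -> Structure:
    """Atoms of one chain, order preserved.  Idempotent."""
    available = s.chain_order()
    if chain_id not in available:
        raise KeyError(f"chain {chain_id!r} not present; available: {available}")
    mask = np.array([c == chain_id for c in s.chain_ids])
    return s.select(mask)
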