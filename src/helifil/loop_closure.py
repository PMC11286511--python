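"""Fragment-based loop closure.

Protomers are connected into a single chain by looking up short backbone
fragments whose two terminal residues superpose onto the target termini (the
C-terminal residue of the upstream protomer and the N-terminal residue of the
downstream one) within an RMSD tolerance, then stitching the best candidate's
interior residues into the gap.

The default acceptance tolerance is 0.35 Å RMSD over the backbone N, CA, C, O
atoms of one terminal residue on each side (4 + 4 atoms superposed jointly);
the number of anchor residues per side is configurable.  Candidate ranking is
pure RMSD with lexical fragment-id tie-breaks.  Stitched loops keep
poly-alanine identity; no sequence design or torsion-space relaxation is
attempted, but junction peptide geometry is checked.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._superpose import kabsch
from .errors import StitchingError, ValidationError
from .helical_geometry import RigidTransform
from .model_io import Structure

__all__ = [
    "Fragment",
    "FragmentDB",
    "LoopCandidate",
    "superpose",
    "find_loop_candidates",
    "close_chain",
    "BACKBONE_ATOMS",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# acceptable peptide-bond C-N distance range at stitched junctions, Å
_PEPTIDE_CN = (1.2, 1.5)


@dataclass(frozen=True)
class Fragment:
    """A backbone fragment: (n_residues, 4, 3) coordinates in N, CA, C, O order."""

    fragment_id: str
    coords: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 3 or c.shape[1] != 4 or c.shape[2] != 3:
            raise ValidationError(
                f"fragment {self.fragment_id}: coords must be (n_residues, 4, 3)"
            )
        if c.shape[0] < 3:
            raise ValidationError(
                f"fragment {self.fragment_id}: needs >= 3 residues, got {c.shape[0]}"
            )
        object.__setattr__(self, "coords", c)

    @property
    def n_residues(self) -> int:
        return int(self.coords.shape[0])

    def terminal_coords(self, n_anchor: int = 1) -> np.ndarray:
        """Backbone coordinates of the first and last ``n_anchor`` residues,
        flattened to (n_anchor*8, 3): N-side anchors then C-side anchors."""
        head = self.coords[:n_anchor].reshape(-1, 3)
        tail = self.coords[-n_anchor:].reshape(-1, 3)
        return np.concatenate([head, tail])


@dataclass
class FragmentDB:
    """An in-memory fragment database with JSON (de)serialisation."""

    fragments: list[Fragment]

    def __post_init__(self):
        ids = [f.fragment_id for f in self.fragments]
        if len(set(ids)) != len(ids):
            raise ValidationError("fragment ids must be unique")

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def to_json(self, path: str) -> None:
        payload = {
            "format": "helifil-fragment-db-v1",
            "atom_order": list(BACKBONE_ATOMS),
            "fragments": [
                {
                    "id": f.fragment_id,
                    "n_residues": f.n_residues,
                    "coords": np.round(f.coords, 6).tolist(),
                }
                for f in self.fragments
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "FragmentDB":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            fragments=[
                Fragment(d["id"], np.asarray(d["coords"], dtype=float))
                for d in payload["fragments"]
            ]
        )


@dataclass(frozen=True)
class LoopCandidate:
    """A fragment accepted at the junction: its RMSD and aligned coordinates."""

    fragment_id: str
    rmsd: float
    aligned_coords: np.ndarray
    n_anchor: int = 1


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition (Kabsch) of two equal-size point sets.

    Returns the optimal transform mapping ``mobile`` onto ``target`` and the
    residual RMSD, which is the global minimum over rigid transforms.
    """
    R, t, rmsd = kabsch(mobile, target)
    return RigidTransform(R, t), rmsd


def _terminal_backbone(s: Structure, end: str, n_anchor: int) -> np.ndarray:
    """Backbone N, CA, C, O coordinates of the first/last ``n_anchor`` residues."""
    resids = s.residue_indices
    order = sorted(set(resids.tolist()))
    if len(order) < n_anchor:
        raise ValidationError(f"structure has fewer than {n_anchor} residues")
    wanted = order[-n_anchor:] if end == "C" else order[:n_anchor]
    rows = []
    for r in wanted:
        for name in BACKBONE_ATOMS:
            hit = [
                i
                for i in range(len(s))
                if s.residue_indices[i] == r and s.names[i] == name
            ]
            if not hit:
                raise ValidationError(
                    f"residue {r} lacks backbone atom {name}; complete N/CA/C/O required"
                )
            rows.append(s.coords[hit[0]])
    return np.asarray(rows)


def find_loop_candidates(
    n_side: Structure,
    c_side: Structure,
    db: FragmentDB,
    tolerance: float = 0.35,
    n_anchor: int = 1,
) -> list[LoopCandidate]:
    """Fragments whose termini superpose onto the junction within tolerance.

    The query is the C-terminal anchor residue(s) of ``n_side`` (the upstream
    protomer) jointly with the N-terminal anchor residue(s) of ``c_side``;
    each fragment's two ends are superposed jointly onto it.  Candidates with
    RMSD <= tolerance are returned sorted ascending by RMSD, ties broken by
    fragment id.  An empty list (no error) means no fragment qualifies.
    """
    if not (1 <= n_anchor <= 3):
        raise ValidationError("n_anchor must be 1..3")
    if len(db) == 0:
        raise ValidationError("fragment database is empty")
    query = np.concatenate(
        [
            _terminal_backbone(n_side, "C", n_anchor),
            _terminal_backbone(c_side, "N", n_anchor),
        ]
    )
    out: list[LoopCandidate] = []
    for frag in db:
        if frag.n_residues < 2 * n_anchor:
            continue
        term = frag.terminal_coords(n_anchor)
        transform, rmsd = superpose(term, query)
        if rmsd <= tolerance:
            aligned = transform.apply(frag.coords.reshape(-1, 3)).reshape(frag.coords.shape)
            out.append(LoopCandidate(frag.fragment_id, rmsd, aligned, n_anchor))
    out.sort(key=lambda c: (c.rmsd, c.fragment_id))
    return out


def close_chain(
    protomers: Sequence[Structure],
    loops: Sequence[LoopCandidate],
    chain_id: str = "A",
    endpoint_tol: float = 0.5,
) -> Structure:
    """Stitch protomers into one chain using accepted loop candidates.

    Loop k bridges protomer k's C-terminus to protomer k+1's N-terminus: the
    anchor residues stay, the fragment's interior residues are inserted, and
    residues are renumbered consecutively.  Raises :class:`StitchingError`
    when a loop endpoint sits farther than ``endpoint_tol`` Å from its
    junction anchors or a resulting junction peptide C-N distance falls
    outside [1.2, 1.5] Å.
    """
    if len(loops) != len(protomers) - 1:
        raise ValidationError(
            f"need {len(protomers) - 1} loops for {len(protomers)} protomers, got {len(loops)}"
        )
    names: list[str] = []
    elements: list[str] = []
    coords: list[np.ndarray] = []
    resnames: list[str] = []
    res_counter = 0
    resids: list[int] = []

    def _append_structure(s: Structure):
        nonlocal res_counter
        last = None
        for i in range(len(s)):
            r = int(s.residue_indices[i])
            if r != last:
                res_counter += 1
                last = r
            names.append(s.names[i])
            elements.append(s.elements[i])
            coords.append(s.coords[i])
            resnames.append(s.residue_names[i])
            resids.append(res_counter)

    def _append_fragment_interior(frag_coords: np.ndarray):
        nonlocal res_counter
        for res in frag_coords[1:-1]:
            res_counter += 1
            for name, xyz in zip(BACKBONE_ATOMS, res):
                names.append(name)
                elements.append(name[0])
                coords.append(np.asarray(xyz))
                resnames.append("ALA")
                resids.append(res_counter)

    for k, prot in enumerate(protomers):
        _append_structure(prot)
        if k < len(loops):
            loop = loops[k]
            a_anchor = _terminal_backbone(prot, "C", loop.n_anchor)
            b_anchor = _terminal_backbone(protomers[k + 1], "N", loop.n_anchor)
            term = np.concatenate(
                [
                    loop.aligned_coords[: loop.n_anchor].reshape(-1, 3),
                    loop.aligned_coords[-loop.n_anchor :].reshape(-1, 3),
                ]
            )
            dev = np.linalg.norm(term - np.concatenate([a_anchor, b_anchor]), axis=1).max()
            if dev > endpoint_tol:
                raise StitchingError(
                    f"junction {k}: loop endpoint {dev:.2f} Å from anchors "
                    f"(tolerance {endpoint_tol} Å)"
                )
            _append_fragment_interior(loop.aligned_coords)

    out = Structure.from_arrays(
        names,
        elements,
        np.asarray(coords),
        resids,
        resnames,
        [chain_id] * len(names),
    )
    _check_junction_geometry(out)
    return out


def _check_junction_geometry(s: Structure) -> None:
    """Every consecutive-residue peptide C-N distance must be in [1.2, 1.5] Å."""
    c_pos: dict[int, np.ndarray] = {}
    n_pos: dict[int, np.ndarray] = {}
    for i in range(len(s)):
        r = int(s.residue_indices[i])
        if s.names[i] == "C":
            c_pos[r] = s.coords[i]
        elif s.names[i] == "N":
            n_pos[r] = s.coords[i]
    for r in sorted(c_pos):
        if r + 1 in n_pos:
            d = float(np.linalg.norm(n_pos[r + 1] - c_pos[r]))
            if not (_PEPTIDE_CN[0] <= d <= _PEPTIDE_CN[1]):
                raise StitchingError(
                    f"junction between residues {r} and {r + 1}: peptide C-N "
                    f"distance {d:.2f} Å outside [1.2, 1.5] Å"
                )
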