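"""Screw-transform algebra for helical filaments.

A filament is generated by repeated application of a single rigid transform
(the screw operation) to a subunit.  This module propagates subunits into
filaments, decomposes transforms into helical parameters (axial rise in Å and
twist in degrees), fits those parameters back from bare coordinates, and
analyses lattice structure: ring closure in cross-section, strand count, and
antiparallel (dihedral, D1-like) arrangements.  A grid sampler enumerates
candidate helical docks with clash/contact bookkeeping.

Sign convention
---------------
Twist follows the right-hand rule about ``axis_direction``, and the axis
direction is chosen so that the rise is non-negative (both are flipped
together when needed).  With the filament axis along +z, a negative twist is
a left-handed per-step rotation.  Twist is always wrapped to (-180, 180].
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from ._superpose import kabsch
from .errors import DegeneracyError, NoContactError, ValidationError
from .model_io import Structure

__all__ = [
    "RigidTransform",
    "HelicalParams",
    "Filament",
    "DockSample",
    "screw_decompose",
    "propagate",
    "fit_helical_params",
    "ring_count",
    "strand_step",
    "detect_antiparallel",
    "sample_docks",
    "chain_id_for_index",
]

_ORTHO_TOL = 1e-9


def wrap_angle_deg(angle: float) -> float:
    """Wrap an angle in degrees to the interval (-180, 180]."""
    wrapped = -((-float(angle) + 180.0) % 360.0 - 180.0)
    return 180.0 if wrapped == -180.0 else wrapped


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> rotation @ x + translation (Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-8:
            raise ValidationError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValidationError("rotation matrix must be proper (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(
        cls,
        axis: Sequence[float],
        angle_deg: float,
        translation: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        a = np.asarray(axis, dtype=float)
        a = a / np.linalg.norm(a)
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * a).as_matrix()
        return cls(R, np.asarray(translation, dtype=float))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self ∘ other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def power(self, k: int) -> "RigidTransform":
        out = RigidTransform.identity()
        for _ in range(k):
            out = self.compose(out)
        return out


@dataclass(frozen=True)
class HelicalParams:
    """Screw parameters: axial rise (Å) and twist (degrees in (-180, 180])
    about the axis through ``axis_point`` along unit ``axis_direction``."""

    rise: float
    twist: float
    axis_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        p = np.asarray(self.axis_point, dtype=float).reshape(3)
        d = np.asarray(self.axis_direction, dtype=float).reshape(3)
        object.__setattr__(self, "axis_point", p)
        object.__setattr__(self, "axis_direction", d)
        if abs(np.linalg.norm(d) - 1.0) > _ORTHO_TOL * 10:
            raise ValidationError("axis_direction must be a unit vector")
        if not (-180.0 < self.twist <= 180.0):
            raise ValidationError("twist must lie in (-180, 180]")

    @property
    def handedness(self) -> int:
        """Sign of the twist: +1 right-handed, -1 left-handed, 0 untwisted."""
        return int(np.sign(self.twist))

    def recompose(self) -> RigidTransform:
        """The rigid transform realising these screw parameters."""
        R = Rotation.from_rotvec(np.deg2rad(self.twist) * self.axis_direction).as_matrix()
        t = self.rise * self.axis_direction + (np.eye(3) - R) @ self.axis_point
        return RigidTransform(R, t)


def screw_decompose(t: RigidTransform, angle_tol: float = 1e-9) -> HelicalParams:
    """Chasles decomposition of a rigid transform into screw parameters.

    The axis direction is flipped, together with the twist sign, so that the
    rise is non-negative.  A pure translation decomposes as twist 0 with the
    axis along the translation; the identity transform has no axis and raises
    :class:`DegeneracyError`.
    """
    rotvec = Rotation.from_matrix(t.rotation).as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    tr = t.translation
    if angle < angle_tol:
        norm = float(np.linalg.norm(tr))
        if norm < 1e-12:
            raise DegeneracyError("identity transform: screw axis undefined")
        axis = tr / norm
        return HelicalParams(rise=norm, twist=0.0, axis_point=np.zeros(3), axis_direction=axis)
    axis = rotvec / angle
    twist = np.rad2deg(angle)
    rise = float(tr @ axis)
    if rise < 0.0:
        axis = -axis
        twist = -twist
        rise = -rise
    elif rise == 0.0:
        # rise-free rotation: fix the axis sign deterministically
        k = int(np.argmax(np.abs(axis)))
        if axis[k] < 0:
            axis = -axis
            twist = -twist
    twist = wrap_angle_deg(twist)
    # axis point: least-squares solution of (I - R) p = t_perp, p ⟂ axis
    t_perp = tr - (tr @ axis) * axis
    A = np.eye(3) - t.rotation
    p, *_ = np.linalg.lstsq(A, t_perp, rcond=None)
    p = p - (p @ axis) * axis
    return HelicalParams(rise=rise, twist=float(twist), axis_point=p, axis_direction=axis)


def chain_id_for_index(k: int) -> str:
    """Chain id for filament copy k: A..Z, then AA, AB, ... (mmCIF only)."""
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    if k < 26:
        return letters[k]
    k -= 26
    return letters[k // 26] + letters[k % 26]


@dataclass
class Filament:
    """Ordered subunit copies under a generating screw transform.

    Copy k equals ``transform`` applied k times to ``subunit``; copy 0 is the
    subunit itself.  Copies carry distinct chain ids A, B, ... .
    """

    subunit: Structure
    transform: RigidTransform
    n_subunits: int

    def __post_init__(self):
        if self.n_subunits < 1:
            raise ValidationError("n_subunits must be >= 1")

    def copy(self, k: int) -> Structure:
        if not 0 <= k < self.n_subunits:
            raise IndexError(f"copy index {k} out of range [0, {self.n_subunits})")
        tk = self.transform.power(k)
        out = self.subunit.with_coords(tk.apply(self.subunit.coords))
        out.chain_ids = [chain_id_for_index(k)] * len(out)
        return out

    @property
    def copies(self) -> list[Structure]:
        return [self.copy(k) for k in range(self.n_subunits)]

    def coords(self) -> np.ndarray:
        """(n_subunits, n_atoms, 3) coordinate stack."""
        return np.stack([c.coords for c in self.copies])

    def as_structure(self) -> Structure:
        parts = self.copies
        names: list[str] = []
        elements: list[str] = []
        resids: list[int] = []
        resnames: list[str] = []
        chains: list[str] = []
        coords = np.concatenate([p.coords for p in parts]) if parts else np.zeros((0, 3))
        for p in parts:
            names.extend(p.names)
            elements.extend(p.elements)
            resids.extend(p.residue_indices.tolist())
            resnames.extend(p.residue_names)
            chains.extend(p.chain_ids)
        return Structure.from_arrays(
            names, elements, coords, resids, resnames, chains, self.subunit.metadata
        )


def propagate(subunit: Structure, t: RigidTransform, n: int) -> Filament:
    """Generate an n-copy filament from a subunit and its screw transform."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    return Filament(subunit=subunit, transform=t, n_subunits=n)


def _subunit_stack(f) -> np.ndarray:
    """Normalise a Filament / sequence of coordinate arrays to (k, n, 3)."""
    if isinstance(f, Filament):
        return f.coords()
    arrays = [np.asarray(a, dtype=float) for a in f]
    if len(arrays) < 2:
        raise ValidationError("need >= 2 consecutive subunits to fit a transform")
    shape = arrays[0].shape
    for a in arrays:
        if a.shape != shape:
            raise ValidationError("consecutive subunits must share atom count and order")
    return np.stack(arrays)


def fit_helical_params(f: "Filament | Iterable[np.ndarray]") -> HelicalParams:
    """Recover screw parameters from consecutive subunit coordinates.

    A single least-squares rigid transform is fitted over all consecutive
    pairs jointly (equivalent to averaging the per-pair Kabsch solutions in
    the least-squares sense) and then screw-decomposed.  On noise-free
    generated filaments this reproduces the generating parameters to
    numerical precision.
    """
    stack = _subunit_stack(f)
    if stack.shape[0] < 2:
        raise ValidationError("need >= 2 subunits")
    mobile = stack[:-1].reshape(-1, 3)
    target = stack[1:].reshape(-1, 3)
    R, t, _ = kabsch(mobile, target)
    return screw_decompose(RigidTransform(R, t))


def ring_count(p: HelicalParams, angle_tol: float = 30.0, n_max: int = 24):
    """Smallest n in 2..n_max whose cumulative twist closes a ring.

    n closes a ring when n·twist lies within ``angle_tol`` degrees of a
    multiple of 360°.  Returns ``None`` when no n qualifies or the twist is 0
    (no ring defined).
    """
    if p.twist == 0.0:
        return None
    for n in range(2, n_max + 1):
        residual = abs(wrap_angle_deg(n * p.twist))
        if residual < angle_tol:
            return n
    return None


def strand_step(f: Filament, contact_cutoff: float = 4.5) -> int:
    """Smallest index offset k at which subunits touch; k strands when k > 1.

    Contacts are heavy-atom pairs within ``contact_cutoff`` Å, evaluated from
    a central subunit outward to avoid end effects.
    """
    if f.n_subunits < 4:
        raise ValidationError("strand_step needs >= 4 subunits")
    heavy_idx = [i for i, e in enumerate(f.subunit.elements) if e.upper() not in ("H", "D")]
    stack = f.coords()[:, heavy_idx, :]
    i = (f.n_subunits - 1) // 2
    tree = cKDTree(stack[i])
    for k in range(1, f.n_subunits - i):
        other = cKDTree(stack[i + k])
        if tree.count_neighbors(other, contact_cutoff) > 0:
            return k
    raise NoContactError(
        f"no inter-subunit heavy-atom contacts within {contact_cutoff} Å at any offset"
    )


def detect_antiparallel(
    s: Structure, axis: Sequence[float]
) -> tuple[bool, dict[str, int]]:
    """Classify per-chain orientation relative to the filament axis.

    Each chain's principal axis is the leading eigenvector of its CA
    coordinate covariance, with the direction disambiguated N-terminus →
    C-terminus.  The orientation sign is the sign of its dot product with
    the filament axis; the arrangement is antiparallel (dihedral-symmetric,
    D1-like) iff both signs occur.
    """
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    signs: dict[str, int] = {}
    for cid in s.chain_order():
        chain = s.chains[cid]
        ca = chain.coords[[n == "CA" for n in chain.names]]
        if ca.shape[0] < 2:
            raise DegeneracyError(f"chain {cid!r}: too few CA atoms for a principal axis")
        centred = ca - ca.mean(axis=0)
        cov = centred.T @ centred / ca.shape[0]
        evals, evecs = np.linalg.eigh(cov)
        # a usable principal axis needs a clear anisotropy margin; near-equal
        # leading eigenvalues mean a spherical subunit with no defined axis
        if evals[2] < 1e-12 or (evals[2] - evals[1]) / evals[2] < 0.1:
            raise DegeneracyError(f"chain {cid!r}: degenerate (spherical) subunit")
        pax = evecs[:, 2]
        nc = ca[-1] - ca[0]
        if pax @ nc < 0:
            pax = -pax
        signs[cid] = 1 if pax @ a >= 0 else -1
    return len(set(signs.values())) > 1, signs


@dataclass(frozen=True)
class DockSample:
    """One candidate helical dock from the grid sampler."""

    transform: RigidTransform
    n_contacts: int
    min_distance: float
    clash: bool
    rise: float = np.nan
    twist: float = np.nan
    radial_offset: float = 0.0
    axial_spin: float = 0.0


def sample_docks(
    subunit: Structure,
    grid: dict,
    clash_cutoff: float = 2.4,
    contact_cutoff: float = 4.5,
    n_copies: int = 5,
) -> list[DockSample]:
    """Enumerate helical docks over a (rise, twist, radial_offset, axial_spin)
    grid about the +z axis.

    For each grid point the subunit is spun about z by ``axial_spin``,
    displaced radially by ``radial_offset`` along +x, and propagated for
    ``n_copies`` copies under the screw (rise, twist).  ``min_distance`` is
    the minimum inter-copy heavy-atom distance over all copy pairs;
    ``n_contacts`` counts inter-copy heavy-atom pairs within
    ``contact_cutoff``; ``clash`` flags ``min_distance < clash_cutoff``.
    Grid order is the deterministic nested product rise → twist → offset →
    spin.
    """
    rises = list(grid.get("rise", []))
    twists = list(grid.get("twist", []))
    offsets = list(grid.get("radial_offset", [0.0]))
    spins = list(grid.get("axial_spin", [0.0]))
    if not rises or not twists or not offsets or not spins:
        raise ValidationError("dock grid must provide non-empty rise and twist ranges")
    heavy_idx = [i for i, e in enumerate(subunit.elements) if e.upper() not in ("H", "D")]
    base = subunit.coords[heavy_idx]
    out: list[DockSample] = []
    for rise, twist, offset, spin in itertools.product(rises, twists, offsets, spins):
        pre = RigidTransform.from_axis_angle([0, 0, 1], spin).compose(
            RigidTransform(np.eye(3), np.array([offset, 0.0, 0.0]))
        )
        placed = pre.apply(base)
        screw = RigidTransform.from_axis_angle([0, 0, 1], twist, [0.0, 0.0, rise])
        copies = []
        cur = placed
        for _ in range(n_copies):
            copies.append(cur)
            cur = screw.apply(cur)
        min_d = np.inf
        n_contacts = 0
        trees = [cKDTree(c) for c in copies]
        for i in range(n_copies):
            for j in range(i + 1, n_copies):
                d = trees[i].sparse_distance_matrix(
                    trees[j], max_distance=contact_cutoff, output_type="coo_matrix"
                )
                if d.nnz:
                    n_contacts += d.nnz
                    min_d = min(min_d, float(d.data.min()))
        if not np.isfinite(min_d):
            # no pair within contact cutoff; report the true global minimum
            min_d = min(
                float(np.min(np.linalg.norm(copies[i][:, None, :] - copies[j][None, :, :], axis=-1)))
                for i in range(n_copies)
                for j in range(i + 1, n_copies)
            )
        out.append(
            DockSample(
                transform=screw,
                n_contacts=n_contacts,
                min_distance=min_d,
                clash=min_d < clash_cutoff,
                rise=rise,
                twist=twist,
                radial_offset=offset,
                axial_spin=spin,
            )
        )
    return out
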