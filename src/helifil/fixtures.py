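"""Deterministic generators for every synthetic input the test surface needs.

All generators are pure functions of their arguments (seeds are explicit;
there is no global RNG state), so repeated calls are bit-identical.

The backbone builder chains ideal internal coordinates (bond lengths and
angles below, trans peptide ω = 180°), which guarantees proper peptide-bond
C-N distances everywhere.  The helical (φ, ψ) pair is the numerical solution
under that geometry for a helix with exactly 1.5 Å rise and 100° twist per
residue — the textbook ideal α-helix parameters used throughout the package.

Generated bundle subunits are poly-alanine (N, CA, C, O, CB): sequence design
is out of scope, but the CB atoms make burial and contact metrics meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._superpose import kabsch
from .errors import ValidationError
from .helical_geometry import RigidTransform, screw_decompose
from .loop_closure import Fragment, FragmentDB
from .model_io import Structure

__all__ = [
    "BundleSpec",
    "Preset",
    "make_bundle_subunit",
    "get_preset",
    "list_presets",
    "make_design_records",
    "make_fragment_db",
    "build_backbone",
    "HELIX_PHI",
    "HELIX_PSI",
]

# ideal backbone internal coordinates (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
# N-CA-C tuned with (φ, ψ) below so the textbook helix parameters are exactly
# realisable under the ideal bond lengths; within the observed protein range.
ANGLE_N_CA_C = 109.74588558
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.4
OMEGA = 180.0

# helical torsions solved numerically (with ANGLE_N_CA_C above) so the
# ideal-geometry helix has 1.5 Å rise and 100.0°/residue twist to < 1e-6;
# calibrated once, see docs/methods.md
HELIX_PHI = -63.55924164448926
HELIX_PSI = -41.43290878232572

# per-residue atom order emitted by the builders
BB_ATOMS = ("N", "CA", "C", "O")
RESIDUE_ATOMS = ("N", "CA", "C", "O", "CB")


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float
) -> np.ndarray:
    """Place atom D from references A-B-C with |CD| = bond, angle(BCD) and
    torsion(ABCD) in degrees (natural extension of reference frame, NeRF)."""
    ang = np.deg2rad(angle)
    tor = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    torsions: Sequence[tuple[float, float]], with_cb: bool = False
) -> np.ndarray:
    """Chain a backbone from per-residue (φ, ψ) torsions.

    Returns (n_residues, 4, 3) coordinates in N, CA, C, O order, or
    (n_residues, 5, 3) with CB appended when ``with_cb``.  ω is fixed trans.
    The first residue's φ and the last residue's ψ close the construction but
    have no upstream/downstream partner, matching the usual convention.
    """
    n_res = len(torsions)
    if n_res < 1:
        raise ValidationError("need at least one residue")
    n_at = 5 if with_cb else 4
    out = np.zeros((n_res, n_at, 3))
    # seed frame for residue 0
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    C = CA + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    prev_N, prev_CA, prev_C = N, CA, C
    for i, (phi, psi) in enumerate(torsions):
        if i > 0:
            N = place_atom(prev_N, prev_CA, prev_C, BOND_C_N, ANGLE_CA_C_N, torsions[i - 1][1])
            CA = place_atom(prev_CA, prev_C, N, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
            C = place_atom(prev_C, N, CA, BOND_CA_C, ANGLE_N_CA_C, phi)
        O = place_atom(N, CA, C, BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        out[i, 0], out[i, 1], out[i, 2], out[i, 3] = N, CA, C, O
        if with_cb:
            out[i, 4] = place_atom(C, N, CA, BOND_CA_CB, ANGLE_N_CA_CB, -122.6)
        prev_N, prev_CA, prev_C = N, CA, C
    return out


def _canonical_helix(n_res: int, with_cb: bool = True) -> np.ndarray:
    """Ideal helix with its screw axis along +z through the origin, rise
    positive from residue 1 to n (N→C runs along +z)."""
    raw = build_backbone([(HELIX_PHI, HELIX_PSI)] * n_res, with_cb=with_cb)
    mobile = raw[:-1].reshape(-1, 3)
    target = raw[1:].reshape(-1, 3)
    R, t, _ = kabsch(mobile, target)
    params = screw_decompose(RigidTransform(R, t))
    axis = params.axis_direction
    # rotation taking the helix axis onto +z
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    c = float(axis @ z)
    if s < 1e-12:
        Rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]])
        Rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    flat = (raw.reshape(-1, 3) - params.axis_point) @ Rot.T
    flat[:, 2] -= flat[:, 2].mean()
    return flat.reshape(raw.shape)


@dataclass(frozen=True)
class BundleSpec:
    """Specification of an idealized helical-bundle subunit (a stand-in for a
    loop-connected three-protomer monomer)."""

    n_helices: int = 3
    residues_per_helix: int = 20
    bundle_radius: float = 7.0
    seed: int = 0

    def __post_init__(self):
        if self.n_helices < 1:
            raise ValidationError("n_helices must be >= 1")
        if self.residues_per_helix < 4:
            raise ValidationError("residues_per_helix must be >= 4")
        if self.bundle_radius < 0:
            raise ValidationError("bundle_radius must be >= 0")


def make_bundle_subunit(spec: BundleSpec, clash_cutoff: float = 2.4) -> Structure:
    """Poly-alanine helical bundle: ideal helices on a circle of
    ``bundle_radius``, alternating up/down, each with a seed-derived azimuthal
    spin about its own axis.  Deterministic for a fixed spec."""
    rng = np.random.default_rng(spec.seed)
    spins = rng.uniform(0.0, 360.0, size=spec.n_helices)
    helix = _canonical_helix(spec.residues_per_helix, with_cb=True)
    names: list[str] = []
    elements: list[str] = []
    coords: list[np.ndarray] = []
    resids: list[int] = []
    resnames: list[str] = []
    res_counter = 0
    flip = np.diag([1.0, -1.0, -1.0])  # 180° about x: up helix -> down helix
    helix_blocks = []
    for h in range(spec.n_helices):
        block = helix.reshape(-1, 3).copy()
        if h % 2 == 1:
            block = block @ flip.T
        spin = np.deg2rad(spins[h])
        Rz = np.array(
            [
                [np.cos(spin), -np.sin(spin), 0.0],
                [np.sin(spin), np.cos(spin), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        block = block @ Rz.T
        theta = 2.0 * np.pi * h / spec.n_helices
        block += spec.bundle_radius * np.array([np.cos(theta), np.sin(theta), 0.0])
        helix_blocks.append(block.reshape(spec.residues_per_helix, 5, 3))
    for block in helix_blocks:
        for res in block:
            res_counter += 1
            for name, xyz in zip(RESIDUE_ATOMS, res):
                names.append(name)
                elements.append(name[0])
                coords.append(xyz)
                resids.append(res_counter)
                resnames.append("ALA")
    if spec.n_helices > 1:
        # construction check: adjacent helices must not clash
        min_d = min(
            float(
                np.min(
                    np.linalg.norm(
                        helix_blocks[i].reshape(-1, 1, 3)
                        - helix_blocks[j].reshape(1, -1, 3),
                        axis=-1,
                    )
                )
            )
            for i in range(spec.n_helices)
            for j in range(i + 1, spec.n_helices)
        )
        if min_d <= clash_cutoff:
            raise ValidationError(
                f"bundle_radius {spec.bundle_radius} Å produces an inter-helix "
                f"clash (min distance {min_d:.2f} Å <= {clash_cutoff} Å)"
            )
    return Structure.from_arrays(
        names,
        elements,
        np.asarray(coords),
        resids,
        resnames,
        ["A"] * len(names),
        {"generator": f"make_bundle_subunit({spec!r})"},
    )


@dataclass(frozen=True)
class Preset:
    """A named generating transform with provenance notes."""

    name: str
    transform: RigidTransform
    notes: str

    @property
    def rise(self) -> float:
        return screw_decompose(self.transform).rise if _is_nonidentity(self.transform) else 0.0

    @property
    def twist(self) -> float:
        return screw_decompose(self.transform).twist if _is_nonidentity(self.transform) else 0.0


def _is_nonidentity(t: RigidTransform) -> bool:
    return not (
        np.allclose(t.rotation, np.eye(3), atol=1e-12)
        and np.allclose(t.translation, 0.0, atol=1e-12)
    )


def _preset_registry() -> dict[str, Preset]:
    return {
        "identity": Preset(
            "identity", RigidTransform.identity(), "null transform (no rise, no twist)"
        ),
        "DpHF19": Preset(
            "DpHF19",
            RigidTransform.from_axis_angle([0, 0, 1], -148.9, [0.0, 0.0, 8.4]),
            "one-start helical symmetry of the optimized pH-responsive filament "
            "design: 8.4 Å rise, -148.9° twist per subunit about +z",
        ),
    }


def get_preset(name: str) -> Preset:
    """Look up a named preset transform ('identity' or 'DpHF19')."""
    registry = _preset_registry()
    if name not in registry:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(registry)}")
    return registry[name]


def list_presets() -> list[str]:
    return sorted(_preset_registry())


def make_design_records(n: int, seed: int) -> pd.DataFrame:
    """Synthetic design-record table exercising the filter pipeline.

    Metric columns are drawn uniformly from documented ranges that straddle
    every filter threshold: energy_gap U(-30, 0), buried_area U(300, 1200) Å²,
    sc U(0.3, 0.9), unsat_count integer U(0, 10).  A dock_id column groups
    roughly ten designs per dock.  Deterministic per seed.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    rng = np.random.default_rng(seed)
    n_docks = max(1, n // 10)
    df = pd.DataFrame(
        {
            "design_id": [f"design_{i:05d}" for i in range(n)],
            "dock_id": [f"dock_{int(d):04d}" for d in rng.integers(0, n_docks, size=n)],
            "energy_gap": rng.uniform(-30.0, 0.0, size=n),
            "buried_area": rng.uniform(300.0, 1200.0, size=n),
            "sc": rng.uniform(0.3, 0.9, size=n),
            "unsat_count": rng.integers(0, 11, size=n),
        }
    )
    return df


def make_fragment_db(n_fragments: int, seed: int) -> FragmentDB:
    """Miniature synthetic loop-fragment database.

    Fragments are 3-8 residues with helical (φ, ψ) on both terminal residues
    (helical caps) and randomized loop torsions in between, built with the
    ideal-geometry backbone chainer.  Deterministic per seed.
    """
    if n_fragments < 1:
        raise ValidationError("n_fragments must be >= 1")
    rng = np.random.default_rng(seed)
    fragments: list[Fragment] = []
    for i in range(n_fragments):
        n_res = int(rng.integers(3, 9))
        torsions: list[tuple[float, float]] = []
        for j in range(n_res):
            if j == 0 or j == n_res - 1:
                torsions.append((HELIX_PHI, HELIX_PSI))
            else:
                torsions.append(
                    (float(rng.uniform(-150.0, -45.0)), float(rng.uniform(-60.0, 150.0)))
                )
        coords = build_backbone(torsions, with_cb=False)
        fragments.append(Fragment(f"frag_{i:04d}", coords))
    return FragmentDB(fragments)


def make_linear_trace(L0: float, slope: float, t_end: float, dt: float):
    """Noiseless straight-line length trace (nm vs min) for estimator tests;
    length is clipped at zero."""
    from .disassembly_kinetics import FibreTrace

    times = np.arange(0.0, t_end + dt / 2, dt)
    length = np.clip(L0 + slope * times, 0.0, None)
    return FibreTrace(
        times=times,
        length_total=length.copy(),
        length_longest=length.copy(),
        end1_recession=np.zeros_like(times),
        end2_recession=np.zeros_like(times),
        seed=0,
    )
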