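"""Interface-quality metrics and the four-filter design pipeline.

Per-interface metrics on filament subunit pairs:

* buried surface area — Shrake-Rupley solvent-accessible areas with a
  deterministic golden-spiral quadrature; interface area is the both-sides
  total ``sasa(i) + sasa(j) - sasa(i ∪ j)`` (configurable to per-side).
* shape complementarity — the Lawrence-Colman statistic on dot surfaces of
  the buried patches, ``exp(-w d²) (n̂_a · -n̂_b)`` scored to the nearest
  partner dot, mean of the two directional medians, peripheral band trimmed.
* buried unsatisfied polars — interface residues with a buried polar heavy
  atom lacking any partner polar heavy atom within 3.5 Å (donor hydrogens
  are waived: design-stage models are hydrogen-free).
* energy gap — a transparent pairwise contact pseudo-energy standing in for
  a full force-field bound-minus-unbound score: -1 per heavy-atom contact
  pair within 4.5 Å, capped at -3 per residue pair, +10 per clash pair
  under 2.4 Å.  Its absolute scale is NOT claimed to match any force-field
  unit; filter thresholds are configuration.

The filter pipeline keeps designs with energy_gap <= -15.0, buried_area >
700 Å², sc > 0.62 and unsat_count < 5, and reports per-criterion attrition;
a top-per-dock selector picks the best-scoring survivor of each docked
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import UndefinedMetricError, ValidationError
from .helical_geometry import Filament
from .model_io import Structure

__all__ = [
    "VDW_RADII",
    "InterfaceReport",
    "FilterThresholds",
    "sasa",
    "interface_area",
    "shape_complementarity",
    "sc_from_dots",
    "unsat_polar_count",
    "energy_gap",
    "contact_energy",
    "interface_report",
    "apply_filters",
    "select_top_per_dock",
]

# heavy-atom van der Waals radii, Å
VDW_RADII: Mapping[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

PROBE_RADIUS = 1.4  # Å
DEFAULT_N_POINTS = 960  # quadrature points per sphere

CONTACT_CUTOFF = 4.5  # Å, heavy-atom contact
CLASH_CUTOFF = 2.4  # Å
CONTACT_CAP_PER_RESPAIR = 3  # max |energy| per residue pair
CLASH_PENALTY = 10.0

# side-chain polar heavy atoms by residue type; backbone N and O are polar
# in every residue
SIDECHAIN_POLARS: Mapping[str, frozenset] = {
    "ASN": frozenset({"OD1", "ND2"}),
    "GLN": frozenset({"OE1", "NE2"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "LYS": frozenset({"NZ"}),
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "TRP": frozenset({"NE1"}),
}
BACKBONE_POLARS = frozenset({"N", "O", "OXT"})


def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _radii(s: Structure) -> np.ndarray:
    out = np.empty(len(s))
    for i, e in enumerate(s.elements):
        key = e.upper()
        if key not in VDW_RADII:
            raise ValidationError(
                f"no van der Waals radius for element {e!r}; known: {sorted(VDW_RADII)}"
            )
        out[i] = VDW_RADII[key]
    return out


def sasa(
    s: Structure, probe: float = PROBE_RADIUS, n_points: int = DEFAULT_N_POINTS
) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (Å², Shrake-Rupley).

    Hydrogens get zero area and do not occlude; the quadrature point set has
    a fixed lab-frame orientation, so areas carry a small (<0.5%) jitter
    under rigid motion of the structure.
    """
    heavy_mask = np.array([e.upper() not in ("H", "D") for e in s.elements])
    areas = np.zeros(len(s))
    idx = np.flatnonzero(heavy_mask)
    if len(idx) == 0:
        return areas
    coords = s.coords[idx]
    radii = _radii(s.select(heavy_mask))
    ext = radii + probe
    unit = _golden_spiral(n_points)
    tree = cKDTree(coords)
    r_max = float(ext.max())
    for k in range(len(idx)):
        neighbours = [
            j for j in tree.query_ball_point(coords[k], ext[k] + r_max) if j != k
        ]
        pts = coords[k] + ext[k] * unit
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 >= ext[j] ** 2
        areas[idx[k]] = 4.0 * np.pi * ext[k] ** 2 * exposed.mean()
    return areas


def _pair_structures(f: Filament, i: int, j: int) -> tuple[Structure, Structure]:
    if i == j:
        raise ValidationError("subunit indices must differ")
    return f.copy(i), f.copy(j)


def _merge(s1: Structure, s2: Structure) -> Structure:
    return Structure.from_arrays(
        s1.names + s2.names,
        s1.elements + s2.elements,
        np.concatenate([s1.coords, s2.coords]),
        np.concatenate([s1.residue_indices, s2.residue_indices]),
        s1.residue_names + s2.residue_names,
        s1.chain_ids + s2.chain_ids,
    )


def buried_area_pair(
    s1: Structure,
    s2: Structure,
    probe: float = PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    per_side: bool = False,
) -> float:
    """Total buried area of a pair: sasa(1) + sasa(2) - sasa(1 ∪ 2)."""
    # quick reject: no atom pair can be closer than 2 (r_max + probe)
    r_max = max(VDW_RADII.values())
    t1, t2 = cKDTree(s1.coords), cKDTree(s2.coords)
    if t1.count_neighbors(t2, 2.0 * (r_max + probe)) == 0:
        return 0.0
    a1 = sasa(s1, probe, n_points).sum()
    a2 = sasa(s2, probe, n_points).sum()
    a12 = sasa(_merge(s1, s2), probe, n_points).sum()
    buried = max(0.0, float(a1 + a2 - a12))
    return buried / 2.0 if per_side else buried


def interface_area(
    f: Filament,
    i: int,
    j: int,
    probe: float = PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    per_side: bool = False,
) -> float:
    """Buried surface area (Å²) between subunits i and j of a filament.

    Both-sides total by convention (``per_side=True`` halves it); 0 for a
    non-contacting pair.  Exactly symmetric in (i, j): the pair is evaluated
    in canonical index order.
    """
    s1, s2 = _pair_structures(f, min(i, j), max(i, j))
    return buried_area_pair(s1, s2, probe, n_points, per_side)


# ------------------------------------------------------------ shape complementarity


def _dot_surface(
    s: Structure, density: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dots on the exposed van der Waals surface of a structure.

    Returns (points, outward normals, owner atom index); about ``density``
    dots per Å² of sphere surface before occlusion.
    """
    heavy = s.heavy()
    coords = heavy.coords
    radii = _radii(heavy)
    pts_all, nrm_all, owner_all = [], [], []
    tree = cKDTree(coords)
    r_max = float(radii.max())
    for k in range(len(coords)):
        n_dots = max(8, int(round(4.0 * np.pi * radii[k] ** 2 * density)))
        unit = _golden_spiral(n_dots)
        pts = coords[k] + radii[k] * unit
        keep = np.ones(n_dots, dtype=bool)
        for j in tree.query_ball_point(coords[k], radii[k] + r_max):
            if j == k:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            keep &= d2 >= radii[j] ** 2
        if keep.any():
            pts_all.append(pts[keep])
            nrm_all.append(unit[keep])
            owner_all.append(np.full(int(keep.sum()), k))
    if not pts_all:
        return np.zeros((0, 3)), np.zeros((0, 3)), np.zeros(0, dtype=int)
    return np.concatenate(pts_all), np.concatenate(nrm_all), np.concatenate(owner_all)


def sc_from_dots(
    dots_a: np.ndarray,
    normals_a: np.ndarray,
    dots_b: np.ndarray,
    normals_b: np.ndarray,
    w: float = 0.5,
) -> float:
    """Shape-complementarity statistic for two pre-computed dot patches.

    For every dot on one patch the nearest dot on the partner patch scores
    ``exp(-w d²) (n̂_a · -n̂_b)``; the statistic is the mean of the two
    directional medians and lies in [-1, 1].
    """
    if len(dots_a) == 0 or len(dots_b) == 0:
        raise UndefinedMetricError("empty buried patch: shape complementarity undefined")
    tree_a, tree_b = cKDTree(dots_a), cKDTree(dots_b)
    d_ab, idx_ab = tree_b.query(dots_a)
    s_ab = np.exp(-w * d_ab**2) * np.einsum("ij,ij->i", normals_a, -normals_b[idx_ab])
    d_ba, idx_ba = tree_a.query(dots_b)
    s_ba = np.exp(-w * d_ba**2) * np.einsum("ij,ij->i", normals_b, -normals_a[idx_ba])
    return float((np.median(s_ab) + np.median(s_ba)) / 2.0)


def shape_complementarity(
    f: Filament,
    i: int,
    j: int,
    w: float = 0.5,
    band_trim: float = 1.5,
    dot_density: float = 10.0,
    probe: float = PROBE_RADIUS,
) -> float:
    """Lawrence-Colman shape complementarity of the i-j interface.

    Dot surfaces are generated on each side's exposed van der Waals surface;
    a dot belongs to the buried patch when a solvent probe no longer fits
    between it and the partner (gap < 2·probe).  Dots within ``band_trim`` Å
    of the patch periphery are excluded before scoring.
    """
    s1, s2 = _pair_structures(f, i, j)
    patches = []
    for own, other in ((s1, s2), (s2, s1)):
        pts, nrm, _ = _dot_surface(own, dot_density)
        if len(pts) == 0:
            raise UndefinedMetricError("no exposed surface dots")
        other_heavy = other.heavy()
        radii_o = _radii(other_heavy)
        tree_o = cKDTree(other_heavy.coords)
        d, idx = tree_o.query(pts)
        buried = d < radii_o[idx] + 2.0 * probe
        if buried.sum() == 0:
            raise UndefinedMetricError("empty buried patch: subunits do not meet")
        # peripheral band: drop buried dots close to any non-buried dot
        if band_trim > 0 and (~buried).any():
            rim_tree = cKDTree(pts[~buried])
            d_rim, _ = rim_tree.query(pts[buried])
            keep = d_rim > band_trim
        else:
            keep = np.ones(int(buried.sum()), dtype=bool)
        if keep.sum() == 0:
            raise UndefinedMetricError(
                "buried patch vanished after peripheral band trimming"
            )
        patches.append((pts[buried][keep], nrm[buried][keep]))
    (pa, na), (pb, nb) = patches
    return sc_from_dots(pa, na, pb, nb, w)


# ------------------------------------------------------- buried unsatisfied polars


def _polar_mask(s: Structure) -> np.ndarray:
    out = np.zeros(len(s), dtype=bool)
    for i in range(len(s)):
        name = s.names[i]
        res = s.residue_names[i].upper()
        if name in BACKBONE_POLARS or name in SIDECHAIN_POLARS.get(res, frozenset()):
            out[i] = True
    return out


def unsat_polar_count(
    f: Filament,
    i: int,
    j: int,
    d_max: float = 3.5,
    burial_sasa: float = 5.0,
    contact_cutoff: float = CONTACT_CUTOFF,
    n_points: int = DEFAULT_N_POINTS,
) -> int:
    """Number of interface residues with a buried, unsatisfied polar atom.

    A residue is an interface residue when any of its heavy atoms lies within
    ``contact_cutoff`` of the partner subunit.  Its polar heavy atom is
    buried when its per-atom SASA in the complex is below ``burial_sasa`` Å²,
    and unsatisfied when no polar heavy atom of another residue (either
    subunit) lies within ``d_max`` Å.  Solvent-exposed polars never count.
    """
    s1, s2 = _pair_structures(f, i, j)
    merged = _merge(s1, s2).heavy()
    complex_sasa = sasa(merged, n_points=n_points)
    polar = _polar_mask(merged)
    n1 = len(s1.heavy())
    side = np.array([0] * n1 + [1] * (len(merged) - n1))
    coords = merged.coords
    tree1 = cKDTree(coords[side == 0])
    tree2 = cKDTree(coords[side == 1])
    # interface residues: any atom within contact cutoff of the partner
    d_to_partner = np.empty(len(merged))
    d_to_partner[side == 0] = tree2.query(coords[side == 0])[0]
    d_to_partner[side == 1] = tree1.query(coords[side == 1])[0]
    res_key = [
        (merged.chain_ids[k], int(merged.residue_indices[k])) for k in range(len(merged))
    ]
    interface_residues = {
        res_key[k] for k in range(len(merged)) if d_to_partner[k] <= contact_cutoff
    }
    polar_idx = np.flatnonzero(polar)
    polar_tree = cKDTree(coords[polar_idx])
    unsat_residues = set()
    for k in polar_idx:
        rk = res_key[k]
        if rk not in interface_residues or rk in unsat_residues:
            continue
        if complex_sasa[k] >= burial_sasa:
            continue
        partners = polar_tree.query_ball_point(coords[k], d_max)
        satisfied = any(res_key[polar_idx[p]] != rk for p in partners)
        if not satisfied:
            unsat_residues.add(rk)
    return len(unsat_residues)


# ----------------------------------------------------------------- energy surrogate


def contact_energy(s1: Structure, s2: Structure) -> float:
    """Pairwise contact pseudo-energy between two subunits.

    -1 per heavy-atom pair within 4.5 Å, capped at -3 per residue pair;
    +10 per clash pair closer than 2.4 Å (clashes are not capped).
    """
    h1, h2 = s1.heavy(), s2.heavy()
    if len(h1) == 0 or len(h2) == 0:
        return 0.0
    t1, t2 = cKDTree(h1.coords), cKDTree(h2.coords)
    pairs = t1.sparse_distance_matrix(t2, CONTACT_CUTOFF, output_type="coo_matrix")
    if pairs.nnz == 0:
        return 0.0
    contact_by_respair: dict[tuple, int] = {}
    n_clash = 0
    for a, b, d in zip(pairs.row, pairs.col, pairs.data):
        if d < CLASH_CUTOFF:
            n_clash += 1
        key = (int(h1.residue_indices[a]), int(h2.residue_indices[b]))
        contact_by_respair[key] = contact_by_respair.get(key, 0) + 1
    energy = -float(
        sum(min(n, CONTACT_CAP_PER_RESPAIR) for n in contact_by_respair.values())
    )
    return energy + CLASH_PENALTY * n_clash


def energy_gap(f: Filament, i: int) -> float:
    """Bound-minus-unbound surrogate energy of subunit i in its filament
    context.  The rigid monomer's unbound energy is zero by construction, so
    the gap is the summed inter-subunit contact energy (negative favours
    assembly); an isolated subunit returns 0."""
    si = f.copy(i)
    total = 0.0
    for j in range(f.n_subunits):
        if j != i:
            total += contact_energy(si, f.copy(j))
    return total


@dataclass(frozen=True)
class InterfaceReport:
    """The four filter metrics for one interface/design."""

    buried_area: float
    sc: float
    unsat_count: int
    energy_gap: float

    def __post_init__(self):
        if self.buried_area < 0:
            raise ValidationError("buried_area must be >= 0")
        if not -1.0 <= self.sc <= 1.0:
            raise ValidationError("sc must lie in [-1, 1]")
        if self.unsat_count < 0:
            raise ValidationError("unsat_count must be >= 0")


def interface_report(f: Filament, i: int, j: int) -> InterfaceReport:
    """All four metrics for the i-j interface of a filament."""
    return InterfaceReport(
        buried_area=interface_area(f, i, j),
        sc=shape_complementarity(f, i, j),
        unsat_count=unsat_polar_count(f, i, j),
        energy_gap=energy_gap(f, i),
    )


# ------------------------------------------------------------------ filter pipeline


@dataclass(frozen=True)
class FilterThresholds:
    """The four-filter acceptance rule for design records."""

    max_energy_gap: float = -15.0  # keep if energy_gap <= this
    min_area: float = 700.0  # keep if buried_area > this (strict)
    min_sc: float = 0.62  # keep if sc > this (strict)
    max_unsat: int = 5  # keep if unsat_count < this (strict)

    def __post_init__(self):
        if self.min_area <= 0:
            raise ValidationError("min_area must be > 0")
        if not (0.0 < self.min_sc < 1.0):
            raise ValidationError("min_sc must lie in (0, 1)")


METRIC_COLUMNS = ("energy_gap", "buried_area", "sc", "unsat_count")


def _masks(records: pd.DataFrame, th: FilterThresholds) -> dict[str, pd.Series]:
    return {
        "energy_gap": records["energy_gap"] <= th.max_energy_gap,
        "buried_area": records["buried_area"] > th.min_area,
        "sc": records["sc"] > th.min_sc,
        "unsat_count": records["unsat_count"] < th.max_unsat,
    }


def apply_filters(
    records: pd.DataFrame, th: FilterThresholds | None = None
) -> tuple[pd.DataFrame, dict]:
    """Apply the four-filter rule; returns (survivors, attrition report).

    The report gives the count removed by each criterion applied
    independently and the joint survivor count.
    """
    th = th or FilterThresholds()
    missing = [c for c in METRIC_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"records table lacks metric column(s): {missing}")
    masks = _masks(records, th)
    joint = pd.Series(True, index=records.index)
    report: dict = {"n_input": int(len(records)), "removed_by": {}}
    for name, mask in masks.items():
        report["removed_by"][name] = int((~mask).sum())
        joint &= mask
    survivors = records[joint]
    report["n_survivors"] = int(len(survivors))
    report["removed_jointly"] = report["n_input"] - report["n_survivors"]
    return survivors, report


def select_top_per_dock(records: pd.DataFrame) -> pd.DataFrame:
    """One record per dock_id: minimal energy_gap, ties broken by design_id."""
    for col in ("dock_id", "energy_gap", "design_id"):
        if col not in records.columns:
            raise ValidationError(f"records table lacks column {col!r}")
    ordered = records.sort_values(["dock_id", "energy_gap", "design_id"], kind="mergesort")
    return ordered.groupby("dock_id", sort=True).head(1).reset_index(drop=True)
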