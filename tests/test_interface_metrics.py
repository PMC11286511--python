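import numpy as np
import pandas as pd
import pytest

from conftest import random_rotation
from helifil import fixtures as fx
from helifil import helical_geometry as hg
from helifil import interface_metrics as im
from helifil import model_io as mio
from helifil.errors import UndefinedMetricError, ValidationError


def _atoms(names, elements, coords, resids=None, resnames=None):
    n = len(names)
    return mio.Structure.from_arrays(
        names,
        elements,
        np.asarray(coords, dtype=float),
        resids if resids is not None else range(1, n + 1),
        resnames if resnames is not None else ["ALA"] * n,
        ["A"] * n,
    )


@pytest.fixture(scope="module")
def small_filament(bundle_subunit):
    return hg.propagate(bundle_subunit, fx.get_preset("DpHF19").transform, 3)


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        s = _atoms(["C1"], ["C"], [[0, 0, 0]])
        total = im.sasa(s).sum()
        analytic = 4 * np.pi * (1.7 + 1.4) ** 2
        assert total == pytest.approx(analytic, rel=0.01)

    def test_distant_spheres_are_isolated(self):
        d = 2 * (1.7 + 1.4) + 0.5
        s = _atoms(["C1", "C2"], ["C", "C"], [[0, 0, 0], [d, 0, 0]])
        areas = im.sasa(s)
        analytic = 4 * np.pi * 3.1**2
        assert areas[0] == pytest.approx(analytic, rel=0.01)
        assert areas[1] == pytest.approx(analytic, rel=0.01)

    @pytest.mark.parametrize("d", [2.0, 3.0, 4.5])
    def test_two_sphere_overlap_matches_cap_formula(self, d):
        """Total accessible area of two equal fused spheres: each loses the
        spherical cap beyond the bisecting plane, area 2πR(R - d/2)."""
        s = _atoms(["C1", "C2"], ["C", "C"], [[0, 0, 0], [d, 0, 0]])
        total = im.sasa(s).sum()
        R = 1.7 + 1.4
        analytic = 2 * (4 * np.pi * R**2 - 2 * np.pi * R * (R - d / 2))
        assert total == pytest.approx(analytic, rel=0.01)

    def test_rigid_motion_invariance_within_quadrature_jitter(self, bundle_subunit):
        total = im.sasa(bundle_subunit).sum()
        rng = np.random.default_rng(6)
        for _ in range(3):
            moved = bundle_subunit.with_coords(
                bundle_subunit.coords @ random_rotation(rng).T + rng.uniform(-30, 30, 3)
            )
            assert im.sasa(moved).sum() == pytest.approx(total, rel=0.005)

    def test_agrees_with_independent_implementation(self, bundle_subunit):
        """Cross-check against biotite's Shrake-Rupley (same Bondi radii)."""
        import biotite.structure as struc

        arr = struc.AtomArray(len(bundle_subunit))
        arr.coord = bundle_subunit.coords.astype(np.float32)
        arr.element = np.array(bundle_subunit.elements)
        arr.res_id = bundle_subunit.residue_indices
        arr.res_name = np.array(bundle_subunit.residue_names)
        arr.chain_id = np.array(bundle_subunit.chain_ids)
        arr.atom_name = np.array(bundle_subunit.names)
        ref = struc.sasa(arr, vdw_radii="Single", point_number=960).sum()
        assert im.sasa(bundle_subunit).sum() == pytest.approx(ref, rel=0.02)

    def test_unknown_element_named_in_error(self):
        s = _atoms(["FE"], ["Fe"], [[0, 0, 0]])
        with pytest.raises(ValidationError, match="Fe"):
            im.sasa(s)


class TestInterfaceArea:
    def test_distant_pair_is_zero(self, bundle_subunit):
        far = hg.RigidTransform(np.eye(3), np.array([200.0, 0.0, 0.0]))
        f = hg.propagate(bundle_subunit, far, 2)
        assert im.interface_area(f, 0, 1) == 0.0

    def test_symmetric_in_pair_order(self, small_filament):
        a = im.interface_area(small_filament, 0, 1)
        b = im.interface_area(small_filament, 1, 0)
        assert a == b
        assert a > 0

    def test_refinement_oracle_doubled_quadrature(self, small_filament):
        coarse = im.interface_area(small_filament, 0, 1, n_points=960)
        fine = im.interface_area(small_filament, 0, 1, n_points=1920)
        assert coarse == pytest.approx(fine, rel=0.02)

    def test_per_side_is_half_total(self, small_filament):
        total = im.interface_area(small_filament, 0, 1)
        per_side = im.interface_area(small_filament, 0, 1, per_side=True)
        assert per_side == pytest.approx(total / 2)


class TestShapeComplementarity:
    def _plane_dots(self, n=40, half=5.0):
        xs, ys = np.meshgrid(np.linspace(-half, half, n), np.linspace(-half, half, n))
        return np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])

    def test_perfectly_mated_planes(self):
        dots = self._plane_dots()
        up = np.tile([0.0, 0.0, 1.0], (len(dots), 1))
        sc = im.sc_from_dots(dots, up, dots.copy(), -up, w=0.5)
        assert sc == pytest.approx(1.0, abs=0.02)

    def test_planes_at_unit_gap_closed_form(self):
        dots = self._plane_dots()
        up = np.tile([0.0, 0.0, 1.0], (len(dots), 1))
        above = dots + [0.0, 0.0, 1.0]
        sc = im.sc_from_dots(dots, up, above, -up, w=0.5)
        assert sc == pytest.approx(np.exp(-0.5), abs=0.02)

    def test_random_unmated_patches_score_low(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.uniform(-5, 5, (300, 3))
            b = rng.uniform(-5, 5, (300, 3)) + [0, 0, 8.0]
            na = rng.normal(size=(300, 3))
            na /= np.linalg.norm(na, axis=1, keepdims=True)
            nb = rng.normal(size=(300, 3))
            nb /= np.linalg.norm(nb, axis=1, keepdims=True)
            assert im.sc_from_dots(a, na, b, nb, w=0.5) < 0.3

    def test_filament_interface_bounded_and_symmetric(self, small_filament):
        sc01 = im.shape_complementarity(small_filament, 0, 1)
        sc10 = im.shape_complementarity(small_filament, 1, 0)
        assert -1.0 <= sc01 <= 1.0
        assert sc01 == pytest.approx(sc10, abs=1e-12)

    def test_non_contacting_pair_undefined(self, bundle_subunit):
        far = hg.RigidTransform(np.eye(3), np.array([200.0, 0.0, 0.0]))
        f = hg.propagate(bundle_subunit, far, 2)
        with pytest.raises(UndefinedMetricError):
            im.shape_complementarity(f, 0, 1)


def _slab_subunit(with_og: bool) -> mio.Structure:
    """7x7 carbon slab with an asparagine OD1 substituted at the centre;
    optionally a serine OG placed to satisfy only the partner copy's OD1."""
    names, elements, coords, resids, resnames = [], [], [], [], []
    r = 0
    for ix in range(7):
        for iy in range(7):
            r += 1
            if ix == 3 and iy == 3:
                names.append("OD1"); elements.append("O"); resnames.append("ASN")
            else:
                names.append("C"); elements.append("C"); resnames.append("GLY")
            coords.append([ix * 1.8, iy * 1.8, 0.0])
            resids.append(r)
    if with_og:
        r += 1
        names.append("OG"); elements.append("O"); resnames.append("SER")
        coords.append([10.1, 6.3, 4.1])
        resids.append(r)
    return mio.Structure.from_arrays(
        names, elements, np.asarray(coords), resids, resnames, ["A"] * len(names)
    )


_SLAB_STEP = hg.RigidTransform(np.eye(3), np.array([1.9, 0.0, 3.2]))


class TestUnsatPolarCount:
    def test_poly_alanine_interface_has_none(self, small_filament):
        """Helical backbone N/O always have a neighbouring-residue polar
        within 3.5 Å, so a poly-alanine interface scores zero."""
        assert im.unsat_polar_count(small_filament, 0, 1) == 0

    def test_single_buried_unpartnered_asparagine(self):
        f = hg.Filament(_slab_subunit(with_og=True), _SLAB_STEP, 2)
        # brute-force confirmation of the constructed geometry: copy 0's OD1
        # has no polar heavy atom of another residue within 3.5 Å
        merged = im._merge(f.copy(0), f.copy(1))
        od1_0 = next(
            i
            for i in range(len(merged))
            if merged.names[i] == "OD1" and merged.chain_ids[i] == "A"
        )
        polars = [
            i
            for i in range(len(merged))
            if merged.names[i] in ("OD1", "OG")
            and (merged.chain_ids[i], int(merged.residue_indices[i]))
            != (merged.chain_ids[od1_0], int(merged.residue_indices[od1_0]))
        ]
        dists = np.linalg.norm(merged.coords[polars] - merged.coords[od1_0], axis=1)
        assert dists.min() > 3.5
        assert im.unsat_polar_count(f, 0, 1) == 1

    def test_partnered_polar_not_counted(self):
        """Without the asymmetric OG, both copies' OD1 are buried and
        unsatisfied; bringing a partner within 3.5 Å removes them."""
        f_bare = hg.Filament(_slab_subunit(with_og=False), _SLAB_STEP, 2)
        assert im.unsat_polar_count(f_bare, 0, 1) == 2
        assert im.unsat_polar_count(f_bare, 0, 1, d_max=4.0) == 0  # OD1-OD1 = 3.72 Å

    def test_exposed_polar_never_counts(self):
        names, elements, coords, resids, resnames = [], [], [], [], []
        r = 0
        for ix in range(7):
            for iy in range(7):
                r += 1
                names.append("C"); elements.append("C"); resnames.append("GLY")
                coords.append([ix * 1.8, iy * 1.8, 0.0]); resids.append(r)
        r += 1
        names += ["CG", "OD1"]; elements += ["C", "O"]; resnames += ["ASN", "ASN"]
        coords += [[5.4, 5.4, 1.0], [5.4, 14.0, 1.6]]; resids += [r, r]
        sub = mio.Structure.from_arrays(
            names, elements, np.asarray(coords), resids, resnames, ["A"] * len(names)
        )
        f = hg.Filament(sub, _SLAB_STEP, 2)
        assert im.unsat_polar_count(f, 0, 1) == 0


class TestEnergyGap:
    def _contact_subunit(self):
        names, elements, coords, resids = [], [], [], []
        for r in range(10):
            x = r * 10.0
            names += ["CA", "CB"]
            elements += ["C", "C"]
            coords += [[x, 0.0, 0.0], [x, 2.4, 0.0]]
            resids += [r + 1, r + 1]
        return mio.Structure.from_arrays(
            names, elements, np.asarray(coords), resids, ["ALA"] * 20, ["A"] * 20
        )

    def test_no_contacts_zero(self, bundle_subunit):
        far = hg.RigidTransform(np.eye(3), np.array([200.0, 0.0, 0.0]))
        f = hg.propagate(bundle_subunit, far, 2)
        assert im.energy_gap(f, 0) == 0.0

    def test_hand_counted_twenty_contacts(self):
        """10 residue pairs × 2 atom pairs at 4.0 Å, no clashes, no caps."""
        f = hg.Filament(
            self._contact_subunit(),
            hg.RigidTransform(np.eye(3), np.array([0.0, 0.0, 4.0])),
            2,
        )
        assert im.energy_gap(f, 0) == -20.0

    def test_clash_raises_energy(self):
        sub = self._contact_subunit()
        close = hg.Filament(
            sub, hg.RigidTransform(np.eye(3), np.array([0.0, 0.0, 2.0])), 2
        )
        apart = hg.Filament(
            sub, hg.RigidTransform(np.eye(3), np.array([0.0, 0.0, 4.0])), 2
        )
        assert im.energy_gap(close, 0) > im.energy_gap(apart, 0)


class TestFilterPipeline:
    def test_empty_table(self):
        survivors, report = im.apply_filters(fx.make_design_records(0, seed=0))
        assert len(survivors) == 0
        assert report["n_survivors"] == 0
        assert all(v == 0 for v in report["removed_by"].values())

    def test_each_record_violates_one_criterion(self):
        rows = pd.DataFrame(
            {
                "design_id": ["a", "b", "c", "d"],
                "dock_id": ["k"] * 4,
                "energy_gap": [-10.0, -20.0, -20.0, -20.0],  # a fails energy
                "buried_area": [900.0, 600.0, 900.0, 900.0],  # b fails area
                "sc": [0.8, 0.8, 0.5, 0.8],  # c fails sc
                "unsat_count": [0, 0, 0, 7],  # d fails unsat
            }
        )
        survivors, report = im.apply_filters(rows)
        assert len(survivors) == 0
        assert all(v == 1 for v in report["removed_by"].values())

    def test_survivors_equal_brute_force_predicate(self):
        records = fx.make_design_records(1000, seed=7)
        survivors, report = im.apply_filters(records)
        brute = records[
            (records.energy_gap <= -15.0)
            & (records.buried_area > 700.0)
            & (records.sc > 0.62)
            & (records.unsat_count < 5)
        ]
        assert survivors.equals(brute)
        assert report["n_survivors"] == len(brute)

    def test_tightening_thresholds_shrinks_survivors(self):
        records = fx.make_design_records(500, seed=11)
        base, _ = im.apply_filters(records)
        tighter = im.FilterThresholds(
            max_energy_gap=-18.0, min_area=800.0, min_sc=0.7, max_unsat=3
        )
        sub, _ = im.apply_filters(records, tighter)
        assert set(sub.design_id) <= set(base.design_id)

    def test_missing_column_is_schema_error(self):
        records = fx.make_design_records(10, seed=0).drop(columns=["sc"])
        with pytest.raises(ValidationError, match="sc"):
            im.apply_filters(records)


class TestSelectTopPerDock:
    def test_single_record(self):
        records = fx.make_design_records(1, seed=0)
        assert im.select_top_per_dock(records).equals(records.reset_index(drop=True))

    def test_crafted_minima(self):
        rows = []
        for dock in range(3):
            for k in range(5):
                rows.append(
                    {
                        "design_id": f"d{dock}_{k}",
                        "dock_id": f"dock{dock}",
                        "energy_gap": -10.0 - (5 - k),
                        "buried_area": 800.0,
                        "sc": 0.7,
                        "unsat_count": 1,
                    }
                )
        records = pd.DataFrame(rows)
        top = im.select_top_per_dock(records)
        assert sorted(top.design_id) == ["d0_0", "d1_0", "d2_0"]

    def test_matches_groupby_min_brute_force(self):
        records = fx.make_design_records(1000, seed=3)
        top = im.select_top_per_dock(records)
        brute = (
            records.sort_values(["energy_gap", "design_id"])
            .groupby("dock_id", sort=True)
            .head(1)
            .sort_values("dock_id")
            .reset_index(drop=True)
        )
        assert top.reset_index(drop=True).equals(brute)
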