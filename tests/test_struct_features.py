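import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brafclass.fixtures import ToyStructureSpec, make_toy_model
from brafclass.structure import Atom, StructureModel, key_atoms
from brafclass.struct_features import (RadiusTable, distance_features,
                                       min_distance, min_distance_atom,
                                       normalized_b, sasa_side_chain,
                                       shrake_rupley, sphere_points,
                                       ss_context)


def _single_atom_model(position=460, resname="ALA", atoms=None, b=20.0):
    atoms = atoms or [Atom("CB", "C", (0.0, 0.0, 0.0), b)]
    return StructureModel(id="t", chain="A",
                          residues={position: (resname, atoms)},
                          het_groups={}, ss_spans=[])


class TestShrakeRupley:
    def test_isolated_sphere_matches_analytic_area(self):
        area = shrake_rupley(np.zeros((1, 3)), np.array([1.9]))[0]
        assert area == pytest.approx(4 * math.pi * (1.9 + 1.4) ** 2, rel=1e-9)

    def test_fully_enclosed_atom_has_zero_area(self):
        shell = sphere_points(60) * 2.0
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        radii = np.array([1.5] + [2.0] * 60)
        assert shrake_rupley(coords, radii, subset=np.array([0]))[0] == 0.0

    def test_two_sphere_closed_form_within_1pct(self):
        r1, r2, d, rp = 1.9, 1.7, 2.5, 1.4
        R1, R2 = r1 + rp, r2 + rp
        areas = shrake_rupley(np.array([[0, 0, 0], [d, 0, 0]], dtype=float),
                              np.array([r1, r2]))
        h1 = R1 - (d * d + R1 * R1 - R2 * R2) / (2 * d)
        h2 = R2 - (d * d + R2 * R2 - R1 * R1) / (2 * d)
        exact = [4 * math.pi * R1 * R1 - 2 * math.pi * R1 * h1,
                 4 * math.pi * R2 * R2 - 2 * math.pi * R2 * h2]
        assert areas == pytest.approx(exact, rel=0.01)

    def test_neighbor_never_increases_area(self):
        coords = np.array([[0.0, 0.0, 0.0]])
        radii = np.array([1.9])
        alone = shrake_rupley(coords, radii)[0]
        rng = np.random.default_rng(0)
        for _ in range(10):
            extra = rng.uniform(-4, 4, 3)
            both = shrake_rupley(np.vstack([coords, extra]),
                                 np.array([1.9, 1.7]), subset=np.array([0]))[0]
            assert both <= alone + 1e-9

    def test_doubling_points_changes_result_below_1pct(self):
        coords = np.array([[0, 0, 0], [2.5, 0, 0], [1.0, 2.0, 0.5]], dtype=float)
        radii = np.array([1.9, 1.7, 1.8])
        a = shrake_rupley(coords, radii, n_points=960)
        b = shrake_rupley(coords, radii, n_points=1920)
        assert np.all(np.abs(b - a) <= 0.01 * np.maximum(a, 1.0))


class TestSasaSideChain:
    def test_single_side_chain_atom_far_from_context(self):
        # CB 50 A away from the lone backbone atom: effectively isolated
        atoms = [Atom("CA", "C", (50.0, 0.0, 0.0), 20.0),
                 Atom("CB", "C", (0.0, 0.0, 0.0), 20.0)]
        model = _single_atom_model(atoms=atoms)
        radii = RadiusTable.packaged()
        expected = 4 * math.pi * (radii.by_name["CB"] + 1.4) ** 2
        assert sasa_side_chain(model, 460) == pytest.approx(expected, rel=1e-9)

    def test_unresolved_position_gives_nan(self, toy_model):
        assert math.isnan(sasa_side_chain(toy_model, 999))

    def test_glycine_uses_alpha_hydrogens(self, toy_model):
        # toy glycine at 460 has explicit HA2/HA3
        area = sasa_side_chain(toy_model, 460)
        assert area > 0.0

    def test_glycine_hydrogens_rebuilt_when_absent(self):
        atoms = [Atom("N", "N", (-1.2, 0.6, 0.0), 20.0),
                 Atom("CA", "C", (0.0, 0.0, 0.0), 20.0),
                 Atom("C", "C", (1.3, 0.6, 0.0), 20.0)]
        model = _single_atom_model(resname="GLY", atoms=atoms)
        area = sasa_side_chain(model, 460)
        assert area > 0.0

    def test_occluded_side_chain_smaller_than_isolated(self, toy_model):
        # residue 464 flanked by neighbors vs the same residue alone
        in_context = sasa_side_chain(toy_model, 464)
        resname, atoms = toy_model.residues[464]
        alone = _single_atom_model(position=464, resname=resname, atoms=atoms)
        isolated = sasa_side_chain(alone, 464)
        assert np.isfinite(in_context)
        assert in_context < isolated


class TestMinDistance:
    def test_pythagorean_triple(self):
        model = _single_atom_model(atoms=[Atom("CB", "C", (0.0, 0.0, 0.0), 1.0)])
        key = Atom("MG", "MG", (3.0, 4.0, 0.0), 1.0)
        assert min_distance(model, 460, key) == pytest.approx(5.0)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.tuples(*[st.floats(-20, 20) for _ in range(3)]),
                    min_size=1, max_size=6),
           st.tuples(*[st.floats(-20, 20) for _ in range(3)]))
    def test_equals_brute_force_minimum(self, coords, key_pos):
        atoms = [Atom(f"C{i}", "C", c, 1.0) for i, c in enumerate(coords)]
        model = _single_atom_model(atoms=atoms)
        key = Atom("MG", "MG", key_pos, 1.0)
        brute = min(math.dist(c, key_pos) for c in coords)
        assert min_distance(model, 460, key) == pytest.approx(brute)

    def test_hydrogens_ignored(self):
        atoms = [Atom("HB", "H", (0.5, 0.0, 0.0), 1.0),
                 Atom("CB", "C", (0.0, 0.0, 0.0), 1.0)]
        model = _single_atom_model(atoms=atoms)
        key = Atom("MG", "MG", (2.0, 0.0, 0.0), 1.0)
        assert min_distance(model, 460, key) == pytest.approx(2.0)

    def test_minimizing_atom_named(self):
        # side-chain tip nearest the ion, as for a leucine pointing at Mg2+
        atoms = [Atom("CA", "C", (0.0, 0.0, 0.0), 1.0),
                 Atom("CB", "C", (1.5, 0.0, 0.0), 1.0),
                 Atom("CG1", "C", (3.0, 0.0, 0.0), 1.0)]
        model = _single_atom_model(resname="LEU", atoms=atoms)
        key = Atom("MG", "MG", (6.0, 0.0, 0.0), 1.0)
        d, name = min_distance_atom(model, 460, key)
        assert name == "CG1"
        assert d == pytest.approx(3.0)

    def test_unresolved_position_nan(self, toy_model):
        key = Atom("MG", "MG", (0.0, 0.0, 0.0), 1.0)
        assert math.isnan(min_distance(toy_model, 999, key))


class TestNormalizedB:
    def test_flat_b_column_returns_zero(self):
        model = make_toy_model(ToyStructureSpec(
            seed=0, b_factor_profile=[20.0] * 10, include_dfg_residue=False))
        assert normalized_b(model, 461) == 0.0

    def test_hand_zscore(self):
        residues = {
            460: ("ALA", [Atom("CA", "C", (0, 0, 0), 10.0)]),
            461: ("ALA", [Atom("CA", "C", (4, 0, 0), 20.0)]),
            462: ("ALA", [Atom("CA", "C", (8, 0, 0), 30.0)]),
        }
        model = StructureModel(id="t", chain="A", residues=residues,
                               het_groups={}, ss_spans=[])
        # population z-score of 30 in {10, 20, 30}
        assert normalized_b(model, 462) == pytest.approx(1.224744871, abs=1e-6)

    def test_mean_over_chain_is_zero(self, toy_model):
        values = [normalized_b(toy_model, pos) for pos in toy_model.residues]
        assert np.mean(values) == pytest.approx(0.0, abs=1e-9)

    def test_mixed_atom_bs_use_residue_mean(self):
        residues = {
            460: ("ALA", [Atom("CA", "C", (0, 0, 0), 10.0),
                          Atom("CB", "C", (1, 0, 0), 30.0)]),  # mean 20
            461: ("ALA", [Atom("CA", "C", (4, 0, 0), 40.0)]),
        }
        model = StructureModel(id="t", chain="A", residues=residues,
                               het_groups={}, ss_spans=[])
        assert normalized_b(model, 460) == pytest.approx(-1.0)
        assert normalized_b(model, 461) == pytest.approx(1.0)


class TestSsContext:
    @pytest.mark.parametrize("position, expected", [
        (495, 2),   # inside the helix span
        (491, 2),   # closed-interval start endpoint
        (506, 2),   # closed-interval end endpoint
        (480, 0),   # outside all spans -> coil
        (510, 1),   # inside the sheet span
    ])
    def test_encoding(self, position, expected):
        model = StructureModel(id="t", chain="A", residues={},
                               het_groups={},
                               ss_spans=[("helix", 491, 506), ("sheet", 508, 512)])
        assert ss_context(model, position) == expected

    def test_no_spans_is_coil(self):
        model = StructureModel(id="t", chain="A", residues={}, het_groups={},
                               ss_spans=[])
        assert ss_context(model, 500) == 0


class TestDistanceFeatures:
    def test_identical_models_zero_absdiff(self, toy_model):
        keys = key_atoms(toy_model)
        feats = distance_features(toy_model, toy_model, 462, keys)
        assert all(v == 0.0 for v in feats.d_absdiff.values())

    def test_exactly_four_absdiff_values(self, toy_model):
        keys = key_atoms(toy_model)
        feats = distance_features(toy_model, toy_model, 462, keys)
        assert set(feats.d_absdiff) == {"Mg", "Pa", "Pb", "Pg"}

    def test_matches_brute_force_on_toy_pair(self, toy_model):
        mt = make_toy_model(ToyStructureSpec(seed=8, jitter=0.1))
        keys = key_atoms(toy_model)
        feats = distance_features(toy_model, mt, 462, keys)
        for lbl, key in keys.as_dict().items():
            brute_wt = min(np.linalg.norm(a.xyz - key.xyz)
                           for a in toy_model.heavy_atoms(462))
            brute_mt = min(np.linalg.norm(a.xyz - key.xyz)
                           for a in mt.heavy_atoms(462))
            assert feats.d_wt[lbl] == pytest.approx(brute_wt)
            assert feats.d_mt[lbl] == pytest.approx(brute_mt)
            assert feats.d_absdiff[lbl] == pytest.approx(abs(brute_wt - brute_mt))

    def test_swapping_models_preserves_absdiff(self, toy_model):
        mt = make_toy_model(ToyStructureSpec(seed=9, jitter=0.1))
        keys = key_atoms(toy_model)
        fwd = distance_features(toy_model, mt, 463, keys)
        rev = distance_features(mt, toy_model, 463, keys)
        for lbl in fwd.d_absdiff:
            assert fwd.d_absdiff[lbl] == pytest.approx(rev.d_absdiff[lbl])
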