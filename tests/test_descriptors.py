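"""Descriptor panel: TPSA, ClogP, HBD/HBA, polarizability, LogS, pKa,
ClogD, conformers and minimal projection area."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from rdkit import Chem
from rdkit.Chem import Descriptors

from bpaprof import chem, descriptors as d
from bpaprof.descriptors import (
    PERMANENT_CATION,
    Conformer3D,
    compute_clogd,
    compute_clogp,
    compute_logs,
    compute_mpa,
    compute_polarizability,
    compute_tpsa,
    count_hbd_hba,
    estimate_pka_basic,
    generate_conformer,
    projection_area,
)


def mol(smiles: str) -> Chem.Mol:
    return chem.parse_structure(smiles).mol


class TestTpsa:
    def test_series_anchor_values(self, reference_lib):
        pp1 = reference_lib.compound("PP1").graph()
        hr1 = reference_lib.compound("HR1").graph()
        assert round(compute_tpsa(pp1), 2) == 66.84
        assert round(compute_tpsa(hr1), 2) == 49.77

    def test_pure_hydrocarbon_is_zero(self):
        assert compute_tpsa(mol("CCCCc1ccccc1")) == 0.0

    def test_diethanolamine_hand_sum(self):
        # secondary amine 12.03 + two hydroxyls at 20.23 each
        assert compute_tpsa(mol("OCCNCCO")) == pytest.approx(12.03 + 2 * 20.23)

    def test_additive_over_disconnected_fragments(self):
        combined = compute_tpsa(Chem.MolFromSmiles("OCCO.NCCN"))
        assert combined == pytest.approx(
            compute_tpsa(mol("OCCO")) + compute_tpsa(mol("NCCN"))
        )

    def test_invariant_to_atom_ordering(self, pp1_graph):
        base = compute_tpsa(pp1_graph.mol)
        n = pp1_graph.mol.GetNumAtoms()
        order = list(range(n))[::-1]
        renumbered = Chem.RenumberAtoms(pp1_graph.mol, order)
        assert compute_tpsa(renumbered) == pytest.approx(base)

    def test_matches_independent_fragment_oracle_on_fixture(self, reference_lib):
        for comp in reference_lib.compounds:
            g = comp.graph()
            assert compute_tpsa(g.mol) == pytest.approx(
                Descriptors.TPSA(g.mol), abs=1e-6
            ), comp.id


class TestClogp:
    def test_atom_contribution_hand_sums(self):
        assert compute_clogp(mol("C")) == pytest.approx(0.6361, abs=1e-4)
        assert compute_clogp(mol("c1ccccc1")) == pytest.approx(1.6866, abs=1e-4)

    def test_homologation_increases_lipophilicity(self):
        assert compute_clogp(mol("CC")) > compute_clogp(mol("C"))


class TestHbdHba:
    @pytest.mark.parametrize(
        "smiles, expected",
        [("O", (2, 1)), ("c1ccccc1", (0, 0))],
    )
    def test_simple_conventions(self, smiles, expected):
        assert count_hbd_hba(mol(smiles)) == expected

    def test_pp1_neutral_form(self, pp1_graph):
        # one OH donor; ether + ketone + amide + hydroxyl oxygens accept,
        # the amide nitrogen does not
        assert count_hbd_hba(pp1_graph.mol) == (1, 4)

    def test_basic_amine_protonated_at_ph7(self, reference_lib):
        # HR32's side-chain amine (pKa 9.5 > 7) is protonated: one extra
        # donor, one fewer acceptor
        g = reference_lib.compound("HR32").graph()
        assert count_hbd_hba(g.mol) == (2, 3)
        assert count_hbd_hba(g.mol, pka_basic=None) == (1, 4)


class TestPolarizability:
    def test_atomic_hybrid_hand_sums(self):
        assert compute_polarizability(mol("C")) == pytest.approx(2.609)
        assert compute_polarizability(mol("O")) == pytest.approx(1.411)

    def test_strictly_additive_methylene_increment(self):
        alkanes = [compute_polarizability(mol("C" * n)) for n in (2, 3, 4, 5)]
        increments = np.diff(alkanes)
        assert np.allclose(increments, increments[0])

    def test_halogen_swap_shifts_by_component_difference(self, reference_lib):
        pp1 = compute_polarizability(reference_lib.compound("PP1").graph().mol)
        hr9 = compute_polarizability(reference_lib.compound("HR9").graph().mol)
        assert pp1 - hr9 == pytest.approx(2.315 - 0.296)


class TestLogs:
    def test_direct_formula_evaluation(self):
        value = compute_logs(clogp=2, mw=300, rotatable_bonds=4,
                             aromatic_proportion=0.5)
        assert value == pytest.approx(-3.066 + math.log10(300))

    def test_monotone_decreasing_in_clogp(self):
        lows = [compute_logs(c, 300, 4, 0.5) for c in np.linspace(-1, 6, 10)]
        assert all(a > b for a, b in zip(lows, lows[1:]))

    def test_nonpositive_mw_rejected(self):
        with pytest.raises(ValueError):
            compute_logs(2, 0, 4, 0.5)


class TestPkaAndClogd:
    def test_rule_lookups_on_series(self, reference_lib):
        get = lambda cid: estimate_pka_basic(reference_lib.compound(cid).graph().mol)
        assert get("PP1") is None          # amide N is non-basic
        assert get("HR32") == 9.5          # diethylaminoethyl amide side chain
        assert get("HR34") == 7.8          # amide-substituted piperazine
        assert get("HR35") == 7.8          # same centre, protonated salt parent
        assert get("HR36") == PERMANENT_CATION

    @pytest.mark.parametrize(
        "pka, expected_shift",
        [(None, 0.0), (7.4, math.log10(2)), (9.4, 2.0043)],
    )
    def test_clogd_closed_forms(self, pka, expected_shift):
        assert compute_clogd(2.5, pka) == pytest.approx(2.5 - expected_shift, abs=1e-4)

    def test_permanent_cation_capped_penalty(self):
        assert compute_clogd(1.0, PERMANENT_CATION) == -3.0

    @given(
        clogp=st.floats(-3, 8),
        pka=st.one_of(st.none(), st.floats(0, 14)),
    )
    def test_clogd_never_exceeds_clogp(self, clogp, pka):
        clogd = compute_clogd(clogp, pka)
        assert clogd <= clogp + 1e-12
        if pka is None:
            assert clogd == clogp


class TestConformer:
    def test_methane_bond_lengths(self):
        conf = generate_conformer(mol("C"), seed=3)
        c = conf.coords[0]
        for h in conf.coords[1:]:
            assert np.linalg.norm(h - c) == pytest.approx(1.09, rel=0.15)

    def test_deterministic_for_same_seed(self, pp1_graph):
        a = generate_conformer(pp1_graph.mol, seed=7)
        b = generate_conformer(pp1_graph.mol, seed=7)
        assert np.array_equal(a.coords, b.coords)

    def test_pp1_geometry_satisfies_invariants(self, pp1_graph):
        generate_conformer(pp1_graph.mol, seed=7).validate()


class TestMpa:
    def test_single_disc_closed_form(self):
        conf = Conformer3D(np.zeros((1, 3)), np.array([1.7]), ("C",), 0)
        assert compute_mpa(conf) == pytest.approx(math.pi * 1.7 ** 2, rel=0.01)

    def test_concentric_discs_union(self):
        conf = Conformer3D(np.zeros((2, 3)), np.array([1.7, 1.7]), ("C", "C"), 0)
        assert compute_mpa(conf) == pytest.approx(math.pi * 1.7 ** 2, rel=0.01)

    def test_rotation_invariance_within_raster_tolerance(self, pp1_graph):
        conf = generate_conformer(pp1_graph.mol, seed=7)
        theta = 0.9
        rot = np.array([
            [math.cos(theta), -math.sin(theta), 0],
            [math.sin(theta), math.cos(theta), 0],
            [0, 0, 1],
        ])
        rotated = Conformer3D(conf.coords @ rot.T, conf.radii, conf.elements,
                              conf.seed, conf.bonds)
        assert compute_mpa(rotated) == pytest.approx(compute_mpa(conf), rel=0.02)

    def test_beats_monte_carlo_orientation_oracle(self):
        rng = np.random.default_rng(42)
        coords = rng.normal(scale=2.0, size=(10, 3))
        radii = rng.uniform(1.2, 1.8, size=10)
        conf = Conformer3D(coords, radii, ("C",) * 10, 0)
        result = compute_mpa(conf)
        dirs = rng.normal(size=(1000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        oracle = min(d._area_along(conf, dd, 0.1) for dd in dirs)
        assert result <= oracle * 1.02


def test_build_panel_invariants(pp1_graph):
    panel = d.build_panel(pp1_graph, compound_id="PP1")
    assert panel.psa >= 0
    assert panel.mpa > 0
    assert panel.hbd >= 0 and panel.hba >= 0
    assert panel.mw > 0
    assert panel.clogd <= panel.clogp
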