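"""Structural flags, activity calls, matched pairs, rule induction and
dose-response fitting."""

import math

import numpy as np
import pytest

from bpaprof.chem import CvRecord, LibraryTable, enumerate_bpa_variants
from bpaprof.sar import (
    PharmacophoreFlags,
    PharmacophoreRule,
    activity_labels,
    call_activity,
    fit_dose_response,
    induce_rule,
    matched_pairs,
    substructure_flags,
)


class TestSubstructureFlags:
    def test_pp1_full_pharmacophore(self, pp1_graph):
        flags = substructure_flags(pp1_graph)
        assert flags == PharmacophoreFlags(
            carbonyl_linker=True, para_chloro=True, gem_dimethyl=True,
            amide_class="tertiary", permanent_cation=False,
        )

    def test_benzylic_linker_lacks_carbonyl(self, reference_lib):
        assert not substructure_flags(
            reference_lib.compound("HR2").graph()
        ).carbonyl_linker

    def test_quaternary_salt_is_permanent_cation(self, reference_lib):
        assert substructure_flags(
            reference_lib.compound("HR36").graph()
        ).permanent_cation

    def test_scaffold_free_molecule_all_false(self):
        from bpaprof.chem import parse_structure
        flags = substructure_flags(parse_structure("CC(=O)NC"))
        assert not flags.carbonyl_linker
        assert not flags.para_chloro
        assert not flags.gem_dimethyl
        assert flags.amide_class == "secondary"


class TestActivityCall:
    def test_strong_active_and_inactive(self, reference_lib):
        assert call_activity(reference_lib.measurements_for("PP1"))
        assert not call_activity(reference_lib.measurements_for("HR36"))

    def test_boundary_is_active(self):
        assert call_activity(CvRecord("X", 25.0, 50.0, 1.0))

    def test_missing_reference_dose_rejected(self):
        with pytest.raises(ValueError, match="no CV record"):
            call_activity([CvRecord("X", 10.0, 40.0, 1.0)])

    def test_other_concentration_on_request(self):
        assert call_activity([CvRecord("X", 10.0, 40.0, 1.0)], concentration=10.0)

    def test_monotone_in_cv(self):
        # lowering CV can only keep or make a compound active
        for cv in np.linspace(0, 100, 21):
            if call_activity(CvRecord("X", 25.0, cv)):
                assert call_activity(CvRecord("X", 25.0, cv - 5.0))


class TestMatchedPairs:
    def test_two_by_one_grid_gives_single_region_a_pair(self):
        variants = enumerate_bpa_variants({
            "A": ["Cl", "F"], "B": ["carbonyl"], "C": ["gem_dimethyl"],
            "D": ["N_methyl"],
        })
        lib = LibraryTable(variants)
        pairs = matched_pairs(lib, "A")
        assert len(pairs) == 1
        assert {pairs[0].tag_a, pairs[0].tag_b} == {"Cl", "F"}
        assert not matched_pairs(lib, "B")

    def test_fixture_halogen_pair_delta(self, reference_lib):
        pairs = matched_pairs(reference_lib, "A")
        pp1_hr9 = [p for p in pairs if {p.id_a, p.id_b} == {"PP1", "HR9"}]
        assert len(pp1_hr9) == 1
        assert pp1_hr9[0].delta_cv == pytest.approx(35.55 - 1.04)

    def test_pairs_differing_in_two_regions_excluded(self, reference_lib):
        # HR1 differs from every other fixture compound in at least two
        # regions (A and B): it can never appear in a matched pair
        for region in "ABCD":
            for p in matched_pairs(reference_lib, region):
                assert "HR1" not in (p.id_a, p.id_b)

    def test_canonical_ordering(self, reference_lib):
        for region in "ABCD":
            for p in matched_pairs(reference_lib, region):
                assert p.id_a < p.id_b


def flags_for(carbonyl=True, chloro=True, gem=True, amide="tertiary", cation=False):
    return PharmacophoreFlags(carbonyl, chloro, gem, amide, cation)


class TestRuleInduction:
    PLANTED = PharmacophoreRule(
        required=frozenset({"carbonyl_linker", "para_chloro", "gem_dimethyl"}),
        min_amide_class="tertiary",
    )

    def build_noiseless(self, n_active=4, n_inactive=8):
        flags = [flags_for() for _ in range(n_active)]
        activity = [True] * n_active
        breakers = [
            flags_for(carbonyl=False), flags_for(chloro=False),
            flags_for(gem=False), flags_for(amide="secondary"),
        ]
        for i in range(n_inactive):
            flags.append(breakers[i % len(breakers)])
            activity.append(False)
        return flags, activity

    def test_planted_rule_recovered_without_noise(self):
        flags, activity = self.build_noiseless()
        assert induce_rule(flags, activity) == self.PLANTED

    def test_degenerate_labels_rejected(self):
        flags, _ = self.build_noiseless()
        with pytest.raises(ValueError, match="degenerate"):
            induce_rule(flags, [True] * len(flags))

    def test_too_few_labelled_rejected(self):
        flags, activity = self.build_noiseless(1, 2)
        with pytest.raises(ValueError, match="at least"):
            induce_rule(flags, activity)

    def test_fixture_regression_recovers_series_conclusions(self, reference_lib):
        """Strong actives (CV <= 30 %) on the literature compounds require the
        benzophenone carbonyl, the 4'-Cl and the alpha gem-dimethyl."""
        labels = activity_labels(reference_lib, threshold=30.0)
        flags = [
            substructure_flags(reference_lib.compound(cid).graph())
            for cid in labels
        ]
        rule = induce_rule(flags, list(labels.values()), min_labelled=5)
        assert {"carbonyl_linker", "para_chloro", "gem_dimethyl"} <= rule.required
        assert "permanent_cation" not in rule.required
        assert rule.min_amide_class in ("secondary", "tertiary")


class TestDoseResponse:
    @staticmethod
    def exact_curve(ic50, hill, concs):
        return [
            CvRecord("X", c, 100.0 / (1.0 + (c / ic50) ** hill)) for c in concs
        ]

    def test_noiseless_parameter_recovery(self):
        fit = fit_dose_response(self.exact_curve(10.0, 1.5, [1, 3, 10, 30, 100]))
        assert fit.converged
        assert fit.ic50 == pytest.approx(10.0, abs=1e-4)
        assert fit.hill == pytest.approx(1.5, abs=1e-4)

    def test_series_lead_ic50_near_10_micromolar(self, reference_lib):
        fit = fit_dose_response(reference_lib.measurements_for("PP1"))
        assert fit.converged
        assert 8.0 <= fit.ic50 <= 11.0

    def test_duplicate_points_do_not_change_exact_fit(self):
        data = self.exact_curve(10.0, 1.5, [1, 3, 10, 30])
        doubled = data + [data[1]]
        a, b = fit_dose_response(data), fit_dose_response(doubled)
        assert a.ic50 == pytest.approx(b.ic50, abs=1e-5)
        assert a.hill == pytest.approx(b.hill, abs=1e-5)

    def test_scale_equivariance(self):
        base = fit_dose_response(self.exact_curve(10.0, 1.5, [1, 3, 10, 30]))
        scaled = fit_dose_response(self.exact_curve(30.0, 1.5, [3, 9, 30, 90]))
        assert scaled.ic50 == pytest.approx(3.0 * base.ic50, rel=1e-4)

    def test_non_monotone_data_does_not_converge(self):
        data = [CvRecord("X", c, v) for c, v in
                [(1, 20.0), (5, 90.0), (10, 15.0), (25, 85.0)]]
        assert not fit_dose_response(data).converged

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_dose_response(self.exact_curve(10.0, 1.5, [1, 10, 100]))
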