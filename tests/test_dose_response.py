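"""Dose-response curves, effective doses, synergy, severity scans."""

import math

import numpy as np
import pytest

import wntapc as w
from wntapc.dose_response import (
    MutationScanRecord,
    dose_response,
    effective_dose,
    combination_surface,
    isobole_from_response,
    restoration_threshold,
    scan_hypothetical,
)


class TestDoseResponse:
    def test_zero_dose_matches_untreated_simulation(self, bundle_for, ctx, wt_ref, tcf_of):
        curve = dose_response(
            bundle_for("neoR/neoR"), ctx, "Dkk1", [0.0, 1e-9, 1e-8], reference=wt_ref
        )
        assert curve.relative_tcf[0] == pytest.approx(tcf_of("neoR/neoR"), rel=1e-6)

    def test_inhibitors_only_suppress_wild_type(self, bundle_for, ctx, wt_ref):
        curve = dose_response(
            bundle_for("WT/WT"), ctx, "sFRP1", [0.0, 1e-8, 1e-7, 1e-6], reference=wt_ref
        )
        assert np.all(curve.relative_tcf <= 1.0 + 1e-9)
        assert np.all(np.diff(curve.relative_tcf) <= 1e-9)  # nonincreasing
        assert curve.asymptote <= curve.relative_tcf.min() + 1e-9

    def test_severe_mutant_stays_elevated_at_huge_dose(self, bundle_for, ctx, wt_ref):
        """Near-null cells cannot be brought back even by 5000 nM sFRP1."""
        curve = dose_response(
            bundle_for("1638N/1638N"), ctx, "sFRP1", [0.0, 5e-6], reference=wt_ref
        )
        assert curve.relative_tcf[-1] > 1.0

    def test_unknown_inhibitor_rejected(self, bundle_for, ctx):
        with pytest.raises(ValueError, match="inhibitor"):
            dose_response(bundle_for("WT/WT"), ctx, "aspirin", [0.0, 1e-9])


class TestEffectiveDose:
    def test_resimulation_closure(self, bundle_for, ctx, wt_ref):
        """The reported dose, re-simulated from scratch, restores the target."""
        ed = effective_dose(bundle_for("neoR/neoR"), ctx, "Dkk1", reference=wt_ref)
        assert ed.finite
        t, _ = w.relative_tcf(
            bundle_for("neoR/neoR"), ctx.with_dose("Dkk1", ed.dose), reference=wt_ref
        )
        assert t == pytest.approx(1.0, rel=0.01)
        assert ed.bracket[0] <= ed.dose <= ed.bracket[1]
        assert ed.bracket[1] / ed.bracket[0] <= 1.011

    def test_wild_type_needs_no_dose(self, bundle_for, ctx, wt_ref):
        ed = effective_dose(bundle_for("WT/WT"), ctx, "Dkk1", reference=wt_ref)
        assert ed.dose == 0.0

    def test_near_null_genotype_not_restorable(self, bundle_for, ctx, wt_ref):
        for inhibitor in ("sFRP1", "Dkk1"):
            ed = effective_dose(bundle_for("1638N/1638N"), ctx, inhibitor, reference=wt_ref)
            assert math.isinf(ed.dose)
            assert ed.achieved_tcf > 1.0

    def test_dkk1_more_potent_than_sfrp1(self, bundle_for, ctx, wt_ref):
        for g in ("neoR/neoR", "1638N/1638T"):
            ed_s = effective_dose(bundle_for(g), ctx, "sFRP1", reference=wt_ref)
            ed_d = effective_dose(bundle_for(g), ctx, "Dkk1", reference=wt_ref)
            assert ed_d.dose < ed_s.dose

    def test_target_above_untreated_rejected(self, bundle_for, ctx, wt_ref):
        with pytest.raises(ValueError, match="restore"):
            effective_dose(bundle_for("WT/WT"), ctx, "Dkk1", target=2.0, reference=wt_ref)


class TestCombinationSurface:
    @pytest.fixture(scope="class")
    @staticmethod
    def surface(bundle_for, ctx, wt_ref):
        return combination_surface(
            bundle_for("neoR/neoR"), ctx,
            sfrp_grid=[0.0, 5e-8, 4e-7], dkk_grid=[0.0, 2e-9, 1.3e-8],
            reference=wt_ref,
        )

    def test_corner_is_untreated_activity(self, surface, tcf_of):
        assert surface.relative_tcf[0, 0] == pytest.approx(tcf_of("neoR/neoR"), rel=1e-6)

    def test_zero_dkk_row_equals_single_agent_curve(self, surface, bundle_for, ctx, wt_ref):
        curve = dose_response(
            bundle_for("neoR/neoR"), ctx, "sFRP1", [0.0, 5e-8, 4e-7], reference=wt_ref
        )
        assert surface.relative_tcf[:, 0] == pytest.approx(curve.relative_tcf, rel=1e-6)

    def test_monotone_in_each_inhibitor(self, surface):
        assert np.all(np.diff(surface.relative_tcf, axis=0) <= 1e-9)
        assert np.all(np.diff(surface.relative_tcf, axis=1) <= 1e-9)


class TestSynergy:
    def test_additive_null_model_has_unit_combination_index(self):
        """A response depending only on the equivalent-dose sum is, by
        construction, non-synergistic: every isobole point has CI = 1."""
        ed_s, ed_d = 1e-7, 3e-9

        def additive(s, d):
            x = s + d * (ed_s / ed_d)
            return 3.0 * math.exp(-x * math.log(3.0) / ed_s)  # equals 1 at x = ed_s

        res = isobole_from_response(additive, ed_s, ed_d, target=1.0, n_points=7)
        assert res.dose_fraction_sums == pytest.approx([1.0] * 7, rel=0.02)

    def test_model_synergy_for_expression_mutant(self, bundle_for, ctx, wt_ref):
        """The pathway model is synergistic: the best combination uses well
        under half of each single-agent dose, and the isobole reproduces
        the wild-type target."""
        bundle = bundle_for("neoR/neoR")
        res = w.isobole_and_max_synergy(bundle, ctx, n_points=7, reference=wt_ref)
        assert min(res.dose_fraction_sums) < 0.8
        s, d = res.max_synergy_point
        t, _ = w.relative_tcf(
            bundle, ctx.with_dose("sFRP1", s).with_dose("Dkk1", d), reference=wt_ref
        )
        assert t == pytest.approx(1.0, rel=0.02)

    def test_refused_when_single_agent_dose_infinite(self, bundle_for, ctx, wt_ref):
        with pytest.raises(ValueError, match="refused"):
            w.isobole_and_max_synergy(bundle_for("1638N/1638N"), ctx, reference=wt_ref)


class TestScanAndThreshold:
    @pytest.fixture(scope="class")
    @staticmethod
    def small_scan(ctx, base, wt_ref):
        records = []
        records += scan_hypothetical(
            "het_truncated_null", ctx, base,
            kd1_grid=[1.0, 20.0], k6_grid=[0.05, 1.0], reference=wt_ref,
        )
        records += scan_hypothetical(
            "expression_reduced", ctx, base,
            pt_fractions=[0.02, 0.2, 0.51, 1.0], reference=wt_ref,
        )
        return records

    def test_identity_point_is_wild_type(self, small_scan):
        idy = [r for r in small_scan if r.scenario == "expression_reduced" and r.pt_fraction == 1.0]
        assert idy[0].untreated_tcf == pytest.approx(1.0, abs=1e-6)
        assert idy[0].ed_sfrp1 == 0.0 and idy[0].ed_dkk1 == 0.0

    def test_expression_scan_consistent_with_catalog_genotype(self, small_scan, tcf_of):
        rec = [r for r in small_scan if r.pt_fraction == 0.51][0]
        assert rec.untreated_tcf == pytest.approx(tcf_of("1638N/1638T"), rel=1e-6)

    def test_untreated_activity_never_below_wild_type(self, small_scan):
        assert all(r.untreated_tcf >= 1.0 - 1e-9 for r in small_scan)

    def test_doses_increase_with_severity_within_scenario(self, small_scan):
        expr = sorted(
            (r for r in small_scan if r.scenario == "expression_reduced"),
            key=lambda r: r.untreated_tcf,
        )
        finite = [r.ed_dkk1 for r in expr if math.isfinite(r.ed_dkk1)]
        assert all(b >= a for a, b in zip(finite, finite[1:]))

    def test_threshold_from_wild_type_only_is_lower_bound(self):
        rec = MutationScanRecord("expression_reduced", "WT/WT", 1.0, 1.0, 1.0, 1.0, 0.0, 0.0)
        th = restoration_threshold([rec])
        assert th.threshold == 1.0
        assert th.is_lower_bound

    def test_threshold_separates_restorable_from_not(self, small_scan):
        th = restoration_threshold(small_scan)
        below, above = th.bracket_records
        assert not th.is_lower_bound  # the severe corner is not restorable
        assert below.untreated_tcf == th.threshold
        assert above is not None
        assert math.isinf(above.ed_sfrp1) and math.isinf(above.ed_dkk1)

    def test_unknown_scenario_rejected(self, ctx, base):
        with pytest.raises(ValueError, match="scenario"):
            scan_hypothetical("bogus", ctx, base)
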