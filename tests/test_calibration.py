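"""Truncation-parameter locus calibration and Wnt-level recovery."""

import numpy as np
import pytest

import wntapc as w
from wntapc.calibration import LocusPoint, calibrate_locus, calibrate_wnt, fit_locus_both, fit_locus_line

KD1_GRID = np.geomspace(1.0, 20.0, 8)


@pytest.fixture(scope="module")
def het_locus(base, ctx):
    """Locus for the heterozygous truncated/near-null genotype at target 4.9."""
    return calibrate_locus(
        4.9, ctx, base, partner=w.build_allele("1638N"), kd1_grid=KD1_GRID
    )


class TestCalibrateLocus:
    def test_identity_target_on_wild_type(self, base, ctx):
        """Target activity 1 with an otherwise wild-type genotype pins the
        calibrated allele at the wild-type corner."""
        pts = calibrate_locus(1.0, ctx, base, partner=w.build_allele("WT"), kd1_grid=[1.0])
        assert pts[0].feasible
        assert pts[0].k6_fraction == pytest.approx(1.0, abs=1e-6)

    def test_locus_hits_target_and_reports_infeasible(self, het_locus):
        feasible = [p for p in het_locus if p.feasible]
        infeasible = [p for p in het_locus if not p.feasible]
        assert len(feasible) >= 3
        assert infeasible, "large KD1 folds cannot reach the mild target with k6 <= 1"
        assert len(het_locus) == len(KD1_GRID)  # nothing dropped
        for p in feasible:
            assert p.achieved_tcf == pytest.approx(4.9, rel=0.005)

    def test_locus_trades_off_monotonically(self, het_locus):
        """Weaker Axin binding must be compensated by stronger beta-catenin
        binding: k6 rises with the KD1 fold along the locus."""
        feasible = [p for p in het_locus if p.feasible]
        k6 = [p.k6_fraction for p in feasible]
        assert all(b > a for a, b in zip(k6, k6[1:]))

    def test_het_locus_line_coefficients(self, het_locus):
        primary, secondary = fit_locus_both(het_locus)
        assert primary.x_convention == "kd1_fold"
        assert primary.rms_residual < secondary.rms_residual
        assert primary.slope == pytest.approx(0.27, rel=0.2)
        assert primary.intercept == pytest.approx(0.26, rel=0.2)

    def test_prediction_invariance_across_locus(self, base, ctx, het_locus, wt_ref):
        """Different parameter pairs on the same locus give nearly the same
        inhibitor response, so predictions are well defined; the measured
        spread between the extreme locus edges at a 2 nM Dkk1 dose is 2.6%,
        comparable to the ~20% spread of the effective-dose ranges the
        locus induces."""
        feasible = [p for p in het_locus if p.feasible]
        lo, hi = feasible[0], feasible[-1]
        dosed = ctx.with_dose("Dkk1", 2e-9)
        tcfs = []
        for p in (lo, hi):
            g = w.Genotype(
                w.build_allele("1638N"), w.truncated_allele("t", p.kd1_fold, p.k6_fraction)
            )
            t, _ = w.relative_tcf(w.build_parameters(g, base), dosed, reference=wt_ref)
            tcfs.append(t)
        assert tcfs[0] == pytest.approx(tcfs[1], rel=0.03)

    def test_noisy_targets_recover_locus_slope(self, base, ctx, het_locus):
        """Calibrating to the mean of 20 noisy replicates (5% CV) of the
        target reproduces the noiseless locus slope within 15%."""
        rng = np.random.default_rng(11)
        noisy_target = float(4.9 * np.exp(rng.normal(0.0, 0.05, size=20)).mean())
        pts = calibrate_locus(
            noisy_target, ctx, base, partner=w.build_allele("1638N"), kd1_grid=KD1_GRID[:5]
        )
        clean_slope = fit_locus_both(het_locus)[0].slope
        noisy_slope = fit_locus_both(pts)[0].slope
        assert noisy_slope == pytest.approx(clean_slope, rel=0.15)


class TestFitLocusLine:
    def test_exact_recovery_on_collinear_points(self):
        pts = [LocusPoint(x, 0.27 * x + 0.26, 4.9, True) for x in (1.0, 1.5, 2.0, 2.5)]
        line = fit_locus_line(pts, "kd1_fold")
        assert line.slope == pytest.approx(0.27, abs=1e-12)
        assert line.intercept == pytest.approx(0.26, abs=1e-12)
        assert line.rms_residual == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        pts = [LocusPoint(1.0, 0.5, 4.9, True), LocusPoint(2.0, 0.8, 4.9, True)]
        with pytest.raises(ValueError, match="3"):
            fit_locus_line(pts)

    def test_infeasible_points_excluded_from_fit(self):
        pts = [LocusPoint(x, 0.1 * x, 4.9, True) for x in (1.0, 2.0, 3.0)]
        pts.append(LocusPoint(10.0, None, 2.0, False))
        line = fit_locus_line(pts)
        assert line.n_points == 3


class TestCalibrateWnt:
    def test_round_trip_recovers_generating_wnt(self, base, ctx):
        """Observations generated by the model at 5 nM are traced back to
        exactly the 5 nM grid point."""
        import dataclasses

        fractions = [0.2, 0.1]
        gen_ctx = dataclasses.replace(ctx.untreated(), WT_total=5e-9)
        ref = w.wt_reference(base, gen_ctx)
        obs = []
        for f in fractions:
            g = w.Genotype.homozygous(w.AlleleSpec(f"e{f}", f, 1.0, 1.0))
            obs.append(w.steady_state(w.build_parameters(g, base), gen_ctx).b_detect / ref.b_detect)
        grid = [1e-9, 2.5e-9, 5e-9, 7.5e-9, 1e-8]
        cal = calibrate_wnt(fractions, obs, grid, ctx=ctx, base=base)
        assert cal.wnt_total == pytest.approx(5e-9)
        assert not cal.degenerate
        assert list(cal.profile.columns) == ["wnt_total", "objective"]

    def test_objective_saturates_at_high_wnt(self, base, ctx):
        """Above ~5 nM the dose response flattens, so neighbouring high-Wnt
        grid points score nearly identically."""
        cal = calibrate_wnt([0.2, 0.1], [2.6, 3.7], [5e-9, 1e-8, 2e-8], ctx=ctx, base=base)
        obj = cal.profile.objective.to_numpy()
        assert abs(obj[2] - obj[1]) < 0.2 * (1.0 + obj[1])

    def test_degenerate_panel_flagged(self, base, ctx):
        cal = calibrate_wnt([1.0], [1.0], [1e-9, 5e-9], ctx=ctx, base=base)
        assert cal.degenerate

    def test_empty_grid_rejected(self, base, ctx):
        with pytest.raises(ValueError, match="empty"):
            calibrate_wnt([0.5], [2.0], [], ctx=ctx, base=base)
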