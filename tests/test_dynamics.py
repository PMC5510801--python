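"""ODE dynamics: closures, steady states, convergence honesty, sensitivities."""

import dataclasses
import math

import numpy as np
import pytest

import wntapc as w
from wntapc.dynamics import (
    InconsistentStateError,
    PathwayState,
    integrate_to_steady_state,
    local_sensitivity,
    rhs_and_closure,
)
from wntapc.parameters import AlleleSpec, Genotype


@pytest.fixture(scope="module")
def null_bundle(base):
    """No APC at all: the destruction complex cannot form."""
    allele = AlleleSpec("null", 0.0, 1.0, 1.0)
    return w.build_parameters(Genotype.homozygous(allele), base)


class TestRhsAndClosure:
    def test_beta_catenin_balance_without_complex(self, null_bundle, ctx, base):
        """With no destruction complex, dB/dt = k7 - k8*B vanishes at k7/k8."""
        b_eq = base.k7 / base.k8
        state = dataclasses.replace(PathwayState.zeros(), B=b_eq)
        dy, clos = rhs_and_closure(state, null_bundle, ctx)
        assert dy[8] == pytest.approx(0.0, abs=1e-25)
        state2 = dataclasses.replace(PathwayState.zeros(), B=b_eq / 2)
        dy2, _ = rhs_and_closure(state2, null_bundle, ctx)
        assert dy2[8] == pytest.approx(base.k7 - base.k8 * b_eq / 2, rel=1e-12)

    def test_wnt_conservation_identity(self, bundle_for, ctx, base):
        """The free-Wnt closure balances the ligand budget identically."""
        from wntapc.parameters import partition_coefficients

        ksu_ex, _ = partition_coefficients(ctx, base)
        bundle = bundle_for("WT/WT")
        state = PathwayState(
            SW=0.0, LD=10.0, FW=50.0, LF=20.0, CL=5.0, CLp=0.0, C=1e-9, Cp=0.0, B=1e-6
        )
        _, clos = rhs_and_closure(state, bundle, ctx)
        budget = clos.W + (state.FW + state.LF + state.CL + state.CLp) * ksu_ex + state.SW
        assert budget == pytest.approx(ctx.WT_total, rel=1e-14)

    def test_inconsistent_state_rejected(self, bundle_for, ctx):
        """More receptor-bound species than receptors exist is an error."""
        bad = dataclasses.replace(PathwayState.zeros(), LF=1e9)
        with pytest.raises(InconsistentStateError, match="L"):
            rhs_and_closure(bad, bundle_for("WT/WT"), ctx)


class TestSteadyState:
    def test_wnt_raises_beta_catenin(self, base, bundle_for):
        """The Wnt-free baseline lies strictly below the 5 nM Wnt steady state."""
        bundle = bundle_for("WT/WT")
        quiet = w.steady_state(bundle, dataclasses.replace(w.standard_context(), WT_total=0.0))
        stim = w.steady_state(bundle, w.standard_context())
        assert quiet.converged and stim.converged
        assert quiet.b_detect < stim.b_detect

    def test_saturating_sfrp_recovers_wnt_free_baseline(self, base, bundle_for):
        """A huge sFRP1 dose sequesters all Wnt: back to the Wnt-free level."""
        bundle = bundle_for("WT/WT")
        quiet = w.steady_state(bundle, dataclasses.replace(w.standard_context(), WT_total=0.0))
        drowned = w.steady_state(
            bundle, dataclasses.replace(w.standard_context(), ST_total=5e-5)
        )
        assert drowned.b_detect == pytest.approx(quiet.b_detect, rel=0.01)

    def test_no_sfrp_means_no_bound_wnt(self, bundle_for):
        ss = w.steady_state(bundle_for("neoR/neoR"), w.standard_context())
        assert ss.state.SW == 0.0
        assert ss.closures.S == 0.0

    def test_initial_condition_independence(self, bundle_for, ctx, base):
        """Starting from the complex-free, beta-catenin-rich corner converges
        to the same stationary point as the default resting start."""
        bundle = bundle_for("neoR/neoR")
        default = integrate_to_steady_state(bundle, ctx)
        alt0 = dataclasses.replace(PathwayState.zeros(), B=base.k7 / base.k8)
        alt = integrate_to_steady_state(bundle, ctx, initial_state=alt0)
        assert alt.converged
        assert alt.b_detect == pytest.approx(default.b_detect, rel=1e-3)

    def test_reproducible_across_integrator_tolerances(self, bundle_for, ctx):
        bundle = bundle_for("neoF/neoF")
        loose = integrate_to_steady_state(bundle, ctx, rtol=1e-8, refine=False)
        tight = integrate_to_steady_state(bundle, ctx, rtol=1e-10, refine=False)
        assert loose.b_detect == pytest.approx(tight.b_detect, rel=1e-3)

    def test_unconverged_horizon_reported_honestly(self, bundle_for, ctx):
        """A deliberately short horizon without polish must not claim convergence."""
        ss = integrate_to_steady_state(bundle_for("1638N/1638N"), ctx, horizon=3600.0, refine=False)
        assert not ss.converged
        assert ss.max_rel_rate > 1e-6
        assert ss.t_final == pytest.approx(3600.0)

    def test_closures_stay_physical_along_approach(self, bundle_for, ctx):
        """States at intermediate horizons keep every closed species nonnegative."""
        bundle = bundle_for("neoR/neoR")
        dosed = dataclasses.replace(ctx, ST_total=1e-7, DT_total=1e-8)
        for horizon in (600.0, 6e4, 6e5):
            ss = integrate_to_steady_state(bundle, dosed, horizon=horizon, refine=False)
            _, clos = rhs_and_closure(ss.state, bundle, dosed, equilibrium=ss.equilibrium)
            assert min(vars(clos).values()) >= -1e-12


class TestLocalSensitivity:
    def test_production_elasticity_is_one_without_complex(self, null_bundle, ctx):
        """When degradation is linear in B, b_detect scales exactly with k7."""
        entries = {e.parameter: e for e in local_sensitivity(null_bundle, ctx)}
        assert entries["k7"].elasticity == pytest.approx(1.0, abs=1e-6)
        assert entries["k8"].elasticity == pytest.approx(-1.0, abs=1e-6)

    def test_zero_step_gives_zero_elasticities(self, null_bundle, ctx):
        entries = local_sensitivity(null_bundle, ctx, rel_step=0.0)
        finite = [e for e in entries if not math.isnan(e.elasticity)]
        assert finite and all(e.elasticity == 0.0 for e in finite)

    def test_complex_forming_parameters_dominate_at_wild_type(self, bundle_for, ctx):
        """The destruction-complex supply (APC/Axin/GSK totals, dissociation
        constants) carries the largest influence on beta-catenin."""
        entries = local_sensitivity(bundle_for("WT/WT"), ctx)
        assert all(e.converged for e in entries if not math.isnan(e.elasticity))
        top5 = {e.parameter for e in entries[:5]}
        complex_params = {"PT", "AT", "GT", "KD1", "KD2", "k6", "k_m6"}
        assert len(top5 & complex_params) >= 2

    def test_zero_valued_parameters_flagged_not_dropped(self, bundle_for, ctx):
        entries = {e.parameter: e for e in local_sensitivity(bundle_for("WT/WT"), ctx)}
        assert math.isnan(entries["ST_total"].elasticity)
        assert "zero" in entries["ST_total"].note
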