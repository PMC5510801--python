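"""Inhibitor dose-response analysis: curves, effective doses, synergy, scans.

All responses are steady-state TCF activities relative to an untreated
wild-type cell simulated under the identical context (same Wnt, well volume
and cell number).  The two extracellular inhibitors act at different points:
sFRP1 sequesters Wnt ligand in the medium, Dkk1 occupies LRP receptors;
both reduce ternary-complex formation, free more destruction complex, and
thereby lower beta-catenin.  Because the inhibitory effect saturates, a
mutant's activity may stay above the wild-type level at any dose -- the
*effective dose* restoring wild-type activity is then reported as infinite,
decided by probing far beyond the dose cap rather than by a fixed cut-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .dynamics import SteadyState, steady_state
from .parameters import (
    AlleleSpec,
    ExperimentContext,
    Genotype,
    KineticParameters,
    ParameterBundle,
    build_allele,
    build_parameters,
    truncated_allele,
    wild_type_bundle,
)
from .readout import DEFAULT_EXPONENT, tcf_relative

__all__ = [
    "DOSE_CAPS",
    "DoseResponseCurve",
    "EffectiveDose",
    "SynergyResult",
    "MutationScanRecord",
    "ThresholdResult",
    "wt_reference",
    "relative_tcf",
    "dose_response",
    "effective_dose",
    "combination_surface",
    "CombinationSurface",
    "isobole_from_response",
    "isobole_and_max_synergy",
    "scan_hypothetical",
    "restoration_threshold",
    "SCENARIOS",
]

#: Default dose caps (molar) above which the asymptote probe decides
#: finiteness; chosen well above the experimentally explored ranges.
DOSE_CAPS = {"sFRP1": 1e-4, "Dkk1": 1e-5}
ASYMPTOTE_FACTOR = 100.0

SCENARIOS = ("het_truncated_null", "hom_truncated", "expression_reduced")


def wt_reference(base: KineticParameters, ctx: ExperimentContext, **kw) -> SteadyState:
    """Steady state of the untreated wild-type cell under this context."""
    return steady_state(wild_type_bundle(base), ctx.untreated(), **kw)


def relative_tcf(
    bundle: ParameterBundle,
    ctx: ExperimentContext,
    a: float = DEFAULT_EXPONENT,
    reference: SteadyState | None = None,
    warm_start=None,
) -> tuple[float, SteadyState]:
    """Relative TCF activity of a genotype under a context, plus its steady state."""
    ref = reference if reference is not None else wt_reference(bundle.base, ctx)
    ss = steady_state(bundle, ctx, warm_start=warm_start)
    return tcf_relative(ss.b_detect, ref.b_detect, a), ss


@dataclass(frozen=True)
class DoseResponseCurve:
    inhibitor: str
    doses: np.ndarray            # molar, ascending
    relative_tcf: np.ndarray
    converged: np.ndarray        # bool per dose; non-converged points flagged, never interpolated
    asymptote: float             # relative TCF probed at 100x the top dose


@dataclass(frozen=True)
class EffectiveDose:
    """Smallest inhibitor total restoring the target relative TCF.

    ``dose`` is molar, ``math.inf`` when the saturating response cannot
    reach the target; ``bracket`` is the final bisection interval.
    """

    inhibitor: str
    dose: float
    target: float
    bracket: tuple[float, float]
    achieved_tcf: float
    untreated_tcf: float

    @property
    def finite(self) -> bool:
        return math.isfinite(self.dose)


@dataclass(frozen=True)
class SynergyResult:
    isobole: list[tuple[float, float]]          # (sFRP1 dose, Dkk1 dose), molar
    max_synergy_point: tuple[float, float]
    single_agent_doses: tuple[float, float]     # (ED sFRP1, ED Dkk1)
    dose_fraction_sums: list[float]             # combination index per isobole point
    target: float


@dataclass(frozen=True)
class CombinationSurface:
    sfrp_doses: np.ndarray
    dkk_doses: np.ndarray
    relative_tcf: np.ndarray   # shape (len(sfrp), len(dkk))
    converged: np.ndarray


@dataclass(frozen=True)
class MutationScanRecord:
    scenario: str
    label: str
    pt_fraction: float
    kd1_fold: float
    k6_fraction: float
    untreated_tcf: float
    ed_sfrp1: float  # molar; inf if not restorable
    ed_dkk1: float


@dataclass(frozen=True)
class ThresholdResult:
    """Supremum of untreated relative TCF still restorable to wild type."""

    threshold: float                   # any inhibitor
    threshold_by_inhibitor: dict[str, float]
    is_lower_bound: bool               # True when the scan contained no non-restorable record
    bracket_records: tuple[MutationScanRecord | None, MutationScanRecord | None]


def _tcf_at_dose(bundle, ctx, inhibitor, dose, a, ref, warm_start=None):
    ss = steady_state(bundle, ctx.with_dose(inhibitor, dose), warm_start=warm_start)
    return tcf_relative(ss.b_detect, ref.b_detect, a), ss


def dose_response(
    bundle: ParameterBundle,
    ctx: ExperimentContext,
    inhibitor: str,
    dose_grid: Sequence[float],
    a: float = DEFAULT_EXPONENT,
    reference: SteadyState | None = None,
) -> DoseResponseCurve:
    """Relative TCF at each dose of one inhibitor, plus the saturation level.

    The grid must be sorted ascending; steady states are chained as warm
    starts along it.  The asymptote is probed at 100x the top dose.
    """
    doses = np.asarray(dose_grid, dtype=float)
    if doses.size < 2 or np.any(np.diff(doses) < 0):
        raise ValueError("dose_grid must be ascending with at least 2 points")
    ref = reference if reference is not None else wt_reference(bundle.base, ctx)
    tcfs, conv = [], []
    ws = None
    for d in doses:
        t, ss = _tcf_at_dose(bundle, ctx, inhibitor, d, a, ref, warm_start=ws)
        tcfs.append(t)
        conv.append(ss.converged)
        ws = ss.state
    top = doses[-1] if doses[-1] > 0 else DOSE_CAPS[inhibitor]
    asym, _ = _tcf_at_dose(bundle, ctx, inhibitor, ASYMPTOTE_FACTOR * top, a, ref, warm_start=ws)
    return DoseResponseCurve(inhibitor, doses, np.array(tcfs), np.array(conv, bool), asym)


def effective_dose(
    bundle: ParameterBundle,
    ctx: ExperimentContext,
    inhibitor: str,
    target: float = 1.0,
    dose_cap: float | None = None,
    a: float = DEFAULT_EXPONENT,
    reference: SteadyState | None = None,
    rel_precision: float = 0.01,
) -> EffectiveDose:
    """Bisect the inhibitor total until relative TCF equals the target.

    Bisection runs on log-dose to ``rel_precision`` relative precision.  If
    even the asymptote probe (100x the cap) leaves activity above the
    target, the dose is infinite.  A target above the untreated activity is
    an error: there is nothing to restore.
    """
    if dose_cap is None:
        dose_cap = DOSE_CAPS[inhibitor]
    ref = reference if reference is not None else wt_reference(bundle.base, ctx)
    t0, ss0 = _tcf_at_dose(bundle, ctx, inhibitor, 0.0, a, ref)
    if t0 < target * (1.0 - 1e-9):
        raise ValueError(
            f"untreated relative TCF {t0:.4g} is below the target {target:.4g}: nothing to restore"
        )
    if t0 <= target * (1.0 + 1e-9):
        return EffectiveDose(inhibitor, 0.0, target, (0.0, 0.0), t0, t0)

    t_cap, ss_cap = _tcf_at_dose(bundle, ctx, inhibitor, dose_cap, a, ref, warm_start=ss0.state)
    if t_cap > target:
        t_asym, _ = _tcf_at_dose(
            bundle, ctx, inhibitor, ASYMPTOTE_FACTOR * dose_cap, a, ref, warm_start=ss_cap.state
        )
        if t_asym > target:
            return EffectiveDose(
                inhibitor, math.inf, target, (dose_cap, ASYMPTOTE_FACTOR * dose_cap), t_asym, t0
            )
        lo, hi = dose_cap, ASYMPTOTE_FACTOR * dose_cap
        ws = ss_cap.state
    else:
        lo, hi = dose_cap * 1e-6, dose_cap
        ws = ss0.state
        # make sure the lower edge is still above target (very mild mutants)
        while lo > 1e-18:
            t_lo, ss_lo = _tcf_at_dose(bundle, ctx, inhibitor, lo, a, ref, warm_start=ws)
            if t_lo > target:
                ws = ss_lo.state
                break
            hi = lo
            lo *= 1e-3
        else:
            return EffectiveDose(inhibitor, lo, target, (0.0, lo), t0, t0)

    t_mid = t0
    while hi / lo > 1.0 + rel_precision:
        mid = math.sqrt(lo * hi)
        t_mid, ss_mid = _tcf_at_dose(bundle, ctx, inhibitor, mid, a, ref, warm_start=ws)
        ws = ss_mid.state
        if t_mid > target:
            lo = mid
        else:
            hi = mid
    dose = math.sqrt(lo * hi)
    return EffectiveDose(inhibitor, dose, target, (lo, hi), t_mid, t0)


def combination_surface(
    bundle: ParameterBundle,
    ctx: ExperimentContext,
    sfrp_grid: Sequence[float],
    dkk_grid: Sequence[float],
    a: float = DEFAULT_EXPONENT,
    reference: SteadyState | None = None,
) -> CombinationSurface:
    """Full-factorial steady-state relative TCF over a two-inhibitor grid."""
    s_doses = np.asarray(sfrp_grid, dtype=float)
    d_doses = np.asarray(dkk_grid, dtype=float)
    if np.any(np.diff(s_doses) < 0) or np.any(np.diff(d_doses) < 0):
        raise ValueError("dose grids must be sorted ascending")
    ref = reference if reference is not None else wt_reference(bundle.base, ctx)
    tcf = np.empty((s_doses.size, d_doses.size))
    conv = np.empty_like(tcf, dtype=bool)
    row_ws = None
    for i, s in enumerate(s_doses):
        ws = row_ws
        for j, d in enumerate(d_doses):
            cctx = ctx.with_dose("sFRP1", s).with_dose("Dkk1", d)
            ss = steady_state(bundle, cctx, warm_start=ws)
            tcf[i, j] = tcf_relative(ss.b_detect, ref.b_detect, a)
            conv[i, j] = ss.converged
            ws = ss.state
            if j == 0:
                row_ws = ss.state
    return CombinationSurface(s_doses, d_doses, tcf, conv)


def isobole_from_response(
    response: Callable[[float, float], float],
    ed_sfrp: float,
    ed_dkk: float,
    target: float,
    n_points: int = 9,
    rel_precision: float = 0.01,
) -> SynergyResult:
    """Trace the target-level isobole of a two-dose response function.

    For a ladder of fixed sFRP1 doses between 0 and its single-agent
    effective dose, the Dkk1 dose reaching the target is found by bisection
    (the response must be decreasing in each dose).  The combination index
    of a point is the sum of its fractional single-agent doses; the
    maximally synergistic combination minimises it.
    """
    if not (math.isfinite(ed_sfrp) and math.isfinite(ed_dkk)):
        raise ValueError("synergy analysis requires finite single-agent effective doses")
    fracs = np.linspace(0.0, 1.0, n_points)
    isobole, ci = [], []
    for f in fracs:
        s = f * ed_sfrp
        if f >= 1.0:
            isobole.append((ed_sfrp, 0.0))
            ci.append(1.0)
            continue
        lo, hi = 0.0, ed_dkk * 1.5
        # expand if the response at the expected cap is still above target
        while response(s, hi) > target and hi < ed_dkk * 1e3:
            hi *= 2.0
        lo_pos = hi * 1e-9
        while hi / max(lo, lo_pos) > 1.0 + rel_precision:
            mid = math.sqrt(max(lo, lo_pos) * hi)
            if response(s, mid) > target:
                lo = mid
            else:
                hi = mid
        d = math.sqrt(max(lo, lo_pos) * hi)
        isobole.append((s, d))
        ci.append(s / ed_sfrp + d / ed_dkk)
    k = int(np.argmin(ci))
    return SynergyResult(isobole, isobole[k], (ed_sfrp, ed_dkk), ci, target)


def isobole_and_max_synergy(
    bundle: ParameterBundle,
    ctx: ExperimentContext,
    single_agent: tuple[EffectiveDose, EffectiveDose] | None = None,
    target: float = 1.0,
    n_points: int = 9,
    a: float = DEFAULT_EXPONENT,
    reference: SteadyState | None = None,
) -> SynergyResult:
    """Isobole and maximally synergistic sFRP1+Dkk1 combination for a genotype."""
    ref = reference if reference is not None else wt_reference(bundle.base, ctx)
    if single_agent is None:
        single_agent = (
            effective_dose(bundle, ctx, "sFRP1", target=target, a=a, reference=ref),
            effective_dose(bundle, ctx, "Dkk1", target=target, a=a, reference=ref),
        )
    ed_s, ed_d = single_agent
    if not (ed_s.finite and ed_d.finite):
        raise ValueError(
            f"synergy analysis refused: infinite single-agent dose for {bundle.label}"
        )
    cache: dict[tuple[float, float], float] = {}
    ws_holder = {"ws": None}

    def response(s, d):
        key = (s, d)
        if key not in cache:
            cctx = ctx.with_dose("sFRP1", s).with_dose("Dkk1", d)
            ss = steady_state(bundle, cctx, warm_start=ws_holder["ws"])
            ws_holder["ws"] = ss.state
            cache[key] = tcf_relative(ss.b_detect, ref.b_detect, a)
        return cache[key]

    return isobole_from_response(response, ed_s.dose, ed_d.dose, target, n_points)


def _scan_genotypes(scenario, kd1_grid, k6_grid, pt_fractions):
    if scenario == "het_truncated_null":
        null = build_allele("1638N")
        for kf in kd1_grid:
            for k6 in k6_grid:
                yield Genotype(truncated_allele(f"trunc(kd1x{kf:.3g},k6x{k6:.3g})", kf, k6), null), kf, k6, 1.0
    elif scenario == "hom_truncated":
        for kf in kd1_grid:
            for k6 in k6_grid:
                al = truncated_allele(f"trunc(kd1x{kf:.3g},k6x{k6:.3g})", kf, k6)
                yield Genotype.homozygous(al), kf, k6, 1.0
    elif scenario == "expression_reduced":
        for f in pt_fractions:
            al = AlleleSpec(f"expr{f:.3g}", f, 1.0, 1.0)
            yield Genotype.homozygous(al), 1.0, 1.0, f
    else:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")


def scan_hypothetical(
    scenario: str,
    ctx: ExperimentContext,
    base: KineticParameters | None = None,
    kd1_grid: Sequence[float] | None = None,
    k6_grid: Sequence[float] | None = None,
    pt_fractions: Sequence[float] | None = None,
    a: float = DEFAULT_EXPONENT,
    reference: SteadyState | None = None,
) -> list[MutationScanRecord]:
    """Mutation-severity scan: untreated TCF plus both effective doses.

    Scenarios: ``het_truncated_null`` pairs each hypothetical truncated
    allele with the near-null 1638N allele (loss of heterozygosity),
    ``hom_truncated`` makes it homozygous (copy-neutral LOH), and
    ``expression_reduced`` varies total full-length APC expression only.
    Grids default to coarse log-spaced coverage of the plausible ranges
    (KD1 fold 1..20, k6 fraction 0.05..1, expression 0.02..1).
    """
    base = base if base is not None else KineticParameters()
    kd1_grid = np.geomspace(1.0, 20.0, 10) if kd1_grid is None else np.asarray(kd1_grid, float)
    k6_grid = np.geomspace(0.05, 1.0, 10) if k6_grid is None else np.asarray(k6_grid, float)
    pt_fractions = (
        np.geomspace(0.02, 1.0, 12) if pt_fractions is None else np.asarray(pt_fractions, float)
    )
    ref = reference if reference is not None else wt_reference(base, ctx)
    records = []
    for genotype, kf, k6, ptf in _scan_genotypes(scenario, kd1_grid, k6_grid, pt_fractions):
        bundle = build_parameters(genotype, base)
        t0, _ = _tcf_at_dose(bundle, ctx, "sFRP1", 0.0, a, ref)
        eds = {}
        for inhibitor in ("sFRP1", "Dkk1"):
            if t0 <= 1.0 + 1e-9:
                eds[inhibitor] = 0.0
                continue
            eds[inhibitor] = effective_dose(
                bundle, ctx, inhibitor, target=1.0, a=a, reference=ref
            ).dose
        records.append(
            MutationScanRecord(
                scenario, genotype.label, ptf, kf, k6, t0, eds["sFRP1"], eds["Dkk1"]
            )
        )
    return records


def restoration_threshold(records: Sequence[MutationScanRecord]) -> ThresholdResult:
    """Largest untreated relative TCF for which some finite effective dose exists.

    Reports the overall supremum and the per-inhibitor suprema.  When the
    scan contains no record with both doses infinite the value is only a
    lower bound on the true threshold, and is flagged as such.
    """
    if not records:
        raise ValueError("empty scan")
    finite_any = [r for r in records if math.isfinite(r.ed_sfrp1) or math.isfinite(r.ed_dkk1)]
    infinite_both = [r for r in records if not (math.isfinite(r.ed_sfrp1) or math.isfinite(r.ed_dkk1))]
    threshold = max((r.untreated_tcf for r in finite_any), default=1.0)
    by_inh = {
        "sFRP1": max((r.untreated_tcf for r in records if math.isfinite(r.ed_sfrp1)), default=1.0),
        "Dkk1": max((r.untreated_tcf for r in records if math.isfinite(r.ed_dkk1)), default=1.0),
    }
    below = max(finite_any, key=lambda r: r.untreated_tcf) if finite_any else None
    above = min(infinite_both, key=lambda r: r.untreated_tcf) if infinite_both else None
    return ThresholdResult(threshold, by_inh, not infinite_both, (below, above))
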