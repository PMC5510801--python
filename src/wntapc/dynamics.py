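"""Receptor-level ODE dynamics of the Wnt pathway, integrated to steady state.

Nine species evolve dynamically, in deliberately mixed units: soluble pools
(sFRP1-bound Wnt ``SW``, free destruction complexes ``C``/``Cp``, free
beta-catenin ``B``) are molar, membrane pools (Dkk1-bound LRP ``LD``,
Wnt-bound Frizzled ``FW``, ternary complex ``LF``, ternary-bound destruction
complexes ``CL``/``CLp``) are copies per cell.  The partition coefficients
``Ksu_in``/``Ksu_ex`` appear exactly where a membrane copy number enters an
intracellular or extracellular mass-action product, which keeps every rate
term dimensionally auditable.  Seven further species (complex-bound
beta-catenin ``CB``/``CBp``, free LRP, Frizzled, Wnt, sFRP1 and Dkk1) are
closed algebraically by conservation of the receptor numbers and the
soluble totals.

The destruction-complex totals ``CT``/``CTp`` entering the closures are the
rapid-equilibrium values from :mod:`wntapc.equilibrium`.  Steady states are
obtained the way the underlying experiments were interpreted -- integration
over seven simulated days -- followed by an optional Newton polish of the
integrated endpoint, which matters for severe mutants whose slowest mode
(plain beta-catenin turnover, ``1/k8`` = 2.8 days) has not fully decayed
within the horizon.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize
from scipy.integrate import solve_ivp

from .equilibrium import ComplexEquilibrium, equilibrium_for_bundle
from .parameters import ExperimentContext, ParameterBundle, partition_coefficients

__all__ = [
    "PathwayState",
    "Closures",
    "SteadyState",
    "InconsistentStateError",
    "SteadyStateError",
    "rhs_and_closure",
    "integrate_to_steady_state",
    "steady_state",
    "local_sensitivity",
    "SensitivityEntry",
    "SEVEN_DAYS",
    "T_CHAR",
]

log = logging.getLogger(__name__)

SEVEN_DAYS = 7 * 24 * 3600.0  # default integration horizon, s
T_CHAR = 3600.0  # characteristic time for the relative-rate convergence metric, s

# state vector layout
_NAMES = ("SW", "LD", "FW", "LF", "CL", "CLp", "C", "Cp", "B")
_MOLAR = np.array([True, False, False, False, False, False, True, True, True])


class InconsistentStateError(ValueError):
    """A closure variable is negative beyond tolerance: the state violates
    one of the conservation relations."""


class SteadyStateError(RuntimeError):
    """Integration or refinement produced an unusable state."""


@dataclass(frozen=True)
class PathwayState:
    """Dynamic species; molar for soluble pools, copies/cell for membrane pools."""

    SW: float
    LD: float
    FW: float
    LF: float
    CL: float
    CLp: float
    C: float
    Cp: float
    B: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _NAMES], dtype=float)

    @classmethod
    def from_array(cls, y) -> "PathwayState":
        return cls(*map(float, y))

    @classmethod
    def zeros(cls) -> "PathwayState":
        return cls(*([0.0] * 9))


@dataclass(frozen=True)
class Closures:
    """Algebraically closed species (same unit conventions as the state)."""

    CB: float
    CBp: float
    L: float
    F: float
    W: float
    S: float
    D: float


@dataclass(frozen=True)
class SteadyState:
    """Integrated (and optionally polished) stationary point of the pathway."""

    state: PathwayState
    closures: Closures
    equilibrium: ComplexEquilibrium
    b_detect: float  # B + CB + CBp: total detectable beta-catenin, M
    t_final: float
    converged: bool
    max_rel_rate: float  # max_i |dy_i/dt| * T_CHAR / scale_i at termination


def _coefficients(bundle: ParameterBundle, ctx: ExperimentContext, eq: ComplexEquilibrium):
    p = bundle.base
    ksu_ex, ksu_in = partition_coefficients(ctx, p)
    return (
        p.k1, p.k_m1, p.k2, p.k_m2, p.k3, p.k_m3, p.k4, p.k_m4, p.k5, p.k_m5,
        bundle.k6, bundle.k6p, p.k_m6, p.k7, p.k8,
        ctx.FT, ctx.LT, ctx.WT_total, ctx.ST_total, ctx.DT_total,
        eq.CT, eq.CTp, ksu_ex, ksu_in,
    )


def _make_rhs(coef):
    (k1, km1, k2, km2, k3, km3, k4, km4, k5, km5,
     k6, k6p, km6, k7, k8, FT, LT, WT, ST, DT, CT, CTp, kex, kin) = coef

    def rhs(t, y):
        SW, LD, FW, LF, CL, CLp, C, Cp, B = y
        CB = CT - C - kin * CL
        CBp = CTp - Cp - kin * CLp
        L = LT - LF - CL - CLp - LD
        F = FT - FW - LF - CL - CLp
        W = WT - (FW + LF + CL + CLp) * kex - SW
        S = ST - SW
        D = DT - LD * kex
        return (
            k1 * S * W - km1 * SW,
            k4 * D * L - km4 * LD,
            k2 * F * W - km2 * FW - kin * k3 * L * FW + km3 * LF,
            kin * k3 * L * FW - km3 * LF - k5 * LF * C - k5 * LF * Cp,
            k5 * LF * C - km5 * CL,
            k5 * LF * Cp - km5 * CLp,
            -kin * k5 * LF * C + kin * km5 * CL - k6 * C * B + km6 * CB,
            -kin * k5 * LF * Cp + kin * km5 * CLp - k6p * Cp * B + km6 * CBp,
            k7 - k8 * B - k6 * C * B - k6p * Cp * B,
        )

    return rhs


def _closures(coef, y) -> Closures:
    (k1, km1, k2, km2, k3, km3, k4, km4, k5, km5,
     k6, k6p, km6, k7, k8, FT, LT, WT, ST, DT, CT, CTp, kex, kin) = coef
    SW, LD, FW, LF, CL, CLp, C, Cp, B = y
    return Closures(
        CB=CT - C - kin * CL,
        CBp=CTp - Cp - kin * CLp,
        L=LT - LF - CL - CLp - LD,
        F=FT - FW - LF - CL - CLp,
        W=WT - (FW + LF + CL + CLp) * kex - SW,
        S=ST - SW,
        D=DT - LD * kex,
    )


def rhs_and_closure(
    state: PathwayState,
    bundle: ParameterBundle,
    ctx: ExperimentContext,
    equilibrium: ComplexEquilibrium | None = None,
) -> tuple[np.ndarray, Closures]:
    """Evaluate time-derivatives and closure variables at a given state.

    Validates physicality: any closure variable negative beyond -1e-12
    (absolute, in its own units) means the state is inconsistent with the
    conservation totals and raises :class:`InconsistentStateError`.
    """
    eq = equilibrium if equilibrium is not None else equilibrium_for_bundle(bundle)
    coef = _coefficients(bundle, ctx, eq)
    y = state.as_array()
    if not np.all(np.isfinite(y)):
        raise ValueError("state contains non-finite entries")
    clos = _closures(coef, y)
    for name, value in vars(clos).items():
        if value < -1e-12:
            raise InconsistentStateError(
                f"closure variable {name} = {value:.6e} is negative: state violates conservation"
            )
    dy = np.array(_make_rhs(coef)(0.0, y))
    return dy, clos


def _scales(coef, y):
    """Per-species magnitude scales used for rate normalisation and clamping."""
    (k1, km1, k2, km2, k3, km3, k4, km4, k5, km5,
     k6, k6p, km6, k7, k8, FT, LT, WT, ST, DT, CT, CTp, kex, kin) = coef
    molar_scale = max(WT, ST, DT, CT + CTp, k7 / k8, 1e-12)
    count_scale = max(FT, LT, 1.0)
    scales = np.where(_MOLAR, molar_scale, count_scale)
    return np.maximum(np.abs(y), 1e-6 * scales)


def _max_rel_rate(coef, y):
    dy = np.array(_make_rhs(coef)(0.0, y))
    return float(np.max(np.abs(dy) * T_CHAR / _scales(coef, y)))


def _clamp_nonnegative(coef, y):
    """Zero out tiny negative excursions; large ones are integration failures."""
    y = np.array(y, dtype=float)
    floor = -1e-4 * _scales(coef, np.zeros_like(y))
    if np.any(y < floor):
        bad = {n: v for n, v, f in zip(_NAMES, y, floor) if v < f}
        raise SteadyStateError(f"state went significantly negative: {bad}")
    neg = y < 0
    if np.any(neg):
        log.debug("clamping negative excursions to zero: %s",
                  {n: v for n, v in zip(_NAMES, y) if v < 0})
        y[neg] = 0.0
    return y


def _refine_root(coef, y0):
    """Newton polish of an integrated endpoint towards rhs == 0.

    Works on the steady-state reduction rather than the raw 9-dimensional
    system: at a stationary point the fast binding equilibria give the free
    complexes in closed form, ``C = CT / (1 + Ksu_in*k5*LF/k_m5 + k6*B/k_m6)``
    (likewise C'), with the ternary-bound and beta-catenin-bound complexes
    following by mass action.  That leaves five unknowns (SW, LD, FW, LF, B)
    whose residuals are well conditioned, where a Newton iteration on the
    raw stiff system stalls.
    """
    (k1, km1, k2, km2, k3, km3, k4, km4, k5, km5,
     k6, k6p, km6, k7, k8, FT, LT, WT, ST, DT, CT, CTp, kex, kin) = coef

    def expand(x):
        SW, LD, FW, LF, B = x
        C = CT / (1.0 + kin * k5 * LF / km5 + k6 * B / km6)
        Cp = CTp / (1.0 + kin * k5 * LF / km5 + k6p * B / km6)
        CL, CLp = k5 * LF * C / km5, k5 * LF * Cp / km5
        return np.array([SW, LD, FW, LF, CL, CLp, C, Cp, B])

    def residual(x):
        SW, LD, FW, LF, B = x
        y = expand(x)
        CL, CLp, C, Cp = y[4], y[5], y[6], y[7]
        L = LT - LF - CL - CLp - LD
        F = FT - FW - LF - CL - CLp
        W = WT - (FW + LF + CL + CLp) * kex - SW
        S = ST - SW
        D = DT - LD * kex
        return np.array([
            k1 * S * W - km1 * SW,
            k4 * D * L - km4 * LD,
            k2 * F * W - km2 * FW - kin * k3 * L * FW + km3 * LF,
            kin * k3 * L * FW - km3 * LF - k5 * LF * (C + Cp),
            k7 - k8 * B - k6 * C * B - k6p * Cp * B,
        ])

    x0 = np.array([y0[0], y0[1], y0[2], y0[3], y0[8]])
    floors = np.array([
        1e-9 * max(WT, ST, 1e-12), 1e-6 * LT, 1e-6 * FT, 1e-6 * LT, 1e-9 * k7 / k8,
    ])
    s = np.maximum(np.abs(x0), floors)

    sol = optimize.root(lambda z: residual(z * s) * (T_CHAR / s), x0 / s, method="hybr")
    if not sol.success:
        return None
    y = expand(sol.x * s)
    # species that are structurally zero must come out exactly zero,
    # not as round-off dust from the Newton iteration
    if ST == 0.0:
        y[0] = 0.0
    if DT == 0.0:
        y[1] = 0.0
    if WT == 0.0:
        y[[0, 2, 3, 4, 5]] = 0.0
    if CT == 0.0:
        y[[4, 6]] = 0.0
    if CTp == 0.0:
        y[[5, 7]] = 0.0
    scales = _scales(coef, y)
    if np.any(y < -1e-4 * scales):
        return None
    y = np.maximum(y, 0.0)
    clos = _closures(coef, y)
    molar_tol = 1e-4 * float(scales[_MOLAR].max())
    count_tol = 1e-4 * float(scales[~_MOLAR].max())
    for name, value in vars(clos).items():
        tol = count_tol if name in ("L", "F") else molar_tol
        if value < -tol:
            return None
    return y


def integrate_to_steady_state(
    bundle: ParameterBundle,
    ctx: ExperimentContext,
    horizon: float = SEVEN_DAYS,
    tol: float = 1e-6,
    refine: bool = True,
    rtol: float = 1e-8,
    warm_start: PathwayState | np.ndarray | None = None,
    initial_state: PathwayState | None = None,
    equilibrium: ComplexEquilibrium | None = None,
) -> SteadyState:
    """Integrate the pathway from the resting state until stationary.

    The default initial condition has every binding complex empty, the free
    destruction complexes at their rapid-equilibrium totals, and no
    beta-catenin; ``warm_start`` (for example, the steady state at a
    neighbouring inhibitor dose) lets the Newton polish be attempted first,
    falling back to full integration whenever it fails or lands on an
    unphysical point.  ``initial_state`` replaces the default initial
    condition outright (useful for probing initial-condition independence).
    Convergence is declared when every species' relative
    rate ``|dy/dt| * T_CHAR / scale`` falls below ``tol``; if the horizon is
    reached first the state is returned with ``converged=False``.
    """
    eq = equilibrium if equilibrium is not None else equilibrium_for_bundle(bundle)
    coef = _coefficients(bundle, ctx, eq)
    rhs = _make_rhs(coef)
    atol = np.where(_MOLAR, 1e-16, 1e-6)

    if warm_start is not None:
        y_ws = warm_start.as_array() if isinstance(warm_start, PathwayState) else np.asarray(warm_start, float)
        y = _refine_root(coef, y_ws)
        if y is not None:
            rate = _max_rel_rate(coef, y)
            if rate < tol:
                clos = _closures(coef, y)
                return SteadyState(
                    PathwayState.from_array(y), clos, eq,
                    float(y[8] + clos.CB + clos.CBp), 0.0, True, rate,
                )

    if initial_state is not None:
        y0 = initial_state.as_array()
    else:
        y0 = np.zeros(9)
        y0[6], y0[7] = eq.CT, eq.CTp
    sol = solve_ivp(rhs, (0.0, horizon), y0, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise SteadyStateError(f"integration failed: {sol.message}")
    y = _clamp_nonnegative(coef, sol.y[:, -1])

    if refine:
        y_ref = _refine_root(coef, y)
        if y_ref is not None:
            y = y_ref

    rate = _max_rel_rate(coef, y)
    clos = _closures(coef, y)
    b_detect = float(y[8] + clos.CB + clos.CBp)
    return SteadyState(
        PathwayState.from_array(y), clos, eq, b_detect,
        float(sol.t[-1]), bool(rate < tol), rate,
    )


def steady_state(
    bundle: ParameterBundle,
    ctx: ExperimentContext,
    warm_start: PathwayState | np.ndarray | None = None,
    **kwargs,
) -> SteadyState:
    """Convenience wrapper around :func:`integrate_to_steady_state`."""
    return integrate_to_steady_state(bundle, ctx, warm_start=warm_start, **kwargs)


@dataclass(frozen=True)
class SensitivityEntry:
    parameter: str
    elasticity: float  # d ln(b_detect) / d ln(theta)
    converged: bool
    note: str = ""


def _perturbable(bundle: ParameterBundle, ctx: ExperimentContext):
    """(name, apply(factor) -> (bundle, ctx)) for every positive parameter."""
    entries = []

    def bundle_field(name):
        entries.append((name, lambda f, n=name: (replace(bundle, **{n: getattr(bundle, n) * f}), ctx)))

    def base_field(name):
        entries.append((
            name,
            lambda f, n=name: (
                replace(bundle, base=replace(bundle.base, **{n: getattr(bundle.base, n) * f})),
                ctx,
            ),
        ))

    def ctx_field(name):
        entries.append((name, lambda f, n=name: (bundle, replace(ctx, **{n: getattr(ctx, n) * f}))))

    for n in ("PT", "KD1", "k6"):
        bundle_field(n)
    if not bundle.homozygous:
        for n in ("PTp", "KD1p", "k6p"):
            bundle_field(n)
    for n in ("k1", "k_m1", "k2", "k_m2", "k3", "k_m3", "k4", "k_m4", "k5", "k_m5",
              "k_m6", "k7", "k8", "KD2", "AT", "GT", "Vcell"):
        base_field(n)
    for n in ("WT_total", "ST_total", "DT_total", "FT", "LT", "Vexp", "Ncell"):
        ctx_field(n)
    return entries


def local_sensitivity(
    bundle: ParameterBundle,
    ctx: ExperimentContext,
    rel_step: float = 0.05,
    **steady_kwargs,
) -> list[SensitivityEntry]:
    """Logarithmic sensitivities (elasticities) of steady-state b_detect.

    Central finite differences on the log scale: each parameter theta is
    multiplied by ``1 +/- rel_step`` and the elasticity is
    ``d ln(b_detect) / d ln(theta)``.  Parameters whose current value is
    exactly zero (for example, an absent inhibitor) cannot be perturbed
    multiplicatively and are reported with elasticity ``nan`` and a note.
    Entries are sorted by decreasing magnitude; perturbed runs that fail to
    converge are flagged, never dropped.
    """
    baseline = steady_state(bundle, ctx, **steady_kwargs)
    if not baseline.converged:
        raise SteadyStateError("baseline steady state did not converge; cannot take sensitivities")
    out = []
    ws = baseline.state
    for name, apply in _perturbable(bundle, ctx):
        b0, c0 = apply(1.0)
        value = getattr(b0, name, None)
        if value is None:
            value = getattr(b0.base, name, None)
        if value is None:
            value = getattr(c0, name)
        if value == 0.0:
            out.append(SensitivityEntry(name, float("nan"), True, "zero-valued parameter"))
            continue
        if rel_step == 0.0:
            out.append(SensitivityEntry(name, 0.0, True))
            continue
        try:
            hi = steady_state(*apply(1.0 + rel_step), warm_start=ws, **steady_kwargs)
            lo = steady_state(*apply(1.0 - rel_step), warm_start=ws, **steady_kwargs)
        except (SteadyStateError, ValueError) as exc:
            out.append(SensitivityEntry(name, float("nan"), False, f"perturbed run failed: {exc}"))
            continue
        ok = hi.converged and lo.converged
        elast = (math.log(hi.b_detect) - math.log(lo.b_detect)) / (
            math.log1p(rel_step) - math.log1p(-rel_step)
        )
        out.append(SensitivityEntry(name, elast, ok, "" if ok else "perturbed run not converged"))
    out.sort(key=lambda e: (math.isnan(e.elasticity), -abs(e.elasticity) if not math.isnan(e.elasticity) else 0.0))
    return out
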