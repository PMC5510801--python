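"""Rapid-equilibrium assembly of the beta-catenin destruction complex.

Complex formation is treated as a two-stage reversible association held at
equilibrium on the timescale of the receptor dynamics: APC binds Axin with
dissociation constant ``KD1`` (per APC species), and the Axin/APC dimer
binds GSK3beta with shared dissociation constant ``KD2``.  With two APC
species P and P' competing for the same Axin and GSK pools the unknowns are
eight concentrations tied together by four mass-action ratios and four
conservation relations:

    P*A / A_P   = KD1          A_P*G  / C_T  = KD2
    P'*A / A_P' = KD1'         A_P'*G / C_T' = KD2

    P_T  = P  + A_P  + C_T          A_T = A + A_P + A_P' + C_T + C_T'
    P_T' = P' + A_P' + C_T'         G_T = G + C_T + C_T'

Each complex and each dimer contains exactly one APC molecule of its own
type, so each APC pool is depleted only by its own-type assemblies, while
Axin and GSK are shared.  Given the free pools (A, G) every other species
follows in closed form, so the system reduces to two equations in (A, G),
each strictly monotone in its own unknown -- the nonnegative root is unique.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .parameters import KineticParameters, ParameterBundle

__all__ = ["ComplexEquilibrium", "EquilibriumError", "solve_equilibrium", "equilibrium_for_bundle"]


class EquilibriumError(RuntimeError):
    """Raised when the equilibrium solver cannot reach the residual tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class ComplexEquilibrium:
    """Equilibrium concentrations (molar) of the destruction-complex system."""

    P_free: float
    Pp_free: float
    A_free: float
    G_free: float
    AP: float
    APp: float
    CT: float
    CTp: float
    residual: float  # max conservation residual relative to the totals

    @property
    def CT_total(self) -> float:
        return self.CT + self.CTp


def _species_from_free(A, G, PT, KD1, KD2):
    """Free-pool closed form: P, A_P, C_T for one APC species given (A, G)."""
    den = 1.0 + A / KD1 + A * G / (KD1 * KD2)
    P = PT / den
    AP = P * A / KD1
    CT = AP * G / KD2
    return P, AP, CT


def solve_equilibrium(
    PT: float,
    PTp: float,
    AT: float,
    GT: float,
    KD1: float,
    KD1p: float,
    KD2: float,
    rtol: float = 1e-12,
) -> ComplexEquilibrium:
    """Solve the two-species destruction-complex equilibrium.

    Parameters are molar totals and dissociation constants; ``PTp = 0``
    recovers the single-species (homozygous) system exactly, with all primed
    outputs identically zero.  The solver works on the (A, G) reduction:
    a quasi-Newton root find on log-free-pools (positivity by construction),
    falling back to nested bracketing bisection, which cannot fail on this
    monotone system.  Residuals are the Axin and GSK conservation defects
    relative to their totals; convergence demands ``residual < rtol`` scaled
    to the system.
    """
    for nm, v in (("PT", PT), ("PTp", PTp), ("AT", AT), ("GT", GT)):
        if v < 0 or not math.isfinite(v):
            raise ValueError(f"total {nm} must be nonnegative, got {v}")
    for nm, v in (("KD1", KD1), ("KD2", KD2)):
        if not v > 0:
            raise ValueError(f"dissociation constant {nm} must be positive, got {v}")
    if PTp > 0 and not KD1p > 0:
        raise ValueError(f"dissociation constant KD1p must be positive, got {KD1p}")
    if KD1p <= 0:
        KD1p = KD1  # unused when PTp == 0; keep formulas finite

    if AT == 0.0 or GT == 0.0 or (PT == 0.0 and PTp == 0.0):
        # no complex can form; everything stays free
        return ComplexEquilibrium(PT, PTp, AT, GT, 0.0, 0.0, 0.0, 0.0, 0.0)

    def residuals(A, G):
        P, AP, CT = _species_from_free(A, G, PT, KD1, KD2)
        Pp, APp, CTp = _species_from_free(A, G, PTp, KD1p, KD2)
        rA = (A + AP + APp + CT + CTp - AT) / AT
        rG = (G + CT + CTp - GT) / GT
        return rA, rG

    def pack(A, G):
        P, AP, CT = _species_from_free(A, G, PT, KD1, KD2)
        Pp, APp, CTp = _species_from_free(A, G, PTp, KD1p, KD2)
        rA, rG = residuals(A, G)
        res = max(abs(rA), abs(rG))
        return ComplexEquilibrium(P, Pp, A, G, AP, APp, CT, CTp, res)

    # primary route: root find in log-space starting from the all-free guess
    sol = optimize.root(
        lambda x: residuals(math.exp(x[0]), math.exp(x[1])),
        x0=np.log([AT, GT]),
        method="hybr",
        options={"xtol": 1e-14},
    )
    if sol.success:
        eq = pack(math.exp(sol.x[0]), math.exp(sol.x[1]))
        if eq.residual < rtol:
            return eq

    # fallback: nested bracketing on the monotone reduction
    def inner_A(G):
        def fA(A):
            rA, _ = residuals(A, G)
            return rA

        return optimize.brentq(fA, 0.0, AT, xtol=1e-300, rtol=8.9e-16, maxiter=200)

    def outer_G(G):
        A = inner_A(G)
        _, rG = residuals(A, G)
        return rG

    try:
        G = optimize.brentq(outer_G, 0.0, GT, xtol=1e-300, rtol=8.9e-16, maxiter=200)
        eq = pack(inner_A(G), G)
    except Exception as exc:  # pragma: no cover - bracketing on monotone residuals
        raise EquilibriumError(f"equilibrium bracketing failed: {exc}") from exc
    if eq.residual > rtol * 10:
        raise EquilibriumError(
            f"equilibrium solver stalled at relative residual {eq.residual:.3e}",
            residual=eq.residual,
        )
    return eq


def equilibrium_for_bundle(bundle: ParameterBundle) -> ComplexEquilibrium:
    """Destruction-complex equilibrium for a genotype parameter bundle."""
    base: KineticParameters = bundle.base
    return solve_equilibrium(
        bundle.PT, bundle.PTp, base.AT, base.GT, bundle.KD1, bundle.KD1p, base.KD2
    )
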