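"""Synthetic measurement panels with the noise structure of reporter assays.

Reporter-assay readouts are strictly positive with roughly proportional
error bars, so replicates are drawn as the noiseless model output times a
lognormal factor ``exp(N(0, cv))``.  Every generated dataset carries its
ground truth (noiseless values, generating parameters, seed) alongside the
observations, so recovery tests never have to re-derive the truth from the
noisy file, and regeneration under the same seed is bit-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import steady_state
from .dose_response import wt_reference
from .parameters import (
    ExperimentContext,
    Genotype,
    KineticParameters,
    build_parameters,
    calibration_context,
)
from .readout import DEFAULT_EXPONENT, DEFAULT_LAMBDA, tcf_relative

__all__ = ["SyntheticPanel", "BetaDoseResponse", "gen_tcf_panel", "gen_beta_dose_response"]


@dataclass(frozen=True)
class SyntheticPanel:
    """Replicated TCF-activity measurements across genotypes."""

    data: pd.DataFrame            # columns: genotype, replicate, value
    truth: dict[str, float]       # genotype -> noiseless relative TCF
    beta_ratios: dict[str, float]  # genotype -> noiseless b_detect ratio vs WT
    n_replicates: int
    cv: float
    seed: int

    def write(self, csv_path: str | Path) -> None:
        """CSV of observations plus a ``.truth.json`` sidecar with the ground truth."""
        csv_path = Path(csv_path)
        self.data.to_csv(csv_path, index=False)
        sidecar = {
            "truth_relative_tcf": self.truth,
            "beta_ratios": self.beta_ratios,
            "n_replicates": self.n_replicates,
            "cv": self.cv,
            "seed": self.seed,
        }
        csv_path.with_suffix(".truth.json").write_text(json.dumps(sidecar, indent=1))


@dataclass(frozen=True)
class BetaDoseResponse:
    """Synthetic beta-catenin vs Wnt-dose curve in assay measurement units."""

    data: pd.DataFrame            # columns: wnt_molar, value
    truth: pd.DataFrame           # columns: wnt_molar, b_detect_molar, value_noiseless
    lam: float
    cv: float
    seed: int

    def write(self, csv_path: str | Path) -> None:
        csv_path = Path(csv_path)
        self.data.to_csv(csv_path, index=False)
        sidecar = {
            "truth": self.truth.to_dict(orient="list"),
            "lam": self.lam,
            "cv": self.cv,
            "seed": self.seed,
        }
        csv_path.with_suffix(".truth.json").write_text(json.dumps(sidecar, indent=1))


def gen_tcf_panel(
    genotypes: Sequence[str | Genotype],
    ctx: ExperimentContext | None = None,
    base: KineticParameters | None = None,
    a: float = DEFAULT_EXPONENT,
    cv: float = 0.05,
    n: int = 3,
    seed: int = 0,
) -> SyntheticPanel:
    """Generate a noisy relative-TCF panel for a list of genotypes.

    Genotype strings are parsed through the allele catalog.  ``cv = 0``
    reproduces the noiseless model output in every replicate.
    """
    if cv < 0:
        raise ValueError("cv must be nonnegative")
    if n < 1:
        raise ValueError("need at least one replicate")
    base = base if base is not None else KineticParameters()
    ctx = ctx if ctx is not None else ExperimentContext()
    ref = wt_reference(base, ctx)
    rng = np.random.default_rng(seed)
    rows, truth, betas = [], {}, {}
    for g in genotypes:
        genotype = Genotype.from_string(g) if isinstance(g, str) else g
        ss = steady_state(build_parameters(genotype, base), ctx.untreated())
        t = tcf_relative(ss.b_detect, ref.b_detect, a)
        truth[genotype.label] = t
        betas[genotype.label] = ss.b_detect / ref.b_detect
        noise = np.exp(rng.normal(0.0, cv, size=n)) if cv > 0 else np.ones(n)
        for i, value in enumerate(t * noise):
            rows.append({"genotype": genotype.label, "replicate": i, "value": value})
    return SyntheticPanel(pd.DataFrame(rows), truth, betas, n, cv, seed)


def gen_beta_dose_response(
    wnt_grid: Sequence[float],
    ctx: ExperimentContext | None = None,
    base: KineticParameters | None = None,
    lam: float = DEFAULT_LAMBDA,
    cv: float = 0.05,
    seed: int = 0,
) -> BetaDoseResponse:
    """Synthetic wild-type beta-catenin curve over a Wnt titration.

    Uses the small-well calibration context by default.  The noiseless
    curve is nondecreasing in Wnt (more ligand sequesters more destruction
    complex at the membrane); measured values are ``b_detect * lam`` with
    multiplicative lognormal noise.  Doses outside the assay's titrated
    range [0, 10 nM] trigger a warning, not an error.
    """
    wnt = np.asarray(wnt_grid, float)
    if np.any(wnt < 0):
        raise ValueError("Wnt totals must be nonnegative")
    if np.any(wnt > 1e-8):
        warnings.warn("Wnt grid extends beyond the titrated range [0, 1e-8 M]", stacklevel=2)
    base = base if base is not None else KineticParameters()
    ctx = ctx if ctx is not None else calibration_context()
    rng = np.random.default_rng(seed)
    bundle = build_parameters(Genotype.from_string("WT/WT"), base)
    b = []
    ws = None
    for w in wnt:
        ss = steady_state(bundle, replace(ctx.untreated(), WT_total=float(w)), warm_start=ws)
        ws = ss.state
        b.append(ss.b_detect)
    b = np.asarray(b)
    clean = b * lam
    noise = np.exp(rng.normal(0.0, cv, size=b.size)) if cv > 0 else np.ones(b.size)
    data = pd.DataFrame({"wnt_molar": wnt, "value": clean * noise})
    truth = pd.DataFrame({"wnt_molar": wnt, "b_detect_molar": b, "value_noiseless": clean})
    return BetaDoseResponse(data, truth, lam, cv, seed)
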