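# Methods

## Model structure and assumptions

The cell is a well-mixed three-compartment system: extracellular medium
(shared by `N_cell` cells in a well of volume `V_exp`), cell membrane
(receptor copy numbers), and cytosol (volume `V_cell`). Nine species evolve
dynamically — sFRP1-bound Wnt, Dkk1-bound LRP, Wnt-bound Frizzled, the
Wnt/Frizzled/LRP ternary complex, ternary-bound destruction complex (per
APC species), free destruction complex (per APC species), and free
β-catenin — while seven more (complex-bound β-catenin, free LRP, Frizzled,
Wnt, sFRP1, Dkk1) are closed algebraically by conservation of receptor
numbers and soluble totals. The state vector deliberately keeps mixed
units, molar for soluble pools and copies/cell for membrane pools, so that
the partition coefficients `K_su-in = 1/(N_A·V_cell)` and
`K_su-ex = N_cell/(N_A·V_exp)` appear exactly where a membrane copy number
enters an intracellular or extracellular mass-action product; every term is
dimensionally auditable against the model equations.

Key biological assumptions:

- The destruction complex (Axin/APC/GSK3β) is at rapid equilibrium with its
  components; assembly is two-stage (APC+Axin with `K_D1`, dimer+GSK with
  `K_D2`). Heterozygous cells carry two APC species competing for shared
  Axin and GSK pools; each complex contains one APC of its own type, so
  each APC pool is conserved against its own-type dimer and complex only,
  while Axin and GSK conservation sums both types.
- Truncation affects only APC–Axin affinity (`K_D1` up) and the complex's
  β-catenin binding (`k6` down); GSK recruitment, ternary-complex binding
  (both Axin-mediated) and the lumped phosphorylation/degradation step
  `k_m6` are untouched. β-catenin leaving through `k_m6` is degraded, never
  returned to the free pool.
- TCF reporter activity is a pure power law of total detectable β-catenin
  relative to untreated wild type, exponent `a = 1.51`; the scale `λ`
  (2.2e4 measurement units/M) is carried only for emulating the raw
  calibration assay.
- Per-allele expression: a genotype's APC total is
  `Σ_i pt_fraction_i · P_T/2`, with `pt_fraction` the allele's full-length
  output relative to one wild-type allele. The catalog stores the
  near-null allele at 0.02, neoR at 0.2 and neoF at 0.1, which reproduces
  the aggregate expression levels these cell lines are described by
  (2%, 51%, 100% across the 1638N/1638T series; 20% and 10% for the
  homozygous neo lines).

Dissociation constants `K_D1`, `K_D2` are 50 nM and 10 nM. These magnitudes
are the only ones consistent with the printed protein totals (tens of nM)
and they reproduce the reference destruction-complex total of 8.05 nM,
which the equilibrium solver recovers to 0.03%.

## Numerics

**Equilibrium.** Given free Axin A and GSK G, every other species has a
closed form; the two conservation relations in (A, G) are solved by a
quasi-Newton iteration on (log A, log G) (positive by construction,
residuals scaled by the totals, tolerance 1e-12 relative), falling back to
nested bracketing bisection, which cannot fail because each residual is
strictly monotone in its own unknown. The homozygous case (`P_T' = 0`)
returns exactly zero primed outputs. An independent pure-Python dense
bisection serves as the test oracle on a 5×5×5 grid of totals (agreement
1e-9 relative).

**Steady states.** Integration with LSODA over 7 simulated days (rtol 1e-8,
atol 1e-16 M for soluble species, 1e-6 copies for membrane species) from
the resting state (no bound complexes, free destruction complex at its
equilibrium total, no β-catenin), followed by an algebraic polish of the
endpoint. The polish does not Newton-iterate the raw 9-dimensional system —
its fast binding equilibria make that iteration stall — but a steady-state
reduction: at a stationary point the free complexes follow
`C = C_T/(1 + K_su-in·k5·L_F/k_m5 + k6·B/k_m6)` (likewise C′), leaving a
well-conditioned 5-unknown root problem (bound Wnt, bound LRP, bound
Frizzled, ternary complex, β-catenin). Convergence is declared when every
species' relative rate `|dy/dt|·(1 h)/scale` is below 1e-6; an unconverged
horizon is reported as such, never silently accepted. Structurally zero
species (e.g. sFRP1-bound Wnt with no sFRP1 present) are pinned to exact
zero; negative excursions beyond 1e-4 of a species' scale abort the run,
smaller ones are clamped and logged. Warm starts (the polish attempted from
a neighbouring steady state, with fallback to full integration) accelerate
dose scans without changing results.

The slowest mode is plain β-catenin turnover, `1/k8 ≈ 2.8 days`, so severe
mutants — where the destruction complex no longer dominates degradation —
are still a few percent below their stationary level after 7 days. All
*predictions* (activity levels, dose responses, effective doses, scans) use
the polished, fully converged steady state. The *truncation-parameter
calibration* instead defaults to the unpolished 7-day protocol: its target
activity levels were matched under exactly that measurement procedure, and
the severe-mutant locus line is reproduced only when the calibration
re-enacts it (`refine=True` switches to true steady states; for the
moderate truncation the two protocols agree to <0.5%).

**Effective doses.** Bisection on log-dose to 1% relative precision, with
the wild-type untreated steady state under the identical context as the
unit reference. Finiteness is decided by the saturating asymptote: if the
activity at 100× the dose cap (defaults 100 µM sFRP1, 10 µM Dkk1) still
exceeds the target, the dose is infinite. Every reported dose re-simulates
to the target within 1%.

**Synergy.** The target isobole is traced by per-point bisection of the
Dkk1 dose at a ladder of fixed sFRP1 doses (never by contouring a coarse
surface); the combination index of a point is the sum of its fractional
single-agent doses and the maximally synergistic combination minimises it.
This definition is standard isobologram practice; the full isobole is
returned so alternative synergy scores can be applied post hoc.

**Severity scans.** Three scenarios: heterozygous truncation over a
near-null partner (loss of heterozygosity), homozygous truncation
(copy-neutral LOH), and pure expression reduction. Default grids are
coarse and log-spaced — 10×10 in (K_D1 fold ∈ [1, 20], k6 fraction ∈
[0.05, 1]) per truncation scenario, 12 expression fractions in [0.02, 1] —
chosen to straddle the restorability boundary while keeping a full scan in
the minutes range; the acceptance script uses 6×6 and 10 for the same
reason. The restoration threshold is the largest untreated activity with a
finite effective dose of at least one inhibitor; when a scan contains no
non-restorable record the value is flagged as a lower bound only.

## Synthetic data

Reporter assays produce strictly positive readouts with roughly
proportional error bars, so replicates are the noiseless model output times
`exp(N(0, cv))` (default cv 0.05). Panels carry their ground truth
(noiseless values, β-catenin ratios, generating parameters, seed) in a
sidecar, and regeneration under a seed is bit-identical. The β-catenin vs
Wnt titration emulates the small-well calibration assay (20 µl, 5×10³
cells, Wnt 0–10 nM) in measurement units via `λ`. What the generator does
*not* emulate: between-laboratory offsets, non-stationary assays (readouts
taken before steady state), receptor-expression heterogeneity, or crosstalk
from other β-catenin-regulating pathways — recovery tests passing on this
data show the estimators are consistent under the model's own assumptions,
not that the model captures every feature of live-cell panels.

## Design choices made where the design was open

- **Locus abscissa convention.** The linear locus of calibrated
  `(K_D1, k6)` pairs can be written against `K_D1/K_D1,WT` or its
  reciprocal. Both are fitted and reported with residuals; empirically the
  fold convention is linear (rms ~5e-4) and the reciprocal is not
  (rms ~3e-2), so it is returned as primary.
- **Locus k6 bounds.** Calibration bisects k6 within the biologically
  plausible [0.05, 1]; grid points whose whole range misses the target are
  reported infeasible rather than dropped, so the locus always documents
  where the parameterisation runs out.
- **b_detect in heterozygotes** sums both complex-bound β-catenin pools —
  the readout should not depend on an arbitrary allele labelling.
- **Dose caps as asymptote probes.** "Infinite dose" is a statement about
  the saturating limit, so it is decided at 100× the cap rather than at a
  fixed large dose.

## Known limitations

- Single-cell deterministic description: no stochasticity, no cell-to-cell
  variability, no spatial structure beyond the three-compartment partition.
- No downstream cell-fate modelling and no crosstalk (NF-κB, p53,
  non-canonical Wnt); TCF activity is the terminal readout.
- The truncation locus is one-dimensional by construction; experiments
  constraining `K_D1` and `k6` separately would collapse it and are outside
  the model.
- No pharmacokinetics: doses are total concentrations in a well, not tissue
  exposures.
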