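"""Synthetic data round trips: exponent refit and Wnt-level recovery.

Generates a noisy TCF reporter panel across genotypes, refits the power-law
exponent from (beta-catenin ratio, mean TCF) pairs, then recovers the
unmeasured culture Wnt level by grid search against beta-catenin ratios the
model itself produced at 5 nM.  Both calibrations close the loop on their
generating parameters.
"""

import dataclasses

import wntapc as w
from wntapc.readout import fit_power_exponent
from wntapc.synthetic import gen_tcf_panel

base = w.KineticParameters()
ctx = w.standard_context()

panel = gen_tcf_panel(
    ["1638N/1638T", "neoR/neoR", "neoF/neoF"], ctx, base, cv=0.05, n=50, seed=20170714
)
means = panel.data.groupby("genotype").value.mean()
pairs = [(panel.beta_ratios[g], means[g]) for g in means.index]
a_hat = fit_power_exponent(pairs)
print(f"power-law exponent refit from noisy panel: a = {a_hat:.3f} (generated with 1.51)")

fractions = [0.2, 0.1]
gen_ctx = dataclasses.replace(ctx, WT_total=5e-9)
ref = w.wt_reference(base, gen_ctx)
observed = []
for f in fractions:
    g = w.Genotype.homozygous(w.AlleleSpec(f"expr{f}", f, 1.0, 1.0))
    ss = w.steady_state(w.build_parameters(g, base), gen_ctx)
    observed.append(ss.b_detect / ref.b_detect)
cal = w.calibrate_wnt(fractions, observed, [1e-9, 2.5e-9, 5e-9, 7.5e-9, 1e-8], ctx=ctx, base=base)
print(f"recovered Wnt total: {cal.wnt_total * 1e9:.1f} nM (generated at 5.0 nM)")
print("\nobjective profile (nM, squared log-error):")
for _, row in cal.profile.iterrows():
    print(f"  {row.wnt_total * 1e9:5.1f}  {row.objective:.4f}")
print("\nThe profile flattens above ~5 nM: the dose response saturates, so")
print("only a lower bound on the true Wnt level is identifiable there.")
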