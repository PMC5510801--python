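"""Two-inhibitor synergy: isobole and maximally synergistic combination.

For the truncation heterozygote calibrated to 4.9-fold activity, traces the
curve of (sFRP1, Dkk1) dose pairs that jointly restore wild-type TCF
activity.  The combination index (sum of fractional single-agent doses) of
the best pair is well below 1: acting on ligand and co-receptor
simultaneously is super-additive.
"""

import wntapc as w

base = w.KineticParameters()
ctx = w.standard_context()
ref = w.wt_reference(base, ctx)

locus = w.calibrate_locus(4.9, ctx, base, partner=w.build_allele("1638N"), kd1_grid=[1.0])
genotype = w.Genotype(
    w.build_allele("1638N"), w.truncated_allele("1572T", 1.0, locus[0].k6_fraction)
)
bundle = w.build_parameters(genotype, base)

eds = (
    w.effective_dose(bundle, ctx, "sFRP1", reference=ref),
    w.effective_dose(bundle, ctx, "Dkk1", reference=ref),
)
print(f"single-agent effective doses: sFRP1 {eds[0].dose * 1e9:.0f} nM, "
      f"Dkk1 {eds[1].dose * 1e9:.2f} nM")

res = w.isobole_and_max_synergy(bundle, ctx, single_agent=eds, reference=ref)
print("\nisobole restoring wild-type activity (sFRP1 nM, Dkk1 nM, CI):")
for (s, d), ci in zip(res.isobole, res.dose_fraction_sums):
    print(f"  {s * 1e9:7.1f}  {d * 1e9:6.2f}   {ci:.2f}")
s, d = res.max_synergy_point
print(f"\nmaximally synergistic combination: ({s * 1e9:.0f} nM, {d * 1e9:.2f} nM)")
print(f"  = {s / eds[0].dose:.0%} and {d / eds[1].dose:.0%} of the single-agent doses")
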