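"""Estimate and predict design effects for a small teratology study.

Builds a three-litter dose group by hand, estimates its Rao-Scott design
effect, and compares with the historical prediction for mice at the same
proportion affected.
"""

import litterbmd as lb

# three mouse litters at one dose: 5 fetuses each, 1/0/4 affected
litters = tuple(
    lb.LitterRecord("demo", "mouse", 0.0, f"L{i}", 5, a)
    for i, a in enumerate([1, 0, 4])
)
group = lb.DoseGroup(dose=0.0, litters=litters)
summary = lb.summarize_group(group)

d_hat = lb.rao_scott_design_effect(group)
d_hist = lb.predict_design_effect("mouse", summary.p_fetal)

print(f"group: N_F={summary.n_fetuses}, A_F={summary.n_affected:.0f}, "
      f"P_F={summary.p_fetal:.3f}")
print(f"estimated design effect D_g       = {d_hat.value:.3f}")
print(f"historical mouse prediction D_h   = {d_hist.value:.3f}")

t = lb.rao_scott_transform(summary, d_hat)
print(f"effective counts after division:  {t.eff_a:.3f} of {t.eff_n:.3f}")
print("-> D_g ~ 3.9 says fetuses in these litters carry about 1/3.9 of an "
      "independent observation's information; the effective counts feed any "
      "binomial dose-response model.")
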