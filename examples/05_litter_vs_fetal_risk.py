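"""Relate litter-level risk to fetal-level risk.

When only the proportion of affected litters (P_L) is reported, inference
about fetal risk needs a mapping between the two scales. Under independence
P_L = 1 - (1 - P_F)^n; empirically the historical relation is log-linear.
"""

import litterbmd as lb

relations = lb.shipped_pl_pf_relations()

print("P_F     independence(n=11)  orthogonal fit  OLS fit")
for pf in (0.01, 0.02, 0.05):
    ind = lb.litter_risk(pf, lb.PlPfRelation("independence", (11,)))
    orth = lb.litter_risk(pf, relations["orthogonal"])
    ols = lb.litter_risk(pf, relations["ols"])
    print(f"{pf:.2f}    {ind:18.3f}  {orth:14.3f}  {ols:7.3f}")

print("\n-> at the screening-relevant P_F <= 0.05, litter risk runs about "
      "4-10x fetal risk, so a 5% fetal benchmark corresponds to a much "
      "larger litter-level benchmark response (hence 30-40% extra risk is "
      "used when modeling affected-litter counts).")
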