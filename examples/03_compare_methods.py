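"""Benchmark summary-data BMD methods against the nested baseline.

Runs the full 15-method comparison on one simulated study: each method uses
only dose-group summaries (counts, litter means, or affected-litter counts),
and its BMD/BMDL is expressed as a log10 ratio to the litter-level nested
log-logistic fit. Ratios near 0 mean the summary route loses little.
"""

import litterbmd as lb

study = lb.simulate_study(lb.species_config("mouse", seed=7))
table = lb.compare_methods(study)
print(table[["method", "label", "bmd", "bmdl",
             "log10_bmdl_ratio", "gof_p"]].round(3).to_string(index=False))

print("\n-> methods 1-3 and 5 (design-effect-adjusted counts) usually sit "
      "within ~0.1 log10 units (a factor 1.3) of the nested baseline; "
      "method 7 (litter count as effective N) is biased low; method 15 "
      "(affected litters at the fetal BMR) is far too low because litter "
      "risk greatly exceeds fetal risk.")
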