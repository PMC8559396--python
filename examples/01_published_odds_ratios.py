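"""Worked example: crude odds ratios from the published weighted cross-table.

Builds the 2x2 expansion-weighted tables shipped with the package (healthy
vs less-healthy counts per socio-demographic level) and recomputes the
bivariate odds-ratio column by the cross-product formula with Woolf
confidence intervals. An OR below 1 means lower odds of being in the
healthy-ageing group at that level than at the reference.
"""

from hale import published_bivariate_ors

print(f"{'variable':<18}{'level':<14}{'vs':<10}{'OR':>7}  95% CI")
for r in published_bivariate_ors():
    print(f"{r.variable:<18}{r.level:<14}{r.reference:<10}{r.odds_ratio:>7.2f}"
          f"  ({r.ci_low:.3f}, {r.ci_high:.3f})")
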