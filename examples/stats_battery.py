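"""The statistical battery on a synthetic fly-level metric table.

Paired/unpaired t tests, one-way ANOVA with Holm-corrected pairwise tests,
unbalanced two-way ANOVA with Tukey-Kramer HSD, and the Monte-Carlo
Lilliefors normality check.
"""

import numpy as np
import pandas as pd

import flyca as fc

rng = np.random.default_rng(0)

# paired pre/post drug comparison (per-fly step responses)
pre = rng.normal(1.0, 0.15, 8)
post = pre * 0.35 + rng.normal(0, 0.05, 8)
res = fc.t_test(pre, post, paired=True)
print(f"paired t: t = {res.statistic:.2f}, df = {res.df:.0f}, "
      f"p = {res.p:.2e} {res.stars}")

# dose series: one-way ANOVA + Holm pairwise
groups = [rng.normal(mu, 0.15, 6) for mu in (1.0, 0.9, 0.4)]
omnibus, pairwise = fc.one_way_anova_holm(groups, labels=["sham", "low", "high"])
print(f"one-way ANOVA: F{omnibus.df} = {omnibus.statistic:.2f}, "
      f"p = {omnibus.p:.2e}")
for r in pairwise:
    print(f"  {r.groups[0]:>4s} vs {r.groups[1]:<4s} "
          f"p_holm = {r.p_adjusted:.3g} {r.stars}")

# genotype x drug: unbalanced two-way ANOVA + Tukey
rows = []
for geno, drug, mu, n in (("ctrl", "pre", 1.0, 7), ("ctrl", "post", 0.3, 7),
                          ("resc", "pre", 1.0, 5), ("resc", "post", 0.85, 5)):
    for v in rng.normal(mu, 0.12, n):
        rows.append({"A": geno, "B": drug, "value": v})
effects, tukey = fc.two_way_anova_tukey(pd.DataFrame(rows))
for e in effects:
    print(f"{e.test}: F = {e.statistic:.1f}, p = {e.p:.2g}")
sig = tukey[tukey.p_tukey < 0.05]
print(f"Tukey-Kramer: {len(sig)}/{len(tukey)} cell pairs significant")

# normality of the per-fly values
lf = fc.lilliefors(pre, n_mc=10_000, seed=0)
print(f"Lilliefors: D = {lf.statistic:.3f}, p = {lf.p:.2f} "
      "(p > 0.05: no evidence against normality)")
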