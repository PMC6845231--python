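"""Relative transcript quantification with the percent ΔΔCt method.

Builds a Ct table for a disrupted (D) vs non-disrupting (ND) genotype pair
(three biological x three technical replicates), averages technical
readings, applies the ΔΔCt formula against the housekeeping reference, and
normalizes to the control mean.
"""

import numpy as np
import pandas as pd

from flyca import qpcr

rng = np.random.default_rng(0)
rows = []
for cond, d_ct in (("ND", 0.0), ("D", 2.6)):   # ~2.6 extra cycles = ~16%
    for rep in range(1, 4):
        for gene, base in (("target", 20.0), ("reference", 18.0)):
            mu = base + (d_ct if (cond == "D" and gene == "target") else 0.0)
            for tech in range(3):
                rows.append({"condition": cond, "gene": gene, "bio_rep": rep,
                             "tech_rep": tech,
                             "ct": mu + rng.normal(0, 0.08)})
table = pd.DataFrame(rows)

means = qpcr.mean_ct(table)
res = qpcr.ddct_percent(means, efficiencies=None)  # printed formula, base 2
print("per-replicate % transcript (D vs ND):",
      np.round(res.per_replicate.to_numpy(), 1))
print(f"mean ± SEM: {res.mean:.1f} ± {res.sem:.1f} %")
normalized = qpcr.normalize_to_control(
    np.r_[[100.0] * 3, res.per_replicate.to_numpy()],
    np.r_[["ND"] * 3, ["D"] * 3], control="ND")
print("normalized to control mean:", np.round(normalized, 3))
# ~16% means the disrupted allele retains about a sixth of the control
# transcript level relative to the housekeeping gene.
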