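"""Relative transcript quantification by the percent ΔΔCt method.

Ct tables are tidy frames with one row per technical reading
(columns: sample, condition, gene, bio_rep, tech_rep, ct).  Technical
replicates are averaged per biological replicate; the percent transcript
difference between the disrupted (D) and non-disrupting (ND) conditions is

    % transcript = 100 · 2^([Ct_ND,target − Ct_ND,ref] − [Ct_D,target − Ct_D,ref])

computed per biological replicate against the mean ND ΔCt and summarized
as mean ± SEM.  An efficiency-corrected (Pfaffl-style) mode uses measured
per-gene primer efficiencies instead of base 2; with E = 2 it reproduces
the default exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DEFAULT_EFFICIENCIES",
    "load_ct_table",
    "mean_ct",
    "ddct_percent",
    "DdctResult",
    "normalize_to_control",
    "standard_curve_efficiency",
]

REQUIRED_COLUMNS = ("condition", "gene", "bio_rep", "tech_rep", "ct")

#: Measured primer efficiencies for the default target/reference pair
#: (GluClα target against the GAPDH2 housekeeping reference).
DEFAULT_EFFICIENCIES = {"target": 1.91, "reference": 1.96}


def load_ct_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    return table


def mean_ct(table: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct over technical replicates per (condition, gene, bio_rep)."""
    if table.empty:
        raise ValueError("empty Ct table")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    grouped = table.groupby(["condition", "gene", "bio_rep"])["ct"]
    counts = grouped.count()
    if (counts < 2).any():
        warnings.warn("some Ct means rest on a single technical replicate",
                      stacklevel=2)
    return grouped.mean().reset_index()


@dataclass
class DdctResult:
    per_replicate: pd.Series   # D bio_rep -> percent transcript
    mean: float
    sem: float | None


def ddct_percent(
    ct_means: pd.DataFrame,
    condition_d: str = "D",
    condition_nd: str = "ND",
    target: str = "target",
    reference: str = "reference",
    efficiencies: dict | None = None,
) -> DdctResult:
    """Percent transcript difference D vs ND by the ΔΔCt formula.

    ``ct_means`` is the output of :func:`mean_ct`.  Each disrupted
    biological replicate is compared against the mean ND ΔCt.  Pass
    ``efficiencies={'target': E_t, 'reference': E_r}`` (for example
    :data:`DEFAULT_EFFICIENCIES`) for the efficiency-corrected mode; the
    default uses base 2 for both genes.
    """
    e_t = e_r = 2.0
    if efficiencies is not None:
        e_t, e_r = float(efficiencies["target"]), float(efficiencies["reference"])
    pivot = ct_means.pivot_table(index=["condition", "bio_rep"],
                                 columns="gene", values="ct")
    for gene in (target, reference):
        if gene not in pivot.columns or pivot[gene].isna().any():
            raise ValueError(f"missing mean Ct values for gene {gene!r}")
    for cond in (condition_d, condition_nd):
        if cond not in pivot.index.get_level_values("condition"):
            raise ValueError(f"condition {cond!r} absent from the Ct table")
    nd = pivot.loc[condition_nd]
    d = pivot.loc[condition_d]
    nd_t, nd_r = nd[target].mean(), nd[reference].mean()
    # per disrupted replicate: E_t^(Ct_ND,t - Ct_D,t) / E_r^(Ct_ND,r - Ct_D,r)
    per_rep = 100.0 * (e_t ** (nd_t - d[target])) / (e_r ** (nd_r - d[reference]))
    per_rep.name = "percent_transcript"
    n = len(per_rep)
    sem = None if n < 2 else float(per_rep.std(ddof=1) / np.sqrt(n))
    return DdctResult(per_replicate=per_rep, mean=float(per_rep.mean()), sem=sem)


def normalize_to_control(values, conditions, control: str) -> np.ndarray:
    """Divide every value by the mean of the control condition's values.

    The control group then averages to 1.0 (reported as 100%).
    """
    values = np.asarray(values, dtype=float)
    conditions = np.asarray(conditions)
    ctrl = values[conditions == control]
    if len(ctrl) == 0:
        raise ValueError(f"no values for control condition {control!r}")
    ctrl_mean = float(ctrl.mean())
    if ctrl_mean <= 0:
        raise ValueError("control mean must be > 0")
    return values / ctrl_mean


def standard_curve_efficiency(log10_template, ct) -> float:
    """Primer efficiency from a dilution series: E = 10^(-1/slope) of the
    Ct vs log10(template) regression (E = 2 for ideal doubling)."""
    slope = sps.linregress(np.asarray(log10_template, dtype=float),
                           np.asarray(ct, dtype=float)).slope
    if slope >= 0:
        raise ValueError("Ct must decrease with template amount")
    return float(10.0 ** (-1.0 / slope))
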