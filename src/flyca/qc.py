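"""ROI inclusion rules and paired-ROI tracking across drug conditions.

Three rules, combined by intersection: (i) positive Pearson correlation of
the trial-averaged flash response with a ±1 stimulus square wave, (ii) a
standard-deviation ceiling on the 2 s pre-stimulus window (discards noisy
ROIs), and (iii) an absolute peak-|dF/F| floor (keeps well-responding ROIs).
Named presets ship the rule combinations used for the different experiment
types; for paired pharmacology the pre-drug filters decide inclusion and the
identical ROI ids are carried to the post-drug condition unfiltered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .protocols import StimulusProtocol
from .traces import DffTraceSet, trial_average

__all__ = [
    "FilterPolicy",
    "FilterReport",
    "POLICIES",
    "load_policy",
    "stimulus_regressor",
    "apply_policy",
    "pair_rois",
]


@dataclass(frozen=True)
class FilterPolicy:
    use_correlation_filter: bool = True
    prestim_sd_threshold: float | None = 0.2
    abs_response_threshold: float | None = 0.5
    paired: bool = False

    def __post_init__(self) -> None:
        for t in (self.prestim_sd_threshold, self.abs_response_threshold):
            if t is not None and t < 0:
                raise ValueError("thresholds must be >= 0")


#: Experiment-type presets.
POLICIES: dict[str, FilterPolicy] = {
    # paired pharmacology in Mi1/Tm3: all three rules, paired ROIs
    "mi1_pharma": FilterPolicy(True, 0.2, 0.5, paired=True),
    # unpaired genotype comparisons: no absolute response floor
    "unpaired": FilterPolicy(True, 0.2, None, paired=False),
    # T4/T5: both response polarities expected, so no correlation filter
    "t4t5": FilterPolicy(False, 0.2, 0.5, paired=True),
    # extracellular glutamate sensor: response floor only
    "iglusnfr": FilterPolicy(False, None, 0.5, paired=False),
}


def load_policy(path) -> FilterPolicy:
    """Read a filter policy from YAML: either ``policy: <preset name>`` or
    explicit rule fields."""
    import yaml
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "policy" in cfg:
        return POLICIES[cfg["policy"]]
    return FilterPolicy(**cfg)


@dataclass
class FilterReport:
    table: pd.DataFrame           # per-ROI pass/fail per rule
    policy: FilterPolicy
    n_before: int
    n_after: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def stimulus_regressor(protocol: StimulusProtocol, rate_hz: float = 10.0) -> np.ndarray:
    """Contrast square wave on the 10 Hz grid: +1 during flash_on, -1 during
    flash_off, over the whole flash protocol."""
    kinds = {e.kind for e in protocol.epochs}
    if not protocol.epochs:
        raise ValueError("empty protocol")
    if not kinds <= {"flash_on", "flash_off"}:
        raise ValueError("stimulus regressor is defined for flash protocols only")
    parts = []
    for e in protocol.epochs:
        n = int(round(e.duration_s * rate_hz))
        parts.append(np.full(n, 1.0 if e.kind == "flash_on" else -1.0))
    return np.concatenate(parts)


def _cycle_trace(avgs, roi_id) -> tuple[np.ndarray, np.ndarray] | None:
    """Concatenate the ROI's trial-averaged ON and OFF epochs with the
    matching ±1 regressor."""
    on = avgs.get((roi_id, "flash_on"))
    off = avgs.get((roi_id, "flash_off"))
    if on is None or off is None:
        return None
    trace = np.concatenate([on.epoch_values, off.epoch_values])
    reg = np.concatenate([np.ones(len(on.epoch_values)),
                          -np.ones(len(off.epoch_values))])
    return trace, reg


def apply_policy(
    dff: DffTraceSet,
    policy: FilterPolicy,
    protocol: StimulusProtocol,
) -> tuple[DffTraceSet, FilterReport]:
    """Apply the policy's rules to trial-averaged responses; keep survivors.

    Survivor set is the intersection of the per-rule passes, so the rules
    commute and raising any threshold can only shrink it.
    """
    kinds = {e.kind for e in protocol.epochs}
    if policy.use_correlation_filter and "edge" in kinds:
        raise ValueError("correlation filter is undefined for edge protocols")
    avgs = trial_average(dff)
    rows = []
    survivors = []
    n_win = int(round(2.0 * dff.rate_hz))
    for rid in dff.roi_ids:
        ok_corr = ok_sd = ok_abs = True
        r_val = np.nan
        if policy.use_correlation_filter:
            cyc = _cycle_trace(avgs, rid)
            if cyc is None:
                ok_corr = False
            else:
                trace, reg = cyc
                if np.std(trace) == 0:
                    warnings.warn(
                        f"ROI {rid}: zero-variance trace fails the "
                        "correlation rule", stacklevel=2)
                    ok_corr = False
                else:
                    r_val = float(np.corrcoef(trace, reg)[0, 1])
                    ok_corr = r_val > 0
        roi_avgs = [a for k, a in avgs.items() if k[0] == rid]
        if policy.prestim_sd_threshold is not None:
            pres = [a.values[max(0, a.n_pre - n_win):a.n_pre]
                    for a in roi_avgs if a.kind == "flash_on"] or \
                   [a.values[max(0, a.n_pre - n_win):a.n_pre] for a in roi_avgs]
            pre = np.concatenate(pres) if pres else np.array([])
            if len(pre) < 2:
                raise ValueError(
                    "pre-stimulus sd filter needs pre-onset context")
            ok_sd = float(np.std(pre)) <= policy.prestim_sd_threshold
        if policy.abs_response_threshold is not None:
            peak = max((float(np.max(np.abs(a.epoch_values)))
                        for a in roi_avgs), default=0.0)
            ok_abs = peak >= policy.abs_response_threshold
        rows.append({"roi": rid, "pearson_r": r_val, "pass_correlation": ok_corr,
                     "pass_prestim_sd": ok_sd, "pass_abs_response": ok_abs,
                     "pass": ok_corr and ok_sd and ok_abs})
        if ok_corr and ok_sd and ok_abs:
            survivors.append(rid)
    table = pd.DataFrame(rows)
    filtered = _subset(dff, survivors)
    report = FilterReport(table=table, policy=policy,
                          n_before=len(dff.roi_ids), n_after=len(survivors))
    return filtered, report


def _subset(dff: DffTraceSet, roi_ids: list[int]) -> DffTraceSet:
    keep = set(roi_ids)
    return DffTraceSet(
        segments=[s for s in dff.segments if s.roi_id in keep],
        rate_hz=dff.rate_hz, roi_ids=[r for r in dff.roi_ids if r in keep],
        f0_mode=dff.f0_mode,
        f0=None if dff.f0 is None else {r: dff.f0[r] for r in roi_ids},
        fly_id=dff.fly_id, condition=dff.condition)


def pair_rois(pre: DffTraceSet, post: DffTraceSet) -> tuple[DffTraceSet, DffTraceSet]:
    """Keep only ROI ids present in both conditions (paired design).

    Inclusion filters are applied to the pre-drug condition beforehand; the
    surviving ids are carried to the post-drug set unfiltered, matching the
    paired-analysis convention of imaging identical ROIs before and after
    toxin application.
    """
    common = [r for r in pre.roi_ids if r in set(post.roi_ids)]
    if not common:
        raise ValueError("no common ROI ids between the paired conditions")
    return _subset(pre, common), _subset(post, common)
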