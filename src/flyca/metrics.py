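"""Response metrics, direction tuning, fly-level summaries, normalizations.

Window metrics operate on trial-averaged dF/F segments on the 10 Hz
stimulus-locked grid:

- step: peak during the epoch minus the mean of the 500 ms before onset;
- plateau: mean of the last 500 ms of the epoch minus the same pre mean;
- integral: plain sum of the epoch's samples (50 for a 5 s epoch at 10 Hz);
- edge amplitude: as step, on gray-referenced edge segments.

Direction selectivity uses the 8-direction edge amplitudes:
DSI = (PD - ND) / PD with PD the maximal response and ND the response 180°
away.  Population summaries follow the fly-level convention: ROIs are
averaged within each fly first, and mean ± SEM are taken across flies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traces import TrialAverage

__all__ = [
    "step_response",
    "plateau_response",
    "integrated_response",
    "edge_amplitude",
    "align_and_average",
    "DirectionTuning",
    "direction_tuning",
    "FlySummary",
    "fly_summary",
    "normalize_to_condition",
    "CurrentRecording",
    "normalized_peak_current",
    "response_table",
]

_WIN_S = 0.5  # metric window: 500 ms


def _windows(trace: TrialAverage) -> tuple[np.ndarray, np.ndarray, int]:
    n_win = int(round(_WIN_S * trace.rate_hz))
    if trace.n_pre < n_win:
        raise ValueError(
            f"need {n_win} pre-onset samples for the 500 ms baseline window")
    pre = trace.values[trace.n_pre - n_win:trace.n_pre]
    epoch = trace.epoch_values
    return pre, epoch, n_win


def step_response(trace: TrialAverage) -> float:
    """Peak dF/F during the epoch minus the 500 ms pre-onset mean.

    Negative values are allowed: they signal response suppression.
    """
    pre, epoch, _ = _windows(trace)
    return float(epoch.max() - pre.mean())


def plateau_response(trace: TrialAverage) -> float:
    """Mean of the last 500 ms of the epoch minus the 500 ms pre-onset mean."""
    pre, epoch, n_win = _windows(trace)
    return float(epoch[-n_win:].mean() - pre.mean())


def integrated_response(trace: TrialAverage, nominal_s: float = 5.0,
                        per_second: bool = False) -> float:
    """Plain sum of the epoch's dF/F samples (no baseline subtraction).

    Reported in dF/F·samples on the 10 Hz grid by default (50 samples for a
    5 s epoch); ``per_second=True`` scales by the sample spacing instead.
    """
    n_nominal = int(round(nominal_s * trace.rate_hz))
    epoch = trace.epoch_values
    if len(epoch) < n_nominal:
        raise ValueError(
            f"epoch has {len(epoch)} samples; expected {n_nominal}")
    total = float(epoch[:n_nominal].sum())
    return total / trace.rate_hz if per_second else total


def edge_amplitude(trace: TrialAverage) -> float:
    """Maximum during the edge epoch minus the 500 ms pre-onset mean."""
    return step_response(trace)


def align_and_average(traces: list[np.ndarray]) -> np.ndarray:
    """Population mean after circularly shifting each trace so its peak lands
    at the median peak index."""
    if not traces:
        raise ValueError("need at least one trace")
    arrs = [np.asarray(t, dtype=float) for t in traces]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("traces must share a length")
    peaks = np.array([int(np.argmax(a)) for a in arrs])
    target = int(np.median(peaks))
    shifted = [np.roll(a, target - p) for a, p in zip(arrs, peaks)]
    return np.mean(shifted, axis=0)


@dataclass
class DirectionTuning:
    """Edge amplitudes over the 8 motion directions with PD/ND/DSI."""

    directions_deg: np.ndarray   # (8,) ascending, 45° spacing
    responses: np.ndarray        # (8,)
    pd_deg: float
    pd_response: float
    nd_response: float
    dsi: float | None            # None when PD response <= 0 (undefined)


def direction_tuning(responses, directions_deg=None) -> DirectionTuning:
    """DSI = (PD - ND) / PD over 8 directions at 45° spacing.

    PD is the direction of the maximal response (ties broken toward the
    smallest angle); ND is the response 180° away.  A non-positive PD
    response leaves the DSI undefined (flagged as None).
    """
    if isinstance(responses, dict):
        directions_deg = np.array(sorted(responses), dtype=float)
        responses = np.array([responses[d] for d in directions_deg], dtype=float)
    else:
        responses = np.asarray(responses, dtype=float)
        if directions_deg is None:
            directions_deg = np.arange(0.0, 360.0, 45.0)
        directions_deg = np.asarray(directions_deg, dtype=float)
    if len(responses) != 8 or len(directions_deg) != 8:
        raise ValueError("need exactly 8 directions")
    order = np.argsort(directions_deg)
    directions_deg, responses = directions_deg[order], responses[order]
    if not np.allclose(np.diff(directions_deg), 45.0):
        raise ValueError("directions must be 45° apart")
    i_pd = int(np.argmax(responses))           # argmax keeps the first max
    pd_deg = float(directions_deg[i_pd])
    pd_resp = float(responses[i_pd])
    nd_resp = float(responses[(i_pd + 4) % 8])
    if pd_resp <= 0:
        warnings.warn("non-positive PD response: DSI undefined", stacklevel=2)
        dsi = None
    else:
        dsi = (pd_resp - nd_resp) / pd_resp
    return DirectionTuning(directions_deg=directions_deg, responses=responses,
                           pd_deg=pd_deg, pd_response=pd_resp,
                           nd_response=nd_resp, dsi=dsi)


@dataclass
class FlySummary:
    per_fly: pd.Series     # fly id -> mean over that fly's ROIs
    mean: float
    sem: float | None      # None when n_flies == 1
    n_flies: int
    n_cells: int

    def label(self) -> str:
        """Sample size in the 'n = flies (cells)' convention."""
        return f"n = {self.n_flies} ({self.n_cells})"


def fly_summary(table: pd.DataFrame, metric: str,
                fly_col: str = "fly") -> FlySummary:
    """Mean ± SEM across flies after averaging ROIs within each fly.

    Equal-fly weighting: duplicating ROIs within a fly does not change the
    group mean.  SEM = sd(per-fly means, ddof=1) / sqrt(n_flies); undefined
    for a single fly.
    """
    if table.empty:
        raise ValueError("empty table")
    per_fly = table.groupby(fly_col)[metric].mean()
    n_flies = len(per_fly)
    sem = None if n_flies < 2 else float(per_fly.std(ddof=1) / np.sqrt(n_flies))
    return FlySummary(per_fly=per_fly, mean=float(per_fly.mean()), sem=sem,
                      n_flies=n_flies, n_cells=len(table))


def normalize_to_condition(post_values, pre_values) -> np.ndarray:
    """Divide post-drug per-fly metrics by the pre-drug group mean."""
    pre_mean = float(np.mean(pre_values))
    if pre_mean <= 0:
        raise ValueError("pre-condition mean must be > 0 for normalization")
    return np.asarray(post_values, dtype=float) / pre_mean


@dataclass
class CurrentRecording:
    """Voltage-clamp membrane current with agonist-application annotations.

    ``epochs`` is a list of ``(kind, t_start, t_end)`` where kind is
    ``glutamate`` (agonist alone), ``glutamate_antagonist`` (agonist in the
    presence of the antagonist) or ``washout`` (agonist after antagonist
    wash-out — the normalization reference).
    """

    times: np.ndarray
    current: np.ndarray
    epochs: list[tuple[str, float, float]]

    def _peaks(self, kind: str) -> list[float]:
        out = []
        for k, t0, t1 in self.epochs:
            if k != kind:
                continue
            sel = (self.times >= t0) & (self.times <= t1)
            if sel.any():
                out.append(float(np.max(np.abs(self.current[sel]))))
        return out


def normalized_peak_current(rec: CurrentRecording) -> float:
    """|peak current with agonist + antagonist| relative to the mean |peak|
    of the agonist responses after antagonist wash-out."""
    test = rec._peaks("glutamate_antagonist")
    ref = rec._peaks("washout")
    if not ref:
        raise ValueError("recording lacks a wash-out reference epoch")
    if not test:
        raise ValueError("recording lacks a glutamate+antagonist epoch")
    return float(np.mean(test) / np.mean(ref))


def response_table(
    avgs: dict[tuple, TrialAverage],
    fly_id: str = "fly0",
    condition: str = "ctrl",
    integral_nominal_s: float = 5.0,
) -> pd.DataFrame:
    """Tidy per-ROI metric table from trial-averaged segments.

    Flash rows carry step/plateau/integral; edge rows carry the edge
    amplitude per contrast x direction.
    """
    rows = []
    for key, ta in avgs.items():
        roi = key[0]
        base = {"roi": roi, "fly": fly_id, "condition": condition,
                "kind": ta.kind, "contrast": ta.contrast,
                "direction": ta.direction_deg, "n_trials": ta.n_trials}
        if ta.kind == "edge":
            base["edge_amplitude"] = edge_amplitude(ta)
        else:
            base["step"] = step_response(ta)
            base["plateau"] = plateau_response(ta)
            base["integral"] = integrated_response(ta, integral_nominal_s)
        rows.append(base)
    return pd.DataFrame(rows)
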