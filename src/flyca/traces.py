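"""ROI trace extraction, stimulus-locked resampling, dF/F, trial averaging.

The processing chain mirrors the standard fly two-photon workflow: per-frame
ROI means are background subtracted, linearly interpolated onto a uniform
10 Hz grid whose phase is locked to each stimulus-epoch onset, converted to
dF/F under one of two F0 conventions (whole-trace mean for full-field
flashes; mean of the last second of the preceding gray epoch for moving
edges), and trial averaged per epoch kind (flashes) or per direction x
contrast (edges).

Locking the grid phase to the epoch onset makes the windowed metrics
sample-count stable: "500 ms before onset" and "the last 500 ms" each
contain exactly 5 samples at 10 Hz.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .protocols import StimulusProtocol

__all__ = [
    "ROISet",
    "TraceSet",
    "Segment",
    "SegmentSet",
    "DffTraceSet",
    "TrialAverage",
    "extract_traces",
    "resample_and_segment",
    "compute_dff",
    "trial_average",
]


@dataclass
class ROISet:
    """Integer label mask: values >= 1 are ROIs, 0 is outside.

    The background region used for subtraction defaults to everything
    outside the ROIs; pass an explicit boolean ``background_mask`` to use a
    dedicated region instead.
    """

    labels: np.ndarray
    roi_ids: list[int] | None = None
    background_mask: np.ndarray | None = None
    fly_id: str = "fly0"
    condition: str = "ctrl"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.roi_ids is None:
            self.roi_ids = sorted(int(v) for v in np.unique(self.labels) if v > 0)
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise ValueError("roi ids must be unique")
        for rid in self.roi_ids:
            if not (self.labels == rid).any():
                raise ValueError(f"ROI {rid} absent from the label mask")
        if self.background_mask is None:
            self.background_mask = self.labels == 0
        else:
            self.background_mask = np.asarray(self.background_mask, dtype=bool)
            if (self.background_mask & (self.labels > 0)).any():
                raise ValueError("background region overlaps ROIs")

    def save_tiff(self, path) -> None:
        tifffile.imwrite(Path(path), self.labels.astype(np.int32))

    @classmethod
    def from_tiff(cls, path, **kwargs) -> "ROISet":
        return cls(labels=tifffile.imread(Path(path)), **kwargs)


@dataclass
class TraceSet:
    """Background-subtracted per-ROI fluorescence at native frame times."""

    times: np.ndarray            # (T,)
    values: np.ndarray           # (n_roi, T)
    roi_ids: list[int]
    background: np.ndarray       # (T,) background-region trace
    fly_id: str = "fly0"
    condition: str = "ctrl"
    protocol: StimulusProtocol | None = None

    def trace(self, roi_id: int) -> np.ndarray:
        return self.values[self.roi_ids.index(roi_id)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, rid in enumerate(self.roi_ids):
            rows.append(pd.DataFrame({
                "roi": rid, "fly": self.fly_id, "condition": self.condition,
                "t": self.times, "value": self.values[i],
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class Segment:
    """One ROI's resampled trace around one epoch instance.

    ``values`` holds ``n_pre`` pre-onset context samples followed by the
    epoch's samples; ``t[n_pre] == 0`` is the epoch onset.
    """

    roi_id: int
    epoch_index: int
    kind: str
    contrast: float
    direction_deg: float | None
    values: np.ndarray
    n_pre: int
    rate_hz: float
    duration_s: float
    f0_gray: float | None = None   # mean of the preceding gray tail (edges)

    @property
    def t(self) -> np.ndarray:
        return (np.arange(len(self.values)) - self.n_pre) / self.rate_hz

    @property
    def epoch_values(self) -> np.ndarray:
        return self.values[self.n_pre:]

    def group_key(self):
        if self.kind == "edge":
            return ("edge", self.contrast, self.direction_deg)
        return (self.kind,)


@dataclass
class SegmentSet:
    segments: list[Segment]
    rate_hz: float
    roi_ids: list[int]
    whole_trace_mean: dict[int, float]
    fly_id: str = "fly0"
    condition: str = "ctrl"


@dataclass
class DffTraceSet:
    """Per-ROI, per-epoch dF/F segments on the stimulus-locked 10 Hz grid."""

    segments: list[Segment]
    rate_hz: float
    roi_ids: list[int]
    f0_mode: str
    f0: dict[int, float] | None = None   # per-ROI F0 (whole-trace mode)
    fly_id: str = "fly0"
    condition: str = "ctrl"

    def for_roi(self, roi_id: int) -> list[Segment]:
        return [s for s in self.segments if s.roi_id == roi_id]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.segments:
            rows.append(pd.DataFrame({
                "roi": s.roi_id, "fly": self.fly_id, "condition": self.condition,
                "epoch": s.epoch_index, "kind": s.kind,
                "direction": s.direction_deg if s.direction_deg is not None else np.nan,
                "t": s.t, "value": s.values,
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class TrialAverage:
    """Pointwise trial mean for one ROI and one epoch kind (or direction)."""

    roi_id: int
    kind: str
    contrast: float
    direction_deg: float | None
    values: np.ndarray
    n_pre: int
    rate_hz: float
    duration_s: float
    n_trials: int

    @property
    def t(self) -> np.ndarray:
        return (np.arange(len(self.values)) - self.n_pre) / self.rate_hz

    @property
    def epoch_values(self) -> np.ndarray:
        return self.values[self.n_pre:]


# ---------------------------------------------------------------------------

def extract_traces(movie, rois: ROISet) -> TraceSet:
    """Per-frame ROI means minus the background-region mean."""
    data = movie.data
    if data.shape[1:] != rois.labels.shape:
        raise ValueError("label mask shape does not match movie frames")
    flat = data.reshape(data.shape[0], -1)
    bg_idx = rois.background_mask.ravel()
    if bg_idx.any():
        background = flat[:, bg_idx].mean(axis=1)
    else:
        warnings.warn("empty background region: no subtraction applied",
                      stacklevel=2)
        background = np.zeros(data.shape[0])
    values = np.empty((len(rois.roi_ids), data.shape[0]))
    for i, rid in enumerate(rois.roi_ids):
        idx = (rois.labels == rid).ravel()
        values[i] = flat[:, idx].mean(axis=1) - background
    return TraceSet(times=movie.timestamps.copy(), values=values,
                    roi_ids=list(rois.roi_ids), background=background,
                    fly_id=rois.fly_id, condition=rois.condition)


def resample_and_segment(
    traces: TraceSet,
    protocol: StimulusProtocol,
    rate_hz: float = 10.0,
    pre_s: float = 2.0,
) -> SegmentSet:
    """Linear interpolation onto an onset-locked grid, one segment per epoch.

    Each segment's grid has spacing ``1/rate_hz`` with t = 0 exactly at the
    epoch onset and up to ``pre_s`` seconds of pre-onset context (clipped to
    the recorded range).  Epochs extending beyond the recording are dropped
    with a warning.  For edge epochs the mean of the last second of the
    preceding gray epoch is recorded as the segment's F0 candidate.
    """
    dt = 1.0 / rate_hz
    t0, t1 = traces.times[0], traces.times[-1]
    onsets = protocol.onsets()
    segments: list[Segment] = []
    for i, rid in enumerate(traces.roi_ids):
        y = traces.values[i]
        for ei, (epoch, onset) in enumerate(zip(protocol.epochs, onsets)):
            n_epoch = int(round(epoch.duration_s * rate_hz))
            n_pre = min(int(round(pre_s * rate_hz)),
                        int(np.floor((onset - t0) / dt + 1e-9)))
            grid = onset + (np.arange(-n_pre, n_epoch)) * dt
            if grid[-1] > t1 + 1e-9 or grid[0] < t0 - 1e-9:
                warnings.warn(f"epoch {ei} extends outside the recording; dropped",
                              stacklevel=2)
                continue
            vals = np.interp(grid, traces.times, y)
            f0_gray = None
            if epoch.kind == "edge" and ei > 0 and protocol.epochs[ei - 1].kind == "gray":
                g_end = onset
                g_start = max(onsets[ei - 1], g_end - 1.0)
                gg = np.arange(g_start, g_end - 1e-9, dt)
                if len(gg) and gg[0] >= t0 - 1e-9:
                    f0_gray = float(np.interp(gg, traces.times, y).mean())
            segments.append(Segment(
                roi_id=rid, epoch_index=ei, kind=epoch.kind,
                contrast=epoch.contrast, direction_deg=epoch.direction_deg,
                values=vals, n_pre=n_pre, rate_hz=rate_hz,
                duration_s=epoch.duration_s, f0_gray=f0_gray,
            ))
    wtm = {rid: float(traces.values[i].mean())
           for i, rid in enumerate(traces.roi_ids)}
    return SegmentSet(segments=segments, rate_hz=rate_hz,
                      roi_ids=list(traces.roi_ids), whole_trace_mean=wtm,
                      fly_id=traces.fly_id, condition=traces.condition)


def compute_dff(
    segments: SegmentSet,
    f0_mode: str = "whole_trace_mean",
    f0_override: dict[int, float] | None = None,
) -> DffTraceSet:
    """dF/F = (F - F0) / F0 under the chosen F0 convention.

    ``whole_trace_mean``
        F0 is the mean of the ROI's full background-subtracted native trace
        (the flash convention); computed before segmentation.
    ``gray_last_second``
        F0 is the mean of the last second of the gray epoch preceding each
        edge epoch (the edge convention); requires such a gray epoch.

    ROIs whose F0 is not positive are excluded with a warning (dF/F would be
    unbounded or sign-flipped).  ``f0_override`` replaces the per-ROI F0
    with known values — useful on synthetic data where the true baseline is
    available as ground truth.
    """
    if f0_mode not in ("whole_trace_mean", "gray_last_second"):
        raise ValueError(f"unknown f0_mode {f0_mode!r}")
    out: list[Segment] = []
    f0_map: dict[int, float] = {}
    bad: set[int] = set()
    for s in segments.segments:
        if f0_mode == "whole_trace_mean":
            f0 = segments.whole_trace_mean[s.roi_id]
            if f0_override is not None:
                f0 = f0_override[s.roi_id]
            f0_map[s.roi_id] = f0
        else:
            if s.kind != "edge":
                continue
            f0 = s.f0_gray
            if f0_override is not None:
                f0 = f0_override[s.roi_id]
            if f0 is None:
                raise ValueError(
                    "gray_last_second requires a gray epoch before each edge")
        if not f0 > 0:
            bad.add(s.roi_id)
            continue
        out.append(Segment(
            roi_id=s.roi_id, epoch_index=s.epoch_index, kind=s.kind,
            contrast=s.contrast, direction_deg=s.direction_deg,
            values=(s.values - f0) / f0, n_pre=s.n_pre, rate_hz=s.rate_hz,
            duration_s=s.duration_s, f0_gray=s.f0_gray,
        ))
    if bad:
        warnings.warn(f"excluded ROIs with non-positive F0: {sorted(bad)}",
                      stacklevel=2)
    kept = [r for r in segments.roi_ids if r not in bad]
    return DffTraceSet(segments=out, rate_hz=segments.rate_hz, roi_ids=kept,
                       f0_mode=f0_mode,
                       f0=f0_map if f0_mode == "whole_trace_mean" else None,
                       fly_id=segments.fly_id, condition=segments.condition)


def trial_average(dff: DffTraceSet) -> dict[tuple, TrialAverage]:
    """Pointwise mean over trials of the same epoch kind (flashes) or the
    same contrast x direction (edges), aligned at epoch onset.

    Trials may carry different amounts of pre-onset context (the first epoch
    has none); the average at each pre-onset sample uses the trials that
    reach it.  Keys are ``(roi_id,) + segment.group_key()``.
    """
    groups: dict[tuple, list[Segment]] = {}
    for s in dff.segments:
        if s.kind == "gray":
            continue
        groups.setdefault((s.roi_id,) + s.group_key(), []).append(s)
    out: dict[tuple, TrialAverage] = {}
    for key, segs in groups.items():
        n_pre = max(s.n_pre for s in segs)
        n_ep = max(len(s.values) - s.n_pre for s in segs)
        acc = np.full((len(segs), n_pre + n_ep), np.nan)
        for j, s in enumerate(segs):
            acc[j, n_pre - s.n_pre:n_pre - s.n_pre + len(s.values)] = s.values
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(acc, axis=0)
        s0 = segs[0]
        out[key] = TrialAverage(
            roi_id=s0.roi_id, kind=s0.kind, contrast=s0.contrast,
            direction_deg=s0.direction_deg, values=mean, n_pre=n_pre,
            rate_hz=dff.rate_hz, duration_s=s0.duration_s, n_trials=len(segs),
        )
    return out
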