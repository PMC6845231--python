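"""Visual stimulus protocols.

A :class:`StimulusProtocol` is an ordered list of epochs (full-field flashes,
moving edges, or intermediate gray) together with the trial structure and the
display geometry.  Protocols are the time base everything downstream is locked
to: epoch onsets are derived from the cumulative epoch durations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "Epoch",
    "StimulusProtocol",
    "build_flash_protocol",
    "build_edge_protocol",
]

EPOCH_KINDS = ("flash_on", "flash_off", "gray", "edge")


@dataclass(frozen=True)
class Epoch:
    """One stimulus epoch.

    Parameters
    ----------
    kind : {'flash_on', 'flash_off', 'gray', 'edge'}
    contrast : float
        Weber contrast in [-1, 1]; positive = brightening.
    duration_s : float
        Epoch duration in seconds, > 0.
    direction_deg : float or None
        Motion direction for ``edge`` epochs, degrees in [0, 360).
    """

    kind: str
    contrast: float
    duration_s: float
    direction_deg: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in EPOCH_KINDS:
            raise ValueError(f"unknown epoch kind {self.kind!r}")
        if not self.duration_s > 0:
            raise ValueError("epoch duration must be > 0")
        if not -1.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [-1, 1]")
        if self.kind == "edge" and self.direction_deg is None:
            raise ValueError("edge epochs require a direction")


@dataclass
class StimulusProtocol:
    """Ordered stimulus epochs plus trial structure and display geometry."""

    epochs: list[Epoch]
    n_trials: int = 1
    display_rate_hz: float = 100.0
    field_span_deg: float = 60.0
    seed: int | None = None  # order-randomization seed, kept for re-sync

    @property
    def total_duration_s(self) -> float:
        return float(sum(e.duration_s for e in self.epochs))

    def onsets(self) -> np.ndarray:
        """Epoch onset times in seconds (cumulative durations, t=0 start)."""
        durs = np.array([e.duration_s for e in self.epochs], dtype=float)
        return np.concatenate(([0.0], np.cumsum(durs)[:-1]))

    def to_json(self, path) -> None:
        payload = {
            "epochs": [asdict(e) for e in self.epochs],
            "n_trials": self.n_trials,
            "display_rate_hz": self.display_rate_hz,
            "field_span_deg": self.field_span_deg,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "StimulusProtocol":
        with open(path) as fh:
            payload = json.load(fh)
        epochs = [Epoch(**e) for e in payload.pop("epochs")]
        return cls(epochs=epochs, **payload)


def build_flash_protocol(n_trials: int = 7, epoch_s: float = 5.0) -> StimulusProtocol:
    """Alternating full-contrast ON/OFF full-field flashes.

    Defaults follow the standard fly full-field flash design: 5 s epochs,
    ~7 trials, full contrast.  Returns ``2 * n_trials`` epochs alternating
    ``flash_on`` / ``flash_off``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not epoch_s > 0:
        raise ValueError("epoch_s must be > 0")
    epochs = []
    for _ in range(n_trials):
        epochs.append(Epoch("flash_on", +1.0, epoch_s))
        epochs.append(Epoch("flash_off", -1.0, epoch_s))
    return StimulusProtocol(epochs=epochs, n_trials=n_trials)


def build_edge_protocol(
    speed_dps: float = 20.0,
    reps: int = 3,
    gray_s: float = 2.0,
    field_span_deg: float = 60.0,
    seed: int | None = 0,
) -> StimulusProtocol:
    """Moving bright/dark edges in 8 directions, randomized, gray-interleaved.

    Edges move at ``speed_dps`` deg/s across a square field of
    ``field_span_deg`` degrees, so each edge epoch lasts exactly
    ``field_span_deg / speed_dps`` seconds.  The design crosses
    {bright, dark} x 8 directions (0, 45, ..., 315 deg) x ``reps``, presented
    in a seeded random order with an intermediate gray epoch before every
    edge (the gray tail provides the F0 window for edge dF/F).
    """
    if not speed_dps > 0:
        raise ValueError("speed_dps must be > 0")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not gray_s > 0:
        raise ValueError("gray_s must be > 0")
    edge_s = field_span_deg / speed_dps
    design = [
        (contrast, float(d))
        for contrast in (+1.0, -1.0)
        for d in range(0, 360, 45)
    ] * reps
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(design))
    epochs: list[Epoch] = []
    for i in order:
        contrast, direction = design[i]
        epochs.append(Epoch("gray", 0.0, gray_s))
        epochs.append(Epoch("edge", contrast, edge_s, direction_deg=direction))
    # trailing gray so the last edge has post-stimulus context
    epochs.append(Epoch("gray", 0.0, gray_s))
    return StimulusProtocol(
        epochs=epochs, n_trials=reps, field_span_deg=field_span_deg, seed=seed
    )
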