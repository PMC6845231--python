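"""Synthetic two-photon movies and traces with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: ON/OFF medulla-style cells responding to full-field flashes with a
fast transient that decays to a plateau within ~2 s, cosine-tuned or untuned
responses to moving edges, a two-receptor (glutamatergic GluClα / GABAergic
Rdl) gain model for pharmacology and pharmacogenetic rescue, photon shot
noise, Gaussian read noise, and bounded integer frame-to-frame translation.

Every rendered artifact is paired with its :class:`GroundTruth` (true
per-frame shifts and per-cell ideal dF/F), so registration, trace extraction
and metric computation can all be validated by parameter recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .movie import Movie
from .protocols import StimulusProtocol, build_flash_protocol
from .traces import ROISet, TraceSet

__all__ = [
    "Tuning",
    "CellSpec",
    "DrugCondition",
    "MovieConfig",
    "GroundTruth",
    "ideal_response",
    "render_movie",
    "simulate_trace_set",
]


@dataclass(frozen=True)
class Tuning:
    """Direction tuning of edge responses.

    ``untuned`` cells respond equally to all motion directions;
    ``cosine_rectified`` cells scale edge responses by
    ``max(0, cos(direction - pref_dir))``.
    """

    kind: str = "untuned"
    pref_dir_deg: float = 0.0

    def factor(self, direction_deg: float) -> float:
        if self.kind == "untuned":
            return 1.0
        if self.kind == "cosine_rectified":
            return max(0.0, float(np.cos(np.deg2rad(direction_deg - self.pref_dir_deg))))
        raise ValueError(f"unknown tuning kind {self.kind!r}")


@dataclass
class CellSpec:
    """Ground-truth description of one simulated cell.

    Amplitudes are in dF/F units relative to the cell's true baseline
    ``f_baseline``: the flash response peaks at ``amp_transient`` and settles
    at ``amp_plateau``.  ``receptor_weights = (w_glu, w_gaba)`` partitions the
    response between the glutamate-gated (GluClα) and GABA-gated (Rdl)
    chloride-channel pathways; the weights are nonnegative and sum to 1.
    """

    id: int
    center_px: tuple[int, int] = (0, 0)
    radius_px: float = 3.0
    polarity: int = +1
    f_baseline: float = 1.0
    amp_transient: float = 1.0
    amp_plateau: float = 0.4
    tau_rise_s: float = 0.1
    tau_transient_s: float = 0.8
    tau_plateau_s: float = 0.5
    tuning: Tuning = field(default_factory=Tuning)
    receptor_weights: tuple[float, float] = (0.5, 0.5)
    rf_center_deg: tuple[float, float] = (0.0, 0.0)  # (azimuth, elevation)

    def __post_init__(self) -> None:
        if self.radius_px < 1:
            raise ValueError("radius_px must be >= 1")
        if not self.f_baseline > 0:
            raise ValueError("f_baseline must be > 0")
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 (ON) or -1 (OFF)")
        if not self.amp_transient >= self.amp_plateau >= 0:
            raise ValueError("need amp_transient >= amp_plateau >= 0")
        w = self.receptor_weights
        if min(w) < 0 or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("receptor_weights must be nonnegative and sum to 1")


@dataclass(frozen=True)
class DrugCondition:
    """A pharmacological condition in the two-receptor block model.

    ``block_glu`` / ``block_gaba`` are the blocked fractions of each pathway
    (picrotoxin blocks both).  The ``insensitive_*`` flags model the
    PTX-insensitive point-mutant alleles (GluClα^S278T, Rdl^MDRR): an
    insensitive pathway has effective block 0 regardless of the drug.
    """

    name: str = "sham"
    block_glu: float = 0.0
    block_gaba: float = 0.0
    insensitive_glu: bool = False
    insensitive_gaba: bool = False

    def __post_init__(self) -> None:
        for b in (self.block_glu, self.block_gaba):
            if not 0.0 <= b <= 1.0:
                raise ValueError("block fractions must lie in [0, 1]")

    @property
    def effective_blocks(self) -> tuple[float, float]:
        bg = 0.0 if self.insensitive_glu else self.block_glu
        bb = 0.0 if self.insensitive_gaba else self.block_gaba
        return bg, bb

    def gain(self, receptor_weights: tuple[float, float]) -> float:
        """Scalar response gain w_glu*(1-b_glu) + w_gaba*(1-b_gaba)."""
        bg, bb = self.effective_blocks
        w_glu, w_gaba = receptor_weights
        return w_glu * (1.0 - bg) + w_gaba * (1.0 - bb)


SHAM = DrugCondition("sham")


@dataclass
class MovieConfig:
    """Rendering configuration for synthetic movies.

    ``photon_gain`` is the expected detector counts per unit fluorescence;
    shot noise is Poisson in counts when ``shot_noise`` is on.  Motion is a
    global integer-pixel random walk (per-frame steps ~ round(N(0, sd)))
    reflected at ``±motion_walk_max_px`` — in-vivo drift is bounded, and the
    bound keeps registration with the default search radius well posed.
    """

    height_px: int = 64
    width_px: int = 64
    frame_rate_hz: float = 15.0
    photon_gain: float = 100.0
    read_noise_sd: float = 0.0
    motion_walk_sd: float = 0.0
    motion_walk_max_px: int = 8
    background_level: float = 0.2
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be > 0")
        if self.photon_gain < 0 or self.read_noise_sd < 0 or self.motion_walk_sd < 0:
            raise ValueError("noise parameters must be >= 0")

    def to_yaml(self, path) -> None:
        import yaml
        from dataclasses import asdict
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "MovieConfig":
        import yaml
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """What the generator knows: true shifts and ideal per-cell dF/F."""

    shifts: np.ndarray          # (T, 2) integer (dy, dx) per frame
    dff: np.ndarray             # (n_cells, T) ideal dF/F at frame times
    frame_times: np.ndarray     # (T,)
    cell_ids: list[int]


# ---------------------------------------------------------------------------
# response kernels

def _rise(t: np.ndarray, tau: float) -> np.ndarray:
    if tau <= 0:
        return (t >= 0).astype(float)
    return np.where(t >= 0, 1.0 - np.exp(-np.maximum(t, 0.0) / tau), 0.0)


def _transient_kernel_unit(t: np.ndarray, tau_rise: float, tau_dec: float) -> np.ndarray:
    """rise x decay kernel, normalized to unit peak."""
    u = _rise(t, tau_rise) * np.exp(-np.maximum(t, 0.0) / tau_dec)
    tt = np.linspace(0.0, max(5.0, 10.0 * tau_dec), 20001)
    umax = (_rise(tt, tau_rise) * np.exp(-tt / tau_dec)).max()
    return u / umax


def flash_kernel(t: np.ndarray, cell: CellSpec) -> np.ndarray:
    """Ideal single-epoch flash response: peaks at ``amp_transient`` and
    settles at ``amp_plateau``.

    The kernel is ``amp_plateau * rise(t) + c * rise(t) * exp(-t/tau_tr)``
    with ``c`` calibrated so the true maximum equals ``amp_transient``
    exactly; the amplitudes are thus by construction the quantities the
    step/plateau metrics recover.
    """
    A, P = cell.amp_transient, cell.amp_plateau
    tr, td = cell.tau_rise_s, cell.tau_transient_s
    tt = np.linspace(0.0, max(5.0, 10.0 * td), 20001)
    rise_tt = _rise(tt, tr)
    u_tt = rise_tt * np.exp(-tt / td)
    if A <= P + 1e-12:
        c = 0.0
    else:
        c = A - P
        for _ in range(8):  # fixed-point calibration of the transient scale
            k = P * rise_tt + c * u_tt
            i = int(np.argmax(k))
            if u_tt[i] < 1e-12:
                break
            c = (A - P * rise_tt[i]) / u_tt[i]
    return P * _rise(t, tr) + c * _rise(t, tr) * np.exp(-np.maximum(t, 0.0) / td)


def _split_components(t: np.ndarray, cell: CellSpec) -> tuple[np.ndarray, np.ndarray]:
    """Split-component kernels: fast transient (Glu-gated) and slow-rising
    sustained plateau (GABA-gated)."""
    T = cell.amp_transient * _transient_kernel_unit(t, cell.tau_rise_s, cell.tau_transient_s)
    P = cell.amp_plateau * _rise(t, cell.tau_plateau_s)
    return T, P


def _edge_crossing_time(cell: CellSpec, direction_deg: float,
                        span_deg: float, duration_s: float) -> float:
    """Time (within the epoch) at which the edge front crosses the cell's
    receptive-field center.  The edge travels ``span_deg`` along the motion
    axis over the epoch."""
    th = np.deg2rad(direction_deg)
    az, el = cell.rf_center_deg
    p = az * np.cos(th) + el * np.sin(th)          # projection on motion axis
    frac = (p + span_deg / 2.0) / span_deg
    return float(np.clip(frac, 0.0, 1.0) * duration_s)


def ideal_response(
    cell: CellSpec,
    protocol: StimulusProtocol,
    times: np.ndarray,
    drug: DrugCondition = SHAM,
    split_components: bool = False,
) -> np.ndarray:
    """Noise-free dF/F of one cell at the given sample times.

    Flash responses are driven by the epoch whose contrast sign matches the
    cell's polarity and are truncated at epoch offset (the luminance step
    back shuts the response; offset kinetics are idealized as instantaneous).
    Edge responses start when the edge front crosses the cell's receptive
    field and decay freely into the following gray epoch, scaled by the
    tuning factor for tuned cells.

    Default drug model: the scalar gain
    ``g = w_glu*(1-b_glu) + w_gaba*(1-b_gaba)`` multiplies the whole
    response.  With ``split_components=True`` the fast transient kernel
    carries the glutamatergic gain and the slow-rising plateau kernel the
    GABAergic gain, reproducing the step-vs-plateau dissociation of the
    pharmacogenetic rescue experiments.
    """
    times = np.asarray(times, dtype=float)
    out = np.zeros_like(times)
    bg, bb = drug.effective_blocks
    g_glu, g_gaba = 1.0 - bg, 1.0 - bb
    g_scalar = drug.gain(cell.receptor_weights)
    onsets = protocol.onsets()
    for epoch, onset in zip(protocol.epochs, onsets):
        if epoch.kind in ("flash_on", "flash_off"):
            driven = (cell.polarity > 0) == (epoch.contrast > 0)
            if not driven:
                continue
            tloc = times - onset
            inside = (tloc >= 0) & (tloc < epoch.duration_s)
            if not inside.any():
                continue
            if split_components:
                T, P = _split_components(tloc[inside], cell)
                out[inside] += g_glu * T + g_gaba * P
            else:
                out[inside] += g_scalar * flash_kernel(tloc[inside], cell)
        elif epoch.kind == "edge":
            driven = (cell.polarity > 0) == (epoch.contrast > 0)
            if not driven:
                continue
            tune = cell.tuning.factor(epoch.direction_deg)
            if tune <= 0.0:
                continue
            t_c = onset + _edge_crossing_time(
                cell, epoch.direction_deg, protocol.field_span_deg, epoch.duration_s
            )
            tloc = times - t_c
            active = tloc >= 0
            if not active.any():
                continue
            k = cell.amp_transient * _transient_kernel_unit(
                tloc[active], cell.tau_rise_s, cell.tau_transient_s
            )
            out[active] += g_scalar * tune * k
    return out


# ---------------------------------------------------------------------------
# rendering

def _walk(n: int, sd: float, bound: int, rng: np.random.Generator) -> np.ndarray:
    """Integer random walk from (0,0), reflected at ±bound."""
    shifts = np.zeros((n, 2), dtype=int)
    if sd <= 0:
        return shifts
    steps = np.rint(rng.normal(0.0, sd, size=(n - 1, 2))).astype(int)
    pos = np.zeros(2, dtype=int)
    for i, step in enumerate(steps, start=1):
        pos = pos + step
        for a in range(2):  # reflect into [-bound, bound]
            while pos[a] > bound or pos[a] < -bound:
                if pos[a] > bound:
                    pos[a] = 2 * bound - pos[a]
                else:
                    pos[a] = -2 * bound - pos[a]
        shifts[i] = pos
    return shifts


def _translate(img: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    out = np.full_like(img, fill)
    h, w = img.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = img[ys_src, xs_src]
    return out


def render_movie(
    cells: list[CellSpec],
    protocol: StimulusProtocol,
    config: MovieConfig,
    drug: DrugCondition = SHAM,
    split_components: bool = False,
) -> tuple[Movie, ROISet, GroundTruth]:
    """Render a synthetic movie plus its ROI label mask and ground truth.

    Pixel model: a uniform ``background_level`` everywhere plus
    ``f_baseline * (1 + dF/F)`` inside each cell disc; Poisson shot noise in
    counts at ``photon_gain`` counts per unit fluorescence, additive Gaussian
    read noise, and a per-frame global integer translation recorded in the
    returned :class:`GroundTruth`.  Identical config + seed reproduce the
    movie bit for bit.
    """
    h, w = config.height_px, config.width_px
    rng = np.random.default_rng(config.seed)
    n_frames = int(round(protocol.total_duration_s * config.frame_rate_hz))
    times = np.arange(n_frames) / config.frame_rate_hz

    yy, xx = np.mgrid[0:h, 0:w]
    labels = np.zeros((h, w), dtype=np.int32)
    discs = []
    for cell in cells:
        cy, cx = cell.center_px
        r = cell.radius_px
        if cy - r < 0 or cx - r < 0 or cy + r > h - 1 or cx + r > w - 1:
            raise ValueError(f"cell {cell.id} does not fit inside the frame")
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        if (labels[disc] != 0).any():
            warnings.warn("overlapping cells: intensities are summed",
                          stacklevel=2)
        labels[disc] = cell.id
        discs.append(disc)

    dff = np.stack(
        [ideal_response(c, protocol, times, drug, split_components) for c in cells]
    ) if cells else np.zeros((0, n_frames))
    shifts = _walk(n_frames, config.motion_walk_sd, config.motion_walk_max_px, rng)

    data = np.empty((n_frames, h, w), dtype=float)
    for f in range(n_frames):
        scene = np.full((h, w), config.background_level, dtype=float)
        for ci, cell in enumerate(cells):
            scene[discs[ci]] += cell.f_baseline * (1.0 + dff[ci, f])
        scene = _translate(scene, int(shifts[f, 0]), int(shifts[f, 1]),
                           config.background_level)
        counts = scene * config.photon_gain
        if config.shot_noise:
            counts = rng.poisson(np.maximum(counts, 0.0)).astype(float)
        if config.read_noise_sd > 0:
            counts = counts + rng.normal(0.0, config.read_noise_sd, size=(h, w))
        data[f] = counts

    movie = Movie(data=data, timestamps=times)
    rois = ROISet(labels=labels, roi_ids=[c.id for c in cells])
    gt = GroundTruth(shifts=shifts, dff=dff, frame_times=times,
                     cell_ids=[c.id for c in cells])
    return movie, rois, gt


def simulate_trace_set(
    cells: list[CellSpec],
    protocol: StimulusProtocol,
    frame_rate_hz: float = 15.0,
    drug: DrugCondition = SHAM,
    noise_dff_sd: float = 0.05,
    seed: int = 0,
    split_components: bool = False,
    fly_id: str = "fly0",
    condition: str | None = None,
) -> tuple[TraceSet, GroundTruth]:
    """Simulate background-subtracted ROI traces directly (no rendering).

    Equivalent to rendering + extraction in the noiseless limit, but cheap
    enough for population-scale experiments: per-ROI fluorescence is
    ``f_baseline * (1 + dF/F + eps)`` with white Gaussian trace noise
    ``eps ~ N(0, noise_dff_sd)`` in dF/F units.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(round(protocol.total_duration_s * frame_rate_hz))
    times = np.arange(n_frames) / frame_rate_hz
    dff = np.stack(
        [ideal_response(c, protocol, times, drug, split_components) for c in cells]
    ) if cells else np.zeros((0, n_frames))
    values = np.empty_like(dff)
    for i, cell in enumerate(cells):
        eps = rng.normal(0.0, noise_dff_sd, size=n_frames) if noise_dff_sd > 0 else 0.0
        values[i] = cell.f_baseline * (1.0 + dff[i] + eps)
    ts = TraceSet(
        times=times,
        values=values,
        roi_ids=[c.id for c in cells],
        background=np.zeros(n_frames),
        fly_id=fly_id,
        condition=condition or drug.name,
        protocol=protocol,
    )
    gt = GroundTruth(shifts=np.zeros((n_frames, 2), dtype=int), dff=dff,
                     frame_times=times, cell_ids=[c.id for c in cells])
    return ts, gt
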