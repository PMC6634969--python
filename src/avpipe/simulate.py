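"""Synthetic axon-tip time-lapse generator.

Renders multi-channel 2D+time videos of autophagosome biogenesis events at
the distal tip of a neuron, together with an exhaustive ground-truth record,
so that the detection → tracking → classification pipeline can be exercised
and validated without any microscope data.

The generative model:

* Biogenesis events arrive as a homogeneous Poisson process at
  ``event_rate_per_min`` (the per-minute rate live-cell studies report as
  de-novo GFP-LC3B puncta).  Each event is *productive* with probability
  ``productive_fraction``, otherwise *stalled*.
* A productive event shows a transient early-marker punctum (ATG13/ATG5/
  WIPI2B) dwelling ``marker_dwell_s`` (~100–150 s), whose decay coincides
  with a monotonic rise of LC3B over ``lc3b_rise_s`` (~3 min) to a mature
  punctum of ``final_diameter_um`` (~1 µm, defined at half maximum).
* A stalled event shows the early marker persisting for at least
  ``stalled_min_persist_s`` (≥5 min) and never recruits LC3B; ATG9 is
  persistently retained with probability ``atg9_persistent_on_stalled_p``.
* Spots are isotropic 2D Gaussians on a confined (reflected) random walk;
  camera noise is Poisson shot noise on (background + signal) plus additive
  Gaussian read noise.

For productive events the sampled onset is the *LC3B appearance* time — the
quantity the biogenesis-rate assay counts — and the early-marker phase
precedes it.  Stalled onsets are restricted to the window in which the
≥5-min persistence criterion is observable.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SimConfig",
    "GroundTruthEvent",
    "Video",
    "sample_event_onsets",
    "sample_events",
    "event_kinetics",
    "generate_video",
    "write_video",
    "read_video",
    "write_ground_truth",
    "young_adult_config",
    "aged_config",
    "PRODUCTIVE",
    "STALLED",
]

PRODUCTIVE = "productive"
STALLED = "stalled"

#: channels the kinetic model understands
KNOWN_CHANNELS = ("LC3B", "ATG13", "ATG5", "ATG9", "WIPI2B")
#: channels that behave as transient early markers of the initiation complex
MARKER_CHANNELS = ("ATG13", "ATG5", "WIPI2B")

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Physical and kinetic parameters of one simulated acquisition.

    Durations are seconds, lengths are µm, rates are events per minute.
    Defaults follow a spinning-disk acquisition of a DRG axon tip:
    10 min at one frame per 3 s, 100× EMCCD sampling (0.16 µm/px).
    """

    duration_s: float = 600.0
    frame_interval_s: float = 3.0
    pixel_size_um: float = 0.16
    field_shape: tuple[int, int] = (64, 256)  # (height, width) px
    channels: tuple[str, ...] = ("ATG13", "LC3B")
    event_rate_per_min: float = 0.5
    productive_fraction: float = 0.85
    marker_dwell_s: float = 125.0
    marker_rise_s: float = 30.0
    marker_decay_s: float = 45.0
    lc3b_rise_s: float = 180.0
    stalled_min_persist_s: float = 360.0
    final_diameter_um: float = 1.0
    spot_sigma_um: float = 0.25
    atg9_dwell_s: float = 60.0
    atg9_ramp_s: float = 15.0
    atg9_persistent_on_stalled_p: float = 0.9
    mobility_sigma_um: float = 0.05
    edge_margin_px: int = 10
    background_level: float = 100.0
    spot_amplitude: float = 200.0
    read_noise: float = 2.0
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.frame_interval_s <= 0:
            raise ValueError("duration_s and frame_interval_s must be > 0")
        if self.event_rate_per_min < 0:
            raise ValueError("event_rate_per_min must be >= 0")
        if not 0.0 <= self.productive_fraction <= 1.0:
            raise ValueError("productive_fraction must lie in [0, 1]")
        if not 0.0 <= self.atg9_persistent_on_stalled_p <= 1.0:
            raise ValueError("atg9_persistent_on_stalled_p must lie in [0, 1]")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        unknown = set(self.channels) - set(KNOWN_CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")
        if len(self.channels) == 0:
            raise ValueError("at least one channel is required")
        for name in ("marker_dwell_s", "lc3b_rise_s", "stalled_min_persist_s",
                     "final_diameter_um", "spot_sigma_um", "background_level",
                     "spot_amplitude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def n_frames(self) -> int:
        return int(self.duration_s // self.frame_interval_s)

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    @property
    def final_sigma_um(self) -> float:
        """Gaussian σ whose half-max width equals ``final_diameter_um``."""
        return self.final_diameter_um / _FWHM_PER_SIGMA

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["field_shape"] = list(self.field_shape)
        d["channels"] = list(self.channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "field_shape" in d:
            d["field_shape"] = tuple(d["field_shape"])
        if "channels" in d:
            d["channels"] = tuple(d["channels"])
        return cls(**d)


def young_adult_config(**overrides) -> SimConfig:
    """Preset mirroring young-adult neurons: 0.47 AVs/min, mostly productive."""
    kw = dict(event_rate_per_min=0.47, productive_fraction=0.85)
    kw.update(overrides)
    return SimConfig(**kw)


def aged_config(**overrides) -> SimConfig:
    """Preset mirroring aged neurons: 0.21 AVs/min, stalling dominates."""
    kw = dict(event_rate_per_min=0.21, productive_fraction=0.2)
    kw.update(overrides)
    return SimConfig(**kw)


@dataclasses.dataclass
class GroundTruthEvent:
    """Simulator-side truth for one biogenesis event.

    ``windows`` maps channel → (t_appear_s, t_disappear_s); times may lie
    outside [0, duration) when the event is clipped by the acquisition
    window (the rendered video only shows the overlap).  ``trajectory`` is
    the (n_frames, 2) array of (x, y) spot-centre pixel coordinates.
    """

    event_id: int
    true_class: str
    onset_s: float
    windows: dict[str, tuple[float, float]]
    trajectory: np.ndarray
    peak_amplitude: dict[str, float]
    atg9_persistent: bool = False

    def censored(self, duration_s: float) -> bool:
        """Marker visibility clipped by either end of the acquisition."""
        a, d = self.marker_window
        return a < 0.0 or d >= duration_s

    @property
    def marker_channel(self) -> str | None:
        for ch in MARKER_CHANNELS:
            if ch in self.windows:
                return ch
        return None

    @property
    def marker_window(self) -> tuple[float, float]:
        ch = self.marker_channel
        if ch is None:
            raise ValueError("event has no early-marker channel")
        return self.windows[ch]


@dataclasses.dataclass
class Video:
    """A calibrated multi-channel 2D time-lapse stack.

    ``pixels`` is indexed (channel, frame, row, column) and is finite and
    non-negative.
    """

    pixels: np.ndarray
    channels: tuple[str, ...]
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        if self.pixels.ndim != 4:
            raise ValueError("pixels must be (channel, frame, row, col)")
        if self.pixels.shape[0] != len(self.channels):
            raise ValueError("channel axis does not match channel names")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    def channel_index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(f"channel {channel!r} not in video {self.channels}")

    def frame(self, channel: str, frame: int) -> np.ndarray:
        if not 0 <= frame < self.n_frames:
            raise IndexError(f"frame {frame} outside [0, {self.n_frames})")
        return self.pixels[self.channel_index(channel), frame]


# ---------------------------------------------------------------------------
# event sampling
# ---------------------------------------------------------------------------

def sample_event_onsets(rate_per_min: float, duration_s: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Onset times (s) of a homogeneous Poisson process on [0, duration).

    The number of onsets is Poisson with mean ``rate_per_min * duration_s/60``.
    """
    if rate_per_min < 0:
        raise ValueError("rate_per_min must be >= 0")
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    n = rng.poisson(rate_per_min * duration_s / 60.0)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def _confined_walk(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Reflected random walk within the field interior, (n_frames, 2) px."""
    h, w = cfg.field_shape
    m = cfg.edge_margin_px
    lo = np.array([m, m], dtype=float)
    hi = np.array([w - 1 - m, h - 1 - m], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("field too small for the configured edge margin")
    sigma_px = cfg.mobility_sigma_um / cfg.pixel_size_um
    pos = rng.uniform(lo, hi)
    steps = rng.normal(0.0, sigma_px, size=(cfg.n_frames, 2))
    traj = np.empty((cfg.n_frames, 2))
    for i in range(cfg.n_frames):
        pos = pos + steps[i]
        # reflect into [lo, hi]
        for ax in range(2):
            if pos[ax] < lo[ax]:
                pos[ax] = 2 * lo[ax] - pos[ax]
            elif pos[ax] > hi[ax]:
                pos[ax] = 2 * hi[ax] - pos[ax]
            pos[ax] = min(max(pos[ax], lo[ax]), hi[ax])
        traj[i] = pos
    return traj


def sample_events(cfg: SimConfig,
                  rng: np.random.Generator) -> list[GroundTruthEvent]:
    """Draw the latent event record for one video."""
    marker = next((c for c in cfg.channels if c in MARKER_CHANNELS), None)
    onsets = sample_event_onsets(cfg.event_rate_per_min, cfg.duration_s, rng)
    events: list[GroundTruthEvent] = []
    stall_latest = max(0.0, cfg.duration_s - cfg.stalled_min_persist_s)
    for i, onset in enumerate(onsets):
        productive = bool(rng.random() < cfg.productive_fraction)
        windows: dict[str, tuple[float, float]] = {}
        atg9_persistent = False
        if productive:
            # onset is the LC3B appearance time; the marker phase precedes it
            # and its decay overlaps the LC3B rise.
            marker_appear = onset - (cfg.marker_dwell_s - cfg.marker_decay_s)
            marker_gone = marker_appear + cfg.marker_dwell_s
            if marker is not None:
                windows[marker] = (marker_appear, marker_gone)
            if "LC3B" in cfg.channels:
                windows["LC3B"] = (onset, cfg.duration_s)
            if "ATG9" in cfg.channels:
                windows["ATG9"] = (marker_appear,
                                   marker_appear + cfg.atg9_dwell_s)
            event_onset = marker_appear if marker is not None else onset
        else:
            # restrict onset so the >= 5-min persistence is observable
            onset = float(rng.uniform(0.0, stall_latest)) if stall_latest > 0 \
                else 0.0
            persist = float(rng.uniform(cfg.stalled_min_persist_s,
                                        max(cfg.stalled_min_persist_s,
                                            cfg.duration_s - onset)))
            if marker is not None:
                windows[marker] = (onset, onset + persist)
            atg9_persistent = bool(rng.random()
                                   < cfg.atg9_persistent_on_stalled_p)
            if "ATG9" in cfg.channels:
                if atg9_persistent:
                    windows["ATG9"] = (onset, onset + persist)
                else:
                    windows["ATG9"] = (onset, onset + cfg.atg9_dwell_s)
            event_onset = onset
        if not windows:
            continue  # no configured channel can show this event
        events.append(GroundTruthEvent(
            event_id=i,
            true_class=PRODUCTIVE if productive else STALLED,
            onset_s=float(event_onset),
            windows=windows,
            trajectory=_confined_walk(cfg, rng),
            peak_amplitude={ch: 1.0 for ch in windows},
            atg9_persistent=atg9_persistent,
        ))
    return events


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def _trapezoid(t, a, d, rise, decay):
    """Piecewise-linear 0→1→0 pulse on [a, d]; ramps fit inside the window."""
    t = np.asarray(t, dtype=float)
    span = d - a
    rise = min(rise, span / 3.0)
    decay = min(decay, span / 3.0)
    amp = np.zeros_like(t)
    inside = (t >= a) & (t < d)
    tt = t[inside]
    up = np.minimum(1.0, (tt - a) / rise) if rise > 0 else np.ones_like(tt)
    down = np.minimum(1.0, (d - tt) / decay) if decay > 0 else np.ones_like(tt)
    amp[inside] = np.minimum(up, down)
    return amp


def event_kinetics(event: GroundTruthEvent, t, channel: str,
                   cfg: SimConfig) -> np.ndarray:
    """Relative fluorescence amplitude of ``event`` in ``channel`` at ``t``.

    Returns values in [0, 1]; 0 before the channel's appearance.  Stalled
    events never show LC3B; their marker plateaus until disappearance.
    """
    if channel not in KNOWN_CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    scalar = np.isscalar(t) or np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if channel not in event.windows:
        amp = np.zeros_like(t)
    elif channel == "LC3B":
        if event.true_class == STALLED:
            amp = np.zeros_like(t)
        else:
            a, d = event.windows[channel]
            amp = np.clip((t - a) / cfg.lc3b_rise_s, 0.0, 1.0)
            amp[(t < a) | (t >= d)] = 0.0
    else:
        a, d = event.windows[channel]
        if channel == "ATG9":
            rise = decay = cfg.atg9_ramp_s
        else:
            rise, decay = cfg.marker_rise_s, cfg.marker_decay_s
        amp = _trapezoid(t, a, d, rise, decay)
    return float(amp[0]) if scalar else amp


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _render_spot(frame: np.ndarray, x: float, y: float, peak: float,
                 sigma_px: float) -> None:
    """Add an isotropic Gaussian of given peak value in place."""
    h, w = frame.shape
    r = max(2, int(math.ceil(4.0 * sigma_px)))
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - x
    ys = np.arange(y0, y1) - y
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sigma_px ** 2))
    frame[y0:y1, x0:x1] += peak * g


def generate_video(cfg: SimConfig,
                   events: list[GroundTruthEvent] | None = None,
                   ) -> tuple[Video, list[GroundTruthEvent]]:
    """Render a video from ``cfg`` (sampling events unless supplied).

    Identical configs (including seed) produce bit-identical pixel data and
    ground truth.  Raises ``ValueError`` if the field cannot contain a
    mature spot inside the edge margin.
    """
    h, w = cfg.field_shape
    final_sigma_px = cfg.final_sigma_um / cfg.pixel_size_um
    if min(h, w) <= 2 * cfg.edge_margin_px or min(h, w) < 8 * final_sigma_px:
        raise ValueError("field too small to contain a mature spot")
    rng = np.random.default_rng(cfg.seed)
    if events is None:
        events = sample_events(cfg, rng)
    times = cfg.frame_times_s
    sigma0_px = cfg.spot_sigma_um / cfg.pixel_size_um
    stack = np.zeros((len(cfg.channels), cfg.n_frames, h, w))
    for ci, ch in enumerate(cfg.channels):
        for ev in events:
            if ch not in ev.windows:
                continue
            amps = event_kinetics(ev, times, ch, cfg)
            live = np.nonzero(amps > 0)[0]
            peak0 = cfg.spot_amplitude * ev.peak_amplitude[ch]
            for fi in live:
                if ch == "LC3B":
                    # punctum grows as LC3B accumulates, to ~1 µm at plateau
                    sigma = sigma0_px + (final_sigma_px - sigma0_px) * amps[fi]
                else:
                    sigma = sigma0_px
                x, y = ev.trajectory[fi]
                _render_spot(stack[ci, fi], x, y, peak0 * amps[fi], sigma)
    stack += cfg.background_level
    if cfg.noise:
        stack = rng.poisson(np.clip(stack, 0.0, None)).astype(float)
        stack += rng.normal(0.0, cfg.read_noise, size=stack.shape)
        np.clip(stack, 0.0, None, out=stack)
    video = Video(pixels=stack.astype(np.float32), channels=cfg.channels,
                  pixel_size_um=cfg.pixel_size_um,
                  frame_interval_s=cfg.frame_interval_s)
    return video, events


# ---------------------------------------------------------------------------
# IO: multi-page TIFF + JSON sidecar, ground-truth CSVs
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_video(video: Video, path, config: SimConfig | None = None) -> Path:
    """Write pages frame-major within channel, plus a JSON sidecar."""
    path = Path(path)
    c, t, h, w = video.pixels.shape
    tifffile.imwrite(path, video.pixels.reshape(c * t, h, w))
    meta = {
        "channels": list(video.channels),
        "pixel_size_um": video.pixel_size_um,
        "frame_interval_s": video.frame_interval_s,
        "n_frames": t,
    }
    if config is not None:
        meta["sim_config"] = config.to_dict()
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_video(path) -> Video:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    pages = tifffile.imread(path)
    c = len(meta["channels"])
    t = meta["n_frames"]
    pixels = np.asarray(pages).reshape(c, t, *pages.shape[-2:])
    return Video(pixels=pixels, channels=tuple(meta["channels"]),
                 pixel_size_um=meta["pixel_size_um"],
                 frame_interval_s=meta["frame_interval_s"])


def write_ground_truth(events: list[GroundTruthEvent], prefix) -> tuple[Path, Path]:
    """Write events.csv (one row per event per channel) and trajectories.csv."""
    prefix = Path(prefix)
    rows, traj_rows = [], []
    for ev in events:
        for ch, (a, d) in sorted(ev.windows.items()):
            rows.append({"event_id": ev.event_id, "true_class": ev.true_class,
                         "channel": ch, "t_appear_s": a, "t_disappear_s": d,
                         "atg9_persistent": ev.atg9_persistent})
        for fi, (x, y) in enumerate(ev.trajectory):
            traj_rows.append({"event_id": ev.event_id, "frame": fi,
                              "x_px": x, "y_px": y})
    ev_path = prefix.with_name(prefix.name + "_events.csv")
    tr_path = prefix.with_name(prefix.name + "_trajectories.csv")
    pd.DataFrame(rows, columns=["event_id", "true_class", "channel",
                                "t_appear_s", "t_disappear_s",
                                "atg9_persistent"]).to_csv(ev_path, index=False)
    pd.DataFrame(traj_rows, columns=["event_id", "frame", "x_px", "y_px"]
                 ).to_csv(tr_path, index=False)
    return ev_path, tr_path
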