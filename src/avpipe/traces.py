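"""Per-event intensity/area profiles, half-maximum alignment and averaging.

Productive events are aligned at the time the LC3B intensity first crosses
half of its maximum (computed on a smoothed trace with sub-frame
interpolation); stalled events, which never recruit LC3B, are aligned at
marker appearance.  Aligned profiles are averaged per time bin with SEM.
Intensities are min–max normalized per event by default, since published
event-triggered averages plot relative intensity; pass
``normalize=False`` to keep absolute photometry.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import uniform_filter1d

from . import detection
from .detection import DetectionParams
from .events import AVEvent
from .simulate import Video

__all__ = ["EventTrace", "MeanProfile", "FlatTraceError",
           "InsufficientDataError", "half_max_time", "extract_event_trace",
           "align_and_average", "area_growth", "plot_mean_profile"]


class FlatTraceError(ValueError):
    """The trace never rises above its baseline: no half-max crossing."""


class InsufficientDataError(ValueError):
    """Too few frames to support the requested measurement."""


@dataclasses.dataclass
class EventTrace:
    """Multi-channel profile of one event, with its alignment anchor."""

    event_id: int
    times_s: np.ndarray                       # absolute, frame-spaced
    intensity: dict[str, np.ndarray]          # channel -> values (NaN = edge)
    area_um2: np.ndarray | None               # LC3B half-max area, if tracked
    anchor_time_s: float


@dataclasses.dataclass
class MeanProfile:
    """Event-triggered average for one channel: mean ± SEM per time bin."""

    channel: str
    rel_time_s: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray


def half_max_time(values, frame_interval_s: float, t_start_s: float = 0.0,
                  smooth_frames: int = 5, baseline_frames: int = 5) -> float:
    """Time of the first upward half-maximum crossing of a rising trace.

    The trace is smoothed with a ``smooth_frames`` moving average, the
    baseline is the mean of the first ``baseline_frames`` smoothed points,
    and the crossing of baseline + 0.5 × (max − baseline) is located with
    linear interpolation between frames.

    Raises ``FlatTraceError`` if the maximum does not exceed the baseline,
    ``InsufficientDataError`` for traces shorter than 10 points.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 10:
        raise InsufficientDataError("need at least 10 points")
    s = uniform_filter1d(v, size=smooth_frames, mode="nearest")
    baseline = float(s[:baseline_frames].mean())
    peak = float(s.max())
    if peak <= baseline:
        raise FlatTraceError("trace never rises above baseline")
    thr = baseline + 0.5 * (peak - baseline)
    above = np.nonzero(s >= thr)[0]
    i = int(above[0])
    if i == 0:
        frac = 0.0
    else:
        lo, hi = s[i - 1], s[i]
        frac = (thr - lo) / (hi - lo) if hi > lo else 0.0
        i -= 1
        i += frac
    return t_start_s + float(i) * frame_interval_s


def _reference_positions(event: AVEvent, frames: np.ndarray
                         ) -> dict[int, tuple[float, float]]:
    """Best-available spot position per frame: own channel first, then the
    event's other tracks, then nearest known frame."""
    prefer = [t for t in (event.marker_track, event.lc3b_track,
                          event.atg9_track) if t is not None]
    known: dict[int, tuple[float, float]] = {}
    for tr in prefer:
        for f, pos in tr.positions().items():
            known.setdefault(f, pos)
    out = {}
    known_frames = np.array(sorted(known))
    for f in frames:
        if f in known:
            out[f] = known[f]
        else:
            nearest = int(known_frames[np.argmin(np.abs(known_frames - f))])
            out[f] = known[nearest]
    return out


def extract_event_trace(video: Video, event: AVEvent,
                        det_params: DetectionParams = DetectionParams(),
                        pre_frames: int = 10, post_frames: int = 10,
                        normalize: bool = True) -> EventTrace:
    """Measure every channel of ``video`` along the event's trajectory.

    The window spans from ``pre_frames`` before the earliest track birth to
    ``post_frames`` after the latest death (clipped to the video).  For each
    frame the channel's own detection centroid is used when available,
    otherwise the closest position known from the event's other channels.
    Frames whose measurement disk exits the field are recorded as NaN and
    excluded from averaging downstream.
    """
    tracks = [t for t in (event.marker_track, event.lc3b_track,
                          event.atg9_track) if t is not None]
    first = min(t.birth_frame for t in tracks)
    last = max(t.death_frame for t in tracks)
    frames = np.arange(max(0, first - pre_frames),
                       min(video.n_frames, last + post_frames + 1))
    ref = _reference_positions(event, frames)
    own = {t.channel: t.positions() for t in tracks}
    h, w = video.shape
    r = det_params.disk_radius_px
    intensity: dict[str, np.ndarray] = {}
    for ch in video.channels:
        vals = np.empty(len(frames))
        for i, f in enumerate(frames):
            pos = own.get(ch, {}).get(f, ref[f])
            if (pos[0] < r or pos[0] >= w - r or pos[1] < r
                    or pos[1] >= h - r):
                vals[i] = np.nan  # edge-flagged, excluded from averaging
                continue
            vals[i] = detection.measure_trace_point(video, ch, int(f), pos,
                                                    det_params)
        if normalize:
            finite = np.isfinite(vals)
            if finite.any():
                lo = np.nanmin(vals)
                hi = np.nanmax(vals)
                if hi > lo:
                    vals = (vals - lo) / (hi - lo)
                else:
                    vals = np.where(finite, 0.0, np.nan)
        intensity[ch] = vals
    area = None
    if event.lc3b_track is not None:
        area = np.full(len(frames), np.nan)
        lpos = event.lc3b_track.positions()
        for i, f in enumerate(frames):
            if f in lpos:
                area[i] = detection.measure_area(video, "LC3B", int(f),
                                                 lpos[f], det_params)
    times = frames * video.frame_interval_s
    if event.event_class == "productive" and "LC3B" in intensity:
        anchor = half_max_time(intensity["LC3B"], video.frame_interval_s,
                               t_start_s=float(times[0]))
    else:
        anchor = event.marker_track.birth_frame * video.frame_interval_s
    return EventTrace(event_id=event.event_id, times_s=times,
                      intensity=intensity, area_um2=area,
                      anchor_time_s=anchor)


def align_and_average(traces: list[EventTrace], channel: str,
                      frame_interval_s: float) -> MeanProfile:
    """Shift traces so anchors coincide at t = 0 and average per time bin.

    SEM is the sample standard deviation over n (0 where n = 1); bins
    covered by fewer than half of the traces are trimmed.
    """
    if not traces:
        raise ValueError("no traces to average")
    bins: dict[int, list[float]] = {}
    for tr in traces:
        if channel not in tr.intensity:
            raise KeyError(f"trace {tr.event_id} lacks channel {channel!r}")
        rel = tr.times_s - tr.anchor_time_s
        for t, v in zip(rel, tr.intensity[channel]):
            if not np.isfinite(v):
                continue
            bins.setdefault(int(round(t / frame_interval_s)), []).append(v)
    min_n = max(1, len(traces) // 2)
    keys = sorted(k for k, vals in bins.items() if len(vals) >= min_n)
    if not keys:
        raise ValueError("no time bin is covered by enough traces")
    mean = np.array([np.mean(bins[k]) for k in keys])
    n = np.array([len(bins[k]) for k in keys])
    sem = np.array([np.std(bins[k], ddof=1) / np.sqrt(len(bins[k]))
                    if len(bins[k]) > 1 else 0.0 for k in keys])
    return MeanProfile(channel=channel,
                       rel_time_s=np.array(keys) * frame_interval_s,
                       mean=mean, sem=sem, n=n)


def area_growth(video: Video, event: AVEvent,
                det_params: DetectionParams = DetectionParams(),
                growth_threshold_um2: float = 0.1, edge_frames: int = 5
                ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Per-frame half-max area along the event's LC3B track.

    Returns (times_s, areas_um2, grew); ``grew`` is True when the mean of
    the last ``edge_frames`` areas exceeds the mean of the first
    ``edge_frames`` by more than ``growth_threshold_um2`` (≈4 pixels at
    default calibration).
    """
    if event.lc3b_track is None:
        raise ValueError("event has no LC3B track")
    track = event.lc3b_track
    if track.n_frames < 10:
        raise InsufficientDataError("LC3B track shorter than 10 frames")
    frames = track.frames()
    areas = np.array([detection.measure_area(video, "LC3B", int(f),
                                             (d.x, d.y), det_params)
                      for f, d in zip(frames, track.detections)])
    grew = bool(areas[-edge_frames:].mean() - areas[:edge_frames].mean()
                > growth_threshold_um2)
    return frames * video.frame_interval_s, areas, grew


def plot_mean_profile(profiles: list[MeanProfile], path,
                      colors: dict[str, str] | None = None) -> None:
    """Write a PNG of mean ± SEM aligned profiles (one line per channel)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    default = {"LC3B": "tab:green", "ATG13": "tab:red", "ATG5": "tab:red",
               "ATG9": "tab:blue", "WIPI2B": "tab:purple"}
    colors = {**default, **(colors or {})}
    fig, ax = plt.subplots(figsize=(5, 3))
    for p in profiles:
        c = colors.get(p.channel)
        ax.plot(p.rel_time_s, p.mean, label=p.channel, color=c)
        ax.fill_between(p.rel_time_s, p.mean - p.sem, p.mean + p.sem,
                        alpha=0.3, color=c)
    ax.axvline(0.0, ls="--", c="k", lw=0.8)
    ax.set_xlabel("time from alignment anchor (s)")
    ax.set_ylabel("relative intensity")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
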