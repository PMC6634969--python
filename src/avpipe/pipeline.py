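"""Configuration, file formats and the end-to-end pipeline.

All randomness flows from a single root seed, split deterministically per
field with ``numpy.random.SeedSequence``; every CSV/JSON output carries the
configuration hash and root seed in a comment header, so re-running the
same configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats as avstats
from .detection import DetectionParams, SpotDetection, detect_all
from .events import (AVEvent, ClassificationParams, NeuronSummary,
                     assemble_events)
from .simulate import MARKER_CHANNELS, SimConfig, Video, generate_video, \
    write_video
from .tracking import Track, TrackingParams, link_tracks, residence_time
from .traces import align_and_average, extract_event_trace

__all__ = ["PipelineConfig", "config_hash", "process_video", "run_pipeline",
           "write_detections_csv", "read_detections_csv", "write_tracks_csv",
           "write_events_csv", "setup_logging"]

log = logging.getLogger("avpipe")


def setup_logging(logfile: Path | None = None,
                  level: int = logging.INFO) -> None:
    """Log to stderr and optionally to a file, with timestamps."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    log.setLevel(level)
    log.handlers.clear()
    for h in handlers:
        h.setFormatter(fmt)
        log.addHandler(h)


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Everything one reproducible run needs."""

    sim: SimConfig = SimConfig()
    detection: DetectionParams = DetectionParams()
    tracking: TrackingParams = TrackingParams()
    classification: ClassificationParams = ClassificationParams()
    n_fields: int = 5
    seed: int = 0
    save_videos: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimConfig.from_dict(d["sim"])
        if "detection" in d:
            d["detection"] = DetectionParams(**d["detection"])
        if "tracking" in d:
            d["tracking"] = TrackingParams(**d["tracking"])
        if "classification" in d:
            d["classification"] = ClassificationParams(**d["classification"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def config_hash(config: PipelineConfig | SimConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# CSV formats (comment header carries provenance; pandas reads them back
# with comment="#")
# ---------------------------------------------------------------------------

def _write_df(df: pd.DataFrame, path: Path, header: str) -> Path:
    with open(path, "w") as fh:
        fh.write(f"# avpipe {header}\n")
        df.to_csv(fh, index=False)
    return path


def write_detections_csv(detections: list[SpotDetection], path,
                         header: str = "") -> Path:
    rows = [{"frame": d.frame, "channel": d.channel, "x_px": d.x,
             "y_px": d.y, "intensity": d.intensity, "area_um2": d.area_um2,
             "snr": d.peak_snr, "edge_flag": int(d.edge)}
            for d in detections]
    df = pd.DataFrame(rows, columns=["frame", "channel", "x_px", "y_px",
                                     "intensity", "area_um2", "snr",
                                     "edge_flag"])
    return _write_df(df, Path(path), header)


def read_detections_csv(path) -> list[SpotDetection]:
    df = pd.read_csv(path, comment="#")
    return [SpotDetection(frame=int(r.frame), channel=str(r.channel),
                          x=float(r.x_px), y=float(r.y_px),
                          intensity=float(r.intensity),
                          area_um2=float(r.area_um2), peak_snr=float(r.snr),
                          edge=bool(r.edge_flag))
            for r in df.itertuples()]


def write_tracks_csv(tracks: list[Track], path, video_duration_s: float,
                     frame_interval_s: float, header: str = ""
                     ) -> tuple[Path, Path]:
    """Per-detection track table plus per-track summary with residence."""
    path = Path(path)
    rows, summary = [], []
    for tr in tracks:
        for d in tr.detections:
            rows.append({"track_id": tr.track_id, "channel": tr.channel,
                         "frame": d.frame, "x_px": d.x, "y_px": d.y,
                         "intensity": d.intensity, "area_um2": d.area_um2})
        res, cens = residence_time(tr, video_duration_s, frame_interval_s)
        summary.append({"track_id": tr.track_id, "channel": tr.channel,
                        "birth_s": tr.birth_frame * frame_interval_s,
                        "death_s": tr.death_frame * frame_interval_s,
                        "residence_s": res, "censored": int(cens)})
    _write_df(pd.DataFrame(rows, columns=["track_id", "channel", "frame",
                                          "x_px", "y_px", "intensity",
                                          "area_um2"]), path, header)
    spath = path.with_name(path.stem + "_summary.csv")
    _write_df(pd.DataFrame(summary, columns=["track_id", "channel",
                                             "birth_s", "death_s",
                                             "residence_s", "censored"]),
              spath, header)
    return path, spath


def write_events_csv(events: list[AVEvent], path, neuron_id: int = 0,
                     header: str = "") -> Path:
    rows = [{"neuron_id": neuron_id, "event_id": ev.event_id,
             "class": ev.event_class, "onset_s": ev.onset_s,
             "marker_dwell_s": ev.marker_dwell_s,
             "lc3b_recruited": int(ev.lc3b_recruited),
             "atg9_associated": int(ev.atg9_associated),
             "censored": int(ev.censored)}
            for ev in events]
    df = pd.DataFrame(rows, columns=["neuron_id", "event_id", "class",
                                     "onset_s", "marker_dwell_s",
                                     "lc3b_recruited", "atg9_associated",
                                     "censored"])
    return _write_df(df, Path(path), header)


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

def process_video(video: Video, detection: DetectionParams = DetectionParams(),
                  tracking: TrackingParams = TrackingParams(),
                  classification: ClassificationParams = ClassificationParams(),
                  neuron_id: int = 0
                  ) -> tuple[dict[str, list[Track]], NeuronSummary]:
    """detect → track → classify one video; returns tracks and summary."""
    tracks_by_channel: dict[str, list[Track]] = {}
    for ch in video.channels:
        per_frame = detect_all(video, ch, detection)
        tracks_by_channel[ch] = link_tracks(
            per_frame, n_frames=video.n_frames,
            pixel_size_um=video.pixel_size_um, params=tracking)
    marker = next((c for c in video.channels if c in MARKER_CHANNELS), None)
    if marker is None:
        marker = video.channels[0]
    summary = assemble_events(tracks_by_channel, marker, video.duration_s,
                              video.frame_interval_s, video.pixel_size_um,
                              classification, neuron_id=neuron_id)
    return tracks_by_channel, summary


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """simulate → detect → track → classify → traces → stats for a cohort.

    Writes per-stage CSVs and a stats JSON into ``out_dir``; every output
    carries the config hash and root seed.  Returns the stats dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    header = f"config_hash={chash} seed={config.seed}"
    seeds = np.random.SeedSequence(config.seed).generate_state(
        config.n_fields) % (2 ** 31)
    all_events, summaries, traces = [], [], []
    all_dets, all_tracks = [], []
    t0 = time.perf_counter()
    for field, field_seed in enumerate(seeds):
        cfg = dataclasses.replace(config.sim, seed=int(field_seed))
        video, truth = generate_video(cfg)
        if config.save_videos:
            write_video(video, out / f"field{field:03d}.tif", cfg)
        tracks_by_channel, summary = process_video(
            video, config.detection, config.tracking, config.classification,
            neuron_id=field)
        summaries.append(summary)
        for ch, trs in tracks_by_channel.items():
            all_tracks.extend(trs)
            for tr in trs:
                all_dets.extend(tr.detections)
        for ev in summary.events:
            all_events.append((field, ev))
            if ev.event_class in ("productive", "stalled"):
                try:
                    traces.append(extract_event_trace(video, ev,
                                                      config.detection))
                except ValueError:
                    pass
        log.info("field %d: rate %.3f/min, %d productive / %d stalled / "
                 "%d ambiguous", field, summary.biogenesis_rate_per_min,
                 summary.n_productive, summary.n_stalled,
                 summary.n_ambiguous)
    log.info("simulate+detect+track+classify: %.1f s over %d fields",
             time.perf_counter() - t0, config.n_fields)

    write_detections_csv(all_dets, out / "detections.csv", header)
    write_tracks_csv(all_tracks, out / "tracks.csv", config.sim.duration_s,
                     config.sim.frame_interval_s, header)
    ev_rows = []
    for field, ev in all_events:
        ev_rows.append({"neuron_id": field, "event_id": ev.event_id,
                        "class": ev.event_class, "onset_s": ev.onset_s,
                        "marker_dwell_s": ev.marker_dwell_s,
                        "lc3b_recruited": int(ev.lc3b_recruited),
                        "atg9_associated": int(ev.atg9_associated),
                        "censored": int(ev.censored)})
    _write_df(pd.DataFrame(ev_rows, columns=["neuron_id", "event_id",
                                             "class", "onset_s",
                                             "marker_dwell_s",
                                             "lc3b_recruited",
                                             "atg9_associated", "censored"]),
              out / "events.csv", header)
    sum_rows = [{"neuron_id": s.neuron_id, "duration_s": s.duration_s,
                 "n_denovo_lc3b": s.n_denovo_lc3b,
                 "rate_per_min": s.biogenesis_rate_per_min,
                 "n_productive": s.n_productive, "n_stalled": s.n_stalled,
                 "n_ambiguous": s.n_ambiguous} for s in summaries]
    _write_df(pd.DataFrame(sum_rows), out / "summary.csv", header)

    # aligned event-triggered averages over classified events
    prof_rows = []
    aligned = [t for t in traces if t is not None]
    if aligned:
        for ch in config.sim.channels:
            try:
                prof = align_and_average(aligned, ch,
                                         config.sim.frame_interval_s)
            except (ValueError, KeyError):
                continue
            for t, m, s, n in zip(prof.rel_time_s, prof.mean, prof.sem,
                                  prof.n):
                prof_rows.append({"channel": ch, "rel_time_s": t, "mean": m,
                                  "sem": s, "n": n})
    _write_df(pd.DataFrame(prof_rows, columns=["channel", "rel_time_s",
                                               "mean", "sem", "n"]),
              out / "profiles.csv", header)

    n_prod = sum(s.n_productive for s in summaries)
    n_stall = sum(s.n_stalled for s in summaries)
    rates = [s.biogenesis_rate_per_min for s in summaries]
    results = {
        "config_hash": chash,
        "seed": config.seed,
        "n_fields": config.n_fields,
        "mean_rate_per_min": float(np.mean(rates)),
        "sem_rate_per_min": float(np.std(rates, ddof=1)
                                  / np.sqrt(len(rates))) if len(rates) > 1
        else 0.0,
        "n_productive": n_prod,
        "n_stalled": n_stall,
        "n_ambiguous": sum(s.n_ambiguous for s in summaries),
    }
    if n_prod + n_stall > 0:
        frac = n_prod / (n_prod + n_stall)
        lo, hi = avstats.proportion_ci(n_prod, n_prod + n_stall)
        results["productive_fraction"] = frac
        results["productive_fraction_ci95"] = [lo, hi]
    (out / "stats.json").write_text(json.dumps(results, indent=1,
                                               sort_keys=True))
    return results
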