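"""End-to-end orchestration: simulate/load → beats → PTT/BP/HR →
respiration → hemoglobin → breath-hold epochs → reports.

Every run is deterministic given (config, seed); all outputs are
stamped with a hash of the fully resolved configuration so result
bundles are self-describing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .core import ConfigError, EventSeries, Recording, TimeSeries
from .epochs import (AveragedResponse, average_epochs, baseline_correct,
                     beat_series_to_timeseries, epoch)
from .filtering import zero_phase_filter
from .io import read_recording, write_markers, write_recording
from .nirs import NIRSGeometry, compute_delta_od, mbll_inverse
from .pttbp import match_beat_series, meg_ptt_bp, ptt_bp_pipeline
from .respiration import detect_breath_holds, extract_respiration
from .simulate import SimulationConfig, simulate_recording

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """One self-contained description of a pipeline run.

    Exactly one of ``recording_path`` / ``simulation`` must be given.
    """

    output_dir: str
    recording_path: str | None = None
    simulation: SimulationConfig | None = None
    seed: int | None = None              # overrides simulation.seed when set

    chest_channel: str = "chest"
    neck_channel: str = "neck"
    meg_channel: str | None = "meg"      # None disables the MEG variant
    nirs_channels: tuple[str, str] | None = ("nirs_660", "nirs_850")
    hold_marker: str = "hold_onset"

    lag_window: tuple[float, float] = (0.02, 0.4)
    respiration_cutoff: float = 0.5      # Hz
    nirs_baseline_window: tuple[float, float] = (0.0, 30.0)
    nirs_geometry: NIRSGeometry = field(default_factory=NIRSGeometry)
    epoch_tmin: float = -5.0
    epoch_tmax: float = 80.0
    beat_resample_rate: float = 4.0      # Hz grid for per-beat series

    def __post_init__(self) -> None:
        if (self.recording_path is None) == (self.simulation is None):
            raise ConfigError("exactly one of recording_path / simulation must be set")

    def resolved(self) -> dict:
        """JSON-able echo of every analysis parameter (defaults included).

        ``output_dir`` is excluded: the hash describes the analysis, not
        where its results are written.
        """
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return enc(dataclasses.asdict(obj))
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            return obj
        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)
                if f.name != "output_dir"}

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    output_dir: str
    report: dict
    files: dict[str, str]
    averaged: dict[str, AveragedResponse]


def _write_tsv(path: str, columns: dict[str, np.ndarray]) -> None:
    keys = list(columns)
    n = len(next(iter(columns.values())))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(keys) + "\n")
        for i in range(n):
            fh.write("\t".join("%.9g" % columns[k][i] for k in keys) + "\n")


def _decimated(ts: TimeSeries, rate: float) -> TimeSeries:
    """Anti-aliased resampling of a slow series onto a coarse grid."""
    if rate >= ts.rate:
        return ts
    smooth = zero_phase_filter(ts.data, ts.rate, None, min(rate / 2 * 0.8, ts.rate / 2 * 0.9))
    grid = np.arange(ts.start, ts.end - 0.5 / ts.rate, 1.0 / rate)
    return TimeSeries(np.interp(grid, ts.times, smooth), rate=rate, start=ts.start,
                      label=ts.label, units=ts.units)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every analysis stage and write the result bundle.

    Outputs (under ``cfg.output_dir``): ``per_beat.tsv`` (time, ptt,
    bp), ``heart_rate.tsv``, ``meg_bp.tsv`` (when a MEG channel is
    configured), ``respiration.csv`` recording, ``hemoglobin.csv``
    recording, ``holds.markers.tsv``, ``averaged_<series>.tsv`` per
    epoched series, ``report.json`` (QC counts, config echo + hash) and
    ``pipeline.log``.
    """
    os.makedirs(cfg.output_dir, exist_ok=True)
    log: list[str] = []
    files: dict[str, str] = {}
    report: dict = {"config": cfg.resolved(), "config_hash": cfg.config_hash(),
                    "stages": {}}

    def out(name: str) -> str:
        path = os.path.join(cfg.output_dir, name)
        files[name] = path
        return path

    if cfg.simulation is not None:
        sim = cfg.simulation
        if cfg.seed is not None:
            sim = dataclasses.replace(sim, seed=cfg.seed)
        rec, _gt = simulate_recording(sim)
        log.append(f"simulated session: {sim.duration:.0f} s, seed {sim.seed}")
    else:
        rec = read_recording(cfg.recording_path)
        log.append(f"loaded recording {cfg.recording_path}")

    chest = rec.channel(cfg.chest_channel)
    neck = rec.channel(cfg.neck_channel)

    # --- chest→neck PTT / BP / HR -------------------------------------
    bp, ptt, hr, qc = ptt_bp_pipeline(chest, neck, lag_window=cfg.lag_window)
    report["stages"]["ptt_bp"] = qc
    log.append(f"chest beats: {qc['beats_detected']}, used for PTT: {qc['beats_used']}")
    _write_tsv(out("per_beat.tsv"),
               {"time": ptt.beat_times.times, "ptt": ptt.ptt, "bp": bp.bp})
    _write_tsv(out("heart_rate.tsv"), {"time": hr.times, "bpm": hr.bpm})

    # --- MEG-proximal variant -----------------------------------------
    meg_bp = None
    if cfg.meg_channel and cfg.meg_channel in rec.channels:
        meg_bp, meg_ptt, _meg_hr, meg_qc = meg_ptt_bp(rec.channel(cfg.meg_channel), neck)
        report["stages"]["meg_ptt_bp"] = meg_qc
        ia, ib = match_beat_series(bp.beat_times.times, meg_bp.beat_times.times)
        if ia.size >= 3:
            r = float(np.corrcoef(bp.bp[ia], meg_bp.bp[ib])[0, 1])
            report["stages"]["meg_ptt_bp"]["corr_with_chest_bp"] = r
            log.append(f"MEG-based BP vs chest-based BP: r = {r:.3f} on {ia.size} beats")
        _write_tsv(out("meg_bp.tsv"),
                   {"time": meg_bp.beat_times.times, "ptt": meg_ptt.ptt, "bp": meg_bp.bp})

    # --- respiration and holds ----------------------------------------
    resp = extract_respiration(chest, cutoff=cfg.respiration_cutoff)
    write_recording(Recording(channels={resp.label: resp},
                              metadata={"config_hash": cfg.config_hash()}),
                    out("respiration.csv"))
    if cfg.hold_marker in rec.markers:
        onsets = rec.markers[cfg.hold_marker].times
        hold_source = "marker"
    else:
        holds = detect_breath_holds(resp)
        onsets = np.array([h.onset for h in holds])
        hold_source = "detected"
    report["stages"]["holds"] = {"n": int(onsets.size), "source": hold_source,
                                 "onsets": [float(t) for t in onsets]}
    log.append(f"breath holds ({hold_source}): {onsets.size}")
    if onsets.size:
        write_markers({"hold_onset": EventSeries(onsets, label="hold_onset")},
                      out("holds.markers.tsv"))

    # --- NIRS hemoglobin ----------------------------------------------
    hemo = None
    if cfg.nirs_channels and all(c in rec.channels for c in cfg.nirs_channels):
        dod1 = compute_delta_od(rec.channel(cfg.nirs_channels[0]), cfg.nirs_baseline_window)
        dod2 = compute_delta_od(rec.channel(cfg.nirs_channels[1]), cfg.nirs_baseline_window)
        hemo = mbll_inverse(dod1, dod2, cfg.nirs_geometry)
        hrate = cfg.beat_resample_rate
        hb_chans = {ts.label: _decimated(ts, hrate)
                    for ts in (hemo.delta_hbo, hemo.delta_hb, hemo.delta_hbt)}
        write_recording(Recording(channels=hb_chans,
                                  metadata={"config_hash": cfg.config_hash(),
                                            "units": "uM"}),
                        out("hemoglobin.csv"))
        log.append("NIRS converted to hemoglobin concentration changes")

    # --- breath-hold epoch averages -----------------------------------
    averaged: dict[str, AveragedResponse] = {}
    if onsets.size:
        events = EventSeries(onsets, label="hold_onset")
        series: dict[str, TimeSeries] = {
            "ptt": beat_series_to_timeseries(ptt.beat_times.times, ptt.ptt,
                                             cfg.beat_resample_rate, 0.0, rec.duration,
                                             label="ptt", units="s"),
            "bp": beat_series_to_timeseries(bp.beat_times.times, bp.bp,
                                            cfg.beat_resample_rate, 0.0, rec.duration,
                                            label="bp", units=bp.units),
            "hr": beat_series_to_timeseries(hr.times, hr.bpm, cfg.beat_resample_rate,
                                            0.0, rec.duration, label="hr", units="bpm"),
        }
        if hemo is not None:
            series["hbo"] = _decimated(hemo.delta_hbo, cfg.beat_resample_rate)
            series["hb"] = _decimated(hemo.delta_hb, cfg.beat_resample_rate)
        epoch_counts = {}
        for name, ts in series.items():
            es = epoch(ts, events, cfg.epoch_tmin, cfg.epoch_tmax)
            av = average_epochs(baseline_correct(es))
            averaged[name] = av
            epoch_counts[name] = es.n_epochs
            _write_tsv(out(f"averaged_{name}.tsv"),
                       {"time": av.times, "mean": av.mean, "sd": av.sd})
        report["stages"]["epochs"] = {"window": [cfg.epoch_tmin, cfg.epoch_tmax],
                                      "n_epochs": epoch_counts}
        log.append(f"epoch averages over {epoch_counts} repeats")

    with open(out("report.json"), "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(out("pipeline.log"), "w", encoding="utf-8") as fh:
        fh.write("\n".join(log) + "\n")
    return PipelineResult(output_dir=cfg.output_dir, report=report, files=files,
                          averaged=averaged)
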