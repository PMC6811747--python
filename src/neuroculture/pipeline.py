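"""Pipeline driver: configuration, staged execution, run manifest.

``run_pipeline`` executes simulate (optional) → filter → detect → sort
→ rates → bursts → synchrony → classify → dose (optional) in order,
writing each stage's outputs and a manifest of parameter echoes and
output checksums.  Identical config + seed give identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as ncio
from . import mea, netactivity
from .containers import RateSeries
from .doseresponse import build_experiment, fit_dose_lme, suppression_summary
from .synthdata import (
    DrugProtocol,
    MEARenderConfig,
    NetworkSimConfig,
    apply_drug_protocol,
    render_mea,
    simulate_spike_trains,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "write_reports"]

log = logging.getLogger("neuroculture")


@dataclass
class PipelineConfig:
    """All stage parameters for one pipeline run.

    Fully serializable: ``to_json``/``from_json`` (and YAML) round-trip
    the config exactly.
    """

    culture: str = "Chx10"  # {HB9 | Chx10 | coculture}
    out_dir: str = "run_out"
    input_recording: str | None = None  # path; None => simulate
    # simulate stage
    sim: NetworkSimConfig = field(default_factory=NetworkSimConfig)
    render: MEARenderConfig = field(default_factory=MEARenderConfig)
    drug: DrugProtocol | None = None
    # filter stage
    filter_order: int = 4
    filter_cutoff: float = 400.0
    # detect stage
    k: float = 5.0
    dead_time: float = 0.001
    # rate stage
    bin_width: float = 0.1
    # bursts
    burst_factor: float = 5.0
    burst_min_duration: float = 0.1
    burst_merge_gap: float = 0.2
    activity_threshold: float = 0.1
    # classification
    min_iso_events: int = 3
    min_burst_frac: float = 0.5
    # synchrony
    max_lag: float | None = None
    # dose fit
    dose_window: tuple[float, float] | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        def listify(obj):
            if isinstance(obj, tuple):
                return [listify(v) for v in obj]
            if isinstance(obj, list):
                return [listify(v) for v in obj]
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            return obj

        return listify(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("sim"), dict):
            sim = dict(d["sim"])
            if isinstance(sim.get("ibi_range"), list):
                sim["ibi_range"] = tuple(sim["ibi_range"])
            d["sim"] = NetworkSimConfig(**sim)
        if isinstance(d.get("render"), dict):
            d["render"] = MEARenderConfig(**d["render"])
        if isinstance(d.get("drug"), dict):
            d["drug"] = DrugProtocol(**d["drug"])
        if isinstance(d.get("dose_window"), list):
            d["dose_window"] = tuple(d["dose_window"])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(s))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_json(text)


@dataclass
class RunManifest:
    """Record of one run: config snapshot, per-stage outputs, checksums."""

    config: dict
    version: str
    stages: list[str]
    checksums: dict[str, str]
    started: float
    finished: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the configured stages end to end, returning the manifest."""
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.time()
    stages: list[str] = []
    outputs: list[Path] = []
    results: dict = {}

    def stage(name):
        log.info("stage %s", name)
        stages.append(name)

    try:
        stage("simulate" if config.input_recording is None else "load")
        if config.input_recording is None:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            truth = simulate_spike_trains(sim)
            if config.drug is not None:
                truth = apply_drug_protocol(truth, config.drug, seed=config.seed + 1)
            render = dataclasses.replace(config.render, seed=config.seed + 2)
            raw = render_mea(truth, render)
            ncio.write_ground_truth_json(truth, out / "ground_truth.json")
            outputs.append(out / "ground_truth.json")
        else:
            path = config.input_recording
            raw = (
                ncio.read_mc_text(path)
                if str(path).endswith(".txt")
                else ncio.read_recording_h5(path)
            )
    except Exception as exc:
        raise StageError(stages[-1], exc) from exc

    try:
        stage("filter")
        log.info("bessel order=%d cutoff=%g", config.filter_order, config.filter_cutoff)
        filtered = mea.highpass_filter(raw, config.filter_order, config.filter_cutoff)
    except Exception as exc:
        raise StageError("filter", exc) from exc

    try:
        stage("detect")
        events = mea.detect_spikes(filtered, k=config.k, dead_time=config.dead_time)
        stage("sort")
        polylines = mea.propose_polylines(events)
        events = mea.sort_spikes(events, polylines)
        trains = mea.events_to_trains(events, duration=raw.duration)
        ncio.write_spike_csv(trains, out / "spikes.csv")
        outputs.append(out / "spikes.csv")
    except Exception as exc:
        raise StageError(stages[-1], exc) from exc

    try:
        stage("rates")
        rates = {key: mea.compute_rate(tr, config.bin_width) for key, tr in trains.items()}
        ncio.write_rate_csv(list(rates.values()), out / "rates.csv")
        outputs.append(out / "rates.csv")
    except Exception as exc:
        raise StageError("rates", exc) from exc

    try:
        stage("bursts")
        pop = netactivity.population_rate(
            list(trains.values()), config.bin_width, config.activity_threshold
        )
        bursts = netactivity.detect_network_bursts(
            pop,
            config.burst_factor,
            config.burst_min_duration,
            config.burst_merge_gap,
            trains=list(trains.values()),
        )
        ncio.write_bursts_csv(bursts, out / "bursts.csv")
        outputs.append(out / "bursts.csv")
        results["bursts"] = bursts
        results["population_rate_hz"] = float(pop.series.values.mean())
        results["duration_s"] = raw.duration
    except Exception as exc:
        raise StageError("bursts", exc) from exc

    try:
        stage("synchrony")
        if len(rates) >= 2:
            sync = netactivity.synchrony(list(rates.values()), max_lag=config.max_lag)
            np.savetxt(out / "synchrony.csv", sync.matrix, delimiter=",")
            outputs.append(out / "synchrony.csv")
            results["mean_pairwise_correlation"] = sync.mean_pairwise
        else:
            results["mean_pairwise_correlation"] = None
    except Exception as exc:
        raise StageError("synchrony", exc) from exc

    try:
        stage("classify")
        events_by_cell = {f"{ch}:{unit}": tr.times for (ch, unit), tr in trains.items()}
        classes = netactivity.classify_activity(
            events_by_cell, results["bursts"], config.min_iso_events, config.min_burst_frac
        )
        summary = netactivity.classification_summary(
            classes_by_group={config.culture: classes}
        )
        summary.to_csv(out / "classification.csv", index=False)
        outputs.append(out / "classification.csv")
        results["classes"] = classes
    except Exception as exc:
        raise StageError("classify", exc) from exc

    if config.drug is not None:
        try:
            stage("dose")
            normed: dict[str, RateSeries] = {}
            for key, s in rates.items():
                try:
                    normed[f"{key[0]}:{key[1]}"] = mea.normalize_rate(s)
                except ValueError:
                    continue  # silent baseline: excluded
            if len(normed) >= 2:
                exp = build_experiment(
                    {k: v for k, v in normed.items()}, config.drug
                )
                fit = fit_dose_lme(exp, window=config.dose_window)
                (out / "dose_fit.json").write_text(json.dumps(fit.to_dict(), indent=2))
                outputs.append(out / "dose_fit.json")
                results["dose_fit"] = fit
                results["suppression"] = suppression_summary(exp)
        except Exception as exc:
            raise StageError("dose", exc) from exc

    write_reports(results, out, culture=config.culture)
    outputs.append(out / "summary.json")

    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        stages=stages,
        checksums={p.name: _sha256(p) for p in outputs},
        started=started,
        finished=time.time(),
    )
    # written atomically: full serialization first, then a single rename
    tmp = out / ".manifest.tmp"
    tmp.write_text(manifest.to_json())
    tmp.replace(out / "manifest.json")
    return manifest


def write_reports(results: dict, out_dir: str | Path, culture: str = "culture") -> None:
    """Per-culture summary (rates, burst stats, synchrony, classes, dose fit)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bursts = results.get("bursts", [])
    ibis = netactivity.inter_burst_intervals(bursts)
    summary = {
        "culture": culture,
        "mean_population_rate_hz": results.get("population_rate_hz"),
        "n_bursts": len(bursts),
        "burst_rate_per_min": (
            60.0 * len(bursts) / results["duration_s"]
            if results.get("duration_s")
            else None
        ),
        "mean_burst_duration_s": (
            float(np.mean([b.duration for b in bursts])) if bursts else None
        ),
        "mean_inter_burst_interval_s": float(ibis.mean()) if ibis.size else None,
        "mean_pairwise_correlation": results.get("mean_pairwise_correlation"),
        "classification": None,
        "dose_fit": None,
        "suppression_ratio": None,
    }
    if "classes" in results:
        counts = {c: 0 for c in netactivity.ACTIVITY_CLASSES}
        for v in results["classes"].values():
            counts[v] += 1
        summary["classification"] = counts
    if results.get("dose_fit") is not None:
        summary["dose_fit"] = results["dose_fit"].to_dict()
    if results.get("suppression") is not None:
        summary["suppression_ratio"] = results["suppression"].ratio
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
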