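"""File formats: HDF5 recording containers, the MC-export text dialect,
and the tidy CSV/JSON interchange files used between pipeline stages.

The text dialect is defined by this package (the original acquisition
export format is proprietary): comment-prefixed header lines carrying
the sampling rate and channel ids, then one tab-separated sample row
per time point.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import NetworkBurst, RateSeries, RawRecording, ROITrace, SpikeTrain
from .patch import StepTraceFamily
from .synthdata import SimGroundTruth

__all__ = [
    "write_recording_h5",
    "read_recording_h5",
    "write_mc_text",
    "read_mc_text",
    "write_spike_csv",
    "read_spike_csv",
    "write_rate_csv",
    "read_rate_csv",
    "write_ground_truth_json",
    "read_ground_truth_json",
    "write_roi_traces_csv",
    "read_roi_traces_csv",
    "write_step_family_csv",
    "read_step_family_csv",
    "write_bursts_csv",
    "read_tiff_stack",
    "write_tiff_stack",
    "read_rois_json",
    "write_rois_json",
]


# ---------------------------------------------------------------------------
# recordings


def write_recording_h5(rec: RawRecording, path: str | Path) -> None:
    """HDF5 container: /data (channels x samples), /meta attrs."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.samples.astype(np.float32))
        meta = f.create_group("meta")
        meta.attrs["sampling_rate"] = rec.sampling_rate
        meta.attrs["unit"] = rec.unit
        meta.attrs["channel_ids"] = [str(c) for c in rec.channel_ids]


def read_recording_h5(path: str | Path) -> RawRecording:
    with h5py.File(path, "r") as f:
        data = f["data"][...]
        meta = f["meta"].attrs
        ids = [c.decode() if isinstance(c, bytes) else str(c) for c in meta["channel_ids"]]
        return RawRecording(
            samples=data,
            sampling_rate=float(meta["sampling_rate"]),
            channel_ids=ids,
            unit=str(meta["unit"]),
        )


def write_mc_text(rec: RawRecording, path: str | Path, fmt: str = "%.4f") -> None:
    """MC-export-style text: header lines, then tab-separated sample rows."""
    with open(path, "w") as f:
        f.write("# neuroculture MC-export text v1\n")
        f.write(f"# sampling_rate_hz\t{rec.sampling_rate:g}\n")
        f.write(f"# unit\t{rec.unit}\n")
        f.write("# channels\t" + "\t".join(rec.channel_ids) + "\n")
        np.savetxt(f, rec.samples.T, fmt=fmt, delimiter="\t")


def read_mc_text(path: str | Path) -> RawRecording:
    """Parse the text dialect; malformed headers or ragged rows raise
    with the offending line number."""
    sampling_rate = None
    unit = "uV"
    channel_ids: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if parts[0] == "sampling_rate_hz" and len(parts) > 1:
                    sampling_rate = float(parts[1])
                elif parts[0] == "unit" and len(parts) > 1:
                    unit = parts[1]
                elif parts[0] == "channels":
                    channel_ids = parts[1:]
                continue
            if sampling_rate is None or channel_ids is None:
                raise ValueError(
                    f"line {lineno}: data before a complete header "
                    "(need sampling_rate_hz and channels)"
                )
            fields = line.split("\t")
            if len(fields) != len(channel_ids):
                raise ValueError(
                    f"line {lineno}: expected {len(channel_ids)} columns, "
                    f"got {len(fields)}"
                )
            try:
                rows.append([float(x) for x in fields])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric sample: {exc}") from None
    if sampling_rate is None or channel_ids is None:
        raise ValueError("missing header (sampling_rate_hz / channels)")
    data = np.asarray(rows, dtype=np.float64).T if rows else np.empty((len(channel_ids), 0))
    return RawRecording(
        samples=data, sampling_rate=sampling_rate, channel_ids=channel_ids, unit=unit
    )


# ---------------------------------------------------------------------------
# spikes and rates


def write_spike_csv(trains: dict[tuple[str, str], SpikeTrain] | list[SpikeTrain],
                    path: str | Path) -> None:
    if isinstance(trains, dict):
        trains = list(trains.values())
    rows = [
        (tr.channel_id, tr.unit or "unit1", t)
        for tr in trains
        for t in tr.times
    ]
    pd.DataFrame(rows, columns=["channel", "unit", "time_s"]).to_csv(path, index=False)


def read_spike_csv(path: str | Path, duration: float) -> dict[tuple[str, str], SpikeTrain]:
    df = pd.read_csv(path)
    out: dict[tuple[str, str], SpikeTrain] = {}
    for (ch, unit), grp in df.groupby(["channel", "unit"]):
        out[(str(ch), str(unit))] = SpikeTrain(
            times=grp["time_s"].to_numpy(), duration=duration,
            channel_id=str(ch), unit=str(unit),
        )
    return out


def write_rate_csv(series: dict[str, RateSeries] | list[RateSeries], path: str | Path) -> None:
    if isinstance(series, dict):
        series = list(series.values())
    rows = []
    for s in series:
        for i, v in enumerate(s.values):
            rows.append((s.channel_id, s.bin_width, s.start_time + (i + 0.5) * s.bin_width,
                         v, int(s.normalized)))
    pd.DataFrame(
        rows, columns=["channel", "bin_width_s", "t_mid_s", "value", "normalized"]
    ).to_csv(path, index=False)


def read_rate_csv(path: str | Path) -> dict[str, RateSeries]:
    df = pd.read_csv(path)
    out: dict[str, RateSeries] = {}
    for ch, grp in df.groupby("channel"):
        grp = grp.sort_values("t_mid_s")
        bw = float(grp["bin_width_s"].iloc[0])
        start = float(grp["t_mid_s"].iloc[0]) - 0.5 * bw
        out[str(ch)] = RateSeries(
            values=grp["value"].to_numpy(), bin_width=bw, start_time=start,
            channel_id=str(ch), normalized=bool(grp["normalized"].iloc[0]),
        )
    return out


# ---------------------------------------------------------------------------
# ground truth


def write_ground_truth_json(truth: SimGroundTruth, path: str | Path) -> None:
    payload = {
        "duration": truth.duration,
        "phenotypes": truth.phenotypes,
        "unit_times": [t.tolist() for t in truth.unit_times],
        "burst_windows": [list(w) for w in truth.burst_windows],
        "joined_bursts": [sorted(j) for j in truth.joined_bursts],
        "drug_effect": truth.drug_effect,
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth_json(path: str | Path) -> SimGroundTruth:
    p = json.loads(Path(path).read_text())
    return SimGroundTruth(
        unit_times=[np.asarray(t, dtype=np.float64) for t in p["unit_times"]],
        phenotypes=list(p["phenotypes"]),
        burst_windows=[tuple(w) for w in p["burst_windows"]],
        duration=float(p["duration"]),
        joined_bursts=[set(j) for j in p.get("joined_bursts", [])],
        drug_effect=p.get("drug_effect"),
    )


# ---------------------------------------------------------------------------
# calcium and patch

def write_roi_traces_csv(traces: list[ROITrace], path: str | Path) -> None:
    rows = []
    for tr in traces:
        t = tr.times()
        corr = tr.corrected if tr.corrected is not None else np.full(tr.n_frames, np.nan)
        norm = tr.normalized if tr.normalized is not None else np.full(tr.n_frames, np.nan)
        for i in range(tr.n_frames):
            rows.append((tr.roi_id, i, t[i], tr.raw[i], corr[i], norm[i]))
    pd.DataFrame(
        rows, columns=["roi_id", "frame", "t_s", "raw", "corrected", "normalized"]
    ).to_csv(path, index=False)


def read_roi_traces_csv(path: str | Path) -> list[ROITrace]:
    df = pd.read_csv(path)
    out = []
    for roi_id, grp in df.groupby("roi_id", sort=False):
        grp = grp.sort_values("frame")
        t = grp["t_s"].to_numpy()
        fi = float(t[1] - t[0]) if t.size > 1 else 0.15
        tr = ROITrace(roi_id=str(roi_id), frame_interval=fi, raw=grp["raw"].to_numpy())
        if grp["corrected"].notna().all():
            tr.corrected = grp["corrected"].to_numpy()
        if grp["normalized"].notna().all():
            tr.normalized = grp["normalized"].to_numpy()
        out.append(tr)
    return out


def write_step_family_csv(family: StepTraceFamily, path: str | Path) -> None:
    """Wide CSV: time_s, then one response column per command level."""
    t = family.time()
    df = pd.DataFrame({"time_s": t})
    for level, trace in zip(family.levels, family.traces):
        df[f"level_{level:g}"] = trace
    header = (
        f"# mode={family.mode} sampling_rate={family.sampling_rate:g} "
        f"onset={family.onset:g} offset={family.offset:g}\n"
    )
    with open(path, "w") as f:
        f.write(header)
        df.to_csv(f, index=False)


def read_step_family_csv(path: str | Path) -> StepTraceFamily:
    with open(path) as f:
        header = f.readline()
        if not header.startswith("#"):
            raise ValueError("missing step-family header line")
        meta = dict(kv.split("=") for kv in header[1:].split())
        df = pd.read_csv(f)
    level_cols = [c for c in df.columns if c.startswith("level_")]
    levels = np.array([float(c.split("_", 1)[1]) for c in level_cols])
    order = np.argsort(levels)
    traces = np.vstack([df[level_cols[i]].to_numpy() for i in order])
    return StepTraceFamily(
        mode=meta["mode"],
        levels=levels[order],
        traces=traces,
        sampling_rate=float(meta["sampling_rate"]),
        onset=float(meta["onset"]),
        offset=float(meta["offset"]),
    )


def read_tiff_stack(path: str | Path) -> np.ndarray:
    """Multi-frame single-channel TIFF as a (frames, height, width) array."""
    import tifffile

    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"expected a single-channel stack, got shape {stack.shape}")
    return stack


def write_tiff_stack(stack: np.ndarray, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(stack), photometric="minisblack")


def read_rois_json(path: str | Path) -> list:
    """ROI polygons: [{"roi_id", "vertices" [[x, y], ...], "cfp_value"?,
    "gfp_value"?}, ...]."""
    from .calcium import ROI

    payload = json.loads(Path(path).read_text())
    return [
        ROI(
            roi_id=str(r["roi_id"]),
            vertices=np.asarray(r["vertices"], dtype=np.float64),
            cfp_value=r.get("cfp_value"),
            gfp_value=r.get("gfp_value"),
        )
        for r in payload
    ]


def write_rois_json(rois: list, path: str | Path) -> None:
    payload = [
        {
            "roi_id": r.roi_id,
            "vertices": r.vertices.tolist(),
            "cfp_value": r.cfp_value,
            "gfp_value": r.gfp_value,
        }
        for r in rois
    ]
    Path(path).write_text(json.dumps(payload))


def write_bursts_csv(bursts: list[NetworkBurst], path: str | Path) -> None:
    pd.DataFrame(
        [(b.start, b.end, b.participation) for b in bursts],
        columns=["start_s", "end_s", "participation"],
    ).to_csv(path, index=False)
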