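"""HDF5 / TIFF / JSON serialisation of the package's containers.

Layouts
-------
RoiTraceSet HDF5::

    /traces/f_roi          (n_roi, n_frames)
    /traces/f_neuropil     (n_roi, n_frames)
    /schedule              event table (onset_s, duration_ms, ...)
    /truth                 per-neuron ground-truth table (if present)
    attrs: frame_rate, r_true, paradigm, soa

TrialAlignedResponses HDF5::

    /values                (n_trials, n_frames)
    /frame_offsets         (n_frames,)
    /metadata/<column>     one dataset per trial-metadata column
    attrs: frame_rate, baseline_frames, qc_json
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np
import pandas as pd
import tifffile

from .classify import BfMap
from .paradigms import StimulusSchedule, ToneEvent
from .preprocess import TrialAlignedResponses
from .synthetic import NeuronGroundTruth, RoiTraceSet

_SCHED_COLS = ("onset_s", "duration_ms", "frequency_hz", "photostim")


def _write_schedule(group: h5py.Group, schedule: StimulusSchedule) -> None:
    df = schedule.to_frame()
    for c in _SCHED_COLS:
        group.create_dataset(c, data=df[c].to_numpy(dtype=float))
    group.create_dataset(
        "role", data=np.array(df["role"], dtype=h5py.string_dtype()))
    bp = df["block_position"].fillna(-1).to_numpy(dtype=int)
    group.create_dataset("block_position", data=bp)
    group.attrs["paradigm"] = schedule.paradigm
    group.attrs["soa"] = schedule.soa
    if schedule.f_odd is not None:
        group.attrs["f_odd"] = schedule.f_odd
    if schedule.seed is not None:
        group.attrs["seed"] = schedule.seed


def _read_schedule(group: h5py.Group) -> StimulusSchedule:
    roles = [r.decode() if isinstance(r, bytes) else str(r)
             for r in group["role"][()]]
    bp = group["block_position"][()]
    events = tuple(
        ToneEvent(
            onset_s=float(o), duration_ms=float(d), frequency_hz=float(f),
            role=roles[i], photostim=bool(ps),
            block_position=None if bp[i] < 0 else int(bp[i]),
        )
        for i, (o, d, f, ps) in enumerate(zip(
            group["onset_s"][()], group["duration_ms"][()],
            group["frequency_hz"][()], group["photostim"][()]))
    )
    return StimulusSchedule(
        events=events, paradigm=str(group.attrs["paradigm"]),
        soa=float(group.attrs["soa"]),
        seed=int(group.attrs["seed"]) if "seed" in group.attrs else None,
        f_odd=float(group.attrs["f_odd"]) if "f_odd" in group.attrs else None,
    )


def save_roi_traces(path, ts: RoiTraceSet) -> None:
    with h5py.File(path, "w") as f:
        tr = f.create_group("traces")
        tr.create_dataset("f_roi", data=ts.f_roi)
        tr.create_dataset("f_neuropil", data=ts.f_neuropil)
        _write_schedule(f.create_group("schedule"), ts.schedule)
        f.attrs["frame_rate"] = ts.frame_rate
        if ts.r_true is not None:
            f.attrs["r_true"] = ts.r_true
        if ts.truth is not None:
            g = f.create_group("truth")
            rows = [dataclasses.asdict(n) for n in ts.truth]
            for k in rows[0]:
                vals = [r[k] for r in rows]
                if isinstance(vals[0], str):
                    g.create_dataset(
                        k, data=np.array(vals, dtype=h5py.string_dtype()))
                else:
                    g.create_dataset(k, data=np.asarray(vals, dtype=float))


def load_roi_traces(path) -> RoiTraceSet:
    with h5py.File(path, "r") as f:
        schedule = _read_schedule(f["schedule"])
        truth = None
        if "truth" in f:
            g = f["truth"]
            keys = list(g.keys())
            n = g[keys[0]].shape[0]
            truth = []
            for i in range(n):
                kw = {}
                for k in keys:
                    v = g[k][i]
                    kw[k] = v.decode() if isinstance(v, bytes) else float(v)
                truth.append(NeuronGroundTruth(**kw))
        return RoiTraceSet(
            f_roi=f["traces/f_roi"][()],
            f_neuropil=f["traces/f_neuropil"][()],
            frame_rate=float(f.attrs["frame_rate"]),
            schedule=schedule,
            truth=truth,
            r_true=float(f.attrs["r_true"]) if "r_true" in f.attrs else None,
        )


def save_aligned_trials(path, tr: TrialAlignedResponses) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=tr.values)
        f.create_dataset("frame_offsets", data=tr.frame_offsets)
        md = f.create_group("metadata")
        for c in tr.metadata.columns:
            col = tr.metadata[c]
            if col.dtype == object:
                md.create_dataset(c, data=np.array(
                    ["" if v is None else str(v) for v in col],
                    dtype=h5py.string_dtype()))
            else:
                md.create_dataset(c, data=col.to_numpy(dtype=float))
        f.attrs["frame_rate"] = tr.frame_rate
        f.attrs["baseline_frames"] = tr.baseline_frames
        f.attrs["qc_json"] = json.dumps(tr.qc)


def load_aligned_trials(path) -> TrialAlignedResponses:
    with h5py.File(path, "r") as f:
        md = {}
        for c in f["metadata"]:
            data = f["metadata"][c][()]
            if data.dtype.kind in "SO":
                md[c] = [v.decode() if isinstance(v, bytes) else v
                         for v in data]
            else:
                md[c] = data
        return TrialAlignedResponses(
            values=f["values"][()],
            frame_offsets=f["frame_offsets"][()],
            frame_rate=float(f.attrs["frame_rate"]),
            metadata=pd.DataFrame(md),
            baseline_frames=int(f.attrs["baseline_frames"]),
            qc=json.loads(f.attrs["qc_json"]),
        )


def save_movie_tiff(path, movie: np.ndarray) -> None:
    """Write a (frames, H, W) stack as a multi-page TIFF."""
    tifffile.imwrite(path, np.asarray(movie, dtype=np.float32))


def load_movie_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def save_bf_map(tiff_path, json_path, bfmap: BfMap) -> None:
    """Write a BF map as a TIFF of frequency codes plus a JSON legend.

    Code 0 marks masked pixels; codes 1..n index ``bfmap.frequencies``.
    """
    codes = np.zeros(bfmap.bf.shape, dtype=np.uint8)
    for i, fhz in enumerate(bfmap.frequencies):
        codes[bfmap.bf == fhz] = i + 1
    codes[np.isnan(bfmap.bf)] = 0
    tifffile.imwrite(tiff_path, codes)
    legend = {
        "codes": {str(i + 1): f for i, f in enumerate(bfmap.frequencies)},
        "masked_code": 0,
        "n_levels": int(bfmap.levels.max()) if bfmap.levels.size else 0,
    }
    with open(json_path, "w") as fh:
        json.dump(legend, fh, indent=2)


def save_qc_report(path, qc: dict) -> None:
    with open(path, "w") as fh:
        json.dump(qc, fh, indent=2, default=float)
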