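"""HDF5 run container (with an NPZ fallback) and CSV table export.

Container layout::

    /stimulus/frames            (n_frames, rows, cols), attrs: frame_duration,
                                kind, rms_contrast, pixel_size_deg, seed
    /spikes/repeat_<i>          float64 seconds
    /labels/repeat_<i>          int64 per-spike codes (optional)
    /filters/<kind>_<k>         (lags, rows, cols), attrs: eigenvalue,
                                significant, rank

The NPZ fallback flattens the same names with ``/`` replaced by ``__``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from burstrf.datatypes import SpikeRecord, StimulusMovie, SubunitFilter

__all__ = [
    "write_container", "read_stimulus", "read_spikes", "read_filters",
    "write_npz", "read_npz",
]


def write_container(
    path,
    stimulus: StimulusMovie | None = None,
    spikes: SpikeRecord | None = None,
    filters: list[SubunitFilter] | None = None,
    mode: str = "a",
) -> None:
    with h5py.File(path, mode) as f:
        if stimulus is not None:
            g = f.require_group("stimulus")
            if "frames" in g:
                del g["frames"]
            d = g.create_dataset("frames", data=stimulus.frames)
            d.attrs["frame_duration"] = stimulus.frame_duration
            d.attrs["kind"] = stimulus.kind
            d.attrs["rms_contrast"] = stimulus.rms_contrast
            d.attrs["pixel_size_deg"] = stimulus.pixel_size_deg
            d.attrs["seed"] = stimulus.seed
        if spikes is not None:
            g = f.require_group("spikes")
            for i, rep in enumerate(spikes.repeats):
                name = f"repeat_{i}"
                if name in g:
                    del g[name]
                g.create_dataset(name, data=rep)
            if spikes.labels is not None:
                gl = f.require_group("labels")
                for i, lab in enumerate(spikes.labels):
                    name = f"repeat_{i}"
                    if name in gl:
                        del gl[name]
                    gl.create_dataset(name, data=np.asarray(lab, dtype=np.int64))
        if filters:
            g = f.require_group("filters")
            for k, filt in enumerate(filters):
                name = f"{filt.kind}_{k}"
                if name in g:
                    del g[name]
                d = g.create_dataset(name, data=filt.weights)
                if filt.eigenvalue is not None:
                    d.attrs["eigenvalue"] = filt.eigenvalue
                if filt.significant is not None:
                    d.attrs["significant"] = bool(filt.significant)
                if filt.rank is not None:
                    d.attrs["rank"] = filt.rank


def read_stimulus(path) -> StimulusMovie:
    with h5py.File(path, "r") as f:
        d = f["stimulus/frames"]
        return StimulusMovie(
            frames=d[()],
            frame_duration=float(d.attrs["frame_duration"]),
            kind=str(d.attrs.get("kind", "gaussian")),
            rms_contrast=float(d.attrs.get("rms_contrast", 0.33)),
            pixel_size_deg=float(d.attrs.get("pixel_size_deg", 1.0)),
            seed=int(d.attrs.get("seed", -1)),
        )


def read_spikes(path) -> SpikeRecord:
    with h5py.File(path, "r") as f:
        g = f["spikes"]
        names = sorted(g.keys(), key=lambda s: int(s.split("_")[1]))
        repeats = [g[name][()] for name in names]
        labels = None
        if "labels" in f:
            gl = f["labels"]
            labels = [gl[name][()] for name in names if name in gl]
            if len(labels) != len(repeats):
                labels = None
    return SpikeRecord(repeats=repeats, labels=labels)


def read_filters(path) -> list[SubunitFilter]:
    out = []
    with h5py.File(path, "r") as f:
        if "filters" not in f:
            return out
        g = f["filters"]
        for name in sorted(g.keys()):
            d = g[name]
            out.append(SubunitFilter(
                weights=d[()],
                kind=name.rsplit("_", 1)[0],
                eigenvalue=(float(d.attrs["eigenvalue"])
                            if "eigenvalue" in d.attrs else None),
                significant=(bool(d.attrs["significant"])
                             if "significant" in d.attrs else None),
                rank=int(d.attrs["rank"]) if "rank" in d.attrs else None,
            ))
    return out


def write_npz(path, stimulus: StimulusMovie, spikes: SpikeRecord) -> None:
    """Plain NPZ fallback mirroring the HDF5 names (``/`` -> ``__``)."""
    data = {
        "stimulus__frames": stimulus.frames,
        "stimulus__frame_duration": np.array(stimulus.frame_duration),
        "stimulus__kind": np.array(stimulus.kind),
        "stimulus__rms_contrast": np.array(stimulus.rms_contrast),
    }
    for i, rep in enumerate(spikes.repeats):
        data[f"spikes__repeat_{i}"] = rep
        if spikes.labels is not None:
            data[f"labels__repeat_{i}"] = np.asarray(spikes.labels[i], np.int64)
    np.savez(path, **data)


def read_npz(path) -> tuple[StimulusMovie, SpikeRecord]:
    with np.load(path, allow_pickle=False) as z:
        stimulus = StimulusMovie(
            frames=z["stimulus__frames"],
            frame_duration=float(z["stimulus__frame_duration"]),
            kind=str(z["stimulus__kind"]),
            rms_contrast=float(z["stimulus__rms_contrast"]),
        )
        rep_names = sorted((k for k in z.files if k.startswith("spikes__repeat_")),
                           key=lambda s: int(s.rsplit("_", 1)[1]))
        repeats = [z[k] for k in rep_names]
        labels = None
        lab_names = [k.replace("spikes__", "labels__") for k in rep_names]
        if all(k in z.files for k in lab_names):
            labels = [z[k] for k in lab_names]
    return stimulus, SpikeRecord(repeats=repeats, labels=labels)


def export_burst_table(path, rows: list[dict]) -> None:
    """CSV burst table: cell_id, t_cardinal_s, n_spikes, duration_ms,
    criteria, cluster."""
    import pandas as pd

    cols = ["cell_id", "t_cardinal_s", "n_spikes", "duration_ms",
            "criteria", "cluster"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
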