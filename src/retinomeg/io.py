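"""Serialization of the package's data objects.

Tabular objects (sensor layouts, source spaces with atlas labels, source
estimates, accuracy tables) are tab- or comma-separated text; dense arrays
(epoched data, lead fields) are portable .npy containers with a JSON
sidecar header recording dimensions, units and provenance.  All positions
are meters in the head frame (+x right, +y anterior, +z superior).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RetinotopicAtlas
from .geometry import SensorArray, SourceSpace
from .minimum_norm import SourceEstimate

_FRAME_NOTE = "head frame: +x right, +y anterior, +z superior; meters"


def write_sensor_layout(sensors: SensorArray, path) -> None:
    df = pd.DataFrame(
        {
            "sensor_id": sensors.ids,
            "kind": sensors.kinds,
            "x": sensors.positions[:, 0],
            "y": sensors.positions[:, 1],
            "z": sensors.positions[:, 2],
            "ox": sensors.orientations[:, 0],
            "oy": sensors.orientations[:, 1],
            "oz": sensors.orientations[:, 2],
            "baseline": sensors.baselines,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# {_FRAME_NOTE}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_sensor_layout(path) -> SensorArray:
    from .geometry import _tangent_pair

    df = pd.read_csv(path, sep="\t", comment="#")
    oris = df[["ox", "oy", "oz"]].to_numpy()
    tangs = np.full((len(df), 3), np.nan)
    for i, (sid, kind) in enumerate(zip(df["sensor_id"], df["kind"])):
        if kind == "planar_gradiometer":
            t1, t2 = _tangent_pair(oris[i])
            tangs[i] = t1 if str(sid).endswith("a") else t2
    return SensorArray(
        ids=df["sensor_id"].to_numpy(dtype=str),
        positions=df[["x", "y", "z"]].to_numpy(),
        orientations=oris,
        kinds=df["kind"].to_numpy(dtype=object),
        baselines=df["baseline"].to_numpy(),
        tangentials=tangs,
    )


def write_source_space(space: SourceSpace, atlas: RetinotopicAtlas | None, path) -> None:
    df = space.df[["vertex_id", "hemi", "x", "y", "z", "nx", "ny", "nz"]].copy()
    if atlas is not None:
        df["area"] = atlas.area
        df["polarity"] = atlas.polarity
        df["ecc_band"] = atlas.ecc_band
    with open(path, "w") as fh:
        fh.write(f"# {_FRAME_NOTE}; spacing={space.spacing}; "
                 f"sphere_radius={space.sphere_radius}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_estimate(est: SourceEstimate, path) -> None:
    df = pd.DataFrame(
        {
            "vertex_id": np.arange(len(est.values)),
            "value": est.values,
            "kind": est.kind,
            "window_lo_ms": est.window_ms[0],
            "window_hi_ms": est.window_ms[1],
            "method": est.method,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_estimate(path) -> SourceEstimate:
    df = pd.read_csv(path, sep="\t")
    return SourceEstimate(
        values=df["value"].to_numpy(),
        kind=str(df["kind"].iloc[0]),
        window_ms=(float(df["window_lo_ms"].iloc[0]),
                   float(df["window_hi_ms"].iloc[0])),
        method=str(df["method"].iloc[0]),
    )


def write_epochs(data, directory, stem: str = "epochs") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / f"{stem}.npy", data.data)
    header = {
        "dimensions": ["trial", "sensor", "sample"],
        "shape": list(data.data.shape),
        "sampling_rate_hz": data.sampling_rate,
        "tmin_ms": data.tmin_ms,
        "filter_pad_ms": data.filter_pad_ms,
        "subject_id": data.subject_id,
        "seed": data.seed,
        "frame": _FRAME_NOTE,
    }
    (directory / f"{stem}.json").write_text(json.dumps(header, indent=1))
    pd.DataFrame({"trial": np.arange(data.n_trials),
                  "stimulus": data.trial_labels}).to_csv(
        directory / f"{stem}_labels.csv", index=False
    )


def write_lead_field(leadfield, directory, stem: str = "leadfield") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / f"{stem}.npy", leadfield.gain)
    header = {
        "dimensions": ["sensor", "source"],
        "shape": list(leadfield.gain.shape),
        "orientation_mode": leadfield.orientation_mode,
        "units": "T/(A m) for magnetometers, (T/m)/(A m) for gradiometers",
        "frame": _FRAME_NOTE,
    }
    (directory / f"{stem}.json").write_text(json.dumps(header, indent=1))
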