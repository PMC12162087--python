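"""File formats: BIDS-style events TSV, dense arrays with JSON sidecars,
CSV tables, optional NIfTI-1 exports of 2D label/tuning maps."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .stimuli import ApertureMovie, Block, BlockSchedule
from .synth import SyntheticHemisphere, TimeSeriesMatrix

__all__ = [
    "write_events",
    "read_events",
    "write_timeseries",
    "read_timeseries",
    "write_apertures",
    "read_apertures",
    "write_hemisphere",
    "write_nifti_map",
]


def write_events(schedule: BlockSchedule, path: str | Path) -> None:
    """BIDS-style events table (onset, duration, trial_type) + sidecar."""
    path = Path(path)
    schedule.to_events().to_csv(path, sep="\t", index=False)
    sidecar = {"total_duration": schedule.total_duration, "tr": schedule.tr}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_events(path: str | Path) -> BlockSchedule:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(".json").read_text())
    blocks = [
        Block(str(r.trial_type), float(r.onset), float(r.duration))
        for r in df.itertuples()
    ]
    return BlockSchedule(blocks, float(meta["total_duration"]), float(meta["tr"]))


def write_timeseries(ts: TimeSeriesMatrix, path: str | Path, **extra) -> None:
    path = Path(path)
    np.save(path, ts.values)
    sidecar = {
        "tr": ts.tr,
        "units": ts.units,
        "n_vertices": int(ts.values.shape[0]),
        "n_timepoints": int(ts.values.shape[1]),
        **extra,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_timeseries(path: str | Path) -> TimeSeriesMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing time-series file: {path}")
    try:
        values = np.load(path)
    except Exception as err:  # surface the offending file
        raise ValueError(f"could not parse time-series file {path}: {err}") from err
    meta = json.loads(path.with_suffix(".json").read_text())
    return TimeSeriesMatrix(values=values, tr=float(meta["tr"]), units=meta["units"])


def write_apertures(ap: ApertureMovie, path: str | Path) -> None:
    path = Path(path)
    np.save(path, ap.grid)
    sidecar = {
        "radius": ap.radius,
        "kind": ap.kind,
        "tr": ap.tr,
        "grid_size": ap.grid_size,
        "n_timepoints": ap.n_timepoints,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_apertures(path: str | Path) -> ApertureMovie:
    path = Path(path)
    grid = np.load(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return ApertureMovie(
        grid=grid, radius=float(meta["radius"]), kind=meta["kind"], tr=float(meta["tr"])
    )


def write_hemisphere(hemi: SyntheticHemisphere, path: str | Path) -> None:
    """Ground-truth table: one row per vertex with labels and tuning."""
    df = hemi.tuning.copy()
    df["atlas_label"] = hemi.atlas_label.ravel()
    df.to_csv(path, index=False)


def write_nifti_map(values: np.ndarray, path: str | Path, spacing: float = 1.0) -> None:
    """Optional NIfTI-1 export of a 2D vertex map (single-slice volume)."""
    import nibabel as nib

    data = np.asarray(values, dtype=np.float32)[:, :, None]
    affine = np.diag([spacing, spacing, 1.0, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))
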