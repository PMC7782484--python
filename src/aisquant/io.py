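"""Readers and writers for the pipeline's tabular and image formats.

Formats are deliberately plain: profiles, traces and cohort tables are
CSV with ``#``-prefixed header comments (seed / provenance metadata);
images are TIFF (single plane or stack); traced paths are two-column
pixel-coordinate tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .ephys import Sweep, SweepSet
from .morphometry import IntensityProfile

__all__ = [
    "write_profile_csv", "read_profile_csv",
    "write_sweepset_csv", "read_sweepset_csv",
    "write_table_csv", "read_table_csv",
    "write_tiff", "read_tiff",
    "write_path_csv", "read_path_csv",
]


def _write_csv_with_header(path, df: pd.DataFrame, meta: dict | None):
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def _read_meta(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v.strip()
    return meta


def write_profile_csv(path, profile: IntensityProfile, meta: dict | None = None):
    m = {"pixel_size_um": profile.pixel_size_um,
         "source_id": profile.source_id, **(meta or {})}
    _write_csv_with_header(path, pd.DataFrame({
        "position_um": profile.positions_um,
        "intensity": profile.intensities}), m)


def read_profile_csv(path) -> IntensityProfile:
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    return IntensityProfile(
        positions_um=df.position_um.values,
        intensities=df.intensity.values,
        pixel_size_um=float(meta.get("pixel_size_um",
                                     df.position_um.diff().iloc[1])),
        source_id=meta.get("source_id", ""))


def write_sweepset_csv(path, ss: SweepSet, meta: dict | None = None):
    frames = []
    for k, sw in enumerate(ss.sweeps):
        frames.append(pd.DataFrame({
            "time_s": ss.time_s, "value": sw.signal, "sweep_id": k,
            "step_pA": sw.step_pA, "step_onset_s": sw.step_onset_s,
            "step_duration_s": sw.step_duration_s}))
    m = {"clamp_mode": ss.clamp_mode, "ljp_corrected": ss.ljp_corrected,
         **(meta or {})}
    _write_csv_with_header(path, pd.concat(frames, ignore_index=True), m)


def read_sweepset_csv(path) -> SweepSet:
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    sweeps = []
    time_s = None
    for _, g in df.groupby("sweep_id"):
        if time_s is None:
            time_s = g.time_s.values
        sweeps.append(Sweep(signal=g.value.values,
                            step_pA=float(g.step_pA.iloc[0]),
                            step_onset_s=float(g.step_onset_s.iloc[0]),
                            step_duration_s=float(g.step_duration_s.iloc[0])))
    return SweepSet(time_s=time_s, sweeps=sweeps,
                    clamp_mode=meta.get("clamp_mode", "current"),
                    ljp_corrected=meta.get("ljp_corrected", "False") == "True")


def write_table_csv(path, table: pd.DataFrame, meta: dict | None = None):
    _write_csv_with_header(path, table, meta)


def read_table_csv(path):
    return pd.read_csv(path, comment="#"), _read_meta(path)


def write_tiff(path, image):
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def read_tiff(path):
    return tifffile.imread(path)


def write_path_csv(path, path_px, pixel_size_um: float):
    _write_csv_with_header(path, pd.DataFrame(
        {"x_px": np.asarray(path_px)[:, 0], "y_px": np.asarray(path_px)[:, 1]}),
        {"pixel_size_um": pixel_size_um})


def read_path_csv(path):
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    return df[["x_px", "y_px"]].values, float(meta["pixel_size_um"])
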