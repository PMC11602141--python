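"""File formats: TIFF stacks, kymograph CSV/TIFF, track tables, configs.

All genomic coordinates in external outputs are kilobases from the left
tether; pixel columns are carried alongside for traceability.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .kinetics import ResidenceModel
from .preprocess import Kymograph
from .synthetic import CondensationScenario, GroundTruthTrack, SimConfig
from .tracking import PeakObservation, Track

__all__ = [
    "write_stack_tiff", "read_stack_tiff",
    "write_kymograph_csv", "read_kymograph_csv",
    "write_kymograph_tiff", "read_kymograph_tiff",
    "tracks_to_table", "write_tracks_csv", "read_tracks_csv",
    "ground_truth_to_table",
    "sim_config_from_dict", "sim_config_to_yaml", "load_sim_config",
    "write_json_report",
]

TRACK_COLUMNS = ["track_id", "kind", "frame", "position_px", "position_kb",
                 "fraction", "size_kb"]


def write_stack_tiff(stack: np.ndarray, path, dtype=np.uint16) -> int:
    """Write a (frames, h, w) stack as a multi-page TIFF.

    Values outside the dtype range are clipped; returns the number of
    clipped pixels (also emitted as a warning when nonzero).
    """
    stack = np.asarray(stack)
    info = np.iinfo(dtype)
    n_clipped = int(np.sum((stack < info.min) | (stack > info.max)))
    if n_clipped:
        warnings.warn(f"{n_clipped} pixels clipped to {dtype.__name__} range")
    tifffile.imwrite(str(path), np.clip(stack, info.min, info.max).astype(dtype),
                     photometric="minisblack")
    return n_clipped


def read_stack_tiff(path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return np.asarray(arr, dtype=float)


def _kymo_meta(kymo: Kymograph) -> dict:
    return dict(frame_interval_s=kymo.frame_interval_s,
                kb_per_pixel=kymo.kb_per_pixel,
                end_pixels=list(kymo.end_pixels),
                channel=kymo.channel)


def write_kymograph_csv(kymo: Kymograph, path) -> None:
    """Kymograph as CSV: ``# key: json`` header lines, then the matrix."""
    path = Path(path)
    with path.open("w") as fh:
        for key, val in _kymo_meta(kymo).items():
            fh.write(f"# {key}: {json.dumps(val)}\n")
        np.savetxt(fh, kymo.intensity, delimiter=",")


def read_kymograph_csv(path) -> Kymograph:
    path = Path(path)
    meta: dict = {}
    skip = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = json.loads(val)
    matrix = np.loadtxt(path, delimiter=",", skiprows=skip)
    if matrix.ndim == 1:
        matrix = matrix[None]
    return Kymograph(intensity=matrix,
                     frame_interval_s=float(meta["frame_interval_s"]),
                     kb_per_pixel=float(meta["kb_per_pixel"]),
                     end_pixels=tuple(meta["end_pixels"]),
                     channel=meta.get("channel", "dna"))


def write_kymograph_tiff(kymo: Kymograph, path) -> None:
    tifffile.imwrite(str(path), kymo.intensity.astype(np.float32),
                     description=json.dumps(_kymo_meta(kymo)))


def read_kymograph_tiff(path) -> Kymograph:
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        meta = json.loads(tf.pages[0].description)
    return Kymograph(intensity=np.asarray(arr, dtype=float),
                     frame_interval_s=float(meta["frame_interval_s"]),
                     kb_per_pixel=float(meta["kb_per_pixel"]),
                     end_pixels=tuple(meta["end_pixels"]),
                     channel=meta.get("channel", "dna"))


def tracks_to_table(tracks: list[Track], kymo: Kymograph) -> pd.DataFrame:
    rows = []
    for t in tracks:
        kb = t.positions_kb(kymo)
        for o, p in zip(t.observations, kb):
            rows.append((t.id, t.kind, o.frame, o.position_px, float(p),
                         o.fraction, o.size_kb))
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def write_tracks_csv(tracks: list[Track], kymo: Kymograph, path) -> None:
    tracks_to_table(tracks, kymo).to_csv(path, index=False, float_format="%.6g")


def read_tracks_csv(path) -> list[Track]:
    """Read a track table; frames must be strictly increasing per track."""
    df = pd.read_csv(path)
    missing = set(["track_id", "frame", "position_px"]) - set(df.columns)
    if missing:
        raise ValueError(f"track table missing columns: {sorted(missing)}")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        frames = grp["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            bad = int(np.argmax(np.diff(frames) <= 0))
            raise ValueError(
                f"track {tid}: frames not strictly increasing at row {grp.index[bad + 1]}")
        obs = [PeakObservation(frame=int(r.frame), position_px=int(r.position_px),
                               peak_value=float(getattr(r, "peak_value", np.nan)),
                               fraction=None if pd.isna(getattr(r, "fraction", np.nan))
                               else float(r.fraction),
                               size_kb=None if pd.isna(getattr(r, "size_kb", np.nan))
                               else float(r.size_kb))
               for r in grp.itertuples()]
        kind = grp["kind"].iloc[0] if "kind" in grp else "unknown"
        tracks.append(Track(id=int(tid), observations=obs, kind=str(kind)))
    return tracks


def ground_truth_to_table(tracks: list[GroundTruthTrack]) -> pd.DataFrame:
    rows = []
    for i, t in enumerate(tracks):
        for k, f in enumerate(range(t.birth_frame, t.death_frame)):
            rows.append((i, t.kind, f, float(t.positions_kb[k]),
                         float(t.size_kb[k]), t.labeled))
    return pd.DataFrame(rows, columns=["track_id", "kind", "frame",
                                       "position_kb", "size_kb", "labeled"])


def _from_dict(cls, data: dict, path: str):
    field_names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - field_names
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {path or 'config'}")
    return data


def sim_config_from_dict(data: dict, path: str = "sim") -> SimConfig:
    """Build a SimConfig from a plain dict, rejecting unknown keys."""
    data = dict(data)
    _from_dict(SimConfig, data, path)
    if "residence_model" in data and isinstance(data["residence_model"], dict):
        rm = dict(data["residence_model"])
        _from_dict(ResidenceModel, rm, f"{path}.residence_model")
        data["residence_model"] = ResidenceModel(**rm)
    if "condensation" in data and isinstance(data["condensation"], dict):
        cs = dict(data["condensation"])
        _from_dict(CondensationScenario, cs, f"{path}.condensation")
        data["condensation"] = CondensationScenario(**cs)
    cfg = SimConfig(**data)
    cfg.validate()
    return cfg


def sim_config_to_yaml(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_sim_config(path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return sim_config_from_dict(data, str(path))


def write_json_report(report: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"cannot serialise {type(o)}")
    Path(path).write_text(json.dumps(report, indent=2, default=default,
                                     allow_nan=True) + "\n")
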