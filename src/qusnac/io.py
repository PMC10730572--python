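"""File formats: HDF5 RF containers, CSV feature tables, JSON run configs.

The RF container layout is::

    /rf                  float64 dataset (axial samples x lines)
    /meta                group with acquisition attributes
    /truth               optional JSON-encoded ground truth (phantoms only)
    /maps/<PARAM>        optional parametric-map rasters with grid attributes

Feature tables are CSV (one row per patient, canonical column order) with a
JSON sidecar carrying the census metadata; missing features serialize as
empty cells and round-trip as NaN.
"""

from __future__ import annotations

import json
import hashlib
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .frame import RFFrame
from .phantom import TransducerSpec
from .features import SUBTYPE_NAMES, canonical_census

__all__ = [
    "FormatError",
    "ConfigError",
    "write_rf_container",
    "read_rf_container",
    "write_feature_table",
    "read_feature_table",
    "load_run_config",
    "config_hash",
]

log = logging.getLogger("qusnac")

_META_FIELDS = (
    "centre_frequency",
    "band_low",
    "band_high",
    "sampling_rate",
    "n_lines",
    "lateral_extent",
    "axial_extent",
    "sound_speed",
    "pulse_fractional_bandwidth",
)


class FormatError(ValueError):
    """Container or table does not match the expected schema."""


class ConfigError(ValueError):
    """Run configuration invalid (unknown or missing keys)."""


def write_rf_container(path, frame: RFFrame, maps: dict | None = None) -> None:
    """Write an RF frame (and optionally parametric maps) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("rf", data=frame.samples, compression="gzip", compression_opts=4)
        meta = f.create_group("meta")
        t = frame.transducer
        for k in _META_FIELDS:
            meta.attrs[k] = getattr(t, k)
        meta.attrs["depth_origin"] = frame.depth_origin
        if frame.truth is not None:
            f.create_dataset("truth", data=json.dumps(frame.truth))
        if maps:
            g = f.create_group("maps")
            for name, pmap in maps.items():
                d = g.create_dataset(name, data=pmap.values)
                d.attrs["units"] = pmap.units


def read_rf_container(path) -> RFFrame:
    """Read an RF frame written by :func:`write_rf_container`."""
    with h5py.File(path, "r") as f:
        if "rf" not in f:
            raise FormatError(f"{path}: missing /rf dataset")
        if "meta" not in f:
            raise FormatError(f"{path}: missing /meta group")
        meta = f["meta"].attrs
        missing = [k for k in _META_FIELDS if k not in meta]
        if missing:
            raise FormatError(f"{path}: /meta missing attributes {missing}")
        t = TransducerSpec(
            **{k: (int(meta[k]) if k == "n_lines" else float(meta[k])) for k in _META_FIELDS}
        )
        truth = json.loads(f["truth"][()]) if "truth" in f else None
        return RFFrame(
            samples=f["rf"][()],
            sampling_rate=t.sampling_rate,
            line_spacing=t.line_spacing,
            depth_origin=float(meta.get("depth_origin", 0.0)),
            transducer=t,
            truth=truth,
        )


def write_feature_table(df: pd.DataFrame, path) -> None:
    """CSV + JSON-sidecar serialization of a per-patient feature table."""
    path = Path(path)
    ultrasound = [c for c in canonical_census() if c in df.columns]
    subtype = [c for c in SUBTYPE_NAMES if c in df.columns]
    lead = [c for c in ("patient_id", "response") if c in df.columns]
    cols = lead + ultrasound + subtype
    extra = [c for c in df.columns if c not in cols]
    if extra:
        raise FormatError(f"columns outside the census: {extra[:5]}")
    df[cols].to_csv(path, index=False)
    sidecar = {
        "n_rows": int(df.shape[0]),
        "ultrasound_features": ultrasound,
        "subtype_features": subtype,
        "lead_columns": lead,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table, validating columns against its sidecar."""
    path = Path(path)
    df = pd.read_csv(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        expected = (
            sidecar["lead_columns"] + sidecar["ultrasound_features"] + sidecar["subtype_features"]
        )
        absent = [c for c in expected if c not in df.columns]
        extra = [c for c in df.columns if c not in expected]
        if absent or extra:
            raise FormatError(f"feature table mismatch: absent={absent[:5]} extra={extra[:5]}")
    return df


_CONFIG_SCHEMA = {
    "seed": int,
    "overlap": float,
    "n_levels": int,
    "texture_stride": int,
    "margin_width_mm": float,
    "noise_level": float,
    "feature_set": str,
    "classifier": str,
    "cv": str,
    "n_responders": int,
    "n_nonresponders": int,
    "n_reference_frames": int,
    "mrmr_top": int,
    "sfs_max": int,
    "smote_neighbors": int,
    "inner_folds": int,
}


def load_run_config(path) -> dict:
    """JSON run configuration; unknown keys are rejected."""
    cfg = json.loads(Path(path).read_text())
    unknown = set(cfg) - set(_CONFIG_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for k, v in cfg.items():
        want = _CONFIG_SCHEMA[k]
        if want is float and isinstance(v, int):
            v = float(v)
        if not isinstance(v, want):
            raise ConfigError(f"config key {k!r} must be {want.__name__}")
        cfg[k] = v
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration (logged for reproducibility)."""
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]
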