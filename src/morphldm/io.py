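"""NIfTI I/O, cohort manifests, and run configuration.

Volumes are written as NIfTI-1 with an RAS affine scaled by the voxel
spacing; displacement fields persist as 4D NIfTI with the 3 displacement
channels on the last axis. Cohort manifests follow the participants-table
convention (TSV with one row per subject). Run configuration is a nested
mapping resolved from a preset, an optional YAML file, and
``key.path=value`` overrides, with a content hash for provenance.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .spatial import DisplacementField, Volume

__all__ = ["read_volume", "write_volume", "read_field", "write_field",
           "load_manifest", "write_manifest", "PRESETS", "resolve_config",
           "config_hash"]


# ----------------------------------------------------------------- NIfTI I/O

def _affine(spacing) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def read_volume(path) -> Volume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got shape {data.shape} "
            "(use read_field for displacement fields)")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(np.asarray(data, dtype=float), spacing=spacing,
                  affine=np.asarray(img.affine))


def write_volume(volume: Volume, path, dtype=np.float32):
    aff = volume.affine if volume.affine is not None else _affine(volume.spacing)
    img = nib.Nifti1Image(np.asarray(volume.intensities, dtype=dtype), aff)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_field(path) -> DisplacementField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"{path}: expected a (D,H,W,3) field, got {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DisplacementField(np.moveaxis(data, -1, 0), spacing=spacing)


def write_field(field: DisplacementField, path):
    data = np.moveaxis(field.u, 0, -1).astype(np.float32)
    img = nib.Nifti1Image(data, _affine(field.spacing))
    nib.save(img, str(path))


# ------------------------------------------------------------------ manifests

_SEX_ALIASES = {"0": 0, "1": 1, "m": 0, "male": 0, "f": 1, "female": 1}
_MANIFEST_COLUMNS = ["participant_id", "image", "labels", "age", "sex", "seed"]


def write_manifest(rows: list[dict], path):
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(
        path, sep="\t", index=False)


def load_manifest(path, check_paths: bool = True) -> pd.DataFrame:
    """Load a cohort manifest TSV; sex aliases M/F are mapped to 0/1."""
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str})
    missing = [c for c in ("participant_id", "image", "age", "sex")
               if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns {missing}")
    base = Path(path).parent

    def map_sex(v):
        key = str(v).strip().lower()
        if key not in _SEX_ALIASES:
            raise ValueError(f"unrecognised sex value {v!r}")
        return _SEX_ALIASES[key]

    df["sex"] = df["sex"].map(map_sex)
    df["age"] = pd.to_numeric(df["age"], errors="raise")
    if check_paths:
        for col in ("image", "labels"):
            if col not in df.columns:
                continue
            for p in df[col].dropna():
                full = base / p
                if not full.exists():
                    raise FileNotFoundError(f"manifest entry does not exist: {full}")
    return df


# -------------------------------------------------------------- configuration

PRESETS: dict[str, dict] = {
    # desk-scale preset: trains in minutes on one CPU
    "desk32": {
        "data": {"grid_shape": [32, 32, 32], "n": 200, "age_range": [5, 100],
                 "sex_ratio": 0.5, "fold_amplitude": 0.06, "noise_sd": 0.02,
                 "smoothing_sigma": 0.5},
        "stage1": {"channels": [8, 16, 16], "latent_channels": 8,
                   "conditional": False, "alpha": 5.0, "beta": 1.0,
                   "kl_weight": 1e-7, "adversarial_weight": 0.005,
                   "centrality_weight": 100.0, "epochs": 40, "batch_size": 8,
                   "lr": 2e-3, "bin_width": 10.0},
        "stage2": {"T": 100, "schedule": "linear", "channels": [16, 32, 32],
                   "cross_attention": True, "n_steps": 800, "batch_size": 16,
                   "lr": 2e-3},
        "eval": {"n_pairs": 100, "predictor_steps": 400,
                 "predictor_channels": [8, 16]},
        "seed": 0,
        "deterministic": True,
    },
    # full-scale constants (MNI-grid volumes, H100-class budgets)
    "paper_full": {
        "data": {"grid_shape": [160, 192, 176], "n": 27066,
                 "age_range": [5, 100], "sex_ratio": 0.5,
                 "fold_amplitude": 0.06, "noise_sd": 0.02,
                 "smoothing_sigma": 0.5},
        "stage1": {"channels": [64, 128, 128], "latent_channels": 8,
                   "conditional": False, "alpha": 5.0, "beta": 1.0,
                   "kl_weight": 1e-7, "adversarial_weight": 0.005,
                   "centrality_weight": 100.0, "epochs": 100, "batch_size": 4,
                   "lr": 1e-4, "bin_width": 10.0},
        "stage2": {"T": 1000, "schedule": "linear",
                   "channels": [384, 512, 512], "cross_attention": True,
                   "n_steps": 100000, "batch_size": 8, "lr": 1e-4},
        "eval": {"n_pairs": 1000, "predictor_steps": 20000,
                 "predictor_channels": [16, 32]},
        "seed": 0,
        "deterministic": True,
    },
}


def _deep_update(base: dict, upd: dict, path=""):
    for k, v in upd.items():
        where = f"{path}.{k}" if path else k
        if k not in base:
            raise KeyError(f"unknown config key {where!r}")
        if isinstance(base[k], dict):
            if not isinstance(v, dict):
                raise ValueError(f"config key {where!r} expects a mapping")
            _deep_update(base[k], v, where)
        else:
            base[k] = v


def _parse_scalar(text: str):
    try:
        return yaml.safe_load(text)
    except yaml.YAMLError:
        return text


def resolve_config(path=None, overrides: list[str] = (),
                   preset: str = "desk32") -> dict:
    """Preset defaults <- optional YAML file <- key.path=value overrides."""
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; have {sorted(PRESETS)}")
    cfg = copy.deepcopy(PRESETS[preset])
    if path is not None:
        with open(path) as fh:
            file_cfg = yaml.safe_load(fh) or {}
        _deep_update(cfg, file_cfg)
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override {item!r} is not key=value")
        key, value = item.split("=", 1)
        node = cfg
        parts = key.split(".")
        for p in parts[:-1]:
            if p not in node or not isinstance(node[p], dict):
                raise KeyError(f"unknown config section {p!r} in {key!r}")
            node = node[p]
        if parts[-1] not in node:
            raise KeyError(f"unknown config key {key!r}")
        node[parts[-1]] = _parse_scalar(value)
    cfg["preset"] = preset
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable content hash of a resolved configuration."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
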