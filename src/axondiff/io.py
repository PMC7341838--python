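"""File formats, configuration and provenance.

Units at every I/O boundary are fixed package-wide: um, ms, um^2/ms, and b
in ms/um^2.  Labeled volumes travel as NIfTI with the voxel size in the
header; profiles, skeletons, spectra and moment records as CSV with 17
significant digits (lossless for float64); configuration as a YAML mapping
validated against a published schema (unknown keys are errors); every
pipeline run writes a JSON manifest recording the config snapshot, seeds,
package version and file hashes.
"""
from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .substrate import LabeledVolume, RadiusProfile, Skeleton
from .walk import M2_LABELS, M4_EXPONENTS, MomentRecord

__all__ = [
    "ConfigError",
    "CONFIG_SCHEMA",
    "save_labeled_volume",
    "load_labeled_volume",
    "save_profile",
    "load_profile",
    "save_moments",
    "load_moments",
    "load_config",
    "validate_config",
    "build_manifest",
]

FLOAT_FMT = "%.17g"


class ConfigError(ValueError):
    """Configuration violates the schema; message carries the field path."""


def save_labeled_volume(vol: LabeledVolume, path: str | Path) -> Path:
    path = Path(path)
    affine = np.diag([vol.h, vol.h, vol.h, 1.0])
    img = nib.Nifti1Image(vol.labels.astype(np.uint8), affine)
    img.header.set_zooms((vol.h, vol.h, vol.h))
    nib.save(img, str(path))
    return path


def load_labeled_volume(path: str | Path) -> LabeledVolume:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0]):
        raise ValueError("labeled volumes must have isotropic voxels")
    labels = np.asarray(img.dataobj).astype(np.uint8)
    return LabeledVolume(labels=labels, h=float(zooms[0]))


def save_profile(
    profile: RadiusProfile, path: str | Path, skeleton: Skeleton | None = None
) -> Path:
    path = Path(path)
    data: dict[str, np.ndarray] = {"z": profile.z, "r": profile.r}
    if skeleton is not None:
        data["x"] = skeleton.x
        data["y"] = skeleton.y
    pd.DataFrame(data).to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


def load_profile(path: str | Path) -> tuple[RadiusProfile, Skeleton | None]:
    df = pd.read_csv(path, float_precision="round_trip")
    z = df["z"].to_numpy()
    dz = float(z[1] - z[0]) if z.size > 1 else 1.0
    profile = RadiusProfile(dz=dz, r=df["r"].to_numpy())
    skeleton = None
    if "x" in df.columns and "y" in df.columns:
        skeleton = Skeleton(dz=dz, x=df["x"].to_numpy(), y=df["y"].to_numpy())
    return profile, skeleton


def save_moments(rec: MomentRecord, path: str | Path) -> Path:
    path = Path(path)
    cols: dict[str, np.ndarray] = {"t": rec.t, "W": rec.W}
    for i, lab in enumerate(M2_LABELS):
        cols[f"m2_{lab}"] = rec.m2[:, i]
    for i, (a, b, c) in enumerate(M4_EXPONENTS):
        cols[f"m4_x{a}y{b}z{c}"] = rec.m4[:, i]
    df = pd.DataFrame(cols)
    df.attrs["n_walkers"] = rec.n_walkers
    with open(path, "w") as fh:
        fh.write(f"# n_walkers={rec.n_walkers}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)
    return path


def load_moments(path: str | Path) -> MomentRecord:
    with open(path) as fh:
        header = fh.readline()
        n_walkers = int(header.split("=")[1])
        df = pd.read_csv(fh, float_precision="round_trip")
    m2 = df[[f"m2_{lab}" for lab in M2_LABELS]].to_numpy()
    m4 = df[[f"m4_x{a}y{b}z{c}" for a, b, c in M4_EXPONENTS]].to_numpy()
    return MomentRecord(
        t=df["t"].to_numpy(), W=df["W"].to_numpy(), m2=m2, m4=m4, n_walkers=n_walkers
    )


# ---------------------------------------------------------------------------
# configuration

# schema: section -> key -> (type, required, default)
CONFIG_SCHEMA: dict[str, dict[str, tuple]] = {
    "substrate": {
        "scenario": (str, False, "II"),
        "L": (float, False, 60.0),
        "r0": (float, False, 0.5),
        "a_mean": (float, False, 5.70),
        "a_sd": (float, False, 2.88),
        "l_mean": (float, False, 5.6),
        "amplitude": (float, False, 1.2),
        "dz": (float, False, 0.1),
        "h": (float, False, 0.15),
        "undulation": (float, False, 0.0),
        "sigma_s": (float, False, 1.0),
    },
    "compartments": {
        "D_a": (float, False, 2.0),
        "D_m": (float, False, 0.13),
        "T2_a": (float, False, 80.0),
        "T2_m": (float, False, 20.0),
        "f_m": (float, False, 0.06),
    },
    "simulation": {
        "n_walkers": (int, False, 10000),
        "t_min": (float, False, 2.0),
        "t_max": (float, False, 80.0),
        "n_times": (int, False, 16),
        "step_fraction": (float, False, 0.5),
        "t2_weighting": (bool, False, False),
    },
    "fit": {
        "window": (list, False, [20.0, 80.0]),
    },
}


def validate_config(config: dict[str, Any]) -> dict[str, Any]:
    """Check a config mapping against the schema, filling defaults.

    Unknown sections or keys raise :class:`ConfigError` with the offending
    field path.
    """
    if not isinstance(config, dict):
        raise ConfigError("configuration must be a mapping")
    out: dict[str, Any] = {}
    for section in config:
        if section not in CONFIG_SCHEMA:
            raise ConfigError(f"unknown config section {section!r}")
        if not isinstance(config[section], dict):
            raise ConfigError(f"{section}: must be a mapping")
        for key in config[section]:
            if key not in CONFIG_SCHEMA[section]:
                raise ConfigError(f"{section}.{key}: unknown key")
    for section, keys in CONFIG_SCHEMA.items():
        sec_in = config.get(section, {})
        sec_out: dict[str, Any] = {}
        for key, (typ, required, default) in keys.items():
            if key in sec_in:
                val = sec_in[key]
                if typ is float and isinstance(val, int) and not isinstance(val, bool):
                    val = float(val)
                if not isinstance(val, typ):
                    raise ConfigError(
                        f"{section}.{key}: expected {typ.__name__}, got {type(val).__name__}"
                    )
                sec_out[key] = val
            elif required:
                raise ConfigError(f"{section}.{key}: required key missing")
            else:
                sec_out[key] = default
        out[section] = sec_out
    return out


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


# ---------------------------------------------------------------------------
# provenance


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def build_manifest(
    config: dict[str, Any],
    seed: int,
    files: dict[str, Path],
    timings: dict[str, float] | None = None,
) -> dict[str, Any]:
    """Run manifest: config snapshot, seed, version, file hashes, timing."""
    return {
        "axondiff_version": __version__,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": seed,
        "config": config,
        "files": {name: {"path": str(p), "sha256": _sha256(Path(p))}
                  for name, p in files.items() if Path(p).exists()},
        "timings_s": timings or {},
    }


def write_manifest(manifest: dict[str, Any], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
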