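"""File formats and run-configuration handling.

CSV is the interchange format for series, curves and fit tables (comma
separated, '.' decimal, UTF-8, mandatory header row); image stacks are
multi-page 8-bit TIFF with the pixel size in ImageJ-style metadata.
Series/curve CSVs carry their scalar metadata (R0, pair type, seed,
config hash, ...) in leading ``# key: value`` comment lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .fusion import NeckSeries
from .indentation import IndentationCurve

__all__ = [
    "write_neck_series",
    "read_neck_series",
    "write_indentation_curve",
    "read_indentation_curve",
    "write_stack",
    "read_stack",
    "load_config",
    "config_hash",
]


def _write_csv_with_meta(path: Path, df: pd.DataFrame, meta: dict) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)


def _read_meta(path: Path) -> dict:
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
    return meta


def write_neck_series(path: str | Path, series: NeckSeries, extra_meta: dict | None = None) -> None:
    """Write a neck trajectory as CSV (time_h, neck_radius_um, radius_a_um, radius_b_um)."""
    path = Path(path)
    nan = np.full(len(series), np.nan)
    df = pd.DataFrame(
        {
            "time_h": series.times,
            "neck_radius_um": series.neck_radius,
            "radius_a_um": series.radius_a if series.radius_a is not None else nan,
            "radius_b_um": series.radius_b if series.radius_b is not None else nan,
        }
    )
    meta = {
        "R0_um": repr(series.R0),
        "pair_type": series.pair_type,
        "age_days": repr(series.age_days),
    }
    for key in ("seed", "tau_true", "noise_cv"):
        if key in series.meta:
            meta[key] = repr(series.meta[key])
    if extra_meta:
        meta.update(extra_meta)
    _write_csv_with_meta(path, df, meta)


def read_neck_series(path: str | Path) -> NeckSeries:
    path = Path(path)
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    if "R0_um" not in meta:
        raise ValueError(f"{path}: missing required metadata line '# R0_um: ...'")
    rad_a = df["radius_a_um"].to_numpy() if "radius_a_um" in df else None
    rad_b = df["radius_b_um"].to_numpy() if "radius_b_um" in df else None
    extra = {
        k: float(v) for k, v in meta.items() if k in ("seed", "tau_true", "noise_cv")
    }
    return NeckSeries(
        times=df["time_h"].to_numpy(),
        neck_radius=df["neck_radius_um"].to_numpy(),
        R0=float(meta["R0_um"]),
        radius_a=rad_a,
        radius_b=rad_b,
        pair_type=meta.get("pair_type", "unknown"),
        age_days=float(meta.get("age_days", 7.0)),
        meta=extra,
    )


def write_indentation_curve(
    path: str | Path, curve: IndentationCurve, extra_meta: dict | None = None
) -> None:
    """Write an indentation record as CSV (time_s, depth_m, force_N, phase)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": curve.time,
            "depth_m": curve.depth,
            "force_N": curve.force,
            "phase": curve.phase,
        }
    )
    meta = {"tip_radius_m": repr(curve.tip_radius), "nu": repr(curve.nu)}
    for key in ("E1_true", "alpha_true", "seed", "force_noise_sd"):
        if key in curve.meta:
            meta[key] = repr(curve.meta[key])
    if extra_meta:
        meta.update(extra_meta)
    _write_csv_with_meta(path, df, meta)


def read_indentation_curve(
    path: str | Path,
    tip_radius: float | None = None,
    nu: float | None = None,
    stiffness: float | None = None,
) -> IndentationCurve:
    """Read an indentation CSV.

    Accepts either a ``depth_m`` column, or a piezo-position column
    ``piezo_m`` together with a cantilever ``stiffness`` (N/m, from the
    argument or a ``stiffness_N_per_m`` metadata line), in which case the
    indentation is the piezo travel minus the cantilever deflection
    force/stiffness.
    """
    path = Path(path)
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    force = df["force_N"].to_numpy()
    if "depth_m" in df:
        depth = df["depth_m"].to_numpy()
    elif "piezo_m" in df:
        k = stiffness if stiffness is not None else float(meta.get("stiffness_N_per_m", 0) or 0)
        if k <= 0:
            raise ValueError("piezo_m input requires a positive cantilever stiffness")
        depth = df["piezo_m"].to_numpy() - force / k
    else:
        raise ValueError(f"{path}: need a depth_m or piezo_m column")
    if tip_radius is None:
        if "tip_radius_m" not in meta:
            raise ValueError(f"{path}: tip radius not in metadata; pass tip_radius=")
        tip_radius = float(meta["tip_radius_m"])
    if nu is None:
        nu = float(meta.get("nu", 0.5))
    if "phase" in df:
        phase = df["phase"].to_numpy(dtype=str)
    else:
        phase = np.full(len(df), "load", dtype=object)
        i_peak = int(np.argmax(depth))
        phase[i_peak + 1 :] = "retract"
        phase = phase.astype(str)
    extra = {k: float(v) for k, v in meta.items() if k in ("E1_true", "alpha_true", "seed")}
    return IndentationCurve(
        time=df["time_s"].to_numpy(),
        depth=depth,
        force=force,
        phase=phase,
        tip_radius=tip_radius,
        nu=nu,
        meta=extra,
    )


def write_stack(path: str | Path, stack: np.ndarray, pixel_size_um: float) -> None:
    """Write an 8-bit multi-page TIFF with the pixel size in ImageJ metadata."""
    tifffile.imwrite(
        Path(path),
        np.asarray(stack, dtype=np.uint8),
        imagej=True,
        resolution=(1.0 / pixel_size_um, 1.0 / pixel_size_um),
        metadata={"unit": "um", "axes": "TYX"},
    )


def read_stack(path: str | Path, pixel_size_um: float | None = None) -> tuple[np.ndarray, float]:
    """Read a multi-page TIFF; returns (stack, pixel size in µm/px).

    An explicit ``pixel_size_um`` overrides the file's resolution metadata.
    """
    with tifffile.TiffFile(Path(path)) as tf:
        stack = tf.asarray()
        if pixel_size_um is None:
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            if res is None or not res.value[0]:
                raise ValueError("no pixel size in TIFF metadata; pass pixel_size_um=")
            num, den = res.value
            pixel_size_um = den / num
    if stack.ndim == 2:
        stack = stack[None]
    return stack, float(pixel_size_um)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def config_hash(config: dict) -> str:
    """Short deterministic digest of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
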