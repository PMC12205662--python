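"""Shared plumbing: stack/table readers and writers, provenance, pipeline.

Image stacks travel as multi-frame 32-bit-float TIFF with a JSON sidecar
(`<stack>.json`) carrying the frame times (s) and pixel pitch (μm);
tables are UTF-8 comma-separated CSV with a header row; results are JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__ as _version
from .geometry import ChipGeometry, build_domain_mask
from .quantify import CellPoints, HeightProfile

logger = logging.getLogger(__name__)


class StackFormatError(ValueError):
    """Malformed stack file or missing metadata sidecar."""


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_stack(stack: np.ndarray, path, frame_times, pixel_pitch: float) -> None:
    """Lossless multi-frame float32 TIFF plus JSON metadata sidecar."""
    stack = np.asarray(stack, dtype=np.float32)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise StackFormatError(f"stack must be (T, H, W), got shape {stack.shape}")
    frame_times = list(map(float, np.atleast_1d(frame_times)))
    if len(frame_times) != stack.shape[0]:
        raise StackFormatError("one frame time per frame is required")
    tifffile.imwrite(path, stack, photometric="minisblack")
    meta = {"frame_times_s": frame_times, "pixel_pitch_um": float(pixel_pitch)}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_stack(path):
    """Read a stack and its sidecar; returns (stack, frame_times, pixel_pitch)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        stack = tifffile.imread(path)
    except Exception as exc:  # tifffile raises several error types
        raise StackFormatError(f"cannot parse TIFF stack {path}: {exc}") from exc
    if stack.ndim == 2:
        stack = stack[None]
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise StackFormatError(
            f"missing metadata sidecar {sidecar}: required keys frame_times_s, pixel_pitch_um"
        )
    meta = json.loads(sidecar.read_text())
    for key in ("frame_times_s", "pixel_pitch_um"):
        if key not in meta:
            raise StackFormatError(f"sidecar {sidecar} lacks required key {key!r}")
    times = np.asarray(meta["frame_times_s"], dtype=float)
    if times.size != stack.shape[0]:
        raise StackFormatError(
            f"sidecar lists {times.size} frame times for {stack.shape[0]} frames"
        )
    return stack, times, float(meta["pixel_pitch_um"])


def write_mask_tiff(mask, path) -> None:
    """Export a domain mask as an integer-labelled TIFF for inspection."""
    tifffile.imwrite(path, mask.labels.astype(np.uint8))


def read_points_csv(path) -> CellPoints:
    """Point table with columns x_um, y_um[, label]."""
    frame = pd.read_csv(path)
    for col in ("x_um", "y_um"):
        if col not in frame.columns:
            raise ValueError(f"point table {path} lacks required column {col!r}")
    label = str(frame["label"].iloc[0]) if "label" in frame.columns and len(frame) else "cell"
    return CellPoints(coordinates=frame[["x_um", "y_um"]].to_numpy(float), label=label)


def write_points_csv(points: CellPoints, path) -> None:
    pd.DataFrame(
        {"x_um": points.coordinates[:, 0], "y_um": points.coordinates[:, 1],
         "label": points.label}
    ).to_csv(path, index=False)


def read_height_profile_csv(path) -> HeightProfile:
    """Height profile with columns position_um, height_nm."""
    frame = pd.read_csv(path)
    for col in ("position_um", "height_nm"):
        if col not in frame.columns:
            raise ValueError(f"height profile {path} lacks required column {col!r}")
    return HeightProfile(
        positions=frame["position_um"].to_numpy(float),
        heights=frame["height_nm"].to_numpy(float),
    )


def write_height_profile_csv(profile: HeightProfile, path) -> None:
    pd.DataFrame({"position_um": profile.positions, "height_nm": profile.heights}).to_csv(
        path, index=False
    )


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_record(config: dict, seed: int | None) -> dict:
    return {
        "package": "luminachip",
        "version": _version,
        "config_hash": config_hash(config),
        "seed": seed,
        "config": config,
    }


def write_result_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return str(obj)


def run_pipeline(config: dict, out_dir) -> dict:
    """Deterministic synth → simulate → permeability-estimate pipeline.

    ``config`` keys (all optional): geometry (ChipGeometry field dict),
    species {name, molecular_weight, D_lumen, D_matrix, partition_k},
    grid_pitch_um, noise {gaussian_sd, poisson_gain}, gain, seed,
    t_f_s, line_length_um.  Writes the stack, its ground truth and the
    PermeabilityResult JSON (with provenance) into ``out_dir``.
    """
    from .permeability import DEFAULT_LINE_LENGTH, DEFAULT_TF, permeability_from_frames
    from .synthetic_data import NoiseModel, synth_permeability_stack
    from .transport import Species, dextran_10kda

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _validate_pipeline_config(config)

    geometry = ChipGeometry(**config.get("geometry", {}))
    species = Species(**config["species"]) if "species" in config else dextran_10kda()
    noise = NoiseModel(**config.get("noise", {}))
    seed = int(config.get("seed", 0))
    pitch = float(config.get("grid_pitch_um", 5.0))
    t_f = float(config.get("t_f_s", DEFAULT_TF))
    line_length = float(config.get("line_length_um", DEFAULT_LINE_LENGTH))

    assay = synth_permeability_stack(
        geometry, species, noise=noise, seed=seed, grid_pitch=pitch,
        gain=float(config.get("gain", 1.0)),
    )
    write_stack(assay.stack, out_dir / "assay.tiff", assay.frame_times, assay.pixel_pitch)
    write_result_json(assay.ground_truth, out_dir / "assay.ground_truth.json")

    i0 = int(np.argmin(np.abs(assay.frame_times - 0.0)))
    i_f = int(np.argmin(np.abs(assay.frame_times - t_f)))
    result = permeability_from_frames(
        assay.stack[i0], assay.stack[i_f], assay.mask, geometry,
        t_0=float(assay.frame_times[i0]), t_f=float(assay.frame_times[i_f]),
        line_length=line_length, provenance="run_pipeline",
    )
    payload = {
        "P_um_per_s": result.P,
        "P_cm_per_s": result.P_cm_per_s,
        "inputs": asdict(result.inputs),
        "provenance": provenance_record(config, seed),
    }
    write_result_json(payload, out_dir / "permeability.json")
    logger.info("pipeline complete: P = %.4g μm/s", result.P)
    return payload


_PIPELINE_KEYS = {
    "geometry", "species", "noise", "gain", "seed", "grid_pitch_um",
    "t_f_s", "line_length_um",
}


def _validate_pipeline_config(config: dict) -> None:
    unknown = set(config) - _PIPELINE_KEYS
    if unknown:
        raise ValueError(
            f"unknown configuration keys {sorted(unknown)}; allowed: {sorted(_PIPELINE_KEYS)}"
        )
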