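"""Study bundle persistence: NIfTI image stack + JSON sidecar + trace CSV.

A study directory contains:

* ``study.nii`` — one 4-D NIfTI of shape (rows, cols, slices_per_block,
  n_couch * m_per_couch), block-major in the last axis;
* ``study.json`` — sidecar with schema version, acquisition config, body
  region and per-block metadata (couch index, block index, timestamp,
  z origin, ground-truth displacement when simulated);
* ``trace.csv`` — surrogate trace (``time_s,amplitude`` plus optional
  ``internal_mm`` ground truth), absent for breath-hold studies.

Round trips are bit exact for the arrays and field-for-field for metadata.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import SchemaError
from .phantom import AcquisitionConfig, CineStudy
from .resp import RespiratoryTrace
from .sorting import SortedVolume

SCHEMA_VERSION = 1

__all__ = ["read_study", "write_study", "write_volume", "read_volume"]


def write_study(study: CineStudy, path) -> None:
    """Persist a study bundle into a directory (created if needed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cfg = study.config
    n, m, s, rows, cols = study.blocks.shape
    arr = np.ascontiguousarray(
        study.blocks.reshape(n * m, s, rows, cols).transpose(2, 3, 1, 0)
    )
    affine = np.diag([cfg.pixel_spacing, cfg.pixel_spacing, cfg.slice_thickness, 1.0])
    img = nib.Nifti1Image(arr.astype(np.float32), affine)
    img.header.set_data_dtype(np.float32)
    nib.save(img, path / "study.nii")

    blocks_meta = []
    for i in range(n):
        for j in range(m):
            meta = {
                "couch_index": i,
                "block_index": j,
                "timestamp_s": float(study.timestamps[i, j]),
                "z_origin_mm": float(study.couch_z_origins[i]),
            }
            if study.ground_truth_internal is not None:
                meta["displacement_mm"] = float(study.ground_truth_internal[i, j])
            blocks_meta.append(meta)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "config": asdict(cfg),
        "body_region": study.body_region,
        "has_trace": study.trace is not None,
        "blocks": blocks_meta,
    }
    with open(path / "study.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    if study.trace is not None:
        study.trace.to_csv(path / "trace.csv")


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise SchemaError(f"missing key {key!r} in {where}")
    return d[key]


def read_study(path) -> CineStudy:
    """Load and validate a study bundle written by :func:`write_study`."""
    path = Path(path)
    sidecar_path = path / "study.json"
    if not sidecar_path.exists():
        raise SchemaError(f"no study.json in {path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    version = _require(sidecar, "schema_version", "study.json")
    if version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema_version {version}")
    cfg_dict = dict(_require(sidecar, "config", "study.json"))
    known = set(AcquisitionConfig.__dataclass_fields__)
    unknown = set(cfg_dict) - known
    if unknown:
        raise SchemaError(f"unknown config key(s) {sorted(unknown)} in study.json")
    cfg_dict["pixel_grid"] = tuple(cfg_dict["pixel_grid"])
    cfg = AcquisitionConfig(**cfg_dict)

    img = nib.load(path / "study.nii")
    arr = np.asarray(img.dataobj, dtype=np.float32)
    rows, cols, s, nm = arr.shape
    n, m = cfg.n_couch, cfg.m_per_couch
    if (rows, cols) != tuple(cfg.pixel_grid) or s != cfg.slices_per_block or nm != n * m:
        raise SchemaError(
            f"image shape {arr.shape} inconsistent with config "
            f"({cfg.pixel_grid} x {cfg.slices_per_block} x {n * m})"
        )
    blocks = arr.transpose(3, 2, 0, 1).reshape(n, m, s, rows, cols)

    blocks_meta = _require(sidecar, "blocks", "study.json")
    if len(blocks_meta) != n * m:
        raise SchemaError("blocks metadata count does not match image stack")
    timestamps = np.zeros((n, m))
    origins = np.zeros(n)
    gt = np.zeros((n, m))
    has_gt = all("displacement_mm" in b for b in blocks_meta)
    for meta in blocks_meta:
        i = _require(meta, "couch_index", "blocks[]")
        j = _require(meta, "block_index", "blocks[]")
        timestamps[i, j] = _require(meta, "timestamp_s", "blocks[]")
        origins[i] = _require(meta, "z_origin_mm", "blocks[]")
        if has_gt:
            gt[i, j] = meta["displacement_mm"]

    trace = None
    if _require(sidecar, "has_trace", "study.json"):
        trace_path = path / "trace.csv"
        if not trace_path.exists():
            raise SchemaError("sidecar declares a trace but trace.csv is missing")
        trace = RespiratoryTrace.from_csv(trace_path)

    return CineStudy(blocks=blocks, timestamps=timestamps,
                     couch_z_origins=origins, config=cfg, trace=trace,
                     ground_truth_internal=gt if has_gt else None,
                     body_region=sidecar.get("body_region", "thorax"))


def write_volume(volume: SortedVolume, path_prefix) -> None:
    """Write a sorted volume as NIfTI plus a provenance JSON."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    arr = np.ascontiguousarray(volume.data.transpose(1, 2, 0))
    affine = np.diag([1.0, 1.0, volume.slice_thickness, 1.0])
    nib.save(nib.Nifti1Image(arr.astype(np.float32), affine), f"{prefix}.nii")
    from .sorting import write_provenance

    write_provenance(volume, f"{prefix}.json")


def read_volume(path_prefix) -> SortedVolume:
    prefix = Path(path_prefix)
    with open(f"{prefix}.json") as fh:
        meta = json.load(fh)
    arr = np.asarray(nib.load(f"{prefix}.nii").dataobj, dtype=np.float32)
    data = arr.transpose(2, 0, 1)
    return SortedVolume(
        data=data,
        z_origin=float(meta["z_origin_mm"]),
        slice_thickness=float(meta["slice_thickness_mm"]),
        slices_per_block=int(meta["slices_per_block"]),
        bin_index=int(meta["bin_index"]),
        bin_centre=float(meta["bin_centre"]),
        method=str(meta["method"]),
        provenance=meta["selections"],
    )
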