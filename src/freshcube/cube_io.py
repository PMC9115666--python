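"""Readers and writers for all artifact formats.

Cubes travel as ENVI pairs (text header + raw binary, BSQ/BIL/BIP);
masks and abundance maps as a flat little-endian binary with a JSON shape
sidecar; per-pixel scalar maps as fixed-colormap PNGs; sample metadata as
CSV. All writers are deterministic for identical inputs.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from matplotlib import colormaps
from PIL import Image

from .core import (
    HyperCube,
    InvalidParameterError,
    Mask,
    SampleRecord,
    WavelengthGrid,
)

__all__ = [
    "write_envi",
    "read_envi",
    "read_metadata",
    "write_metadata",
    "save_array",
    "load_array",
    "export_map",
    "DatasetManifest",
    "write_dataset",
    "load_dataset",
]

_DTYPE_CODES = {4: np.dtype("float32"), 5: np.dtype("float64"),
                12: np.dtype("uint16")}
_CODE_FOR_DTYPE = {v: k for k, v in _DTYPE_CODES.items()}

METADATA_COLUMNS = ["sample_id", "temperature_C", "day", "replicate",
                    "glucosinolate", "is_outlier"]


# ---------------------------------------------------------------- ENVI I/O

def write_envi(cube: HyperCube, base_path: str, interleave: str = "bil",
               dtype: str = "float32", byte_order: int = 0) -> str:
    """Write header (.hdr) + binary pair; returns the header path."""
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise InvalidParameterError(f"unknown interleave '{interleave}'")
    dt = np.dtype(dtype)
    if dt not in _CODE_FOR_DTYPE:
        raise InvalidParameterError(f"unsupported ENVI dtype '{dtype}'")
    dt = dt.newbyteorder("<" if byte_order == 0 else ">")
    h, w, b = cube.shape
    data = cube.data
    if interleave == "bsq":
        arr = np.transpose(data, (2, 0, 1))
    elif interleave == "bil":
        arr = np.transpose(data, (0, 2, 1))
    else:  # bip
        arr = data
    hdr_path = base_path + ".hdr"
    img_path = base_path + ".img"
    arr.astype(dt).tofile(img_path)
    wavelengths = ", ".join(f"{c:.6g}" for c in cube.grid.centers)
    lines = [
        "ENVI",
        "file type = ENVI Standard",
        f"samples = {w}",
        f"lines = {h}",
        f"bands = {b}",
        "header offset = 0",
        f"data type = {_CODE_FOR_DTYPE[np.dtype(dtype)]}",
        f"interleave = {interleave}",
        f"byte order = {byte_order}",
        "wavelength units = Nanometers",
        "wavelength = {" + wavelengths + "}",
    ]
    with open(hdr_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return hdr_path


def _parse_envi_header(hdr_path: str) -> Dict[str, str]:
    with open(hdr_path) as fh:
        text = fh.read()
    fields: Dict[str, str] = {}
    key, buf, in_braces = None, [], False
    for raw_line in text.splitlines():
        line = raw_line.strip()
        if in_braces:
            buf.append(line)
            if "}" in line:
                fields[key] = " ".join(buf)
                in_braces = False
            continue
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{") and "}" not in value:
            buf = [value]
            in_braces = True
        else:
            fields[key] = value
    return fields


def read_envi(hdr_path: str) -> HyperCube:
    """Read an ENVI header/binary pair into a HyperCube."""
    if not os.path.exists(hdr_path):
        raise InvalidParameterError(f"missing header {hdr_path}")
    fields = _parse_envi_header(hdr_path)
    try:
        w = int(fields["samples"])
        h = int(fields["lines"])
        b = int(fields["bands"])
        code = int(fields["data type"])
        interleave = fields.get("interleave", "bsq").lower()
        byte_order = int(fields.get("byte order", "0"))
    except KeyError as exc:
        raise InvalidParameterError(f"ENVI header missing field {exc}") from exc
    if "wavelength" not in fields:
        raise InvalidParameterError("ENVI header has no wavelength list")
    wl_text = fields["wavelength"].strip().strip("{}")
    centers = np.array([float(tok) for tok in wl_text.split(",") if tok.strip()])
    if centers.size != b:
        raise InvalidParameterError("wavelength list length != bands")
    if code not in _DTYPE_CODES:
        raise InvalidParameterError(f"unsupported ENVI data type {code}")
    dt = _DTYPE_CODES[code].newbyteorder("<" if byte_order == 0 else ">")
    img_path = _find_binary(hdr_path)
    raw = np.fromfile(img_path, dtype=dt)
    if raw.size != h * w * b:
        raise InvalidParameterError(
            f"binary holds {raw.size} values, header implies {h * w * b}"
        )
    if interleave == "bsq":
        data = raw.reshape(b, h, w).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(h, b, w).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(h, w, b)
    else:
        raise InvalidParameterError(f"unknown interleave '{interleave}'")
    return HyperCube(data=data.astype(float), grid=WavelengthGrid(centers=centers),
                     provenance=[f"read_envi({os.path.basename(hdr_path)})"])


def _find_binary(hdr_path: str) -> str:
    base = hdr_path[:-4] if hdr_path.endswith(".hdr") else hdr_path
    for ext in (".img", ".bil", ".bsq", ".bip", ".dat", ""):
        candidate = base + ext
        if candidate != hdr_path and os.path.exists(candidate):
            return candidate
    raise InvalidParameterError(f"no binary found for header {hdr_path}")


# ------------------------------------------------------------- metadata CSV

def write_metadata(records: Sequence[SampleRecord], path: str) -> None:
    frame = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "temperature_C": [r.temperature for r in records],
            "day": [r.day for r in records],
            "replicate": [r.replicate for r in records],
            "glucosinolate": [r.glucosinolate for r in records],
            "is_outlier": [r.is_outlier for r in records],
        }
    )
    frame.to_csv(path, index=False)


def read_metadata(path: str) -> List[SampleRecord]:
    """Typed sample records from CSV; unknown columns become annotations."""
    frame = pd.read_csv(path, float_precision="round_trip")
    required = [c for c in METADATA_COLUMNS if c != "is_outlier"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise InvalidParameterError(f"metadata CSV missing columns: {missing}")
    keys = list(zip(frame["temperature_C"], frame["day"], frame["replicate"]))
    if len(set(keys)) != len(keys):
        raise InvalidParameterError(
            "duplicate (temperature, day, replicate) rows in metadata"
        )
    extra_cols = [c for c in frame.columns if c not in METADATA_COLUMNS]
    records = []
    for _, row in frame.iterrows():
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                temperature=float(row["temperature_C"]),
                day=int(row["day"]),
                replicate=int(row["replicate"]),
                glucosinolate=float(row["glucosinolate"]),
                is_outlier=bool(row.get("is_outlier", False)),
                annotations={c: row[c] for c in extra_cols},
            )
        )
    return records


# ------------------------------------------------- portable binary arrays

def save_array(arr: np.ndarray, base_path: str) -> None:
    """Flat little-endian binary plus JSON sidecar with shape and dtype."""
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        out = arr
    else:
        out = arr.astype("<f4") if arr.dtype.kind == "f" else arr.astype("<i4")
    out.tofile(base_path + ".bin")
    meta = {"shape": list(arr.shape), "dtype": str(out.dtype.name)}
    with open(base_path + ".json", "w") as fh:
        json.dump(meta, fh, sort_keys=True)


def load_array(base_path: str) -> np.ndarray:
    with open(base_path + ".json") as fh:
        meta = json.load(fh)
    dt = np.dtype(meta["dtype"])
    if dt.itemsize > 1:
        dt = dt.newbyteorder("<")
    arr = np.fromfile(base_path + ".bin", dtype=dt)
    return arr.reshape(meta["shape"])


# ----------------------------------------------------------- map rendering

def export_map(values: np.ndarray, mask: Mask, path: str,
               colormap: str = "viridis") -> str:
    """Write per-pixel scalars in [0, 1] as a fixed-colormap PNG.

    Masked-out pixels render black; identical inputs give identical bytes.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != mask.shape:
        raise InvalidParameterError("map and mask shapes differ")
    if values.min() < -1e-9 or values.max() > 1 + 1e-9:
        raise InvalidParameterError("map values must lie in [0, 1]; clip first")
    cmap = colormaps[colormap]
    rgba = cmap(np.clip(values, 0.0, 1.0), bytes=True)
    rgb = rgba[..., :3].copy()
    rgb[mask.values == 0] = 0
    Image.fromarray(rgb, mode="RGB").save(path, format="PNG")
    return path


# -------------------------------------------------------- dataset bundles

@dataclass
class DatasetManifest:
    """Index of an on-disk dataset: one entry per sample."""

    samples: List[dict]
    metadata_csv: str = "design.csv"
    interleave: str = "bil"
    dtype: str = "float32"
    byte_order: int = 0
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "samples": self.samples,
                "metadata_csv": self.metadata_csv,
                "interleave": self.interleave,
                "dtype": self.dtype,
                "byte_order": self.byte_order,
                "extras": self.extras,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "DatasetManifest":
        obj = json.loads(text)
        return cls(
            samples=obj["samples"],
            metadata_csv=obj.get("metadata_csv", "design.csv"),
            interleave=obj.get("interleave", "bil"),
            dtype=obj.get("dtype", "float32"),
            byte_order=obj.get("byte_order", 0),
            extras=obj.get("extras", {}),
        )


def write_dataset(out_dir: str, records: Sequence[SampleRecord],
                  params, endmembers) -> DatasetManifest:
    """Render and write the full synthetic dataset (cubes + truth + CSV)."""
    from .scene_sim import render_cube

    os.makedirs(out_dir, exist_ok=True)
    entries = []
    ids = set()
    for record in records:
        if record.sample_id in ids:
            raise InvalidParameterError(f"duplicate sample id {record.sample_id}")
        ids.add(record.sample_id)
        raw, white, dark, truth = render_cube(record, params, endmembers)
        sdir = os.path.join(out_dir, record.sample_id)
        os.makedirs(sdir, exist_ok=True)
        entry = {"sample_id": record.sample_id}
        for tag, cube in (("raw", raw), ("white", white), ("dark", dark)):
            hdr = write_envi(cube, os.path.join(sdir, tag))
            entry[tag] = os.path.relpath(hdr, out_dir)
        save_array(truth.abundances, os.path.join(sdir, "truth_abundances"))
        save_array(truth.foreground_mask.values, os.path.join(sdir, "fg_mask"))
        save_array(truth.floret_mask.values, os.path.join(sdir, "floret_mask"))
        entry["truth"] = {
            "abundances": f"{record.sample_id}/truth_abundances",
            "fg_mask": f"{record.sample_id}/fg_mask",
            "floret_mask": f"{record.sample_id}/floret_mask",
            "target_index": 1,
            "mean_senesced_fraction": truth.mean_senesced_fraction,
        }
        entries.append(entry)
    em_frame = pd.DataFrame(endmembers.spectra.T,
                            columns=list(endmembers.names or
                                         range(endmembers.n_endmembers)))
    em_frame.insert(0, "wavelength_nm", endmembers.grid.centers)
    em_frame.to_csv(os.path.join(out_dir, "endmembers.csv"), index=False)
    write_metadata(records, os.path.join(out_dir, "design.csv"))
    manifest = DatasetManifest(samples=entries)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        fh.write(manifest.to_json())
    return manifest


def load_dataset(data_dir: str):
    """Load a written dataset; validates referenced files and grid equality.

    Returns (records, samples) where samples maps sample_id to a dict with
    raw/white/dark HyperCubes and truth arrays.
    """
    with open(os.path.join(data_dir, "manifest.json")) as fh:
        manifest = DatasetManifest.from_json(fh.read())
    records = read_metadata(os.path.join(data_dir, manifest.metadata_csv))
    samples = {}
    grid = None
    for entry in manifest.samples:
        sid = entry["sample_id"]
        cubes = {}
        for tag in ("raw", "white", "dark"):
            path = os.path.join(data_dir, entry[tag])
            if not os.path.exists(path):
                raise InvalidParameterError(f"manifest references missing {path}")
            cubes[tag] = read_envi(path)
        if grid is None:
            grid = cubes["raw"].grid
        elif not (grid == cubes["raw"].grid):
            raise InvalidParameterError(f"grid mismatch for sample {sid}")
        truth = entry.get("truth", {})
        loaded_truth = {}
        for key in ("abundances", "fg_mask", "floret_mask"):
            if key in truth:
                loaded_truth[key] = load_array(os.path.join(data_dir, truth[key]))
        loaded_truth.update({k: v for k, v in truth.items()
                             if k not in loaded_truth})
        samples[sid] = {**cubes, "truth": loaded_truth}
    return records, samples
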