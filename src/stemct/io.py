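"""Reading and writing slice stacks, calibration sidecars and trait tables.

Supported stack inputs:

* a DICOM series (one file per slice) — pixel spacing and slice thickness
  are read from the headers and the stored values are windowed to the 8-bit
  scale the segmentation thresholds assume;
* a directory of TIFF or PNG slices, or a single multi-page TIFF, plus a
  JSON calibration sidecar ``calibration.json`` with keys
  ``pixel_spacing_mm`` and ``slice_thickness_mm``.

Slices are ordered by DICOM instance number or by sorted filename.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .imaging import CalibratedSlice

__all__ = [
    "read_calibration",
    "write_calibration",
    "read_stack",
    "write_stack",
    "read_node_annotations",
    "write_truth_table",
]

CALIBRATION_NAME = "calibration.json"


def read_calibration(path: Path) -> dict:
    with open(path) as fh:
        data = json.load(fh)
    for key in ("pixel_spacing_mm", "slice_thickness_mm"):
        if key not in data:
            raise ValueError(f"calibration sidecar {path} missing key {key!r}")
        if not data[key] > 0:
            raise ValueError(f"calibration key {key} must be positive")
    return data


def write_calibration(path: Path, pixel_spacing_mm: float, slice_thickness_mm: float) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "pixel_spacing_mm": pixel_spacing_mm,
                "slice_thickness_mm": slice_thickness_mm,
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def _to_uint8(arr: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    """Window arbitrary stored values (e.g. Hounsfield units) to [0, 255]."""
    arr = np.asarray(arr, dtype=float)
    if window is None:
        lo, hi = float(arr.min()), float(arr.max())
        if hi <= lo:
            hi = lo + 1.0
    else:
        lo, hi = window
    scaled = np.clip((arr - lo) / (hi - lo), 0.0, 1.0) * 255.0
    return np.rint(scaled).astype(np.uint8)


def read_stack(
    path: str | Path,
    window: tuple[float, float] | None = None,
) -> list[CalibratedSlice]:
    """Read a calibrated slice stack from a directory or multi-page TIFF."""
    path = Path(path)
    if path.is_file():
        return _read_multipage_tiff(path)
    dicoms = sorted(path.glob("*.dcm"))
    if dicoms:
        return _read_dicom_series(dicoms, window)
    images = sorted(
        p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".png")
    )
    if not images:
        raise FileNotFoundError(f"no DICOM/TIFF/PNG slices found under {path}")
    cal = read_calibration(path / CALIBRATION_NAME)
    slices = []
    for z, img_path in enumerate(images):
        arr = iio.imread(img_path)
        if arr.ndim == 3:  # RGB(A) PNG: collapse to grayscale
            arr = arr[..., :3].mean(axis=-1)
        if arr.dtype != np.uint8:
            arr = _to_uint8(arr, window)
        slices.append(
            CalibratedSlice(
                pixels=np.asarray(arr, dtype=np.uint8),
                pixel_spacing=cal["pixel_spacing_mm"],
                slice_thickness=cal["slice_thickness_mm"],
                z_index=z,
            )
        )
    return slices


def _read_multipage_tiff(path: Path) -> list[CalibratedSlice]:
    cal = read_calibration(path.parent / CALIBRATION_NAME)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    return [
        CalibratedSlice(
            pixels=stack[z].astype(np.uint8),
            pixel_spacing=cal["pixel_spacing_mm"],
            slice_thickness=cal["slice_thickness_mm"],
            z_index=z,
        )
        for z in range(stack.shape[0])
    ]


def _read_dicom_series(
    paths: list[Path], window: tuple[float, float] | None
) -> list[CalibratedSlice]:
    import pydicom

    datasets = [pydicom.dcmread(str(p)) for p in paths]
    datasets.sort(key=lambda ds: int(getattr(ds, "InstanceNumber", 0)))
    slices = []
    for z, ds in enumerate(datasets):
        spacing = float(ds.PixelSpacing[0])
        thickness = float(ds.SliceThickness)
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        slices.append(
            CalibratedSlice(
                pixels=_to_uint8(arr, window),
                pixel_spacing=spacing,
                slice_thickness=thickness,
                z_index=z,
            )
        )
    return slices


def write_stack(
    slices: list[CalibratedSlice],
    out_dir: str | Path,
    prefix: str = "slice",
) -> Path:
    """Write one TIFF per slice plus the calibration sidecar; returns the
    directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for slc in slices:
        tifffile.imwrite(out_dir / f"{prefix}_{slc.z_index:05d}.tif", slc.pixels)
    if slices:
        write_calibration(
            out_dir / CALIBRATION_NAME,
            slices[0].pixel_spacing,
            slices[0].slice_thickness,
        )
    return out_dir


def read_node_annotations(path: str | Path) -> dict[str, list[int]]:
    """Node annotation CSV with columns (stem_id, node_z_index)."""
    df = pd.read_csv(path)
    required = {"stem_id", "node_z_index"}
    if not required <= set(df.columns):
        raise ValueError(f"node annotation file {path} must have columns {required}")
    return {
        str(stem): sorted(int(z) for z in sub["node_z_index"])
        for stem, sub in df.groupby("stem_id")
    }


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False, float_format="%.6f")
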