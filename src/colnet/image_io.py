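"""Image containers and on-disk formats.

Multi-modal slices are ``(channel, row, column)`` float arrays stored as one
NIfTI per case with channels on the 4th axis; binary masks are 2-D uint8
NIfTI (or 8-bit PNG). A dataset is tied together by a ``manifest.json``
listing case ids, roles, relative paths and pixel spacing. All indices are
0-based row-major.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "MultiModalSlice", "LabelMask", "read_volume", "write_volume",
    "read_mask", "write_mask", "read_manifest", "write_manifest",
]


@dataclass
class MultiModalSlice:
    """A C*H*W multi-modal image slice with isotropic in-plane spacing."""

    values: np.ndarray            # (C, H, W) float32
    spacing_mm: float = 1.0
    case_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError(f"expected (C, H, W) array, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1], self.values.shape[2]


@dataclass
class LabelMask:
    """A binary H*W lesion mask."""

    values: np.ndarray            # (H, W) uint8 in {0, 1}
    spacing_mm: float = 1.0

    def __post_init__(self):
        arr = np.asarray(self.values)
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(
                f"mask must be binary; found values {uniq[~np.isin(uniq, (0, 1))][:5]}")
        if arr.ndim != 2:
            raise ValueError(f"expected (H, W) mask, got shape {arr.shape}")
        self.values = arr.astype(np.uint8)
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")


# -- NIfTI / PNG -----------------------------------------------------------

def write_volume(array: np.ndarray, spacing_mm: float, path) -> Path:
    """Write an image array as NIfTI (gzipped when the suffix is .nii.gz).

    A (C, H, W) array is stored with shape (H, W, 1, C) so the spatial axes
    occupy the NIfTI spatial dimensions and channels the 4th; a 2-D array is
    stored as (H, W).
    """
    path = Path(path)
    array = np.asarray(array)
    if not np.all(np.isfinite(array)):
        raise ValueError("refusing to write non-finite values")
    if path.exists():
        logger.warning("overwriting existing file %s", path)
    if array.ndim == 3:
        data = np.transpose(array, (1, 2, 0))[:, :, None, :]
    elif array.ndim == 2:
        data = array
    else:
        raise ValueError(f"expected 2-D or 3-D array, got shape {array.shape}")
    affine = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((spacing_mm,) * min(data.ndim, 3) + (1.0,) * max(data.ndim - 3, 0))
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise OSError(f"cannot write NIfTI to {path}: {exc}") from exc
    return path


def _load_nifti(path: Path) -> tuple[np.ndarray, float]:
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise OSError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    spacing = float(img.header.get_zooms()[0])
    return data, spacing


def read_volume(path, case_id: str | None = None,
                spacing_mm: float | None = None) -> MultiModalSlice:
    """Read a multi-modal slice from NIfTI or PNG.

    NIfTI spacing comes from the header; PNG has no spacing so the caller
    (normally the manifest) supplies it, defaulting to 1.0 mm.
    """
    path = Path(path)
    if path.suffix.lower() == ".png":
        arr = np.asarray(Image.open(path), dtype=np.float32)
        if arr.ndim == 2:
            arr = arr[None]
        else:
            arr = np.transpose(arr, (2, 0, 1))
        return MultiModalSlice(arr, spacing_mm=spacing_mm or 1.0,
                               case_id=case_id or path.stem)
    data, hdr_spacing = _load_nifti(path)
    if data.ndim == 4:                       # (H, W, 1, C) -> (C, H, W)
        arr = np.transpose(data[:, :, 0, :], (2, 0, 1))
    elif data.ndim == 3 and data.shape[2] == 1:
        arr = data[:, :, 0][None]
    elif data.ndim == 2:
        arr = data[None]
    else:
        raise ValueError(f"unsupported NIfTI layout {data.shape} in {path}")
    return MultiModalSlice(arr.astype(np.float32),
                           spacing_mm=spacing_mm or hdr_spacing,
                           case_id=case_id or path.stem)


def write_mask(mask: LabelMask, path) -> Path:
    path = Path(path)
    if path.suffix.lower() == ".png":
        if path.exists():
            logger.warning("overwriting existing file %s", path)
        Image.fromarray(mask.values * np.uint8(255), mode="L").save(path)
        return path
    return write_volume(mask.values.astype(np.uint8), mask.spacing_mm, path)


def read_mask(path, spacing_mm: float | None = None) -> LabelMask:
    path = Path(path)
    if path.suffix.lower() == ".png":
        arr = np.asarray(Image.open(path).convert("L"))
        vals = np.unique(arr)
        if not np.isin(vals, (0, 255)).all():
            raise ValueError(f"mask PNG {path} is not binary (values {vals[:5]})")
        return LabelMask((arr > 0).astype(np.uint8), spacing_mm=spacing_mm or 1.0)
    data, hdr_spacing = _load_nifti(path)
    data = np.squeeze(data)
    if data.ndim != 2:
        raise ValueError(f"mask file {path} is not a 2-D slice (shape {data.shape})")
    return LabelMask(data, spacing_mm=spacing_mm or hdr_spacing)


# -- manifests -------------------------------------------------------------

def write_manifest(records, path, seed: int | None = None,
                   config: dict | None = None) -> Path:
    """Serialize SampleRecords (see :mod:`colnet.phantom`) to manifest JSON.

    Each record entry carries case_id, role, image/mask relative paths and
    spacing; images and masks are written next to the manifest.
    """
    path = Path(path)
    root = path.parent
    root.mkdir(parents=True, exist_ok=True)
    entries = []
    seen: set[str] = set()
    for rec in records:
        if rec.case_id in seen:
            raise ValueError(f"duplicate case_id {rec.case_id!r}")
        seen.add(rec.case_id)
        img_rel = f"{rec.case_id}_image.nii.gz"
        write_volume(rec.image.values, rec.spacing_mm, root / img_rel)
        entry = {
            "case_id": rec.case_id,
            "role": rec.role,
            "image": img_rel,
            "spacing_mm": rec.spacing_mm,
        }
        if rec.mask is not None:
            mask_rel = f"{rec.case_id}_mask.nii.gz"
            write_mask(rec.mask, root / mask_rel)
            entry["mask"] = mask_rel
        entries.append(entry)
    doc = {"records": entries}
    if seed is not None:
        doc["seed"] = seed
    if config is not None:
        doc["config"] = config
    path.write_text(json.dumps(doc, indent=2))
    return path


def read_manifest(path):
    """Read a manifest and load its images/masks into SampleRecords."""
    from .phantom import SampleRecord   # deferred: phantom imports this module

    path = Path(path)
    doc = json.loads(path.read_text())
    root = path.parent
    records = []
    seen: set[str] = set()
    for entry in doc["records"]:
        cid = entry["case_id"]
        if cid in seen:
            raise ValueError(f"duplicate case_id {cid!r} in manifest {path}")
        seen.add(cid)
        img_path = Path(entry["image"])
        if not img_path.is_absolute():
            img_path = root / img_path
        if not img_path.exists():
            raise FileNotFoundError(f"manifest {path} references missing file {img_path}")
        spacing = float(entry.get("spacing_mm", 1.0))
        image = read_volume(img_path, case_id=cid, spacing_mm=spacing)
        mask = None
        if "mask" in entry:
            mask_path = Path(entry["mask"])
            if not mask_path.is_absolute():
                mask_path = root / mask_path
            if not mask_path.exists():
                raise FileNotFoundError(
                    f"manifest {path} references missing file {mask_path}")
            mask = read_mask(mask_path, spacing_mm=spacing)
        records.append(SampleRecord(case_id=cid, image=image, mask=mask,
                                    role=entry.get("role"), spacing_mm=spacing))
    return records
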