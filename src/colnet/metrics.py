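"""SPES-style evaluation metrics: Dice coefficient, Hausdorff distance and
average symmetric surface distance, all spacing-aware.

Surface pixels are foreground pixels with at least one background pixel
among their 8-neighbours; the image border counts as background. HD and
ASSD are computed between the two surface point sets with exact Euclidean
distance transforms and reported in millimetres. Both are undefined when
either mask is empty; :func:`evaluate_cases` flags such cases and excludes
them from the HD/ASSD aggregates while still counting their Dice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import LabelMask

__all__ = [
    "SurfaceSet", "MetricReport", "dice_coefficient", "extract_surface",
    "hausdorff_distance", "assd", "evaluate_cases", "summarize_reports",
]

_FULL_3X3 = np.ones((3, 3), dtype=bool)


@dataclass
class SurfaceSet:
    points: np.ndarray            # (n, 2) integer (row, col) coordinates
    spacing_mm: float = 1.0


@dataclass
class MetricReport:
    case_id: str
    dc: float
    hd_mm: float                  # NaN when flagged
    assd_mm: float                # NaN when flagged
    spacing_mm: float
    empty_flag: bool = False      # either mask empty: HD/ASSD undefined


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, LabelMask):
        return mask.values.astype(bool)
    arr = np.asarray(mask)
    if not np.isin(np.unique(arr), (0, 1)).all():
        raise ValueError("mask must be binary")
    return arr.astype(bool)


def dice_coefficient(pred, truth) -> float:
    """2|X n Y| / (|X| + |Y|); 1.0 when both masks are empty (perfect match)."""
    p, t = _as_bool(pred), _as_bool(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    denom = p.sum() + t.sum()
    if denom == 0:
        warnings.warn("both masks empty; Dice defined as 1.0 by convention")
        return 1.0
    return float(2.0 * np.logical_and(p, t).sum() / denom)


def extract_surface(mask, spacing_mm: float = 1.0) -> SurfaceSet:
    """Foreground pixels 8-adjacent to background (border = background)."""
    m = _as_bool(mask)
    if not m.any():
        return SurfaceSet(points=np.empty((0, 2), dtype=np.int64),
                          spacing_mm=spacing_mm)
    interior = ndimage.binary_erosion(m, structure=_FULL_3X3, border_value=0)
    surface = m & ~interior
    return SurfaceSet(points=np.argwhere(surface), spacing_mm=spacing_mm)


def _surface_distances(pred: np.ndarray, truth: np.ndarray,
                       spacing_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Directed nearest-surface distances (pred->truth, truth->pred) in mm."""
    ps = extract_surface(pred).points
    ts = extract_surface(truth).points
    shape = pred.shape
    ps_mask = np.zeros(shape, dtype=bool)
    ps_mask[tuple(ps.T)] = True
    ts_mask = np.zeros(shape, dtype=bool)
    ts_mask[tuple(ts.T)] = True
    # EDT of the complement gives the exact distance to the nearest surface pixel
    dt_truth = ndimage.distance_transform_edt(~ts_mask, sampling=spacing_mm)
    dt_pred = ndimage.distance_transform_edt(~ps_mask, sampling=spacing_mm)
    return dt_truth[tuple(ps.T)], dt_pred[tuple(ts.T)]


def hausdorff_distance(pred, truth, spacing_mm: float = 1.0) -> float:
    """max of the two directed maximum surface distances, in mm."""
    p, t = _as_bool(pred), _as_bool(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if not p.any() or not t.any():
        raise ValueError("Hausdorff distance is undefined for an empty mask")
    d_pt, d_tp = _surface_distances(p, t, spacing_mm)
    return float(max(d_pt.max(), d_tp.max()))


def assd(pred, truth, spacing_mm: float = 1.0) -> float:
    """Average symmetric surface distance in mm: mean of the two directed means."""
    p, t = _as_bool(pred), _as_bool(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if not p.any() or not t.any():
        raise ValueError("ASSD is undefined for an empty mask")
    d_pt, d_tp = _surface_distances(p, t, spacing_mm)
    return float(0.5 * (d_pt.mean() + d_tp.mean()))


def evaluate_cases(predictions: dict, truths: dict,
                   spacing_mm: float = 1.0) -> tuple[list[MetricReport], dict]:
    """Per-case DC/HD/ASSD plus mean (+/- sample sd) aggregates.

    ``predictions`` and ``truths`` map case_id -> binary mask; their key sets
    must match. Cases where either mask is empty are flagged: Dice is still
    reported (1.0 if both empty, 0.0 otherwise) but HD/ASSD are NaN and
    excluded from the aggregates.
    """
    missing = sorted(set(predictions) ^ set(truths))
    if missing:
        raise ValueError(f"unmatched case ids: {missing}")
    reports = []
    for cid in sorted(predictions):
        p, t = _as_bool(predictions[cid]), _as_bool(truths[cid])
        dc = dice_coefficient(p, t)
        if p.any() and t.any():
            reports.append(MetricReport(cid, dc, hausdorff_distance(p, t, spacing_mm),
                                        assd(p, t, spacing_mm), spacing_mm))
        else:
            warnings.warn(f"case {cid}: empty mask, HD/ASSD flagged as missing")
            reports.append(MetricReport(cid, dc, float("nan"), float("nan"),
                                        spacing_mm, empty_flag=True))
    return reports, summarize_reports(reports)


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    if values.size == 0:
        return float("nan"), float("nan")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return float(np.mean(values)), sd


def summarize_reports(reports: list[MetricReport]) -> dict:
    dcs = np.array([r.dc for r in reports], dtype=float)
    hds = np.array([r.hd_mm for r in reports if not r.empty_flag], dtype=float)
    assds = np.array([r.assd_mm for r in reports if not r.empty_flag], dtype=float)
    dc_m, dc_s = _mean_sd(dcs)
    hd_m, hd_s = _mean_sd(hds)
    as_m, as_s = _mean_sd(assds)
    return {
        "dc_mean": dc_m, "dc_sd": dc_s,
        "hd_mean_mm": hd_m, "hd_sd_mm": hd_s,
        "assd_mean_mm": as_m, "assd_sd_mm": as_s,
        "n_cases": len(reports),
        "n_flagged_empty": sum(r.empty_flag for r in reports),
    }


def reports_to_csv(reports: list[MetricReport], path) -> None:
    """Write per-case rows plus MEAN/SD summary rows to ``metrics.csv``."""
    df = pd.DataFrame([{
        "case_id": r.case_id, "dc": r.dc, "hd_mm": r.hd_mm,
        "assd_mm": r.assd_mm, "flags": "empty" if r.empty_flag else "",
    } for r in reports])
    s = summarize_reports(reports)
    df = pd.concat([df, pd.DataFrame([
        {"case_id": "MEAN", "dc": s["dc_mean"], "hd_mm": s["hd_mean_mm"],
         "assd_mm": s["assd_mean_mm"], "flags": ""},
        {"case_id": "SD", "dc": s["dc_sd"], "hd_mm": s["hd_sd_mm"],
         "assd_mm": s["assd_sd_mm"], "flags": ""},
    ])], ignore_index=True)
    df.to_csv(path, index=False)
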