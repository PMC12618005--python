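"""Fluorescence quantification: z-projection, ROI means, per-nucleus means.

Mirrors the standard confocal quantification pipeline: an average-intensity
z-projection collapses the stack, mean fluorescence is read over manually
drawn anatomical ROIs (e.g. stomach / midgut / hindgut / rectum for gut DHE
signal), and per-nucleus mean fluorescence is read over an integer label
mask (e.g. Cellpose output for γH2AX or CPD staining).  Segmentation itself
is out of scope — masks and polygons are inputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath

__all__ = [
    "z_project_mean",
    "z_project_max",
    "roi_mean_fluorescence",
    "nucleus_mean_fluorescence",
    "quantify_stack",
    "read_roi_json",
    "read_tiff",
    "write_tiff",
]


def z_project_mean(stack: np.ndarray) -> np.ndarray:
    """Pixelwise arithmetic mean over slices (ImageJ "Average Intensity")."""
    s = np.asarray(stack, dtype=float)
    if s.ndim == 2:
        s = s[None]
    if s.ndim != 3 or s.shape[0] < 1:
        raise ValueError("stack must be slices x height x width with >= 1 slice")
    return s.mean(axis=0)


def z_project_max(stack: np.ndarray) -> np.ndarray:
    """Pixelwise maximum over slices."""
    s = np.asarray(stack, dtype=float)
    if s.ndim == 2:
        s = s[None]
    if s.ndim != 3 or s.shape[0] < 1:
        raise ValueError("stack must be slices x height x width with >= 1 slice")
    return s.max(axis=0)


def roi_mean_fluorescence(
    image: np.ndarray, rois: Mapping[str, Sequence[tuple[float, float]]]
) -> pd.DataFrame:
    """Per-ROI mean fluorescence over pixels whose centers fall inside the polygon.

    ``rois`` maps region name -> list of (x, y) polygon vertices in pixel
    coordinates; pixel (row r, col c) has center (c, r).  Returns a DataFrame
    with columns region, n_pixels, mean_fluorescence.  A polygon enclosing no
    pixel center is an error naming the ROI.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D (project the stack first)")
    h, w = img.shape
    xx, yy = np.meshgrid(np.arange(w), np.arange(h))
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    rows = []
    for name, verts in rois.items():
        poly = MplPath(np.asarray(verts, dtype=float))
        inside = poly.contains_points(pts).reshape(h, w)
        n = int(inside.sum())
        if n == 0:
            raise ValueError(f"ROI {name!r} contains no pixel centers")
        rows.append(
            {"region": name, "n_pixels": n, "mean_fluorescence": float(img[inside].mean())}
        )
    return pd.DataFrame(rows)


def nucleus_mean_fluorescence(
    image: np.ndarray,
    mask: np.ndarray,
    background_policy: str = "none",
) -> pd.DataFrame:
    """Mean fluorescence per nucleus area from an integer label mask.

    Label 0 is background; each label k > 0 yields the mean intensity over
    its pixels.  background_policy ``median`` subtracts the median of the
    background pixels from every mean (``none``, the default, reports raw
    means as the figures do).  An empty label set returns an empty table.
    """
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask)
    if img.shape != m.shape:
        raise ValueError("mask must align with the image")
    if background_policy not in ("none", "median"):
        raise ValueError("background_policy must be 'none' or 'median'")
    labels = np.unique(m)
    labels = labels[labels > 0]
    offset = 0.0
    if background_policy == "median":
        bg = img[m == 0]
        if bg.size:
            offset = float(np.median(bg))
    rows = []
    flat_m, flat_i = m.ravel(), img.ravel()
    sums = np.bincount(flat_m, weights=flat_i)
    counts = np.bincount(flat_m)
    for k in labels:
        rows.append(
            {
                "region": int(k),
                "n_pixels": int(counts[k]),
                "mean_fluorescence": float(sums[k] / counts[k] - offset),
            }
        )
    return pd.DataFrame(rows, columns=["region", "n_pixels", "mean_fluorescence"])


def quantify_stack(
    stack: np.ndarray,
    mask: np.ndarray,
    projection: str = "mean",
    background_policy: str = "none",
) -> pd.DataFrame:
    """Project a stack (mean or max) and quantify per-nucleus means."""
    if projection == "mean":
        img = z_project_mean(stack)
    elif projection == "max":
        img = z_project_max(stack)
    else:
        raise ValueError("projection must be 'mean' or 'max'")
    return nucleus_mean_fluorescence(img, mask, background_policy)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_roi_json(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """ROI polygons as JSON: {name: [[x, y], ...], ...}."""
    with open(path) as fh:
        raw = json.load(fh)
    return {name: [tuple(pt) for pt in verts] for name, verts in raw.items()}


def read_tiff(path: str | Path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)


def write_tiff(path: str | Path, array: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(path, array)
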