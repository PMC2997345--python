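"""Gel/column band densitometry: background-subtracted intensity per pixel.

Band intensity is quantified as the mean absorbance over a rectangular
region of interest minus the mean over a background region, i.e. the
(AU - B) / px^2 statistic of classical image-gauge densitometry.  "Per
square pixel" is read as a per-pixel mean, the only dimensionally
consistent interpretation; negative values (band dimmer than background)
are reported, not clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

logger = logging.getLogger("raftomics")

#: 0-based, half-open pixel rectangle (x0, y0, x1, y1)
Roi = tuple[int, int, int, int]


@dataclass(frozen=True)
class BandMeasurement:
    roi: Roi
    background_roi: Roi
    au_per_px2: float
    area_px2: int
    negative: bool


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    df: float
    p_value: float
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    method: str


def load_grayscale(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF image as a float array normalized to [0, 1].

    8- and 16-bit integer images divide by their dtype maximum so the
    statistic is camera-format independent; multichannel images are
    rejected (densitometry needs a single absorbance channel).
    """
    from PIL import Image

    img = Image.open(path)
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected single-channel image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    return arr.astype(float)


def _check_roi(image: np.ndarray, roi: Roi, name: str) -> None:
    x0, y0, x1, y1 = roi
    h, w = image.shape
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise ValueError(f"{name} {roi} out of bounds or zero-area for image {w}x{h}")


def quantify_band(image: np.ndarray, roi: Roi, background_roi: Roi) -> BandMeasurement:
    """Mean ROI intensity minus mean background intensity.

    ``image`` is a 2-D array (row = y); ROIs are 0-based half-open
    rectangles (x0, y0, x1, y1) and must be in-bounds with positive area.
    """
    if image.ndim != 2:
        raise ValueError(f"expected 2-D grayscale image, got shape {image.shape}")
    _check_roi(image, roi, "roi")
    _check_roi(image, background_roi, "background_roi")
    x0, y0, x1, y1 = roi
    bx0, by0, bx1, by1 = background_roi
    band = image[y0:y1, x0:x1]
    bg = image[by0:by1, bx0:bx1]
    au = float(band.mean() - bg.mean())
    if au < 0:
        logger.warning("band intensity below background (%.4g); reporting negative value", au)
    return BandMeasurement(
        roi=roi,
        background_roi=background_roi,
        au_per_px2=au,
        area_px2=(x1 - x0) * (y1 - y0),
        negative=au < 0,
    )


def compare_groups(
    measurements_a: list[float] | list[BandMeasurement],
    measurements_b: list[float] | list[BandMeasurement],
    method: str = "welch",
) -> GroupComparison:
    """Two-tailed two-sample comparison of band intensities.

    ``welch`` (default) and ``pooled`` run the unpaired t-test; the
    Mann-Whitney U test is available as a nonparametric alternative
    (its ``df`` is reported as NaN).
    """
    def values(ms) -> np.ndarray:
        return np.array(
            [m.au_per_px2 if isinstance(m, BandMeasurement) else float(m) for m in ms]
        )

    a, b = values(measurements_a), values(measurements_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"need >= 2 measurements per group, got {len(a)} and {len(b)}")
    if method in ("welch", "pooled"):
        res = stats.ttest_ind(a, b, equal_var=(method == "pooled"))
        stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    elif method == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        stat, p, df = float(res.statistic), float(res.pvalue), float("nan")
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(
        statistic=stat,
        df=df,
        p_value=p,
        mean_a=float(a.mean()),
        sem_a=float(stats.sem(a)),
        mean_b=float(b.mean()),
        sem_b=float(stats.sem(b)),
        method=method,
    )
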