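"""Image-based screening readouts.

Chromatin state is read from DAPI: heterochromatin is brighter than
euchromatin, so (i) the ratio of the 80th to the 20th intensity
percentile inside a nucleus (i80/i20) summarises compaction, and (ii)
pixels above a per-nucleus Otsu threshold are called heterochromatin
foci, whose localisation near the nuclear envelope is quantified as the
fraction of focus pixels in a thin boundary shell. Migration is read
from spheroid images as the spread area of the outgrowth; the dense
initial spheroid is the core.

All percentiles use linear interpolation between order statistics.
Intensities never enter any metric absolutely — everything is a ratio,
a count or an area — so the pipeline is invariant to rescaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian
from skimage.measure import label as sk_label
from skimage.morphology import disk
from skimage.segmentation import watershed


def _drop_small(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Remove connected components smaller than min_size pixels."""
    labels = sk_label(mask)
    if labels.max() == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[labels]

logger = logging.getLogger("mechanotf")


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu threshold of a 1-D intensity sample.

    Exhaustively maximizes the between-class variance
    ``w0*w1*(mu0-mu1)^2`` over all cuts between observed values; the
    low class is ``value <= t``. On ties the lowest maximizing
    threshold is returned. Raises on constant input.
    """
    values = np.asarray(values, dtype=float).ravel()
    uniq, counts = np.unique(values, return_counts=True)
    if uniq.size < 2:
        raise ValueError("no threshold: input has fewer than 2 distinct values")
    # cumulative statistics; candidate cuts are the unique values except the max
    w = np.cumsum(counts)[:-1]
    total = values.size
    csum = np.cumsum(uniq * counts)[:-1]
    mu0 = csum / w
    mu1 = (uniq @ counts - csum) / (total - w)
    w0 = w / total
    var_between = w0 * (1 - w0) * (mu0 - mu1) ** 2
    best = int(np.argmax(var_between))  # argmax takes the first (lowest) maximizer
    return float(uniq[best])


def segment_nuclei(
    dapi: np.ndarray,
    min_area: int = 100,
    smooth_sigma: float = 2.0,
    split_min_distance: int = 10,
) -> np.ndarray:
    """Segment DAPI nuclei into a label mask (0 background, 1..k nuclei).

    Gaussian smoothing, Otsu foreground, small-object removal, then a
    distance-transform watershed to split touching nuclei. A blank
    (constant) image yields an empty mask with a warning.
    """
    img = np.asarray(dapi, dtype=float)
    smooth = gaussian(img, sigma=smooth_sigma, preserve_range=True)
    if np.unique(smooth).size < 2:
        logger.warning("segment_nuclei: blank image, returning empty mask")
        return np.zeros(img.shape, dtype=int)
    fg = smooth > otsu_threshold(smooth)
    fg = ndi.binary_fill_holes(fg)
    fg = _drop_small(fg, min_area)
    if not fg.any():
        logger.warning("segment_nuclei: no foreground after filtering")
        return np.zeros(img.shape, dtype=int)
    distance = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(
        distance, min_distance=split_min_distance, labels=fg, exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels = sk_label(fg)
    else:
        labels = watershed(-distance, markers, mask=fg)
    labels[~_drop_small(labels > 0, min_area)] = 0
    return _relabel(labels)


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Relabel contiguously from 1, preserving object order."""
    out = np.zeros_like(labels, dtype=int)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return out


def i80_i20(dapi: np.ndarray, mask: np.ndarray, nucleus_id: int) -> float | None:
    """Chromatin-compaction ratio: 80th / 20th percentile of the
    within-nucleus intensity distribution (linear interpolation).

    Always >= 1. When the 20th percentile is zero it is floored at the
    smallest positive within-nucleus intensity; if no positive pixel
    exists the metric is missing (None) and logged.
    """
    vals = np.asarray(dapi, dtype=float)[np.asarray(mask) == nucleus_id]
    if vals.size < 10:
        raise ValueError(f"nucleus {nucleus_id}: fewer than 10 pixels")
    p20, p80 = np.percentile(vals, [20, 80])
    if p20 <= 0:
        positive = vals[vals > 0]
        if positive.size == 0:
            logger.warning("i80_i20: nucleus %d has no positive intensity", nucleus_id)
            return None
        p20 = float(positive.min())
        if p20 <= 0:
            return None
    return float(p80 / p20)


def heterochromatin_foci(
    dapi: np.ndarray,
    mask: np.ndarray,
    nucleus_id: int,
    min_focus_area: int = 5,
) -> tuple[np.ndarray, dict]:
    """Heterochromatin foci of one nucleus: pixels above the per-nucleus
    Otsu threshold, kept as connected components of at least
    ``min_focus_area`` pixels.

    Returns the focus label mask (full image shape) and a metrics dict
    with ``focus_count``, ``total_focus_area`` and ``nucleus_area``.
    """
    dapi = np.asarray(dapi, dtype=float)
    inside = np.asarray(mask) == nucleus_id
    vals = dapi[inside]
    metrics = {"nucleus_id": nucleus_id, "nucleus_area": int(inside.sum())}
    try:
        thr = otsu_threshold(vals)
    except ValueError:  # constant nucleus: no foci
        focus_labels = np.zeros(dapi.shape, dtype=int)
        metrics.update(focus_count=0, total_focus_area=0)
        return focus_labels, metrics
    bright = inside & (dapi > thr)
    labels = sk_label(bright & _drop_small(bright, min_focus_area))
    metrics.update(
        focus_count=int(labels.max()), total_focus_area=int((labels > 0).sum())
    )
    return labels, metrics


def peripheral_fraction(
    focus_mask: np.ndarray, nucleus_mask: np.ndarray, shell_width: int = 3
) -> float:
    """Fraction of focus pixels within ``shell_width`` of the nucleus
    boundary; the shell is the nucleus minus its erosion by a disk of
    that radius. Complementary core fraction is 1 minus this value.
    Returns NaN when the nucleus has no focus pixels.
    """
    if shell_width < 1:
        raise ValueError("shell_width must be >= 1")
    nucleus = np.asarray(nucleus_mask, dtype=bool)
    foci = np.asarray(focus_mask) > 0
    foci = foci & nucleus
    if not foci.any():
        return float("nan")
    core = ndi.binary_erosion(nucleus, disk(shell_width))
    if not core.any():
        logger.warning("peripheral_fraction: shell wider than nucleus radius")
        return 1.0
    shell = nucleus & ~core
    return float((foci & shell).sum() / foci.sum())


def nuclei_metrics(
    dapi: np.ndarray,
    mask: np.ndarray | None = None,
    min_area: int = 100,
    min_focus_area: int = 5,
    shell_width: int = 3,
) -> pd.DataFrame:
    """Per-nucleus chromatin metrics table: i80_i20, focus count/area,
    peripheral fraction, nucleus area."""
    if mask is None:
        mask = segment_nuclei(dapi, min_area=min_area)
    rows = []
    for nid in np.unique(mask[mask > 0]):
        focus_labels, m = heterochromatin_foci(dapi, mask, nid, min_focus_area)
        try:
            ratio = i80_i20(dapi, mask, nid)
        except ValueError:
            ratio = None
        m["i80_i20"] = np.nan if ratio is None else ratio
        m["peripheral_fraction"] = peripheral_fraction(
            focus_labels, mask == nid, shell_width
        )
        rows.append(m)
    return pd.DataFrame(
        rows,
        columns=[
            "nucleus_id",
            "nucleus_area",
            "focus_count",
            "total_focus_area",
            "i80_i20",
            "peripheral_fraction",
        ],
    )


@dataclass
class MigrationMetrics:
    spread_area: float
    core_area: float
    units: str = "px^2"

    def __post_init__(self):
        if self.spread_area < self.core_area:
            raise ValueError("spread_area must be >= core_area")


def spheroid_spread_area(
    image: np.ndarray,
    closing_radius: int = 1,
    core_opening_radius: int = 8,
    pixel_size: float | None = None,
) -> MigrationMetrics:
    """Spheroid migration readout.

    ``spread_area`` is the filled union of the foreground after Otsu
    thresholding and morphological closing: the spheroid plus its
    outward-migrating cells, which are typically disconnected from the
    core and therefore must all count. ``core_area`` is the largest
    connected dense region surviving a morphological opening that erases
    the small migrated-cell blobs. Areas are in pixels unless
    ``pixel_size`` (microns/pixel) is given.
    """
    img = np.asarray(image, dtype=float)
    if np.unique(img).size < 2:
        raise ValueError("no foreground: blank image")
    fg = img > otsu_threshold(img)
    if not fg.any():
        raise ValueError("no foreground above threshold")
    spread = ndi.binary_closing(fg, structure=disk(closing_radius))
    spread = ndi.binary_fill_holes(spread)
    n_objects = int(sk_label(spread).max())
    if n_objects > 1:
        logger.info(
            "spheroid_spread_area: %d foreground objects in the union", n_objects
        )
    core = ndi.binary_opening(fg, structure=disk(core_opening_radius))
    core = ndi.binary_fill_holes(core)
    core_labels = sk_label(core)
    if core_labels.max() == 0:
        core_area = 0
    else:
        core_area = int(np.bincount(core_labels.ravel())[1:].max())
    scale = 1.0 if pixel_size is None else pixel_size**2
    units = "px^2" if pixel_size is None else "um^2"
    return MigrationMetrics(
        spread_area=float(max(spread.sum(), core_area)) * scale,
        core_area=float(core_area) * scale,
        units=units,
    )


def cytoskeleton_area_ratio(actin: np.ndarray, core_mask: np.ndarray) -> float:
    """Actin-positive area outside the initial spheroid core, relative
    to the core area. Otsu-thresholded, hence invariant to uniform
    intensity rescaling."""
    core = np.asarray(core_mask, dtype=bool)
    core_area = int(core.sum())
    if core_area == 0:
        raise ValueError("zero core area")
    actin = np.asarray(actin, dtype=float)
    positive = actin > otsu_threshold(actin)
    outside = positive & ~core
    return float(outside.sum() / core_area)
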