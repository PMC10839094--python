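"""Segmentation and sizing of hypofluorescent glutamine-synthetase lesions.

Overstimulation electroporates Müller cell endfeet and releases the
soluble enzyme glutamine synthetase (GS), so stimulated zones appear as
hypofluorescent discs — often with a darker ring near the electrode
edge — in GS-immunostained retinal wholemounts.  This module segments
such lesions by background-relative thresholding, measures their area
and equivalent diameter, relates the calculated electrode footprint to
lesion size, and groups lesion size against stimulus charge density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure, morphology

#: Stimulus pulse charge densities tested, in uC/cm^2/phase.
CHARGE_DENSITIES = (133, 230, 442, 749)


def chamber_area_cm2(diameter_mm: float = 12.0) -> float:
    """Area (cm^2) of the circular eyecup recording chamber.

    The 12 mm chamber exposes 1.13 cm^2 of retinal surface, large
    enough for several spatially separate stimulation zones per eyecup.
    """
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    r_cm = diameter_mm / 10.0 / 2.0
    return math.pi * r_cm**2


@dataclass(frozen=True)
class StimulationZone:
    """Stimulus bookkeeping for one retinal zone."""

    zone_id: str
    charge_density_uC_cm2: float
    frequency_hz: float = 50.0
    phase_duration_ms: float = 1.0
    train_duration_min: float = 5.0
    electrode_proximity_um: float = 30.0
    electrode_inner_diameter_um: float = 380.0
    face_angle_deg: float = 45.0

    def __post_init__(self) -> None:
        if self.charge_density_uC_cm2 <= 0:
            raise ValueError("charge density must be positive")
        if not 0 < self.face_angle_deg <= 90:
            raise ValueError("face angle must be in (0, 90] degrees")


@dataclass
class LesionMeasure:
    """Size and shape of a segmented hypofluorescent lesion."""

    area_um2: float
    equivalent_diameter_um: float
    centroid_um: tuple[float, float]  # (x, y)
    boundary_polygon_um: np.ndarray = field(repr=False, default=None)  # (N, 2) x,y
    ring_detected: bool | None = None

    def __post_init__(self) -> None:
        if self.area_um2 < 0:
            raise ValueError("area must be non-negative")
        expected = 2.0 * math.sqrt(self.area_um2 / math.pi)
        if not math.isclose(self.equivalent_diameter_um, expected, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("equivalent_diameter must equal 2*sqrt(area/pi)")


def segment_lesion(
    image: np.ndarray,
    background_annulus: tuple[float, float, float, float],
    depth_threshold: float = 0.3,
    scale_um: float = 1.0,
    closing_radius_um: float = 10.0,
    min_diameter_um: float = 50.0,
    dark_reference: float = 0.0,
) -> np.ndarray:
    """Segment the hypofluorescent lesion of a wholemount image.

    Pixels darker than ``(1 - depth_threshold)`` of the background
    median (measured in the ``(cx, cy, r_in, r_out)`` annulus, pixel
    units) are marked, morphologically closed, and the largest
    connected component is kept (one electrode -> one lesion).
    Components smaller than a ``min_diameter_um`` disc are treated as
    background texture, so a lesion-free image yields an empty mask.
    The threshold is background-relative, making the mask invariant to
    a global intensity gain; a non-zero acquisition offset can be
    removed via ``dark_reference``.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    if not 0 <= depth_threshold <= 1:
        raise ValueError("depth_threshold must be in [0, 1]")
    cx, cy, r_in, r_out = background_annulus
    h, w = img.shape
    if not (0 < r_in < r_out) or cx - r_out < -0.5 or cy - r_out < -0.5 \
            or cx + r_out > w - 0.5 or cy + r_out > h - 0.5:
        raise ValueError("background annulus must lie inside the image")
    yy, xx = np.mgrid[0:h, 0:w]
    rr2 = (xx - cx) ** 2 + (yy - cy) ** 2
    ann = (rr2 >= r_in**2) & (rr2 <= r_out**2)
    bg_median = float(np.median(img[ann]))
    thr = dark_reference + (1.0 - depth_threshold) * (bg_median - dark_reference)
    raw = img < thr
    if not np.any(raw):
        return np.zeros_like(raw)
    radius_px = max(1, int(round(closing_radius_um / scale_um)))
    closed = morphology.closing(raw, morphology.disk(radius_px))
    labels = measure.label(closed)
    if labels.max() == 0:
        return np.zeros_like(raw)
    counts = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(counts)) + 1
    min_area_px = math.pi * (min_diameter_um / scale_um / 2.0) ** 2
    if counts[best - 1] < min_area_px:
        return np.zeros_like(raw)
    return labels == best


def measure_lesion(
    mask: np.ndarray,
    scale_um: float = 1.0,
    image: np.ndarray | None = None,
    background_sd: float | None = None,
) -> LesionMeasure:
    """Measure a binary lesion mask: area, equivalent diameter, centroid, polygon.

    Area is the pixel count times ``scale_um**2``; the equivalent
    diameter is that of the circle of equal area.  If ``image`` and
    ``background_sd`` are given, ring detection is run (see
    :func:`detect_edge_ring`).  An empty mask yields a zero-area
    measure.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(np.count_nonzero(mask))
    if n == 0:
        return LesionMeasure(0.0, 0.0, (float("nan"), float("nan")),
                             np.empty((0, 2)), ring_detected=None)
    area = n * scale_um**2
    eqd = 2.0 * math.sqrt(area / math.pi)
    ys, xs = np.nonzero(mask)
    centroid = (float(xs.mean()) * scale_um, float(ys.mean()) * scale_um)
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    polygon = np.empty((0, 2))
    if contours:
        c = max(contours, key=len) - 1.0  # undo padding; rows, cols
        polygon = np.column_stack([c[:, 1], c[:, 0]]) * scale_um  # -> x, y
    ring = None
    if image is not None and background_sd is not None:
        ring = detect_edge_ring(image, mask, background_sd)
    return LesionMeasure(area, eqd, centroid, polygon, ring_detected=ring)


def detect_edge_ring(image: np.ndarray, mask: np.ndarray, background_sd: float) -> bool:
    """Detect a dark ring at the lesion edge.

    Criterion: the median intensity in the edge annulus (80–100% of the
    equivalent radius) is below the median of the central disc (<50% of
    the radius) by more than one background standard deviation.
    """
    img = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not np.any(mask):
        return False
    ys, xs = np.nonzero(mask)
    cx, cy = xs.mean(), ys.mean()
    r_eq = math.sqrt(mask.sum() / math.pi)
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    rr = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    edge = mask & (rr >= 0.8 * r_eq) & (rr <= r_eq)
    center = mask & (rr < 0.5 * r_eq)
    if not np.any(edge) or not np.any(center):
        return False
    return bool(np.median(img[edge]) < np.median(img[center]) - background_sd)


def polygon_area_measure(vertices_um: np.ndarray, ring_detected: bool | None = None) -> LesionMeasure:
    """Lesion measure from a manually traced polygon (x, y vertices in um).

    Shoelace area; supports the hand-drawn polygon outline workflow.
    """
    v = np.asarray(vertices_um, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
        raise ValueError("polygon needs at least 3 (x, y) vertices")
    x, y = v[:, 0], v[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    eqd = 2.0 * math.sqrt(area / math.pi)
    return LesionMeasure(area, eqd, (float(x.mean()), float(y.mean())), v, ring_detected)


def electrode_footprint_diameter(
    inner_diameter_um: float = 380.0, face_angle_deg: float = 45.0, truncate: bool = False
) -> float:
    """Area-equivalent diameter (um) of the elliptical electrode footprint.

    A tube of inner diameter ``d`` whose cut face meets the retinal
    surface at ``face_angle_deg`` projects an elliptical lumen with
    minor axis ``d`` and major axis ``d / sin(angle)``; the
    area-equivalent (geometric-mean) diameter is ``d / sqrt(sin(angle))``.
    A perpendicular face (90 deg) gives back ``d``.
    """
    if not 0 < face_angle_deg <= 90:
        raise ValueError("face angle must be in (0, 90] degrees")
    if inner_diameter_um <= 0:
        raise ValueError("inner diameter must be positive")
    d = inner_diameter_um / math.sqrt(math.sin(math.radians(face_angle_deg)))
    return float(math.trunc(d)) if truncate else d


def lesion_vs_charge_density(
    zones: list[tuple],
    low_densities: tuple = (133, 230),
    high_densities: tuple = (442, 749),
) -> tuple[pd.DataFrame, bool | None]:
    """Group lesion size and ILM distension by stimulus charge density.

    ``zones`` is a list of ``(StimulationZone, LesionMeasure,
    SwellingMetrics)`` triples.  Returns a per-charge-density summary
    table (mean ± sd of lesion area, equivalent diameter, and the
    post/pre ILM-IPL distension ratio — the coordinates of the cluster
    plot) and a flag that is True when the low- and high-density
    clusters are disjoint by mean ± sd intervals on both axes.  With a
    single charge-density group no overlap test is run (flag is None).
    """
    if not zones:
        raise ValueError("no zones supplied")
    rows = []
    for zone, lesion, swelling in zones:
        rows.append(
            {
                "zone_id": zone.zone_id,
                "charge_density_uC_cm2": zone.charge_density_uC_cm2,
                "lesion_area_um2": lesion.area_um2,
                "lesion_diameter_um": lesion.equivalent_diameter_um,
                "distension_ratio": swelling.distension_ratio_post_over_pre,
            }
        )
    df = pd.DataFrame(rows)
    grouped = (
        df.groupby("charge_density_uC_cm2")
        .agg(
            n=("zone_id", "size"),
            area_mean=("lesion_area_um2", "mean"),
            area_sd=("lesion_area_um2", "std"),
            diameter_mean=("lesion_diameter_um", "mean"),
            diameter_sd=("lesion_diameter_um", "std"),
            ratio_mean=("distension_ratio", "mean"),
            ratio_sd=("distension_ratio", "std"),
        )
        .reset_index()
        .sort_values("charge_density_uC_cm2")
        .reset_index(drop=True)
    )
    if grouped["charge_density_uC_cm2"].nunique() < 2:
        return grouped, None

    def pooled(densities, mean_col, sd_col):
        sel = grouped["charge_density_uC_cm2"].isin(densities)
        if not sel.any():
            return None
        m = grouped.loc[sel, mean_col]
        s = grouped.loc[sel, sd_col].fillna(0.0)
        return float((m - s).min()), float((m + s).max())

    flag = None
    lo_area = pooled(low_densities, "area_mean", "area_sd")
    hi_area = pooled(high_densities, "area_mean", "area_sd")
    lo_ratio = pooled(low_densities, "ratio_mean", "ratio_sd")
    hi_ratio = pooled(high_densities, "ratio_mean", "ratio_sd")
    if None not in (lo_area, hi_area, lo_ratio, hi_ratio):
        disjoint_area = lo_area[1] < hi_area[0] or hi_area[1] < lo_area[0]
        disjoint_ratio = lo_ratio[1] < hi_ratio[0] or hi_ratio[1] < lo_ratio[0]
        flag = bool(disjoint_area and disjoint_ratio)
    return grouped, flag
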