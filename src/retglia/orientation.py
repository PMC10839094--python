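"""Lesion-centric microglia process orientation scoring.

After focal overstimulation, microglia processes outside the lesion
re-orient toward the lesion center.  The measurement chain is:

1. gradient structure tensor -> per-pixel orientation (axial, modulo
   180 deg), coherency (lambda1 - lambda2) / (lambda1 + lambda2) and
   energy (tensor trace);
2. an ellipse fitted to the lesion edge from mask moments;
3. circular ROIs (default eight, 100 um diameter) placed around the
   ellipse;
4. per-ROI energy-weighted axial mean orientation and ROI coherency;
5. the alignment index: per ROI the acute axial angle dtheta between
   the measured orientation and the radial direction to the lesion
   center is scored as cos^2(dtheta), and scores are averaged weighted
   by ROI coherency.

Under the cos^2 scoring, uniformly random axial orientations average to
0.5; perfectly radial fields score 1 and perfectly tangential fields 0.

All angles use the Cartesian display convention of directional image
analysis: degrees counterclockwise from the +x (column) axis with y
pointing up (i.e. against the row direction), axial (modulo 180 deg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter

__all__ = [
    "OrientationField",
    "Ellipse",
    "RoiRing",
    "AlignmentResult",
    "structure_tensor_field",
    "fit_lesion_ellipse",
    "place_ring_rois",
    "roi_orientation",
    "alignment_index",
    "score_zone",
    "orientation_timecourse",
]


#: Study design of the microglia time course: zones analysed per
#: time post-stimulation (hours).
MICROGLIA_ZONES_PER_TIMEPOINT = {0.0: 5, 0.5: 3, 1.0: 5, 2.0: 5, 3.0: 5, 4.0: 3}


def total_microglia_zones(
    zones_per_timepoint: dict[float, int] | None = None,
) -> int:
    """Total number of analysed microglia lesion zones across timepoints."""
    counts = zones_per_timepoint or MICROGLIA_ZONES_PER_TIMEPOINT
    if any(n < 0 for n in counts.values()):
        raise ValueError("zone counts must be non-negative")
    return int(sum(counts.values()))


@dataclass
class OrientationField:
    """Per-pixel structure-tensor orientation, coherency and energy."""

    orientation_deg: np.ndarray  # [0, 180) per pixel
    coherency: np.ndarray  # [0, 1] per pixel
    energy: np.ndarray  # tensor trace, arbitrary units
    grad_sigma_um: float
    tensor_sigma_um: float
    pixel_scale_um: float = 1.0


@dataclass(frozen=True)
class Ellipse:
    """Lesion-edge ellipse: center (x, y), semi-axes a >= b, tilt of the
    major axis in degrees (axial).  All lengths share the mask's pixel
    units unless scaled by the caller."""

    center: tuple[float, float]
    a: float
    b: float
    tilt_deg: float


@dataclass
class RoiRing:
    """Ring of circular ROIs on the lesion-edge ellipse."""

    ellipse: Ellipse
    centers: np.ndarray  # (n, 2) x, y
    roi_diameter: float

    def __post_init__(self) -> None:
        if self.roi_diameter <= 0:
            raise ValueError("roi diameter must be positive")


@dataclass
class AlignmentResult:
    """Coherency-weighted radial alignment of one stimulation zone."""

    per_roi: pd.DataFrame  # orientation_deg, coherency, dtheta_deg, score
    index: float
    timepoint_h: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.index <= 1.0 + 1e-12:
            raise ValueError(f"alignment index {self.index} outside [0, 1]")


def structure_tensor_field(
    image: np.ndarray,
    grad_sigma_um: float = 2.0,
    tensor_sigma_um: float = 10.0,
    pixel_scale_um: float = 1.0,
) -> OrientationField:
    """Gradient structure tensor of a grayscale image.

    Gaussian-derivative gradients at scale ``grad_sigma_um`` are
    averaged over a Gaussian window of scale ``tensor_sigma_um`` to
    form J = <grad I grad I^T>; the dominant structure orientation is
    ``0.5 * atan2(2 Jxy, Jyy - Jxx)`` mapped to [0, 180) degrees, and
    the coherency is ``(l1 - l2) / (l1 + l2)`` (0 where the tensor
    trace vanishes).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    if grad_sigma_um <= 0 or tensor_sigma_um <= 0 or pixel_scale_um <= 0:
        raise ValueError("scales must be positive")
    sg = grad_sigma_um / pixel_scale_um
    st = tensor_sigma_um / pixel_scale_um
    # order=(dy, dx): axis 0 is y (rows), axis 1 is x (columns)
    Ix = gaussian_filter(img, sg, order=(0, 1), mode="nearest")
    Iy = gaussian_filter(img, sg, order=(1, 0), mode="nearest")
    Jxx = gaussian_filter(Ix * Ix, st, mode="nearest")
    Jxy = gaussian_filter(Ix * Iy, st, mode="nearest")
    Jyy = gaussian_filter(Iy * Iy, st, mode="nearest")
    orientation = np.degrees(0.5 * np.arctan2(2 * Jxy, Jyy - Jxx)) % 180.0
    trace = Jxx + Jyy
    spread = np.sqrt((Jyy - Jxx) ** 2 + 4 * Jxy**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherency = np.where(trace > 0, spread / np.where(trace > 0, trace, 1.0), 0.0)
    return OrientationField(
        orientation_deg=orientation,
        coherency=np.clip(coherency, 0.0, 1.0),
        energy=trace,
        grad_sigma_um=grad_sigma_um,
        tensor_sigma_um=tensor_sigma_um,
        pixel_scale_um=pixel_scale_um,
    )


def fit_lesion_ellipse(mask: np.ndarray, min_pixels: int = 9) -> Ellipse:
    """Ellipse around the lesion edge from second-order mask moments.

    Center = centroid; axis directions from the eigendecomposition of
    the pixel-coordinate covariance; axis lengths scaled so the ellipse
    area equals the mask area.  Degenerate masks (too few pixels or a
    collapsed minor axis) are rejected.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise ValueError("empty lesion mask")
    if n < min_pixels:
        raise ValueError(f"mask with {n} pixels is too small to fit an ellipse")
    ys, xs = np.nonzero(mask)
    cx, cy = float(xs.mean()), float(ys.mean())
    cov = np.cov(np.stack([xs - cx, ys - cy]).astype(float), bias=True)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] <= 1e-9:
        raise ValueError("degenerate (collapsed) lesion mask")
    # Solid-ellipse second moments: var along axis = (semi-axis)^2 / 4.
    b, a = 2.0 * np.sqrt(evals[0]), 2.0 * np.sqrt(evals[1])
    scale = math.sqrt(n / (math.pi * a * b))
    a, b = a * scale, b * scale
    major = evecs[:, 1]
    # Cartesian tilt: row coordinates point down, so the y component flips.
    tilt = math.degrees(math.atan2(-major[1], major[0])) % 180.0
    return Ellipse(center=(cx, cy), a=float(a), b=float(b), tilt_deg=float(tilt))


def place_ring_rois(
    ellipse: Ellipse, n_rois: int = 8, roi_diameter: float = 100.0
) -> RoiRing:
    """Place ROI centers at equal parametric angles around the ellipse.

    The first center sits on the major axis; subsequent centers proceed
    in order of increasing parametric angle.
    """
    if n_rois < 1:
        raise ValueError("need at least one ROI")
    t = 2.0 * math.pi * np.arange(n_rois) / n_rois
    # Counterclockwise in the Cartesian display convention; the whole
    # Cartesian frame maps into row-down image coordinates by negating y.
    tilt = math.radians(ellipse.tilt_deg)
    R = np.array([[math.cos(tilt), -math.sin(tilt)], [-math.sin(tilt), -math.cos(tilt)]])
    pts = np.stack([ellipse.a * np.cos(t), ellipse.b * np.sin(t)])
    centers = (R @ pts).T + np.asarray(ellipse.center)
    return RoiRing(ellipse=ellipse, centers=centers, roi_diameter=roi_diameter)


def roi_orientation(
    field: OrientationField, center_xy: tuple[float, float], diameter: float
) -> tuple[float, float]:
    """Axial mean orientation and coherency of one ROI.

    The per-pixel structure tensors are summed over the circular ROI
    and the aggregate tensor's orientation and anisotropy are returned;
    equivalently, the doubled-angle vectors (cos 2theta, sin 2theta)
    are averaged with energy * coherency weights and normalised by the
    total energy.  The ROI coherency is 1 iff all energy shares one
    coherent orientation and 0 for balanced orthogonal mixtures,
    whether the mixing happens across the ROI or inside the tensor
    window.  ``center_xy`` and ``diameter`` are in pixels.  Returns
    ``(orientation_deg, coherency)``; an ROI with no energy has
    coherency 0.
    """
    h, w = field.orientation_deg.shape
    cx, cy = center_xy
    r = diameter / 2.0
    if cx - r < -0.5 or cy - r < -0.5 or cx + r > w - 0.5 or cy + r > h - 0.5:
        raise ValueError(f"ROI at {center_xy} with diameter {diameter} falls outside the image")
    x0, x1 = int(math.floor(cx - r)), int(math.ceil(cx + r)) + 1
    y0, y1 = int(math.floor(cy - r)), int(math.ceil(cy + r)) + 1
    x0, y0 = max(x0, 0), max(y0, 0)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    energy = field.energy[y0:y1, x0:x1][inside]
    coh = field.coherency[y0:y1, x0:x1][inside]
    ang = np.radians(2.0 * field.orientation_deg[y0:y1, x0:x1][inside])
    total = float(np.sum(energy))
    if total <= 0:
        return 0.0, 0.0
    w = energy * coh  # = lambda1 - lambda2 per pixel: the tensor anisotropy
    vx = float(np.sum(w * np.cos(ang))) / total
    vy = float(np.sum(w * np.sin(ang))) / total
    ori = math.degrees(0.5 * math.atan2(vy, vx)) % 180.0
    return ori, float(min(1.0, math.hypot(vx, vy)))


def _acute_axial_difference(a_deg: float, b_deg: float) -> float:
    """Acute angle between two axial directions, in [0, 90] degrees."""
    d = abs(a_deg - b_deg) % 180.0
    return min(d, 180.0 - d)


def alignment_index(
    rois: list[tuple[float, float, tuple[float, float]]],
    lesion_center: tuple[float, float],
    timepoint_h: float | None = None,
) -> AlignmentResult:
    """Coherency-weighted radial alignment index of one zone.

    ``rois`` is a list of ``(orientation_deg, coherency, center_xy)``.
    For each ROI the ideal orientation is the axial direction from the
    ROI center to the lesion center; the score is ``cos^2`` of the acute
    axial difference, and the zone index is the coherency-weighted mean
    score: ``sum(c_i * cos^2(dtheta_i)) / sum(c_i)``.
    """
    if not rois:
        raise ValueError("need at least one ROI")
    rows = []
    for ori, coh, center in rois:
        if not 0.0 <= coh <= 1.0:
            raise ValueError(f"coherency {coh} outside [0, 1]")
        dx = lesion_center[0] - center[0]
        dy = lesion_center[1] - center[1]
        # Cartesian angle of the radial direction (rows point down).
        radial = math.degrees(math.atan2(-dy, dx)) % 180.0
        dtheta = _acute_axial_difference(ori, radial)
        score = math.cos(math.radians(dtheta)) ** 2
        rows.append(
            {
                "orientation_deg": ori,
                "coherency": coh,
                "radial_deg": radial,
                "dtheta_deg": dtheta,
                "score": score,
            }
        )
    df = pd.DataFrame(rows)
    total = df["coherency"].sum()
    if total <= 0:
        raise ValueError("alignment index undefined: all ROI coherencies are zero")
    idx = float((df["coherency"] * df["score"]).sum() / total)
    return AlignmentResult(per_roi=df, index=min(idx, 1.0), timepoint_h=timepoint_h)


def score_zone(
    image: np.ndarray,
    lesion_mask: np.ndarray,
    n_rois: int = 8,
    roi_diameter_um: float = 100.0,
    grad_sigma_um: float = 2.0,
    tensor_sigma_um: float = 10.0,
    pixel_scale_um: float = 1.0,
    timepoint_h: float | None = None,
) -> AlignmentResult:
    """Full orientation stage for one zone image with its lesion mask.

    Z-stacks should be maximum-projected before calling.  Runs the
    structure tensor, fits the lesion-edge ellipse, places the ring of
    ROIs, measures each ROI and returns the zone alignment index.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:  # stack: maximum projection
        img = img.max(axis=0)
    field = structure_tensor_field(img, grad_sigma_um, tensor_sigma_um, pixel_scale_um)
    ellipse = fit_lesion_ellipse(lesion_mask)
    ring = place_ring_rois(ellipse, n_rois, roi_diameter_um / pixel_scale_um)
    rois = []
    for center in ring.centers:
        ori, coh = roi_orientation(field, tuple(center), ring.roi_diameter)
        rois.append((ori, coh, tuple(center)))
    return alignment_index(rois, ellipse.center, timepoint_h=timepoint_h)


def orientation_timecourse(
    results: dict[float, list],
    baseline_h: float = 0.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-timepoint summary of zone alignment indices with tests vs baseline.

    ``results`` maps the time post-stimulation (hours) to the zone-level
    results (``AlignmentResult`` objects or plain indices).  Each later
    timepoint is compared with the baseline by a paired t-test when the
    group sizes match (zones paired in listed order) and by a Welch
    two-sample t-test otherwise; each group needs at least two zones.
    """
    from .stats_report import paired_t

    if baseline_h not in results:
        raise ValueError(f"missing {baseline_h} h baseline group")

    def values(group):
        return np.asarray(
            [r.index if isinstance(r, AlignmentResult) else float(r) for r in group],
            dtype=float,
        )

    base = values(results[baseline_h])
    if len(base) < 2:
        raise ValueError("baseline group needs at least two zones")
    rows = []
    for tp in sorted(results):
        vals = values(results[tp])
        if len(vals) < 2:
            raise ValueError(f"timepoint {tp} h has fewer than two zones")
        if tp == baseline_h:
            t = p = np.nan
            kind = ""
        elif len(vals) == len(base):
            t, p, _ = paired_t(base, vals)
            kind = "paired"
        else:
            t, p = stats.ttest_ind(vals, base, equal_var=False)
            kind = "welch"
        rows.append(
            {
                "timepoint_h": tp,
                "n": len(vals),
                "mean_index": float(vals.mean()),
                "sd_index": float(vals.std(ddof=1)),
                "t": float(t),
                "p": float(p),
                "test": kind,
                "significant": bool(p < alpha) if not np.isnan(p) else False,
            }
        )
    return pd.DataFrame(rows)
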