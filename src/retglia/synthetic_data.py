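"""Seeded synthetic data emulating the eyecup stimulation-injury study.

Every downstream stage of the pipeline is testable without external
data because each generator returns machine-readable ground truth next
to its image or waveform:

* :func:`generate_bscan` — layered OCT B-scan reflectivity with a
  stimulation effect (ILM detachment bleb, GCL/IPL swelling, IPL
  hyperreflectivity) and the true layer boundary depths;
* :func:`generate_wholemount` — a block-like Müller-endfoot mosaic with
  a hypofluorescent disc (optionally ringed) lesion and its true mask;
* :func:`generate_microglia_field` — star-shaped microglia with
  controllable radial (axial von Mises) process alignment around a
  lesion, with a per-cell truth table;
* :func:`generate_charging_waveform` — the two-RC eyewall charging
  forward model (shared with :mod:`retglia.bioimpedance`).

All generators are deterministic in their seed: identical spec + seed
gives bit-identical output, and an all-zero stimulation effect gives an
image identical to the control from the same seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bioimpedance import ChargingWaveform, CircuitParams, PulseSpec, simulate
from .oct_morphometry import BScan, LayerBoundaries

LAYER_NAMES = ("ILM", "GCL", "IPL", "INL", "ONL", "IS/OS", "RPE/BM")


@dataclass(frozen=True)
class Layer:
    """One retinal layer: name, top depth (um) and mean reflectivity (8-bit)."""

    name: str
    depth_top_um: float
    mean_reflectivity: float
    reflectivity_sd: float = 0.0


#: Default layer stack (depths at 2 um/px; reflectivities follow the
#: bright-ILM / moderate-IPL / dark-nuclear / bright-outer-complex
#: appearance of an averaged B-scan).
DEFAULT_LAYERS = (
    Layer("ILM", 120.0, 200.0),
    Layer("GCL", 128.0, 60.0),
    Layer("IPL", 170.0, 120.0),
    Layer("INL", 240.0, 40.0),
    Layer("ONL", 280.0, 40.0),
    Layer("IS/OS", 360.0, 160.0),
    Layer("RPE/BM", 380.0, 220.0),
)


@dataclass(frozen=True)
class LayerSpec:
    """Geometry and reflectivity of the synthetic retina."""

    layers: tuple[Layer, ...] = DEFAULT_LAYERS
    axial_scale_um: float = 2.0
    lateral_scale_um: float = 2.0
    image_shape: tuple[int, int] = (256, 256)  # rows (depth), columns
    vitreous_reflectivity: float = 8.0
    below_reflectivity: float = 16.0
    retina_bottom_um: float = 400.0  # bottom of RPE/BM

    def __post_init__(self) -> None:
        if self.axial_scale_um <= 0 or self.lateral_scale_um <= 0:
            raise ValueError("pixel scales must be positive")
        depths = [lay.depth_top_um for lay in self.layers]
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValueError("layer depths must be strictly increasing")
        for lay in self.layers:
            if lay.name not in LAYER_NAMES:
                raise ValueError(f"unknown layer name {lay.name!r}; allowed: {LAYER_NAMES}")
            if not 0 <= lay.mean_reflectivity <= 255:
                raise ValueError("mean reflectivities must fit the 8-bit range")
        if self.retina_bottom_um <= depths[-1]:
            raise ValueError("retina bottom must lie below the deepest layer top")

    def layer_top(self, name: str) -> float:
        for lay in self.layers:
            if lay.name == name:
                return lay.depth_top_um
        raise KeyError(name)


@dataclass(frozen=True)
class StimEffectSpec:
    """Stimulation-induced structural changes applied inside the electrode footprint.

    A zero-valued spec produces an image identical to the unstimulated
    control from the same seed.
    """

    bleb_height_um: float = 0.0  # ILM displacement above the GCL top
    gcl_swelling_um: float = 0.0
    ipl_swelling_fraction: float = 0.0
    ipl_hyperreflectivity_gain: float = 1.0
    edge_detachment: bool = False
    lateral_extent_um: float = 452.0  # electrode footprint width

    def __post_init__(self) -> None:
        if min(self.bleb_height_um, self.gcl_swelling_um, self.ipl_swelling_fraction) < 0:
            raise ValueError("swelling parameters must be non-negative")
        if self.ipl_hyperreflectivity_gain < 1.0:
            raise ValueError("IPL hyperreflectivity gain must be >= 1")
        if self.lateral_extent_um <= 0:
            raise ValueError("lateral extent must be positive")

    @property
    def is_null(self) -> bool:
        return (
            self.bleb_height_um == 0
            and self.gcl_swelling_um == 0
            and self.ipl_swelling_fraction == 0
            and self.ipl_hyperreflectivity_gain == 1.0
            and not self.edge_detachment
        )


def _footprint_weight(n_cols: int, center: float, half_extent_px: float) -> np.ndarray:
    """Flat-top lateral effect profile: 1 over the central 60% of the
    footprint, raised-cosine taper to 0 at the footprint edges."""
    x = np.abs(np.arange(n_cols) - center)
    flat = 0.6 * half_extent_px
    w = np.zeros(n_cols)
    w[x <= flat] = 1.0
    taper = (x > flat) & (x <= half_extent_px)
    w[taper] = 0.5 * (1 + np.cos(np.pi * (x[taper] - flat) / (half_extent_px - flat)))
    return w


def generate_bscan(
    layer_spec: LayerSpec | None = None,
    effect: StimEffectSpec | None = None,
    speckle_sd: float = 0.0,
    seed: int = 0,
) -> tuple[BScan, LayerBoundaries]:
    """Render a synthetic B-scan and its ground-truth layer boundaries.

    The retina is drawn column by column from the layer stack; inside
    the electrode footprint the ILM band is displaced upward by the
    bleb height (leaving vitreous-dark sub-ILM fluid), the GCL gains
    ``gcl_swelling_um``, the IPL is thickened by
    ``ipl_swelling_fraction`` and brightened by the hyperreflectivity
    gain, and deeper layers shift down accordingly.  ``speckle_sd`` is
    the relative (fractional) speckle standard deviation: multiplicative
    log-normal noise, so SNR = 1 / speckle_sd.  Ground truth reports
    the boundary depths at the footprint center.
    """
    spec = layer_spec or LayerSpec()
    effect = effect or StimEffectSpec()
    if speckle_sd < 0:
        raise ValueError("speckle_sd must be non-negative")
    n_rows, n_cols = spec.image_shape
    ax = spec.axial_scale_um

    ipl_thickness0 = spec.layer_top("INL") - spec.layer_top("IPL")
    max_shift = effect.gcl_swelling_um + effect.ipl_swelling_fraction * ipl_thickness0
    if spec.retina_bottom_um + max_shift + (15.0 if effect.edge_detachment else 0.0) \
            > n_rows * ax:
        raise ValueError(
            "image too small: deepest layer would fall below the bottom row "
            f"({spec.retina_bottom_um + max_shift:.0f} um vs {n_rows * ax:.0f} um)"
        )
    if spec.layer_top("ILM") - effect.bleb_height_um < 2 * ax:
        raise ValueError("bleb would displace the ILM above the top of the image")

    center = (n_cols - 1) / 2.0
    half_extent_px = effect.lateral_extent_um / (2.0 * spec.lateral_scale_um)
    w = _footprint_weight(n_cols, center, half_extent_px)
    if effect.edge_detachment:
        sigma = max(1.0, 0.1 * half_extent_px)
        x = np.arange(n_cols) - center
        w_edge = np.exp(-((np.abs(x) - half_extent_px) ** 2) / (2 * sigma**2))
    else:
        w_edge = np.zeros(n_cols)

    tops = {lay.name: lay.depth_top_um for lay in spec.layers}
    refl = {lay.name: lay.mean_reflectivity for lay in spec.layers}
    img = np.empty((n_rows, n_cols), dtype=float)

    def row_of(depth_um: float) -> int:
        return int(np.clip(round(depth_um / ax), 0, n_rows))

    for c in range(n_cols):
        wc = w[c]
        gcl_extra = wc * effect.gcl_swelling_um
        ipl_extra = wc * effect.ipl_swelling_fraction * ipl_thickness0
        outer_extra = gcl_extra + ipl_extra + w_edge[c] * 15.0
        ilm_top = tops["ILM"] - wc * effect.bleb_height_um
        ilm_bottom = tops["GCL"] - wc * effect.bleb_height_um
        bands = [
            (0.0, ilm_top, spec.vitreous_reflectivity),
            (ilm_top, ilm_bottom, refl["ILM"]),
            (ilm_bottom, tops["GCL"], spec.vitreous_reflectivity),  # sub-ILM fluid
            (tops["GCL"], tops["IPL"] + gcl_extra, refl["GCL"]),
            (
                tops["IPL"] + gcl_extra,
                tops["INL"] + gcl_extra + ipl_extra,
                min(255.0, refl["IPL"] * (1 + wc * (effect.ipl_hyperreflectivity_gain - 1))),
            ),
            (tops["INL"] + gcl_extra + ipl_extra, tops["ONL"] + gcl_extra + ipl_extra, refl["INL"]),
            (tops["ONL"] + gcl_extra + ipl_extra, tops["IS/OS"] + outer_extra, refl["ONL"]),
            (tops["IS/OS"] + outer_extra, tops["RPE/BM"] + outer_extra, refl["IS/OS"]),
            (tops["RPE/BM"] + outer_extra, spec.retina_bottom_um + outer_extra, refl["RPE/BM"]),
            (spec.retina_bottom_um + outer_extra, n_rows * ax, spec.below_reflectivity),
        ]
        col = img[:, c]
        for top, bottom, value in bands:
            r0, r1 = row_of(top), row_of(bottom)
            if r1 > r0:
                col[r0:r1] = value

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_rows, n_cols))
    if speckle_sd > 0:
        img = img * np.exp(speckle_sd * noise - 0.5 * speckle_sd**2)
    image = np.clip(np.round(img), 0, 255).astype(np.uint8)

    gcl_extra = effect.gcl_swelling_um
    ipl_extra = effect.ipl_swelling_fraction * ipl_thickness0
    truth = LayerBoundaries(
        ilm_depth_um=tops["ILM"] - effect.bleb_height_um,
        ipl_inner_depth_um=tops["IPL"] + gcl_extra,
        ipl_outer_depth_um=tops["INL"] + gcl_extra + ipl_extra,
        extra_um={"IS/OS": tops["IS/OS"] + gcl_extra + ipl_extra},
    )
    bscan = BScan(image, axial_scale_um=ax, lateral_scale_um=spec.lateral_scale_um)
    return bscan, truth


@dataclass(frozen=True)
class WholemountSpec:
    """Synthetic GS-immunostained wholemount with a hypofluorescent lesion."""

    field_size_um: float = 1024.0
    pixel_scale_um: float = 1.0
    endfoot_cell_um: float = 12.0
    background_mean: float = 180.0
    background_sd: float = 20.0
    pixel_noise_sd: float = 4.0
    lesion_shape: str = "disc"  # "disc" or "disc_with_ring"
    lesion_diameter_um: float = 500.0
    ring_width_um: float = 40.0
    lesion_center_um: tuple[float, float] | None = None  # default: field center
    hypofluorescence_depth: float = 0.6
    ring_extra_depth: float = 0.5
    nerve_fiber_overlay: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_diameter_um <= 0:
            raise ValueError("lesion diameter must be positive")
        if self.lesion_shape not in ("disc", "disc_with_ring"):
            raise ValueError("lesion_shape must be 'disc' or 'disc_with_ring'")
        if not 0 <= self.hypofluorescence_depth <= 1:
            raise ValueError("hypofluorescence_depth must be in [0, 1]")
        if self.lesion_diameter_um > self.field_size_um:
            raise ValueError("lesion larger than the field")


def generate_wholemount(spec: WholemountSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Render a wholemount image and its ground-truth lesion mask.

    The background is a block mosaic of Müller-endfoot-sized cells with
    Gaussian brightness variation; the lesion multiplies the background
    by ``1 - hypofluorescence_depth`` inside the disc, with an edge
    annulus darkened further for ``disc_with_ring``.  The mask marks
    the full disc; a zero hypofluorescence depth produces no lesion and
    an empty mask.
    """
    spec = spec or WholemountSpec()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.field_size_um / spec.pixel_scale_um))
    cell_px = max(1, int(round(spec.endfoot_cell_um / spec.pixel_scale_um)))
    g = n // cell_px + 2
    mosaic = rng.normal(spec.background_mean, spec.background_sd, (g, g))
    bg = np.kron(mosaic, np.ones((cell_px, cell_px)))[:n, :n]
    bg = bg + rng.normal(0.0, spec.pixel_noise_sd, (n, n))

    if spec.lesion_center_um is None:
        cx = cy = (n - 1) / 2.0 * spec.pixel_scale_um
    else:
        cx, cy = spec.lesion_center_um
    yy, xx = np.mgrid[0:n, 0:n]
    rr = np.hypot(xx * spec.pixel_scale_um - cx, yy * spec.pixel_scale_um - cy)
    radius = spec.lesion_diameter_um / 2.0

    factor = np.ones((n, n))
    depth = spec.hypofluorescence_depth
    if depth > 0:
        disc = rr <= radius
        factor[disc] = 1.0 - depth
        if spec.lesion_shape == "disc_with_ring":
            ring = disc & (rr >= radius - spec.ring_width_um)
            factor[ring] = (1.0 - depth) * (1.0 - spec.ring_extra_depth)
        mask = disc
    else:
        mask = np.zeros((n, n), dtype=bool)
    img = bg * factor

    if spec.nerve_fiber_overlay:
        for _ in range(4):
            theta = rng.uniform(0, math.pi)
            offset = rng.uniform(-0.3, 0.3) * n
            d = np.abs(
                (xx - n / 2) * math.sin(theta) - (yy - n / 2) * math.cos(theta) - offset
            )
            img[d < 1.5] += 40.0

    return np.clip(np.round(img), 0, 255).astype(np.uint8), mask


@dataclass(frozen=True)
class MicrogliaFieldSpec:
    """Synthetic microglia field around a focal lesion.

    ``alignment_model='radial_von_mises'`` draws each cell's process
    axis from an axial von Mises distribution concentrated about the
    radial direction to the lesion center (concentration ``kappa``);
    ``kappa = 0`` reduces to ``uniform_random``.  Orientations are
    axial (modulo 180 deg) throughout.
    """

    n_cells: int = 8
    process_length_um: float = 40.0
    alignment_model: str = "uniform_random"  # or "radial_von_mises"
    kappa: float = 0.0
    coherency_range: tuple[float, float] = (0.5, 0.9)
    field_size_um: float = 512.0
    pixel_scale_um: float = 1.0
    lesion_center_um: tuple[float, float] | None = None  # default: field center
    lesion_radius_um: float = 150.0
    #: Radial band (offsets from the lesion edge) where cells are placed.
    placement_band_um: tuple[float, float] = (10.0, 60.0)
    #: Cells sit at equally spaced angles around the lesion (microglia
    #: congregate around the edge) with this much uniform angular jitter.
    angular_jitter_deg: float = 15.0
    render_core_debris: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.kappa < 0:
            raise ValueError("von Mises concentration must be non-negative")
        if self.alignment_model not in ("uniform_random", "radial_von_mises"):
            raise ValueError("unknown alignment model")
        lo, hi = self.coherency_range
        if not 0 <= lo <= hi <= 1:
            raise ValueError("coherency_range must be an interval within [0, 1]")
        if self.lesion_radius_um <= 0 or self.process_length_um <= 0:
            raise ValueError("lesion radius and process length must be positive")


@dataclass
class MicrogliaField:
    """Rendered field plus per-cell ground truth and the true lesion mask."""

    image: np.ndarray
    cells: pd.DataFrame  # x_um, y_um, orientation_deg, coherency
    lesion_mask: np.ndarray
    spec: MicrogliaFieldSpec = field(repr=False, default=None)


def _splat_segment(canvas: np.ndarray, x0: float, y0: float, angle_rad: float,
                   length: float, amplitude: float) -> None:
    """Accumulate a straight process arm onto the canvas."""
    if length <= 0:
        return
    n_pts = max(2, int(round(length * 2)))
    t = np.linspace(0.0, length, n_pts)
    # Cartesian angle convention: +angle runs counterclockwise with y up,
    # so the row coordinate decreases with +sin.
    xs = np.round(x0 + t * math.cos(angle_rad)).astype(int)
    ys = np.round(y0 - t * math.sin(angle_rad)).astype(int)
    h, w = canvas.shape
    ok = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
    np.add.at(canvas, (ys[ok], xs[ok]), amplitude)


def generate_microglia_field(spec: MicrogliaFieldSpec | None = None) -> MicrogliaField:
    """Render a microglia field with known per-cell orientation truth.

    Each cell is a four-arm star with one dominant elongation axis:
    full-length process axes are drawn at ``theta + delta`` and
    ``theta - delta`` with ``cos(2 delta) = c``, so the axial energy
    resultant of the rendered cluster equals the drawn coherency ``c``
    while both angular populations stay equally resolved.  Cells sit in
    an annular band outside the lesion radius at equally spaced,
    jittered angles (the congregation ring seen around stimulated
    lesions); contracted (rounded) microglia debris is rendered inside
    the lesion core.
    """
    spec = spec or MicrogliaFieldSpec()
    rng = np.random.default_rng(spec.seed)
    scale = spec.pixel_scale_um
    n = int(round(spec.field_size_um / scale))
    if spec.lesion_center_um is None:
        cx = cy = (n - 1) / 2.0 * scale
    else:
        cx, cy = spec.lesion_center_um

    rows = []
    canvas = np.zeros((n, n), dtype=float)
    jitter = math.radians(spec.angular_jitter_deg)
    for k in range(spec.n_cells):
        phi = 2.0 * math.pi * k / spec.n_cells + rng.uniform(-jitter, jitter)
        r = spec.lesion_radius_um + rng.uniform(*spec.placement_band_um)
        x, y = cx + r * math.cos(phi), cy + r * math.sin(phi)
        # Axial angle of the cell-to-lesion-center direction (Cartesian,
        # y up: row coordinates negate).
        radial_deg = math.degrees(math.atan2(-(cy - y), cx - x)) % 180.0
        if spec.alignment_model == "radial_von_mises":
            theta = (math.degrees(rng.vonmises(2.0 * math.radians(radial_deg), spec.kappa)) / 2.0) % 180.0
        else:
            theta = (math.degrees(rng.vonmises(0.0, 0.0)) / 2.0) % 180.0
        c = rng.uniform(*spec.coherency_range)
        rows.append({"x_um": x, "y_um": y, "orientation_deg": theta, "coherency": c})

        # Two full axes at theta +/- delta: the axial resultant of two
        # equal populations at 2(theta +/- delta) has length cos(2 delta),
        # so delta = acos(c) / 2 makes the rendered coherency equal c.
        half = spec.process_length_um / scale / 2.0
        delta = 0.5 * math.acos(c)
        th = math.radians(theta)
        xp, yp = x / scale, y / scale
        for ang in (th + delta, th + delta + math.pi, th - delta, th - delta + math.pi):
            _splat_segment(canvas, xp, yp, ang, half, 1.0)

    if spec.render_core_debris and spec.n_cells > 0:
        n_debris = max(3, spec.n_cells)
        for _ in range(n_debris):
            phi = rng.uniform(0.0, 2.0 * math.pi)
            r = rng.uniform(0.0, 0.7 * spec.lesion_radius_um)
            xp = (cx + r * math.cos(phi)) / scale
            yp = (cy + r * math.sin(phi)) / scale
            ix, iy = int(round(xp)), int(round(yp))
            if 1 <= ix < n - 1 and 1 <= iy < n - 1:
                canvas[iy - 1 : iy + 2, ix - 1 : ix + 2] += 0.6

    from scipy.ndimage import gaussian_filter

    img = gaussian_filter(canvas, 1.0)
    if img.max() > 0:
        img = img * (200.0 / img.max())
    image = np.clip(np.round(img), 0, 255).astype(np.uint8)

    yy, xx = np.mgrid[0:n, 0:n]
    lesion_mask = (
        np.hypot(xx * scale - cx, yy * scale - cy) <= spec.lesion_radius_um
    )
    cells = pd.DataFrame(rows, columns=["x_um", "y_um", "orientation_deg", "coherency"])
    return MicrogliaField(image=image, cells=cells, lesion_mask=lesion_mask, spec=spec)


def generate_charging_waveform(
    params: CircuitParams,
    pulse: PulseSpec | None = None,
    noise_sd_mV: float = 0.0,
    seed: int | None = None,
) -> ChargingWaveform:
    """Two-RC eyewall charging waveform (see :func:`retglia.bioimpedance.simulate`)."""
    return simulate(params, pulse, noise_sd_mV=noise_sd_mV, seed=seed)
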