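# Methods

This note documents the models behind each analysis stage, the
synthetic data they are validated on, the defaults and why, and the
design choices made where the measurement procedure was genuinely open.

## OCT swelling morphometry

**Model.** A B-scan is an intensity matrix with rows as depth (row 0 on
the vitreous side) and explicit pixel scales (default 2 μm/px axial and
lateral). The measurement chain is: (1) average A-scans over a lateral
window — by default the central 20% of columns, the mid-electrode
analysis zone; (2) locate layer boundaries as extrema of the first
derivative of the Gaussian-smoothed profile (default smoothing 6 μm);
(3) convert boundary rows to μm and form the two swelling metrics,
ILM-to-inner-IPL distance and IPL thickness, plus their post/pre ratios
and the fractional IPL reflectivity change.

**Boundary labelling.** Candidate edges are classified through the
plateau sequence they delimit. Bright plateaus (≥ 55% of the profile's
dynamic range) are grouped into runs: the first run is the ILM line —
when the ILM has detached, this is the displaced bright line, not the
top of the GCL — and the last run is the IS/OS–RPE/BM outer complex.
The dark nuclear band (INL/ONL) sits directly above the outer complex;
its top edge is the outer IPL border, and the nearest rising edge above
it is the inner IPL border. This run-based labelling is robust to the
IPL itself turning bright under stimulation-induced hyperreflectivity
and to the dark sub-ILM fluid gap introduced by a bleb. Each labelled
edge is then re-localised on a lightly smoothed (1 px) derivative in a
window around the coarse position: the coarse scale is reliable for
labelling but biases the thin ILM line's edges by about a pixel through
interference of its two opposite derivative lobes. Boundary positions
get parabolic sub-pixel refinement. The operational definition of the
inner IPL border (an intensity-derivative extremum) is this package's
choice; manual cursor placement on the displayed image is the common
alternative and has no closed form.

**Accuracy.** On synthetic scans, boundaries are recovered to well
within 1 px noiseless and within 2 px median absolute error at SNR 5;
injected distension ratios of 3.0–3.35× and IPL thickening of +38–43%
come back within 5%. Detection degrades gracefully: a profile without
the expected bright/dark sequence raises a diagnostic error rather than
returning mislabelled depths.

## Lesion segmentation and sizing

Hypofluorescent lesions are segmented by thresholding at
`(1 − depth) × background median` with the background median taken from
a user-supplied annulus of unstimulated tissue (default depth 0.3),
followed by morphological closing (10 μm disc) and retention of the
largest connected component — one electrode produces one lesion.
Components smaller than a 50 μm disc are discarded as background
texture, so a lesion-free image yields an empty mask. The threshold is
background-relative, hence exactly invariant under a global intensity
gain; a non-zero acquisition offset is removed via the `dark_reference`
argument (the 8-bit zero of a fluorescence image is physically
meaningful, so offset-free two-point normalisation is deliberately not
used — it would break the empty-mask contract on lesion-free images).
A manually traced polygon outline is supported as an alternative input
(`polygon_area_measure`, shoelace area).

The edge-ring criterion: the median intensity in the 80–100% annulus of
the equivalent radius must fall below the central-disc median by more
than one background standard deviation.

The electrode footprint of a tube of inner diameter `d` whose cut face
meets the surface at angle `α` is an ellipse with minor axis `d` and
major axis `d/sin α`; the area-equivalent (geometric-mean) diameter
`d/√(sin α)` is used because it is the diameter of the circle with the
footprint's area. For 380 μm at 45° this gives 451.9 μm (451 truncated);
the arithmetic mean of the axes (459 μm) is not area-equivalent.

## Microglia alignment index

**Structure tensor.** Gaussian-derivative gradients at scale σ_g
(default 2 μm, about a process width) are averaged over a Gaussian
window σ_T (default 10 μm, about a cell-arbor scale) to form
`J = ⟨∇I ∇Iᵀ⟩`. Orientation `½·atan2(2J_xy, J_yy − J_xx)` is axial
(modulo 180°) in the Cartesian display convention (counterclockwise
from +x with y up); coherency is `(λ₁−λ₂)/(λ₁+λ₂)`, zero where the
trace vanishes; energy is the trace. Z-stacks are maximum-projected
before analysis.

**ROI geometry.** An ellipse is fitted to the lesion mask from its
second-order moments (centroid; axes and tilt from the covariance
eigendecomposition, rescaled so the ellipse area equals the mask area),
and circular ROIs — default eight of 100 μm diameter — are placed at
equal parametric angles starting on the major axis.

**ROI aggregation.** Each ROI reports the orientation and anisotropy of
the *summed* structure tensor over its pixels: equivalently, the
doubled-angle vectors are averaged with `energy × coherency` weights
and normalised by total energy. A plain energy-weighted mean of unit
orientation vectors was rejected: once the tensor window blends a
cell's angular populations into a single per-pixel orientation, that
estimator saturates at coherency 1 regardless of the true angular
spread, whereas the tensor aggregate reports the same coherency whether
the dispersion lives across pixels or inside the window.

**Scoring.** Per ROI, Δθ is the acute axial angle between the measured
orientation and the direction to the lesion center, scored as
`cos²Δθ = (1 + cos 2Δθ)/2`; the zone index is the coherency-weighted
mean score. `cos²` rather than `|cos|` is essential: only `cos²`
averages to 0.5 under uniform axial orientations (`|cos|` gives
2/π ≈ 0.64), matching the random-orientation baseline of the index
scale. Weighting happens across the ROIs of a zone (weighted mean),
not after zone averaging. The index is invariant to rotating the zone
about the lesion center and is monotone in the generator's radial
concentration.

**Time course.** Zone indices grouped by time post-stimulation are
compared against the 0 h baseline with a paired t-test when group sizes
match (zones paired in listed order) and a Welch two-sample t-test
otherwise — unequal zone counts per timepoint (as in the study design,
5/3/5/5/5/3) cannot be paired literally; the test kind is recorded per
row.

## Eyewall bioimpedance

The charging response to a constant current pulse is modelled as two
parallel RC branches in series:
`V(t) = I·R_f(1−e^(−t/τ_f)) + I·R_s(1−e^(−t/τ_s))` during the pulse and
a mirrored passive decay with the same time constants after pulse end.
The fast branch is a genuine RC (τ_f ≈ 0.41 ms), not an instantaneous
resistive step. Units are fixed at ms/μA/mV/kΩ. The pulse-on window is
detected from the current channel (|I| > 50% of amplitude) and the
first post-onset sample is excluded. Fitting is bounded nonlinear least
squares initialised by exponential peeling: the complement
`V_∞ − V(t)` is fitted log-linearly on t > 3 ms for the slow branch,
subtracted, and the remainder fitted for the fast branch; τ_f < τ_s is
enforced by relabelling after the fit. Only the charging phase enters
the default fit. A fast amplitude below three residual RMS (or a
collapsed time-constant ratio) flags a degenerate fast branch instead
of inventing one. Drug effects are reported as fitted branch amplitudes
in percent of the control fit; the structural basis of the
interpretation — scaling one branch leaves the other's fitted amplitude
unchanged — holds to well below 1%.

## Statistics

Pre/post swelling uses the two-sided paired t-test; identical samples
return t = 0, p = 1, and zero-variance non-zero differences return a
divergent statistic with the minimal attainable p. Lesion measures
across the four charge-density groups use Kruskal–Wallis with tie
correction always applied (identical pooled data: H = 0, p = 1). Both
are verified in the test suite against from-definition oracles
(closed-form t; brute-force ranking for H) and exhaustive
permutation/rank enumerations on small instances. Tests are two-sided
throughout and no multiple-testing correction is applied, matching the
study's reporting; the report generator is a pure, order-invariant
function of the zone table.

## Synthetic data: what it emulates, and what not

All generators are deterministic in their seed, and every generator
returns machine-readable ground truth.

**B-scans** (default 256×256 px at 2 μm/px) are piecewise-constant
layer stacks — bright ILM line at 120 μm, moderate IPL, dark nuclear
band, bright outer complex — with multiplicative log-normal speckle
(`speckle_sd` is the relative sd, so SNR = 1/speckle_sd; the study's
frame-averaged acquisition justifies a controllable-SNR speckle model).
The stimulation effect displaces the ILM band upward by the bleb
height over a flat-top lateral footprint profile (452 μm, the
electrode footprint, with raised-cosine shoulders), swells GCL and IPL,
brightens the IPL, and optionally detaches the outer retina at the
footprint edges. An all-zero effect reproduces the control image
bit for bit. Not emulated: realistic speckle correlation, curvature,
motion artefacts, shadowing.

**Wholemounts** (1 μm/px) are block mosaics of 12 μm endfoot-sized
cells (Gaussian brightness, mean 180, sd 20, plus 4 sd pixel noise)
with a multiplicative hypofluorescent disc (default depth 0.6),
optionally ring-darkened at the edge, and optional bright nerve-fiber
overlays. Not emulated: depth-resolved structure, staining gradients,
real endfoot morphology.

**Microglia fields** (512×512 μm at 1 μm/px, lesion radius 150 μm)
draw each cell's process axis either uniformly or from an axial von
Mises about the radial direction; the concentration κ acts on the
doubled angle (the standard axial construction), so the axial sd is
approximately `1/(2√κ)` rad — κ = 100 puts ~92% and κ = 400 > 99.9% of
axes within ±5° of radial, and κ ≈ 1.2 lands the measured index in the
0.7–0.8 band. Cells sit at equally spaced, ±15°-jittered angles in an
annular band 10–60 μm outside the lesion edge (one cell per ROI on
average, mirroring the 8-cells-per-zone protocol); fully random angular
placement is deliberately not the default because empty ROIs then pick
up tangentially biased contamination from neighbouring arbors, which
depresses the uniform-orientation null below 0.5. Each cell is a
four-arm star: two full process axes at θ ± δ with `cos 2δ = c`, which
makes the rendered axial energy resultant equal the drawn coherency
`c` exactly in the segment limit. Rounded debris is rendered inside the
lesion core. Not emulated: process branching, somata, motility,
staining variability — so passing tests show the measurement chain
recovers known orientation statistics, not that it handles every real
morphology.

**Waveforms** are the forward model itself plus white Gaussian noise;
noisy conditions use 1% of the plateau voltage. Control amplitudes
R_f = 2.0 kΩ and R_s = 1.5 kΩ are plausible eyewall values chosen once
(the time constants, 0.41 and 4.01 ms, are the reported means); the fit
accuracy statements do not depend on the amplitude choice.

## Problem sizes and numerical notes

The validation suite uses 50-seed Monte-Carlo batches for the OCT and
lesion recovery checks, 100 seeds for the waveform re-fit, 200 zones
for the alignment-index null, and 10,000 replicates for the paired-t
type-I error — sizes at which the quoted tolerances are comfortably
resolved while the whole suite runs in a few minutes. Degenerate
inputs fail loudly: empty masks, flat profiles, missing baselines,
all-zero coherencies and zero-current waveforms raise typed errors
with diagnostics rather than returning numbers.
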