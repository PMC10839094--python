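# retglia

Quantitative analysis of epiretinal electrical-stimulation injury to
retinal glia, built around an ex-vivo rabbit retinal eyecup preparation
imaged with OCT and fluorescence microscopy.

High-charge-density pulse trains (442–749 μC/cm²/phase, 50 Hz) delivered
by a transparent tube electrode on the inner retinal surface injure the
glial cells that lie closest to the electrode. This package implements
the four measurements that quantify that injury, plus a seeded
synthetic-data module that emulates the study's images and waveforms
with known ground truth so every stage is testable end to end:

1. **OCT swelling morphometry** — column-averaged reflectivity profiles
   of B-scans, automatic layer-boundary detection (derivative extrema of
   the smoothed profile, labelled by the bright/dark layer sequence),
   and the two swelling metrics: the ILM–inner-IPL distension
   `d = z_IPL − z_ILM` (which triples when the inner limiting membrane
   detaches into a bleb) and the IPL thickness.
2. **GS lesion sizing** — segmentation of hypofluorescent
   glutamine-synthetase lesions in stained wholemounts
   (background-relative threshold, morphological closing, largest
   component), area `A`, equivalent diameter `d_eq = 2√(A/π)`, edge-ring
   detection, and the electrode-footprint geometry
   `d_fp = d/√(sin α)` for a tube of inner diameter `d` faced at angle
   `α` (380 μm at 45° → 451 μm).
3. **Microglia alignment index** — a gradient structure tensor
   `J = ⟨∇I ∇Iᵀ⟩` gives per-pixel orientation
   `θ = ½·atan2(2J_xy, J_yy − J_xx)`, coherency
   `(λ₁−λ₂)/(λ₁+λ₂)` and energy; circular 100 μm ROIs placed on the
   lesion-edge ellipse are each scored as `cos²Δθ` against the radial
   direction to the lesion center and averaged with coherency weights:

   `index = Σᵢ cᵢ·cos²Δθᵢ / Σᵢ cᵢ`

   Uniformly random axial orientations average to 0.5; a perfectly
   radial ring scores 1.
4. **Eyewall bioimpedance** — the two-time-constant charging model
   `V(t) = I·R_f(1−e^(−t/τ_f)) + I·R_s(1−e^(−t/τ_s))` fitted by
   nonlinear least squares with exponential-peeling initialisation
   (fast branch: retina + choroid/sclera; slow branch: RPE), and
   percent-of-control amplitudes for channel-blocker (barium)
   experiments.

A statistics module assembles per-zone tables: paired t-tests of
pre/post swelling, Kruskal–Wallis across the four charge-density
groups, and the alignment-index time course against the 0 h baseline.

## Worked example

```bash
python examples/oct_swelling.py
```

```
ILM-inner IPL distance pre :   50.1 um
ILM-inner IPL distance post:  168.0 um
distension ratio post/pre  :   3.35
IPL thickness ratio        :   1.43
IPL reflectivity change    : +60.1%
```

The synthetic post-stimulation B-scan carries a 70 μm ILM-detachment
bleb, GCL swelling and a 43% IPL thickening; the measurement chain
recovers the injected 3.35× distension and 1.43× IPL ratio from the
speckled images. The other scripts in `examples/` exercise lesion
sizing (`lesion_sizing.py`), the microglia alignment index and its time
course (`microglia_alignment.py`), the two-time-constant fit and barium
bookkeeping (`eyewall_impedance.py`), and the full cohort report
(`cohort_report.py`); each prints its numbers with a line on what they
mean.

## Layout

```
src/retglia/
  synthetic_data.py    seeded generators + ground truth
  oct_morphometry.py   B-scan profiles, boundaries, swelling metrics
  lesion_quant.py      lesion segmentation/sizing, electrode geometry
  orientation.py       structure tensor, ring ROIs, alignment index
  bioimpedance.py      two-RC forward model, fit, drug effects
  stats_report.py      paired t, Kruskal-Wallis, zone tables
docs/methods.md        model and design notes
```
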