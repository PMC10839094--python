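"""Measure stimulation-induced inner-retinal swelling on synthetic B-scans.

Builds a control B-scan and an overstimulated one (ILM detachment bleb,
GCL swelling, IPL thickening and hyperreflectivity), runs the profile ->
boundary-detection -> swelling-report chain, and prints the metrics.
"""

from retglia import oct_morphometry as oct
from retglia import synthetic_data as sd

effect = sd.StimEffectSpec(
    bleb_height_um=70.0,        # ILM lifts off the GCL, forming a bleb
    gcl_swelling_um=47.5,       # Muller-endfoot layer swells
    ipl_swelling_fraction=0.43, # IPL thickens by 43%
    ipl_hyperreflectivity_gain=1.6,
)
pre, truth_pre = sd.generate_bscan(speckle_sd=0.2, seed=1)
post, truth_post = sd.generate_bscan(effect=effect, speckle_sd=0.2, seed=1)

metrics = oct.measure_bscan_pair(pre, post)

print(f"ILM-inner IPL distance pre : {metrics.ilm_ipl_distance_pre_um:6.1f} um")
print(f"ILM-inner IPL distance post: {metrics.ilm_ipl_distance_post_um:6.1f} um")
print(f"distension ratio post/pre  : {metrics.distension_ratio_post_over_pre:6.2f}")
print(f"IPL thickness ratio        : {metrics.ipl_thickness_ratio_post_over_pre:6.2f}")
print(f"IPL reflectivity change    : {metrics.reflectivity_change_ipl:+6.1%}")
print()
print("A distension ratio near 3.4 and an IPL thickening near +43% are the")
print("hallmarks of high-charge-density overstimulation; an unstimulated")
print("pair would give ratios near 1.0.")
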