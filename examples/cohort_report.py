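"""Assemble the per-zone summary tables for a synthetic stimulation cohort.

Simulates five zones at each of the four charge densities (133-749
uC/cm^2/phase); the two high densities get the full injury phenotype.
Each zone is measured end to end (OCT swelling + lesion sizing), then
the statistics stage produces the grouped tables and cluster plot
coordinates.
"""

import pathlib

import pandas as pd

from retglia import lesion_quant as lq
from retglia import oct_morphometry as oct
from retglia import stats_report as sr
from retglia import synthetic_data as sd

ANNULUS = (511.5, 511.5, 430.0, 500.0)
rows = []
for cd in lq.CHARGE_DENSITIES:
    injured = cd >= 442
    for i in range(5):
        seed = cd * 10 + i
        effect = sd.StimEffectSpec(
            bleb_height_um=70.0 if injured else 0.0,
            gcl_swelling_um=45.0 if injured else 0.0,
            ipl_swelling_fraction=0.4 if injured else 0.0,
            ipl_hyperreflectivity_gain=1.5 if injured else 1.0,
        )
        pre, _ = sd.generate_bscan(speckle_sd=0.2, seed=seed)
        post, _ = sd.generate_bscan(effect=effect, speckle_sd=0.2, seed=seed + 1)
        m = oct.measure_bscan_pair(pre, post)
        wm = sd.WholemountSpec(
            lesion_diameter_um=520.0,
            hypofluorescence_depth=0.6 if injured else 0.0,
            seed=seed,
        )
        img, _ = sd.generate_wholemount(wm)
        lesion = lq.measure_lesion(lq.segment_lesion(img, ANNULUS))
        rows.append(
            {
                "zone_id": f"z{cd}_{i}",
                "charge_density_uC_cm2": cd,
                "ilm_ipl_pre_um": m.ilm_ipl_distance_pre_um,
                "ilm_ipl_post_um": m.ilm_ipl_distance_post_um,
                "ipl_thickness_pre_um": m.ipl_thickness_pre_um,
                "ipl_thickness_post_um": m.ipl_thickness_post_um,
                "lesion_area_um2": lesion.area_um2,
                "lesion_diameter_um": lesion.equivalent_diameter_um,
            }
        )

table = pd.DataFrame(rows)
report = sr.zone_report(table)

out_dir = pathlib.Path("scratch/examples")
out_dir.mkdir(parents=True, exist_ok=True)
for name, df in report.items():
    df.to_csv(out_dir / f"report_{name}.csv", index=False)

sw = report["swelling"]
print(sw[["charge_density_uC_cm2", "n", "ilm_ipl_pre_mean", "ilm_ipl_post_mean",
          "ilm_ipl_p", "ilm_ipl_significant"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print()
les = report["lesion"]
print(les.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print(f"Kruskal-Wallis across densities: H = {les.attrs['kruskal_H']:.2f}, "
      f"p = {les.attrs['kruskal_p']:.2g}")
print()
print("Only the two high charge densities show significant pre/post swelling")
print("and non-zero lesion diameters; the Kruskal-Wallis test separates the")
print("four dose groups, reproducing the dose-response structure of the assay.")
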