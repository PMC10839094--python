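import numpy as np
import pytest

from retglia import bioimpedance as bio
from retglia import synthetic_data as sd


@pytest.fixture(scope="session")
def eyewall_params() -> bio.CircuitParams:
    """Control eyewall circuit at the reported mean time constants."""
    return bio.CircuitParams(
        R_fast_kohm=2.0, tau_fast_ms=0.41, R_slow_kohm=1.5, tau_slow_ms=4.01
    )


@pytest.fixture(scope="session")
def default_bscan_pair():
    """Control and overstimulated B-scans sharing seed and layer spec.

    The effect injects the high-charge-density phenotype: 70 um ILM
    detachment bleb plus GCL swelling chosen so the ILM-inner-IPL
    distension triples and beyond (3.35x), a 43% IPL thickening, and
    IPL hyperreflectivity.
    """
    effect = sd.StimEffectSpec(
        bleb_height_um=70.0,
        gcl_swelling_um=47.5,
        ipl_swelling_fraction=0.43,
        ipl_hyperreflectivity_gain=1.6,
        edge_detachment=True,
    )
    pre, truth_pre = sd.generate_bscan(seed=11)
    post, truth_post = sd.generate_bscan(effect=effect, seed=11)
    return pre, truth_pre, post, truth_post, effect
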