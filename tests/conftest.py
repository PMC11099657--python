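import numpy as np
import pytest

from meioseq.cn import build_panel, call_profile
from meioseq.genome import ChromosomeSpec, make_binning
from meioseq.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def noiseless_study():
    """Deterministic study: no count noise, no biases, no QC failures."""
    cfg = SimulationConfig(
        nb_size=None, bias_sigma=0.0, p_qc_fail=0.0, frac_overrepresented=0.0
    )
    return simulate_study(cfg, 5)


@pytest.fixture(scope="session")
def noisy_study():
    """Study at the default noise settings (QC failures disabled so every
    pair is callable)."""
    cfg = SimulationConfig(p_qc_fail=0.0)
    return simulate_study(cfg, 11)


@pytest.fixture(scope="session")
def small_chromosomes():
    """A three-chromosome toy genome for cheap simulation tests."""
    return [
        ChromosomeSpec("1", 50_000_000, is_sex=False),
        ChromosomeSpec("2", 35_000_000, is_sex=False),
        ChromosomeSpec("X", 40_000_000, is_sex=True),
    ]


@pytest.fixture(scope="session")
def small_binning(small_chromosomes):
    return make_binning(small_chromosomes, window_size=10_000_000)


def observed_pair(study, index):
    """Observed (egg, pb) copy-number maps for one pair of a study."""
    panel_norm = build_panel([study.panel], study.binning)
    egg, pb = study.sample_pairs[index]
    ep = {
        c: v
        for c, v in call_profile(egg, panel_norm, study.binning).observed_cn.items()
        if c != "Y"
    }
    pp = {
        c: v
        for c, v in call_profile(pb, panel_norm, study.binning).observed_cn.items()
        if c != "Y"
    }
    return ep, pp
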