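import numpy as np
import pytest

from laminar_ifc.stimulus_surface import ChirpStimulus, CorticalSheet
from laminar_ifc.synthetic_data import SynthConfig, make_ground_truth, simulate_subject


@pytest.fixture(scope="session")
def stim():
    return ChirpStimulus()


@pytest.fixture(scope="session")
def small_sheet():
    return CorticalSheet(n_rows=6, n_cols=11, spacing_mm=1.5, depths=(0.1, 0.9))


def tiny_synth(**overrides) -> SynthConfig:
    """Small cohort config used across unit tests (fast to simulate)."""
    kw = dict(
        n_subjects=2,
        n_rows=6,
        n_cols=11,
        depths=(0.1,),
        core_rows=(2, 4),
        core_cols=(3, 8),
        gradient_f_low=350.0,
        gradient_f_high=2850.0,
        lambda_table={0.1: {"core": 2.0, "noncore": 1.0}},
        noise_sd=0.05,
    )
    kw.update(overrides)
    return SynthConfig(**kw)


@pytest.fixture(scope="session")
def tiny_cfg():
    return tiny_synth()


@pytest.fixture(scope="session")
def tiny_cohort(stim, tiny_cfg):
    sheet = tiny_cfg.sheet()
    gt = make_ground_truth(sheet, tiny_cfg, seed=0)
    runs = simulate_subject(gt, stim, tiny_cfg, subject=0, seed=123)
    return sheet, gt, runs


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
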