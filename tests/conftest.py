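import numpy as np
import pytest

import kinfit as kf

# canonical synthetic truth used across tests: slow Moser kinetics whose
# substrate depletion and biomass growth span the full 9-day daily-sampling
# window (the data shape the estimation workflow is designed for)
MOSER_TRUTH = dict(mu_max=0.04, Ks=20.0, Y=0.4, kd=0.005, b=1.0)
MOSER_N = 1.5


@pytest.fixture(scope="session")
def moser_spec():
    return kf.get_model("Moser")


@pytest.fixture(scope="session")
def monod_spec():
    return kf.get_model("Monod")


@pytest.fixture(scope="session")
def moser_truth():
    return kf.KineticParams(**MOSER_TRUTH, extras={"n": MOSER_N})


@pytest.fixture(scope="session")
def monod_truth():
    return kf.KineticParams(**MOSER_TRUTH)


@pytest.fixture(scope="session")
def zero_noise_moser_ds(moser_spec, moser_truth):
    design = kf.SyntheticDesign(noise_sd_log10=0.0, n_replicates=1)
    return kf.generate_synthetic(moser_spec, moser_truth, design, seed=42)


@pytest.fixture(scope="session")
def zero_noise_monod_ds(monod_spec, monod_truth):
    design = kf.SyntheticDesign(noise_sd_log10=0.0, n_replicates=1)
    return kf.generate_synthetic(monod_spec, monod_truth, design, seed=42)


@pytest.fixture(scope="session")
def noisy_monod_ds(monod_spec, monod_truth):
    design = kf.SyntheticDesign(noise_sd_log10=0.02, n_replicates=3)
    return kf.generate_synthetic(monod_spec, monod_truth, design, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260918)
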