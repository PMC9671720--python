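import numpy as np
import pytest
from hypothesis import settings

from faintnmr.core import SampleInfo, calibrate_ig
from faintnmr.integrate import integrate_regions
from faintnmr.synthetic import (EXAMPLE_NOISE_REGION, default_calibration_design,
                                default_gain_model, example_regions,
                                example_signals, simulate_calibration_set)

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture(scope="session")
def signals():
    return example_signals()


@pytest.fixture(scope="session")
def regions():
    return example_regions()


def build_calibration(gain, target_snr=None, seed=11, ig_true=1650.0):
    """Simulate the default study design and integrate it; returns
    (per-sample integrals, SampleInfo list, manifest)."""
    design = default_calibration_design()
    spectra, manifest = simulate_calibration_set(
        design, example_signals(), gain, ig_true=ig_true,
        seed=seed, target_snr=target_snr)
    integrals = {}
    for (_, row), spec in zip(manifest.iterrows(), spectra):
        integrals.setdefault(row.sample_id, []).extend(
            integrate_regions(spec, example_regions(),
                              noise_region=EXAMPLE_NOISE_REGION))
    ids = manifest.drop_duplicates("sample_id")[["sample_id", "concentration_mM"]]
    samples = [SampleInfo(sample_id=sid, known_concentration_mM=c)
               for sid, c in ids.itertuples(index=False)]
    return integrals, samples, manifest


@pytest.fixture(scope="session")
def identity_calibration():
    """Noiseless calibration set with a perfectly linear receiver."""
    gain = default_gain_model(identity=True)
    integrals, samples, manifest = build_calibration(gain)
    return {"gain": gain, "integrals": integrals, "samples": samples,
            "manifest": manifest, "cal": calibrate_ig(integrals, samples)}


@pytest.fixture(scope="session")
def noisy_identity_calibration():
    """Calibration set with every spectrum's weakest signal at SNR 200."""
    gain = default_gain_model(identity=True)
    integrals, samples, manifest = build_calibration(gain, target_snr=200.0,
                                                     seed=41)
    return {"gain": gain, "integrals": integrals, "samples": samples,
            "manifest": manifest, "cal": calibrate_ig(integrals, samples)}


@pytest.fixture(scope="session")
def nonlinear_calibration():
    """Noiseless calibration set with the realistically nonlinear receiver."""
    gain = default_gain_model(identity=False)
    integrals, samples, manifest = build_calibration(gain)
    return {"gain": gain, "integrals": integrals, "samples": samples,
            "manifest": manifest, "cal": calibrate_ig(integrals, samples)}
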