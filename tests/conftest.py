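import numpy as np
import pytest

from natremri import synth


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free volume-coil sodium scene with ground truth."""
    spec = synth.ScenePhantomSpec(noise_sigma=0.0, seed=7)
    img, rois, conc = synth.generate_sodium_image(spec)
    return spec, img, rois, conc


@pytest.fixture(scope="session")
def surface_scene():
    """Noise-free surface-coil scene plus its B1 reference image."""
    spec = synth.ScenePhantomSpec(coil_mode="surface", noise_sigma=0.0, seed=11)
    img, rois, conc = synth.generate_sodium_image(spec)
    ref = synth.generate_b1_reference(spec)
    return spec, img, rois, conc, ref


@pytest.fixture(scope="session")
def clean_dwi():
    """Noise-free mono-exponential DWI series with ground-truth ADC map."""
    series, adc_map, tumour = synth.generate_dwi_series(synth.DWISceneSpec(seed=3))
    return series, adc_map, tumour


@pytest.fixture(scope="session")
def cohort():
    return synth.generate_cohort(synth.CohortSpec(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
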