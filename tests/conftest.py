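import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import laims as L

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_acq() -> L.AcquisitionConfig:
    return L.AcquisitionConfig(noise_multiplicative_cv=0.0,
                               noise_additive_sd_cps=0.0)


@pytest.fixture(scope="session")
def default_acq() -> L.AcquisitionConfig:
    return L.AcquisitionConfig()


@pytest.fixture(scope="session")
def phantom() -> L.TissuePhantom:
    return L.generate_phantom(seed=3)


@pytest.fixture(scope="session")
def protocols():
    return L.default_protocols()


@pytest.fixture(scope="session")
def noiseless_cal(noiseless_acq):
    """Calibration fitted on noiseless synthetic gelatin standards."""
    from laims.phantom import DEFAULT_STANDARD_SOLUTIONS_UG_ML
    noms = [L.standard_concentration(0.100, 0.900, c)
            for c in DEFAULT_STANDARD_SOLUTIONS_UG_ML]
    stds = L.generate_standard_set(noms, noiseless_acq, seed=0)
    return L.fit_calibration([L.make_level(ls, "64Zn", c) for c, ls in stds])


@pytest.fixture(scope="session")
def ff_maps(phantom, protocols):
    return L.apply_protocol(phantom, protocols["FF"])


@pytest.fixture(scope="session")
def ff_section(phantom, ff_maps, default_acq):
    """One fresh-frozen section acquired at default noise, as channel maps."""
    ls = L.simulate_linescans(ff_maps, default_acq, seed=11)
    return {ch: L.lines_to_map(ls, ch, phantom.pixel_size_um)
            for ch in ls.channel_names}


def truth_labels(phantom, seg):
    """Ground-truth labels over a segmentation's crop window."""
    return L.crop_to_roi(phantom.label_grid, seg.params.crop_shape_px,
                         seg.crop_origin)


def predicted_labels(seg):
    """Segmentation classes with flagged hotspots mapped to the phantom's
    hotspot code."""
    return np.where(seg.hotspot, L.HOTSPOT, seg.labels.astype(int))
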