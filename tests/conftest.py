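import numpy as np
import pytest

from midas.io import Volume3D, resample_isotropic
from midas.phantom import CMBSpec, PhantomSpec, make_phantom, region_label_volume
from midas.pipeline import _resample_priors_like
from midas.priors import priors_from_labels

#: compact clinical-geometry grid used across the suite (working grid ~60^3)
SMALL_GRID = (96, 96, 15)


def small_spec(**kwargs) -> PhantomSpec:
    kwargs.setdefault("grid_shape", SMALL_GRID)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def lesion_phantom():
    """Noisy, biased phantom with three well-separated lobar lesions."""
    spec = small_spec(
        cmb_list=[
            CMBSpec((20.0, 10.0, 0.0), 6.0, 0.3),
            CMBSpec((-25.0, 15.0, 6.5), 5.0, 0.3),
            CMBSpec((0.0, -30.0, 0.0), 7.0, 0.3),
        ],
        noise_sigma=5.0,
        bias_amplitude=0.1,
        seed=7,
    )
    vol, gt = make_phantom(spec)
    return spec, vol, gt


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, bias-free phantom without lesions."""
    spec = small_spec(seed=3)
    vol, gt = make_phantom(spec)
    return spec, vol, gt


@pytest.fixture(scope="session")
def working_setup(lesion_phantom):
    """Phantom resampled to the working grid with matching priors."""
    spec, vol, gt = lesion_phantom
    work = resample_isotropic(vol, 1.5)
    priors = _resample_priors_like(priors_from_labels(gt.tissue_label_map), work)
    regions = region_label_volume(spec)
    return spec, work, priors, regions, gt


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
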