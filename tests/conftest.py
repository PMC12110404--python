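import numpy as np
import pytest

from drlroi.phantom import PhantomConfig, generate_cohort


def small_phantom_config(**kwargs) -> PhantomConfig:
    """32-px phantom settings shared by the fast tests."""
    defaults = dict(
        n_patients_per_class=6,
        slices_per_patient=3,
        image_size=32,
        roi_radius_range=(5.0, 9.0),
        roi_contrast=0.2,
        roi_texture_freq=(2.0, 5.0),
        background_distractor_count=4,
        distractor_contrast=0.45,
        center_jitter=0.08,
        noise_sigma=0.03,
        seed=0,
    )
    defaults.update(kwargs)
    return PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_phantom_config())


def finite_difference_grad(f, x, eps=1e-6):
    """Central-difference gradient of scalar f at array x."""
    x = np.asarray(x, dtype=np.float64)
    grad = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        hi = f(x)
        x[idx] = orig - eps
        lo = f(x)
        x[idx] = orig
        grad[idx] = (hi - lo) / (2 * eps)
        it.iternext()
    return grad
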