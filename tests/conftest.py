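import numpy as np
import pytest

from morphuniq.procrustes import gpa_align
from morphuniq.simulate import emulate_study
from morphuniq.warps import build_shape_basis, relative_warps, shape_variables


@pytest.fixture(scope="session")
def study():
    """One emulated study dataset with its ground truth (seed fixed)."""
    return emulate_study(seed=42)


@pytest.fixture(scope="session")
def study_chain(study):
    """GPA + shape basis + shape variables + relative warps on the study data."""
    ds, truth = study
    gpa = gpa_align(ds)
    basis = build_shape_basis(gpa.consensus)
    sv = shape_variables(gpa, basis)
    rw = relative_warps(sv)
    return ds, truth, gpa, basis, sv, rw


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_noisy_shapes(rng, n=20, k=11, noise=0.003, transform=True):
    """Small helper: noisy copies of a random template under random similarity."""
    base = rng.normal(size=(k, 2))
    base -= base.mean(0)
    base /= np.sqrt((base**2).sum())
    arr = np.stack([base + rng.normal(scale=noise, size=(k, 2)) for _ in range(n)])
    if transform:
        for i in range(n):
            th = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            arr[i] = arr[i] @ rot * rng.uniform(0.5, 2.0) + rng.normal(size=2)
    return base, arr
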