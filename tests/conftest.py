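import numpy as np
import pytest

from polypnextlstm.synthetic import make_benchmark_suite


@pytest.fixture(scope="session")
def dataset_root(tmp_path_factory):
    """A small synthetic dataset tree: 6 clips x 8 frames at 64x64."""
    root = tmp_path_factory.mktemp("clips")
    make_benchmark_suite(root, n_clips=6, seed=42, image_size=(64, 64),
                         n_frames=8)
    return root


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def numeric_gradient(f, arr, eps: float = 1e-6):
    """Central-difference gradient of scalar-valued f w.r.t. arr (in place)."""
    grad = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = arr[idx]
        arr[idx] = orig + eps
        fp = f()
        arr[idx] = orig - eps
        fm = f()
        arr[idx] = orig
        grad[idx] = (fp - fm) / (2 * eps)
    return grad
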