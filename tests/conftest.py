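import numpy as np
import pytest

import qtimcd as q


@pytest.fixture(scope="session")
def protocol():
    """Default 58-volume linear+spherical protocol."""
    return q.build_protocol(seed=1)


@pytest.fixture(scope="session")
def design(protocol):
    return q.design_matrix(protocol)


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """One full end-to-end run on the default phantom (seed 7), shared by
    the pipeline and acceptance tests."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = q.RunConfig().with_seed(7)
    return q.run_pipeline(cfg, out), out, cfg


def random_psd_tensor(rng, scale=1.0):
    a = rng.standard_normal((3, 3)) * scale
    return a @ a.T / 3.0


def random_mixture(rng, k=3):
    """Random physical tensor distribution (mixture of PSD tensors)."""
    w = rng.dirichlet(np.ones(k))
    tensors = np.stack([random_psd_tensor(rng) for _ in range(k)])
    return q.TensorDistribution(w, tensors)
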