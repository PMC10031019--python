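import os

# pin BLAS threading before numpy is imported anywhere, for bitwise
# reproducibility of training runs across machines
os.environ.setdefault("OMP_NUM_THREADS", "1")
os.environ.setdefault("OPENBLAS_NUM_THREADS", "1")
os.environ.setdefault("MKL_NUM_THREADS", "1")

import numpy as np
import pytest

from symseg_da.phantom import (
    DomainStyle,
    PhantomConfig,
    generate_domain_dataset,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_config():
    return PhantomConfig(image_size=32, nodules_per_image=(1, 2), seed=0)


@pytest.fixture(scope="session")
def tiny_source_dataset(tiny_config):
    return generate_domain_dataset(
        tiny_config, DomainStyle(gamma=0.9), n=10, test_fraction=0.2, seed=7, domain="source"
    )


@pytest.fixture(scope="session")
def tiny_target_dataset(tiny_config):
    return generate_domain_dataset(
        tiny_config, DomainStyle(gamma=1.4, invert=True), n=10, test_fraction=0.2, seed=8,
        domain="target",
    )
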