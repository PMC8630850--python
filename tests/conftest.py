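"""Shared fixtures: small synthetic datasets and trained models.

Training fixtures use 100 bp windows so the full pipeline stays fast; the
architecture is the default one (two blocks, 32/64 filters, width-20
kernels), only the window is shorter.
"""

from __future__ import annotations

import numpy as np
import pytest

from epidmr import ConvNetClassifier, HybridDMRClassifier, generate
from epidmr.simulate import SyntheticSpec

SMALL_WINDOW = 100


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    # mutation rate 0 and a dense CpG load: clearly separable classes even
    # at this small window and sample size
    return SyntheticSpec(
        n_per_class=100,
        window_size=SMALL_WINDOW,
        mutation_rate=0.0,
        motif_copies=2,
        pos_cpg_rate=8,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_ds(small_spec):
    return generate(small_spec)


@pytest.fixture(scope="session")
def small_Xy(small_ds):
    return small_ds.encode(), small_ds.labels


def small_net_params(**overrides):
    params = dict(max_epochs=25, batch_size=32, early_stop_patience=8,
                  random_state=0)
    params.update(overrides)
    return params


@pytest.fixture(scope="session")
def trained_net(small_Xy):
    X, y = small_Xy
    return ConvNetClassifier(**small_net_params()).fit(X, y)


@pytest.fixture(scope="session")
def trained_hybrid(small_Xy):
    X, y = small_Xy
    return HybridDMRClassifier(
        network=ConvNetClassifier(**small_net_params()), random_state=0
    ).fit(X, y)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
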