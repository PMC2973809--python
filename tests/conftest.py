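import numpy as np
import pytest

import fishdyn as fd


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_cycle():
    """Generic 4-gene single-harmonic bursty cycle, no clipping."""
    return fd.sample_bursty_params(4, rng_seed=11, mean_range=(0.1, 0.3),
                                   rel_amp_range=(0.3, 0.8))


@pytest.fixture
def small_switch():
    return fd.sample_switch_params(5, 2, rng_seed=12, min_separation=0.3)


@pytest.fixture
def continuous_model():
    return fd.sample_cycle_params(4, rng_seed=13)


def make_pair_set(arrays, regime="bursty_binary", pairs=None, n_genes=None):
    """Build a PairObservationSet from a list of (M, 2) arrays."""
    arrays = [np.asarray(a, dtype=float) for a in arrays]
    if pairs is None:
        pairs = [(2 * k, 2 * k + 1) for k in range(len(arrays))] \
            if n_genes is None else fd.all_pairs(n_genes)[:len(arrays)]
    n = n_genes or max(max(p) for p in pairs) + 1
    return fd.PairObservationSet(
        gene_names=[f"g{i}" for i in range(n)], pairs=list(pairs),
        counts=arrays, regime=regime)
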