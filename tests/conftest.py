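import numpy as np
import pytest

import spikehar as sh


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small, mildly noisy 3-class dataset for fast training tests (T=64)."""
    spec = sh.SyntheticSpec(n_per_class=30, n_classes=3, T=64, D=3,
                            base_freqs=(3, 6, 9), noise_sd=0.2, seed=7)
    return sh.split_dataset(sh.generate_synthetic(spec), seed=7)


@pytest.fixture(scope="session")
def benchmark_dataset():
    return sh.benchmark_dataset(seed=1000)


@pytest.fixture(scope="session")
def benchmark_suites(benchmark_dataset):
    """The full benchmark run: SpikeCNN seed suites across the tau grid
    {0, 0.25, 0.75} and both reset modes, plus one trained CNN twin.

    Shared by the end-to-end accuracy, ablation-direction, and
    sparsity/energy tests; this is the expensive part of the suite.
    """
    ds = benchmark_dataset
    spec = sh.build_spike_cnn(ds.D, ds.n_classes)
    tc = sh.benchmark_train_config()
    seeds = (1000, 1001, 1002, 1003, 1004)
    suites = {}
    for tau in (0.0, 0.25, 0.75):
        suites[("tau", tau)] = sh.run_seed_suite(
            spec, ds, tc, lif_config=sh.benchmark_lif_config(tau=tau), seeds=seeds)
    suites[("reset", "soft")] = suites[("tau", 0.25)]
    suites[("reset", "hard")] = sh.run_seed_suite(
        spec, ds, tc, lif_config=sh.benchmark_lif_config(reset_mode="hard"),
        seeds=seeds)
    ann_spec = sh.build_cnn(ds.D, ds.n_classes)
    suites["cnn_record"] = sh.train(ann_spec, ds, tc, seed=1000)
    return suites
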