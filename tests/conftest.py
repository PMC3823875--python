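import sys
import warnings
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from predr import (
    BenchmarkParams,
    PairKernel,
    generate_benchmark,
    psd_repair,
)
from predr.pipeline import build_drug_kernels


@pytest.fixture(scope="session")
def default_benchmark():
    """The standard synthetic benchmark: 60 drugs, 40 diseases, 4 planted
    classes, 10% bit noise, seed 0."""
    return generate_benchmark(BenchmarkParams(seed=0))


@pytest.fixture(scope="session")
def small_benchmark():
    """A fast benchmark for structural tests."""
    return generate_benchmark(
        BenchmarkParams(
            n_drugs=16,
            n_diseases=12,
            n_classes=2,
            n_chem_features=60,
            n_se_features=40,
            seq_length=50,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def default_kernels(default_benchmark):
    """PSD-repaired drug kernels + disease kernel for the default bench."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kernels = build_drug_kernels(default_benchmark)
    pheno = psd_repair(default_benchmark.pheno)
    return kernels, pheno


@pytest.fixture(scope="session")
def comb_pair_kernel(default_kernels):
    kernels, pheno = default_kernels
    return PairKernel(kernels["comb"], pheno)


@pytest.fixture(scope="session")
def small_pair_kernel(small_benchmark):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kernels = build_drug_kernels(small_benchmark)
    return PairKernel(kernels["comb"], psd_repair(small_benchmark.pheno))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
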