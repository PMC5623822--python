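import numpy as np
import pandas as pd
import pytest

from muenv import (
    CellLineSimConfig,
    ExpressionMatrix,
    build_signature,
    call_de,
    filter_probes,
    fit_linear_contrast,
    mean_center,
    quantile_normalize,
    simulate_cellline_experiment,
)
from muenv.core_io import SUBTYPES


@pytest.fixture
def tiny_matrix():
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.normal(7, 1, size=(5, 4)),
        index=[f"g{i}" for i in range(5)],
        columns=[f"s{j}" for j in range(4)],
    )
    return ExpressionMatrix(values)


@pytest.fixture(scope="session")
def cellline_experiment():
    """Small but realistic cell-line simulation shared across tests."""
    cfg = CellLineSimConfig(n_genes=2000, seed=11)
    matrix, design, truth = simulate_cellline_experiment(cfg)
    return cfg, matrix, design, truth


@pytest.fixture(scope="session")
def processed_celllines(cellline_experiment):
    cfg, matrix, design, truth = cellline_experiment
    proc = quantile_normalize(filter_probes(matrix))
    return proc, design, truth


@pytest.fixture(scope="session")
def contrasts(processed_celllines):
    proc, design, _ = processed_celllines
    return {s: fit_linear_contrast(proc, design, s) for s in SUBTYPES}


@pytest.fixture(scope="session")
def signatures(processed_celllines, contrasts):
    proc, design, _ = processed_celllines
    centered = mean_center(proc)
    return {
        s: build_signature(call_de(contrasts[s]), centered, design, s)
        for s in SUBTYPES
    }
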