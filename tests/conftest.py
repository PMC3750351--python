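"""Shared fixtures: small seeded synthetic datasets and pipeline runs."""

import logging

import numpy as np
import pandas as pd
import pytest

from comirnet.io_formats import ExpressionMatrix, RunConfig
from comirnet.pipeline import run_pipeline
from comirnet.simulate import SimulationParams, simulate_dataset

logging.getLogger("comirnet").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-scale synthetic dataset reused across read-only tests."""
    return simulate_dataset(SimulationParams(seed=7))


@pytest.fixture(scope="session")
def pipeline_result(default_dataset):
    """Full pipeline run on the default dataset (read-only)."""
    ds = default_dataset
    return run_pipeline(ds.mrna, ds.mirna, ds.phenotypes, ds.covariates,
                        ds.mirna_seqs, ds.utr_seqs, ds.annotation,
                        ds.truth.mirna_families, RunConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_expression(values, probes=None, samples=None, layer_tag="raw"):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples),
                            layer_tag=layer_tag)
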