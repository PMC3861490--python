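"""Shared fixtures: tiny hand-built datasets and collections."""

import numpy as np
import pandas as pd
import pytest

from crossgsea import ExpressionDataset, GeneSetCollection


def make_dataset(values, genes, groups, dataset_id="T", probes=None):
    """Build an ExpressionDataset from a plain nested list / array.

    values: (n_probes, n_samples); genes: per-probe gene symbols; groups:
    per-sample 'case'/'control' tokens.
    """
    arr = np.asarray(values, dtype=float)
    n_probes, n_samples = arr.shape
    if probes is None:
        probes = [f"p{i + 1}" for i in range(n_probes)]
    samples = [f"s{i + 1}" for i in range(n_samples)]
    return ExpressionDataset(
        dataset_id=dataset_id,
        values=pd.DataFrame(arr, index=pd.Index(probes, name="probe_id"),
                            columns=samples),
        gene_of_probe=pd.Series(list(genes), index=pd.Index(probes, name="probe_id"),
                                name="gene"),
        group_of_sample=pd.Series(list(groups), index=pd.Index(samples),
                                  name="group"),
    )


@pytest.fixture
def dataset_factory():
    return make_dataset


@pytest.fixture
def small_collection():
    return GeneSetCollection(
        [
            ("S1", "first", ["g1", "g2", "g3"]),
            ("S2", "second", ["g3", "g4"]),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240924)
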