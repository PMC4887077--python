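import logging

import numpy as np
import pandas as pd
import pytest

import rxdeconv as rx

logging.getLogger("rxdeconv").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort for mechanics tests (not recovery benchmarks)."""
    cfg = rx.GeneratorConfig(
        G=150, M=4, N=5, total_counts=20_000, n_de_genes=10, seed=7
    )
    return rx.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    config = rx.FitConfig(n_restarts=2, max_outer_iterations=15, seed=3)
    return rx.fit_map(small_cohort.panel, small_cohort.counts, config)


@pytest.fixture()
def tiny_panel():
    return rx.ReferencePanel(
        values=np.array([[0.2, 0.1], [0.3, 0.4], [0.5, 0.5]]),
        gene_ids=["gA", "gB", "gC"],
        sample_ids=["s1", "s2"],
    )


@pytest.fixture()
def tiny_counts():
    return rx.CountMatrix(
        values=np.array([[5, 2], [3, 6], [2, 2]]),
        gene_ids=["gA", "gB", "gC"],
        sample_ids=["p1", "p2"],
    )


def make_matrix(values, gene_ids, sample_ids) -> pd.DataFrame:
    return pd.DataFrame(np.asarray(values, dtype=float), index=gene_ids, columns=sample_ids)
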