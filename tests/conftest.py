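"""Shared fixtures and small data builders."""

from __future__ import annotations

import numpy as np
import pytest

from clonetree.emission import GridLikelihood, PrevalenceGrid, compute_grid_likelihood
from clonetree.io_formats import SnvObservation, SnvTable
from clonetree.tree_model import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_obs(
    mutation_id="m0",
    sample_id="s0",
    alt=5,
    depth=10,
    major_cn=1,
    minor_cn=1,
    tumour_content=1.0,
    error_rate=0.001,
):
    return SnvObservation(
        mutation_id=mutation_id,
        sample_id=sample_id,
        ref_counts=depth - alt,
        alt_counts=alt,
        major_cn=major_cn,
        minor_cn=minor_cn,
        normal_cn=2,
        tumour_content=tumour_content,
        error_rate=error_rate,
    )


def make_table(alt_matrix, depth=100, tumour_content=1.0, error_rate=0.001):
    """Diploid-het table from an (mutations x samples) alt-count array."""
    alt_matrix = np.atleast_2d(alt_matrix)
    obs = []
    for i in range(alt_matrix.shape[0]):
        for j in range(alt_matrix.shape[1]):
            obs.append(
                make_obs(
                    mutation_id=f"m{i}",
                    sample_id=f"s{j}",
                    alt=int(alt_matrix[i, j]),
                    depth=depth,
                    tumour_content=tumour_content,
                    error_rate=error_rate,
                )
            )
    return SnvTable(observations=obs)


def make_gl(alt_matrix, depth=100, grid_size=51, density="binomial", precision=None):
    table = make_table(alt_matrix, depth=depth)
    return compute_grid_likelihood(
        table, PrevalenceGrid(grid_size), density, precision
    )


@pytest.fixture
def binom_config():
    return ModelConfig(grid_size=51, density_kind="binomial", precision=None)
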