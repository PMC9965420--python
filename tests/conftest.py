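"""Shared synthetic fixtures. Everything is generated in-process from fixed seeds."""

from __future__ import annotations

import numpy as np
import pytest

import tricontinuum as tc


@pytest.fixture(scope="session")
def noiseless_cohort():
    """300-sample, 400-gene noiseless 3-archetype mixture with planted markers."""
    truth = tc.make_mixture_truth(
        n_samples=300, n_genes=400, k=3, alpha=(1.0, 1.0, 1.0),
        marker_block_size=25, noise_model="none", seed=101,
    )
    matrix, truth = tc.simulate_bulk_cohort(truth)
    return matrix, truth


@pytest.fixture(scope="session")
def poisson_cohort():
    """Same structure as the noiseless cohort but observed through Poisson noise."""
    truth = tc.make_mixture_truth(
        n_samples=300, n_genes=400, k=3, alpha=(1.0, 1.0, 1.0),
        marker_block_size=25, noise_model="poisson", seed=202,
    )
    matrix, truth = tc.simulate_bulk_cohort(truth)
    return matrix, truth


@pytest.fixture(scope="session")
def small_reference():
    """3-type orthogonal-support reference (90 cells) with 8 bulk mixtures."""
    rt = tc.make_reference_truth(
        n_types=3, cells_per_type=30, n_genes=150, n_bulk=8, seed=303,
    )
    ref_m, labels, emb, bulk = tc.simulate_reference_and_bulk(rt)
    atlas = tc.ReferenceAtlas.from_frames(ref_m, labels, emb)
    return rt, atlas, bulk


def true_latent_vertices(truth: tc.MixtureTruth, emb) -> np.ndarray:
    """Project the planted archetype profiles into an embedding's latent space."""
    return (truth.archetype_profiles - emb.center) @ emb.loadings
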