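"""Ground-truthed synthetic cohorts for validating every pipeline stage.

Two generative families are provided:

* **Convex-mixture cohorts** (:class:`MixtureTruth` / :func:`simulate_bulk_cohort`):
  each bulk sample is a convex combination of k extreme ("archetype") gene
  profiles with Dirichlet-distributed weights, optionally observed through
  Poisson or mean-preserving lognormal noise. This is exactly the structure
  assumed by both the simplex-fitting and the grade-of-membership stages, so
  fitted vertices / topic loadings can be compared against the planted
  weights.

* **Single-cell reference + pseudo-bulk** (:class:`ReferenceTruth` /
  :func:`simulate_reference_and_bulk`): a labeled reference of single-cell
  profiles with a 2D cell-state embedding (Gaussian cluster per type), and
  bulk samples formed as weighted sums of per-type mean profiles. This is the
  harness for the deconvolution stage.

Archetype profiles carry per-archetype *exclusive marker blocks* — genes
expressed in exactly one archetype — so marker-recovery rules are testable
against a planted ground truth (the blocks are exported as a GMT library).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "MixtureTruth",
    "ReferenceTruth",
    "make_mixture_truth",
    "make_reference_truth",
    "make_linked_reference",
    "simulate_bulk_cohort",
    "simulate_reference_and_bulk",
    "write_cohort",
]

_NOISE_MODELS = ("none", "poisson", "lognormal")


@dataclass
class MixtureTruth:
    """Ground truth for a convex-mixture bulk cohort.

    ``archetype_profiles`` is k x G (expected expression of each idealized
    extreme), ``weights`` is n x k with rows on the probability simplex
    (the theta_1..theta_k mixture proportions of each sample, drawn from a
    Dirichlet with concentration ``dirichlet_alpha``).
    """

    archetype_profiles: np.ndarray
    weights: np.ndarray
    dirichlet_alpha: np.ndarray
    noise_model: str = "poisson"
    dispersion: float = 0.3
    seed: int = 0
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    archetype_names: list[str] = field(default_factory=list)
    marker_blocks: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.archetype_profiles = np.asarray(self.archetype_profiles, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.dirichlet_alpha = np.asarray(self.dirichlet_alpha, dtype=float)
        k, n_genes = self.archetype_profiles.shape
        if k < 2:
            raise ValueError("need at least k=2 archetypes")
        if n_genes < k:
            raise ValueError("need at least as many genes as archetypes")
        if (self.dirichlet_alpha <= 0).any():
            raise ValueError("Dirichlet concentration parameters must be positive")
        if (self.archetype_profiles < 0).any():
            raise ValueError("archetype profiles must be non-negative")
        if self.weights.shape[1] != k:
            raise ValueError("weights must have one column per archetype")
        if (self.weights < 0).any():
            raise ValueError("mixture weights must be non-negative")
        if not np.allclose(self.weights.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("mixture weight rows must sum to 1")
        if self.noise_model not in _NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {_NOISE_MODELS}")
        if not self.gene_ids:
            self.gene_ids = [f"g{i:04d}" for i in range(n_genes)]
        if not self.sample_ids:
            self.sample_ids = [f"s{i:03d}" for i in range(self.weights.shape[0])]
        if not self.archetype_names:
            self.archetype_names = [f"archetype{t + 1}" for t in range(k)]

    @property
    def k(self) -> int:
        return self.archetype_profiles.shape[0]

    @property
    def n_samples(self) -> int:
        return self.weights.shape[0]


@dataclass
class ReferenceTruth:
    """Ground truth for a labeled single-cell reference and pseudo-bulk set."""

    cell_profiles: np.ndarray  # C x G
    cell_type_labels: list[str]
    embedding: np.ndarray  # C x 2
    bulk_composition: np.ndarray  # n x T, rows sum to 1
    type_names: list[str]
    seed: int = 0
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cell_profiles = np.asarray(self.cell_profiles, dtype=float)
        self.embedding = np.asarray(self.embedding, dtype=float)
        self.bulk_composition = np.asarray(self.bulk_composition, dtype=float)
        n_cells = self.cell_profiles.shape[0]
        if len(self.cell_type_labels) != n_cells:
            raise ValueError("one label per cell required")
        if self.embedding.shape != (n_cells, 2):
            raise ValueError("embedding must be C x 2")
        counts = pd.Series(self.cell_type_labels).value_counts()
        for t in self.type_names:
            if counts.get(t, 0) == 0:
                raise ValueError(f"cell type {t!r} has no cells")
        if self.bulk_composition.shape[1] != len(self.type_names):
            raise ValueError("bulk_composition must have one column per type")
        if (self.bulk_composition < 0).any() or not np.allclose(
            self.bulk_composition.sum(axis=1), 1.0, atol=1e-12
        ):
            raise ValueError("bulk_composition rows must be convex weights")
        if not self.gene_ids:
            self.gene_ids = [f"g{i:04d}" for i in range(self.cell_profiles.shape[1])]

    def type_mean_profiles(self) -> np.ndarray:
        """T x G matrix of per-type mean cell profiles."""
        labels = np.asarray(self.cell_type_labels)
        return np.vstack(
            [self.cell_profiles[labels == t].mean(axis=0) for t in self.type_names]
        )


def make_mixture_truth(
    n_samples: int = 500,
    n_genes: int = 500,
    k: int = 3,
    alpha: tuple[float, ...] | np.ndarray = (1.0, 1.0, 1.0),
    marker_block_size: int = 25,
    depth: float = 1e4,
    noise_model: str = "poisson",
    dispersion: float = 0.3,
    seed: int = 0,
) -> MixtureTruth:
    """Draw archetype profiles and Dirichlet mixture weights.

    Profiles are sparse gamma variates with an exclusive marker block per
    archetype (genes expressed in that archetype only), then rescaled so each
    profile sums to ``depth`` — the expected library size of every sample
    under any convex mixture.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (k,):
        raise ValueError("alpha must have length k")
    if (alpha <= 0).any():
        raise ValueError("Dirichlet concentration parameters must be positive")
    if marker_block_size * k > n_genes:
        raise ValueError("marker blocks exceed the gene universe")
    rng = np.random.default_rng(seed)
    profiles = rng.gamma(shape=0.4, scale=1.0, size=(k, n_genes))
    # sparsify the background so blocks dominate their archetype
    profiles[rng.random(size=profiles.shape) < 0.3] = 0.0

    marker_blocks: dict[str, list[str]] = {}
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    names = [f"archetype{t + 1}" for t in range(k)]
    for t in range(k):
        block = slice(t * marker_block_size, (t + 1) * marker_block_size)
        profiles[:, block] = 0.0
        profiles[t, block] = rng.gamma(shape=5.0, scale=2.0, size=marker_block_size) + 5.0
        marker_blocks[names[t]] = gene_ids[block]

    profiles *= depth / profiles.sum(axis=1, keepdims=True)
    weights = rng.dirichlet(alpha, size=n_samples)
    return MixtureTruth(
        archetype_profiles=profiles,
        weights=weights,
        dirichlet_alpha=alpha,
        noise_model=noise_model,
        dispersion=dispersion,
        seed=seed,
        gene_ids=gene_ids,
        archetype_names=names,
        marker_blocks=marker_blocks,
    )


def simulate_bulk_cohort(truth: MixtureTruth) -> tuple[ExpressionMatrix, MixtureTruth]:
    """Realize the bulk cohort described by ``truth``.

    Sample i has expectation sum_t weights[i, t] * archetype_profiles[t, :];
    the declared noise model is applied on top. The same truth object is
    returned so callers keep the realized weights next to the data.
    """
    expected = truth.weights @ truth.archetype_profiles  # n x G
    rng = np.random.default_rng([truth.seed, 7919])
    if truth.noise_model == "none":
        observed = expected
    elif truth.noise_model == "poisson":
        observed = rng.poisson(expected).astype(float)
    else:  # lognormal, mean-preserving multiplicative noise
        sigma = float(truth.dispersion)
        factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=expected.shape)
        observed = expected * factors
    frame = pd.DataFrame(observed.T, index=truth.gene_ids, columns=truth.sample_ids)
    return ExpressionMatrix(frame), truth


def make_reference_truth(
    n_types: int = 3,
    cells_per_type: int = 100,
    n_genes: int = 300,
    n_bulk: int = 30,
    alpha: tuple[float, ...] | None = None,
    orthogonal_support: bool = True,
    depth: float = 1e4,
    cell_cv: float = 0.3,
    seed: int = 0,
) -> ReferenceTruth:
    """Build a labeled reference with a clustered 2D embedding plus bulk truth.

    With ``orthogonal_support`` each type expresses a disjoint gene block
    (the noiseless deconvolution problem is then exactly solvable); otherwise
    type profiles share background expression. The embedding places each type
    as a Gaussian cluster around a distinct center — all the deconvolution
    smoothing step needs is that same-type cells are mutual neighbors.
    """
    if alpha is None:
        alpha = tuple(1.0 for _ in range(n_types))
    rng = np.random.default_rng(seed)
    type_names = [f"type{t + 1}" for t in range(n_types)]

    means = np.zeros((n_types, n_genes))
    if orthogonal_support:
        block = n_genes // n_types
        for t in range(n_types):
            sl = slice(t * block, (t + 1) * block)
            means[t, sl] = rng.gamma(shape=2.0, scale=1.0, size=block) + 0.5
    else:
        means = rng.gamma(shape=1.0, scale=1.0, size=(n_types, n_genes)) + 0.05
    means *= depth / means.sum(axis=1, keepdims=True)

    shape = 1.0 / cell_cv**2
    profiles = np.vstack(
        [
            means[t] * rng.gamma(shape=shape, scale=1.0 / shape, size=(cells_per_type, n_genes))
            for t in range(n_types)
        ]
    )
    labels = [type_names[t] for t in range(n_types) for _ in range(cells_per_type)]

    angles = 2.0 * np.pi * np.arange(n_types) / n_types
    centers = 10.0 * np.column_stack([np.cos(angles), np.sin(angles)])
    embedding = np.vstack(
        [centers[t] + rng.normal(scale=1.0, size=(cells_per_type, 2)) for t in range(n_types)]
    )

    composition = rng.dirichlet(np.asarray(alpha, dtype=float), size=n_bulk)
    return ReferenceTruth(
        cell_profiles=profiles,
        cell_type_labels=labels,
        embedding=embedding,
        bulk_composition=composition,
        type_names=type_names,
        seed=seed,
    )


def make_linked_reference(
    truth: MixtureTruth,
    cells_per_type: int = 100,
    cell_cv: float = 0.3,
    seed: int | None = None,
) -> ReferenceTruth:
    """Reference whose cell types ARE the cohort's archetypes.

    Type-t cells jitter around archetype profile t and the bulk composition
    equals the cohort's planted mixture weights, so a single ground truth
    drives the archetype, topic, and deconvolution views of the same cohort
    — the setting for end-to-end consistency checks.
    """
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng([seed, 65537])
    k, n_genes = truth.archetype_profiles.shape
    shape = 1.0 / cell_cv**2
    profiles = np.vstack(
        [
            truth.archetype_profiles[t]
            * rng.gamma(shape=shape, scale=1.0 / shape, size=(cells_per_type, n_genes))
            for t in range(k)
        ]
    )
    labels = [truth.archetype_names[t] for t in range(k) for _ in range(cells_per_type)]
    angles = 2.0 * np.pi * np.arange(k) / k
    centers = 10.0 * np.column_stack([np.cos(angles), np.sin(angles)])
    embedding = np.vstack(
        [centers[t] + rng.normal(scale=1.0, size=(cells_per_type, 2)) for t in range(k)]
    )
    return ReferenceTruth(
        cell_profiles=profiles,
        cell_type_labels=labels,
        embedding=embedding,
        bulk_composition=truth.weights.copy(),
        type_names=list(truth.archetype_names),
        seed=seed,
        gene_ids=list(truth.gene_ids),
    )


def simulate_reference_and_bulk(
    truth: ReferenceTruth,
    cells_per_draw: int | None = None,
    noise_model: str = "none",
) -> tuple[ExpressionMatrix, pd.Series, pd.DataFrame, ExpressionMatrix]:
    """Emit (reference matrix, labels, embedding, bulk matrix).

    Bulk sample i has expectation sum_T composition[i, T] * (type-T mean
    profile). With ``cells_per_draw`` set, each bulk sample instead averages
    that many reference cells drawn with type probabilities equal to the
    composition row (adds realistic cell-sampling noise). Poisson observation
    noise is available on top.
    """
    if noise_model not in ("none", "poisson"):
        raise ValueError("noise_model must be 'none' or 'poisson'")
    rng = np.random.default_rng([truth.seed, 104729])
    labels = np.asarray(truth.cell_type_labels)
    type_means = truth.type_mean_profiles()

    n_bulk = truth.bulk_composition.shape[0]
    if cells_per_draw is None:
        expected = truth.bulk_composition @ type_means
    else:
        expected = np.zeros((n_bulk, truth.cell_profiles.shape[1]))
        for i in range(n_bulk):
            type_idx = rng.choice(
                len(truth.type_names), size=cells_per_draw, p=truth.bulk_composition[i]
            )
            chosen = [
                rng.choice(np.flatnonzero(labels == truth.type_names[t])) for t in type_idx
            ]
            expected[i] = truth.cell_profiles[chosen].mean(axis=0)
    bulk_values = rng.poisson(expected).astype(float) if noise_model == "poisson" else expected

    cell_ids = [f"c{i:04d}" for i in range(truth.cell_profiles.shape[0])]
    sample_ids = [f"b{i:03d}" for i in range(n_bulk)]
    reference = ExpressionMatrix(
        pd.DataFrame(truth.cell_profiles.T, index=truth.gene_ids, columns=cell_ids)
    )
    bulk = ExpressionMatrix(
        pd.DataFrame(bulk_values.T, index=truth.gene_ids, columns=sample_ids)
    )
    labels_series = pd.Series(truth.cell_type_labels, index=cell_ids, name="cell_type")
    embedding_frame = pd.DataFrame(truth.embedding, index=cell_ids, columns=["dim1", "dim2"])
    return reference, labels_series, embedding_frame, bulk


def write_cohort(out_dir, matrix: ExpressionMatrix, truth: MixtureTruth) -> dict[str, str]:
    """Write a mixture cohort to disk: expression TSV, marker GMT, truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": str(out / "expression.tsv"),
        "markers": str(out / "true_markers.gmt"),
        "truth": str(out / "truth.json"),
    }
    matrix.to_tsv(paths["expression"])
    from .io import write_gmt

    write_gmt({name: genes for name, genes in truth.marker_blocks.items()}, paths["markers"])
    payload = {
        "seed": truth.seed,
        "noise_model": truth.noise_model,
        "dirichlet_alpha": truth.dirichlet_alpha.tolist(),
        "weights": truth.weights.tolist(),
        "sample_ids": truth.sample_ids,
        "archetype_names": truth.archetype_names,
        "archetype_profiles": truth.archetype_profiles.tolist(),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh, indent=1)
    return paths
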