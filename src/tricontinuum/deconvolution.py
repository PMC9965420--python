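"""Cell-population mapping: bulk deconvolution against a single-cell reference.

The procedure estimates, for every bulk sample, the abundance of each
*individual reference cell* rather than only of discrete cell types, so the
result can resolve continuous cell states. It has two steps:

1. **Deconvolution** — repeated linear support vector regression. Each of N
   runs draws ``model_size`` reference cells uniformly without replacement
   and expresses the bulk profile as a weighted combination of their
   (per-gene standardized) profiles via linear nu-SVR; a cell's abundance is
   the mean of its regression coefficients over the runs in which it was
   drawn. N is chosen so that every cell is drawn at least ``min_selection``
   times — here as a hard guarantee (deficit-aware top-up runs), not just in
   expectation.

2. **Extrapolation** — smoothing over the cell-state embedding: each cell's
   abundance is averaged over its ``neighborhood_size`` nearest neighbors
   (itself included) in the provided 2D embedding.

Cell-type proportions are obtained by clipping the smoothed abundances at
zero, summing per type, and normalizing each sample's row to 1.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import NuSVR

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["ReferenceAtlas", "DeconvolutionResult", "cpm_deconvolve", "quantify_types"]


@dataclass
class ReferenceAtlas:
    """Single-cell reference: profiles (C x G), labels, 2D cell-state embedding."""

    profiles: np.ndarray
    labels: list[str]
    embedding: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        self.embedding = np.asarray(self.embedding, dtype=float)
        C = self.profiles.shape[0]
        if len(self.labels) != C or self.embedding.shape != (C, 2):
            raise ValueError("labels and embedding must match the number of cells")
        if len(self.gene_ids) != self.profiles.shape[1]:
            raise ValueError("gene_ids must match profile columns")
        if not self.cell_ids:
            self.cell_ids = [f"c{i:04d}" for i in range(C)]

    @classmethod
    def from_frames(cls, reference: ExpressionMatrix, labels: pd.Series,
                    embedding: pd.DataFrame) -> "ReferenceAtlas":
        cells = reference.sample_ids
        labels = labels.reindex(cells)
        if labels.isna().any():
            raise ValueError("labels missing for some reference cells")
        emb = embedding.reindex(cells)
        if emb.isna().any().any():
            raise ValueError("embedding missing for some reference cells")
        return cls(
            profiles=reference.values.T,
            labels=labels.astype(str).tolist(),
            embedding=emb.to_numpy(),
            gene_ids=reference.gene_ids,
            cell_ids=cells,
        )

    @property
    def n_cells(self) -> int:
        return self.profiles.shape[0]


@dataclass
class DeconvolutionResult:
    cell_abundance: pd.DataFrame  # samples x cells, smoothed
    raw_abundance: pd.DataFrame  # samples x cells, pre-smoothing
    type_proportions: pd.DataFrame  # samples x types, rows sum to 1
    runs: int
    params: dict


def _plan_draws(n_cells: int, model_size: int, min_selection: int,
                rng: np.random.Generator) -> list[np.ndarray]:
    """Random model_size-subsets with a hard per-cell minimum sampling count.

    The base number of runs is ceil(min_selection * C / model_size); if any
    cell is still under-sampled, extra runs are added that include the
    deficient cells first (remainder filled uniformly), so the guarantee
    holds after finitely many top-ups.
    """
    n_runs = math.ceil(min_selection * n_cells / model_size)
    counts = np.zeros(n_cells, dtype=int)
    draws: list[np.ndarray] = []
    for _ in range(n_runs):
        sub = rng.choice(n_cells, size=model_size, replace=False)
        counts[sub] += 1
        draws.append(np.sort(sub))
    while (counts < min_selection).any():
        deficient = np.flatnonzero(counts < min_selection)
        take = deficient[np.argsort(counts[deficient])][:model_size]
        if len(take) < model_size:
            others = np.setdiff1d(np.arange(n_cells), take)
            fill = rng.choice(others, size=model_size - len(take), replace=False)
            sub = np.concatenate([take, fill])
        else:
            sub = take
        counts[sub] += 1
        draws.append(np.sort(sub))
    return draws


def cpm_deconvolve(
    bulk: ExpressionMatrix,
    ref: ReferenceAtlas,
    model_size: int = 50,
    min_selection: int = 5,
    neighborhood_size: int = 10,
    seed: int = 0,
    nu: float = 0.5,
    svr_C: float = 1.0,
    svr_tol: float = 1e-2,
    svr_max_iter: int = 5000,
) -> DeconvolutionResult:
    """Run the two-step cell-population-mapping procedure.

    Genes are intersected between bulk and reference; both matrices are then
    globally standardized by the reference's overall mean and SD for
    regression scale stability (bulk and reference are expected to be on a
    comparable normalization, e.g. equal totals). Zero-variance bulk samples
    yield a zero abundance vector with a warning.
    """
    if ref.n_cells < model_size:
        raise ValueError(f"reference has {ref.n_cells} cells < model_size={model_size}")
    common = [g for g in bulk.gene_ids if g in set(ref.gene_ids)]
    if len(common) < 2:
        raise ValueError("bulk and reference share too few genes")
    ref_idx = pd.Index(ref.gene_ids).get_indexer(common)
    R = ref.profiles[:, ref_idx]  # C x G'
    B = bulk.data.loc[common].to_numpy().T  # n x G'

    # Global (whole-matrix) standardization by reference statistics: brings both
    # matrices to O(1) scale for the SVR without recentering individual genes —
    # per-gene centering pushes low-abundance cell types to negative
    # coefficients that the later clip step would silently discard.
    mu = float(R.mean())
    sd = float(R.std())
    if sd == 0:
        raise ValueError("reference matrix is constant")
    Rz = (R - mu) / sd
    Bz = (B - mu) / sd

    rng = np.random.default_rng(seed)
    draws = _plan_draws(ref.n_cells, model_size, min_selection, rng)

    n_samples = Bz.shape[0]
    coef_sum = np.zeros((n_samples, ref.n_cells))
    coef_cnt = np.zeros(ref.n_cells, dtype=int)
    zero_variance = Bz.std(axis=1) == 0
    if zero_variance.any():
        warnings.warn(f"{int(zero_variance.sum())} bulk samples have zero variance; "
                      "abundances set to 0", UserWarning, stacklevel=2)
    with warnings.catch_warnings():
        # the capped iteration count is a deliberate speed/precision trade
        warnings.simplefilter("ignore", ConvergenceWarning)
        for sub in draws:
            X = Rz[sub].T  # genes x model_size
            coef_cnt[sub] += 1
            for j in range(n_samples):
                if zero_variance[j]:
                    continue
                svr = NuSVR(kernel="linear", nu=nu, C=svr_C, tol=svr_tol,
                            max_iter=svr_max_iter)
                svr.fit(X, Bz[j])
                coef_sum[j, sub] += svr.coef_.ravel()
    raw = coef_sum / coef_cnt  # every count >= min_selection >= 1

    nn = NearestNeighbors(n_neighbors=min(neighborhood_size, ref.n_cells))
    nn.fit(ref.embedding)
    _, neighbor_idx = nn.kneighbors(ref.embedding)
    smoothed = raw[:, neighbor_idx].mean(axis=2)

    sample_ids = bulk.sample_ids
    raw_df = pd.DataFrame(raw, index=sample_ids, columns=ref.cell_ids)
    smooth_df = pd.DataFrame(smoothed, index=sample_ids, columns=ref.cell_ids)
    props = quantify_types(smoothed, ref.labels, sample_ids=sample_ids)
    return DeconvolutionResult(
        cell_abundance=smooth_df,
        raw_abundance=raw_df,
        type_proportions=props,
        runs=len(draws),
        params=dict(model_size=model_size, min_selection=min_selection,
                    neighborhood_size=neighborhood_size, nu=nu, svr_C=svr_C, seed=seed,
                    min_sampling_count=int(coef_cnt.min())),
    )


def quantify_types(abundance, labels: list[str], sample_ids: list[str] | None = None
                   ) -> pd.DataFrame:
    """Clip-at-zero smoothed abundances, sum per cell type, normalize rows to 1.

    An all-zero row (no positive abundance for any cell) falls back to
    uniform proportions with a warning.
    """
    if isinstance(abundance, pd.DataFrame):
        sample_ids = sample_ids or abundance.index.tolist()
        abundance = abundance.to_numpy()
    abundance = np.asarray(abundance, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != abundance.shape[1]:
        raise ValueError("labels must cover all cells")
    types = sorted(set(labels.tolist()))
    clipped = np.clip(abundance, 0.0, None)
    sums = np.column_stack([clipped[:, labels == t].sum(axis=1) for t in types])
    totals = sums.sum(axis=1, keepdims=True)
    empty = totals.ravel() == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} samples have all-zero abundance; "
                      "uniform proportions reported", UserWarning, stacklevel=2)
    props = np.where(empty[:, None], 1.0 / len(types),
                     sums / np.where(totals == 0, 1.0, totals))
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(abundance.shape[0])]
    return pd.DataFrame(props, index=sample_ids, columns=types)
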