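"""Grade-of-membership (topic) model for bulk expression, via Poisson NMF.

Each sample is modeled as a mixture of k latent "topics": a topic is a
probability distribution over genes (factors F, columns summing to 1) and a
sample is a point on the k-simplex of topic proportions (loadings L, rows
summing to 1). Under the Poisson/multinomial equivalence this is the
maximum-likelihood counterpart of latent Dirichlet allocation for counts:
fitting maximizes the Poisson log-likelihood of X ~ Poisson(W H) over
non-negative factor matrices, then rescales (W, H) to the (F, L)
simplex parametrization.

Optimization follows the classic two-phase schedule: multiplicative EM
updates (fast early progress) followed by cyclic coordinate descent with a
per-row Newton step and monotonicity backtracking (sharp final convergence).
Defaults are 100 EM + 100 CD iterations.

Per-gene topic *posteriors* invert F by Bayes' rule,
``p(topic|gene) = F[g,t] p(t) / sum_s F[g,s] p(s)``, with a uniform prior by
default (1/3 per topic for the canonical k=3 fit); genes with posterior above
0.5 for some topic form that topic's characteristic gene list.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TopicFit",
    "PosteriorTable",
    "fit_topics",
    "topic_posteriors",
    "topic_gene_lists",
    "topic_de",
]

_FLOOR = 1e-300


@dataclass
class TopicFit:
    L: np.ndarray  # n x k, rows on the simplex (topic proportions per sample)
    F: np.ndarray  # G x k, columns on the simplex (p(gene|topic))
    k: int
    loglik_trace: np.ndarray
    seed: int
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.L < 0).any() or (self.F < 0).any():
            raise ValueError("loadings/factors must be non-negative")
        if not np.allclose(self.L.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("L rows must sum to 1")
        if not np.allclose(self.F.sum(axis=0), 1.0, atol=1e-8):
            raise ValueError("F columns must sum to 1")


@dataclass
class PosteriorTable:
    posterior: np.ndarray  # G x k, rows sum to 1
    prior: np.ndarray
    gene_ids: list[str] = field(default_factory=list)


def _poisson_loglik(X: np.ndarray, P: np.ndarray, const: float) -> float:
    return float((X * np.log(np.maximum(P, _FLOOR)) - P).sum() + const)


def _em_update(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> None:
    """One multiplicative EM iteration (monotone in the Poisson likelihood)."""
    P = np.maximum(W @ H, _FLOOR)
    W *= (X / P) @ H.T / np.maximum(H.sum(axis=1), _FLOOR)
    P = np.maximum(W @ H, _FLOOR)
    H *= W.T @ (X / P) / np.maximum(W.sum(axis=0)[:, None], _FLOOR)


def _cd_update_factor(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> None:
    """Cyclic coordinate descent over columns of W (rows are independent).

    For each topic column, a Newton step on the per-row Poisson objective is
    taken simultaneously for all genes, followed by per-row halving until the
    objective has not decreased — the likelihood trace is monotone by
    construction.
    """
    P = W @ H
    k = W.shape[1]
    for t in range(k):
        h = H[t]
        hsum = h.sum()
        w_old = W[:, t].copy()
        rest = np.maximum(P - np.outer(w_old, h), 0.0)

        denom = np.maximum(rest + np.outer(w_old, h), _FLOOR)
        grad = hsum - (X * h / denom).sum(axis=1)
        hess = np.maximum((X * h**2 / denom**2).sum(axis=1), _FLOOR)
        w_new = np.maximum(w_old - grad / hess, 1e-15)

        def row_obj(w: np.ndarray) -> np.ndarray:
            Pn = rest + np.outer(w, h)
            return (X * np.log(np.maximum(Pn, _FLOOR)) - Pn).sum(axis=1)

        f_old = row_obj(w_old)
        for _ in range(25):
            worse = row_obj(w_new) < f_old - 1e-12
            if not worse.any():
                break
            w_new[worse] = 0.5 * (w_new[worse] + w_old[worse])
        else:
            w_new = w_old
        W[:, t] = w_new
        P = rest + np.outer(w_new, h)


def _as_counts(m: ExpressionMatrix, scale_total: float) -> np.ndarray:
    """Counts for the Poisson likelihood.

    Integer-valued input is used as-is; continuous input (e.g. microarray
    intensities) is rescaled to a fixed total per sample and rounded, since
    the factorization's likelihood is defined on counts.
    """
    values = m.values
    if np.allclose(values, np.round(values), atol=1e-9):
        return np.round(values)
    totals = values.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("sample with zero total expression")
    logger.info("fit_topics: non-integer input rescaled to %g per sample and rounded",
                scale_total)
    return np.round(values / totals * scale_total)


def fit_topics(
    m: ExpressionMatrix,
    k: int,
    em_iters: int = 100,
    cd_iters: int = 100,
    seed: int = 0,
    n_restarts: int = 3,
    scale_total: float = 1e4,
) -> TopicFit:
    """Fit the k-topic model by Poisson NMF: EM warm-up then CD refinement.

    Initialization is uniform-random positive matrices drawn from ``seed``;
    ``n_restarts`` independent starts are run and the best final likelihood
    kept. All-zero gene rows are dropped with a warning (their factors are
    reinserted as zeros so output shapes match the input).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X_full = _as_counts(m, scale_total)
    n_genes, n = X_full.shape
    if k >= min(n_genes, n) and k != 1:
        raise ValueError(f"k={k} must be below min(G, n)={min(n_genes, n)}")
    keep = X_full.sum(axis=1) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} all-zero gene rows", UserWarning,
                      stacklevel=2)
    X = X_full[keep]
    const = float(-gammaln(X + 1.0).sum())
    mean_val = X.mean()

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, list[float]] | None = None
    for _ in range(max(1, n_restarts)):
        W = rng.uniform(0.5, 1.5, size=(X.shape[0], k)) * np.sqrt(mean_val / k)
        H = rng.uniform(0.5, 1.5, size=(k, n)) * np.sqrt(mean_val / k)
        trace: list[float] = [_poisson_loglik(X, W @ H, const)]
        for _ in range(em_iters):
            _em_update(X, W, H)
            trace.append(_poisson_loglik(X, W @ H, const))
        for _ in range(cd_iters):
            _cd_update_factor(X, W, H)
            Wt, Ht = H.T.copy(), W.T.copy()
            _cd_update_factor(X.T, Wt, Ht)
            W, H = Ht.T, Wt.T
            trace.append(_poisson_loglik(X, W @ H, const))
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], W, H, trace)

    _, W, H, trace = best
    col = np.maximum(W.sum(axis=0), _FLOOR)
    F_kept = W / col
    L_raw = H.T * col  # n x k
    L = L_raw / np.maximum(L_raw.sum(axis=1, keepdims=True), _FLOOR)

    F = np.zeros((n_genes, k))
    F[keep] = F_kept
    return TopicFit(
        L=L,
        F=F,
        k=k,
        loglik_trace=np.asarray(trace),
        seed=seed,
        gene_ids=m.gene_ids,
        sample_ids=m.sample_ids,
    )


def topic_posteriors(fit: TopicFit, prior="uniform") -> PosteriorTable:
    """Bayes-invert the factors: posterior[g, t] = F[g,t] p(t) / sum_s F[g,s] p(s).

    ``prior`` is a k-vector summing to 1, or ``"uniform"`` for 1/k per topic.
    Genes with zero likelihood under every topic get the prior itself (with a
    warning) rather than an undefined row.
    """
    if isinstance(prior, str):
        if prior != "uniform":
            raise ValueError("prior must be a vector or 'uniform'")
        p = np.full(fit.k, 1.0 / fit.k)
    else:
        p = np.asarray(prior, dtype=float)
        if p.shape != (fit.k,):
            raise ValueError("prior must have length k")
        if (p < 0).any():
            raise ValueError("prior must be non-negative")
        if not np.isclose(p.sum(), 1.0, atol=1e-8):
            raise ValueError("prior must sum to 1")
    num = fit.F * p
    denom = num.sum(axis=1, keepdims=True)
    zero = denom.ravel() == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} genes have zero likelihood under all topics; "
                      "posterior set to the prior", UserWarning, stacklevel=2)
    posterior = np.where(zero[:, None], p, num / np.where(denom == 0, 1.0, denom))
    return PosteriorTable(posterior=posterior, prior=p, gene_ids=fit.gene_ids)


def topic_gene_lists(post: PosteriorTable, cutoff: float = 0.5) -> dict[str, list[str]]:
    """Genes whose posterior for a topic exceeds ``cutoff`` (> 0.5 => unique lists)."""
    k = post.posterior.shape[1]
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must be in (0, 1]")
    gene_ids = post.gene_ids or [f"g{i}" for i in range(post.posterior.shape[0])]
    return {
        f"topic{t + 1}": [g for g, v in zip(gene_ids, post.posterior[:, t]) if v > cutoff]
        for t in range(k)
    }


def topic_de(fit: TopicFit, pseudocount: float = 1e-10) -> np.ndarray:
    """Pairwise log2 fold changes between topics.

    Returns lfc with shape (G, k, k): ``lfc[g, t, s] = log2((F[g,t]+eps) /
    (F[g,s]+eps))``; antisymmetric in (t, s) by construction.
    """
    logF = np.log2(fit.F + pseudocount)
    return logF[:, :, None] - logF[:, None, :]
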