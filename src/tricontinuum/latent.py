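"""PCA embedding and Pareto-style archetype inference.

Samples are embedded by centered-SVD PCA; the cohort is then modeled as a
continuum bounded by k "archetypes" — the vertices of the minimum-volume
simplex enclosing the points in the d = k-1 dimensional latent space (a
triangle for k=3 in the PC1-PC2 plane). Containment is enforced softly, in
the spirit of the SISAL simplex-identification algorithm from hyperspectral
unmixing: the objective trades simplex volume against a hinge penalty on
points left outside, so a few noisy points cannot inflate the fit.

Each vertex is back-projected through the PCA loadings to an "idealized"
expression profile, from which archetype marker genes (over-expressed
relative to *both* other archetypes) are derived and scored against a
user-supplied marker-set library to name the archetypes.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import ConvexHull
from scipy.stats import hypergeom
from sklearn.decomposition import PCA

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "LatentEmbedding",
    "ArchetypeSet",
    "pca_embed",
    "fit_simplex",
    "backproject",
    "archetype_markers",
    "score_markers",
]


@dataclass
class LatentEmbedding:
    """PCA coordinates plus everything needed to back-project to gene space."""

    coords: np.ndarray  # n x d
    loadings: np.ndarray  # G x d
    center: np.ndarray  # G
    explained_variance_ratio: np.ndarray  # d
    sample_ids: list[str]
    gene_ids: list[str]

    def reconstruct(self) -> np.ndarray:
        """Rank-d approximation of the input (n x G)."""
        return self.center + self.coords @ self.loadings.T


@dataclass
class ArchetypeSet:
    """Vertices of the fitted enclosing simplex and their gene-space profiles."""

    vertices: np.ndarray  # k x d
    gene_profiles: np.ndarray  # k x G
    labels: list[str]
    fit_diagnostics: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.vertices.shape[0]


def pca_embed(m: ExpressionMatrix, d: int) -> LatentEmbedding:
    """Centered-SVD PCA of samples; deterministic sign convention.

    The sign of each component is fixed so that its largest-magnitude gene
    loading is positive, making embeddings reproducible across runs and
    platforms.
    """
    X = m.values.T  # n x G
    n, n_genes = X.shape
    if d > min(n_genes, n - 1):
        raise ValueError(f"d={d} exceeds min(G, n-1) = {min(n_genes, n - 1)}")
    pca = PCA(n_components=d, svd_solver="full")
    coords = pca.fit_transform(X)
    loadings = pca.components_.T  # G x d
    for j in range(d):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            coords[:, j] *= -1.0
    return LatentEmbedding(
        coords=coords,
        loadings=loadings,
        center=pca.mean_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        sample_ids=m.sample_ids,
        gene_ids=m.gene_ids,
    )


# ---------------------------------------------------------------------------
# minimum-volume enclosing simplex
# ---------------------------------------------------------------------------


def _canonical_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Center/rotation/scale making the fit equivariant under rigid motions.

    Points are centered, scaled to unit RMS radius, and rotated onto their own
    principal axes (sign fixed by the largest-|projection| sample), so that
    rotating or rescaling the input data transforms the fitted vertices
    exactly — independent of optimizer implementation details.
    """
    center = coords.mean(axis=0)
    Xc = coords - center
    scale = float(np.sqrt((Xc**2).sum(axis=1).mean()))
    if scale == 0:
        raise ValueError("degenerate data: all points identical")
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    R = Vt.T
    proj = Xc @ R
    for j in range(R.shape[1]):
        i = int(np.argmax(np.abs(proj[:, j])))
        if proj[i, j] < 0:
            R[:, j] *= -1.0
    return center, R, scale


def _simplex_volume(vertices: np.ndarray) -> float:
    k, d = vertices.shape
    edges = vertices[1:] - vertices[0]
    return abs(np.linalg.det(edges)) / math.factorial(d)


def _barycentric(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of points w.r.t. a k-vertex simplex in k-1 dims."""
    Mh = np.hstack([vertices, np.ones((vertices.shape[0], 1))])  # k x k
    Yh = np.hstack([points, np.ones((points.shape[0], 1))])
    return np.linalg.solve(Mh.T, Yh.T).T


def _initial_simplex(Y: np.ndarray, k: int) -> np.ndarray:
    """Max-volume simplex over convex-hull extreme points, slightly inflated."""
    d = Y.shape[1]
    if d == 1:
        verts = np.array([[Y.min()], [Y.max()]])
    else:
        hull_idx = np.unique(ConvexHull(Y).vertices)
        candidates = Y[hull_idx]
        if len(candidates) <= 14:
            best, best_vol = None, -1.0
            for combo in itertools.combinations(range(len(candidates)), k):
                vol = _simplex_volume(candidates[list(combo)])
                if vol > best_vol:
                    best_vol, best = vol, candidates[list(combo)]
            verts = best.copy()
        else:
            # greedy: farthest pair, then repeatedly add the volume-maximizing point
            d2 = ((candidates[:, None, :] - candidates[None, :, :]) ** 2).sum(-1)
            i, j = np.unravel_index(np.argmax(d2), d2.shape)
            chosen = [i, j]
            while len(chosen) < k:
                vols = [
                    _simplex_volume(candidates[chosen + [c]])
                    if c not in chosen
                    else -1.0
                    for c in range(len(candidates))
                ]
                chosen.append(int(np.argmax(vols)))
            verts = candidates[chosen].copy()
    centroid = verts.mean(axis=0)
    return centroid + 1.15 * (verts - centroid)


def _constrained_polish(Y: np.ndarray, V0: np.ndarray, soft_objective) -> np.ndarray:
    """Sharpen the soft optimum with a smooth constrained solve.

    Nelder-Mead localizes the hinge objective's minimum only coarsely (the
    optimum sits at a non-smooth kink where containment constraints become
    active). Freezing each point's current containment deficit as allowed
    slack turns the problem into a smooth one — minimize volume subject to
    ``barycentric >= -slack`` — which SLSQP solves to high precision. The
    polish is kept only if it does not worsen the original soft objective.
    """
    k, d = V0.shape
    B0 = _barycentric(Y, V0)
    per_point_min = B0.min(axis=1)
    slack = np.clip(-per_point_min, 0.0, None)
    sel = np.flatnonzero(per_point_min < 0.1)  # boundary region only
    if sel.size == 0:
        return V0
    s = slack[sel]
    Ysel = Y[sel]

    def constraints(flat: np.ndarray) -> np.ndarray:
        return (_barycentric(Ysel, flat.reshape(k, d)) + s[:, None] + 1e-12).ravel()

    res = minimize(
        lambda flat: _simplex_volume(flat.reshape(k, d)),
        V0.ravel(),
        method="SLSQP",
        constraints=[dict(type="ineq", fun=constraints)],
        options=dict(maxiter=500, ftol=1e-14),
    )
    V1 = res.x.reshape(k, d)
    if res.status == 0 and soft_objective(res.x) <= soft_objective(V0.ravel()) + 1e-12:
        return V1
    return V0


def fit_simplex(
    emb: LatentEmbedding,
    k: int,
    tolerance: float = 1e-12,
    seed: int = 0,
    penalty_weight: float = 10.0,
    n_restarts: int = 3,
) -> ArchetypeSet:
    """Fit the minimum-volume k-simplex softly enclosing the embedded samples.

    Minimizes ``volume + penalty_weight * volume0 * sum(hinge(-barycentric))``
    over vertex positions, where the hinge term sums the barycentric deficit
    of every point falling outside the current simplex and ``volume0`` is the
    volume of the convex-hull-based initial simplex (so the penalty is on the
    problem's own scale). Requires k = d+1 (a full-dimensional simplex:
    triangle in 2D, tetrahedron in 3D).

    Deterministic given ``seed``; ``n_restarts`` jittered starts guard
    against local minima. Vertices are returned in angular order around
    their centroid (labels are attached later by marker scoring).
    """
    coords = np.asarray(emb.coords, dtype=float)
    n, d = coords.shape
    if k != d + 1:
        raise ValueError(f"k must equal d+1 for a full-dimensional simplex (k={k}, d={d})")
    if n < k:
        raise ValueError("need at least k samples")
    sv = np.linalg.svd(coords - coords.mean(axis=0), compute_uv=False)
    if sv[d - 1] <= 1e-9 * max(sv[0], 1e-30):
        raise ValueError(f"data rank < {d}; lower the embedding dimension d")

    center, R, scale = _canonical_frame(coords)
    Y = (coords - center) @ R / scale

    init = _initial_simplex(Y, k)
    vol0 = max(_simplex_volume(init), 1e-12)
    lam = penalty_weight * vol0

    def objective(flat: np.ndarray) -> float:
        V = flat.reshape(k, d)
        Mh = np.hstack([V, np.ones((k, 1))])
        det = np.linalg.det(Mh)
        if abs(det) < 1e-12:
            return 1e9
        B = _barycentric(Y, V)
        hinge = np.clip(-B, 0.0, None).sum()
        return abs(det) / math.factorial(d) + lam * hinge

    rng = np.random.default_rng(seed)
    starts = [init]
    spread = np.sqrt((init.var(axis=0)).mean())
    for _ in range(max(0, n_restarts - 1)):
        starts.append(init + rng.normal(scale=0.05 * spread, size=init.shape))

    best_res = None
    for start in starts:
        res = minimize(
            objective,
            start.ravel(),
            method="Nelder-Mead",
            options=dict(maxiter=50000, maxfev=50000, xatol=tolerance, fatol=tolerance,
                         adaptive=True),
        )
        # polish: restart Nelder-Mead from its own solution to escape stagnation
        res = minimize(
            objective,
            res.x,
            method="Nelder-Mead",
            options=dict(maxiter=50000, maxfev=50000, xatol=tolerance, fatol=tolerance,
                         adaptive=True),
        )
        if best_res is None or res.fun < best_res.fun:
            best_res = res

    V = best_res.x.reshape(k, d)
    V = _constrained_polish(Y, V, objective)
    B = _barycentric(Y, V)
    contained = float((B >= -1e-9).all(axis=1).mean())
    volume_canonical = _simplex_volume(V)

    vertices = V * scale @ R.T + center
    # angular order around the centroid: deterministic default ordering
    rel = vertices - vertices.mean(axis=0)
    order = np.argsort(np.arctan2(rel[:, 1], rel[:, 0])) if d >= 2 else np.argsort(rel[:, 0])
    vertices = vertices[order]

    diagnostics = {
        "containment_fraction": contained,
        "simplex_volume": volume_canonical * scale**d,
        "objective": float(best_res.fun),
        "penalty_weight": penalty_weight,
        "n_restarts": n_restarts,
        "seed": seed,
    }
    arch = ArchetypeSet(
        vertices=vertices,
        gene_profiles=np.empty((k, 0)),
        labels=[f"archetype{t + 1}" for t in range(k)],
        fit_diagnostics=diagnostics,
    )
    arch.gene_profiles = backproject(arch, emb)
    return arch


def backproject(archetypes: ArchetypeSet, emb: LatentEmbedding) -> np.ndarray:
    """Map latent vertices to gene space: profile_t = center + vertex_t . loadings^T.

    Back-projection can produce small negative values for genes near zero;
    these are floored at 0 (count logged) so profiles remain interpretable
    as expression.
    """
    if archetypes.vertices.shape[1] != emb.loadings.shape[1]:
        raise ValueError("vertex dimension does not match embedding loadings")
    profiles = emb.center + archetypes.vertices @ emb.loadings.T
    n_neg = int((profiles < 0).sum())
    if n_neg:
        logger.info("backproject: floored %d negative back-projected values at 0", n_neg)
    return np.clip(profiles, 0.0, None)


def archetype_markers(
    archetypes: ArchetypeSet,
    gene_ids: list[str] | None = None,
    fc_threshold: float = 2.0,
    pseudocount: float = 1.0,
) -> dict[str, list[str]]:
    """Per-archetype marker genes: log2 fold change > threshold vs *every* other archetype.

    Gene g belongs to archetype t iff
    ``log2((profile_t[g]+eps) / (profile_s[g]+eps)) > fc_threshold`` for all
    s != t. With the default threshold of 2 this selects genes over-expressed
    more than four-fold against both competing archetypes.
    """
    profiles = archetypes.gene_profiles
    k, n_genes = profiles.shape
    if k < 2:
        raise ValueError("marker comparison needs at least 2 archetypes")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    logp = np.log2(profiles + pseudocount)
    out: dict[str, list[str]] = {}
    for t in range(k):
        others = np.delete(logp, t, axis=0)
        min_lfc = (logp[t] - others).min(axis=0)
        out[archetypes.labels[t]] = [g for g, v in zip(gene_ids, min_lfc) if v > fc_threshold]
    return out


def score_markers(
    marker_lists: dict[str, list[str]],
    library: dict[str, list[str]],
    universe: list[str],
):
    """Label each archetype by hypergeometric enrichment against a marker library.

    For each (archetype list, library set) pair the upper-tail hypergeometric
    probability P(overlap >= observed) is computed over the declared gene
    universe. The archetype's label is the name of its most-enriched set;
    ties break toward larger overlap, then set name. Empty lists are labeled
    ``"unassigned"``.

    Returns
    -------
    labels : dict archetype -> set name
    table : pandas.DataFrame with one row per (archetype, set): overlap sizes
        and p-value.
    """
    import pandas as pd

    uni = set(universe)
    rows = []
    labels: dict[str, str] = {}
    for arch_name, genes in marker_lists.items():
        query = set(genes) & uni
        if not query:
            labels[arch_name] = "unassigned"
        best_key = None
        for set_name, members in library.items():
            hits = set(members) & uni
            overlap = len(query & hits)
            p = float(hypergeom.sf(overlap - 1, len(uni), len(hits), len(query))) if query else 1.0
            rows.append(
                dict(archetype=arch_name, marker_set=set_name, overlap=overlap,
                     query_size=len(query), set_size=len(hits), p_value=p)
            )
            if query and overlap > 0:
                key = (p, -overlap, set_name)
                if best_key is None or key < best_key:
                    best_key = key
                    labels[arch_name] = set_name
        if arch_name not in labels:
            labels[arch_name] = "unassigned"
    return labels, pd.DataFrame(rows)
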