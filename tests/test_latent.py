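"""PCA embedding, minimum-volume simplex fitting, and archetype characterization."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom

import tricontinuum as tc
from tricontinuum.latent import _simplex_volume
from tricontinuum.utils import match_rows
from conftest import true_latent_vertices


def _em(values: np.ndarray) -> tc.ExpressionMatrix:
    g, n = values.shape
    return tc.ExpressionMatrix(
        pd.DataFrame(values, index=[f"g{i}" for i in range(g)],
                     columns=[f"s{j}" for j in range(n)]),
        allow_negative=True,
    )


def _coords_embedding(coords: np.ndarray) -> tc.LatentEmbedding:
    n, d = coords.shape
    return tc.LatentEmbedding(
        coords=coords, loadings=np.eye(d), center=np.zeros(d),
        explained_variance_ratio=np.full(d, 1.0 / d),
        sample_ids=[f"s{i}" for i in range(n)], gene_ids=[f"g{j}" for j in range(d)],
    )


class TestPCAEmbed:
    def test_collinear_points_explained_by_one_component(self):
        t = np.linspace(0, 1, 10)
        values = np.vstack([2 * t + 1, -3 * t + 4])  # 2 genes, collinear samples
        emb = tc.pca_embed(_em(values), d=1)
        np.testing.assert_allclose(emb.explained_variance_ratio, [1.0], atol=1e-12)

    def test_noiseless_three_archetype_cohort_is_rank_two(self, noiseless_cohort):
        m, _ = noiseless_cohort
        emb = tc.pca_embed(m, d=5)
        assert emb.explained_variance_ratio[:2].sum() > 1 - 1e-9
        assert np.all(emb.explained_variance_ratio[2:] < 1e-9)

    def test_full_rank_reconstruction_identity(self):
        rng = np.random.default_rng(11)
        values = rng.gamma(2.0, 5.0, size=(8, 6))
        emb = tc.pca_embed(tc.ExpressionMatrix(
            pd.DataFrame(values, index=[f"g{i}" for i in range(8)],
                         columns=[f"s{j}" for j in range(6)])), d=5)
        np.testing.assert_allclose(emb.reconstruct(), values.T, rtol=0, atol=1e-9)

    def test_dimension_limit_enforced(self, noiseless_cohort):
        m, _ = noiseless_cohort
        with pytest.raises(ValueError, match="exceeds"):
            tc.pca_embed(m, d=m.n_samples + 1)


class TestFitSimplex:
    def test_recovers_exact_triangle_from_its_own_vertices(self):
        triangle = np.array([[0.0, 0.0], [4.0, 0.0], [1.0, 3.0]])
        coords = np.tile(triangle, (5, 1))
        arch = tc.fit_simplex(_coords_embedding(coords), k=3, seed=0)
        perm = match_rows(arch.vertices, triangle)
        np.testing.assert_allclose(arch.vertices[perm], triangle, atol=1e-6)

    def test_noiseless_dirichlet_mixture_vertex_error_below_2pct(self, noiseless_cohort):
        m, truth = noiseless_cohort
        emb = tc.pca_embed(m, d=2)
        arch = tc.fit_simplex(emb, k=3, seed=1)
        true_v = true_latent_vertices(truth, emb)
        perm = match_rows(arch.vertices, true_v)
        err = np.linalg.norm(arch.vertices[perm] - true_v, axis=1)
        assert err.max() < 0.02 * pdist(true_v).max()

    def test_poisson_noise_keeps_containment_high(self, poisson_cohort):
        m, _ = poisson_cohort
        emb = tc.pca_embed(m, d=2)
        arch = tc.fit_simplex(emb, k=3, seed=2)
        assert arch.fit_diagnostics["containment_fraction"] >= 0.95

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(13)
        w = rng.dirichlet(np.ones(3), size=150)
        verts = np.array([[0.0, 0.0], [5.0, 1.0], [2.0, 4.0]])
        coords = w @ verts
        theta = 0.83
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        a1 = tc.fit_simplex(_coords_embedding(coords), k=3, seed=3)
        a2 = tc.fit_simplex(_coords_embedding(coords @ R.T), k=3, seed=3)
        perm = match_rows(a2.vertices, a1.vertices @ R.T)
        np.testing.assert_allclose(a2.vertices[perm], a1.vertices @ R.T, atol=1e-6)

    def test_shrinking_cloud_shrinks_fitted_volume(self):
        rng = np.random.default_rng(14)
        w = rng.dirichlet(np.ones(3), size=120)
        coords = w @ np.array([[0.0, 0.0], [6.0, 0.0], [1.0, 5.0]])
        centroid = coords.mean(axis=0)
        volumes = []
        for s in (1.0, 0.7, 0.4):
            shrunk = centroid + s * (coords - centroid)
            arch = tc.fit_simplex(_coords_embedding(shrunk), k=3, seed=4)
            volumes.append(arch.fit_diagnostics["simplex_volume"])
        assert volumes[0] >= volumes[1] >= volumes[2]

    def test_soft_optimum_beats_hull_vertex_triangles(self):
        """Any all-containing triangle on hull extreme points upper-bounds the optimum."""
        for seed in range(6):
            rng = np.random.default_rng(seed)
            pts = rng.normal(size=(rng.integers(7, 13), 2))
            arch = tc.fit_simplex(_coords_embedding(pts), k=3, seed=seed)
            hull_pts = pts[np.unique(ConvexHull(pts).vertices)]
            best = np.inf
            for combo in itertools.combinations(range(len(hull_pts)), 3):
                tri = hull_pts[list(combo)]
                try:
                    hull = ConvexHull(np.vstack([tri, pts]))
                except Exception:
                    continue
                if len(np.unique(hull.vertices)) == 3 and set(hull.vertices) <= {0, 1, 2}:
                    best = min(best, _simplex_volume(tri))
            if np.isfinite(best):
                assert arch.fit_diagnostics["objective"] <= best + 1e-6

    def test_degenerate_rank_raises(self):
        coords = np.column_stack([np.linspace(0, 1, 20), np.linspace(0, 2, 20)])
        with pytest.raises(ValueError, match="rank"):
            tc.fit_simplex(_coords_embedding(coords), k=3, seed=0)

    def test_k_must_match_dimension(self):
        coords = np.random.default_rng(0).normal(size=(30, 2))
        with pytest.raises(ValueError, match="d\\+1"):
            tc.fit_simplex(_coords_embedding(coords), k=4, seed=0)


class TestBackproject:
    def test_vertex_at_origin_gives_center(self, noiseless_cohort):
        m, _ = noiseless_cohort
        emb = tc.pca_embed(m, d=2)
        arch = tc.ArchetypeSet(vertices=np.zeros((1, 2)), gene_profiles=np.empty((1, 0)),
                               labels=["o"])
        profile = tc.backproject(arch, emb)
        np.testing.assert_allclose(profile[0], np.clip(emb.center, 0, None), rtol=1e-12)

    def test_vertex_at_sample_coords_reproduces_sample(self, noiseless_cohort):
        m, _ = noiseless_cohort  # exact rank 2, so d=2 reconstruction is exact
        emb = tc.pca_embed(m, d=2)
        arch = tc.ArchetypeSet(vertices=emb.coords[[7]], gene_profiles=np.empty((1, 0)),
                               labels=["s"])
        profile = tc.backproject(arch, emb)
        np.testing.assert_allclose(profile[0], m.values[:, 7], atol=1e-8)

    def test_backprojected_profiles_correlate_with_truth(self, noiseless_cohort):
        m, truth = noiseless_cohort
        emb = tc.pca_embed(m, d=2)
        arch = tc.fit_simplex(emb, k=3, seed=5)
        true_v = true_latent_vertices(truth, emb)
        perm = match_rows(arch.vertices, true_v)
        for t in range(3):
            r = np.corrcoef(arch.gene_profiles[perm[t]], truth.archetype_profiles[t])[0, 1]
            assert r > 0.95


class TestArchetypeMarkers:
    def test_hand_computed_fold_change_assignment(self):
        profiles = np.array([[40.0], [8.0], [8.0]])
        arch = tc.ArchetypeSet(vertices=np.zeros((3, 2)), gene_profiles=profiles,
                               labels=["a", "b", "c"])
        lists = tc.archetype_markers(arch, gene_ids=["g"], fc_threshold=2.0, pseudocount=1.0)
        assert lists == {"a": ["g"], "b": [], "c": []}  # log2(41/9) ~ 2.19 > 2

    def test_identical_profiles_yield_empty_lists(self):
        profiles = np.tile(np.array([3.0, 7.0, 1.0]), (3, 1))
        arch = tc.ArchetypeSet(vertices=np.zeros((3, 2)), gene_profiles=profiles,
                               labels=["a", "b", "c"])
        lists = tc.archetype_markers(arch, gene_ids=["g1", "g2", "g3"])
        assert all(v == [] for v in lists.values())

    def test_matches_brute_force_inequality_on_random_profiles(self):
        rng = np.random.default_rng(17)
        profiles = rng.gamma(1.0, 30.0, size=(3, 1000))
        arch = tc.ArchetypeSet(vertices=np.zeros((3, 2)), gene_profiles=profiles,
                               labels=["a", "b", "c"])
        gene_ids = [f"g{i}" for i in range(1000)]
        lists = tc.archetype_markers(arch, gene_ids=gene_ids, fc_threshold=2.0,
                                     pseudocount=1.0)
        for t, name in enumerate(["a", "b", "c"]):
            expected = [
                g for i, g in enumerate(gene_ids)
                if all(np.log2((profiles[t, i] + 1) / (profiles[s, i] + 1)) > 2.0
                       for s in range(3) if s != t)
            ]
            assert lists[name] == expected

    def test_planted_marker_blocks_recovered(self, noiseless_cohort):
        m, truth = noiseless_cohort
        emb = tc.pca_embed(m, d=2)
        arch = tc.fit_simplex(emb, k=3, seed=6)
        true_v = true_latent_vertices(truth, emb)
        perm = match_rows(arch.vertices, true_v)
        arch.vertices = arch.vertices[perm]
        arch.gene_profiles = arch.gene_profiles[perm]
        arch.labels = list(truth.archetype_names)
        lists = tc.archetype_markers(arch, gene_ids=m.gene_ids)
        for t, name in enumerate(truth.archetype_names):
            block = set(truth.marker_blocks[name])
            recovered = block & set(lists[name])
            assert len(recovered) >= 0.9 * len(block)
            for other in truth.archetype_names:
                if other != name:
                    assert not block & set(lists[other])  # zero cross-assignment


class TestScoreMarkers:
    def test_closed_form_hypergeometric_extreme(self):
        universe = [f"g{i}" for i in range(1000)]
        target = universe[:10]
        labels, table = tc.score_markers({"arch1": target}, {"setA": target}, universe)
        row = table.set_index(["archetype", "marker_set"]).loc[("arch1", "setA")]
        expected_p = hypergeom.sf(9, 1000, 10, 10)  # = C(10,10)C(990,0)/C(1000,10)
        assert row["p_value"] == pytest.approx(expected_p, rel=1e-12)
        assert labels["arch1"] == "setA"

    def test_disjoint_lists_are_unassigned(self):
        universe = [f"g{i}" for i in range(100)]
        labels, table = tc.score_markers(
            {"arch1": universe[:5]}, {"setA": universe[50:60]}, universe)
        assert labels["arch1"] == "unassigned"
        assert (table["overlap"] == 0).all()

    def test_planted_blocks_label_all_archetypes(self, noiseless_cohort):
        m, truth = noiseless_cohort
        emb = tc.pca_embed(m, d=2)
        arch = tc.fit_simplex(emb, k=3, seed=7)
        lists = tc.archetype_markers(arch, gene_ids=m.gene_ids)
        labels, _ = tc.score_markers(lists, truth.marker_blocks, m.gene_ids)
        assert sorted(labels.values()) == sorted(truth.archetype_names)
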