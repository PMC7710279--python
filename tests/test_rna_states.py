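"""Normalization, clustering, signature scoring, deconvolution, GSEA and
zonal correlation, each checked against closed forms or brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import spearmanr

from regenmap import rna_states
from regenmap.containers import SignatureSet, make_count_matrix


def _adata(x, cells=None, genes=None):
    x = np.asarray(x)
    cells = cells or [f"c{i}" for i in range(x.shape[0])]
    genes = genes or [f"g{i}" for i in range(x.shape[1])]
    return make_count_matrix(sp.csr_matrix(x), cells, genes)


class TestNormalize:
    def test_exact_formula(self):
        adata = _adata([[10, 0]])
        norm = rna_states.normalize_counts(adata, target_sum=10)
        row = np.asarray(norm.X.todense())[0]
        assert row[0] == pytest.approx(np.log(11))
        assert row[1] == 0.0

    def test_identical_cells_identical_rows(self):
        adata = _adata([[3, 1, 0], [3, 1, 0]])
        norm = np.asarray(rna_states.normalize_counts(adata).X.todense())
        np.testing.assert_array_equal(norm[0], norm[1])

    def test_target_sum_conserved(self, rna_small):
        adata, _ = rna_small
        norm = rna_states.normalize_counts(adata[:20].copy(), target_sum=1e4)
        back = np.expm1(np.asarray(norm.X.todense())).sum(axis=1)
        np.testing.assert_allclose(back, 1e4, rtol=1e-8)

    def test_zero_count_cell_rejected(self):
        adata = _adata([[0, 0], [1, 1]])
        with pytest.raises(ValueError, match="filter"):
            rna_states.normalize_counts(adata)


class TestClustering:
    def test_two_separated_clouds(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 1, (50, 5)), rng.normal(100, 1, (50, 5))])
        res = rna_states.cluster_cells(
            x, n_neighbors=10, resolution=0.2, seed=0, is_embedding=True
        )
        assert res.n_clusters == 2
        assert len(set(res.labels[:50])) == 1 and len(set(res.labels[50:])) == 1

    def test_resolution_to_zero_one_cluster(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (80, 5))
        res = rna_states.cluster_cells(
            x, n_neighbors=10, resolution=1e-4, seed=0, is_embedding=True
        )
        assert res.n_clusters == 1

    def test_deterministic_for_seed(self, rna_small):
        adata, _ = rna_small
        norm = rna_states.normalize_counts(
            adata[:150].copy()[:, np.asarray(adata.X.sum(axis=0)).ravel() > 0].copy()
        )
        r1 = rna_states.cluster_cells(norm, seed=5)
        r2 = rna_states.cluster_cells(norm, seed=5)
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            rna_states.cluster_cells(np.zeros((5, 3)), n_neighbors=10, is_embedding=True)


class TestHierarchicalGrouping:
    def test_identical_profiles_merge_first(self):
        profiles = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 1.0, -5.0]],
            index=[1, 2, 3],
        )
        groups, linkage = rna_states.hierarchical_group_clusters(profiles, 2)
        assert groups[1] == groups[2] != groups[3]
        assert linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_k_equals_n_identity_partition(self):
        rng = np.random.default_rng(2)
        profiles = pd.DataFrame(rng.normal(0, 1, (4, 6)))
        groups, _ = rna_states.hierarchical_group_clusters(profiles, 4)
        assert groups.nunique() == 4

    def test_constant_profile_rejected(self):
        profiles = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["a", "b"])
        with pytest.raises(ValueError, match="a"):
            rna_states.hierarchical_group_clusters(profiles, 2)

    def test_planted_archetypes_recovered(self):
        rng = np.random.default_rng(3)
        archetypes = rng.normal(0, 1, (3, 40))
        profiles = np.vstack(
            [archetypes[i % 3] + rng.normal(0, 0.1, 40) for i in range(9)]
        )
        groups, _ = rna_states.hierarchical_group_clusters(pd.DataFrame(profiles), 3)
        for i in range(9):
            for j in range(9):
                assert (groups[i] == groups[j]) == (i % 3 == j % 3)


class TestSignatureScore:
    def test_all_gene_signature_is_mean_z_row(self, tiny_counts):
        norm = rna_states.normalize_counts(tiny_counts)
        sig = SignatureSet("all", set(norm.var_names))
        scores = rna_states.score_signature(norm, sig)
        x = np.asarray(norm.X.todense())
        z = (x - x.mean(axis=0)) / np.where(x.std(axis=0) == 0, 1, x.std(axis=0))
        np.testing.assert_allclose(scores.to_numpy(), z.mean(axis=1))

    def test_library_size_invariance(self, rna_small):
        adata, _ = rna_small
        sub = adata[:50].copy()
        scaled = sub.copy()
        scaled.X = sub.X * 7
        sig = SignatureSet("s", set(sub.var_names[:20]))
        a = rna_states.score_signature(rna_states.normalize_counts(sub), sig)
        b = rna_states.score_signature(rna_states.normalize_counts(scaled), sig)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-10)

    def test_perivenous_score_tracks_zonation(self, rna_small):
        adata, truth = rna_small
        norm = rna_states.normalize_counts(adata)
        pv = SignatureSet("pv", {g for g in adata.var_names if g.startswith("pv")})
        scores = rna_states.score_signature(norm, pv)
        rho = spearmanr(scores, truth.zonation_coord)[0]
        assert rho <= -0.8

    def test_no_overlap_rejected(self, tiny_counts):
        with pytest.raises(ValueError, match="nope"):
            rna_states.score_signature(tiny_counts, SignatureSet("nope", {"zz"}))


class TestDichotomizedZonation:
    def test_tie_is_coexpressing(self, tiny_counts):
        norm = rna_states.normalize_counts(tiny_counts)
        sig = SignatureSet("s", {"g1", "g2"})
        out = rna_states.dichotomized_zonation(norm, sig, sig)
        assert (out["zonation_class"] == "co-expressing").all()

    def test_swapping_sets_swaps_labels(self, rna_small):
        adata, _ = rna_small
        norm = rna_states.normalize_counts(adata[:100].copy())
        pv = SignatureSet("pv", {g for g in adata.var_names if g.startswith("pv")})
        pp = SignatureSet("pp", {g for g in adata.var_names if g.startswith("pp")})
        a = rna_states.dichotomized_zonation(norm, pv, pp)
        b = rna_states.dichotomized_zonation(norm, pp, pv)
        swap = {"PV": "PP", "PP": "PV", "co-expressing": "co-expressing"}
        assert a["zonation_class"].map(swap).tolist() == b["zonation_class"].tolist()

    def test_pure_central_cells_called_pv(self, rna_small):
        adata, truth = rna_small
        norm = rna_states.normalize_counts(adata)
        pv = SignatureSet("pv", {g for g in adata.var_names if g.startswith("pv")})
        pp = SignatureSet("pp", {g for g in adata.var_names if g.startswith("pp")})
        out = rna_states.dichotomized_zonation(norm, pv, pp)
        central = truth.zonation_coord < 0.1
        frac_pv = (out["zonation_class"].to_numpy()[central] == "PV").mean()
        assert frac_pv >= 0.9


class TestDeconvolution:
    def test_vertex_returns_vertex(self, refs):
        prof = refs.celltype_profiles
        for k, col in enumerate(prof.columns):
            frac = rna_states.deconvolute_bulk(prof[col], prof)
            expected = np.zeros(prof.shape[1])
            expected[k] = 1.0
            np.testing.assert_allclose(
                frac.iloc[0, : prof.shape[1]].to_numpy(), expected, atol=1e-9
            )

    def test_exact_mixture(self, refs):
        prof = refs.celltype_profiles
        bulk = 0.9 * prof.iloc[:, 0] + 0.1 * prof.iloc[:, 1]
        frac = rna_states.deconvolute_bulk(bulk, prof)
        np.testing.assert_allclose(
            frac.iloc[0, :3].to_numpy(), [0.9, 0.1, 0.0], atol=1e-6
        )

    def test_collinear_references_rejected(self):
        prof = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]}, index=["x", "y", "z"]
        )
        with pytest.raises(ValueError, match="condition"):
            rna_states.deconvolute_bulk(prof["a"], prof)


def brute_force_es(scores, in_set, p):
    """Literal running-sum enumeration of the GSEA enrichment score."""
    order = np.argsort(-scores, kind="stable")
    s, mask = scores[order], in_set[order]
    w = np.abs(s) ** p
    total = w[mask].sum()
    running, best = 0.0, 0.0
    n, nh = len(s), mask.sum()
    for i in range(n):
        if mask[i]:
            running += (w[i] / total) if total > 0 else 1.0 / nh
        else:
            running -= 1.0 / (n - nh)
        if abs(running) > abs(best):
            best = running
    return best


class TestGsea:
    def test_top_gene_singleton_scores_one(self):
        scores = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=list("abcde"))
        res = rna_states.gsea_preranked(
            scores, SignatureSet("s", {"a"}), weight_p=0, n_perm=50, seed=0
        )
        assert res["ES"] == pytest.approx(1.0)

    def test_reversed_ranking_flips_tail(self):
        scores = pd.Series(np.arange(10, 0, -1, dtype=float), index=list("abcdefghij"))
        sig = SignatureSet("s", {"a", "b"})
        fwd = rna_states.gsea_preranked(scores, sig, n_perm=50, seed=0)
        rev = rna_states.gsea_preranked(-scores, sig, n_perm=50, seed=0)
        assert fwd["ES"] > 0 > rev["ES"]

    def test_known_instance_matches_enumeration(self):
        scores = pd.Series(np.arange(10, 0, -1, dtype=float),
                           index=[f"g{i}" for i in range(10)])
        sig = SignatureSet("s", {"g0", "g1", "g6"})
        res = rna_states.gsea_preranked(scores, sig, weight_p=0, n_perm=50, seed=0)
        mask = np.asarray([g in sig.genes for g in scores.index])
        expected = brute_force_es(scores.to_numpy(), mask, 0)
        assert res["ES"] == pytest.approx(expected, abs=1e-12)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            n = int(rng.integers(6, 20))
            scores = pd.Series(rng.normal(0, 2, n), index=[f"g{i}" for i in range(n)])
            k = int(rng.integers(1, n - 1))
            genes = set(rng.choice(scores.index, k, replace=False))
            p = float(rng.choice([0.0, 1.0, 2.0]))
            res = rna_states.gsea_preranked(
                scores, SignatureSet("s", genes), weight_p=p, n_perm=10, seed=0
            )
            mask = np.asarray([g in genes for g in scores.index])
            assert res["ES"] == pytest.approx(
                brute_force_es(scores.to_numpy(), mask, p), abs=1e-12
            )

    def test_full_coverage_rejected(self):
        scores = pd.Series([2.0, 1.0], index=["a", "b"])
        with pytest.raises(ValueError):
            rna_states.gsea_preranked(scores, SignatureSet("s", {"a", "b"}))


class TestZonalCorrelation:
    def test_copied_layer_gives_r_one(self, refs):
        zon = refs.zonal_profile
        clusters = pd.DataFrame(
            [zon.loc["L1"], zon.loc["L5"]], index=["k1", "k2"]
        )
        corr, best = rna_states.zonal_correlation(clusters, zon)
        assert corr.loc["k1", "L1"] == pytest.approx(1.0)
        assert best["k1"] == "L1"
        assert best["k2"] == "L5"

    def test_negated_profile_gives_minus_one(self, refs):
        zon = refs.zonal_profile
        clusters = pd.DataFrame([-zon.loc["L1"], zon.loc["L9"]], index=["neg", "pos"])
        corr, _ = rna_states.zonal_correlation(clusters, zon)
        assert corr.loc["neg", "L1"] == pytest.approx(-1.0)

    def test_entries_bounded(self, refs):
        rng = np.random.default_rng(4)
        clusters = pd.DataFrame(
            rng.normal(0, 1, (5, 89)), columns=refs.zonal_profile.columns
        )
        corr, _ = rna_states.zonal_correlation(clusters, refs.zonal_profile)
        assert (corr.to_numpy() >= -1 - 1e-12).all()
        assert (corr.to_numpy() <= 1 + 1e-12).all()
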