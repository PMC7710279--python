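"""Chromatin stages: TF-IDF/LSI, pseudo-bulk conservation, DA statistics
and BH, gene activity against the all-pairs oracle, chromVAR deviations and
the bulk time course."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from regenmap import chromatin, synthdata
from regenmap.containers import ClusterResult, make_genome_annotation, make_peak_matrix


class TestTfidfLsi:
    def test_identical_cells_identical_rows(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(1.0, (40, 80))
        counts[1] = counts[0]
        pmat = _pm(counts)
        emb = chromatin.tfidf_lsi(pmat, n_components=5)
        np.testing.assert_allclose(emb[0], emb[1], atol=1e-10)

    def test_idf_formula_for_ubiquitous_peak(self):
        # a peak present in every cell has idf = log(1 + n/n) = log 2
        rng = np.random.default_rng(1)
        counts = rng.poisson(1.0, (30, 50))
        counts[:, 0] = 1
        binary = (counts > 0).astype(float)
        n_with = binary.sum(axis=0)
        idf = np.log(1 + 30 / n_with)
        assert idf[0] == pytest.approx(np.log(2))

    def test_all_zero_cell_rejected(self):
        counts = np.ones((35, 40))
        counts[3] = 0
        with pytest.raises(ValueError, match="filter_nuclei"):
            chromatin.tfidf_lsi(_pm(counts), n_components=5)


def _pm(counts, chrom="chr1"):
    counts = np.asarray(counts)
    n_peaks = counts.shape[1]
    peaks = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n_peaks) * 1000,
            "end": np.arange(n_peaks) * 1000 + 400,
            "peak_id": [f"p{i:04d}" for i in range(n_peaks)],
        }
    )
    return make_peak_matrix(
        sp.csr_matrix(counts), peaks, [f"c{i:04d}" for i in range(len(counts))]
    )


class TestPseudoBulk:
    def test_single_cluster_equals_column_sums(self):
        rng = np.random.default_rng(2)
        pmat = _pm(rng.poisson(2.0, (20, 30)))
        clusters = ClusterResult(np.ones(20, dtype=int), None, 1.0, 0)
        pb = chromatin.pseudo_bulk(pmat, clusters)
        np.testing.assert_array_equal(
            pb.iloc[0].to_numpy(), np.asarray(pmat.X.sum(axis=0)).ravel()
        )

    def test_totals_conserved_across_clusters(self):
        rng = np.random.default_rng(3)
        pmat = _pm(rng.poisson(2.0, (30, 25)))
        labels = rng.integers(1, 4, 30)
        labels[:3] = [1, 2, 3]
        clusters = ClusterResult(labels, None, 1.0, 0)
        pb = chromatin.pseudo_bulk(pmat, clusters)
        np.testing.assert_array_equal(
            pb.sum(axis=0).to_numpy(), np.asarray(pmat.X.sum(axis=0)).ravel()
        )


class TestBhAdjust:
    def test_textbook_example(self):
        adj = chromatin.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert chromatin.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        np.testing.assert_array_equal(chromatin.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            chromatin.bh_adjust([0.5, 1.5])

    @settings(max_examples=80, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_statsmodels_step_up(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, int(rng.integers(1, 100)))
        ours = chromatin.bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, atol=1e-12)


class TestDifferentialAccessibility:
    def test_identical_groups_no_calls(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(2.0, (20, 40))
        counts = np.vstack([counts, counts])  # group B duplicates group A
        pmat = _pm(counts)
        res = chromatin.differential_accessibility(
            pmat, np.arange(20), np.arange(20, 40)
        )
        np.testing.assert_allclose(res.table["log2_fold_change"], 0.0, atol=1e-12)
        assert (res.table["direction"] == "ns").all()

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(5)
        pmat = _pm(rng.poisson(2.0, (60, 50)))
        a, b = np.arange(30), np.arange(30, 60)
        fwd = chromatin.differential_accessibility(pmat, a, b, lfc_threshold=0.5)
        rev = chromatin.differential_accessibility(pmat, b, a, lfc_threshold=0.5)
        np.testing.assert_allclose(
            fwd.table["log2_fold_change"], -rev.table["log2_fold_change"], atol=1e-12
        )
        np.testing.assert_allclose(
            fwd.table["p_value"], rev.table["p_value"], atol=1e-12
        )

    def test_overlapping_groups_rejected(self):
        rng = np.random.default_rng(6)
        pmat = _pm(rng.poisson(2.0, (30, 10)))
        with pytest.raises(ValueError, match="overlap"):
            chromatin.differential_accessibility(pmat, np.arange(15), np.arange(10, 30))


def brute_force_gene_activity(pmat, genome, extension, decay_bp, max_distance):
    counts = np.asarray(pmat.X.todense()).T  # peaks x cells
    out = np.zeros((len(genome), pmat.n_obs))
    for gi, g in genome.iterrows():
        w0, w1 = g["start"] - extension, g["end"] + extension
        for pi, (chrom, s, e) in enumerate(
            zip(pmat.var["chrom"], pmat.var["start"], pmat.var["end"])
        ):
            if chrom != g["chrom"]:
                continue
            if s < w1 and e > w0:
                w = 1.0
            else:
                gap = max(w0 - e, s - w1)
                if gap > max_distance:
                    continue
                w = np.exp(-gap / decay_bp)
            out[gi] += w * counts[pi]
    return out


class TestGeneActivity:
    def _genome(self):
        return make_genome_annotation(
            pd.DataFrame(
                {
                    "gene_id": ["gA", "gB"],
                    "chrom": ["chr1", "chr1"],
                    "start": [10_000, 200_000],
                    "end": [15_000, 210_000],
                    "strand": ["+", "-"],
                }
            )
        )

    def test_peak_inside_gene_weight_one(self):
        peaks = pd.DataFrame(
            {"chrom": ["chr1"], "start": [11_000], "end": [11_400], "peak_id": ["p"]}
        )
        pmat = make_peak_matrix(sp.csr_matrix([[7], [3]]), peaks, ["c1", "c2"])
        scores = chromatin.gene_activity_scores(pmat, self._genome())
        np.testing.assert_allclose(scores.loc["gA"].to_numpy(), [7.0, 3.0])

    def test_distant_peak_exponential_weight(self):
        # 5000 bp beyond the extended window -> weight e^-1
        peaks = pd.DataFrame(
            {"chrom": ["chr1"], "start": [22_000], "end": [22_400], "peak_id": ["p"]}
        )
        pmat = make_peak_matrix(sp.csr_matrix([[10]]), peaks, ["c1"])
        scores = chromatin.gene_activity_scores(
            pmat, self._genome(), extension=2000, decay_bp=5000
        )
        assert scores.loc["gA", "c1"] == pytest.approx(10 * np.exp(-1))

    def test_random_instances_match_all_pairs_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n_genes, n_peaks = 20, 200
            genome = synthdata.gen_genome(n_genes, seed=int(rng.integers(0, 100)))
            starts = rng.integers(0, 900_000, n_peaks)
            peaks = pd.DataFrame(
                {
                    "chrom": rng.choice(["chr1", "chr2"], n_peaks),
                    "start": starts,
                    "end": starts + 400,
                    "peak_id": [f"p{i}" for i in range(n_peaks)],
                }
            ).sort_values(["chrom", "start"]).reset_index(drop=True)
            pmat = make_peak_matrix(
                sp.csr_matrix(rng.poisson(2.0, (5, n_peaks))), peaks,
                [f"c{i}" for i in range(5)],
            )
            got = chromatin.gene_activity_scores(pmat, genome).to_numpy()
            exp = brute_force_gene_activity(pmat, genome, 2000, 5000.0, 100_000)
            np.testing.assert_allclose(got, exp, atol=1e-9)


class TestChromvar:
    def test_proportional_accessibility_zero_raw_deviation(self):
        # every cell's counts exactly proportional to the peak totals
        base = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        counts = np.outer(np.arange(1, 9), base)
        pmat = _pm(counts)
        hits = pd.DataFrame({"m": [True] * 5 + [False] * 5}, index=pmat.var_names)
        z = chromatin.chromvar_deviations(pmat, hits, n_background=10, seed=0)
        # raw deviations are 0 for every cell, so z is 0/0 -> NaN-safe zero
        x = sp.csr_matrix(pmat.X, dtype=float)
        frac = np.asarray(x.sum(axis=0)).ravel()
        frac /= frac.sum()
        expected = np.outer(
            frac @ hits.to_numpy(), np.asarray(x.sum(axis=1)).ravel()
        )
        observed = np.asarray((x @ hits.to_numpy(dtype=float)).T)
        np.testing.assert_allclose(observed, expected, atol=1e-9)

    def test_all_peak_motif_zero_deviation(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(2.0, (20, 30))
        pmat = _pm(counts)
        hits = pd.DataFrame({"m": [True] * 30}, index=pmat.var_names)
        x = sp.csr_matrix(pmat.X, dtype=float)
        frac = np.asarray(x.sum(axis=0)).ravel()
        frac /= frac.sum()
        observed = np.asarray((x @ hits.to_numpy(dtype=float)).T)
        expected = np.outer(frac @ hits.to_numpy(), np.asarray(x.sum(axis=1)).ravel())
        np.testing.assert_allclose(observed, expected, atol=1e-9)

    def test_planted_block_enriched_in_its_cluster(self):
        wins = 0
        for seed in range(8):
            rng = np.random.default_rng(seed)
            counts = rng.poisson(2.0, (80, 200)).astype(float)
            counts[:40, :25] = rng.poisson(3.5, (40, 25))
            counts[40:, :25] = rng.poisson(0.5, (40, 25))
            pmat = _pm(counts)
            hits = pd.DataFrame(
                {"m": [i < 25 for i in range(200)]}, index=pmat.var_names
            )
            z = chromatin.chromvar_deviations(pmat, hits, n_background=25, seed=seed)
            wins += z.loc["m"].to_numpy()[:40].mean() > z.loc["m"].to_numpy()[40:].mean()
        assert wins == 8

    def test_null_z_calibrated(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(2.0, (60, 300))
        pmat = _pm(counts)
        hits = pd.DataFrame(
            {f"m{j}": rng.random(300) < 0.1 for j in range(15)}, index=pmat.var_names
        )
        z = chromatin.chromvar_deviations(pmat, hits, n_background=40, seed=0)
        vals = z.to_numpy()
        vals = vals[np.isfinite(vals)]
        assert abs(vals.mean()) <= 0.2
        assert abs(vals.std() - 1.0) <= 0.2

    def test_sparse_motif_rejected(self):
        rng = np.random.default_rng(10)
        pmat = _pm(rng.poisson(2.0, (20, 30)))
        hits = pd.DataFrame({"m": [True] * 3 + [False] * 27}, index=pmat.var_names)
        with pytest.raises(ValueError, match="m"):
            chromatin.chromvar_deviations(pmat, hits)


class TestModeratedT:
    def test_d0_zero_reduces_to_ordinary_t(self):
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, (50, 4))
        b = rng.normal(0.3, 1, (50, 3))
        ours = chromatin.moderated_ttest(a, b, d0=0.0, s0_sq=1.0)
        ref = ttest_ind(a, b, axis=1)
        np.testing.assert_allclose(ours["t"], ref.statistic, atol=1e-10)
        np.testing.assert_allclose(ours["p_value"], ref.pvalue, atol=1e-10)

    def test_shrinkage_pulls_variances_to_prior(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, (200, 3))
        b = rng.normal(0, 1, (200, 3))
        mod = chromatin.moderated_ttest(a, b)
        ord_ = chromatin.moderated_ttest(a, b, d0=0.0, s0_sq=1.0)
        # moderation reduces the spread of the t statistics
        assert mod["t"].std() <= ord_["t"].std() + 1e-9


class TestTimecourse:
    def test_flat_null_no_modules(self):
        table, _ = synthdata.gen_bulk_timecourse(
            n_regions=60, signal_fraction=0.0, noise_sd=0.0, seed=1
        )
        da, modules = chromatin.timecourse_modules(table, seed=0, n_restarts=5)
        assert len(modules) == 0
        for res in da.values():
            assert (res.table["direction"] == "ns").all()

    def test_planted_modules_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        table, truth = synthdata.gen_bulk_timecourse(n_regions=400, n_modules=6, seed=2)
        _, modules = chromatin.timecourse_modules(table, seed=0, n_restarts=20)
        planted = pd.Series(truth.module_labels, index=table.index).loc[modules.index]
        assert adjusted_rand_score(planted, modules["module"]) >= 0.8

    def test_requires_replicates(self):
        table = pd.DataFrame(
            np.ones((10, 4)), columns=["t0_r1", "t48_r1", "t72_r1", "t96_r1"]
        )
        with pytest.raises(ValueError, match="replicates"):
            chromatin.timecourse_modules(table)
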