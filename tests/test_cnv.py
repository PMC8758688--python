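"""CNV profile oracle equivalence, malignancy calling, subclones, drivers."""

import anndata
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import lungcomp as lc
from lungcomp.cnv import _chromosome_windows


def brute_force_profile(counts, catalog, ref_idx, window_size, clamp=3.0):
    """Independent re-implementation of the profile by explicit loops."""
    lib = counts.sum(axis=1, keepdims=True).astype(float)
    lib[lib == 0] = 1
    logx = np.log2(counts / lib * 1e5 + 1)
    keep = logx.sum(axis=0) > 0
    logx = logx[:, keep]
    cat = catalog.sort_values(["chromosome", "order_index"]).reset_index(drop=True)
    cat = cat[keep].reset_index(drop=True)
    centered = logx - logx[ref_idx].mean(axis=0)
    cols = []
    min_len = int(np.ceil(window_size / 2))
    for chrom in cat["chromosome"].unique():
        idx = np.flatnonzero((cat["chromosome"] == chrom).to_numpy())
        any_kept = False
        for a in range(len(idx)):
            b = min(a + window_size, len(idx))
            if (b - a) == window_size or (b - a) >= min_len:
                cols.append(centered[:, idx[a:b]].mean(axis=1))
                any_kept = True
        if not any_kept:
            cols.append(centered[:, idx].mean(axis=1))
    V = np.column_stack(cols)
    V = V - np.median(V, axis=1, keepdims=True)
    V = V - V[ref_idx].mean(axis=0)
    return np.clip(V, -clamp, clamp)


def tiny_adata(counts, catalog):
    A = anndata.AnnData(X=sp.csr_matrix(counts.astype(float)))
    A.obs_names = [f"c{i}" for i in range(counts.shape[0])]
    # catalog rows are already in (chromosome, order) layout
    A.var_names = catalog["gene_id"].to_numpy()
    return A


@pytest.fixture(scope="module")
def fixture_200g():
    catalog = lc.generate_gene_catalog(2, 100, seed=11)
    rng = np.random.default_rng(11)
    counts = rng.poisson(rng.lognormal(0.5, 1.0, 200), size=(20, 200))
    return tiny_adata(counts, catalog), catalog, counts


class TestProfileOracle:
    @pytest.mark.parametrize("window_size", [1, 7, 30, 100])
    def test_matches_brute_force(self, fixture_200g, window_size):
        A, catalog, counts = fixture_200g
        ref = list(A.obs_names[:8])
        prof = lc.compute_cnv_profile(A, catalog, ref, window_size=window_size)
        ref_idx = np.arange(8)
        expected = brute_force_profile(counts, catalog, ref_idx, window_size)
        np.testing.assert_allclose(
            prof.values.to_numpy(), expected, atol=1e-10
        )

    def test_window_one_is_centered_expression(self, fixture_200g):
        A, catalog, counts = fixture_200g
        ref = list(A.obs_names[:8])
        prof = lc.compute_cnv_profile(A, catalog, ref, window_size=1)
        lib = counts.sum(axis=1, keepdims=True).astype(float)
        logx = np.log2(counts / lib * 1e5 + 1)
        centered = logx - logx[:8].mean(axis=0)
        centered = centered - np.median(centered, axis=1, keepdims=True)
        centered = centered - centered[:8].mean(axis=0)
        np.testing.assert_allclose(
            prof.values.to_numpy(), np.clip(centered, -3, 3), atol=1e-10
        )

    def test_constant_matrix_all_zero(self):
        catalog = lc.generate_gene_catalog(1, 50, seed=1)
        counts = np.full((10, 50), 4.0)
        A = tiny_adata(counts, catalog)
        prof = lc.compute_cnv_profile(A, catalog, list(A.obs_names), window_size=5)
        np.testing.assert_allclose(prof.values.to_numpy(), 0.0, atol=1e-12)

    def test_reference_window_means_zero(self, default_profile):
        prof, ref = default_profile
        col_means = prof.values.loc[ref].mean(axis=0)
        assert np.abs(col_means.to_numpy()).max() < 1e-6

    def test_windows_never_span_chromosomes(self, default_profile):
        prof, _ = default_profile
        w = prof.windows
        assert (w["first_gene"] <= w["last_gene"]).all()
        # each window label chromosome matches its declared span size bound
        assert ((w["last_gene"] - w["first_gene"] + 1) <= 100).all()

    def test_empty_reference_rejected(self, fixture_200g):
        A, catalog, _ = fixture_200g
        with pytest.raises(ValueError, match="empty"):
            lc.compute_cnv_profile(A, catalog, [])

    def test_bad_window_rejected(self, fixture_200g):
        A, catalog, _ = fixture_200g
        with pytest.raises(ValueError):
            lc.compute_cnv_profile(A, catalog, list(A.obs_names[:2]), window_size=0)


class TestProfileInvariances:
    def test_shuffle_within_window_invariant(self):
        # with one whole-chromosome window per chromosome, permuting genes
        # inside a window leaves the profile unchanged while swapping genes
        # across windows does not (window locality)
        catalog = lc.generate_gene_catalog(6, 8, seed=13)
        rng = np.random.default_rng(13)
        counts = rng.poisson(3.0, size=(12, 48)).astype(float)
        A = tiny_adata(counts, catalog)
        ref = list(A.obs_names[:5])
        base = lc.compute_cnv_profile(A, catalog, ref, window_size=20)
        assert base.values.shape[1] == 6       # one window per chromosome
        perm = np.arange(48)
        perm[:8] = rng.permutation(8)          # shuffle within chr1's window
        A2 = tiny_adata(counts[:, perm], catalog.copy())
        prof_p = lc.compute_cnv_profile(A2, catalog.copy(), ref, window_size=20)
        np.testing.assert_allclose(
            base.values.to_numpy(), prof_p.values.to_numpy(), atol=1e-10
        )
        perm2 = np.arange(48)
        perm2[0], perm2[47] = 47, 0            # swap across chromosomes
        A3 = tiny_adata(counts[:, perm2], catalog.copy())
        prof_s = lc.compute_cnv_profile(A3, catalog.copy(), ref, window_size=20)
        assert not np.allclose(
            base.values.to_numpy(), prof_s.values.to_numpy()
        )

    def test_library_scaling_invariance(self):
        # doubling every count in a cell changes its library but not its
        # CPM-normalized log expression, so the profile is unchanged
        catalog = lc.generate_gene_catalog(1, 60, seed=12)
        rng = np.random.default_rng(12)
        counts = rng.poisson(3.0, size=(12, 60)).astype(float)
        A1 = tiny_adata(counts, catalog)
        A2 = tiny_adata(counts * 2.0, catalog)
        ref = list(A1.obs_names[:5])
        p1 = lc.compute_cnv_profile(A1, catalog, ref, window_size=15)
        p2 = lc.compute_cnv_profile(A2, catalog, ref, window_size=15)
        np.testing.assert_allclose(
            p1.values.to_numpy(), p2.values.to_numpy(), atol=1e-10
        )

    def test_expected_value_ramp(self):
        # noiseless means with a 2x dosage block: interior windows sit at
        # ~log2(2)=1 above reference; the overlap ramps linearly
        catalog = lc.generate_gene_catalog(1, 400, seed=14)
        base = np.full(400, 50.0)
        mal = base.copy()
        mal[100:250] *= 2.0          # 150-gene amplified block
        counts = np.vstack([np.tile(base, (10, 1)), np.tile(mal, (10, 1))])
        A = tiny_adata(counts, catalog)
        ref = list(A.obs_names[:10])
        prof = lc.compute_cnv_profile(A, catalog, ref, window_size=100)
        w = prof.windows
        interior = w.index[(w["first_gene"] >= 100) & (w["last_gene"] <= 249)]
        outside = w.index[w["last_gene"] < 100]
        mal_rows = prof.values.iloc[10:]
        vals = mal_rows[interior].to_numpy()
        assert vals.std() < 1e-8          # interior plateau is flat
        # plateau sits log2(2) = 1 above fully outside windows (library
        # normalization shifts both equally, so the difference is exact)
        gap = vals.mean() - mal_rows[outside].to_numpy().mean()
        assert gap == pytest.approx(1.0, abs=0.02)
        # the 99-gene overlap ramps monotonically up to the plateau
        edge = w.index[(w["first_gene"] < 100) & (w["last_gene"] >= 100)]
        ramp = mal_rows[edge].mean(axis=0).to_numpy()
        assert (np.diff(ramp) > -1e-12).all()


class TestMalignancy:
    def test_cells_at_reference_mean_not_called(self):
        catalog = lc.generate_gene_catalog(1, 80, seed=15)
        rng = np.random.default_rng(15)
        counts = rng.poisson(5.0, size=(30, 80)).astype(float)
        A = tiny_adata(counts, catalog)
        ref = list(A.obs_names)
        prof = lc.compute_cnv_profile(A, catalog, ref, window_size=10)
        call = lc.call_malignancy(prof)
        # the least-deviant reference cells are never flagged
        assert (call.labels.loc[call.burden.nsmallest(10).index]
                == "non_malignant").all()
        assert (call.burden >= 0).all()

    def test_degenerate_reference_raises(self):
        catalog = lc.generate_gene_catalog(1, 30, seed=16)
        counts = np.full((6, 30), 2.0)
        A = tiny_adata(counts, catalog)
        prof = lc.compute_cnv_profile(A, catalog, list(A.obs_names), window_size=5)
        with pytest.raises(ValueError, match="reference"):
            lc.call_malignancy(prof)

    def test_burden_window_permutation_invariant(self, default_profile):
        prof, _ = default_profile
        call = lc.call_malignancy(prof)
        rng = np.random.default_rng(0)
        shuffled = prof.values.iloc[:, rng.permutation(prof.values.shape[1])]
        b2 = (shuffled ** 2).mean(axis=1)
        np.testing.assert_allclose(call.burden.to_numpy(), b2.to_numpy())


class TestSubclones:
    def test_k1_single_subclone(self, default_profile, default_cohort):
        prof, _ = default_profile
        _, _, adata, truth = default_cohort
        mal = truth.cell_subclone[truth.cell_subclone > 0].index[:50]
        asg = lc.cluster_subclones(prof, mal, k=1)
        assert set(asg.subclone) == {1}

    def test_k_exceeding_cells_rejected(self, default_profile, default_cohort):
        prof, _ = default_profile
        _, _, _, truth = default_cohort
        mal = truth.cell_subclone[truth.cell_subclone > 0].index[:5]
        with pytest.raises(ValueError):
            lc.cluster_subclones(prof, mal, k=10)

    def test_duplicate_cells_preserve_comembership(self):
        catalog = lc.generate_gene_catalog(1, 100, seed=17)
        rng = np.random.default_rng(17)
        base = np.full(100, 30.0)
        a = base.copy(); a[:40] *= 2
        b = base.copy(); b[60:] *= 2
        counts = np.vstack(
            [np.tile(base, (10, 1))]
            + [rng.poisson(a, (8, 100)), rng.poisson(b, (8, 100))]
        ).astype(float)
        A = tiny_adata(counts, catalog)
        ref = list(A.obs_names[:10])
        prof = lc.compute_cnv_profile(A, catalog, ref, window_size=20)
        mal = list(A.obs_names[10:])
        asg = lc.cluster_subclones(prof, mal, k=2)
        # duplicate every malignant cell's profile row
        dup = prof.values.loc[mal].copy()
        dup.index = [f"{c}_dup" for c in mal]
        prof2 = lc.CnvProfile(
            values=pd.concat([prof.values, dup]),
            windows=prof.windows, reference=prof.reference,
            window_size=prof.window_size, clamp=prof.clamp,
        )
        asg2 = lc.cluster_subclones(prof2, mal + list(dup.index), k=2)
        for c in mal:
            assert asg2.subclone[c] == asg2.subclone[f"{c}_dup"]
        same = asg.subclone.loc[mal].to_numpy()
        same2 = asg2.subclone.loc[mal].to_numpy()
        # original partition is preserved (up to label swap)
        agree = (same == same2).mean()
        assert agree in (0.0, 1.0) or agree > 0.99


class TestDriverScores:
    def test_amplified_subclone_scores_highest(self, default_profile,
                                               default_cohort):
        prof, _ = default_profile
        catalog, design, _, truth = default_cohort
        mal = truth.cell_subclone[truth.cell_subclone > 0]
        asg = lc.SubcloneAssignment(subclone=mal, k=4)
        # a driver inside subclone 2's private chr3 amplification
        driver = catalog.query("chromosome == 'chr3' and order_index == 100")[
            "gene_id"].iloc[0]
        res = lc.score_driver_genes(prof, asg, [driver], catalog)
        scores = res.scores[driver]
        assert scores.idxmax() == 2

    def test_missing_driver_warned_not_dropped(self, default_profile,
                                               default_cohort):
        prof, _ = default_profile
        catalog, _, _, truth = default_cohort
        mal = truth.cell_subclone[truth.cell_subclone > 0]
        asg = lc.SubcloneAssignment(subclone=mal, k=4)
        with pytest.warns(UserWarning, match="EGFR"):
            res = lc.score_driver_genes(prof, asg, ["EGFR"], catalog)
        assert res.missing == ["EGFR"]

    def test_zero_profile_zero_scores(self):
        catalog = lc.generate_gene_catalog(1, 30, seed=18)
        counts = np.full((8, 30), 3.0)
        A = tiny_adata(counts, catalog)
        prof = lc.compute_cnv_profile(A, catalog, list(A.obs_names), window_size=5)
        asg = lc.SubcloneAssignment(
            subclone=pd.Series([1] * 4, index=A.obs_names[:4]), k=1
        )
        res = lc.score_driver_genes(
            prof, asg, [catalog["gene_id"].iloc[10]], catalog
        )
        assert res.scores.to_numpy().flatten()[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_window_reduces_to_window_mean(self):
        catalog = lc.generate_gene_catalog(1, 8, seed=19)
        rng = np.random.default_rng(19)
        counts = rng.poisson(10.0, size=(10, 8)).astype(float)
        A = tiny_adata(counts, catalog)
        prof = lc.compute_cnv_profile(A, catalog, list(A.obs_names[:5]),
                                      window_size=20)
        assert prof.values.shape[1] == 1
        asg = lc.SubcloneAssignment(
            subclone=pd.Series([1] * 3, index=A.obs_names[5:8]), k=1
        )
        res = lc.score_driver_genes(prof, asg, [catalog["gene_id"].iloc[3]],
                                    catalog)
        expected = prof.values.iloc[5:8, 0].mean()
        assert res.scores.iloc[0, 0] == pytest.approx(expected, abs=1e-12)


class TestMalignantRatio:
    def test_plain_and_corrected_ratios(self):
        labels = pd.Series(
            ["malignant"] * 10 + ["non_malignant"] * 5 + ["malignant"] * 4,
            index=[f"c{i}" for i in range(19)],
        )
        types = pd.Series(
            ["AT2"] * 15 + ["NE"] * 4, index=labels.index
        )
        call = lc.MalignancyCall(
            burden=pd.Series(0.0, index=labels.index), labels=labels, threshold=0.0
        )
        out = lc.malignant_ratio(call, types)
        assert out.loc["AT2", "ratio"] == pytest.approx(2.0)
        assert not out.loc["AT2", "corrected"]
        assert out.loc["NE", "ratio"] == pytest.approx(9.0)
        assert bool(out.loc["NE", "corrected"])

    def test_dominant_malignant_type_ranks_first(self, default_profile,
                                                 default_cohort):
        # planted design: only AT2 and Basal carry events
        prof, _ = default_profile
        _, _, adata, _ = default_cohort
        call = lc.call_malignancy(prof)
        out = lc.malignant_ratio(call, adata.obs["cell_type"])
        top2 = set(out["ratio"].nlargest(2).index)
        assert top2 == {"AT2", "Basal"}
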