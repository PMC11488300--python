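"""Single-cell QC, rank-based scoring, correlation, mixture annotation,
and group comparison."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from senosig import (GeneSignature, QCThresholds, annotate_senescence,
                     compare_groups, correlate_scores, normalize_log,
                     qc_filter, score_cells, simulate_cells)
from senosig import CellScores, ScSimConfig
from senosig.errors import (ConfigurationError, SignatureNotPresentError,
                            UndefinedCorrelationError)

from conftest import SMALL_CELLS
from helpers import direct_pearson


def make_adata(counts, mito=None, groups=None):
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n_cells)])
    obs["mito_fraction"] = mito if mito is not None else 0.05
    if groups is not None:
        obs["group"] = groups
    return ad.AnnData(X=sparse.csr_matrix(counts), obs=obs,
                      var=pd.DataFrame(index=[f"g{j}"
                                              for j in range(n_genes)]))


class TestQC:
    def test_all_inside_window_is_identity(self):
        adata = make_adata(np.ones((5, 10)), mito=0.05)
        out, report = qc_filter(adata, QCThresholds(1, 100, 0.01, 0.2))
        assert out.n_obs == 5
        assert report["removed"] == {"genes_low": 0, "genes_high": 0,
                                     "mito_high": 0, "mito_low": 0}

    def test_planted_violators_removed_exactly(self, small_cells):
        adata, truth = small_cells
        cfg = SMALL_CELLS
        thr = QCThresholds(cfg.min_genes, cfg.max_genes, cfg.min_mito,
                           cfg.max_mito)
        out, report = qc_filter(adata, thr)
        assert report["removed"] == {"genes_low": 4, "genes_high": 4,
                                     "mito_high": 4, "mito_low": 4}
        assert report["retained"] == adata.n_obs - 16
        kept_truth = truth.cells.loc[out.obs_names]
        assert (kept_truth["qc_fail"] == "none").all()

    def test_boundary_cells_retained_under_strict_inequalities(self):
        counts = np.zeros((3, 10))
        counts[0, :2] = 1   # exactly min_genes detected
        counts[1, :5] = 1   # inside
        counts[2, :] = 1    # exactly max_genes detected
        mito = [0.01, 0.05, 0.2]  # exactly min_mito / inside / exactly max
        adata = make_adata(counts, mito=mito)
        out, report = qc_filter(adata, QCThresholds(2, 10, 0.01, 0.2))
        assert out.n_obs == 3

    def test_idempotent(self, small_cells):
        adata, _ = small_cells
        cfg = SMALL_CELLS
        thr = QCThresholds(cfg.min_genes, cfg.max_genes, cfg.min_mito,
                           cfg.max_mito)
        once, _ = qc_filter(adata, thr)
        twice, report = qc_filter(once, thr)
        assert twice.n_obs == once.n_obs
        assert sum(report["removed"].values()) == 0

    def test_attribution_order_first_failing_criterion(self):
        counts = np.zeros((1, 10))  # zero detected genes AND high mito
        adata = make_adata(counts, mito=0.9)
        _, report = qc_filter(adata, QCThresholds(2, 10, 0.01, 0.2))
        assert report["removed"]["genes_low"] == 1
        assert report["removed"]["mito_high"] == 0


class TestNormalize:
    def test_hand_computed_example(self):
        counts = np.array([[1, 2, 1], [0, 5, 5]])
        adata = make_adata(counts)
        out = normalize_log(adata, target_sum=4.0)
        norm = out.layers["lognorm"].toarray()
        assert np.allclose(norm[0], np.log1p([1.0, 2.0, 1.0]))
        assert np.allclose(norm[1], np.log1p([0.0, 2.0, 2.0]))

    def test_depth_invariance(self):
        counts = np.array([[1, 2, 3], [2, 4, 6]])
        adata = make_adata(counts)
        norm = normalize_log(adata).layers["lognorm"].toarray()
        assert np.allclose(norm[0], norm[1])

    def test_single_gene_cell_carries_target_sum(self):
        counts = np.array([[0, 7, 0]])
        norm = normalize_log(make_adata(counts),
                             target_sum=100.0).layers["lognorm"].toarray()
        assert norm[0, 1] == pytest.approx(np.log1p(100.0))

    def test_zero_count_cell_dropped_with_warning(self):
        counts = np.array([[1, 1, 1], [0, 0, 0]])
        with pytest.warns(UserWarning, match="zero-count"):
            out = normalize_log(make_adata(counts))
        assert out.n_obs == 1


class TestScoreCells:
    def test_top_ranks_score_one_and_clipped_score_zero(self):
        n_genes = 60
        counts = np.zeros((2, n_genes))
        counts[0, :3] = [30, 20, 10]   # signature at the very top
        counts[0, 3:] = 1
        counts[1, 3:] = np.arange(2, n_genes - 1)  # signature undetected
        adata = make_adata(counts)
        sig = GeneSignature("s", up=["g0", "g1", "g2"])
        scores = score_cells(adata, sig, r_max=20)
        assert scores.values.iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert scores.values.iloc[1] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_transform_invariance(self, small_cells):
        adata, truth = small_cells
        adata = normalize_log(adata)
        sig = GeneSignature("planted", up=truth.signature_genes)
        base = score_cells(adata, sig)
        warped = adata.copy()
        ln = warped.layers["lognorm"]
        ln = ln.toarray() if sparse.issparse(ln) else np.asarray(ln)
        warped.layers["lognorm"] = np.expm1(ln) + ln**2  # monotone warp
        again = score_cells(warped, sig)
        assert np.allclose(base.values, again.values)

    def test_senescent_cells_score_above_proliferating(self, small_cells):
        adata, truth = small_cells
        cfg = SMALL_CELLS
        thr = QCThresholds(cfg.min_genes, cfg.max_genes, cfg.min_mito,
                           cfg.max_mito)
        adata, _ = qc_filter(adata, thr)
        sig = GeneSignature("planted", up=truth.signature_genes)
        scores = score_cells(adata, sig)
        by_group = scores.values.groupby(adata.obs["group"],
                                         observed=True).mean()
        assert by_group["late"] > by_group["EP_prolif"]

    def test_absent_signature_raises(self, small_cells):
        adata, _ = small_cells
        sig = GeneSignature("ghost", up=["NOPE1", "NOPE2"])
        with pytest.raises(SignatureNotPresentError, match="ghost"):
            score_cells(adata, sig)

    def test_scores_in_unit_interval(self, small_cells):
        adata, truth = small_cells
        sig = GeneSignature("planted", up=truth.signature_genes)
        scores = score_cells(adata, sig)
        assert (scores.values >= 0).all() and (scores.values <= 1).all()


class TestCorrelation:
    def _scores(self, values, name="a"):
        idx = [f"c{i}" for i in range(len(values))]
        return CellScores(values=pd.Series(values, index=idx, name=name),
                          signature=name)

    def test_self_and_negated(self):
        x = np.random.default_rng(0).normal(size=50)
        a = self._scores(x)
        assert correlate_scores(a, self._scores(x, "b"))[0] == pytest.approx(1.0)
        assert correlate_scores(a, self._scores(-x, "b"))[0] == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.normal(size=40)
            y = 0.5 * x + rng.normal(size=40)
            r, _ = correlate_scores(self._scores(x), self._scores(y, "b"))
            assert r == pytest.approx(direct_pearson(x, y), abs=1e-12)

    def test_zero_variance_rejected(self):
        a = self._scores(np.ones(10))
        b = self._scores(np.arange(10.0), "b")
        with pytest.raises(UndefinedCorrelationError):
            correlate_scores(a, b)

    def test_planted_correlation_recovered(self, small_cells):
        adata, truth = small_cells
        cfg = SMALL_CELLS
        adata, _ = qc_filter(adata, QCThresholds(
            cfg.min_genes, cfg.max_genes, cfg.min_mito, cfg.max_mito))
        adata = normalize_log(adata)
        s1 = score_cells(adata, GeneSignature("sig",
                                              up=truth.signature_genes))
        s2 = score_cells(adata, GeneSignature("sasp", up=truth.sasp_genes))
        r, p = correlate_scores(s1, s2)
        assert r == pytest.approx(cfg.target_sasp_corr, abs=0.15)
        assert p < 1e-10


class TestAnnotate:
    def _scores(self, values):
        idx = [f"c{i}" for i in range(len(values))]
        return CellScores(values=pd.Series(values, index=idx, name="s"),
                          signature="s")

    def test_two_component_recovery(self):
        rng = np.random.default_rng(0)
        n = 1000
        z = rng.random(n) < 0.3
        x = np.where(z, rng.normal(3.0, 0.5, n), rng.normal(0.0, 0.5, n))
        call = annotate_senescence(self._scores(x), seed=0)
        assert call.fraction_senescent == pytest.approx(0.3, abs=0.05)
        assert not call.fallback
        assert call.component_means[1] > call.component_means[0]

    def test_constant_scores_fall_back_to_median_split(self):
        with pytest.warns(UserWarning, match="median"):
            call = annotate_senescence(self._scores(np.ones(40)), seed=0)
        assert call.fallback
        assert call.fraction_senescent == pytest.approx(0.5)

    def test_separation_grid_improves_recovery(self):
        rng = np.random.default_rng(1)
        n = 800
        z = rng.random(n) < 0.4
        errors = []
        for sep in (1.0, 2.5, 5.0):
            x = np.where(z, rng.normal(sep, 1.0, n),
                         rng.normal(0.0, 1.0, n))
            call = annotate_senescence(self._scores(x), seed=0)
            errors.append(abs(call.fraction_senescent - z.mean()))
        assert errors[2] <= errors[0]
        assert errors[2] < 0.02

    def test_too_few_cells_rejected(self):
        with pytest.raises(ConfigurationError):
            annotate_senescence(self._scores(np.arange(10.0)))

    def test_group_fractions_on_planted_lifespan(self, small_cells):
        adata, truth = small_cells
        cfg = SMALL_CELLS
        adata, _ = qc_filter(adata, QCThresholds(
            cfg.min_genes, cfg.max_genes, cfg.min_mito, cfg.max_mito))
        adata = normalize_log(adata)
        scores = score_cells(adata, GeneSignature(
            "sig", up=truth.signature_genes))
        call = annotate_senescence(scores, seed=0,
                                   groups=adata.obs["group"])
        for label, _, frac in cfg.groups:
            assert call.group_fractions[label] == pytest.approx(
                frac, abs=0.08)


class TestCompareGroups:
    def _scores_groups(self, arrays, labels):
        values = np.concatenate(arrays)
        groups = np.repeat(labels, [len(a) for a in arrays])
        idx = [f"c{i}" for i in range(values.size)]
        scores = CellScores(values=pd.Series(values, index=idx, name="s"),
                            signature="s")
        return scores, pd.Series(groups, index=idx)

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        scores, groups = self._scores_groups([x, x.copy()], ["a", "b"])
        summary, pairwise = compare_groups(scores, groups)
        assert pairwise["median_diff"].iloc[0] == pytest.approx(0.0)
        assert pairwise["p_adj"].iloc[0] > 0.9

    def test_monotone_group_means_on_planted_data(self, small_cells):
        adata, truth = small_cells
        adata = normalize_log(adata)
        scores = score_cells(adata, GeneSignature(
            "sig", up=truth.signature_genes))
        summary, pairwise = compare_groups(scores, adata.obs["group"])
        means = summary.set_index("group")["mean"]
        assert means["EP_prolif"] < means["mid"] < means["late"]
        assert (pairwise["p_adj"] < 0.01).all()

    def test_small_groups_excluded_with_warning(self):
        rng = np.random.default_rng(4)
        scores, groups = self._scores_groups(
            [rng.normal(size=30), rng.normal(size=2),
             rng.normal(1.0, 1.0, 30)], ["a", "tiny", "b"])
        with pytest.warns(UserWarning, match="tiny"):
            summary, _ = compare_groups(scores, groups)
        assert set(summary["group"]) == {"a", "b"}
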