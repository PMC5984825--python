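"""Pathway algebra, signature scoring/testing, and the random-set null."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from cortexsig import io, preprocess, signatures, simulate
from cortexsig.exceptions import FitError
from conftest import make_meta


def _geneset(name, genes):
    return io.GeneSet(name, frozenset(genes))


def _log2(raw):
    return preprocess.log2_transform(raw, floor=1e-12)


class TestBuildPathway:
    def test_intersection_then_exclusion(self):
        spec = signatures.PathwaySpec(
            base=frozenset({"g1", "g2", "g3", "g4", "g5"}),
            include=frozenset({"g4", "g5", "g6"}),
            exclusions=(frozenset({"g4"}),))
        assert signatures.build_pathway(spec).genes == frozenset({"g5"})

    def test_no_exclusions_is_plain_intersection(self):
        spec = signatures.PathwaySpec(base=frozenset({"g1", "g2"}),
                                      include=frozenset({"g2", "g3"}))
        assert signatures.build_pathway(spec).genes == frozenset({"g2"})

    def test_disjoint_include_errors_with_guidance(self):
        spec = signatures.PathwaySpec(base=frozenset({"g1"}), include=frozenset({"g9"}))
        with pytest.raises(ValueError, match="empty"):
            signatures.build_pathway(spec)


class TestSignatureScores:
    def test_single_gene_pathway_is_that_row(self, toy_expr):
        score = signatures.signature_scores(toy_expr, _geneset("p", ["g1"]))
        pd.testing.assert_series_equal(score.values, toy_expr.loc["g1"],
                                       check_names=False)

    def test_two_gene_mean(self, toy_expr):
        score = signatures.signature_scores(toy_expr, _geneset("p", ["g1", "g2"]))
        np.testing.assert_allclose(score.values, [2.5, 2.5, 2.5, 2.5])

    def test_gene_order_irrelevant_and_extra_genes_ignored(self, toy_expr):
        a = signatures.signature_scores(toy_expr, _geneset("p", ["g1", "g2"]))
        bigger = pd.concat([toy_expr, toy_expr.rename(index=lambda g: g + "_x")])
        b = signatures.signature_scores(bigger, _geneset("p", ["g2", "g1"]))
        pd.testing.assert_series_equal(a.values, b.values)

    def test_missing_genes_tracked(self, toy_expr):
        score = signatures.signature_scores(toy_expr, _geneset("p", ["g1", "zz"]))
        assert score.genes_used == ("g1",)
        assert score.genes_requested == ("g1", "zz")

    def test_zero_overlap_errors(self, toy_expr):
        with pytest.raises(ValueError):
            signatures.signature_scores(toy_expr, _geneset("p", ["zz"]))


class TestSignatureTtest:
    def test_identical_groups_t_zero_p_one(self):
        meta = make_meta([f"s{i}" for i in range(8)], ["autism"] * 4 + ["control"] * 4)
        vals = pd.Series([1.0, 2.0, 3.0, 4.0] * 2, index=meta.index)
        score = signatures.SignatureScore("p", vals, ("g",), ("g",))
        t, p = signatures.signature_ttest(score, meta)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_small_group_rejected(self):
        meta = make_meta(["a", "b", "c"], ["autism", "control", "control"])
        score = signatures.SignatureScore(
            "p", pd.Series([1.0, 2.0, 3.0], index=meta.index), ("g",), ("g",))
        with pytest.raises(ValueError):
            signatures.signature_ttest(score, meta)

    def test_power_against_planted_downshift(self):
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            sets = simulate.planted_defaults(300, delta_mito=-0.5, loading=0.0)
            cfg = simulate.SimConfig(n_genes=300, planted_sets=sets, noise_sd=0.3,
                                     seed=6000 + seed)
            raw, _, meta, truth = simulate.generate_dataset(cfg)
            score = signatures.signature_scores(
                _log2(raw), _geneset("m", truth.delta.index[:50]))
            _, p = signatures.signature_ttest(score, meta)
            hits += p < 0.05
        assert hits / n_rep >= 0.90

    def test_subject_collapse_halves_observations(self):
        cfg = simulate.default_config(n_genes=200, seed=0)
        raw, _, meta, truth = simulate.generate_dataset(cfg)
        score = signatures.signature_scores(_log2(raw), _geneset("m", truth.delta.index[:50]))
        t_pooled, _ = signatures.signature_ttest(score, meta)
        t_collapsed, _ = signatures.signature_ttest(score, meta, collapse_subjects=True)
        assert t_pooled != t_collapsed  # both defined, different resolutions


class TestSignatureLogistic:
    def test_known_slope_recovered_at_large_n(self):
        slopes = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = 400
            x = rng.normal(0, 1, n)
            y = rng.random(n) < expit(0.2 + 1.5 * x)
            meta = make_meta([f"s{i}" for i in range(n)],
                             np.where(y, "autism", "control"), seed=seed)
            score = signatures.SignatureScore(
                "p", pd.Series(x, index=meta.index), ("g",), ("g",))
            coef, _ = signatures.signature_logistic(score, meta, covariates=())
            slopes.append(coef)
        assert abs(np.mean(slopes) - 1.5) < 0.3

    def test_orthogonal_covariates_leave_coefficient(self):
        rng = np.random.default_rng(3)
        n = 200
        x = rng.normal(0, 1, n)
        y = rng.random(n) < expit(x)
        meta = make_meta([f"s{i}" for i in range(n)],
                         np.where(y, "autism", "control"), seed=3)
        score = signatures.SignatureScore("p", pd.Series(x, index=meta.index), ("g",), ("g",))
        plain, _ = signatures.signature_logistic(score, meta, covariates=())
        adjusted, _ = signatures.signature_logistic(score, meta,
                                                    covariates=("RIN", "PMI", "age"))
        assert adjusted == pytest.approx(plain, rel=0.15)

    def test_null_coefficient_rarely_significant(self):
        quiet = 0
        n_rep = 50
        for seed in range(n_rep):
            cfg = simulate.null_config(n_genes=300, seed=7000 + seed)
            raw, _, meta, truth = simulate.generate_dataset(cfg)
            score = signatures.signature_scores(
                _log2(raw), _geneset("m", truth.delta.index[:50]))
            covs = ("RIN", "PMI", "age", "sex", "region")
            if meta["sex"].nunique() == 1:  # degenerate all-male draw
                covs = ("RIN", "PMI", "age", "region")
            _, p = signatures.signature_logistic(score, meta, covariates=covs)
            quiet += p > 0.0455  # |z| < 2
        assert quiet / n_rep >= 0.90

    def test_complete_separation_raises(self):
        meta = make_meta([f"s{i}" for i in range(20)],
                         ["autism"] * 10 + ["control"] * 10)
        vals = pd.Series(np.r_[np.ones(10), np.zeros(10)], index=meta.index)
        score = signatures.SignatureScore("p", vals, ("g",), ("g",))
        with pytest.raises(FitError):
            signatures.signature_logistic(score, meta, covariates=())


class TestPathwayCorrelation:
    def _score(self, vals, index):
        return signatures.SignatureScore("p", pd.Series(vals, index=index), ("g",), ("g",))

    def test_self_and_negated_and_affine(self):
        idx = ["a", "b", "c"]
        s = self._score([1.0, 2.0, 3.0], idx)
        assert signatures.pathway_correlation(s, s) == pytest.approx(1.0)
        assert signatures.pathway_correlation(
            s, self._score([-1.0, -2.0, -3.0], idx)) == pytest.approx(-1.0)
        assert signatures.pathway_correlation(
            s, self._score([2.0, 4.0, 6.0], idx)) == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        idx = ["a", "b", "c"]
        with pytest.raises(ValueError):
            signatures.pathway_correlation(self._score([1.0, 1.0, 1.0], idx),
                                           self._score([1.0, 2.0, 3.0], idx))

    def test_mismatched_samples_rejected(self):
        a = self._score([1.0, 2.0, 3.0], ["a", "b", "c"])
        b = self._score([1.0, 2.0, 3.0], ["a", "c", "b"])
        with pytest.raises(ValueError):
            signatures.pathway_correlation(a, b)


@pytest.fixture(scope="module")
def dataset():
    cfg = simulate.default_config(n_genes=500, seed=42)
    raw, _, meta, truth = simulate.generate_dataset(cfg)
    return _log2(raw), truth


class TestRandomSetNull:

    def test_same_seed_bitwise_identical(self, dataset):
        m, truth = dataset
        mito = _geneset("m", truth.delta.index[:50])
        syn = _geneset("s", truth.delta.index[50:150])
        a = signatures.random_set_null(m, mito, syn, B=700, seed=9)
        b = signatures.random_set_null(m, mito, syn, B=700, seed=9)
        np.testing.assert_array_equal(a.null_r, b.null_r)
        assert a.exceed_frac == b.exceed_frac

    def test_reference_equal_fixed_gives_zero_exceedance(self, dataset):
        m, truth = dataset
        mito = _geneset("m", truth.delta.index[:50])
        res = signatures.random_set_null(m, mito, mito, B=500, seed=1)
        assert res.observed_r == pytest.approx(1.0)
        assert res.exceed_frac == 0.0

    def test_affine_rescaling_of_samples_preserves_exceedance(self, dataset):
        """Pearson r is affine invariant, so a global affine map of the
        matrix leaves every correlation, and hence the exceedance, unchanged."""
        m, truth = dataset
        mito = _geneset("m", truth.delta.index[:50])
        syn = _geneset("s", truth.delta.index[50:150])
        a = signatures.random_set_null(m, mito, syn, B=400, seed=3)
        b = signatures.random_set_null(2.5 * m + 1.0, mito, syn, B=400, seed=3)
        assert a.exceed_frac == b.exceed_frac
        np.testing.assert_allclose(a.null_r, b.null_r, atol=1e-12)

    def test_oversized_reference_rejected(self, dataset):
        m, truth = dataset
        mito = _geneset("m", truth.delta.index[:50])
        huge = _geneset("h", [f"x{i}" for i in range(600)])
        with pytest.raises(ValueError):
            signatures.random_set_null(m, mito, huge, B=10, seed=0)

    def test_null_sets_have_reference_size(self, dataset):
        m, truth = dataset
        mito = _geneset("m", truth.delta.index[:50])
        syn = _geneset("s", truth.delta.index[50:150])
        res = signatures.random_set_null(m, mito, syn, B=50, seed=0)
        assert res.set_size == 100

    def test_permutation_p_add_one_convention(self, dataset):
        m, truth = dataset
        mito = _geneset("m", truth.delta.index[:50])
        res = signatures.random_set_null(m, mito, mito, B=99, seed=0)
        assert res.permutation_p() == pytest.approx(1 / 100)
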