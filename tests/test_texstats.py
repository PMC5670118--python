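"""Texture statistics, transforms, PCA, regression and LMG decomposition."""

import itertools

import numpy as np
import pytest

from texsig import texstats
from texsig.stimuli import GrayImage
from texsig.texstats import (FilterBank, StatDesignMatrix, compute_texture_stats,
                             groupwise_pca, lmg_contributions,
                             signed_sqrt_zscore)

BANK = FilterBank(n_scales=3, base_wavelength=3.0)


class TestComputeTextureStats:
    def test_group_sizes_match_closed_form_and_content_free(self):
        sizes = BANK.group_sizes()
        rng = np.random.default_rng(0)
        for seed in range(2):
            img = GrayImage(rng.standard_normal((64, 64)))
            groups = compute_texture_stats(img, BANK)
            assert [g.group for g in groups] == list(texstats.GROUP_NAMES)
            for g in groups:
                assert len(g.values) == sizes[g.group]

    def test_white_noise_orientation_correlations_near_zero(self):
        rs = []
        for seed in range(20):
            img = GrayImage(
                np.random.default_rng(seed).standard_normal((128, 128)))
            g = {s.group: s.values for s in compute_texture_stats(img, BANK)}
            rs.append(np.abs(g["en_orientation"]).mean())
        assert np.mean(rs) < 0.1

    def test_scale_duplication_raises_cross_scale_correlation(self):
        # an image whose coarse scale literally duplicates its fine scale
        # must show stronger adjacent-scale correlation than white noise
        def coupled(seed):
            rng = np.random.default_rng(seed)
            fine = rng.standard_normal((64, 64))
            lam = BANK.wavelengths[0]
            yy, xx = np.mgrid[0:64, 0:64]
            g1 = np.cos(2 * np.pi * xx / lam)
            g2 = np.cos(2 * np.pi * xx / (2 * lam))
            env = np.where(fine > 1.0, 1.0, 0.0)
            return GrayImage(env * (g1 + g2) + 0.1 * rng.standard_normal((64, 64)))

        coupled_vals, noise_vals = [], []
        for seed in range(10):
            g = {s.group: s.values
                 for s in compute_texture_stats(coupled(seed), BANK)}
            coupled_vals.append(g["en_scale"].mean())
            img = GrayImage(
                np.random.default_rng(seed + 99).standard_normal((64, 64)))
            g = {s.group: s.values for s in compute_texture_stats(img, BANK)}
            noise_vals.append(g["en_scale"].mean())
        assert np.mean(coupled_vals) > np.mean(noise_vals) + 0.1

    def test_constant_image_marginals_flagged_zero(self):
        img = GrayImage(np.full((64, 64), 1.0))
        groups = compute_texture_stats(img, BANK)
        marg = groups[0]
        assert marg.group == "marginal"
        assert marg.degenerate
        np.testing.assert_array_equal(marg.values, 0.0)

    def test_small_image_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            compute_texture_stats(GrayImage(np.zeros((16, 16))), BANK)

    def test_position_stats_invariant_to_grating_phase_shift(self):
        # the mechanism that preserves position statistics under phase
        # scrambling: shifting a grating's phase leaves them unchanged
        yy, xx = np.mgrid[0:128, 0:128]
        vals = []
        for phase in (0.0, 1.1, 2.7):
            img = GrayImage(np.cos(2 * np.pi * 10 * xx / 128 + phase))
            g = {s.group: s.values for s in compute_texture_stats(img, BANK)}
            vals.append(g["en_position"])
        # invariance is exact in the infinite image; borders leave a small
        # residual
        np.testing.assert_allclose(vals[0], vals[1], atol=0.05)
        np.testing.assert_allclose(vals[0], vals[2], atol=0.05)


class TestSignedSqrtZscore:
    def test_hand_example(self):
        z, rec = signed_sqrt_zscore(np.array([[4.0, 1.0], [-4.0, 2.0]]))
        np.testing.assert_allclose(z[:, 0], [1.0, -1.0])

    def test_columns_standardized(self):
        rng = np.random.default_rng(0)
        raw = rng.standard_normal((40, 7)) * 10
        z, _ = signed_sqrt_zscore(raw)
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(z.std(axis=0), 1, atol=1e-10)

    def test_constant_column_dropped_and_recorded(self):
        raw = np.column_stack([np.ones(5), np.arange(5.0)])
        z, rec = signed_sqrt_zscore(raw)
        assert z.shape[1] == 1
        assert list(rec.dropped) == [0]

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            signed_sqrt_zscore(np.ones((1, 3)))


class TestGroupwisePca:
    def test_rank_one_group_gives_single_component(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(30)
        raw = np.column_stack([base * c for c in (1.0, 2.0, -0.5)])
        z, rec = signed_sqrt_zscore(raw)
        design = groupwise_pca(z, {"spectral": (0, z.shape[1])})
        a, b = design.group_spans["spectral"]
        assert b - a == 1
        assert design.variance_retained["spectral"] > 0.999

    def test_iid_columns_need_about_ninety_percent(self):
        k = 10
        counts = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            z = rng.standard_normal((400, k))
            z = (z - z.mean(0)) / z.std(0)
            d = groupwise_pca(z, {"spectral": (0, k)}, var_threshold=0.9)
            a, b = d.group_spans["spectral"]
            counts.append(b - a)
        assert abs(np.mean(counts) - int(np.ceil(0.9 * k))) <= 1

    def test_scores_standardized_and_variance_recorded(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal((50, 6))
        z = (z - z.mean(0)) / z.std(0)
        d = groupwise_pca(z, {"marginal": (0, 2), "spectral": (2, 6)})
        np.testing.assert_allclose(d.scores.mean(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(d.scores.std(axis=0), 1, atol=1e-8)
        for g in ("marginal", "spectral"):
            assert d.variance_retained[g] > 0.9

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            groupwise_pca(np.zeros((5, 2)), {"marginal": (0, 2)},
                          var_threshold=1.5)


def _design(scores, spans):
    return StatDesignMatrix(scores=scores, group_spans=spans, transform=None,
                            variance_retained={g: 1.0 for g in spans})


class TestPmiRegression:
    def test_perfect_fit_when_target_is_design_column(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 4))
        d = _design(X, {"a": (0, 2), "b": (2, 4)})
        fit = texstats.fit_pmi_regression(d, X[:, 1].copy())
        assert fit.rsquared > 1 - 1e-10

    def test_null_r2_matches_columns_over_rows(self):
        # under independence E[R^2] ~ p/(n-1)
        n, p = 100, 5
        r2 = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((n, p))
            y = rng.standard_normal(n)
            fit = texstats.fit_pmi_regression(
                _design(X, {"a": (0, p)}), y)
            r2.append(fit.rsquared)
        assert abs(np.mean(r2) - p / (n - 1)) < 0.02

    def test_two_points_one_column_interpolates(self):
        d = _design(np.array([[0.0], [1.0]]), {"a": (0, 1)})
        fit = texstats.fit_pmi_regression(d, np.array([3.0, 7.0]))
        np.testing.assert_allclose(fit.fittedvalues, [3.0, 7.0], atol=1e-10)

    def test_rank_deficient_design_reported(self):
        X = np.ones((10, 2))
        X[:, 1] = np.arange(10)
        X = np.column_stack([X, X[:, 1]])   # duplicated column
        with pytest.raises(ValueError, match="dependent columns"):
            texstats.fit_pmi_regression(
                _design(X, {"a": (0, 3)}), np.arange(10.0))


def _brute_force_lmg(X, y, spans):
    """Independent oracle: average R^2 increments over explicitly
    enumerated orderings."""
    groups = list(spans)
    contrib = {g: 0.0 for g in groups}
    orders = list(itertools.permutations(groups))
    for order in orders:
        used = []
        prev = 0.0
        for g in order:
            used.append(g)
            cols = np.concatenate([np.arange(*spans[h]) for h in used])
            r2 = texstats._subset_r2(X, y, cols)
            contrib[g] += r2 - prev
            prev = r2
    return {g: c / len(orders) for g, c in contrib.items()}


class TestLmg:
    def test_single_group_gets_everything(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 3))
        y = X @ [1.0, -2.0, 0.5] + 0.1 * rng.standard_normal(30)
        out = lmg_contributions(_design(X, {"a": (0, 3)}), y)
        assert out == {"a": pytest.approx(100.0)}

    def test_orthogonal_groups_split_by_marginal_r2(self):
        n = 4000
        rng = np.random.default_rng(6)
        xa = rng.standard_normal(n)
        xb = rng.standard_normal(n)
        y = 2.0 * xa + 1.0 * xb
        d = _design(np.column_stack([xa, xb]), {"a": (0, 1), "b": (1, 2)})
        raw = lmg_contributions(d, y, as_percent=False)
        # brute force over both orderings: orthogonal predictors make each
        # group's contribution equal its own marginal R^2
        ra = texstats._subset_r2(d.scores, y, np.array([0]))
        rb = texstats._subset_r2(d.scores, y, np.array([1]))
        assert abs(raw["a"] - ra) < 0.01
        assert abs(raw["b"] - rb) < 0.01

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_subset_identity_matches_all_orderings(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((40, 6))
        y = X @ rng.standard_normal(6) + rng.standard_normal(40)
        spans = {"a": (0, 2), "b": (2, 3), "c": (3, 6)}
        d = _design(X, spans)
        fast = lmg_contributions(d, y, as_percent=False)
        slow = _brute_force_lmg(X, y, spans)
        for g in spans:
            assert abs(fast[g] - slow[g]) < 1e-10

    def test_contributions_sum_to_full_r2_and_are_order_invariant(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((50, 8))
        y = X @ rng.standard_normal(8) + rng.standard_normal(50)
        spans1 = {"a": (0, 3), "b": (3, 5), "c": (5, 8)}
        d1 = _design(X, spans1)
        raw = lmg_contributions(d1, y, as_percent=False)
        full = texstats._subset_r2(X, y, np.arange(8))
        assert abs(sum(raw.values()) - full) < 1e-8
        pct = lmg_contributions(d1, y)
        assert abs(sum(pct.values()) - 100.0) < 1e-8
        # permuting group order leaves per-group values unchanged
        X2 = np.column_stack([X[:, 5:8], X[:, 0:3], X[:, 3:5]])
        d2 = _design(X2, {"c": (0, 3), "a": (3, 6), "b": (6, 8)})
        raw2 = lmg_contributions(d2, y, as_percent=False)
        for g in raw:
            assert abs(raw[g] - raw2[g]) < 1e-10

    def test_too_many_groups_refused(self):
        X = np.random.default_rng(0).standard_normal((40, 13))
        spans = {f"g{i}": (i, i + 1) for i in range(13)}
        with pytest.raises(ValueError, match="refused"):
            lmg_contributions(_design(X, spans), X[:, 0])


class TestGroupCorrelation:
    def test_identical_roles_give_unit_correlation(self, small_corpus):
        from texsig.stimuli import StimulusCorpus, StimulusPair
        pairs = [StimulusPair(cm=p.sm, sm=p.sm, pair_id=p.pair_id)
                 for p in small_corpus.pairs]
        corpus = StimulusCorpus(pairs=pairs,
                                n_families=small_corpus.n_families,
                                n_per_family=small_corpus.n_per_family)
        out = texstats.group_correlation_cm_sm(corpus, BANK)
        for g, rec in out.items():
            if not rec["degenerate"]:
                assert rec["r"] == pytest.approx(1.0, abs=1e-10)

    def test_position_exceeds_scale_on_scramble_corpus(self, small_corpus):
        out = texstats.group_correlation_cm_sm(small_corpus, BANK)
        pos = (out["lin_position"]["r"] + out["en_position"]["r"]) / 2
        sca = (out["lin_scale"]["r"] + out["en_scale"]["r"]) / 2
        assert pos > sca

    def test_noise_corpus_correlations_near_zero(self):
        from texsig.stimuli import GrayImage, StimulusCorpus, StimulusPair
        rng = np.random.default_rng(8)
        pairs = []
        for k in range(16):
            a = GrayImage(rng.standard_normal((64, 64)), family_id=1)
            b = GrayImage(rng.standard_normal((64, 64)), family_id=1)
            pairs.append(StimulusPair(cm=a, sm=b, pair_id=k))
        corpus = StimulusCorpus(pairs=pairs, n_families=1, n_per_family=16)
        out = texstats.group_correlation_cm_sm(corpus, BANK)
        rs = [abs(rec["r"]) for rec in out.values()
              if not rec["degenerate"]]
        assert np.mean(rs) < 0.45

    def test_too_few_pairs_rejected(self, small_corpus):
        from texsig.stimuli import StimulusCorpus
        tiny = StimulusCorpus(pairs=small_corpus.pairs[:4], n_families=1,
                              n_per_family=4)
        with pytest.raises(ValueError):
            texstats.group_correlation_cm_sm(tiny, BANK)
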