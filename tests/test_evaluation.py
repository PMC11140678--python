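"""Leave-two-out pairwise evaluation, LOO reconstruction, and SNR."""

import numpy as np
import pytest

from cortrack.containers import EvokedSet
from cortrack.decoders import lag_window_ms
from cortrack.evaluation import (
    PairwiseEngine,
    classify_pair,
    enumerate_splits,
    equalize_pair_lengths,
    estimate_snr,
    loo_reconstruction,
    run_cv,
)

LAGS = lag_window_ms(20, 420)


class TestSplits:
    @pytest.mark.parametrize("n,expected", [(44, 946), (8, 28), (3, 3)])
    def test_counts(self, n, expected):
        splits = enumerate_splits(n)
        assert len(splits) == expected
        assert len(set(splits)) == expected
        assert all(i < j for i, j in splits)

    def test_too_few(self):
        with pytest.raises(ValueError):
            enumerate_splits(2)


class TestEqualize:
    def test_truncates_to_shorter(self):
        f1, f2 = np.ones((2, 81)), np.ones((2, 92))
        a, b = equalize_pair_lengths(f1, f2)
        assert a.shape[-1] == b.shape[-1] == 81

    def test_equal_lengths_unchanged_and_leading_frames_kept(self):
        rng = np.random.default_rng(0)
        f1, f2 = rng.random((1, 10)), rng.random((1, 7))
        a, b = equalize_pair_lengths(f1, f2)
        np.testing.assert_array_equal(a, f1[:, :7])
        np.testing.assert_array_equal(b, f2)
        with pytest.raises(ValueError):
            equalize_pair_lengths(np.empty((1, 0)), f2)


class TestClassifyPair:
    def test_identity_reconstruction_correct(self):
        rng = np.random.default_rng(1)
        s1, s2 = rng.random(20), rng.random(20)
        assert classify_pair(s1, s2, s1, s2).correct == 1.0
        assert classify_pair(s1, s2, s2, s1).correct == 0.0

    def test_hand_example(self):
        s1 = np.array([1.0, 2.0, 3.0])
        s2 = np.array([3.0, 1.0, 2.0])
        p1 = np.array([1.0, 2.0, 2.5])
        p2 = np.array([2.5, 1.0, 2.0])
        out = classify_pair(s1, s2, p1, p2)
        # oracle: the four Pearson correlations computed independently
        sims = [
            np.corrcoef(a, b)[0, 1]
            for a, b in ((s1, p1), (s2, p2), (s1, p2), (s2, p1))
        ]
        np.testing.assert_allclose(out.sims, sims, atol=1e-12)
        assert (sims[0] + sims[1] > sims[2] + sims[3]) == (out.correct == 1.0)
        assert out.correct == 1.0

    def test_swap_invariance(self):
        rng = np.random.default_rng(2)
        s1, s2, p1, p2 = (rng.random(15) for _ in range(4))
        a = classify_pair(s1, s2, p1, p2).correct
        b = classify_pair(s2, s1, p2, p1).correct
        assert a == b

    def test_tie_scores_half(self):
        s1, s2 = np.array([1.0, 2.0, 4.0]), np.array([4.0, 2.0, 1.0])
        p = np.array([1.0, 3.0, 5.0])
        assert classify_pair(s1, s2, p, p).correct == 0.5

    def test_zero_variance_similarity_is_zero(self):
        s1, s2 = np.array([1.0, 2.0, 3.0]), np.array([3.0, 2.0, 1.0])
        flat = np.ones(3)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            out = classify_pair(s1, s2, flat, s2)
        assert out.sims[0] == 0.0


def test_random_reconstructions_near_chance():
    """Stimulus-independent reconstructions decode at ~50%."""
    rng = np.random.default_rng(3)
    accs = []
    for _ in range(25):
        s = rng.random((16, 30))
        p = rng.random((16, 30))
        outs = [classify_pair(s[i], s[j], p[i], p[j]) for i, j in enumerate_splits(16)]
        accs.append(100 * np.mean([o.correct for o in outs]))
    assert abs(np.mean(accs) - 50.0) < 4.0


class TestRunCV:
    def test_noise_free_perfect_accuracy(self, noisefree_cohort):
        c = noisefree_cohort
        res = run_cv(
            c.evoked[0],
            c.stimuli.envelopes,
            LAGS,
            lambda_mode="once",
            standardize=False,
        )
        assert res.accuracy == 100.0
        assert res.n_pairs == len(enumerate_splits(c.spec.n_stimuli))

    def test_accuracy_resolution_and_outcomes(self, small_noisy_cohort):
        c = small_noisy_cohort
        res = run_cv(c.evoked[0], c.stimuli.envelopes, LAGS, lambda_mode="once")
        assert res.n_pairs == 28
        fractional = res.accuracy / 100 * res.n_pairs
        assert fractional == pytest.approx(round(fractional * 2) / 2, abs=1e-9)
        assert len(res.outcomes) == res.n_pairs

    def test_per_split_lambda_matches_once_on_clean_data(self, noisefree_cohort):
        """With a dominant grid optimum both selection modes coincide."""
        c = noisefree_cohort
        a = run_cv(
            c.evoked[0],
            c.stimuli.envelopes,
            lag_window_ms(80, 160),
            grid=(1e-3, 1e-1, 1e1),
            lambda_mode="per-split",
            standardize=False,
        )
        b = run_cv(
            c.evoked[0],
            c.stimuli.envelopes,
            lag_window_ms(80, 160),
            grid=(1e-3, 1e-1, 1e1),
            lambda_mode="once",
            standardize=False,
        )
        assert a.accuracy == b.accuracy == 100.0

    def test_downdating_equals_explicit_refit(self, small_noisy_cohort):
        """The engine's per-split solution equals training from scratch."""
        from cortrack.decoders import build_lagged_design, ridge_primal
        from cortrack.features import standardize_responses, standardize_time_varying

        c = small_noisy_cohort
        ev = c.evoked[0]
        lam = 10.0
        eng = PairwiseEngine(ev, c.stimuli.envelopes, LAGS, lambda_mode="once")
        res = eng.accuracy(lambdas=[lam], return_reconstructions=True)

        feats, _ = standardize_time_varying(
            [np.atleast_2d(e) for e in c.stimuli.envelopes]
        )
        data, _ = standardize_responses(ev.data)
        i, j = 2, 5
        keep = [n for n in range(ev.n_stimuli) if n not in (i, j)]
        design = build_lagged_design(
            [data[n] for n in keep],
            LAGS,
            ev.rate,
            [feats[k].shape[-1] for k in keep],
            ev.onset,
        )
        S = np.concatenate([np.atleast_2d(feats[k]).T for k in keep])
        W = ridge_primal(design.matrix, S, lam)
        from cortrack.decoders import lag_matrix

        L = min(feats[i].shape[-1], feats[j].shape[-1])
        p1 = (lag_matrix(data[i], LAGS, ev.rate, L, ev.onset) @ W).T
        got = res.reconstructions[(i, j)][0]
        np.testing.assert_allclose(got, p1, atol=1e-8)


def test_strict_standardization_mode_runs(small_noisy_cohort):
    """Training-fold-only standardization gives a valid accuracy and
    the same result as the fast engine when standardization is fixed."""
    c = small_noisy_cohort
    lags = np.arange(20.0, 230.0, 10.0)
    strict = run_cv(c.evoked[0], c.stimuli.envelopes, lags, standardize="train-only")
    assert 0.0 <= strict.accuracy <= 100.0
    assert strict.n_pairs == 28


class TestLOOReconstruction:
    def test_noise_free_near_exact(self, noisefree_cohort):
        c = noisefree_cohort
        r = loo_reconstruction(
            c.evoked[0], c.stimuli.envelopes, LAGS, standardize=False
        )
        assert np.all(r > 0.99)

    def test_pure_noise_near_zero_and_bounded(self):
        rng = np.random.default_rng(4)
        feats = [rng.random(40) for _ in range(14)]
        noise = EvokedSet(rng.standard_normal((14, 6, 90)), 100.0, onset=10)
        r = loo_reconstruction(noise, feats, LAGS, lambdas=[10.0])
        assert np.all((r >= -1) & (r <= 1))
        assert abs(r.mean()) < 0.15


def test_reconstruction_degrades_with_noise():
    """Mean LOO reconstruction correlation falls as sensor noise grows."""
    from cortrack.synthetic import CohortSpec, generate_cohort

    means = []
    for nsd in (0.0, 16.0, 48.0, 96.0):
        spec = CohortSpec(n_per_group=1, n_stimuli=8, n_sensors=4, n_bands=16, seed=5)
        c = generate_cohort(spec, 1.0, noise_sd=nsd)
        means.append(
            loo_reconstruction(
                c.evoked[0], c.stimuli.envelopes, LAGS, standardize=False
            ).mean()
        )
    assert np.all(np.diff(means) < 0)


def test_leave_two_out_and_loo_rank_participants_alike():
    """The two cross-validation schemes order participants consistently
    (Spearman rho > 0.8 across a 17 + 17 cohort)."""
    import scipy.stats

    from cortrack.synthetic import CohortSpec, generate_cohort

    spec = CohortSpec(n_per_group=17, n_stimuli=8, n_sensors=4, n_bands=16, seed=77)
    c = generate_cohort(spec, deficit_factor=0.3)
    l2o, l1o = [], []
    for ev in c.evoked:
        l2o.append(run_cv(ev, c.stimuli.envelopes, LAGS, lambda_mode="once").accuracy)
        l1o.append(loo_reconstruction(ev, c.stimuli.envelopes, LAGS).mean())
    assert scipy.stats.spearmanr(l2o, l1o).statistic > 0.8


class TestSNR:
    def _evoked(self, gain, seed=5):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((6, 4, 100))
        data[:, :, 30:80] += gain * np.sin(np.arange(50) / 4)
        return EvokedSet(data, 100.0, onset=30)

    def test_pure_noise_near_unity(self):
        snr = estimate_snr(self._evoked(0.0))
        assert snr == pytest.approx(1.0, abs=0.05)

    def test_monotone_in_amplitude(self):
        s = [estimate_snr(self._evoked(g)) for g in (0.0, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(s) > 0)
        assert np.isfinite(s[-1]) and s[-1] > 0

    def test_zero_baseline_variance_rejected(self):
        data = np.zeros((3, 2, 50))
        data[:, :, 20:] = 1.0
        with pytest.raises(ValueError, match="baseline"):
            estimate_snr(EvokedSet(data, 100.0, onset=20))
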