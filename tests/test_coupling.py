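"""Cross-correlation, coupling metric, and permutation-null contracts."""

import itertools

import numpy as np
import pytest
from scipy.stats import pearsonr

from boldcsf.core import SessionSignals
from boldcsf.coupling import (
    _lagged_corr_matrix,
    coupling_strength,
    crosscorr,
    crosscorr_derivative,
    permutation_null,
    session_mean_ccf,
)
from boldcsf.extraction import negative_derivative

from conftest import cosine_session


def brute_force_ccf(g, f, max_lag_seconds, tr_seconds):
    """Independent oracle: explicit shift, trim, and Pearson at each lag."""
    k_max = int(round(max_lag_seconds / tr_seconds))
    out = []
    n = len(g)
    for k in range(-k_max, k_max + 1):
        if k >= 0:
            a, b = g[k:], f[: n - k]
        else:
            a, b = g[: n + k], f[-k:]
        out.append(pearsonr(a, b)[0])
    return np.array(out)


class TestCrossCorr:
    def test_matches_bruteforce_loop(self, rng):
        for _ in range(20):
            g = rng.standard_normal(130)
            f = rng.standard_normal(130)
            ccf = crosscorr(g, f, 21.0, 3.0)
            np.testing.assert_allclose(ccf.r, brute_force_ccf(g, f, 21.0, 3.0), atol=1e-12)
            assert np.all(np.abs(ccf.r) <= 1)

    def test_lag_zero_is_plain_pearson(self, rng):
        g, f = rng.standard_normal(130), rng.standard_normal(130)
        ccf = crosscorr(g, f, 21.0, 3.0)
        assert ccf.r_at(0.0) == pytest.approx(pearsonr(g, f)[0], abs=1e-12)

    def test_identity_has_unit_correlation_at_zero(self, rng):
        g = rng.standard_normal(130)
        assert crosscorr(g, g, 21.0, 3.0).r_at(0.0) == pytest.approx(1.0)

    def test_swapping_series_reflects_lag_axis(self, rng):
        g, f = rng.standard_normal(130), rng.standard_normal(130)
        a = crosscorr(g, f, 21.0, 3.0)
        b = crosscorr(f, g, 21.0, 3.0)
        np.testing.assert_allclose(a.r, b.r[::-1], atol=1e-12)

    def test_cosine_fixture_fine_grid(self):
        """Analytic law CC(τ) = −sin(2π(τ+3)/20): extrema at +2 s and −8 s
        on a 1 s grid."""
        g, f = cosine_session(tr_seconds=1.0, duration=400.0, dt=0.5)
        ccf = crosscorr(g, f, 9.0, 1.0)
        assert ccf.lags_seconds[np.argmin(ccf.r)] == 2.0
        assert ccf.r_at(2.0) < -0.99
        assert ccf.lags_seconds[np.argmax(ccf.r)] == -8.0
        assert ccf.r_at(-8.0) > 0.99

    def test_cosine_fixture_tr_grid(self):
        """Same fixture at TR = 3 s: CC(+3) = −sin(2π·6/20) ≈ −0.951."""
        g, f = cosine_session(tr_seconds=3.0, duration=420.0)
        ccf = crosscorr(g, f, 9.0, 3.0)
        assert ccf.r_at(3.0) == pytest.approx(-0.951, abs=0.02)
        assert ccf.lags_seconds[np.argmin(ccf.r)] == 3.0
        peak_lag = ccf.lags_seconds[np.argmax(ccf.r)]
        assert peak_lag < 0 and ccf.r.max() > 0.9

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            crosscorr(np.ones(130), np.arange(130.0), 21.0, 3.0)

    def test_length_shortfall_rejected(self):
        with pytest.raises(ValueError):
            crosscorr(np.arange(10.0), np.arange(10.0), 21.0, 3.0)


class TestDerivativeCcf:
    def test_constructed_inflow_peaks_at_minus_delay(self, rng):
        g = np.cumsum(rng.standard_normal(200)) / 10
        gd = negative_derivative(g, 3.0)
        k = 2  # 6 s delay on the TR grid
        f = np.concatenate([np.full(k, gd[0]), gd[: len(g) - k]])
        ccf = crosscorr_derivative(g, f, 21.0, 3.0)
        assert ccf.lags_seconds[np.argmax(ccf.r)] == -6.0
        assert ccf.r.max() > 0.95

    def test_positive_derivative_flips_sign(self, rng):
        g = np.cumsum(rng.standard_normal(200)) / 10
        gd = negative_derivative(g, 3.0)
        f = np.concatenate([[gd[0]], gd])
        trough = crosscorr_derivative(g, -f, 21.0, 3.0)
        peak = crosscorr_derivative(g, f, 21.0, 3.0)
        np.testing.assert_allclose(trough.r, -peak.r, atol=1e-12)

    def test_white_noise_pair_stays_small(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ccf = crosscorr_derivative(rng.standard_normal(190), rng.standard_normal(190), 21.0, 3.0)
            assert np.max(np.abs(ccf.r)) < 0.3


class TestCouplingStrength:
    def test_default_lag_is_one_tr(self):
        g, f = cosine_session(tr_seconds=3.0, duration=420.0)
        ccf = crosscorr(g, f, 9.0, 3.0)
        assert coupling_strength(ccf) == ccf.r_at(3.0)

    def test_invariant_to_rescaling(self, rng):
        g, f = rng.standard_normal(130), rng.standard_normal(130)
        a = coupling_strength(crosscorr(g, f, 21.0, 3.0))
        b = coupling_strength(crosscorr(g, 10 * f + 3, 21.0, 3.0))
        assert a == pytest.approx(b, abs=1e-12)

    def test_missing_lag_raises(self, rng):
        ccf = crosscorr(rng.standard_normal(130), rng.standard_normal(130), 21.0, 3.0)
        with pytest.raises(ValueError, match="lag"):
            coupling_strength(ccf, lag_seconds=1.5)


class TestSessionMean:
    def test_single_session(self, rng):
        ccf = crosscorr(rng.standard_normal(130), rng.standard_normal(130), 21.0, 3.0)
        lags, mean, sem = session_mean_ccf([ccf])
        np.testing.assert_array_equal(mean, ccf.r)
        assert np.all(np.isnan(sem))

    def test_opposite_sessions_cancel(self, rng):
        g, f = rng.standard_normal(130), rng.standard_normal(130)
        a = crosscorr(g, f, 21.0, 3.0)
        b = crosscorr(g, -f, 21.0, 3.0)
        _, mean, _ = session_mean_ccf([a, b])
        np.testing.assert_allclose(mean, 0.0, atol=1e-12)

    def test_mismatched_grids_rejected(self, rng):
        a = crosscorr(rng.standard_normal(130), rng.standard_normal(130), 21.0, 3.0)
        b = crosscorr(rng.standard_normal(130), rng.standard_normal(130), 9.0, 3.0)
        with pytest.raises(ValueError, match="lag grid"):
            session_mean_ccf([a, b])

    def test_coupled_cohort_reproduces_expected_shape(self, default_cohort):
        """Session-mean CCF of coupled sessions: a negative extremum within
        one TR of +3 s and a positive extremum at a negative lag."""
        lags, mean, _ = session_mean_ccf(default_cohort["ccfs"])
        neg_lag = lags[np.argmin(mean)]
        pos_lag = lags[np.argmax(mean)]
        assert abs(neg_lag - 3.0) <= 3.0
        assert pos_lag < 0


def _make_sessions(rng, n_sessions, n_t=60, coupled=False):
    out = []
    for _ in range(n_sessions):
        g = rng.standard_normal(n_t)
        # coupled mode: F leads G by one TR, so CC peaks at the +1 TR lag
        f = 0.8 * np.roll(g, -1) + 0.2 * rng.standard_normal(n_t) if coupled else rng.standard_normal(n_t)
        out.append(SessionSignals(g, f, tr_seconds=3.0))
    return out


class TestPermutationNull:
    def test_pairwise_matrix_matches_naive_recomputation(self, rng):
        sessions = _make_sessions(rng, 4, 130)
        G = np.vstack([s.global_bold for s in sessions])
        F = np.vstack([s.csf for s in sessions])
        for k in (-3, 0, 2):
            M = _lagged_corr_matrix(G, F, k)
            for j in range(4):
                for i in range(4):
                    expected = brute_force_ccf(G[j], F[i], 21.0, 3.0)[k + 7]
                    assert M[j, i] == pytest.approx(expected, abs=1e-12)

    def test_three_session_null_matches_exhaustive_enumeration(self, rng):
        """With 3 sessions every draw of the sampler must land on one of the
        3! enumerable permutation means."""
        sessions = _make_sessions(rng, 3, 60)
        G = np.vstack([s.global_bold for s in sessions])
        F = np.vstack([s.csf for s in sessions])
        ks = np.arange(-7, 8)
        mats = np.stack([_lagged_corr_matrix(G, F, int(k)) for k in ks])
        enumerated = np.array(
            [mats[:, list(perm), [0, 1, 2]].mean(axis=1) for perm in itertools.permutations(range(3))]
        )  # (6, n_lags)
        permutation_null(sessions, n_permutations=60, max_lag_seconds=21.0, seed=5)
        # re-draw the same permutations to inspect individual samples
        rng2 = np.random.default_rng(5)
        for _ in range(60):
            perm = rng2.permutation(3)
            sample = mats[:, perm, [0, 1, 2]].mean(axis=1)
            dists = np.abs(enumerated - sample).max(axis=1)
            assert dists.min() < 1e-12

    def test_observed_mean_is_identity_pairing(self, rng):
        sessions = _make_sessions(rng, 5, 130, coupled=True)
        null = permutation_null(sessions, 50, 21.0, seed=1)
        ccfs = [crosscorr(s.global_bold, s.csf, 21.0, 3.0) for s in sessions]
        _, mean, _ = session_mean_ccf(ccfs)
        np.testing.assert_allclose(null.observed_mean, mean, atol=1e-12)

    def test_p_floor_for_extreme_observation(self, rng):
        sessions = _make_sessions(rng, 8, 130, coupled=True)
        null = permutation_null(sessions, 200, 21.0, seed=2)
        assert np.all(null.p >= 1 / 201)
        assert np.all(null.p <= 1)
        # strong zero-ish-lag coupling should beat every permuted pairing
        idx = list(null.lags_seconds).index(3.0)
        assert null.p[idx] <= 0.05

    def test_deterministic_given_seed(self, rng):
        sessions = _make_sessions(rng, 4, 130)
        a = permutation_null(sessions, 100, 21.0, seed=9)
        b = permutation_null(sessions, 100, 21.0, seed=9)
        np.testing.assert_array_equal(a.p, b.p)
        np.testing.assert_array_equal(a.null_lo, b.null_lo)

    def test_unequal_lengths_truncate_to_shortest(self, rng):
        s1 = SessionSignals(rng.standard_normal(190), rng.standard_normal(190), 3.0)
        s2 = SessionSignals(rng.standard_normal(130), rng.standard_normal(130), 3.0)
        null = permutation_null([s1, s2], 50, 21.0, seed=3)
        assert null.p.size == 15  # ran on the common 130-sample window

    def test_single_session_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_null(_make_sessions(rng, 1, 130), 10, 21.0, seed=0)
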