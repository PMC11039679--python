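import numpy as np
import pytest
from hypothesis import given, strategies as st

from redoxtf.events import (
    ActivationThresholds,
    detect_foxo1_episodes,
    detect_p53_onset,
    p53_rate,
    smooth_trace,
)

from conftest import synthetic_trace

TH = ActivationThresholds()
DT = 1.0 / 3.0


def grid(n):
    return np.arange(n) * DT


# ---------------------------------------------------------------------------
# brute-force oracles, written independently of the implementations
# ---------------------------------------------------------------------------

def oracle_episodes(t, f, hi, lo, k):
    """Exhaustive scan over frame runs (observed frames only)."""
    idx = [i for i in range(len(f)) if np.isfinite(f[i])]
    tv = [t[i] for i in idx]
    fv = [f[i] for i in idx]
    n = len(fv)
    episodes = []
    state_in = False
    i = 0
    while i < n:
        if not state_in:
            if all(j < n and fv[j] >= hi for j in range(i, i + k)):
                entry = tv[i]
                state_in = True
            i += 1
        else:
            if all(j < n and fv[j] <= lo for j in range(i, i + k)):
                episodes.append((entry, tv[i]))
                state_in = False
            i += 1
    if state_in:
        episodes.append((entry, None))
    return episodes


def oracle_onset(t, p, thr, run, after):
    idx = [i for i in range(len(p)) if np.isfinite(p[i]) and t[i] >= after]
    for pos in range(len(idx)):
        window = idx[pos : pos + run]
        if len(window) < run:
            break
        if all(p[j] > thr for j in window):
            return t[idx[pos]]
    return None


class TestSmoothTrace:
    def test_constant_series_unchanged(self):
        x = np.full(10, 0.4)
        np.testing.assert_array_equal(smooth_trace(x), x)

    def test_single_frame_spike_removed(self):
        x = np.full(10, 0.2)
        x[4] = 0.9
        assert smooth_trace(x)[4] == pytest.approx(0.2)

    def test_monotone_series_stays_monotone(self):
        x = np.linspace(0, 1, 15)
        s = smooth_trace(x)
        assert np.all(np.diff(s) >= -1e-12)

    def test_missing_values_propagate(self):
        x = np.array([0.1, np.nan, 0.3, 0.4])
        s = smooth_trace(x)
        assert np.isnan(s[1]) and np.isfinite(s[0]) and np.isfinite(s[2])

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            smooth_trace(np.zeros(5), width=4)


class TestFoxoEpisodes:
    def test_constructed_step_episode(self):
        # step 0.3 -> 0.8 on [2 h, 6 h): entry 2 h, exit 6 h, duration 4 h
        t = grid(73)
        f = np.where((t >= 2.0 - 1e-9) & (t < 6.0 - 1e-9), 0.8, 0.3)
        ep = detect_foxo1_episodes(synthetic_trace("s", t, f, np.full_like(t, 100.0)), TH)
        assert ep.n_episodes == 1
        entry, exit_ = ep.episodes[0]
        assert entry == pytest.approx(2.0)
        assert exit_ == pytest.approx(6.0)
        assert ep.nuclear_duration == pytest.approx(4.0)

    def test_flat_inactive_trace_has_no_episodes(self):
        t = grid(30)
        ep = detect_foxo1_episodes(
            synthetic_trace("f", t, np.full_like(t, 0.3), np.full_like(t, 100.0)), TH
        )
        assert ep.n_episodes == 0 and ep.nuclear_duration == 0.0

    def test_open_episode_counts_to_last_observed_frame(self):
        t = grid(30)
        f = np.where(t >= 3.0 - 1e-9, 0.8, 0.2)
        f[-5:] = np.nan  # death truncation
        ep = detect_foxo1_episodes(
            synthetic_trace("o", t, f, np.full_like(t, 100.0)), TH
        )
        assert ep.n_episodes == 1 and ep.exit_time is None
        assert ep.nuclear_duration == pytest.approx(t[24] - 3.0)

    def test_all_missing_series_flagged(self):
        t = grid(10)
        ep = detect_foxo1_episodes(
            synthetic_trace("m", t, np.full_like(t, np.nan), np.full_like(t, np.nan)), TH
        )
        assert ep.all_missing and ep.n_episodes == 0

    def test_matches_bruteforce_on_random_traces(self):
        rng = np.random.default_rng(99)
        t = grid(60)
        for _ in range(200):
            base = rng.choice([0.2, 0.5, 0.8], size=len(t), p=[0.5, 0.2, 0.3])
            f = np.clip(base + rng.normal(0, 0.05, len(t)), 0, 1)
            if rng.random() < 0.3:
                f[rng.integers(10, 59):] = np.nan
            tr = synthetic_trace("r", t, f, np.full_like(t, 100.0))
            got = detect_foxo1_episodes(tr, TH, smooth_width=1)  # no smoothing
            expected = oracle_episodes(t, f, TH.foxo_hi, TH.foxo_lo, TH.persistence)
            assert len(got.episodes) == len(expected)
            for (ge, gx), (oe, ox) in zip(got.episodes, expected):
                assert ge == pytest.approx(oe)
                if ox is None:
                    assert gx is None
                else:
                    assert gx == pytest.approx(ox)

    @given(
        seed=st.integers(0, 500),
        eps=st.floats(0.001, 0.049),
    )
    def test_hysteresis_robust_to_small_perturbations(self, seed, eps):
        # perturbations smaller than (hi - lo) / 2 applied to values already
        # between the thresholds cannot change the episode calls
        rng = np.random.default_rng(seed)
        t = grid(40)
        f = rng.choice([0.2, 0.8], size=len(t), p=[0.6, 0.4])
        mid = (TH.foxo_hi + TH.foxo_lo) / 2
        f_mid = np.where(rng.random(len(t)) < 0.3, mid, f)
        tr1 = synthetic_trace("h1", t, f_mid, np.full_like(t, 100.0))
        bumped = f_mid + np.where(f_mid == mid, eps * rng.choice([-1, 1], len(t)), 0.0)
        tr2 = synthetic_trace("h2", t, bumped, np.full_like(t, 100.0))
        e1 = detect_foxo1_episodes(tr1, TH, smooth_width=1)
        e2 = detect_foxo1_episodes(tr2, TH, smooth_width=1)
        assert e1.episodes == e2.episodes

    def test_duration_complement_consistency(self, pop_bolus80):
        # duration computed from episodes equals duration from the
        # above-threshold indicator on the smoothed closed-episode regions
        from redoxtf.trace_io import iter_traces

        for tr in list(iter_traces(pop_bolus80))[:40]:
            ep = detect_foxo1_episodes(tr, TH)
            total = sum(
                ((tr.last_observed_time if x is None else x) - e)
                for e, x in ep.episodes
            )
            assert ep.nuclear_duration == pytest.approx(total)


class TestP53Onset:
    def test_flat_then_ramp_onset_within_one_frame(self):
        t = grid(73)
        p = np.where(t < 8.0, 100.0, 100.0 + 60.0 * (t - 8.0))
        on = detect_p53_onset(synthetic_trace("r", t, np.full_like(t, 0.1), p), TH)
        assert on.onset_time is not None
        assert abs(on.onset_time - 8.0) <= DT + 1e-9

    def test_flat_trace_no_onset(self):
        t = grid(40)
        on = detect_p53_onset(
            synthetic_trace("f", t, np.full_like(t, 0.1), np.full_like(t, 100.0)), TH
        )
        assert on.onset_time is None

    def test_missing_baseline_rejected(self):
        t = grid(10)
        p = np.full_like(t, 100.0)
        p[1] = np.nan
        with pytest.raises(ValueError, match="baseline"):
            detect_p53_onset(synthetic_trace("b", t, np.full_like(t, 0.1), p), TH)

    def test_after_argument_skips_early_rises(self):
        t = grid(73)
        p = 100.0 + 80.0 * np.exp(-0.5 * (t - 4.0) ** 2) + 60.0 * np.maximum(t - 15.0, 0)
        tr = synthetic_trace("a", t, np.full_like(t, 0.1), p)
        early = detect_p53_onset(tr, TH, after=0.0)
        late = detect_p53_onset(tr, TH, after=10.0)
        assert early.onset_time < late.onset_time
        assert late.onset_time >= 10.0

    def test_matches_bruteforce_on_random_traces(self):
        rng = np.random.default_rng(7)
        t = grid(60)
        for _ in range(200):
            p = 100.0 * np.exp(rng.normal(0, 0.05, len(t)))
            if rng.random() < 0.6:
                start = rng.uniform(2, 15)
                p = p + np.maximum(t - start, 0) * rng.uniform(20, 80)
            if rng.random() < 0.2:
                p[rng.integers(20, 59):] = np.nan
            tr = synthetic_trace("r", t, np.full_like(t, 0.1), p)
            got = detect_p53_onset(tr, TH)
            base = np.median(p[:3])
            mad = 1.4826 * np.median(np.abs(p[:3] - base))
            thr = base + TH.p53_mad_mult * max(mad, TH.p53_rel_floor * base)
            expected = oracle_onset(t, p, thr, TH.onset_run, 0.0)
            if expected is None:
                assert got.onset_time is None
            else:
                assert got.onset_time == pytest.approx(expected)


class TestP53Rate:
    def test_linear_ramp_recovers_slope(self):
        t = grid(40)
        tr = synthetic_trace("l", t, np.full_like(t, 0.1), 50.0 + 3.0 * t)
        r = p53_rate(tr)
        np.testing.assert_allclose(r[1:-1], 3.0, rtol=1e-9)

    def test_constant_series_zero_rate(self):
        t = grid(20)
        r = p53_rate(synthetic_trace("c", t, np.full_like(t, 0.1), np.full_like(t, 80.0)))
        np.testing.assert_allclose(r, 0.0, atol=1e-12)

    def test_sinusoid_matches_analytic_derivative(self):
        t = grid(73)
        period = 6.0
        w = 2 * np.pi / period
        tr = synthetic_trace("s", t, np.full_like(t, 0.1), 100.0 + 30.0 * np.sin(w * t))
        r = p53_rate(tr)
        analytic = 30.0 * w * np.cos(w * t)
        bound = 30.0 * w**3 * DT**2 / 6.0  # central-difference truncation error
        assert np.nanmax(np.abs(r[1:-1] - analytic[1:-1])) < bound * 1.05

    def test_missing_propagates_and_short_series_all_missing(self):
        t = grid(10)
        p = 100.0 + 3.0 * t
        p[4] = np.nan
        r = p53_rate(synthetic_trace("m", t, np.full_like(t, 0.1), p))
        assert np.isnan(r[4])
        p2 = np.full_like(t, np.nan)
        p2[0] = 100.0
        r2 = p53_rate(synthetic_trace("m2", t, np.full_like(t, 0.1), p2))
        assert np.all(np.isnan(r2))
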