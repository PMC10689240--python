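import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from socialphot.metrics import (
    StatsConfig,
    behavior_mean_fz,
    bh_fdr,
    compute_peth,
    decay_time,
    introduction_peak,
    percent_responsive,
    pointwise_onesample_fdr,
    preference_index,
    presentation_peak,
    session_mean_fz,
    trial_responses,
)


def _bh_oracle(p, q):
    """Literal step-up definition: k* = max{k : p_(k) <= k q / m}."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    return set(order[:k_star].tolist())


class TestPETH:
    def test_constant_trace_gives_flat_peth_zero_sem(self, make_fz, make_bouts):
        fz = make_fz(np.full(2500, 1.7))
        bouts = make_bouts([("male", "investigation", 20.0, 24.0),
                            ("male", "investigation", 40.0, 44.0)])
        p = compute_peth((fz, bouts), stimulus="male", window_pre=5, window_post=5)
        assert np.allclose(p.mean, 1.7)
        assert np.allclose(p.sem, 0.0)
        assert p.n_animals == 1 and p.n_trials == 2

    def test_peak_time_matches_kernel_argmax(self, make_fz, make_bouts):
        fs = 25.0
        x = np.zeros(5000)
        kernel = np.concatenate([np.linspace(0, 1, 25), np.linspace(1, 0, 75)])
        onsets = [50.0, 90.0, 130.0]
        for on in onsets:
            i = int(on * fs)
            x[i : i + kernel.size] += kernel
        fz = make_fz(x, fs=fs)
        bouts = make_bouts([("male", "investigation", on, on + 4.0) for on in onsets])
        p = compute_peth((fz, bouts), stimulus="male", window_pre=2, window_post=6,
                         bin_width=0.2)
        peak_bin = p.time[np.nanargmax(p.mean)]
        assert abs(peak_bin - 1.0) <= 0.2  # kernel argmax at +1 s

    def test_no_matching_bouts_flags_empty(self, make_fz, make_bouts):
        fz = make_fz(np.zeros(100))
        bouts = make_bouts([("male", "attack", 1.0, 2.0)])
        p = compute_peth((fz, bouts), behavior="mount")
        assert p.empty and p.n_trials == 0


class TestScalarMetrics:
    def test_introduction_peak_finds_spike(self, make_fz):
        x = np.zeros(25 * 300)
        x[int(25 * (50 + 30))] = 4.2  # spike at intro + 30 s
        fz = make_fz(x)
        assert introduction_peak(fz, 50.0) == 4.2

    def test_introduction_peak_window_boundary(self, make_fz):
        x = np.zeros(25 * 300)
        x[int(25 * (50 + 150))] = 9.0  # outside [intro, intro+100)
        fz = make_fz(x)
        assert introduction_peak(fz, 50.0) == 0.0
        with pytest.raises(ValueError, match="intro_time"):
            introduction_peak(fz, 400.0)

    def test_monotone_decreasing_peak_at_intro(self, make_fz):
        fz = make_fz(np.linspace(5, 0, 25 * 200))
        assert np.isclose(introduction_peak(fz, 10.0), fz.fz[int(10.0 * 25)])

    def test_presentation_peak_averages_per_bout_maxima(self, make_fz, make_bouts):
        fs = 25.0
        x = np.zeros(int(fs * 300))
        for k, on in enumerate([10.0, 60.0, 110.0, 160.0, 210.0]):
            x[int(on * fs) + 5] = k + 1.0
        fz = make_fz(x, fs=fs)
        bouts = make_bouts([("male", "introduction", on, on + 10.0)
                            for on in [10.0, 60.0, 110.0, 160.0, 210.0]])
        assert np.isclose(presentation_peak(fz, bouts), 3.0)

    def test_all_negative_trace_matches_brute_force(self, make_fz, make_bouts):
        rng = np.random.default_rng(4)
        x = -1.0 - rng.random(int(25.0 * 100))
        fz = make_fz(x)
        rows = [("male", "introduction", 10.0, 20.0), ("male", "introduction", 40.0, 50.0)]
        bouts = make_bouts(rows)
        expected = np.mean([
            np.max(x[int(on * 25) : int(off * 25)]) for _, _, on, off in rows
        ])
        assert np.isclose(presentation_peak(fz, bouts), expected)

    def test_behavior_mean_is_bout_weighted(self, make_fz, make_bouts):
        fs = 25.0
        x = np.zeros(int(fs * 100))
        x[int(10 * fs) : int(11 * fs)] = 0.0    # 1-s bout, mean 0
        x[int(20 * fs) : int(28 * fs)] = 2.0    # 8-s bout, mean 2
        fz = make_fz(x, fs=fs)
        bouts = make_bouts([("male", "investigation", 10.0, 11.0),
                            ("male", "investigation", 20.0, 28.0)])
        assert np.isclose(behavior_mean_fz(fz, bouts, "investigation", "male"), 1.0)

    def test_session_mean_square_wave_and_brute_force(self, make_fz):
        fs = 25.0
        x = np.tile([1.0, -1.0], 1250)
        fz = make_fz(x, fs=fs)
        assert abs(session_mean_fz(fz, (0.0, 100.0))) < 1e-12
        sel = (fz.time >= 10.0) & (fz.time < 60.0)
        assert np.isclose(session_mean_fz(fz, (10.0, 60.0)), x[sel].sum() / sel.sum())
        with pytest.raises(ValueError, match="window"):
            session_mean_fz(fz, (500.0, 600.0))


class TestTrialResponses:
    def test_crossing_latency(self, make_fz, make_bouts):
        fs = 25.0
        x = np.zeros(int(fs * 60))
        on = 10.0
        ramp = np.linspace(0, 2, int(2 * fs))  # reaches 1 at +1.0 s... slope 1/s
        i = int(on * fs)
        x[i : i + ramp.size] = ramp
        fz = make_fz(x, fs=fs)
        bouts = make_bouts([("male", "investigation", on, on + 3.0)])
        res = trial_responses(fz, bouts, "investigation", "male")
        assert res.trials["responded"].iloc[0]
        # ramp value 1 is first reached at ~1.0 s after onset
        assert abs(res.trials["latency_s"].iloc[0] - 1.0) <= 1.5 / fs

    def test_threshold_boundary_not_responded(self, make_fz, make_bouts):
        fs = 25.0
        x = np.zeros(int(fs * 30))
        x[int(10 * fs) + 5] = 0.99
        fz = make_fz(x, fs=fs)
        bouts = make_bouts([("male", "investigation", 10.0, 12.0)])
        res = trial_responses(fz, bouts, "investigation", "male")
        assert not res.trials["responded"].iloc[0]
        assert np.isnan(res.trials["latency_s"].iloc[0])

    def test_latency_bounds_property(self, make_fz, make_bouts):
        rng = np.random.default_rng(8)
        fz = make_fz(rng.normal(0, 0.8, int(25.0 * 400)))
        rows, t = [], 5.0
        while t < 380:
            dur = rng.uniform(1, 6)
            rows.append(("male", "investigation", t, t + dur))
            t += dur + rng.uniform(1, 4)
        res = trial_responses(fz, make_bouts(rows), "investigation", "male")
        ok = res.trials["responded"]
        lat = res.trials.loc[ok, "latency_s"]
        dur = (res.trials["offset_s"] - res.trials["onset_s"])[ok]
        assert (lat >= 0).all() and (lat <= dur + 1e-9).all()
        assert 0 <= res.percent_responsive <= 100

    def test_pooled_vs_per_animal_modes(self, make_fz, make_bouts):
        fs = 25.0
        x = np.zeros(int(fs * 40))
        x[int(5 * fs) + 2] = 3.0
        fz = make_fz(x, fs=fs)
        hit = trial_responses(fz, make_bouts([("male", "investigation", 5.0, 7.0)]),
                              "investigation", "male")
        miss = trial_responses(fz, make_bouts([("male", "investigation", 20.0, 22.0)]),
                               "investigation", "male")
        assert percent_responsive([hit, miss], "pooled") == 50.0
        assert percent_responsive([hit, miss], "per_animal") == 50.0


class TestPreferenceIndex:
    def test_exclusive_response(self):
        assert preference_index({"male": 1.0, "female": 0.0, "pup": 0.0}, "male").pi == 1.0

    def test_symmetric_response_is_zero(self):
        pi = preference_index({"male": 0.7, "female": 0.7, "pup": 0.7}, "male")
        assert abs(pi.pi) < 1e-12

    def test_printed_formula_arithmetic(self):
        pi = preference_index({"male": 2.0, "female": 1.0, "pup": 1.0}, "male")
        assert np.isclose(pi.pi, 1.0 / 3.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        zm=st.floats(-5, 5), zf=st.floats(-5, 5), zp=st.floats(-5, 5),
        scale=st.floats(0.01, 10),
    )
    def test_bounds_and_scale_invariance(self, zm, zf, zp, scale):
        z = {"male": zm, "female": zf, "pup": zp}
        pi = preference_index(z, "male")
        if pi.defined:
            assert -1 - 1e-9 <= pi.pi <= 1 + 1e-9
            scaled = preference_index({k: scale * v for k, v in z.items()}, "male")
            assert np.isclose(pi.pi, scaled.pi, atol=1e-9)

    def test_zero_denominator_undefined(self):
        pi = preference_index({"male": 0.0, "female": 1.0, "pup": -1.0}, "male")
        assert not pi.defined

    def test_missing_stimulus_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            preference_index({"male": 1.0, "female": 0.0}, "male")


class TestFDR:
    def test_worked_example_rejects_two_smallest(self):
        rej = bh_fdr(np.array([0.01, 0.02, 0.04, 0.2]), q=0.05)
        assert set(rej.tolist()) == {0, 1}

    def test_degenerate_vectors(self):
        assert bh_fdr(np.ones(5), 0.05).size == 0
        assert set(bh_fdr(np.zeros(5), 0.05).tolist()) == {0, 1, 2, 3, 4}

    def test_matches_bruteforce_oracle_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            n = rng.integers(1, 11)
            p = np.round(rng.random(n), 3)
            q = rng.choice([0.01, 0.05, 0.1, 0.25])
            assert set(bh_fdr(p, q).tolist()) == _bh_oracle(p, q)

    def test_monotone_in_q(self):
        rng = np.random.default_rng(12)
        p = rng.random(20)
        prev = set()
        for q in (0.01, 0.05, 0.1, 0.2, 0.5):
            cur = set(bh_fdr(p, q).tolist())
            assert prev <= cur
            prev = cur

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError, match="0, 1"):
            bh_fdr(np.array([0.5, 1.2]), 0.05)


class TestPointwise:
    def test_all_zero_matrix_flags_nothing(self):
        assert not pointwise_onesample_fdr(np.zeros((5, 20))).any()

    def test_single_strong_bin_flagged(self):
        rng = np.random.default_rng(13)
        m = rng.normal(0, 0.01, (8, 40))
        m[:, 13] = 10.0
        mask = pointwise_onesample_fdr(m)
        assert mask[13] and mask.sum() == 1

    def test_negative_deflections_never_flagged(self):
        rng = np.random.default_rng(14)
        m = rng.normal(0, 0.01, (8, 40))
        m[:, 5] = -10.0
        assert not pointwise_onesample_fdr(m)[5]

    def test_single_animal_rejected(self):
        with pytest.raises(ValueError, match="two animals"):
            pointwise_onesample_fdr(np.zeros((1, 10)))

    def test_q_validation(self):
        with pytest.raises(ValueError, match="q"):
            StatsConfig(q=1.5)


def test_decay_time_recovers_exponential_constant():
    tau = 2.0
    t = np.arange(-50, 150) * 0.1
    y = np.where(t < 0, 1.0, np.exp(-np.maximum(t, 0) / tau))
    from socialphot.metrics import PETHResult
    p = PETHResult(t, [], np.atleast_2d(y), y, np.zeros_like(y), "offset")
    assert abs(decay_time(p) - tau * np.log(10)) < 0.1
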