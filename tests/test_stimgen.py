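"""Stimulus-stream generation: trial schedules, block composition, train summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tempopred import stimgen
from tempopred.stimgen import Condition, Validity, generate_block, generate_trial


class TestGenerateTrial:
    def test_rhythmic_short_valid_schedule(self, rng):
        t = generate_trial("Rhythmic", 700, "valid", 4, rng)
        assert t.onsets == [
            (0, "stream_black"), (700, "stream_black"), (1400, "stream_black"),
            (2100, "stream_black"), (2800, "ws"), (3500, "target"),
        ]

    def test_invalid_target_at_other_soa(self, rng):
        t = generate_trial("Rhythmic", 700, "invalid", 4, rng)
        assert t.target_time == t.ws_time + 1300
        t = generate_trial("Rhythmic", 1300, "invalid", 5, rng)
        assert t.target_time == t.ws_time + 700

    @pytest.mark.parametrize("cue_soa,jitter_lo,jitter_hi,step", [
        (700, 1500, 1900, 50), (1300, 1900, 2700, 100),
    ])
    def test_repeated_interval_gaps(self, rng, cue_soa, jitter_lo, jitter_hi, step):
        for _ in range(20):
            t = generate_trial("RepeatedInterval", cue_soa, "valid", 5, rng)
            times = dict((lab, []) for lab in ("stream_black", "stream_red"))
            seq = [(tt, lab) for tt, lab in t.onsets]
            for (a, la), (b, lb) in zip(seq, seq[1:]):
                gap = b - a
                if la == "stream_black":
                    assert gap == cue_soa  # within-pair
                elif la == "stream_red" and lb == "stream_black":
                    assert jitter_lo <= gap <= jitter_hi and gap % step == 0
            # the WS-target pair repeats the cue SOA on valid trials
            assert t.target_soa == cue_soa

    def test_random_stream_jitter(self, rng):
        for _ in range(20):
            t = generate_trial("Random", 700, "valid", 6, rng)
            stream = [tt for tt, lab in t.onsets if lab in ("stream_black", "ws")]
            gaps = np.diff(stream)
            assert np.all((gaps >= 500) & (gaps <= 900)) and np.all(gaps % 50 == 0)
            assert 500 <= t.target_soa <= 900

    def test_random_invalid_target_from_other_distribution(self, rng):
        soas = [generate_trial("Random", 700, "invalid", 4, rng).target_soa
                for _ in range(20)]
        assert all(1100 <= s <= 1500 for s in soas)

    def test_catch_has_no_target_and_blank_end(self, rng):
        t = generate_trial("RepeatedInterval", 700, "catch", 4, rng)
        assert t.target_time is None
        assert t.end_ms == t.ws_time + 1500

    def test_invalid_enum_rejected(self, rng):
        with pytest.raises(ValueError, match="Condition"):
            generate_trial("Jittered", 700, "valid", 4, rng)
        with pytest.raises(ValueError, match="cue SOA"):
            generate_trial("Rhythmic", 900, "valid", 4, rng)
        with pytest.raises(ValueError, match="n_pre_ws"):
            generate_trial("Rhythmic", 700, "valid", 7, rng)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        cond=st.sampled_from(["Rhythmic", "RepeatedInterval", "Random"]),
        soa=st.sampled_from([700, 1300]),
        val=st.sampled_from(["valid", "invalid", "catch"]),
        n=st.sampled_from([4, 5, 6]),
        seed=st.integers(0, 2**20),
    )
    def test_trial_invariants(self, cond, soa, val, n, seed):
        t = generate_trial(cond, soa, val, n, np.random.default_rng(seed))
        times = t.onset_times
        assert all(b > a for a, b in zip(times, times[1:]))
        labels = [lab for _, lab in t.onsets]
        assert labels.count("ws") == 1
        assert labels.count("target") == (0 if val == "catch" else 1)
        if cond == "Rhythmic":
            pre = times[: times.index(t.ws_time) + 1]
            assert set(np.diff(pre)) == {soa}


class TestBlocksAndSessions:
    def test_predictive_block_counts(self, rng):
        b = generate_block("Rhythmic", 32, rng)
        counts = {v: sum(t.validity is v for t in b.trials) for v in Validity}
        assert counts == {Validity.VALID: 24, Validity.INVALID: 4, Validity.CATCH: 4}

    def test_random_block_counts(self, rng):
        b = generate_block("Random", 32, rng)
        counts = {v: sum(t.validity is v for t in b.trials) for v in Validity}
        assert counts == {Validity.VALID: 14, Validity.INVALID: 14, Validity.CATCH: 4}

    def test_indivisible_size_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_block("Rhythmic", 30, rng)

    def test_block_deterministic_under_seed(self):
        b1 = generate_block("Rhythmic", 32, np.random.default_rng(5))
        b2 = generate_block("Rhythmic", 32, np.random.default_rng(5))
        assert [t.onsets for t in b1.trials] == [t.onsets for t in b2.trials]

    def test_session_structure_and_counts(self):
        blocks = stimgen.generate_session(np.random.default_rng(3))
        assert len(blocks) == 10
        assert sum(len(b.trials) for b in blocks) == 320
        assert [b.condition for b in blocks[:2]] == [Condition.RANDOM] * 2
        # 48 valid trials per predictive condition per cue SOA
        trials = stimgen.session_trials(blocks)
        for cond in (Condition.RHYTHMIC, Condition.REPEATED_INTERVAL):
            for soa in (700, 1300):
                n = sum(
                    t.condition is cond and t.cue_soa == soa and t.validity is Validity.VALID
                    for t in trials
                )
                assert n == 48

    def test_counterbalancing_flag_swaps_order_only(self):
        a = stimgen.generate_session(np.random.default_rng(3), repeated_interval_first=True)
        b = stimgen.generate_session(np.random.default_rng(3), repeated_interval_first=False)
        assert [x.condition for x in a[2:4]] == [y.condition for y in b[2:4]][::-1]
        assert sorted(x.condition.value for x in a) == sorted(y.condition.value for y in b)


class TestImpulseTrain:
    def test_onsets_become_ones(self, rng):
        t = generate_trial("Rhythmic", 700, "valid", 4, rng)
        train = stimgen.trial_impulse_train(t)
        assert train.values.sum() == len(t.onsets)
        assert np.all(train.values[[0, 700, 1400, 2100, 2800, 3500]] == 1)

    def test_concatenation_conserves_onsets(self, rng):
        trials = [generate_trial("Random", 700, "valid", 4, rng) for _ in range(5)]
        train = stimgen.to_impulse_train(trials)
        assert train.values.sum() == sum(len(t.onsets) for t in trials)

    def test_empty_input_gives_empty_train(self):
        train = stimgen.to_impulse_train([])
        assert train.values.sum() == 0

    def test_roundtrip_identity_on_onsets(self, rng):
        t = generate_trial("RepeatedInterval", 1300, "valid", 5, rng)
        train = stimgen.trial_impulse_train(t)
        assert list(np.flatnonzero(train.values)) == t.onset_times


class TestSequenceSummaries:
    def test_periodic_train_peaks_at_stimulation_frequency(self):
        values = np.zeros(70000)
        values[::700] = 1
        train = stimgen.ImpulseTrain(fs=1000, values=values, onsets_idx=np.flatnonzero(values))
        s = stimgen.sequence_spectrum(train)
        band = (s.freqs > 0.5) & (s.freqs < 2.5)
        assert abs(s.freqs[band][np.argmax(s.amplitude[band])] - 1000 / 700) < 0.05

    def test_parseval_energy_equals_impulse_count(self, rng):
        trials = [generate_trial("Rhythmic", 700, "valid", 4, rng) for _ in range(4)]
        train = stimgen.to_impulse_train(trials)
        x = train.values.astype(float)
        spec = np.abs(np.fft.rfft(x))
        # sum of squares oracle (real FFT doubles interior bins)
        energy = (2 * (spec**2).sum() - spec[0] ** 2 - (spec[-1] ** 2 if x.size % 2 == 0 else 0)) / x.size
        assert energy == pytest.approx(train.values.sum(), rel=1e-9)

    def _amp_at(self, condition, freq=1000 / 700, seed=42):
        rng = np.random.default_rng(seed)
        trials = [t for _ in range(3) for t in generate_block(condition, 32, rng).trials]
        train = stimgen.to_impulse_train(trials, inter_trial_ms=(500, 1500), rng=rng)
        s = stimgen.sequence_spectrum(train, normalize=True)
        sel = np.abs(s.freqs - freq) < 0.02
        return s.amplitude[sel].max()

    def test_stimulation_frequency_amplitude_ordering(self):
        """At the cued frequency the Rhythmic stream carries the strongest
        amplitude, the Random stream less, the Repeated-Interval the least."""
        rhythmic = self._amp_at("Rhythmic")
        random_ = self._amp_at("Random")
        repeated = self._amp_at("RepeatedInterval")
        assert rhythmic > random_ > repeated

    def test_autocorrelation_properties(self, rng):
        trials = [generate_trial("Rhythmic", 700, "valid", 5, rng) for _ in range(40)]
        acf_r = stimgen.sequence_autocorrelation(stimgen.to_impulse_train(trials))
        assert acf_r.acf[0] == pytest.approx(1.0)
        # peaks at multiples of 700 ms stand out against neighbouring lags
        for k in (1, 2, 3):
            lag = 700 * k
            assert acf_r.acf[lag] > acf_r.acf[lag - 100] + 0.01
        trials_rand = [generate_trial("Random", 700, "valid", 5, rng) for _ in range(40)]
        acf_n = stimgen.sequence_autocorrelation(stimgen.to_impulse_train(trials_rand))
        assert acf_n.acf[700] < acf_r.acf[700]


class TestDesignAnalytics:
    def test_meta_interval_mean_and_cv(self):
        """Every-second-stimulus interval of short-cue Repeated-Interval streams:
        mean 700 + mean(jitter) = 2400 ms, CV in the 5-7% range (analytic 5.38%)."""
        jit = stimgen.REPEATED_JITTER[700].astype(float)
        mean_meta = 700 + jit.mean()
        assert mean_meta == 2400
        cv = jit.std() / mean_meta
        assert 0.05 <= cv <= 0.07
        assert cv == pytest.approx(0.0538, abs=1e-3)
        # empirical check on generated streams
        rng = np.random.default_rng(11)
        gaps = []
        for _ in range(300):
            t = generate_trial("RepeatedInterval", 700, "valid", 6, rng)
            blacks = [tt for tt, lab in t.onsets if lab == "stream_black"]
            gaps.extend(np.diff(blacks))
        gaps = np.asarray(gaps, dtype=float)
        assert gaps.mean() == pytest.approx(2400, abs=15)
        assert 0.045 <= gaps.std() / gaps.mean() <= 0.075

    def test_soa_variance_by_condition(self, rng):
        def soa_var(cond):
            v = []
            for _ in range(50):
                t = generate_trial(cond, 700, "valid", 6, rng)
                v.extend(np.diff([tt for tt, _ in t.onsets]))
            return np.var(v)

        assert soa_var("Rhythmic") == 0
        assert soa_var("Random") > 0
        assert soa_var("RepeatedInterval") > 0
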