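"""Wavelet frames, clustering, rule corrections, dive typing and budgets."""

import numpy as np
import pytest

from fmrcal import behaviour
from fmrcal.behaviour import (
    Ethogram,
    apply_rules,
    assign_behaviours,
    budget,
    classify_dives,
    cluster_frames,
    wavelet_frames,
)

RATE = 25.0


class TestWaveletFrames:
    def test_pure_tone_peak_band(self):
        t = np.arange(int(30 * RATE)) / RATE
        z = np.sin(2 * np.pi * 3.5 * t)
        frames = wavelet_frames(z, RATE)
        # FFT oracle: the dominant frequency of the signal itself
        freqs = np.fft.rfftfreq(len(z), 1.0 / RATE)
        f_fft = freqs[np.argmax(np.abs(np.fft.rfft(z)))]
        band = frames.freqs_hz[np.argmax(frames.spectra.mean(axis=0))]
        # agreement within the log-spaced band resolution
        ratio = np.exp(np.diff(np.log(frames.freqs_hz))[0])
        assert f_fft / ratio <= band <= f_fft * ratio

    def test_zero_input_zero_spectra(self):
        frames = wavelet_frames(np.zeros(int(10 * RATE)), RATE)
        assert np.allclose(frames.spectra, 0.0)
        assert np.allclose(frames.rms_dynamic, 0.0)

    def test_frame_count_is_floor_of_duration(self):
        frames = wavelet_frames(np.zeros(int(7.8 * RATE)), RATE)
        assert len(frames) == 7

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            wavelet_frames(np.zeros(10), RATE)

    def test_chunking_matches_single_pass(self, rng):
        x = rng.normal(size=int(40 * RATE))
        a = wavelet_frames(x, RATE, chunk_s=8.0)
        b = wavelet_frames(x, RATE, chunk_s=4000.0)
        assert np.allclose(a.spectra, b.spectra, rtol=1e-3, atol=1e-6)


class TestClustering:
    def _two_regime_frames(self, rng):
        t = np.arange(int(60 * RATE)) / RATE
        z = np.where(t < 30, 2.0 * np.sin(2 * np.pi * 3.5 * t), 0.2 * np.sin(2 * np.pi * 0.8 * t))
        z = z + rng.normal(0, 0.02, len(z))
        return wavelet_frames(z, RATE)

    def test_separable_regimes_perfectly_split(self, rng):
        frames = self._two_regime_frames(rng)
        labels = cluster_frames(frames, k=2, seed=0)
        first, second = labels[:30], labels[30:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]

    def test_same_seed_same_labels(self, rng):
        frames = self._two_regime_frames(rng)
        assert np.array_equal(
            cluster_frames(frames, k=4, seed=3), cluster_frames(frames, k=4, seed=3)
        )

    def test_k_exceeding_frames_raises(self, rng):
        frames = self._two_regime_frames(rng)
        with pytest.raises(ValueError):
            cluster_frames(frames, k=100)

    def test_label_permutation_invariance(self, rng):
        # mapping to behaviours depends on cluster statistics, not ids
        frames = self._two_regime_frames(rng)
        labels = cluster_frames(frames, k=2, seed=0)
        mapped_a, _ = assign_behaviours(labels, frames)
        mapped_b, _ = assign_behaviours(1 - labels, frames)
        assert np.array_equal(mapped_a, mapped_b)


class TestAssign:
    def test_heuristic_ordering(self):
        # three artificial clusters: burst, wingbeat-band, low
        n = 30
        freqs = np.geomspace(0.5, 12.0, 12)
        spectra = np.zeros((n, 12))
        rms = np.zeros(n)
        clusters = np.repeat([0, 1, 2], 10)
        spectra[clusters == 0, 3] = 5.0
        rms[clusters == 0] = 2.5  # dive burst
        flap_band = np.argmin(np.abs(freqs - 3.5))
        spectra[clusters == 1, flap_band] = 2.0
        rms[clusters == 1] = 1.2  # flapping
        spectra[clusters == 2, 1] = 0.1
        rms[clusters == 2] = 0.15  # low
        frames = behaviour.SpectralFrames(np.arange(n), freqs, spectra, rms)
        labels, mapping = assign_behaviours(clusters, frames)
        assert mapping == {0: "dive", 1: "flapping", 2: "low"}


class TestRules:
    def test_rule_application(self):
        prov = np.array(["low", "low", "low", "flapping"], dtype=object)
        speed = np.array([40.0, 1.0, 1.0, 50.0])
        land = np.array([False, True, False, False])
        out = apply_rules(prov, speed, land)
        assert list(out) == ["gliding", "rest_land", "rest_sea", "flapping"]

    def test_idempotent(self):
        prov = np.array(["low", "low", "low", "flapping", "dive"], dtype=object)
        speed = np.array([40.0, 1.0, 1.0, 50.0, 0.0])
        land = np.array([False, True, False, False, False])
        once = apply_rules(prov, speed, land)
        twice = apply_rules(once, speed, land)
        assert np.array_equal(once, twice)

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError):
            apply_rules(np.array(["low"], dtype=object), np.zeros(2), np.zeros(2, bool))


class TestDiveTyping:
    def test_dive_after_flight_is_plunge(self):
        lab = np.array(["flapping", "flapping", "dive", "dive", "rest_sea"], dtype=object)
        out, n_p, n_d = classify_dives(lab)
        assert list(out[2:4]) == ["plunge_dive", "plunge_dive"]
        assert (n_p, n_d) == (1, 0)

    def test_dive_after_surface_rest_is_duck(self):
        lab = np.array(["rest_sea", "dive", "rest_sea"], dtype=object)
        out, n_p, n_d = classify_dives(lab)
        assert out[1] == "duck_dive"
        assert (n_p, n_d) == (0, 1)

    def test_close_dive_seconds_merge_into_one_bout(self):
        lab = np.array(["flapping", "dive", "rest_sea", "dive", "rest_sea"], dtype=object)
        out, n_p, n_d = classify_dives(lab, merge_gap_s=2)
        assert n_p + n_d == 1
        assert out[1] == out[3] == "plunge_dive"

    def test_dive_at_start_warns(self):
        lab = np.array(["dive", "rest_sea"], dtype=object)
        with pytest.warns(UserWarning, match="record start"):
            out, n_p, n_d = classify_dives(lab)
        assert n_p == 1


class TestBudget:
    def _eth(self, labels, vedba=None):
        t = np.datetime64("2014-12-06T00:00:00") + np.arange(len(labels)).astype(
            "timedelta64[s]"
        )
        v = np.ones(len(labels)) * 0.3 if vedba is None else vedba
        return Ethogram(t, np.array(labels, dtype=object), v)

    def test_proportions_sum_to_one(self):
        eth = self._eth(["flapping"] * 10 + ["rest_sea"] * 30 + ["rest_land"] * 60)
        b = budget(eth)
        assert sum(b.proportion.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(b.T_h.values()) == pytest.approx(eth.duration_h)

    def test_all_land(self):
        b = budget(self._eth(["rest_land"] * 100))
        assert b.T_h["rest_land"] == pytest.approx(100 / 3600)
        assert all(v == 0 for k, v in b.T_h.items() if k != "rest_land")
        assert b.dive_rate_per_h == 0.0

    def test_vedba_sums_follow_labels(self):
        v = np.concatenate([np.full(10, 1.0), np.full(20, 0.1)])
        eth = self._eth(["flapping"] * 10 + ["rest_sea"] * 20, v)
        b = budget(eth)
        assert b.vedba_sum["flapping"] == pytest.approx(10.0)
        assert b.vedba_sum["rest_sea"] == pytest.approx(2.0)

    def test_budget_invariant_under_count_preserving_relabelling(self):
        lab = ["flapping"] * 5 + ["rest_sea"] * 5
        shuffled = ["rest_sea", "flapping"] * 5
        v = np.ones(10)
        a = budget(self._eth(lab, v))
        b = budget(self._eth(shuffled, v))
        assert a.T_h == b.T_h
        assert a.vedba_sum == pytest.approx(b.vedba_sum)

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            budget(self._eth(["swimming"] * 5))
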