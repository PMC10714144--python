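"""Synthetic deployment generator: structure, conservation, determinism."""

import numpy as np
import pytest
from scipy import stats

from fmrcal import synthetic, trips
from fmrcal.accel import compute_vedba, split_static_dynamic
from tests.conftest import short_sim_config


class TestEthogram:
    def test_zero_at_sea_config_is_all_rest_land(self, rng):
        cfg = short_sim_config(trip_h=0.0)
        eth, truth = synthetic.simulate_ethogram(cfg, "b0", rng)
        assert set(np.unique(eth.behaviour)) == {"rest_land"}
        assert truth.true_T_h["rest_land"] == pytest.approx(cfg.deployment_h)

    def test_behaviour_times_conserve_deployment(self, short_config, rng):
        eth, truth = synthetic.simulate_ethogram(short_config, "b0", rng)
        assert sum(truth.true_T_h.values()) == pytest.approx(short_config.deployment_h)
        assert len(eth) == int(short_config.deployment_h * 3600)

    def test_fixed_seed_reproduces_labels(self, short_config):
        a, _ = synthetic.simulate_ethogram(short_config, "b0", np.random.default_rng(7))
        b, _ = synthetic.simulate_ethogram(short_config, "b0", np.random.default_rng(7))
        assert np.array_equal(a.behaviour, b.behaviour)

    def test_deployment_shorter_than_dwell_raises(self):
        cfg = short_sim_config()
        cfg.deployment_h = 1.0 / 3600.0  # one second < shortest dwell (2 s)
        with pytest.raises(ValueError, match="dwell"):
            synthetic.simulate_ethogram(cfg, "b0")

    def test_dive_context(self, short_config):
        # plunge dives entered from flight, duck dives from surface rest
        rng = np.random.default_rng(3)
        eth, _ = synthetic.simulate_ethogram(short_config, "b0", rng)
        lab = eth.behaviour
        for i in np.nonzero((lab == "plunge_dive") & (np.roll(lab, 1) != "plunge_dive"))[0]:
            if i > 0:
                assert lab[i - 1] in ("flapping", "gliding")
        for i in np.nonzero((lab == "duck_dive") & (np.roll(lab, 1) != "duck_dive"))[0]:
            if i > 0:
                assert lab[i - 1] == "rest_sea"

    def test_true_ee_is_dot_product_of_budget_and_rates(self, short_config, rng):
        _, truth = synthetic.simulate_ethogram(short_config, "b0", rng)
        expected = sum(
            short_config.true_coefficients[b] * truth.true_T_h[b]
            for b in truth.true_T_h
        )
        assert truth.true_EE_kj == pytest.approx(expected, rel=1e-12)

    def test_dwell_sampler_matches_exponential_chisquare(self):
        # 1e4 draws of the 1-s-rounded exponential dwell vs its exact cell
        # probabilities
        rng = np.random.default_rng(12345)
        mean = 60.0
        draws = np.array([synthetic.draw_dwell(rng, mean) for _ in range(10_000)])
        edges = np.arange(1, 250)

        def cell_p(k):
            lo = 0.0 if k == 1 else k - 0.5
            return np.exp(-lo / mean) - np.exp(-(k + 0.5) / mean)

        probs = np.array([cell_p(k) for k in edges])
        counts = np.array([(draws == k).sum() for k in edges], dtype=float)
        # merge the tail and low-expectation cells
        tail_p = 1.0 - probs.sum()
        probs = np.append(probs, tail_p)
        counts = np.append(counts, (draws >= 250).sum())
        keep = probs * len(draws) >= 5
        p_merged = np.append(probs[keep], probs[~keep].sum())
        c_merged = np.append(counts[keep], counts[~keep].sum())
        stat, p = stats.chisquare(c_merged, p_merged * len(draws))
        assert p > 1e-3


class TestAccelSim:
    def test_zero_amplitude_zero_noise_gives_zero_vedba(self, rng):
        cfg = short_sim_config(trip_h=0.0, vedba_noise_sd=0.0)
        cfg.behaviour_accel = dict(cfg.behaviour_accel, rest_land=(0.7, 0.0, (0.0, 0.0, 1.0)))
        eth, _ = synthetic.simulate_ethogram(cfg, "b0", rng)
        tr = synthetic.simulate_accel(eth, cfg, rng)
        _, dyn = split_static_dynamic(tr, 2.0)
        assert compute_vedba(dyn).vedba.max() < 1e-9

    def test_vedba_monotone_in_amplitude(self, rng):
        cfg = short_sim_config()
        eth, _ = synthetic.simulate_ethogram(cfg, "b0", rng)
        tr = synthetic.simulate_accel(eth, cfg, rng)
        _, dyn = split_static_dynamic(tr, 2.0)
        v = compute_vedba(dyn).vedba
        per = int(cfg.sampling_rate)
        sec_mean = v[: (len(v) // per) * per].reshape(-1, per).mean(axis=1)
        lab = eth.behaviour[: len(sec_mean)]
        assert sec_mean[lab == "flapping"].mean() > sec_mean[lab == "rest_sea"].mean()
        assert sec_mean[lab == "rest_sea"].mean() > sec_mean[lab == "rest_land"].mean()

    def test_flapping_spectral_peak_at_configured_frequency(self, rng):
        cfg = short_sim_config(vedba_noise_sd=0.0)
        eth, _ = synthetic.simulate_ethogram(cfg, "b0", rng)
        tr = synthetic.simulate_accel(eth, cfg, rng)
        # longest uninterrupted flapping bout
        lab = eth.behaviour
        runs = []
        i = 0
        while i < len(lab):
            if lab[i] == "flapping":
                j = i
                while j + 1 < len(lab) and lab[j + 1] == "flapping":
                    j += 1
                runs.append((i, j))
                i = j + 1
            else:
                i += 1
        a, b = max(runs, key=lambda r: r[1] - r[0])
        per = int(cfg.sampling_rate)
        z = tr.z[a * per : (b + 1) * per]
        z = z - z.mean()
        freqs = np.fft.rfftfreq(len(z), 1.0 / cfg.sampling_rate)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(z)))]
        f_cfg = cfg.behaviour_accel["flapping"][0]
        assert peak == pytest.approx(f_cfg, abs=0.2)


class TestGpsSim:
    def test_all_land_fixes_stay_at_colony(self, rng):
        cfg = short_sim_config(trip_h=0.0)
        eth, truth = synthetic.simulate_ethogram(cfg, "b0", rng)
        gps = synthetic.simulate_gps(eth, cfg, rng, truth)
        d = trips.haversine_km(
            gps["lat"].to_numpy(), gps["lon"].to_numpy(), *cfg.colony_latlon
        )
        assert d.max() < 0.2

    def test_track_distance_matches_truth(self, rng):
        # noise-free fixes: measured trip distance is a clean oracle for
        # the recorded true path length
        cfg = short_sim_config(deployment_h=10.0, trip_h=3.0, gps_noise_km=0.0)
        eth, truth = synthetic.simulate_ethogram(cfg, "b0", rng)
        gps = synthetic.simulate_gps(eth, cfg, rng, truth)
        s = trips.segment_trips(gps, cfg.colony_latlon, 0.5)
        assert truth.true_trip_distance_km > 10
        assert s.total_distance_km == pytest.approx(truth.true_trip_distance_km, rel=0.02)

    def test_fixed_seed_reproduces_track(self, short_config):
        eth, _ = synthetic.simulate_ethogram(short_config, "b0", np.random.default_rng(9))
        a = synthetic.simulate_gps(eth, short_config, np.random.default_rng(5))
        b = synthetic.simulate_gps(eth, short_config, np.random.default_rng(5))
        assert np.array_equal(a["lat"], b["lat"]) and np.array_equal(a["lon"], b["lon"])


def test_config_validation_rejects_bad_behaviour_set():
    cfg = short_sim_config()
    cfg.behaviour_dwell = {"flying": 10.0}
    with pytest.raises(ValueError, match="behaviour set"):
        cfg.validate()


def test_config_validation_rejects_nonpositive_rates():
    cfg = short_sim_config()
    cfg.true_coefficients = dict(cfg.true_coefficients, flapping=-1.0)
    with pytest.raises(ValueError):
        cfg.validate()
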