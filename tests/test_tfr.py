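import numpy as np
import pandas as pd
import pytest

from betareach import designs, simulate as sim, tfr as tf


def _tiny_layout(n=8):
    # minimal 3-region layout for fixture-scale spectral tests
    regions = (["frontal"] * 3 + ["left"] * 3 + ["right"] * 2)[:n]
    rng = np.random.default_rng(0)
    return tf.ChannelLayout(
        pd.DataFrame(
            {
                "channel": np.arange(n),
                "x": rng.uniform(-1, 1, n),
                "y": rng.uniform(-1, 1, n),
                "region": regions,
            }
        )
    )


class TestSegmentation:
    def test_counts_and_edge_drops(self):
        fs = 250.0
        layout = _tiny_layout()
        signal = np.random.default_rng(1).normal(size=(8, int(fs * 60)))
        events = [3.0, 10.0, 30.0, 58.9]  # last one too close to the end
        ep = tf.segment_epochs(signal, fs, events, window=(-2, 2), layout=layout)
        assert ep.n_trials == 3
        assert ep.info["n_presented"] == 4
        assert ep.info["n_edge_dropped"] == 1
        assert ep.times[0] == pytest.approx(-2.0)
        assert ep.data.shape == (3, 8, 1000)

    def test_epoch_content_matches_source(self):
        fs = 250.0
        layout = _tiny_layout()
        signal = np.arange(8 * 5000, dtype=float).reshape(8, 5000)
        ep = tf.segment_epochs(signal, fs, [10.0], window=(-2, 2), layout=layout)
        start = int((10.0 - 2.0) * fs)
        assert np.array_equal(ep.data[0], signal[:, start : start + 1000])


class TestRealignment:
    def _epochs(self, onsets, n=4):
        fs = 250.0
        layout = _tiny_layout()
        times = -2.0 + np.arange(int(5.5 * fs)) / fs
        data = np.zeros((n, 8, times.size), np.float32)
        for i, o in enumerate(onsets):
            if np.isfinite(o) and times[0] <= o <= times[-1]:
                data[i, :, int(round((o - times[0]) * fs))] = 1.0  # marker spike
        return (
            tf.EEGEpochs(data, times, fs, layout, "target_onset"),
            np.asarray(onsets, float),
        )

    def test_zero_onset_preserves_data(self):
        ep, onsets = self._epochs([0.0, 0.0, 0.0, 0.0])
        re = tf.realign_to_movement_onset(ep, onsets)
        assert re.alignment == "movement_onset"
        assert re.times[0] == pytest.approx(-1.0)
        sel = (ep.times >= -1.0) & (ep.times < 2.5 - 1e-9)
        assert np.array_equal(re.data, ep.data[:, :, sel])

    def test_marker_lands_at_time_zero(self):
        ep, onsets = self._epochs([0.1, 0.3, 0.52, 0.9])
        re = tf.realign_to_movement_onset(ep, onsets)
        zero_idx = int(np.argmin(np.abs(re.times)))
        for i in range(4):
            assert re.data[i, 0, zero_idx] == 1.0

    def test_invalid_and_excluded_trials_dropped(self):
        ep, onsets = self._epochs([0.3, np.nan, 0.3, 5.0])
        re = tf.realign_to_movement_onset(
            ep, onsets, keep_mask=[True, True, False, True]
        )
        assert re.n_trials == 1
        assert re.info["n_invalid_or_excluded"] == 2
        assert re.info["n_window_dropped"] == 1
        assert re.info["n_input"] == re.n_trials + 2 + 1

    def test_all_invalid_gives_empty(self):
        ep, onsets = self._epochs([np.nan] * 4)
        re = tf.realign_to_movement_onset(ep, onsets)
        assert re.n_trials == 0


class TestMorlet:
    def test_pure_sinusoid_frequency_and_flat_power(self):
        fs = 250.0
        layout = _tiny_layout()
        t = np.arange(int(2 * fs)) / fs
        data = np.tile(np.sin(2 * np.pi * 20.0 * t), (1, 8, 1))
        ep = tf.EEGEpochs(data.astype(float), t - 1.0, fs, layout)
        freqs = np.arange(10.0, 30.5, 0.5)
        out = tf.morlet_tfr(ep, freqs, 7.0)
        interior = np.isfinite(out.power[0]).all(axis=0)
        prof = out.power[0][:, interior].mean(axis=1)
        assert abs(freqs[np.argmax(prof)] - 20.0) <= 0.25
        p20 = out.power[0, np.argmax(prof), interior]
        assert p20.std() / p20.mean() < 0.01

    def test_amplitude_doubling_quadruples_power(self):
        fs = 250.0
        layout = _tiny_layout()
        rng = np.random.default_rng(2)
        x = rng.normal(size=(1, 8, 500))
        t = np.arange(500) / fs
        a = tf.morlet_tfr(tf.EEGEpochs(x, t, fs, layout), np.array([15.0]), 5.0)
        b = tf.morlet_tfr(tf.EEGEpochs(2 * x, t, fs, layout), np.array([15.0]), 5.0)
        m = np.isfinite(a.power)
        assert np.allclose(b.power[m], 4 * a.power[m], rtol=1e-6)

    def test_white_noise_matches_direct_convolution_oracle(self):
        fs = 250.0
        layout = _tiny_layout()
        rng = np.random.default_rng(3)
        data = rng.normal(size=(2, 8, 500))  # float64 -> full precision path
        t = np.arange(500) / fs
        ep = tf.EEGEpochs(data, t, fs, layout)
        freqs = np.array([8.0, 21.0])
        got = tf.morlet_tfr(ep, freqs, 6.0, average=False)
        for k, f in enumerate(freqs):
            w = tf._morlet_wavelet(f, 6.0, fs)
            for i in range(2):
                for c in range(8):
                    ref = np.abs(np.convolve(data[i, c], w, mode="same")) ** 2
                    vals = got.power[i, c, k]
                    m = np.isfinite(vals)
                    rel = np.abs(vals[m] - ref[m]) / ref[m]
                    assert rel.max() < 1e-6

    def test_nyquist_rejected(self):
        layout = _tiny_layout()
        ep = tf.EEGEpochs(
            np.zeros((1, 8, 500)), np.arange(500) / 250.0, 250.0, layout
        )
        with pytest.raises(ValueError):
            tf.morlet_tfr(ep, np.array([130.0]), 7.0)

    def test_cycle_mapping_endpoints(self):
        c = tf.cycles_linear(np.array([1.0, 55.0]))
        assert c[0] == pytest.approx(3.0)
        assert c[1] == pytest.approx(10.0)


class TestNormalization:
    def _raw(self):
        rng = np.random.default_rng(4)
        power = rng.uniform(0.5, 2.0, size=(8, 5, 100))
        return tf.TFR(
            power=power,
            freqs=np.arange(14.0, 16.5, 0.5),
            times=np.linspace(-1, 2.5, 100),
            n_trials=10,
        )

    def test_self_reference_is_zero_mean(self):
        tfr = self._raw()
        out = tf.normalize_relative(tfr)
        assert out.normalization == "relative_own"
        assert np.allclose(np.nanmean(out.power, axis=-1), 0.0, atol=1e-10)

    def test_doubled_power_reads_plus_100_percent(self):
        tfr = self._raw()
        mu = np.nanmean(tfr.power, axis=-1)
        from dataclasses import replace

        doubled = replace(tfr, power=2 * tfr.power)
        out = tf.normalize_relative(doubled, reference=2 * mu)
        ratio = tf.normalize_relative(doubled, reference=mu)
        assert np.allclose(
            ratio.power, 2 * (out.power + 1) - 1, atol=1e-10
        )
        exact = tf.normalize_relative(replace(tfr, power=2 * mu[..., None] * np.ones_like(tfr.power)), reference=mu)
        assert np.allclose(exact.power, 1.0, atol=1e-10)

    def test_nonpositive_reference_rejected(self):
        tfr = self._raw()
        mu = np.nanmean(tfr.power, axis=-1)
        mu[3, 2] = 0.0
        with pytest.raises(ValueError, match="14.5|channel"):
            tf.normalize_relative(tfr, reference=mu)

    def test_double_normalization_rejected(self):
        out = tf.normalize_relative(self._raw())
        with pytest.raises(ValueError):
            tf.normalize_relative(out)


class TestBandPower:
    def test_flat_spectrum_band_mean_equals_value(self):
        power = np.full((4, 5, 50), 3.0)
        tfr = tf.TFR(
            power=power,
            freqs=np.arange(14.0, 16.5, 0.5),
            times=np.linspace(0, 1, 50),
        )
        btc = tf.beta_band_power(tfr, band=(14.0, 16.0))
        assert np.allclose(btc.values, 3.0)

    def test_single_bin_band(self):
        rng = np.random.default_rng(5)
        power = rng.uniform(1, 2, (4, 5, 50))
        tfr = tf.TFR(
            power=power, freqs=np.arange(14.0, 16.5, 0.5), times=np.linspace(0, 1, 50)
        )
        btc = tf.beta_band_power(tfr, band=(15.0, 15.0))
        assert np.allclose(btc.values, power[:, 2, :])

    def test_empty_band_rejected(self):
        tfr = tf.TFR(
            power=np.ones((4, 5, 50)),
            freqs=np.arange(14.0, 16.5, 0.5),
            times=np.linspace(0, 1, 50),
        )
        with pytest.raises(ValueError):
            tf.beta_band_power(tfr, band=(30.0, 31.0))

    def test_planted_erd_dip_recovered(self, layout32):
        """A planted -40% beta ERD reads ~= -0.4 on the relative time course."""
        d = designs.build_mov_design(11)
        d.targets = d.targets[:50]
        d.movements_per_set = 50
        subj = sim.SubjectParams(
            rng_seed=11,
            eeg=sim.default_eeg_params("mov", erd_depth=0.4, ers_gain=0.0),
        )
        trajs = sim.simulate_block_kinematics(d, subj)
        uniform = {
            "frontal": np.ones(layout32.n_channels),
            "left": np.zeros(layout32.n_channels),
            "right": np.zeros(layout32.n_channels),
        }
        epochs, truth = sim.simulate_epochs(
            d, trajs, subj, layout=layout32, weights=uniform
        )
        onsets = np.array([t.true_onset_s for t in trajs])
        re = tf.realign_to_movement_onset(epochs, onsets)
        raw = tf.morlet_tfr(re, tf.BETA_FREQS, tf.cycles_linear(tf.BETA_FREQS), decim=5)
        btc = tf.beta_band_power(tf.normalize_relative(raw))
        sel = (btc.times >= truth.erd_window[0] + 0.2) & (
            btc.times <= truth.erd_window[1] - 0.2
        )
        dip = np.nanmin(np.nanmean(btc.values[:, sel], axis=0))
        assert dip == pytest.approx(-0.4, abs=0.05)
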