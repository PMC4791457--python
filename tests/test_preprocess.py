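"""Filtering, optical density, and Beer-Lambert inversion."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import signal

import fnirs_deception as fd
from fnirs_deception.preprocess import DEFAULT_EXTINCTION, FilterConfig


def make_recording(channel, fs=2.004, n_voxels=1, baseline_s=10.0):
    """Wrap a single positive channel into a recording (same signal on all
    voxels/wavelengths)."""
    n = channel.size
    intensity = np.tile(channel[:, None, None], (1, n_voxels, 2))
    return fd.RawRecording(
        subject_id="F",
        fs=fs,
        wavelengths=(730.0, 850.0),
        intensity=intensity,
        baseline_interval=(0.0, baseline_s),
    )


# ---------------------------------------------------------------------------
# FIR design
# ---------------------------------------------------------------------------

class TestFilterDesign:
    def test_dc_gain_is_one(self):
        taps = fd.design_fir_lowpass(2.004, 0.14, 21)
        assert taps.sum() == pytest.approx(1.0, abs=1e-12)

    def test_taps_symmetric_linear_phase(self):
        taps = fd.design_fir_lowpass(2.004, 0.14, 21)
        assert np.allclose(taps, taps[::-1])

    def test_stopband_attenuation_at_0p9_hz(self):
        taps = fd.design_fir_lowpass(2.004, 0.14, 21)
        _, h = signal.freqz(taps, worN=[0.9], fs=2.004)
        assert 20 * np.log10(abs(h[0])) <= -20.0

    @pytest.mark.parametrize("cutoff,n_taps", [(1.1, 21), (0.14, 20), (0.14, 3)])
    def test_invalid_designs_rejected(self, cutoff, n_taps):
        with pytest.raises(ValueError):
            fd.design_fir_lowpass(2.004, cutoff, n_taps)


class TestLowpassFilter:
    def test_constant_channel_unchanged(self):
        rec = make_recording(np.full(400, 123.0))
        out = fd.lowpass_filter(rec)
        assert np.allclose(out.intensity, 123.0, atol=1e-9)

    def test_fast_sinusoid_attenuated_20db(self):
        t = np.arange(2000) / 2.004
        rec = make_recording(100.0 + np.sin(2 * np.pi * 1.0 * t))
        out = fd.lowpass_filter(rec)
        resid = out.intensity[300:-300, 0, 0] - 100.0
        assert resid.std() <= 10 ** (-20 / 20) / np.sqrt(2)

    def test_slow_component_preserved(self):
        t = np.arange(4000) / 2.004
        slow = np.sin(2 * np.pi * 0.02 * t)
        rec = make_recording(100.0 + slow + np.sin(2 * np.pi * 1.0 * t))
        out = fd.lowpass_filter(rec)
        core = slice(300, -300)
        r = np.corrcoef(out.intensity[core, 0, 0], slow[core])[0, 1]
        assert r > 0.99

    def test_output_length_and_identical_channels(self):
        rng = np.random.default_rng(0)
        chan = rng.uniform(50, 150, 500)
        rec = make_recording(chan, n_voxels=3)
        out = fd.lowpass_filter(rec)
        assert out.intensity.shape == rec.intensity.shape
        # every voxel/wavelength filtered identically
        assert np.allclose(out.intensity, out.intensity[:, :1, :1])

    def test_too_short_recording_rejected(self):
        rec = make_recording(np.full(50, 10.0), baseline_s=5.0)
        with pytest.raises(ValueError, match="too short"):
            fd.lowpass_filter(rec)


# ---------------------------------------------------------------------------
# baseline + optical density
# ---------------------------------------------------------------------------

class TestBaseline:
    def test_constant_baseline(self):
        rec = make_recording(np.full(100, 42.0))
        assert np.allclose(fd.compute_baseline(rec), 42.0)

    def test_two_sample_mean(self):
        chan = np.full(100, 9.0)
        chan[0], chan[1] = 2.0, 4.0
        rec = make_recording(chan, fs=2.0, baseline_s=1.0)  # samples {0, 1}
        assert np.allclose(fd.compute_baseline(rec), 3.0)

    def test_brute_force_index_oracle(self):
        rng = np.random.default_rng(1)
        chan = rng.uniform(10, 20, 200)
        fs, t0, t1 = 2.004, 3.7, 31.2
        rec = dataclasses.replace(
            make_recording(chan, fs=fs), baseline_interval=(t0, t1)
        )
        expected = np.mean([chan[k] for k in range(200) if t0 <= k / fs < t1])
        assert np.allclose(fd.compute_baseline(rec), expected)

    def test_empty_baseline_rejected(self):
        rec = make_recording(np.full(100, 5.0))
        rec.baseline_interval = (0.0, 0.4)  # < 2 samples at 2.004 Hz
        with pytest.raises(ValueError, match="baseline"):
            fd.compute_baseline(rec)


class TestOpticalDensity:
    @pytest.mark.parametrize(
        "I,I_b,expected", [(5.0, 5.0, 0.0), (0.5, 5.0, 1.0), (50.0, 5.0, -1.0)]
    )
    def test_log10_convention(self, I, I_b, expected):
        assert fd.optical_density(np.array(I), np.array(I_b)) == pytest.approx(
            expected
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fd.optical_density(np.array(-1.0), np.array(5.0))


# ---------------------------------------------------------------------------
# Beer-Lambert inversion
# ---------------------------------------------------------------------------

class TestBeerLambert:
    def test_zero_od_gives_zero_concentration(self):
        hb, hbo2 = fd.invert_beer_lambert(np.zeros(2))
        assert hb == 0.0 and hbo2 == 0.0

    def test_identity_table(self):
        ext = fd.ExtinctionTable(alpha=np.eye(2))
        hb, hbo2 = fd.invert_beer_lambert(np.array([2.0, 3.0]), ext)
        assert hb == pytest.approx(2.0) and hbo2 == pytest.approx(3.0)

    def test_forward_inverse_round_trip(self):
        rng = np.random.default_rng(2)
        dC = rng.normal(0, 5, (1000, 2))  # columns (Hb, HbO2)
        dOD = dC @ DEFAULT_EXTINCTION.alpha.T
        hb, hbo2 = fd.invert_beer_lambert(dOD)
        rec = np.column_stack([hb, hbo2])
        assert np.max(np.abs(rec - dC) / np.maximum(np.abs(dC), 1e-12)) < 1e-10

    def test_singular_table_rejected(self):
        with pytest.raises(ValueError, match="ill-conditioned|singular"):
            fd.ExtinctionTable(alpha=np.array([[1.0, 2.0], [2.0, 4.0]]))

    def test_extinction_csv_round_trip(self, tmp_path):
        DEFAULT_EXTINCTION.to_csv(tmp_path / "ext.csv")
        back = fd.ExtinctionTable.from_csv(tmp_path / "ext.csv")
        assert np.allclose(back.alpha, DEFAULT_EXTINCTION.alpha)


class TestVolumeOxygenation:
    def test_worked_sum_difference(self):
        dB, dO = fd.derive_volume_oxygenation(np.array(1.0), np.array(3.0))
        assert dB == 4.0 and dO == 2.0

    def test_equal_chromophores_zero_oxygenation(self):
        x = np.arange(12.0).reshape(3, 4)
        _, dO = fd.derive_volume_oxygenation(x, x.copy())
        assert np.all(dO == 0.0)

    @given(st.integers(0, 2**31 - 1))
    def test_algebraic_identities(self, seed):
        rng = np.random.default_rng(seed)
        hb = rng.normal(size=(5, 3))
        hbo2 = rng.normal(size=(5, 3))
        dB, dO = fd.derive_volume_oxygenation(hb, hbo2)
        assert np.allclose((dB + dO) / 2, hbo2)
        assert np.allclose(dB - dO, 2 * hb)
        assert np.allclose(dB + dO, 2 * hbo2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            fd.derive_volume_oxygenation(np.zeros(3), np.zeros(4))


# ---------------------------------------------------------------------------
# whole-chain properties
# ---------------------------------------------------------------------------

class TestPreprocessChain:
    def test_noiseless_recovery_without_filter(self, noiseless_subject):
        _, rec, truth = noiseless_subject
        series = fd.preprocess_recording(rec, filter_config=None)
        assert np.abs(series.dC_Hb - truth.clean_dC_Hb).max() < 1e-6
        assert np.abs(series.dC_HbO2 - truth.clean_dC_HbO2).max() < 1e-6
        r = np.corrcoef(series.dC_HbO2[:, 0], truth.clean_dC_HbO2[:, 0])[0, 1]
        assert r > 0.99

    def test_volume_oxygenation_identities_hold(self, noiseless_subject):
        _, rec, _ = noiseless_subject
        series = fd.preprocess_recording(rec)
        assert np.array_equal(series.dB, series.dC_HbO2 + series.dC_Hb)
        assert np.array_equal(series.dO, series.dC_HbO2 - series.dC_Hb)

    def test_baseline_od_mean_near_zero_unfiltered(self, noiseless_subject):
        _, rec, _ = noiseless_subject
        I_b = fd.compute_baseline(rec)
        from fnirs_deception.preprocess import baseline_sample_indices

        idx = baseline_sample_indices(rec)
        od = fd.optical_density(rec.intensity[idx], I_b[None])
        assert np.abs(od.mean(axis=0)).max() < 1e-9

    def test_filter_and_inversion_commute(self, default_subject):
        """Inversion is linear, so filtering intensities' OD and filtering the
        recovered concentrations agree in the noiseless linear regime."""
        _, rec, _ = default_subject
        taps = fd.design_fir_lowpass(rec.fs)
        I_b = fd.compute_baseline(rec)
        od_raw = fd.optical_density(rec.intensity, I_b[None])
        # filter-then-invert on the OD (the linear domain)
        od_f = signal.filtfilt(taps, [1.0], od_raw, axis=0)
        hb_a, hbo2_a = fd.invert_beer_lambert(od_f)
        # invert-then-filter
        hb, hbo2 = fd.invert_beer_lambert(od_raw)
        hb_b = signal.filtfilt(taps, [1.0], hb, axis=0)
        hbo2_b = signal.filtfilt(taps, [1.0], hbo2, axis=0)
        assert np.abs(hb_a - hb_b).max() < 1e-8
        assert np.abs(hbo2_a - hbo2_b).max() < 1e-8

    def test_filtered_chain_matches_filtered_planted_series(self, noiseless_subject):
        """With the low-pass enabled the recovered concentrations equal the
        *filtered* planted series (linearity), even though the filter distorts
        the raw hemodynamic kernel."""
        _, rec, truth = noiseless_subject
        series = fd.preprocess_recording(rec)  # zero-phase filter on intensity
        taps = fd.design_fir_lowpass(rec.fs)
        want = signal.filtfilt(taps, [1.0], truth.clean_dC_HbO2, axis=0)
        # intensity-domain filtering is applied to I, not OD; the agreement is
        # first-order in the (percent-level) intensity modulation, so allow a
        # second-order-sized discrepancy on umol/L-scale responses
        assert np.abs(series.dC_HbO2 - want).max() < 2e-2
        r = np.corrcoef(series.dC_HbO2[:, 0], want[:, 0])[0, 1]
        assert r > 0.999
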