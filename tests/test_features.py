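"""Spectral estimation, band summarization, naming and stability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bingedbs as bd
from bingedbs.features import (
    DEFAULT_WELCH,
    NoRestDataError,
    band_summarize,
    compute_coherence,
    compute_psd,
    feature_label,
    feature_names,
    feature_stability,
    segment_rest_intervals,
)
from bingedbs.schemes import Band, BandScheme, ChannelScheme


def _recording(data, fs=1000.0, intervals=None, labels=None):
    n = data.shape[0]
    labels = labels or ("cl", "cr", "sl", "sr")[:n]
    return bd.LFPRecording(
        data=data,
        fs=fs,
        channels=ChannelScheme(tuple(labels)),
        rest_intervals=intervals if intervals is not None else [(0.0, data.shape[1] / fs)],
    )


class TestRestSegments:
    @pytest.mark.parametrize(
        "intervals, expected",
        [
            ([(0.0, 120.0)], [(0, 120_000)]),
            ([(0.0, 2.0), (1.0, 5.0)], [(0, 5_000)]),  # overlap merges, then kept
            ([(10.0, 14.0), (0.0, 4.0)], [(0, 4_000), (10_000, 14_000)]),
        ],
    )
    def test_merge_and_convert(self, intervals, expected):
        rec = _recording(np.zeros((2, 120_000)), intervals=intervals)
        assert segment_rest_intervals(rec, min_len_s=4.0) == expected

    def test_all_short_intervals_raise_no_rest_data(self):
        rec = _recording(np.zeros((2, 120_000)), intervals=[(0.0, 3.0), (10.0, 12.0)])
        with pytest.raises(NoRestDataError, match="no rest interval"):
            segment_rest_intervals(rec, min_len_s=4.0)


class TestPSD:
    def test_sinusoid_band_power_matches_parseval(self):
        fs, dur, amp, f0 = 1000.0, 60.0, 2.0, 7.5  # theta-band center
        t = np.arange(int(fs * dur)) / fs
        spec = compute_psd([amp * np.sin(2 * np.pi * f0 * t)], fs)
        band = (spec.freqs >= 5) & (spec.freqs <= 10)
        power = np.trapezoid(spec.values[band], spec.freqs[band])
        assert power == pytest.approx(amp**2 / 2, rel=0.05)

    def test_white_noise_density_is_flat_at_variance_over_nyquist(self):
        fs, sigma = 1000.0, 1.5
        rng = np.random.default_rng(0)
        means = []
        for _ in range(100):
            spec = compute_psd([sigma * rng.standard_normal(8000)], fs)
            means.append(spec.values[(spec.freqs > 5) & (spec.freqs < 450)].mean())
        assert np.mean(means) == pytest.approx(sigma**2 / (fs / 2), rel=0.02)

    def test_zero_signal_gives_zero_density(self):
        spec = compute_psd([np.zeros(10_000)], 1000.0)
        assert np.all(spec.values == 0)

    def test_short_segments_skipped_then_error(self):
        with pytest.raises(ValueError, match="shorter than one Welch window"):
            compute_psd([np.zeros(100)], 1000.0)


class TestCoherence:
    def test_identical_channels_give_unit_coherence(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(20_000)
        spec = compute_coherence([x], [x.copy()], 1000.0)
        assert np.all(spec.values > 0.999)

    def test_independent_channels_sit_at_window_count_bias_floor(self):
        rng = np.random.default_rng(2)
        n_windows = 1000
        n = (n_windows + 1) * 1000  # 2 s windows, 50% overlap at 1 kHz
        spec = compute_coherence(
            [rng.standard_normal(n)], [rng.standard_normal(n)], 1000.0
        )
        mean_coh = spec.values[(spec.freqs > 1) & (spec.freqs < 450)].mean()
        assert mean_coh < 3.0 / n_windows

    def test_single_window_rejected_as_degenerate(self):
        x = np.zeros(2000)  # exactly one 2 s window
        with pytest.raises(ValueError, match="Welch windows"):
            compute_coherence([x], [x], 1000.0)

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_invariant_to_common_positive_rescaling(self, scale):
        rng = np.random.default_rng(3)
        shared = rng.standard_normal(12_000)
        x = shared + 0.5 * rng.standard_normal(12_000)
        y = shared + 0.5 * rng.standard_normal(12_000)
        base = compute_coherence([x], [y], 1000.0)
        scaled = compute_coherence([scale * x], [scale * y], 1000.0)
        np.testing.assert_allclose(base.values, scaled.values, atol=1e-9)


class TestBandSummarize:
    def test_flat_power_density_returns_log10(self):
        freqs = np.arange(0.5, 100.0, 0.5)
        spec = bd.Spectrum(freqs=freqs, values=np.full_like(freqs, 0.02), kind="power")
        vals = band_summarize(spec)
        assert all(v == pytest.approx(np.log10(0.02)) for v in vals.values())

    def test_unit_coherence_summarizes_to_one(self):
        freqs = np.arange(0.5, 100.0, 0.5)
        spec = bd.Spectrum(freqs=freqs, values=np.ones_like(freqs), kind="coherence")
        assert all(v == pytest.approx(1.0) for v in band_summarize(spec).values())

    def test_empty_band_error_names_the_band(self):
        spec = bd.Spectrum(freqs=np.array([50.0, 60.0]), values=np.ones(2), kind="power")
        with pytest.raises(ValueError, match="Δ"):
            band_summarize(spec)

    def test_single_band_source_dominates_driven_band(self):
        a = np.zeros((2, 6))
        a[:, 1] = 3.0  # drive theta only
        spec = bd.MixingSpec.from_shared_gains(
            a, noise_sd=0.1, duration=30.0, seed=4
        )
        rec = bd.simulate_lfp_recording(spec, channels=ChannelScheme(("cl", "cr")))
        fv = bd.extract_feature_vector(rec)
        assert fv.values["Pcl θ"] > fv.values["Pcl β"] + 2
        assert fv.values["Cclcr θ"] > 0.9


class TestFeatureVector:
    @pytest.mark.parametrize(
        "n_channels, n_bands, total, n_power, n_coh",
        [(4, 6, 60, 24, 36), (2, 6, 18, 12, 6), (3, 1, 6, 3, 3)],
    )
    def test_feature_count_law(self, n_channels, n_bands, total, n_power, n_coh):
        channels = ChannelScheme(("cl", "cr", "sl", "sr")[:n_channels])
        bands = BandScheme(tuple(b for b in bd.DEFAULT_BANDS)[:n_bands])
        names = feature_names(channels, bands)
        assert len(names) == total
        assert sum(n.startswith("P") for n in names) == n_power
        assert sum(n.startswith("C") for n in names) == n_coh

    def test_extraction_produces_60_named_features(self, uniform_features):
        assert len(uniform_features) == 60
        assert "Pcr Δ" in uniform_features.values
        assert "Cclcr hγ" in uniform_features.values

    @pytest.mark.parametrize(
        "kind, locs, band, expected",
        [
            ("power", ("cr",), "Δ", "Pcr Δ"),
            ("coherence", ("cl", "cr"), "hγ", "Cclcr hγ"),
            ("coherence", ("cr", "cl"), "hγ", "Cclcr hγ"),  # order normalized
            ("coherence", ("sr", "sl"), "θ", "Cslsr θ"),
        ],
    )
    def test_feature_label_convention(self, kind, locs, band, expected):
        assert feature_label(kind, locs, band, bd.DEFAULT_CHANNELS) == expected

    def test_feature_label_rejects_unknown_names(self):
        with pytest.raises(KeyError):
            feature_label("power", ("cl",), "nope", bd.DEFAULT_CHANNELS)
        with pytest.raises(KeyError):
            feature_label("power", ("xx",), "Δ", bd.DEFAULT_CHANNELS)


class TestStability:
    def _table(self, rng, n_animals=6, shift=0.0, jitter=0.0):
        rows = []
        for i in range(n_animals):
            group = "A" if i < n_animals // 2 else "B"
            base = rng.standard_normal()
            for sess in ("T1", "T2"):
                rows.append(
                    {
                        "animal_id": f"r{i}",
                        "session_id": sess,
                        "feat": base
                        + (shift if group == "B" else 0.0)
                        + jitter * rng.standard_normal(),
                    }
                )
        groups = {f"r{i}": ("A" if i < n_animals // 2 else "B") for i in range(n_animals)}
        return pd.DataFrame(rows), groups

    def test_identical_sessions_have_zero_within_difference(self):
        table, groups = self._table(np.random.default_rng(0), jitter=0.0, shift=1.0)
        rep = feature_stability(table, groups)
        assert rep.loc["feat", "within_abs_diff"] == 0.0
        assert rep.loc["feat", "ratio"] == 0.0

    def test_planted_group_effect_gives_ratio_below_one(self):
        table, groups = self._table(np.random.default_rng(1), jitter=0.05, shift=3.0)
        rep = feature_stability(table, groups)
        assert rep.loc["feat", "ratio"] < 1.0

    def test_single_group_rejected(self):
        table, _ = self._table(np.random.default_rng(2))
        with pytest.raises(ValueError, match="two groups"):
            feature_stability(table, {a: "A" for a in table["animal_id"]})

    def test_animal_missing_session_excluded(self, caplog):
        table, groups = self._table(np.random.default_rng(3), shift=2.0)
        table = table.drop(table[(table.animal_id == "r0") & (table.session_id == "T2")].index)
        rep = feature_stability(table, groups)
        assert np.isfinite(rep.loc["feat", "ratio"])
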