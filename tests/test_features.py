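import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from leadii.features import (
    FEATURE_SUBSETS,
    METADATA_FEATURES,
    SIGNAL_FEATURES,
    DegenerateSignalWarning,
    PowerSpectrum,
    approximate_entropy,
    extract_spectral_features,
    extract_time_features,
    fuzzy_entropy,
    lac,
    power_spectrum,
    signal_features,
    spectral_entropy,
    wavelet_entropy,
)

FS = 500.0


@pytest.fixture(scope="module")
def fixture_200(request):
    return np.random.default_rng(99).standard_normal(200)


def _flat_spectrum(n=64, value=2.0, band=(0.5, 50.0)):
    freqs = np.linspace(0.0, 250.0, n)
    power = np.full(n, value)
    return PowerSpectrum(freqs=freqs, amplitude=np.sqrt(power), power=power,
                         band=band)


class TestTimeFeatures:
    def test_amplitude_range_tiny_example(self):
        x = np.tile([0.0, 1.0, -1.0, 0.0], 30)
        assert extract_time_features(x, FS)["AR"] == 2.0

    def test_constant_signal_degenerate(self):
        x = np.full(500, 2.5)
        with pytest.warns(DegenerateSignalWarning):
            f = extract_time_features(x, FS)
        assert f["AR"] == 0.0
        assert f["MA"] == 2.5
        assert f["MSI"] == 0.0
        assert f["RMS1"] == 2.5
        assert f["MS"] == 0.0

    def test_sneo_matches_tone_closed_form(self):
        a, f0 = 1.3, 15.0
        t = np.arange(5000) / FS
        sneo = extract_time_features(a * np.sin(2 * np.pi * f0 * t), FS)["SNEO"]
        predicted = a ** 2 * np.sin(2 * np.pi * f0 / FS) ** 2
        assert abs(sneo - predicted) / predicted < 0.01

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            extract_time_features(np.zeros(50), FS)

    @pytest.mark.parametrize("name, oracle", [
        ("AR", lambda x: oracles.amplitude_range(list(x))),
        ("MA", lambda x: oracles.mean_amplitude(list(x))),
        ("MSI", lambda x: oracles.median_stepping_increment(list(x))),
        ("SignInt", lambda x: oracles.signal_integral(list(x), FS)),
        ("RMS1", lambda x: oracles.rms(list(x))),
        ("MS", lambda x: oracles.mean_slope(list(x), FS)),
        ("MdS", lambda x: oracles.median_slope(list(x), FS)),
        ("SNEO", lambda x: oracles.sneo(list(x))),
    ])
    def test_agrees_with_brute_force(self, fixture_200, name, oracle):
        ours = extract_time_features(fixture_200, FS)[name]
        assert ours == pytest.approx(oracle(fixture_200), rel=1e-9)


class TestPowerSpectrum:
    def test_tone_peak_within_one_bin(self):
        t = np.arange(5000) / FS
        ps = power_spectrum(np.sin(2 * np.pi * 10.0 * t), FS)
        pf = extract_spectral_features(ps)["PF"]
        assert abs(pf - 10.0) <= FS / 2048

    def test_zero_signal_zero_power(self):
        ps = power_spectrum(np.zeros(5000), FS)
        assert ps.power.sum() == 0.0

    def test_short_input_zero_padded_and_flagged(self):
        ps = power_spectrum(np.ones(100), FS)
        assert ps.zero_padded
        assert ps.freqs.size == 1025

    def test_white_noise_flat_bounded_ratio(self):
        rng = np.random.default_rng(5)
        ps = power_spectrum(rng.standard_normal(60000), FS)
        p = ps.power[ps.band_mask()]
        assert p.max() / p.min() < 50  # chi^2 fluctuation only, no structure


class TestSpectralFeatures:
    def test_tone_concentrated(self):
        t = np.arange(5000) / FS
        sf = extract_spectral_features(power_spectrum(np.sin(2 * np.pi * 10 * t), FS))
        assert abs(sf["CF"] - 10.0) <= 2 * FS / 2048
        assert abs(sf["PF"] - 10.0) <= FS / 2048
        assert sf["SFM"] < 0.05

    def test_white_noise_flat(self):
        vals = [extract_spectral_features(
            power_spectrum(np.random.default_rng(s).standard_normal(20000), FS)
        )["SFM"] for s in range(20)]
        assert np.mean(vals) > 0.8

    def test_uniform_band_exact(self):
        sf = extract_spectral_features(_flat_spectrum())
        assert sf["SFM"] == 1.0
        mask = _flat_spectrum().band_mask()
        f = _flat_spectrum().freqs[mask]
        assert sf["CF"] == pytest.approx(f.mean())
        assert sf["PSA"] == pytest.approx(sf["ENRG"] / mask.sum())

    def test_zero_band_power_flagged_missing(self):
        ps = _flat_spectrum(value=0.0)
        with pytest.warns(DegenerateSignalWarning):
            sf = extract_spectral_features(ps)
        assert all(np.isnan(v) for v in sf.values())

    @pytest.mark.parametrize("name, oracle", [
        ("CF", oracles.centroid_frequency),
        ("PF", oracles.peak_frequency),
        ("ENRG", oracles.total_energy),
        ("SFM", oracles.spectral_flatness),
        ("MP", oracles.max_power),
    ])
    def test_agrees_with_brute_force(self, fixture_200, name, oracle):
        ps = power_spectrum(fixture_200, FS)
        ours = extract_spectral_features(ps)[name]
        ref = oracle(list(ps.freqs), list(ps.power), *ps.band)
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_amsa_agrees_with_brute_force(self, fixture_200):
        ps = power_spectrum(fixture_200, FS)
        ours = extract_spectral_features(ps)["AMSA"]
        ref = oracles.amplitude_spectrum_area(list(ps.freqs), list(ps.amplitude),
                                              *ps.band)
        assert ours == pytest.approx(ref, rel=1e-9)


class TestEntropyFamily:
    def test_spectral_entropy_uniform_is_one(self):
        assert spectral_entropy(_flat_spectrum()) == 1.0

    def test_spectral_entropy_single_bin_is_zero(self):
        ps = _flat_spectrum(value=0.0)
        power = ps.power.copy()
        power[5] = 5.0  # in-band bin (freq ~19.8 Hz)
        single = PowerSpectrum(freqs=ps.freqs, amplitude=np.sqrt(power),
                               power=power, band=ps.band)
        assert spectral_entropy(single) == 0.0

    def test_spectral_entropy_agrees_with_brute_force(self, fixture_200):
        ps = power_spectrum(fixture_200, FS)
        ref = oracles.spectral_entropy(list(ps.freqs), list(ps.power), *ps.band)
        assert spectral_entropy(ps) == pytest.approx(ref, rel=1e-9)

    def test_noise_more_irregular_than_tone(self):
        rng = np.random.default_rng(0)
        noise = rng.standard_normal(1000)
        tone = np.sin(2 * np.pi * 5 * np.arange(1000) / 125)
        assert approximate_entropy(noise) > approximate_entropy(tone)
        assert fuzzy_entropy(noise) > fuzzy_entropy(tone)

    def test_apen_agrees_with_brute_force(self, fixture_200):
        ours = approximate_entropy(fixture_200)
        ref = oracles.approximate_entropy(list(fixture_200))
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_wavelet_entropy_in_unit_interval(self, rng):
        assert 0.0 <= wavelet_entropy(rng.standard_normal(5000)) <= 1.0

    def test_constant_signal_entropies_missing(self):
        with pytest.warns(DegenerateSignalWarning):
            assert np.isnan(approximate_entropy(np.full(300, 1.0)))
        with pytest.warns(DegenerateSignalWarning):
            assert np.isnan(fuzzy_entropy(np.full(300, 1.0)))


class TestLAC:
    def test_agrees_with_brute_force(self, fixture_200):
        assert lac(fixture_200) == pytest.approx(
            oracles.lac(list(fixture_200)), rel=1e-9)

    def test_tone_exceeds_white_noise(self, rng):
        noise = rng.standard_normal(2000)
        tone = np.sin(2 * np.pi * 10 * np.arange(2000) / FS)
        assert lac(tone) > lac(noise)

    def test_ar1_single_lag(self):
        # AR(1) with coefficient 0.5: rho(1) -> 0.5 at large N
        rng = np.random.default_rng(3)
        x = np.zeros(200000)
        eps = rng.standard_normal(x.size)
        for i in range(1, x.size):
            x[i] = 0.5 * x[i - 1] + eps[i]
        assert lac(x, max_lag=1) == pytest.approx(np.log10(0.5), abs=0.02)

    def test_zero_variance_flagged(self):
        with pytest.warns(DegenerateSignalWarning):
            assert np.isnan(lac(np.full(300, 2.0)))


class TestInvariances:
    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=10.0,
                     allow_nan=False, allow_infinity=False))
    def test_scale_equivariance(self, c):
        x = np.random.default_rng(12).standard_normal(1200)
        f1 = signal_features(x, FS)
        f2 = signal_features(c * x, FS)
        linear = ("AR", "PPA", "MA", "MSI", "SignInt", "RMS1", "RMS2", "MS", "MdS")
        quadratic = ("SNEO", "ENRG", "MP", "CP")
        invariant = ("SFM", "SpeEnt", "Hu", "ScE", "ApEn", "FuzzyEn")
        for k in linear:
            assert f2[k] == pytest.approx(c * f1[k], rel=1e-6, abs=1e-12)
        for k in quadratic:
            assert f2[k] == pytest.approx(c ** 2 * f1[k], rel=1e-6, abs=1e-12)
        for k in invariant:
            assert f2[k] == pytest.approx(f1[k], rel=1e-6, abs=1e-9)

    def test_spectral_features_shift_invariant_within_bin(self):
        t = np.arange(5000) / FS
        x = np.sin(2 * np.pi * 7 * t) + 0.5 * np.sin(2 * np.pi * 19 * t)
        f1 = extract_spectral_features(power_spectrum(x, FS))
        f2 = extract_spectral_features(power_spectrum(np.roll(x, 1024), FS))
        bin_hz = FS / 2048
        assert abs(f1["CF"] - f2["CF"]) <= bin_hz
        assert abs(f1["PF"] - f2["PF"]) <= bin_hz
        for k in ("ENRG", "MP", "AMSA", "PSA"):
            assert f2[k] == pytest.approx(f1[k], rel=0.02)
        # SFM (geometric mean) and CP (a leakage bin between the tones) are
        # dominated by the phase-sensitive leakage floor: order of magnitude only
        assert f2["SFM"] == pytest.approx(f1["SFM"], rel=0.5)
        assert f2["CP"] == pytest.approx(f1["CP"], rel=0.5)


class TestAssembly:
    def test_table_contract(self, small_table):
        assert small_table.shape[1] == 39  # 38 features + label
        assert list(small_table.columns[:13]) == list(METADATA_FEATURES)
        assert list(small_table.columns[13:38]) == list(SIGNAL_FEATURES)
        assert set(small_table["label"]) == {"AFIB", "SB", "SR", "GSVT"}

    def test_gender_encoded_binary(self, small_table):
        assert set(small_table["gender"]) <= {0.0, 1.0}

    def test_subset_registry_sizes(self):
        assert len(FEATURE_SUBSETS["general4"]) == 4
        assert len(FEATURE_SUBSETS["morph13"]) == 13
        assert len(FEATURE_SUBSETS["ours29"]) == 29
        assert len(FEATURE_SUBSETS["all38"]) == 38
        assert set(FEATURE_SUBSETS["general4"]) <= set(FEATURE_SUBSETS["ours29"])

    def test_record_without_diagnostics_skipped(self, small_cohort):
        from leadii.features import assemble_feature_table
        from leadii.io import get_scheme
        records, diags = small_cohort
        table = assemble_feature_table(records[:4], diags[:3],
                                       get_scheme("four"), denoise=False)
        assert table.shape[0] == 3
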