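"""Feature extraction: per-epoch oracle equivalence and windowing contracts.

The oracle functions here are deliberately naive single-window
re-implementations (explicit loops, no shared code with the package).
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capscore.features import (
    FEATURE_ORDER,
    FeatureSeries,
    MmsdParams,
    extract_feature_matrix,
    higuchi_fd,
    lz76_complexity,
    lzc_feature,
    mean_amplitude,
    mmsd,
    shannon_entropy_feature,
    stft_features,
    teo_feature,
    variance_feature,
    zcr_feature,
)
from capscore.recording import EegRecording


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def oracle_teo_epoch(x, fs, t):
    vals = []
    for n in range(t * fs, (t + 1) * fs):
        if 0 < n < len(x) - 1:
            vals.append(x[n] ** 2 - x[n - 1] * x[n + 1])
        elif n == 0:
            vals.append(x[1] ** 2 - x[0] * x[2])
        else:
            vals.append(x[-2] ** 2 - x[-3] * x[-1])
    return max(vals)


def oracle_zcr_epoch(x, fs, t):
    seg = x[t * fs:(t + 1) * fs]
    signs, last = [], 0.0
    for v in seg:
        s = int(v > 0) - int(v < 0)
        if s == 0:
            s = last
        signs.append(s)
        last = s if s != 0 else last
    # leading zeros inherit the first nonzero sign
    first = next((s for s in signs if s != 0), 0)
    signs = [first if s == 0 else s for s in signs]
    return sum(1 for a, b in zip(signs, signs[1:]) if a != b)


def oracle_lz76(bits):
    """Exhaustive parsing by explicit substring enumeration."""
    s = "".join("1" if b else "0" for b in bits)
    phrases, i = 0, 0
    while i < len(s):
        k = 1
        while i + k <= len(s):
            candidate = s[i:i + k]
            history = s[:i + k - 1]
            found = any(history[j:j + k] == candidate for j in range(len(history) - k + 1))
            if not found:
                break
            k += 1
        phrases += 1
        i += k
    return phrases


def oracle_shent_epoch(x, fs, t, bins=16):
    seg = x[t * fs:(t + 1) * fs]
    lo, hi = min(seg), max(seg)
    if hi <= lo:
        return 0.0
    counts = [0] * bins
    for v in seg:
        idx = min(int((v - lo) / (hi - lo) * bins), bins - 1)
        counts[idx] += 1
    total = sum(counts)
    return -sum(c / total * np.log2(c / total) for c in counts if c)


def oracle_variance_epoch(x, fs, t):
    seg = x[t * fs:(t + 1) * fs]
    mean = sum(seg) / len(seg)
    return sum((v - mean) ** 2 for v in seg) / (len(seg) - 1)


def oracle_mean_amp(x, fs, window, t):
    i1 = (t + 1) * fs
    i0 = max(0, i1 - window * fs)
    seg = x[i0:i1]
    return sum(abs(v) for v in seg) / len(seg)


def oracle_higuchi(seg, k_max=8):
    n = len(seg)
    logs_k, logs_l = [], []
    for k in range(1, k_max + 1):
        lms = []
        for m in range(k):
            idx = list(range(m, n, k))
            if len(idx) < 2:
                continue
            dist = sum(abs(seg[idx[i]] - seg[idx[i - 1]]) for i in range(1, len(idx)))
            lms.append(dist * (n - 1) / ((len(idx) - 1) * k) / k)
        logs_k.append(np.log(1.0 / k))
        logs_l.append(np.log(np.mean(lms)))
    return np.polyfit(logs_k, logs_l, 1)[0]


def oracle_stft(x, fs, t):
    i1 = (t + 1) * fs
    i0 = max(0, i1 - 3 * fs)
    seg = np.asarray(x[i0:i1]) * np.hamming(i1 - i0)
    mag = np.abs(np.fft.rfft(seg))
    freqs = np.fft.rfftfreq(i1 - i0, 1.0 / fs)
    if mag.sum() == 0:
        return 0.0, 0.0, 0.0
    return (freqs[np.argmax(mag)],
            float((freqs * mag).sum() / mag.sum()),
            float(np.trapezoid(mag, freqs)))


FS = 128
RNG = np.random.default_rng(99)
SIGNAL = RNG.standard_normal(FS * 70) * 12
EPOCHS = sorted(RNG.choice(70, size=20, replace=False))


class TestOracleEquivalence:
    """Every per-epoch feature equals its single-window oracle on 20 random epochs."""

    def test_mean_amplitude_matches_windowed_mean(self):
        for window in (2, 60):
            series = mean_amplitude(SIGNAL, FS, window, window - 1)
            for t in EPOCHS:
                assert series.values[t] == pytest.approx(
                    oracle_mean_amp(SIGNAL, FS, window, t), rel=1e-9)

    def test_teo_matches_direct_epoch_max(self):
        series = teo_feature(SIGNAL, FS)
        for t in EPOCHS:
            assert series.values[t] == pytest.approx(
                oracle_teo_epoch(SIGNAL, FS, t), rel=1e-9)

    def test_zcr_matches_exactly(self):
        series = zcr_feature(SIGNAL, FS)
        for t in EPOCHS:
            assert series.values[t] == oracle_zcr_epoch(SIGNAL, FS, t)

    def test_lzc_matches_enumeration_oracle_exactly(self):
        series = lzc_feature(SIGNAL, FS)
        for t in EPOCHS:
            seg = SIGNAL[t * FS:(t + 1) * FS]
            assert series.values[t] == oracle_lz76(seg > np.median(seg))

    def test_shannon_entropy_matches_histogram_oracle(self):
        series = shannon_entropy_feature(SIGNAL, FS)
        for t in EPOCHS:
            assert series.values[t] == pytest.approx(
                oracle_shent_epoch(SIGNAL, FS, t), rel=1e-9)

    def test_variance_matches_two_pass_oracle(self):
        series = variance_feature(SIGNAL, FS)
        for t in EPOCHS:
            assert series.values[t] == pytest.approx(
                oracle_variance_epoch(SIGNAL, FS, t), rel=1e-9)

    def test_higuchi_matches_direct_implementation(self):
        for t in EPOCHS:
            seg = SIGNAL[t * FS:(t + 1) * FS]
            assert higuchi_fd(seg) == pytest.approx(oracle_higuchi(seg), rel=1e-9)

    def test_stft_descriptors_match_fft_oracle(self):
        mx, mn, ar = stft_features(SIGNAL, FS)
        for t in EPOCHS:
            omx, omn, oar = oracle_stft(SIGNAL, FS, t)
            assert mx.values[t] == pytest.approx(omx, rel=1e-9, abs=1e-12)
            assert mn.values[t] == pytest.approx(omn, rel=1e-9)
            assert ar.values[t] == pytest.approx(oar, rel=1e-9)


class TestAmplitudeFeatures:
    def test_constant_signal_gives_constant_amplitude(self):
        series = mean_amplitude(np.full(FS * 70, -3.0), FS, 60, 59)
        assert np.allclose(series.values, 3.0)

    def test_long_window_shares_59s_of_samples(self):
        # consecutive trailing 60 s windows at 1 s step differ by fs samples
        series = mean_amplitude(SIGNAL, FS, 60, 59)
        t = 65
        w1 = np.abs(SIGNAL[(t + 1 - 60) * FS:(t + 1) * FS])
        w2 = np.abs(SIGNAL[(t + 2 - 60) * FS:(t + 2) * FS])
        assert len(np.intersect1d(w1, w2)) >= 59 * FS  # shared 59 s
        assert series.values[t] == pytest.approx(w1.mean())

    def test_step_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mean_amplitude(SIGNAL, FS, 60, 57)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            mean_amplitude(SIGNAL[:FS * 10], FS, 60, 59)

    def test_mmsd_zero_when_short_equals_long(self):
        c = mean_amplitude(SIGNAL, FS, 2, 1)
        assert np.allclose(mmsd(c, c).values, 0.0)

    def test_mmsd_is_one_when_short_doubles_long(self):
        c = mean_amplitude(SIGNAL, FS, 2, 1)
        c2 = FeatureSeries(c.name, 2 * c.values)
        assert np.allclose(mmsd(c2, c).values, 1.0)

    def test_mmsd_detects_planted_delta_burst(self):
        t = np.arange(FS * 200) / FS
        x = np.sin(2 * np.pi * 2 * t)  # 2 Hz tone
        x[100 * FS:110 * FS] *= 2.0    # 10 s amplitude doubling
        c_long = mean_amplitude(x, FS, 60, 59)
        c_short = mean_amplitude(x, FS, 2, 1)
        vals = mmsd(c_short, c_long).values
        assert vals[102:109].mean() > 0.8
        assert abs(vals[60:95].mean()) < 0.1

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=20, deadline=None)
    def test_mmsd_scale_invariance(self, a):
        x = SIGNAL[:FS * 65]
        def compute(sig):
            return mmsd(mean_amplitude(sig, FS, 2, 1),
                        mean_amplitude(sig, FS, 60, 59)).values
        assert np.allclose(compute(a * x), compute(x), atol=1e-9)


class TestEpochFeatures:
    def test_teo_of_constant_is_zero(self):
        assert np.allclose(teo_feature(np.full(FS * 3, 5.0), FS).values, 0.0)

    def test_teo_arithmetic_on_triple(self):
        from capscore.features import teager_energy
        assert teager_energy(np.array([1.0, 2.0, 3.0]))[1] == 4 - 3

    def test_teo_sinusoid_epoch_max(self):
        omega = 2 * np.pi * 5 / FS
        x = 3.0 * np.sin(omega * np.arange(FS * 10))
        vals = teo_feature(x, FS).values
        assert np.allclose(vals, 9 * np.sin(omega) ** 2, rtol=1e-6)

    def test_zcr_positive_constant_is_zero(self):
        assert np.allclose(zcr_feature(np.ones(FS * 3), FS).values, 0.0)

    def test_zcr_alternating_is_127(self):
        x = np.resize([1.0, -1.0], FS * 2)
        assert zcr_feature(x, FS).values[0] == FS - 1

    def test_zcr_5hz_tone_is_10_per_second(self):
        # 2 crossings per cycle x 5 cycles; cosine phase keeps every
        # crossing strictly inside its epoch
        t = np.arange(FS * 5) / FS
        x = np.cos(2 * np.pi * 5 * t)
        assert np.allclose(zcr_feature(x, FS).values, 10)

    def test_lz76_constant_string_is_2(self):
        assert lz76_complexity([0] * 128) == 2
        assert lz76_complexity([1] * 128) == 2

    def test_lz76_periodic_below_random(self):
        periodic = [0, 1] * 64
        random = list(RNG.integers(0, 2, 128))
        assert lz76_complexity(periodic) < lz76_complexity(random)

    def test_stft_zero_signal_convention(self):
        mx, mn, ar = stft_features(np.zeros(FS * 5), FS)
        assert (mx.values == 0).all() and (ar.values == 0).all()

    def test_stft_pure_tone_peak_within_one_bin(self):
        t = np.arange(FS * 10) / FS
        mx, _, _ = stft_features(np.sin(2 * np.pi * 10 * t), FS)
        assert np.all(np.abs(mx.values[3:] - 10) <= 1 / 3 + 1e-9)

    def test_stft_centroid_between_mixed_tones(self):
        t = np.arange(FS * 10) / FS
        x = np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 20 * t)
        _, mn, _ = stft_features(x, FS)
        assert np.all((mn.values[3:] > 5) & (mn.values[3:] < 20))

    def test_shent_two_point_distribution_is_one_bit(self):
        x = np.resize([0.0, 1.0], FS * 2)
        assert np.allclose(shannon_entropy_feature(x, FS).values, 1.0)

    def test_shent_constant_epoch_is_zero(self):
        assert np.allclose(shannon_entropy_feature(np.full(FS * 2, 3.0), FS).values, 0.0)

    def test_higuchi_ramp_near_one(self):
        fd = higuchi_fd(np.linspace(0, 1, FS))
        assert 1.0 - 1e-9 <= fd <= 1.1

    def test_higuchi_white_noise_near_two(self):
        fd = higuchi_fd(RNG.standard_normal(FS))
        assert 1.8 <= fd <= 2.05

    def test_higuchi_constant_convention(self):
        assert higuchi_fd(np.full(FS, 7.0)) == 1.0

    def test_variance_of_123_is_one(self):
        # 3-sample epochs: s^2([1,2,3]) with the N-1 divisor is exactly 1
        assert variance_feature(np.array([1.0, 2.0, 3.0]), fs=3).values[0] == 1.0

    def test_variance_constant_epoch_is_zero(self):
        assert np.allclose(variance_feature(np.full(FS, 2.5), FS).values, 0.0)

    def test_variance_unbiased_divisor(self):
        x = np.zeros(FS)
        x[:3] = [1.0, 2.0, 3.0]
        manual = np.var(x, ddof=1)
        assert variance_feature(x, FS).values[0] == pytest.approx(manual, rel=1e-12)


class TestEmd:
    def test_reconstruction_identity(self):
        from capscore._emd import emd
        x = SIGNAL[:FS * 30]
        imfs = emd(x, max_imfs=12)
        residual = x - np.sum(imfs, axis=0)
        recon = np.sum(imfs, axis=0) + residual
        assert np.abs(recon - x).max() <= 1e-6 * np.abs(x).max()

    def test_pure_tone_concentrates_in_first_imf(self):
        from capscore._emd import emd
        t = np.arange(FS * 20) / FS
        x = np.sin(2 * np.pi * 10 * t)
        imfs = emd(x, max_imfs=12)
        energy = [np.sum(i ** 2) for i in imfs]
        assert energy[0] / np.sum(x ** 2) >= 0.9

    def test_always_twelve_series(self):
        from capscore.features import emd_features
        out = emd_features(SIGNAL[:FS * 20], FS)
        assert len(out) == 12
        assert [s.name for s in out] == [f"EMD_{i}" for i in range(1, 13)]

    def test_too_short_signal_rejected(self):
        from capscore.features import emd_features
        with pytest.raises(ValueError):
            emd_features(SIGNAL[:FS * 5], FS)


class TestFullMatrix:
    def test_exactly_55_rows_in_table_order(self, short_features):
        fm, _ = short_features
        assert fm.names == list(FEATURE_ORDER)
        assert len(fm.names) == 55

    def test_band_inventory(self):
        def count(prefix):
            return sum(1 for n in FEATURE_ORDER if n.split("_")[0] == prefix)
        assert count("MMSD") == 5 and count("TEO") == 5
        assert sum(1 for n in FEATURE_ORDER if n.startswith("C_tau_")) == 5
        assert sum(1 for n in FEATURE_ORDER if n.startswith("C_tau0_")) == 5
        assert count("ZCR") == 6 and count("LZC") == 6 and count("Var") == 6
        assert count("EMD") == 12
        assert {"Max_freq", "Mean_freq", "Spec_area", "ShEnt", "FD"} < set(FEATURE_ORDER)

    def test_one_value_per_second(self, short_features):
        fm, _ = short_features
        assert fm.n_seconds == 600

    def test_all_finite(self, short_features):
        fm, _ = short_features
        assert np.isfinite(fm.data.to_numpy()).all()

    def test_deterministic(self):
        rec = EegRecording(SIGNAL[:FS * 130] if len(SIGNAL) >= FS * 130
                           else np.resize(SIGNAL, FS * 130), fs=FS, subject_id="X")
        a = extract_feature_matrix(rec)
        b = extract_feature_matrix(rec)
        assert a.data.equals(b.data)

    def test_short_recording_rejected(self):
        rec = EegRecording(SIGNAL[:FS * 70], fs=FS)
        with pytest.raises(ValueError, match="120"):
            extract_feature_matrix(rec)

    def test_mmsd_params_validation(self):
        with pytest.raises(ValueError):
            MmsdParams(tau=2, tau0=2)
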