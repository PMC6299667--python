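"""The 55 per-second EEG features.

All features are emitted at exactly 1 Hz on a shared time base of
``n_seconds`` whole-second epochs:

* ``MMSD_phi``      (5 sub-bands) - relative excess of the 2 s mean amplitude
  over the trailing 60 s background amplitude, (C_tau0 - C_tau)/C_tau;
* ``C_tau_phi``     (5) - trailing 60 s mean rectified amplitude (59 s overlap);
* ``C_tau0_phi``    (5) - trailing 2 s mean rectified amplitude (1 s overlap);
* ``TEO_phi``       (5) - per-second maximum of the Teager energy
  x[n]^2 - x[n-1]x[n+1], computed over the whole series first;
* ``ZCR_phi``       (6, incl. BB) - zero crossings per 1 s epoch;
* ``LZC_phi``       (6) - LZ76 exhaustive-parsing complexity of the epoch
  binarized at its median;
* ``Max_freq``, ``Mean_freq``, ``Spec_area`` (broadband) - short-time Fourier
  descriptors on a trailing 3 s window stepping 1 s;
* ``EMD_1..12``     - per-second means of the first 12 intrinsic mode
  functions of the broadband signal (full-signal decomposition first);
* ``ShEnt``         - Shannon entropy of a 16-bin amplitude histogram;
* ``FD``            - Higuchi fractal dimension (k_max = 8);
* ``Var_phi``       (6) - unbiased sample variance per epoch.

Warm-up: seconds earlier than a trailing window's nominal length use a
growing window over all samples available so far, so every row shares the
same time base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from capscore._emd import emd
from capscore.bands import SUB_BANDS, decompose
from capscore.recording import EegRecording

ALL_BANDS = ("BB",) + SUB_BANDS

#: canonical row order of the 55-feature matrix
FEATURE_ORDER: tuple = (
    tuple(f"MMSD_{b}" for b in SUB_BANDS)
    + tuple(f"C_tau_{b}" for b in SUB_BANDS)
    + tuple(f"C_tau0_{b}" for b in SUB_BANDS)
    + tuple(f"TEO_{b}" for b in SUB_BANDS)
    + tuple(f"ZCR_{b}" for b in ALL_BANDS)
    + tuple(f"LZC_{b}" for b in ALL_BANDS)
    + ("Max_freq", "Mean_freq", "Spec_area")
    + tuple(f"EMD_{i}" for i in range(1, 13))
    + ("ShEnt", "FD")
    + tuple(f"Var_{b}" for b in ALL_BANDS)
)

MMSD_EPS = 1e-12  # µV floor for the background amplitude denominator


@dataclass
class MmsdParams:
    """Background (tau) and foreground (tau0) window lengths in seconds."""

    tau: float = 60.0
    tau0: float = 2.0

    def __post_init__(self) -> None:
        if not self.tau > self.tau0 >= 1:
            raise ValueError("windows must satisfy tau > tau0 >= 1")


@dataclass
class FeatureSeries:
    """One named feature sampled at 1 Hz."""

    name: str
    values: np.ndarray
    band: str = "none"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class FeatureMatrix:
    """55 named feature rows aligned to seconds, for one subject."""

    data: pd.DataFrame  # index = feature names, columns = seconds
    subject_id: str = ""

    @classmethod
    def from_series(cls, series: list[FeatureSeries], subject_id: str = "") -> "FeatureMatrix":
        names = [s.name for s in series]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names")
        lengths = {len(s) for s in series}
        if len(lengths) != 1:
            raise ValueError(f"feature rows have unequal lengths: {sorted(lengths)}")
        df = pd.DataFrame(np.vstack([s.values for s in series]), index=names)
        return cls(data=df, subject_id=subject_id)

    @property
    def names(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_seconds(self) -> int:
        return self.data.shape[1]

    def row(self, name: str) -> np.ndarray:
        return self.data.loc[name].to_numpy()

    def samples(self, names=None) -> np.ndarray:
        """(n_seconds, n_features) design matrix for the classifiers."""
        df = self.data if names is None else self.data.loc[list(names)]
        return df.to_numpy().T


def _epochs(x: np.ndarray, fs: int) -> np.ndarray:
    """View the signal as (n_seconds, fs) whole-second epochs."""
    n = (len(x) // fs) * fs
    return x[:n].reshape(-1, fs)


# ---------------------------------------------------------------------------
# amplitude features
# ---------------------------------------------------------------------------

def mean_amplitude(band_signal, fs: float, window: float, overlap: float,
                   name: str = "C", band: str = "none") -> FeatureSeries:
    """Trailing-window mean rectified amplitude, one value per second.

    The value at second t is the mean of |x| over the window ending at
    t+1 s; ``window - overlap`` must be 1 s so the series is at 1 Hz.
    Early seconds use a growing window over the samples available so far.
    """
    if not window > overlap >= 0:
        raise ValueError("need window > overlap >= 0")
    if abs((window - overlap) - 1.0) > 1e-9:
        raise ValueError("window minus overlap must be 1 s for a 1 Hz feature")
    x = np.asarray(band_signal, dtype=float)
    fsi = int(round(fs))
    n_sec = len(x) // fsi
    if window * fsi > len(x):
        raise ValueError(f"window of {window} s exceeds signal length")
    cs = np.concatenate([[0.0], np.cumsum(np.abs(x))])
    ends = (np.arange(1, n_sec + 1)) * fsi
    starts = np.maximum(0, ends - int(round(window * fsi)))
    vals = (cs[ends] - cs[starts]) / (ends - starts)
    return FeatureSeries(name=name, values=vals, band=band)


def mmsd(c_short: FeatureSeries, c_long: FeatureSeries, band: str = "none") -> FeatureSeries:
    """(C_tau0 - C_tau) / C_tau, the macro-micro structure descriptor."""
    if len(c_short) != len(c_long):
        raise ValueError("series must be aligned")
    denom = np.maximum(c_long.values, MMSD_EPS)
    vals = (c_short.values - c_long.values) / denom
    return FeatureSeries(name=f"MMSD_{band}" if band != "none" else "MMSD",
                         values=vals, band=band)


# ---------------------------------------------------------------------------
# per-epoch features
# ---------------------------------------------------------------------------

def teager_energy(x: np.ndarray) -> np.ndarray:
    """Pointwise Teager energy x[n]^2 - x[n-1]x[n+1]; edges replicated."""
    x = np.asarray(x, dtype=float)
    psi = np.empty_like(x)
    psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    psi[0] = psi[1]
    psi[-1] = psi[-2]
    return psi


def teo_feature(band_signal, fs: float, name: str = "TEO", band: str = "none") -> FeatureSeries:
    """Per-second maximum of the Teager energy (whole-series operator first)."""
    x = np.asarray(band_signal, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    vals = _epochs(teager_energy(x), int(round(fs))).max(axis=1)
    return FeatureSeries(name=name, values=vals, band=band)


def _filled_signs(x: np.ndarray) -> np.ndarray:
    """Signs with zeros taking the previous nonzero sign (then next, at the start)."""
    s = np.sign(x)
    nz = s != 0
    if not nz.any():
        return s
    idx = np.where(nz, np.arange(len(s)), 0)
    np.maximum.accumulate(idx, out=idx)
    filled = s[idx]
    first = np.argmax(nz)
    filled[:first] = s[first]  # leading zeros inherit the first nonzero sign
    return filled


def zcr_feature(band_signal, fs: float, name: str = "ZCR", band: str = "none") -> FeatureSeries:
    """Zero crossings per 1 s epoch (strict sign changes within the epoch)."""
    x = np.asarray(band_signal, dtype=float)
    fsi = int(round(fs))
    ep = _epochs(x, fsi)
    counts = np.empty(ep.shape[0])
    for t in range(ep.shape[0]):
        s = _filled_signs(ep[t])
        counts[t] = np.count_nonzero(s[1:] != s[:-1])
    return FeatureSeries(name=name, values=counts, band=band)


def lz76_complexity(bits) -> int:
    """LZ76 exhaustive-parsing complexity: the number of parsed phrases.

    A phrase grows while it can still be copied from the text preceding
    its last symbol; the count includes the final (possibly reproducible)
    phrase.  The constant sequence of length >= 2 has complexity 2.
    """
    s = "".join("1" if b else "0" for b in bits)
    n = len(s)
    c, i = 0, 0
    while i < n:
        k = 1
        while i + k <= n and s.find(s[i:i + k], 0, i + k - 1) != -1:
            k += 1
        c += 1
        i += k
    return c


def lzc_feature(band_signal, fs: float, name: str = "LZC", band: str = "none",
                threshold_rule: str = "median") -> FeatureSeries:
    """Per-epoch LZ76 complexity of the signal binarized at its epoch median."""
    if threshold_rule != "median":
        raise ValueError(f"unsupported threshold rule {threshold_rule!r}")
    x = np.asarray(band_signal, dtype=float)
    ep = _epochs(x, int(round(fs)))
    vals = np.empty(ep.shape[0])
    for t in range(ep.shape[0]):
        td = np.median(ep[t])
        vals[t] = lz76_complexity(ep[t] > td)
    return FeatureSeries(name=name, values=vals, band=band)


def stft_features(bb_signal, fs: float) -> tuple[FeatureSeries, FeatureSeries, FeatureSeries]:
    """Short-time Fourier descriptors on a trailing 3 s Hamming window, 2 s overlap.

    Per second: the frequency of the magnitude-spectrum maximum
    (``Max_freq``), the magnitude-weighted mean frequency / spectral
    centroid (``Mean_freq``), and the trapezoidal area under the magnitude
    spectrum (``Spec_area``).  A zero window yields 0 for all three.
    """
    x = np.asarray(bb_signal, dtype=float)
    fsi = int(round(fs))
    n_sec = len(x) // fsi
    if n_sec < 3:
        raise ValueError("need at least 3 s of signal")
    max_f = np.zeros(n_sec)
    mean_f = np.zeros(n_sec)
    area = np.zeros(n_sec)
    for t in range(n_sec):
        i1 = (t + 1) * fsi
        i0 = max(0, i1 - 3 * fsi)
        seg = x[i0:i1] * np.hamming(i1 - i0)
        mag = np.abs(np.fft.rfft(seg))
        freqs = np.fft.rfftfreq(i1 - i0, d=1.0 / fsi)
        total = mag.sum()
        if total > 0:
            max_f[t] = freqs[int(np.argmax(mag))]
            mean_f[t] = float(np.sum(freqs * mag) / total)
            area[t] = float(np.trapezoid(mag, freqs))
    return (FeatureSeries("Max_freq", max_f, "BB"),
            FeatureSeries("Mean_freq", mean_f, "BB"),
            FeatureSeries("Spec_area", area, "BB"))


def emd_features(bb_signal, fs: float, levels: int = 12) -> list[FeatureSeries]:
    """Per-second means of the first ``levels`` IMFs of the whole signal.

    The decomposition runs on the entire signal first (windowed EMD has
    severe edge effects); missing higher levels are zero-filled, extra
    modes are discarded.
    """
    x = np.asarray(bb_signal, dtype=float)
    fsi = int(round(fs))
    if len(x) < 10 * fsi:
        raise ValueError("need at least 10 s of signal for EMD")
    n_sec = len(x) // fsi
    imfs = emd(x, max_imfs=levels)
    out = []
    for lev in range(levels):
        if lev < len(imfs):
            vals = _epochs(imfs[lev], fsi).mean(axis=1)
        else:
            vals = np.zeros(n_sec)
        out.append(FeatureSeries(f"EMD_{lev + 1}", vals, "BB"))
    return out


def shannon_entropy_feature(bb_signal, fs: float, bins: int = 16) -> FeatureSeries:
    """Shannon entropy (bits) of a fixed-count amplitude histogram per epoch."""
    x = np.asarray(bb_signal, dtype=float)
    ep = _epochs(x, int(round(fs)))
    vals = np.zeros(ep.shape[0])
    for t in range(ep.shape[0]):
        seg = ep[t]
        lo, hi = seg.min(), seg.max()
        if hi <= lo:
            continue  # constant epoch: a single occupied bin, zero entropy
        counts, _ = np.histogram(seg, bins=bins, range=(lo, hi))
        p = counts[counts > 0] / counts.sum()
        vals[t] = float(-np.sum(p * np.log2(p)))
    return FeatureSeries("ShEnt", vals, "BB")


def higuchi_fd(epoch: np.ndarray, k_max: int = 8) -> float:
    """Higuchi fractal dimension of one epoch; 1.0 for degenerate input."""
    x = np.asarray(epoch, dtype=float)
    n = len(x)
    ks = np.arange(1, k_max + 1)
    lengths = np.empty(len(ks))
    for j, k in enumerate(ks):
        lm = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            dist = np.sum(np.abs(np.diff(x[idx])))
            norm = (n - 1) / (len(idx) - 1) / k
            lm.append(dist * norm / k)
        lengths[j] = np.mean(lm) if lm else 0.0
    if np.any(lengths <= 0):
        return 1.0
    slope = np.polyfit(np.log(1.0 / ks), np.log(lengths), 1)[0]
    return float(slope)


def higuchi_fd_feature(bb_signal, fs: float, k_max: int = 8) -> FeatureSeries:
    """Per-epoch Higuchi fractal dimension (ordinary least-squares fit)."""
    ep = _epochs(np.asarray(bb_signal, dtype=float), int(round(fs)))
    vals = np.array([higuchi_fd(ep[t], k_max) for t in range(ep.shape[0])])
    return FeatureSeries("FD", vals, "BB")


def variance_feature(band_signal, fs: float, name: str = "Var", band: str = "none") -> FeatureSeries:
    """Unbiased sample variance (divisor N-1) per 1 s epoch."""
    ep = _epochs(np.asarray(band_signal, dtype=float), int(round(fs)))
    return FeatureSeries(name=name, values=ep.var(axis=1, ddof=1), band=band)


def concat_feature_matrices(matrices: list) -> FeatureMatrix:
    """Concatenate per-subject matrices along the time axis (same row names)."""
    names = matrices[0].names
    for m in matrices[1:]:
        if m.names != names:
            raise ValueError("feature matrices have mismatched row names")
    df = pd.concat([m.data for m in matrices], axis=1, ignore_index=True)
    return FeatureMatrix(data=df, subject_id="+".join(m.subject_id for m in matrices))


# ---------------------------------------------------------------------------
# full matrix
# ---------------------------------------------------------------------------

def extract_feature_matrix(recording: EegRecording,
                           params: MmsdParams | None = None) -> FeatureMatrix:
    """Compute all 55 features for one recording, aligned at 1 Hz."""
    params = params or MmsdParams()
    if recording.duration < 120:
        raise ValueError("recording must be at least 120 s long")
    fs = recording.fs
    bands = decompose(recording)

    series: dict[str, FeatureSeries] = {}
    for b in SUB_BANDS:
        sig = bands[b]
        c_long = mean_amplitude(sig, fs, params.tau, params.tau - 1.0,
                                name=f"C_tau_{b}", band=b)
        c_short = mean_amplitude(sig, fs, params.tau0, params.tau0 - 1.0,
                                 name=f"C_tau0_{b}", band=b)
        series[f"C_tau_{b}"] = c_long
        series[f"C_tau0_{b}"] = c_short
        series[f"MMSD_{b}"] = mmsd(c_short, c_long, band=b)
        series[f"TEO_{b}"] = teo_feature(sig, fs, name=f"TEO_{b}", band=b)
    for b in ALL_BANDS:
        sig = bands[b]
        series[f"ZCR_{b}"] = zcr_feature(sig, fs, name=f"ZCR_{b}", band=b)
        series[f"LZC_{b}"] = lzc_feature(sig, fs, name=f"LZC_{b}", band=b)
        series[f"Var_{b}"] = variance_feature(sig, fs, name=f"Var_{b}", band=b)

    bb = bands["BB"]
    for s in stft_features(bb, fs):
        series[s.name] = s
    for s in emd_features(bb, fs):
        series[s.name] = s
    series["ShEnt"] = shannon_entropy_feature(bb, fs)
    series["FD"] = higuchi_fd_feature(bb, fs)

    ordered = [series[name] for name in FEATURE_ORDER]
    return FeatureMatrix.from_series(ordered, subject_id=recording.subject_id)
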