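"""The surface-EMG feature battery: 58 extraction methods, 81 scalar features.

Every feature is computed on a single analysis window.  Differenced variants
(DAR, DCC, DAMV, DASDV, DLD, DTM, DVARV, DV) apply the base extractor to the
first difference of the window; WL and M2 are intrinsically difference-based.
All spectral features share one periodogram convention (unwindowed one-sided
DFT periodogram of the window, bin width fs/N).  The few features whose
published conventions vary across the literature (DPR, SMR, SNR, PSR, FR,
PSDFD, CEA) are isolated in their own small functions so an alternative
convention is a one-line change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats
from scipy.linalg import solve_toeplitz

__all__ = [
    "FeatureParamProfile",
    "PARAM_PROFILES",
    "FEATURE_NAMES",
    "FEATURE_FAMILIES",
    "first_difference",
    "amplitude_features",
    "threshold_count_features",
    "spectral_features",
    "ar_cc_features",
    "complexity_features",
    "tdpsd_features",
    "windowed_energy_features",
    "extract_battery",
]

_TINY = 1e-300


@dataclass(frozen=True)
class FeatureParamProfile:
    """Per-dataset feature parameters.

    Thresholds are in raw signal units and therefore differ between
    acquisition systems; the three presets carry the recommended values for
    each study protocol.
    """

    zc_threshold: float = 1e-5
    ssc_threshold: float = 1e-10
    wamp_threshold: float = 5e-5
    myop_threshold: float = 5e-5
    ar_order: int = 4
    cc_order: int = 4
    apen_m: int = 2
    apen_r: float = 0.2  # x window sd
    sampen_m: int = 2
    sampen_r: float = 0.2  # x window sd
    dfa_scales: tuple[int, ...] = (4, 8, 16, 32, 64)
    dfa_order: int = 2
    v_order: int = 3
    tm_order: int = 3
    hist_bins: int = 3
    mavs_segments: int = 2
    afb_window_ms: float = 32.0
    max_cutoff_hz: float = 5.0
    max_filter_order: int = 6
    psr_halfwidth_hz: float = 20.0
    fr_low_band: tuple[float, float] = (20.0, 45.0)
    fr_high_band: tuple[float, float] = (95.0, 500.0)
    higuchi_kmax: int = 8

    def __post_init__(self) -> None:
        if min(self.zc_threshold, self.ssc_threshold, self.wamp_threshold,
               self.myop_threshold) < 0:
            raise ValueError("thresholds must be >= 0")
        if min(self.ar_order, self.cc_order, self.dfa_order) < 1:
            raise ValueError("orders must be >= 1")


# recommended thresholds per study protocol (ZC, SSC, WAMP/MYOP triples)
PARAM_PROFILES: dict[str, FeatureParamProfile] = {
    "dataset1": FeatureParamProfile(zc_threshold=10.0, ssc_threshold=16.0,
                                    wamp_threshold=20.0, myop_threshold=20.0),
    "dataset2": FeatureParamProfile(zc_threshold=0.01, ssc_threshold=1e-4,
                                    wamp_threshold=0.02, myop_threshold=0.02),
    "dataset3": FeatureParamProfile(zc_threshold=1e-5, ssc_threshold=1e-10,
                                    wamp_threshold=5e-5, myop_threshold=5e-5),
    "unit": FeatureParamProfile(zc_threshold=0.0, ssc_threshold=0.0,
                                wamp_threshold=0.05, myop_threshold=0.05),
}

FEATURE_NAMES: tuple[str, ...] = (
    "AFB", "ApEn", "SampEn",
    "AR1", "AR2", "AR3", "AR4",
    "DAR1", "DAR2", "DAR3", "DAR4",
    "BC",
    "CC1", "CC2", "CC3", "CC4",
    "DCC1", "DCC2", "DCC3", "DCC4",
    "CEA", "DAMV", "DASDV", "DFA", "DPR", "FR", "HG",
    "HIST1", "HIST2", "HIST3",
    "IEMG", "KATZ", "KURT", "SKEW", "LD", "DLD", "M2",
    "MAV", "MAV1", "MAV2", "MAVS", "MAX", "MDF", "MNF", "MFL",
    "MHW1", "MHW2", "MHW3", "MTW1", "MTW2", "MTW3",
    "MNP", "TTP", "MYOP", "OHM", "PKF", "PSDFD", "PSR", "RMS",
    "SM", "SMR", "SNR", "SSC", "SSI",
    "TDPSD1", "TDPSD2", "TDPSD3", "TDPSD4", "TDPSD5", "TDPSD6",
    "TM", "DTM", "VAR", "DVARV", "VCF", "VFD", "V", "DV",
    "WAMP", "WL", "ZC",
)

# multi-component extraction methods, treated atomically during selection
FEATURE_FAMILIES: dict[str, tuple[str, ...]] = {
    "AR": ("AR1", "AR2", "AR3", "AR4"),
    "DAR": ("DAR1", "DAR2", "DAR3", "DAR4"),
    "CC": ("CC1", "CC2", "CC3", "CC4"),
    "DCC": ("DCC1", "DCC2", "DCC3", "DCC4"),
    "HIST": ("HIST1", "HIST2", "HIST3"),
    "MHW": ("MHW1", "MHW2", "MHW3"),
    "MTW": ("MTW1", "MTW2", "MTW3"),
    "TDPSD": ("TDPSD1", "TDPSD2", "TDPSD3", "TDPSD4", "TDPSD5", "TDPSD6"),
}


def _asarray(window) -> np.ndarray:
    x = np.asarray(window, dtype=float)
    if x.ndim != 1:
        raise ValueError("window must be a 1-D sequence")
    return x


def first_difference(window) -> np.ndarray:
    """x[i+1] - x[i]; differencing renders the signal more stationary."""
    x = _asarray(window)
    if len(x) < 2:
        raise ValueError("first difference requires length >= 2")
    return np.diff(x)


# ---------------------------------------------------------------------------
# amplitude / time-domain family

def _safe_log10(v: float) -> float:
    return float(np.log10(max(abs(v), _TINY)))


def amplitude_features(window, profile: FeatureParamProfile,
                       fs: float = 1000.0) -> dict[str, float]:
    x = _asarray(window)
    n = len(x)
    if n < 2:
        raise ValueError("amplitude features require length >= 2")
    ax = np.abs(x)
    d = np.diff(x)
    out: dict[str, float] = {}
    out["IEMG"] = float(np.sum(ax))
    out["MAV"] = float(np.mean(ax))
    # centre-weighted modified MAVs
    i = np.arange(n)
    w1 = np.where((i >= 0.25 * n) & (i <= 0.75 * n), 1.0, 0.5)
    w2 = np.ones(n)
    lo = i < 0.25 * n
    hi = i > 0.75 * n
    w2[lo] = 4.0 * i[lo] / n
    w2[hi] = 4.0 * (n - i[hi]) / n
    out["MAV1"] = float(np.mean(w1 * ax))
    out["MAV2"] = float(np.mean(w2 * ax))
    half = n // 2
    out["MAVS"] = float(np.mean(ax[half:]) - np.mean(ax[:half]))
    out["RMS"] = float(np.sqrt(np.mean(x ** 2)))
    out["VAR"] = float(np.sum(x ** 2) / (n - 1))  # zero-mean convention
    out["SSI"] = float(np.sum(x ** 2))
    out["WL"] = float(np.sum(np.abs(d)))
    out["DAMV"] = float(np.sum(np.abs(d)) / (n - 1))
    out["DASDV"] = float(np.sqrt(np.sum(d ** 2) / (n - 1)))
    nz = ax > 0
    out["LD"] = float(np.exp(np.mean(np.log(ax[nz])))) if nz.any() else 0.0
    out["TM"] = abs(float(np.mean(x ** profile.tm_order)))
    out["V"] = abs(float(np.mean(x ** profile.v_order))) ** (
        1.0 / profile.v_order)
    out["M2"] = float(np.sum(d ** 2))
    out["MAX"] = _max_amplitude(x, fs, profile)
    out["AFB"] = _first_burst_amplitude(x, fs, profile)
    out["KURT"] = float(spstats.kurtosis(x, fisher=False)) if np.ptp(x) > 0 \
        else 0.0
    out["SKEW"] = float(spstats.skew(x)) if np.ptp(x) > 0 else 0.0
    counts, _ = np.histogram(x, bins=profile.hist_bins)
    for j, c in enumerate(counts, start=1):
        out[f"HIST{j}"] = float(c)
    return out


def _max_amplitude(x: np.ndarray, fs: float,
                   profile: FeatureParamProfile) -> float:
    """Peak of the rectified signal after a zero-phase low-pass envelope."""
    nyq = fs / 2.0
    wn = min(profile.max_cutoff_hz / nyq, 0.99)
    sos = sps.butter(profile.max_filter_order, wn, btype="low", output="sos")
    padlen = min(len(x) - 1, 3 * (2 * sos.shape[0] + 1))
    env = sps.sosfiltfilt(sos, np.abs(x), padlen=padlen)
    return float(np.max(env))


def _first_burst_amplitude(x: np.ndarray, fs: float,
                           profile: FeatureParamProfile) -> float:
    """Moving-RMS envelope value at its first local maximum ("first burst")."""
    w = max(int(round(profile.afb_window_ms * fs / 1000.0)), 1)
    w = min(w, len(x))
    kernel = np.ones(w) / w
    env = np.sqrt(np.convolve(x ** 2, kernel, mode="valid"))
    if len(env) < 3:
        return float(np.max(env))
    interior = (env[1:-1] > env[:-2]) & (env[1:-1] >= env[2:])
    idx = np.nonzero(interior)[0]
    if len(idx) == 0:
        return float(np.max(env))
    return float(env[idx[0] + 1])


# ---------------------------------------------------------------------------
# threshold-count family

def threshold_count_features(window, profile: FeatureParamProfile
                             ) -> dict[str, float]:
    x = _asarray(window)
    if len(x) < 3:
        raise ValueError("threshold-count features require length >= 3")
    d1 = np.abs(np.diff(x))
    sign_change = x[:-1] * x[1:] < 0
    zc = np.sum(sign_change & (d1 >= profile.zc_threshold))
    mid = (x[1:-1] - x[:-2]) * (x[1:-1] - x[2:])
    ssc = np.sum(mid >= profile.ssc_threshold)
    wamp = np.sum(d1 >= profile.wamp_threshold)
    myop = np.mean(np.abs(x) >= profile.myop_threshold)
    return {"ZC": float(zc), "SSC": float(ssc), "WAMP": float(wamp),
            "MYOP": float(myop)}


# ---------------------------------------------------------------------------
# spectral family (one shared periodogram)

def periodogram(window, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided unwindowed DFT periodogram; sum(P) equals mean(x**2)
    (Parseval constant 1/N)."""
    x = _asarray(window)
    n = len(x)
    X = np.fft.rfft(x)
    P = (np.abs(X) ** 2) / (n * n)
    if n % 2 == 0:
        P[1:-1] *= 2.0
    else:
        P[1:] *= 2.0
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    return f, P


def _band_power(f: np.ndarray, P: np.ndarray, lo: float, hi: float) -> float:
    return float(np.sum(P[(f >= lo) & (f <= hi)]))


def _katz_fd(y: np.ndarray) -> float:
    """Katz fractal dimension of an ordinate sequence (amplitude-only
    distances, the EMG-literature variant)."""
    d1 = np.abs(np.diff(y))
    L = float(np.sum(d1))
    d = float(np.max(np.abs(y - y[0])))
    n = len(y) - 1
    if L <= 0 or d <= 0 or n < 1:
        return 1.0
    ratio = d / L
    denom = np.log10(n) + np.log10(ratio)
    if denom == 0:
        return 1.0
    return float(np.log10(n) / denom)


def spectral_features(window, fs: float, profile: FeatureParamProfile
                      ) -> dict[str, float]:
    x = _asarray(window)
    if len(x) < 64:
        raise ValueError("spectral features require length >= 64")
    f, P = periodogram(x, fs)
    ttp = float(np.sum(P))
    out: dict[str, float] = {"TTP": ttp, "MNP": float(np.mean(P))}
    if ttp <= 0:
        warnings.warn("zero-power window: frequency features set to 0")
        for k in ("MNF", "MDF", "PKF", "SM", "VCF", "FR", "OHM", "PSR",
                  "DPR", "SMR", "SNR", "PSDFD"):
            out[k] = 0.0
        return out
    out["MNF"] = float(np.sum(f * P) / ttp)
    cumsum = np.cumsum(P)
    out["MDF"] = float(f[np.searchsorted(cumsum, ttp / 2.0)])
    kpk = int(np.argmax(P))
    pkf = float(f[kpk])
    out["PKF"] = pkf
    sm0 = ttp
    sm1 = float(np.sum(P * f))
    sm2 = float(np.sum(P * f ** 2))
    out["SM"] = sm2
    mu = sm1 / sm0
    out["VCF"] = sm2 / sm0 - mu ** 2
    out["OHM"] = float(np.sqrt(sm2 / sm0) / max(mu, _TINY))
    out["FR"] = _frequency_ratio(f, P, profile, fs)
    out["PSR"] = _band_power(f, P, pkf - profile.psr_halfwidth_hz,
                             pkf + profile.psr_halfwidth_hz) / ttp
    out["DPR"] = _max_min_drop_ratio(f, P, fs)
    out["SMR"] = _signal_motion_ratio(f, P, fs)
    out["SNR"] = _signal_noise_ratio(f, P, fs)
    out["PSDFD"] = _psd_fractal_dimension(P)
    return out


def _frequency_ratio(f, P, profile, fs) -> float:
    """Low-band over high-band power ratio."""
    lo = _band_power(f, P, *profile.fr_low_band)
    hb_lo, hb_hi = profile.fr_high_band
    hi = _band_power(f, P, hb_lo, min(hb_hi, fs / 2.0))
    return lo / max(hi, _TINY)


def _max_min_drop_ratio(f, P, fs) -> float:
    """Max/min of the 9-bin moving-average-smoothed PSD in the analysis
    band (20 Hz .. 0.9 Nyquist)."""
    if len(P) >= 9:
        smooth = np.convolve(P, np.ones(9) / 9.0, mode="same")
    else:
        smooth = P
    band = (f >= 20.0) & (f <= 0.9 * fs / 2.0)
    if not band.any():
        band = slice(None)
    sel = smooth[band]
    return float(np.max(sel) / max(np.min(sel), _TINY))


def _signal_motion_ratio(f, P, fs) -> float:
    """Signal band (20 Hz up) over motion-artefact band (below 20 Hz)."""
    sig = _band_power(f, P, 20.0, min(500.0, fs / 2.0))
    artefact = float(np.sum(P[(f > 0) & (f < 20.0)]))
    return sig / max(artefact, _TINY)


def _signal_noise_ratio(f, P, fs) -> float:
    """Signal band over high-frequency noise band (above 500 Hz, or above
    0.9 Nyquist when the rate leaves no room above 500 Hz)."""
    edge = 500.0 if fs / 2.0 > 500.0 / 0.9 else 0.9 * fs / 2.0
    sig = _band_power(f, P, 20.0, edge)
    noise = float(np.sum(P[f > edge]))
    return sig / max(noise, _TINY)


def _psd_fractal_dimension(P) -> float:
    """Katz fractal dimension of the max-normalized PSD sequence."""
    m = np.max(P)
    return _katz_fd(P / m) if m > 0 else 1.0


# ---------------------------------------------------------------------------
# autoregressive / cepstral family

def ar_coefficients(window, order: int = 4) -> np.ndarray:
    """Yule-Walker AR fit via the biased autocorrelation, coefficients a_k in
    the convention x[n] = sum_k a_k x[n-k] + e[n]."""
    x = _asarray(window)
    n = len(x)
    if n <= 4 * order:
        raise ValueError(f"AR({order}) requires length > {4 * order}")
    r = np.array([np.dot(x[:n - k], x[k:]) / n for k in range(order + 1)])
    if r[0] <= 0:
        raise ValueError("degenerate (zero-power) window for AR fit")
    try:
        a = solve_toeplitz(r[:order], r[1:order + 1])
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
        raise ValueError("numerically singular autocorrelation") from exc
    if not np.all(np.isfinite(a)):
        raise ValueError("numerically singular autocorrelation")
    return a


def cepstral_from_ar(a: np.ndarray) -> np.ndarray:
    """AR -> cepstrum recursion: c1 = -a1,
    c_p = -a_p - sum_{l=1}^{p-1} (1 - l/p) a_l c_{p-l}."""
    order = len(a)
    c = np.zeros(order)
    c[0] = -a[0]
    for p in range(2, order + 1):
        acc = -a[p - 1]
        for ell in range(1, p):
            acc -= (1.0 - ell / p) * a[ell - 1] * c[p - ell - 1]
        c[p - 1] = acc
    return c


def ar_cc_features(window, order: int = 4) -> dict[str, float]:
    a = ar_coefficients(window, order)
    c = cepstral_from_ar(a)
    out = {f"AR{k + 1}": float(a[k]) for k in range(order)}
    out.update({f"CC{k + 1}": float(c[k]) for k in range(order)})
    return out


# ---------------------------------------------------------------------------
# complexity / entropy / fractal family

def _cheby_dists(x: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Chebyshev template distances for lengths m and m+1, built
    incrementally from |x_i - x_j| (running max over shifted diagonals)."""
    d = np.abs(x[:, None] - x[None, :])
    dm = d[:len(x) - m + 1, :len(x) - m + 1].copy()
    for t in range(1, m):
        dm = np.maximum(dm, d[t:t + dm.shape[0], t:t + dm.shape[0]])
    dm1 = np.maximum(dm[:-1, :-1], d[m:, m:])
    return dm, dm1


def approximate_entropy(window, m: int = 2, r_factor: float = 0.2) -> float:
    """Regularity statistic; template self-matches are counted."""
    x = _asarray(window)
    sd = np.std(x)
    if sd == 0:
        return 0.0
    r = r_factor * sd
    dm, dm1 = _cheby_dists(x, m)

    def phi(dist: np.ndarray) -> float:
        nt = dist.shape[0]
        counts = (dist <= r).sum(axis=1)
        return float(np.mean(np.log(counts / nt)))

    return phi(dm) - phi(dm1)


def sample_entropy(window, m: int = 2, r_factor: float = 0.2) -> float:
    """-log(A/B) over matched templates, excluding self-matches; templates
    restricted to the common index range of lengths m and m+1."""
    x = _asarray(window)
    sd = np.std(x)
    if sd == 0:
        return 0.0
    r = r_factor * sd
    nt = len(x) - m
    dm, dm1 = _cheby_dists(x, m)
    dm = dm[:nt, :nt]
    B = (np.sum(dm <= r) - nt) / 2.0
    A = (np.sum(dm1 <= r) - nt) / 2.0
    if B == 0 or A == 0:
        # undefined; return the conservative maximal estimate
        return float(np.log(nt) + np.log(nt - 1) - np.log(2.0))
    return float(-np.log(A / B))


def dfa_exponent(window, scales=(4, 8, 16, 32, 64), order: int = 2) -> float:
    """Detrended fluctuation analysis scaling exponent (polynomial detrend of
    the integrated profile over dyadic box sizes; log2-log2 least squares)."""
    x = _asarray(window)
    y = np.cumsum(x - np.mean(x))
    n = len(y)
    fs_vals, used = [], []
    for s in scales:
        nseg = n // s
        if nseg < 2:
            continue
        segs = y[:nseg * s].reshape(nseg, s)
        V = np.vander(np.arange(s), order + 1)
        beta, *_ = np.linalg.lstsq(V, segs.T, rcond=None)
        res = float(np.sum((segs.T - V @ beta) ** 2))
        fs_vals.append(np.sqrt(res / (nseg * s)))
        used.append(s)
    if len(used) < 2 or min(fs_vals) <= 0:
        return 0.0
    slope = np.polyfit(np.log2(used), np.log2(fs_vals), 1)[0]
    return float(slope)


def higuchi_fd(window, kmax: int = 8) -> float:
    x = _asarray(window)
    n = len(x)
    lk, ks = [], []
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            lm = np.sum(np.abs(np.diff(x[idx]))) * (n - 1) / (
                (len(idx) - 1) * k)
            lengths.append(lm / k)
        if lengths:
            mean_l = np.mean(lengths)
            if mean_l > 0:
                lk.append(np.log(mean_l))
                ks.append(np.log(1.0 / k))
    if len(lk) < 2:
        return 1.0
    return float(np.polyfit(ks, lk, 1)[0])


def box_counting_dimension(window, levels=range(1, 7)) -> float:
    """Box counting on the piecewise-linear graph of the waveform normalized
    to the unit square, over dyadic grids 2^1..2^6."""
    x = _asarray(window)
    n = len(x)
    rng_x = np.ptp(x)
    if rng_x == 0 or n < 2:
        return 1.0
    ynorm = (x - np.min(x)) / rng_x
    tnorm = np.arange(n) / (n - 1)
    logn, loginv = [], []
    for lev in levels:
        g = 2 ** lev
        h = 1.0 / g
        count = 0
        # per time-column min/max of the piecewise-linear curve
        col_edges = np.linspace(0.0, 1.0, g + 1)
        for c in range(g):
            lo_t, hi_t = col_edges[c], col_edges[c + 1]
            ts, vals = [], []
            inside = (tnorm >= lo_t) & (tnorm <= hi_t)
            vals.extend(ynorm[inside])
            # interpolated values at column boundaries
            for tb in (lo_t, hi_t):
                j = np.searchsorted(tnorm, tb)
                if 0 < j < n:
                    t0, t1 = tnorm[j - 1], tnorm[j]
                    frac = (tb - t0) / (t1 - t0)
                    vals.append(ynorm[j - 1] + frac * (ynorm[j] - ynorm[j - 1]))
            if not vals:
                continue
            vmin, vmax = min(vals), max(vals)
            count += int(np.floor(vmax / h) - np.floor(vmin / h)) + 1
        logn.append(np.log(count))
        loginv.append(np.log(g))
    return float(np.polyfit(loginv, logn, 1)[0])


def variance_fd(window, max_lag: int = 32) -> float:
    """Variance fractal dimension: D = 2 - H with 2H the log-log slope of
    increment variance over dyadic lags."""
    x = _asarray(window)
    lags = [k for k in (1, 2, 4, 8, 16, 32) if k <= min(max_lag, len(x) - 2)]
    vs, ks = [], []
    for k in lags:
        inc = x[k:] - x[:-k]
        v = np.var(inc)
        if v > 0:
            vs.append(np.log(v))
            ks.append(np.log(k))
    if len(vs) < 2:
        return 1.0
    slope = np.polyfit(ks, vs, 1)[0]
    return float(2.0 - slope / 2.0)


def critical_exponent(window, scales=(1, 2, 4, 8, 16, 32)) -> float:
    """Coarse-grained variance scaling exponent: slope of log var(block
    means) against log block size."""
    x = _asarray(window)
    vs, ks = [], []
    for s in scales:
        nseg = len(x) // s
        if nseg < 2:
            continue
        means = x[:nseg * s].reshape(nseg, s).mean(axis=1)
        v = np.var(means)
        if v > 0:
            vs.append(np.log(v))
            ks.append(np.log(s))
    if len(vs) < 2:
        return 0.0
    return float(np.polyfit(ks, vs, 1)[0])


def maximum_fractal_length(window) -> float:
    """MFL = log10 sqrt(sum of squared first differences)."""
    d = np.diff(_asarray(window))
    s = float(np.sum(d ** 2))
    return _safe_log10(np.sqrt(s)) if s > 0 else _safe_log10(_TINY)


def complexity_features(window, profile: FeatureParamProfile
                        ) -> dict[str, float]:
    x = _asarray(window)
    if len(x) < 128:
        warnings.warn("complexity features are unreliable below 128 samples")
    if np.ptp(x) == 0:
        return {"ApEn": 0.0, "SampEn": 0.0, "DFA": 0.0, "BC": 1.0, "HG": 1.0,
                "KATZ": 1.0, "MFL": maximum_fractal_length(x), "VFD": 1.0,
                "CEA": 0.0}
    return {
        "ApEn": approximate_entropy(x, profile.apen_m, profile.apen_r),
        "SampEn": sample_entropy(x, profile.sampen_m, profile.sampen_r),
        "DFA": dfa_exponent(x, profile.dfa_scales, profile.dfa_order),
        "BC": box_counting_dimension(x),
        "HG": higuchi_fd(x, profile.higuchi_kmax),
        "KATZ": _katz_fd(x),
        "MFL": maximum_fractal_length(x),
        "VFD": variance_fd(x),
        "CEA": critical_exponent(x),
    }


# ---------------------------------------------------------------------------
# time-dependent power-spectrum descriptors

def _safe_log(v: float) -> float:
    return float(np.log(max(abs(v), _TINY)))


def tdpsd_features(window) -> dict[str, float]:
    """Six descriptors of root-squared spectral moments m0, m2, m4 (computed
    in the time domain from the signal and its first/second differences),
    each moment passed through the power transform m -> m^0.1 / 0.1."""
    x = _asarray(window)
    if len(x) < 8:
        raise ValueError("TDPSD requires length >= 8")
    if not np.any(x):
        raise ValueError("TDPSD undefined for an identically zero window")
    d1 = np.diff(x)
    d2 = np.diff(x, 2)
    m0 = np.sqrt(np.sum(x ** 2))
    m2 = np.sqrt(np.sum(d1 ** 2))
    m4 = np.sqrt(np.sum(d2 ** 2))
    lam = 0.1
    m0, m2, m4 = (m ** lam / lam for m in (m0, m2, m4))
    f1 = _safe_log(m0)
    f2 = _safe_log(m0 - m2)
    f3 = _safe_log(m0 - m4)
    f4 = _safe_log(m0 / max(np.sqrt(abs((m0 - m2) * (m0 - m4))), _TINY))
    f5 = _safe_log(m2 / max(np.sqrt(abs(m0 * m4)), _TINY))
    f6 = _safe_log(np.sum(np.abs(d1)) / max(np.sum(np.abs(d2)), _TINY))
    return {f"TDPSD{i}": float(v)
            for i, v in enumerate((f1, f2, f3, f4, f5, f6), start=1)}


# ---------------------------------------------------------------------------
# multi-window energies

def _trapezoid_taper(n: int, ramp_frac: float = 0.25) -> np.ndarray:
    ramp = max(int(round(ramp_frac * n)), 1)
    w = np.ones(n)
    up = np.linspace(0.0, 1.0, ramp + 1)[1:]
    w[:ramp] = up
    w[n - ramp:] = up[::-1]
    return w


def windowed_energy_features(window) -> dict[str, float]:
    """Energies of three equal consecutive sub-segments under Hamming and
    symmetric trapezoidal (25% ramp) tapers."""
    x = _asarray(window)
    if len(x) < 6:
        raise ValueError("windowed energies require length >= 6")
    seg = len(x) // 3
    out: dict[str, float] = {}
    ham = np.hamming(seg)
    trap = _trapezoid_taper(seg)
    for j in range(3):
        part = x[j * seg:(j + 1) * seg]
        out[f"MHW{j + 1}"] = float(np.sum((ham * part) ** 2))
        out[f"MTW{j + 1}"] = float(np.sum((trap * part) ** 2))
    return out


# ---------------------------------------------------------------------------
# full battery

def extract_battery(window, fs: float,
                    profile: FeatureParamProfile | str = "dataset1"
                    ) -> dict[str, float]:
    """Apply all 58 extraction methods to one window; returns the 81 named
    scalars in canonical order.  Differenced variants apply the base method
    to the first difference of the window."""
    if isinstance(profile, str):
        profile = PARAM_PROFILES[profile]
    x = _asarray(window)
    d = first_difference(x)

    vals: dict[str, float] = {}
    amp = amplitude_features(x, profile, fs)
    amp_d = amplitude_features(d, profile, fs)
    vals.update(amp)
    vals["DLD"] = amp_d["LD"]
    vals["DTM"] = amp_d["TM"]
    vals["DVARV"] = amp_d["VAR"]
    vals["DV"] = amp_d["V"]
    vals.update(threshold_count_features(x, profile))
    vals.update(spectral_features(x, fs, profile))
    try:
        arcc = ar_cc_features(x, profile.ar_order)
        arcc_d = ar_cc_features(d, profile.ar_order)
    except ValueError as exc:
        raise ValueError(f"AR/CC extraction failed: {exc}") from exc
    vals.update(arcc)
    vals.update({f"DAR{k}": arcc_d[f"AR{k}"]
                 for k in range(1, profile.ar_order + 1)})
    vals.update({f"DCC{k}": arcc_d[f"CC{k}"]
                 for k in range(1, profile.cc_order + 1)})
    vals.update(complexity_features(x, profile))
    vals.update(tdpsd_features(x))
    vals.update(windowed_energy_features(x))

    ordered = {name: vals[name] for name in FEATURE_NAMES}
    bad = [k for k, v in ordered.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite feature values: {bad}")
    return ordered
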