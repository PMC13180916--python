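"""Frame-level acoustic low-level descriptors (LLDs) and functionals.

The LLD inventory emulates a minimal prosodic/spectral parameter set:
log-F0 (semitones re 27.5 Hz), jitter, shimmer, loudness, HNR, the first
three formants (frequency, bandwidth, relative energy), alpha ratio,
Hammarberg index, spectral slopes 0-500 / 500-1500 Hz, harmonic
differences H1-H2 and H1-A3, spectral flux and MFCC 1-4. Analysis uses
20 ms frames on a 10 ms hop with a symmetric 3-frame moving average;
pitch-synchronous measures use a 50 ms autocorrelation window on the
same hop grid (a 20 ms frame cannot resolve the 27.5 Hz pitch floor).
Bit-compatibility with any specific toolkit is not claimed; every
descriptor is defined here and unit-tested on synthetic signals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.signal import find_peaks

from ._types import MISSING, AudioClip

__all__ = [
    "LLDMatrix",
    "Segmentation",
    "extract_lld_matrix",
    "detect_voiced_segments",
    "lld_functionals",
    "signal_summary_stats",
    "segment_duration_stats",
    "acoustic_feature_vector",
    "PITCH_FLOOR_HZ",
    "PITCH_CEIL_HZ",
]

PITCH_FLOOR_HZ = 27.5
PITCH_CEIL_HZ = 600.0
_PERIODICITY_THRESHOLD = 0.45

#: LLDs summarized over voiced frames only (loudness runs over all frames;
#: the spectral-balance set is additionally summarized over unvoiced frames).
UNVOICED_ALSO = ("alpharatio", "slope0_500", "slope500_1500", "hammarberg")


@dataclass
class LLDMatrix:
    frame_times: np.ndarray
    descriptors: dict[str, np.ndarray]
    voiced_mask: np.ndarray

    def __post_init__(self) -> None:
        n = self.frame_times.size
        for name, series in self.descriptors.items():
            if series.size != n:
                raise ValueError(f"descriptor {name} has {series.size} frames, expected {n}")
        if self.voiced_mask.size != n:
            raise ValueError("voiced mask frame count mismatch")

    @property
    def n_frames(self) -> int:
        return self.frame_times.size


@dataclass
class Segmentation:
    voiced: list[tuple[float, float]]
    unvoiced: list[tuple[float, float]]


def _frame_indices(n_samples: int, frame: int, hop: int) -> np.ndarray:
    n = 1 + (n_samples - frame) // hop
    return np.arange(n) * hop


def _smooth3(x: np.ndarray) -> np.ndarray:
    """Centered 3-frame moving average; window shrinks at the edges.
    NaN entries (unvoiced pitch frames) stay NaN and are skipped."""
    n = x.size
    out = np.empty_like(x)
    for i in range(n):
        lo, hi = max(0, i - 1), min(n, i + 2)
        win = x[lo:hi]
        if np.isnan(x[i]):
            out[i] = np.nan
        else:
            vals = win[~np.isnan(win)]
            out[i] = vals.mean()
    return out


def _autocorr_pitch(window: np.ndarray, rate: int) -> tuple[float, float]:
    """Return (f0_hz, periodicity) for one analysis window; f0 is NaN when
    no acceptable autocorrelation peak exists."""
    x = window - window.mean()
    n = x.size
    if not np.any(x):
        return np.nan, 0.0
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    r = np.fft.irfft(spec * np.conj(spec))[:n]
    if r[0] <= 0:
        return np.nan, 0.0
    lag_min = max(2, int(rate / PITCH_CEIL_HZ))
    lag_max = min(n - 2, int(rate / PITCH_FLOOR_HZ))
    if lag_max <= lag_min:
        return np.nan, 0.0
    # unbiased normalization so long lags are not penalized
    lags = np.arange(lag_min, lag_max + 1)
    rn = (r[lag_min:lag_max + 1] / r[0]) * (n / (n - lags))
    best = float(rn.max())
    # prefer the shortest lag whose peak is close to the global maximum,
    # otherwise period multiples (subharmonics) win the argmax
    prev = np.r_[-np.inf, rn[:-1]]
    nxt = np.r_[rn[1:], -np.inf]
    local_max = (rn >= prev) & (rn >= nxt)
    candidates = np.flatnonzero(local_max & (rn >= 0.9 * best))
    k = int(candidates[0]) if candidates.size else int(np.argmax(rn))
    peak = float(rn[k])
    lag = lags[k]
    # parabolic interpolation around the peak
    if 0 < k < rn.size - 1:
        a, b, c = rn[k - 1], rn[k], rn[k + 1]
        denom = a - 2 * b + c
        if denom != 0:
            lag = lag + 0.5 * (a - c) / denom
    f0 = rate / lag
    if f0 < PITCH_FLOOR_HZ or f0 > PITCH_CEIL_HZ:
        return np.nan, min(peak, 1.0)
    return f0, float(np.clip(peak, 0.0, 1.0))


def _levinson(r: np.ndarray, order: int) -> np.ndarray:
    """Levinson-Durbin recursion; returns LPC coefficients [1, a1..ap]."""
    a = np.zeros(order + 1)
    a[0] = 1.0
    err = r[0]
    if err <= 0:
        return a
    for i in range(1, order + 1):
        acc = r[i] + a[1:i] @ r[1:i][::-1]
        k = -acc / err
        a[1:i + 1] = a[1:i + 1] + k * a[:i][::-1].copy()
        err *= (1 - k * k)
        if err <= 0:
            break
    return a


def _lpc_formants(frame: np.ndarray, rate: int, order: int = 12,
                  n_formants: int = 3) -> list[tuple[float, float]]:
    """Formant (frequency, bandwidth) estimates from LPC root-solving."""
    x = np.append(frame[0], frame[1:] - 0.97 * frame[:-1])  # pre-emphasis
    x = x * np.hamming(x.size)
    if not np.any(x):
        return []
    r = np.correlate(x, x, mode="full")[x.size - 1:x.size + order]
    a = _levinson(r, order)
    roots = np.roots(a)
    roots = roots[np.imag(roots) > 1e-6]
    freqs = np.angle(roots) * rate / (2 * np.pi)
    bands = -np.log(np.maximum(np.abs(roots), 1e-12)) * rate / np.pi
    order_idx = np.argsort(freqs)
    out = []
    for i in order_idx:
        f, bw = float(freqs[i]), float(bands[i])
        if 90.0 < f < rate / 2 - 50.0 and bw < 1200.0:
            out.append((f, bw))
        if len(out) == n_formants:
            break
    return out


def _band_energy(power: np.ndarray, freqs: np.ndarray, lo: float, hi: float) -> float:
    sel = (freqs >= lo) & (freqs < hi)
    return float(power[sel].sum())


def _harmonic_amplitude_db(power: np.ndarray, freqs: np.ndarray,
                           target: float, tol: float) -> float:
    sel = (freqs >= target - tol) & (freqs <= target + tol)
    if not np.any(sel):
        return np.nan
    p = float(power[sel].max())
    return 10.0 * np.log10(max(p, 1e-20))


def extract_lld_matrix(clip: AudioClip, frame: float = 0.020,
                       hop: float = 0.010) -> LLDMatrix:
    """Extract the per-frame LLD matrix for one clip.

    F0 is reported as ``12*log2(f0/27.5)`` semitones and is defined
    (non-NaN) only on voiced frames; every descriptor is smoothed with a
    symmetric 3-frame moving average (window shrinking at the edges).
    """
    x, rate = clip.samples, clip.rate
    flen = int(round(frame * rate))
    hlen = int(round(hop * rate))
    if x.size < flen:
        raise ValueError("clip shorter than one analysis frame")
    starts = _frame_indices(x.size, flen, hlen)
    n = starts.size
    plen = int(round(0.050 * rate))  # pitch window

    nfft = 1 << int(np.ceil(np.log2(flen)))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rate)
    win = np.hamming(flen)

    names = [
        "f0semitone", "jitter", "shimmer", "loudness", "hnr",
        "f1freq", "f1bw", "f1relenergy", "f2freq", "f2bw", "f2relenergy",
        "f3freq", "f3bw", "f3relenergy",
        "alpharatio", "hammarberg", "slope0_500", "slope500_1500",
        "h1h2", "h1a3", "spectralflux", "mfcc1", "mfcc2", "mfcc3", "mfcc4",
    ]
    d = {k: np.full(n, np.nan) for k in names}
    voiced = np.zeros(n, dtype=bool)
    mel_fb = _mel_filterbank(26, nfft, rate)
    prev_spec: Optional[np.ndarray] = None
    energies = np.empty(n)

    for i, s in enumerate(starts):
        fr = x[s:s + flen]
        rms = float(np.sqrt(np.mean(fr**2)))
        energies[i] = rms
        d["loudness"][i] = rms**0.6  # perceptual power-law compression

        center = s + flen // 2
        lo = max(0, center - plen // 2)
        pw = x[lo:lo + plen]
        f0, periodicity = _autocorr_pitch(pw, rate)
        frame_voiced = (not np.isnan(f0)) and periodicity > _PERIODICITY_THRESHOLD \
            and rms > 1e-5
        voiced[i] = frame_voiced

        spec = np.fft.rfft(fr * win, nfft)
        power = np.abs(spec) ** 2
        tot = power.sum()

        if prev_spec is not None:
            num = np.sqrt(power) - np.sqrt(prev_spec)
            d["spectralflux"][i] = float(np.sqrt(np.sum(num**2)))
        else:
            d["spectralflux"][i] = 0.0
        prev_spec = power

        if tot > 0:
            e_low = _band_energy(power, freqs, 50, 1000)
            e_high = _band_energy(power, freqs, 1000, 5000)
            if e_low > 0 and e_high > 0:
                d["alpharatio"][i] = 10 * np.log10(e_low / e_high)
            p02 = power[(freqs >= 0) & (freqs < 2000)]
            p25 = power[(freqs >= 2000) & (freqs < 5000)]
            if p02.size and p25.size and p02.max() > 0 and p25.max() > 0:
                d["hammarberg"][i] = 10 * np.log10(p02.max() / p25.max())
            for lo_f, hi_f, key in ((0, 500, "slope0_500"),
                                    (500, 1500, "slope500_1500")):
                sel = (freqs >= lo_f) & (freqs < hi_f)
                if sel.sum() >= 3 and power[sel].max() > 0:
                    db = 10 * np.log10(np.maximum(power[sel], 1e-20))
                    khz = freqs[sel] / 1000.0
                    d[key][i] = float(np.polyfit(khz, db, 1)[0])
            logmel = np.log(np.maximum(mel_fb @ power, 1e-20))
            mfcc = _dct2(logmel)
            for j in range(1, 5):
                d[f"mfcc{j}"][i] = mfcc[j]

        if frame_voiced:
            d["f0semitone"][i] = 12.0 * np.log2(f0 / PITCH_FLOOR_HZ)
            r = np.clip(periodicity, 1e-6, 1 - 1e-6)
            d["hnr"][i] = 10 * np.log10(r / (1 - r))
            d["jitter"][i], d["shimmer"][i] = _jitter_shimmer(pw, rate, f0)
            formants = _lpc_formants(fr, rate)
            for j, (ff, bw) in enumerate(formants, start=1):
                d[f"f{j}freq"][i] = ff
                d[f"f{j}bw"][i] = bw
                if tot > 0:
                    d[f"f{j}relenergy"][i] = 10 * np.log10(
                        max(_band_energy(power, freqs, ff - 100, ff + 100), 1e-20)
                        / tot
                    )
            if tot > 0:
                h1 = _harmonic_amplitude_db(power, freqs, f0, f0 / 4)
                h2 = _harmonic_amplitude_db(power, freqs, 2 * f0, f0 / 4)
                if not (np.isnan(h1) or np.isnan(h2)):
                    d["h1h2"][i] = h1 - h2
                if formants and len(formants) >= 3:
                    f3 = formants[2][0]
                    a3 = _harmonic_amplitude_db(power, freqs, f3, max(f0 / 2, 100))
                    if not (np.isnan(h1) or np.isnan(a3)):
                        d["h1a3"][i] = h1 - a3

    for k in names:
        d[k] = _smooth3(d[k])
    times = (starts + flen / 2) / rate
    return LLDMatrix(frame_times=times, descriptors=d, voiced_mask=voiced)


def _jitter_shimmer(window: np.ndarray, rate: int, f0: float) -> tuple[float, float]:
    """Cycle-to-cycle period and amplitude perturbation inside one
    pitch window: jitter = mean |dT| / mean T over consecutive cycle
    lengths from peak picking; shimmer = mean |d amplitude| in dB."""
    period = rate / f0
    # cycle markers from the zero-phase band-passed fundamental: the raw
    # waveform can carry several competing local maxima per period
    spec = np.fft.rfft(window)
    fbin = np.fft.rfftfreq(window.size, d=1.0 / rate)
    band = (fbin >= 0.6 * f0) & (fbin <= 1.5 * f0)
    fund = np.fft.irfft(np.where(band, spec, 0.0), window.size)
    peaks, _ = find_peaks(fund, distance=max(2, int(0.7 * period)))
    peaks = peaks[(peaks > 0) & (peaks < window.size - 1)]
    if peaks.size < 3:
        return np.nan, np.nan
    # parabolic refinement: integer peak positions quantize cycle lengths
    a = fund[peaks - 1]
    b = fund[peaks]
    c = fund[peaks + 1]
    denom = a - 2 * b + c
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (a - c) / denom, 0.0)
    shift = np.clip(shift, -0.5, 0.5)
    refined = peaks + shift
    amps = np.abs(b - 0.25 * (a - c) * shift)
    cycles = np.diff(refined)
    jitter = float(np.mean(np.abs(np.diff(cycles))) / np.mean(cycles))
    amps = np.maximum(amps, 1e-12)
    shimmer = float(np.mean(np.abs(20 * np.log10(amps[1:] / amps[:-1]))))
    return jitter, shimmer


def _mel_filterbank(n_filters: int, nfft: int, rate: int) -> np.ndarray:
    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + f / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)

    mels = np.linspace(hz_to_mel(0), hz_to_mel(rate / 2), n_filters + 2)
    hz = mel_to_hz(mels)
    bins = np.floor((nfft + 1) * hz / rate).astype(int)
    fb = np.zeros((n_filters, nfft // 2 + 1))
    for i in range(n_filters):
        a, b, c = bins[i], bins[i + 1], bins[i + 2]
        for j in range(a, b):
            if b > a:
                fb[i, j] = (j - a) / (b - a)
        for j in range(b, c):
            if c > b:
                fb[i, j] = (c - j) / (c - b)
    return fb


def _dct2(x: np.ndarray) -> np.ndarray:
    from scipy.fft import dct

    return dct(x, type=2, norm="ortho")


# ---------------------------------------------------------------------------
# Voice-activity segmentation


VADBackend = Callable[[AudioClip], Segmentation]


def detect_voiced_segments(
    clip: AudioClip,
    lld: LLDMatrix,
    backend: Optional[VADBackend] = None,
) -> Segmentation:
    """Voiced/unvoiced interval segmentation.

    The default backend marks a frame voiced when its energy exceeds an
    adaptive threshold (0.1 x median of the top-decile frame energies)
    and its periodicity exceeds 0.45 (the LLD voiced mask); voiced
    frames are merged into intervals and gaps shorter than 0.1 s are
    bridged. An external backend (e.g. imported diarization intervals)
    may replace this entirely.
    """
    if backend is not None:
        return backend(clip)
    hop = float(np.median(np.diff(lld.frame_times))) if lld.n_frames > 1 else 0.01
    energy = lld.descriptors["loudness"] ** (1 / 0.6)  # back to RMS
    nz = np.sort(energy[np.isfinite(energy)])[::-1]
    if nz.size == 0 or nz[0] <= 0:
        theta = np.inf
    else:
        top = nz[: max(1, nz.size // 10)]
        theta = 0.1 * float(np.median(top))
    active = (energy > theta) & lld.voiced_mask
    intervals: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(active):
        t0 = lld.frame_times[i] - hop / 2
        t1 = lld.frame_times[i] + hop / 2
        if flag and start is None:
            start = t0
        elif not flag and start is not None:
            intervals.append((start, lld.frame_times[i - 1] + hop / 2))
            start = None
    if start is not None:
        intervals.append((start, lld.frame_times[-1] + hop / 2))
    # bridge short gaps
    merged: list[tuple[float, float]] = []
    for iv in intervals:
        if merged and iv[0] - merged[-1][1] < 0.1:
            merged[-1] = (merged[-1][0], iv[1])
        else:
            merged.append(iv)
    merged = [(max(0.0, a), min(clip.duration, b)) for a, b in merged]
    unvoiced = []
    cursor = 0.0
    for a, b in merged:
        if a > cursor:
            unvoiced.append((cursor, a))
        cursor = b
    if cursor < clip.duration:
        unvoiced.append((cursor, clip.duration))
    return Segmentation(voiced=merged, unvoiced=unvoiced)


# ---------------------------------------------------------------------------
# Functionals


def lld_functionals(series: np.ndarray,
                    mask: Optional[np.ndarray] = None) -> dict[str, float]:
    """Summary functionals of one LLD series.

    mean; coefficient of variation (sd/mean, 0 when the mean is 0);
    linear-interpolation quartiles and IQR; mean of the positive and of
    the negative consecutive differences (0 when none); biased sample
    skewness; excess kurtosis (0 convention for constant series).
    """
    x = np.asarray(series, dtype=float)
    if mask is not None:
        x = x[np.asarray(mask, dtype=bool)]
    x = x[~np.isnan(x)]
    stats = ("mean", "cv", "q1", "q2", "q3", "iqr", "posslope", "negslope",
             "skew", "kurtosis")
    if x.size == 0:
        return {k: MISSING for k in stats}
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    q1, q2, q3 = (float(q) for q in np.quantile(x, [0.25, 0.5, 0.75]))
    diffs = np.diff(x)
    pos = diffs[diffs > 0]
    neg = diffs[diffs < 0]
    m2 = float(np.mean((x - mean) ** 2))
    if m2 > 0:
        skew = float(np.mean((x - mean) ** 3) / m2**1.5)
        kurt = float(np.mean((x - mean) ** 4) / m2**2 - 3.0)
    else:
        skew, kurt = 0.0, 0.0
    return {
        "mean": mean,
        "cv": sd / mean if mean != 0 else 0.0,
        "q1": q1, "q2": q2, "q3": q3, "iqr": q3 - q1,
        "posslope": float(pos.mean()) if pos.size else 0.0,
        "negslope": float(neg.mean()) if neg.size else 0.0,
        "skew": skew, "kurtosis": kurt,
    }


def _basic4(x: np.ndarray) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return {"mean": MISSING, "sd": MISSING, "skew": MISSING, "kurtosis": MISSING}
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    m2 = float(np.mean((x - mean) ** 2))
    skew = float(np.mean((x - mean) ** 3) / m2**1.5) if m2 > 0 else 0.0
    kurt = float(np.mean((x - mean) ** 4) / m2**2 - 3.0) if m2 > 0 else 0.0
    return {"mean": mean, "sd": sd, "skew": skew, "kurtosis": kurt}


def signal_summary_stats(clip: AudioClip, frame: float = 0.020,
                         hop: float = 0.010) -> dict[str, float]:
    """Whole-signal descriptors: 12-bin chromagram, RMS, zero-crossing
    rate, onset strength, spectral bandwidth and centroid — each
    summarized by mean/SD/skewness/kurtosis — plus one global tempo
    estimate from the autocorrelation of the onset envelope (BPM)."""
    x, rate = clip.samples, clip.rate
    flen = int(round(frame * rate))
    hlen = int(round(hop * rate))
    if x.size < flen:
        raise ValueError("clip shorter than one analysis frame")
    starts = _frame_indices(x.size, flen, hlen)
    nfft = 1 << int(np.ceil(np.log2(flen)))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rate)
    win = np.hamming(flen)
    pitch_class = np.zeros(freqs.size, dtype=int)
    valid = freqs > 20
    pitch_class[valid] = np.mod(
        np.round(12 * np.log2(freqs[valid] / 440.0)), 12
    ).astype(int)

    rms_v, zcr_v, onset_v, bw_v, cent_v = [], [], [], [], []
    chroma_rows = []
    prev = None
    for s in starts:
        fr = x[s:s + flen]
        rms_v.append(float(np.sqrt(np.mean(fr**2))))
        zcr_v.append(float(np.mean(np.abs(np.diff(np.signbit(fr).astype(int))))))
        power = np.abs(np.fft.rfft(fr * win, nfft)) ** 2
        tot = power.sum()
        if tot > 0:
            cent = float((freqs * power).sum() / tot)
            bw = float(np.sqrt(((freqs - cent) ** 2 * power).sum() / tot))
        else:
            cent, bw = 0.0, 0.0
        cent_v.append(cent)
        bw_v.append(bw)
        mag = np.sqrt(power)
        onset_v.append(float(np.sum(np.maximum(mag - prev, 0.0))) if prev is not None else 0.0)
        prev = mag
        ch = np.zeros(12)
        np.add.at(ch, pitch_class[valid], power[valid])
        chroma_rows.append(ch / tot if tot > 0 else ch)

    out: dict[str, float] = {}
    for name, vals in (("rms", rms_v), ("zcr", zcr_v), ("onset", onset_v),
                       ("bandwidth", bw_v), ("centroid", cent_v)):
        for stat, v in _basic4(np.asarray(vals)).items():
            out[f"sig_{name}_{stat}"] = v
    chroma = np.asarray(chroma_rows)
    for b in range(12):
        for stat, v in _basic4(chroma[:, b]).items():
            out[f"sig_chroma{b:02d}_{stat}"] = v
    out["sig_tempo"] = _tempo_bpm(np.asarray(onset_v), hop)
    return out


def _tempo_bpm(onset: np.ndarray, hop: float) -> float:
    onset = onset - onset.mean() if onset.size else onset
    if onset.size < 8 or not np.any(onset):
        return 0.0
    r = np.correlate(onset, onset, mode="full")[onset.size - 1:]
    lag_min = max(1, int(round(0.25 / hop)))   # 240 BPM
    lag_max = min(onset.size - 1, int(round(2.0 / hop)))  # 30 BPM
    if lag_max <= lag_min:
        return 0.0
    k = lag_min + int(np.argmax(r[lag_min:lag_max + 1]))
    return 60.0 / (k * hop)


def segment_duration_stats(seg: Segmentation) -> dict[str, float]:
    """Mean/SD/quartiles of the voiced and unvoiced segment durations
    plus counts; an empty class yields zeros with a zero count."""
    out: dict[str, float] = {}
    for name, ivals in (("voiced", seg.voiced), ("unvoiced", seg.unvoiced)):
        durs = np.asarray([b - a for a, b in ivals])
        out[f"{name}_count"] = float(durs.size)
        if durs.size == 0:
            for stat in ("mean", "sd", "q1", "q2", "q3"):
                out[f"{name}_dur_{stat}"] = 0.0
            continue
        out[f"{name}_dur_mean"] = float(durs.mean())
        out[f"{name}_dur_sd"] = float(durs.std(ddof=1)) if durs.size > 1 else 0.0
        q1, q2, q3 = (float(q) for q in np.quantile(durs, [0.25, 0.5, 0.75]))
        out[f"{name}_dur_q1"], out[f"{name}_dur_q2"], out[f"{name}_dur_q3"] = q1, q2, q3
    return out


def acoustic_feature_vector(
    clip: AudioClip,
    vad_backend: Optional[VADBackend] = None,
    task: str = "img",
) -> dict[str, float]:
    """Full acoustic feature map for one clip.

    Functionals are applied to each LLD restricted to voiced frames;
    loudness is summarized over all frames; the spectral-balance LLDs
    (alpha ratio, both slopes, Hammarberg) are additionally summarized
    over unvoiced frames with an ``_unvoiced`` suffix. Signal summary
    statistics and voiced/unvoiced duration statistics are appended.
    Names follow ``ac_<lld>_<stat>[_unvoiced]_<task>``.
    """
    lld = extract_lld_matrix(clip)
    seg = detect_voiced_segments(clip, lld, backend=vad_backend)
    voiced = lld.voiced_mask
    out: dict[str, float] = {}
    for name, series in lld.descriptors.items():
        mask = None if name == "loudness" else voiced
        for stat, v in lld_functionals(series, mask).items():
            out[f"ac_{name}_{stat}_{task}"] = v
        if name in UNVOICED_ALSO:
            for stat, v in lld_functionals(series, ~voiced).items():
                out[f"ac_{name}_{stat}_unvoiced_{task}"] = v
    for stat, v in signal_summary_stats(clip).items():
        out[f"ac_{stat}_{task}"] = v
    for stat, v in segment_duration_stats(seg).items():
        out[f"ac_seg_{stat}_{task}"] = v
    return out
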