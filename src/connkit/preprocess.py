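"""Shared preprocessing: local detrending, resampling, re-referencing,
band filtering with analytic-signal extraction, and segmentation.

The LFP pipeline runs every trace through a moving-window linear detrend
(1 s windows sliding by 0.5 s) to remove slow drift, then downsamples to the
working rate (1 kHz for most metrics, 250 Hz for autoregressive modelling).
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.signal import hilbert

from .recording import AnalyticSignal, BandSpec, MultiChannelRecording, SegmentSet

__all__ = [
    "detrend_local",
    "resample",
    "rereference",
    "bandpass",
    "bandpass_analytic",
    "segment",
    "next_pow2",
]


def next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def _local_linear_trend(x: np.ndarray, win: int, step: int) -> np.ndarray:
    """Overlap-weighted moving least-squares line through ``x``.

    Each window of ``win`` samples (advancing by ``step``) gets its own
    least-squares line; per-sample trend estimates from overlapping windows
    are averaged with uniform weight.  The final partial stretch is covered
    by a window anchored at the end so every sample is fitted.
    """
    n = x.size
    t = np.arange(win)
    # precompute normal-equation pieces for a shared abscissa
    t_mean = t.mean()
    t_c = t - t_mean
    denom = float(t_c @ t_c)

    starts = list(range(0, n - win + 1, step))
    if starts[-1] != n - win:
        starts.append(n - win)

    trend = np.zeros(n)
    weight = np.zeros(n)
    for s in starts:
        seg = x[s : s + win]
        b = float(t_c @ seg) / denom
        a = seg.mean() - b * t_mean
        trend[s : s + win] += a + b * t
        weight[s : s + win] += 1.0
    return trend / weight


def detrend_local(
    rec: MultiChannelRecording, window_s: float = 1.0, step_s: float = 0.5
) -> MultiChannelRecording:
    """Subtract a moving-window local linear trend from every channel.

    Mirrors Chronux-style ``locdetrend`` with a 1 s window sliding by 0.5 s:
    a least-squares line is fit in each window and the overlap-averaged
    line is removed.  Frequencies well above 1/window pass essentially
    unchanged.
    """
    win = int(round(window_s * rec.rate_hz))
    step = max(1, int(round(step_s * rec.rate_hz)))
    if win < 2:
        raise ValueError("window_s * rate must be >= 2 samples")
    if win > rec.n_samples:
        raise ValueError(
            f"detrend window ({win} samples) longer than record ({rec.n_samples})"
        )
    out = np.empty_like(rec.data)
    for i in range(rec.n_channels):
        out[i] = rec.data[i] - _local_linear_trend(rec.data[i], win, step)
    return rec.copy_with(data=out)


def resample(rec: MultiChannelRecording, target_hz: float) -> MultiChannelRecording:
    """Anti-alias filter and polyphase-resample to ``target_hz``.

    Only downsampling (or the identity) is allowed; upsampling a recording
    would fabricate bandwidth.
    """
    if target_hz > rec.rate_hz:
        raise ValueError(f"cannot upsample {rec.rate_hz} Hz -> {target_hz} Hz")
    if target_hz == rec.rate_hz:
        return rec.copy_with(data=rec.data.copy())
    from fractions import Fraction

    frac = Fraction(target_hz / rec.rate_hz).limit_denominator(10_000)
    out = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return rec.copy_with(data=out, rate_hz=float(target_hz))


def rereference(
    rec: MultiChannelRecording, ref_trace: np.ndarray, reference: str = "custom"
) -> MultiChannelRecording:
    """Digitally re-reference: subtract ``ref_trace`` from every channel.

    Moving the reference is a linear operation; applying it with ``-ref``
    restores the original traces exactly.
    """
    ref_trace = np.asarray(ref_trace, dtype=float)
    if ref_trace.ndim != 1 or ref_trace.size != rec.n_samples:
        raise ValueError(
            f"reference trace length {ref_trace.size} != record length {rec.n_samples}"
        )
    return rec.copy_with(data=rec.data - ref_trace[None, :], reference=reference)


def _fir_bandpass(band: BandSpec, rate_hz: float, min_cycles: float = 3.0) -> np.ndarray:
    """Design a linear-phase FIR band-pass for one frequency band.

    The length is the larger of ``min_cycles`` of band.lo and whatever a
    Hamming window needs for a transition width of a quarter of the band
    (never wider than band.lo, so the stopband cannot reach into DC).
    """
    trans = min(band.lo, 0.25 * (band.hi - band.lo))
    ntaps = max(
        int(round(min_cycles * rate_hz / band.lo)),
        int(np.ceil(3.3 * rate_hz / trans)),
    )
    ntaps |= 1  # odd length keeps type-I symmetry
    nyq = rate_hz / 2.0
    return sps.firwin(ntaps, [band.lo / nyq, band.hi / nyq], pass_zero=False)


def bandpass(x: np.ndarray, band: BandSpec, rate_hz: float) -> np.ndarray:
    """Zero-phase (two-pass) FIR band-pass filter of a 1-D trace."""
    if band.hi >= rate_hz / 2:
        raise ValueError(f"band.hi={band.hi} Hz at or above Nyquist {rate_hz / 2} Hz")
    taps = _fir_bandpass(band, rate_hz)
    if x.size <= 3 * taps.size:
        raise ValueError(
            f"record too short ({x.size} samples) for band-pass of length {taps.size}"
        )
    return sps.filtfilt(taps, [1.0], x)


def bandpass_analytic(
    rec_or_trace, band: BandSpec, rate_hz: float | None = None, channel: str | None = None
) -> AnalyticSignal:
    """Band-pass filter then Hilbert-transform to an analytic signal.

    Accepts either a 1-D trace (with ``rate_hz``) or a
    :class:`MultiChannelRecording` plus a channel label.  Returns the
    instantaneous envelope and phase (radians, (-pi, pi], zero at the
    cosine peak).
    """
    if isinstance(rec_or_trace, MultiChannelRecording):
        if channel is None:
            raise ValueError("channel label required for a multichannel recording")
        x = rec_or_trace.channel(channel)
        rate_hz = rec_or_trace.rate_hz
    else:
        x = np.asarray(rec_or_trace, dtype=float)
        if rate_hz is None:
            raise ValueError("rate_hz required for a bare trace")
    filt = bandpass(x, band, rate_hz)
    analytic = hilbert(filt)
    return AnalyticSignal(
        amplitude=np.abs(analytic),
        phase=np.angle(analytic),
        band=band,
        rate_hz=float(rate_hz),
    )


def segment(
    n_samples: int,
    rate_hz: float,
    win_s: float = 1.0,
    overlap_frac: float = 0.0,
    pad_pow2: bool = True,
) -> SegmentSet:
    """Tile a record with equal windows; trailing partial window dropped.

    Window count is ``floor((n - win) / step) + 1`` with
    ``step = win * (1 - overlap_frac)``.
    """
    if not (0 <= overlap_frac < 1):
        raise ValueError("overlap_frac must be in [0, 1)")
    win = int(round(win_s * rate_hz))
    if win < 2:
        raise ValueError("window must span >= 2 samples")
    if win > n_samples:
        raise ValueError(f"window ({win}) longer than record ({n_samples})")
    step = max(1, int(round(win * (1.0 - overlap_frac))))
    n_win = (n_samples - win) // step + 1
    starts = np.arange(n_win) * step
    pad_to = next_pow2(win) if pad_pow2 else win
    return SegmentSet(starts=starts, length=win, overlap=overlap_frac, pad_to=pad_to, rate_hz=rate_hz)
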