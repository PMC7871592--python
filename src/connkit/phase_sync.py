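"""Non-directional phase-synchronization metrics: debiased wPLI, PLV, PPC.

All three are computed from the same per-segment complex cross-spectra:
the record is cut into non-overlapping 1-s windows, each window is Hann
tapered (optionally dpss multitapered with +-0.5 Hz smoothing), zero-padded
to the next power of two and Fourier transformed; the per-window
cross-spectrum is ``X_j(f) = F_x conj(F_y)``.

* debiased wPLI weights phase-lag signs by the magnitude of the imaginary
  cross-spectrum and removes the sample-size bias; zero-lag (volume
  conducted) coupling has a purely real cross-spectrum and scores ~0.
* PLV is the resultant length of the phase differences, biased upward at
  small n.
* PPC is the average pairwise cosine of phase differences and is unbiased;
  it equals ``(n PLV^2 - 1) / (n - 1)`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import dpss, hann

from .preprocess import segment
from .spectral import SpectralMetric, band_aggregates

__all__ = ["CrossSpectrumSet", "cross_spectra", "wpli_debiased", "plv", "ppc"]


@dataclass
class CrossSpectrumSet:
    """Per-segment complex cross-spectral values on a common frequency grid."""

    freqs: np.ndarray
    csd: np.ndarray  # (n_segments, n_freqs) complex
    rate_hz: float

    @property
    def n_segments(self) -> int:
        return self.csd.shape[0]


def cross_spectra(
    x: np.ndarray,
    y: np.ndarray,
    rate_hz: float,
    win_s: float = 1.0,
    pad_pow2: bool = True,
    taper: str = "hann",
    smoothing_hz: float = 0.5,
    freq_range: tuple[float, float] | None = (0.1, 48.0),
) -> CrossSpectrumSet:
    """Per-window tapered cross-spectra of two equal-length traces.

    ``taper="hann"`` uses a single Hann window; ``taper="dpss"`` averages
    Slepian tapers with half-bandwidth ``smoothing_hz`` within each window.
    Windows are demeaned before padding so zero padding adds no DC leakage.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    segs = segment(x.size, rate_hz, win_s=win_s, overlap_frac=0.0, pad_pow2=pad_pow2)
    if segs.n_windows < 2:
        raise ValueError("need at least 2 full windows")
    n = segs.length
    if taper == "hann":
        tapers = hann(n, sym=False)[None, :]
    elif taper == "dpss":
        nw = max(1.0, smoothing_hz * win_s)
        k = max(1, int(2 * nw - 1))
        tapers = dpss(n, nw, Kmax=k)
        tapers = np.atleast_2d(tapers)
    else:
        raise ValueError(f"unknown taper {taper!r}")

    freqs = np.fft.rfftfreq(segs.pad_to, 1.0 / rate_hz)
    csd = np.empty((segs.n_windows, freqs.size), dtype=complex)
    for j, sl in enumerate(segs.slices()):
        xs = x[sl] - x[sl].mean()
        ys = y[sl] - y[sl].mean()
        fx = np.fft.rfft(tapers * xs[None, :], n=segs.pad_to, axis=1)
        fy = np.fft.rfft(tapers * ys[None, :], n=segs.pad_to, axis=1)
        csd[j] = (fx * np.conj(fy)).mean(axis=0)
    if freq_range is not None:
        mask = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
        freqs, csd = freqs[mask], csd[:, mask]
    return CrossSpectrumSet(freqs=freqs, csd=csd, rate_hz=rate_hz)


def wpli_debiased(cs: CrossSpectrumSet, bands=None) -> SpectralMetric:
    """Debiased (squared) weighted phase-lag index per frequency.

    Implements the pairwise estimator
    ``sum_{j<k} Im(X_j) Im(X_k) / sum_{j<k} |Im(X_j)| |Im(X_k)|``
    via the sum trick; 0/0 (all imaginary parts zero, e.g. a common
    zero-lag source) is defined as 0.  The estimator is unbiased and may be
    slightly negative under the null; values are reported unclipped.
    """
    if cs.n_segments < 2:
        raise ValueError("debiased wPLI needs >= 2 segments")
    im = np.imag(cs.csd)
    sum_im = im.sum(axis=0)
    sum_abs = np.abs(im).sum(axis=0)
    sum_sq = (im**2).sum(axis=0)
    num = sum_im**2 - sum_sq
    den = sum_abs**2 - sum_sq
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(den > 0, num / den, 0.0)
    return SpectralMetric(cs.freqs, vals, "wpli_debiased", band_aggregates(cs.freqs, vals, bands))


def plv(cs: CrossSpectrumSet, bands=None) -> SpectralMetric:
    """Phase-locking value: resultant length of per-segment phase differences."""
    if cs.n_segments < 1:
        raise ValueError("PLV needs >= 1 segment")
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(np.abs(cs.csd) > 0, cs.csd / np.abs(cs.csd), 0.0 + 0.0j)
    vals = np.abs(unit.mean(axis=0))
    return SpectralMetric(cs.freqs, vals, "plv", band_aggregates(cs.freqs, vals, bands))


def ppc(cs: CrossSpectrumSet, bands=None) -> SpectralMetric:
    """Pairwise phase consistency: mean pairwise cosine of phase differences.

    Computed through the identity ``PPC = (n PLV^2 - 1) / (n - 1)``, which
    equals the O(n^2) pairwise average exactly and has zero mean under the
    uniform null for any n.
    """
    n = cs.n_segments
    if n < 2:
        raise ValueError("PPC needs >= 2 segments")
    vals = (n * plv(cs).values**2 - 1.0) / (n - 1.0)
    return SpectralMetric(cs.freqs, vals, "ppc", band_aggregates(cs.freqs, vals, bands))
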