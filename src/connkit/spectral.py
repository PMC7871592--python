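"""Multitaper power and coherence (magnitude and phase angle).

Spectra are estimated with Slepian (dpss) tapers.  A :class:`TaperPlan`
pins the half-bandwidth, taper count and window length; the session-long
defaults follow the convention of a 0.2 Hz bandwidth with 220 tapers over
the 10-min window, while the binned time course uses 10-s bins with a 1 Hz
bandwidth and 19 tapers.  Power is reported in 10*log10 units; the analysed
frequency range is restricted to 0.1-48 Hz by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.signal.windows import dpss

from .recording import BandSpec, DEFAULT_BANDS

__all__ = [
    "TaperPlan",
    "SpectralMetric",
    "mt_power",
    "mt_coherence",
    "binned_spectra",
    "SESSION_PLAN",
    "BINNED_PLAN",
    "POWER_FLOOR_DB",
]

FREQ_RANGE = (0.1, 48.0)
POWER_FLOOR_DB = -300.0


@dataclass(frozen=True)
class TaperPlan:
    """Multitaper parameterisation: half-bandwidth (Hz), taper count, window (s).

    The admissible taper count is at most ``2 * window_s * bandwidth_hz - 1``;
    the time-bandwidth product NW is ``window_s * bandwidth_hz``.
    """

    bandwidth_hz: float
    n_tapers: int
    window_s: float

    def __post_init__(self) -> None:
        if self.n_tapers < 1:
            raise ValueError("need at least one taper")
        if self.n_tapers > 2 * self.window_s * self.bandwidth_hz - 1 + 1e-9:
            raise ValueError(
                f"{self.n_tapers} tapers exceeds 2TW-1 = "
                f"{2 * self.window_s * self.bandwidth_hz - 1:g}"
            )

    def tapers(self, n_samples: int) -> np.ndarray:
        nw = self.window_s * self.bandwidth_hz
        return _dpss_cached(n_samples, float(nw), self.n_tapers)


@lru_cache(maxsize=16)
def _dpss_cached(n: int, nw: float, k: int) -> np.ndarray:
    return dpss(n, nw, Kmax=k)


#: Session-long plan: 0.2 Hz bandwidth, 220 tapers over the full 600-s window.
SESSION_PLAN = TaperPlan(bandwidth_hz=0.2, n_tapers=220, window_s=600.0)
#: Time-course plan: 1 Hz bandwidth, 19 tapers in 10-s bins.
BINNED_PLAN = TaperPlan(bandwidth_hz=1.0, n_tapers=19, window_s=10.0)


@dataclass
class SpectralMetric:
    """A real-valued per-frequency estimate with band aggregates.

    ``kind`` tags the quantity: "power_db", "coherence", "phase_deg", ...
    Band aggregates report mean, peak and the frequency of the peak within
    each canonical band.
    """

    freqs: np.ndarray
    values: np.ndarray
    kind: str
    band_aggregates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.freqs.shape != self.values.shape:
            raise ValueError("freqs and values must align")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    def band_value(self, band: str | BandSpec, stat: str = "mean") -> float:
        agg = self.band_aggregates[band if isinstance(band, str) else band.name]
        return agg[stat]


def band_aggregates(freqs: np.ndarray, values: np.ndarray, bands=None) -> dict:
    bands = bands if bands is not None else DEFAULT_BANDS
    out = {}
    for name, band in bands.items():
        mask = band.contains(freqs)
        if not mask.any():
            continue
        v = values[mask]
        f = freqs[mask]
        i = int(np.argmax(v))
        out[name] = {"mean": float(v.mean()), "peak": float(v[i]), "peak_freq": float(f[i])}
    return out


def _taper_ffts(x: np.ndarray, plan: TaperPlan, rate_hz: float):
    """Tapered one-sided FFTs of a single demeaned window: (freqs, K x F)."""
    n = x.size
    x = x - x.mean()
    tapers = plan.tapers(n)
    specs = np.fft.rfft(tapers * x[None, :], axis=1)
    freqs = np.fft.rfftfreq(n, 1.0 / rate_hz)
    return freqs, specs


def _restrict(freqs: np.ndarray, *arrs, freq_range=FREQ_RANGE):
    mask = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
    return (freqs[mask],) + tuple(a[..., mask] for a in arrs)


def mt_power(
    x: np.ndarray,
    rate_hz: float,
    plan: TaperPlan,
    freq_range=FREQ_RANGE,
    bands=None,
) -> SpectralMetric:
    """Taper-averaged power spectral density in 10*log10 units.

    The PSD is one-sided and normalised so that white noise of variance
    sigma^2 has a flat level of sigma^2 / Nyquist (linear units) away from
    the edges.
    """
    x = np.asarray(x, dtype=float)
    n_need = int(round(plan.window_s * rate_hz))
    if x.size < n_need:
        raise ValueError(f"record ({x.size} samples) shorter than plan window ({n_need})")
    x = x[:n_need]
    freqs, specs = _taper_ffts(x, plan, rate_hz)
    psd = (np.abs(specs) ** 2).mean(axis=0) / rate_hz
    # one-sided: double interior bins
    psd[1:] *= 2.0
    if x.size % 2 == 0:
        psd[-1] /= 2.0
    freqs, psd = _restrict(freqs, psd, freq_range=freq_range)
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(psd)
    if np.any(~np.isfinite(db)):
        warnings.warn("zero power encountered; floored at %g dB" % POWER_FLOOR_DB)
        db = np.where(np.isfinite(db), db, POWER_FLOOR_DB)
    return SpectralMetric(freqs, db, "power_db", band_aggregates(freqs, db, bands))


def mt_coherence(
    x: np.ndarray,
    y: np.ndarray,
    rate_hz: float,
    plan: TaperPlan,
    freq_range=FREQ_RANGE,
    bands=None,
) -> tuple[SpectralMetric, SpectralMetric]:
    """Multitaper coherence magnitude and phase angle (degrees).

    Tapers are averaged in the cross- and auto-spectra before normalising:
    ``C(f) = |S_xy| / sqrt(S_xx S_yy)``, ``phi(f) = arg(S_xy)``.
    Magnitude lies in [0, 1]; phase is antisymmetric under argument swap.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n_need = int(round(plan.window_s * rate_hz))
    if x.size < n_need:
        raise ValueError(f"record ({x.size} samples) shorter than plan window ({n_need})")
    x, y = x[:n_need], y[:n_need]
    freqs, fx = _taper_ffts(x, plan, rate_hz)
    _, fy = _taper_ffts(y, plan, rate_hz)
    sxy = (fx * np.conj(fy)).mean(axis=0)
    sxx = (np.abs(fx) ** 2).mean(axis=0)
    syy = (np.abs(fy) ** 2).mean(axis=0)
    denom = np.sqrt(sxx * syy)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(denom > 0, np.abs(sxy) / denom, 0.0)
    coh = np.clip(coh, 0.0, 1.0)
    phase = np.degrees(np.angle(sxy))
    freqs, coh, phase = _restrict(freqs, coh, phase, freq_range=freq_range)
    mag = SpectralMetric(freqs, coh, "coherence", band_aggregates(freqs, coh, bands))
    ph = SpectralMetric(freqs, phase, "phase_deg", band_aggregates(freqs, phase, bands))
    return mag, ph


def binned_spectra(
    x: np.ndarray,
    rate_hz: float,
    y: np.ndarray | None = None,
    bin_s: float = 10.0,
    plan: TaperPlan = BINNED_PLAN,
    freq_range=FREQ_RANGE,
    bands=None,
) -> list:
    """Power (or coherence, if ``y`` given) in non-overlapping time bins.

    Each full ``bin_s`` bin yields one spectrum under ``plan``; a record
    shorter than one bin is an error.
    """
    x = np.asarray(x, dtype=float)
    nbin = int(round(bin_s * rate_hz))
    n_bins = x.size // nbin
    if n_bins < 1:
        raise ValueError(f"record shorter than one {bin_s}-s bin")
    out = []
    for b in range(n_bins):
        seg = slice(b * nbin, (b + 1) * nbin)
        if y is None:
            out.append(mt_power(x[seg], rate_hz, plan, freq_range, bands))
        else:
            out.append(mt_coherence(x[seg], np.asarray(y)[seg], rate_hz, plan, freq_range, bands))
    return out
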