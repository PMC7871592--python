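"""Cross-regional theta-gamma phase-amplitude coupling.

Coupling strength is the Kullback-Leibler modulation index (MI): theta
phases from one region are binned into eighteen 20-degree intervals, the
mean gamma amplitude of the other region is computed per bin, the binned
profile is normalised to a distribution P and compared against uniform:

    MI = KL(P || uniform) / log(18) = (log 18 - H(P)) / log 18

MI is 0 for a phase-uniform amplitude and 1 when all amplitude mass sits
in a single phase bin.  The session is split into 1-min bins; the session
MI is the average of the per-bin values.  Direction is labelled
"theta-region -> gamma-region" (the first-named region contributes the
phase).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import AnalyticSignal

__all__ = ["PacResult", "modulation_index", "mi_from_profile", "N_PHASE_BINS"]

N_PHASE_BINS = 18
_BIN_EDGES = np.linspace(-np.pi, np.pi, N_PHASE_BINS + 1)


@dataclass
class PacResult:
    mi: float
    phase_bin_profile: np.ndarray  # mean amplitude per 20-degree bin
    direction: str
    bin_minutes: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.phase_bin_profile = np.asarray(self.phase_bin_profile, dtype=float)
        if self.phase_bin_profile.size != N_PHASE_BINS:
            raise ValueError(f"profile must have {N_PHASE_BINS} bins")


def mi_from_profile(mean_amp: np.ndarray) -> float:
    """MI of an 18-bin mean-amplitude profile (empty bins contribute 0)."""
    mean_amp = np.asarray(mean_amp, dtype=float)
    total = mean_amp.sum()
    if total <= 0:
        raise ValueError("all-zero amplitude profile")
    p = mean_amp / total
    nz = p > 0
    entropy = -np.sum(p[nz] * np.log(p[nz]))
    # clamp roundoff: KL divergence is >= 0 by construction
    return float(max(0.0, (np.log(N_PHASE_BINS) - entropy) / np.log(N_PHASE_BINS)))


def _profile(phase: np.ndarray, amp: np.ndarray) -> np.ndarray:
    idx = np.clip(np.digitize(phase, _BIN_EDGES) - 1, 0, N_PHASE_BINS - 1)
    sums = np.bincount(idx, weights=amp, minlength=N_PHASE_BINS)
    counts = np.bincount(idx, minlength=N_PHASE_BINS)
    out = np.zeros(N_PHASE_BINS)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return out


def modulation_index(
    theta_phase: AnalyticSignal,
    gamma_amp: AnalyticSignal,
    bin_s: float = 60.0,
    direction: str = "theta->gamma",
) -> PacResult:
    """Kullback-Leibler modulation index of gamma amplitude by theta phase.

    Phase bin 1 spans [-180, -160) degrees in the wrapped convention.
    Computed per ``bin_s`` time bin (1 min by default) and averaged; a
    record shorter than one bin is treated as a single bin.
    """
    phase = theta_phase.phase
    amp = gamma_amp.amplitude
    if phase.shape != amp.shape:
        raise ValueError("phase and amplitude series must have equal length")
    if theta_phase.rate_hz != gamma_amp.rate_hz:
        raise ValueError("phase and amplitude series must share a sampling rate")
    if np.all(amp == 0):
        raise ValueError("all-zero amplitude signal")
    nbin = int(round(bin_s * theta_phase.rate_hz))
    n_bins = max(1, phase.size // nbin)
    mis = []
    for b in range(n_bins):
        sl = slice(b * nbin, (b + 1) * nbin) if phase.size >= nbin else slice(None)
        mis.append(mi_from_profile(_profile(phase[sl], amp[sl])))
    session_profile = _profile(phase, amp)
    return PacResult(
        mi=float(np.mean(mis)),
        phase_bin_profile=session_profile,
        direction=direction,
        bin_minutes=np.asarray(mis),
    )
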