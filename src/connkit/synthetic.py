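"""Ground-truth signal generators for benchmarking coupling metrics.

Real recordings never come with known coupling; these generators do.  Each
produces a :class:`~connkit.recording.MultiChannelRecording` (or spike
train) whose directed influence, phase lag, modulation depth or locking
angle is set explicitly, so every downstream metric can be validated as a
parameter-recovery problem:

* ``gen_var_lfp`` -- channels driven by a stable vector autoregression
  (known Geweke causality, computable in closed form from the true
  coefficients).
* ``gen_phase_lagged_pair`` -- a common oscillation observed twice with a
  fixed phase lag at a chosen frequency.
* ``gen_common_source`` -- zero-lag mixing of one (or more) sources into
  several channels: the volume-conduction confound, with a purely real
  cross-spectrum.
* ``gen_pac_signal`` -- a gamma carrier whose envelope is modulated by the
  theta phase of another channel at known depth.
* ``gen_locked_spikes`` -- spike times von-Mises locked to a theta phase
  series at known angle, concentration and delay.
* ``gen_cohort`` -- two-group cohorts whose coupling drifts linearly over
  the session at group-specific slopes (the habituation-divergence design).

Noise is Gaussian throughout; SNR is defined as the variance ratio of
signal to noise.  One top-level seed deterministically spawns independent
per-component substreams, so identical specs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .recording import MultiChannelRecording

__all__ = [
    "ScenarioSpec",
    "CouplingBlock",
    "gen_var_lfp",
    "gen_phase_lagged_pair",
    "gen_common_source",
    "gen_pac_signal",
    "gen_locked_spikes",
    "gen_cohort",
    "gen_redundant_metric_table",
    "generate_scenario",
    "var_spectral_radius",
]


@dataclass
class CouplingBlock:
    """One ground-truth coupling ingredient of a scenario.

    ``kind`` selects the generator; ``params`` holds its keyword arguments
    (e.g. coefficient matrices for ``var``, frequency and lag for
    ``phase_lag``, a mixing matrix for ``common_source``, depth for
    ``pac``, von-Mises parameters for ``locked_spikes``).
    """

    kind: str
    params: dict = field(default_factory=dict)

    _KINDS = {"var", "phase_lag", "common_source", "pac", "locked_spikes", "drift"}

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown block kind {self.kind!r}; one of {sorted(self._KINDS)}")


@dataclass
class ScenarioSpec:
    """A reproducible simulation scenario: duration, rate, regions, blocks."""

    duration_s: float
    rate_hz: float
    regions: Sequence[str]
    seed: int
    blocks: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        self.regions = list(self.regions)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.rate_hz))

    def substreams(self, n: int):
        """Independent, reproducible per-block random generators."""
        return [np.random.default_rng(s) for s in np.random.SeedSequence(self.seed).spawn(n)]


def var_spectral_radius(coefs: np.ndarray) -> float:
    """Spectral radius of the VAR companion matrix (stability iff < 1)."""
    coefs = np.asarray(coefs, dtype=float)
    p, n, _ = coefs.shape
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = np.concatenate(list(coefs), axis=1)
    if p > 1:
        comp[n:, :-n] = np.eye(n * (p - 1))
    return float(np.abs(np.linalg.eigvals(comp)).max())


def gen_var_lfp(
    coefs: np.ndarray,
    sigma: np.ndarray,
    duration_s: float,
    rate_hz: float,
    seed: int | np.random.Generator = 0,
    labels: Sequence[str] | None = None,
) -> MultiChannelRecording:
    """Simulate a stable VAR(p) process driven by Gaussian noise.

    ``coefs`` has shape (p, n, n); ``sigma`` is the innovation covariance.
    A burn-in of 10 * p samples is discarded to shed initial-condition
    transients.  Unstable coefficient sets are rejected with the offending
    spectral radius in the message.
    """
    coefs = np.asarray(coefs, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    p, n, _ = coefs.shape
    if not np.allclose(sigma, sigma.T):
        raise ValueError("noise covariance must be symmetric")
    np.linalg.cholesky(sigma)  # raises if not positive definite
    rho = var_spectral_radius(coefs)
    if rho >= 1.0:
        raise ValueError(f"unstable VAR: companion spectral radius {rho:.4f} >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_samples = int(round(duration_s * rate_hz))
    burn = 10 * p
    total = n_samples + burn
    chol = np.linalg.cholesky(sigma)
    eps = rng.standard_normal((total, n)) @ chol.T
    x = np.zeros((total, n))
    x[:p] = eps[:p]
    for t in range(p, total):
        acc = eps[t].copy()
        for k in range(p):
            acc += coefs[k] @ x[t - 1 - k]
        x[t] = acc
    labels = list(labels) if labels is not None else [f"ch{i}" for i in range(n)]
    return MultiChannelRecording(data=x[burn:].T, rate_hz=rate_hz, labels=labels)


def gen_phase_lagged_pair(
    f_hz: float,
    lag_deg: float,
    snr: float,
    duration_s: float,
    rate_hz: float,
    seed: int | np.random.Generator = 0,
    labels: Sequence[str] = ("A", "B"),
    amplitude: float = 1.0,
) -> MultiChannelRecording:
    """Two channels sharing a sinusoid, the second delayed by ``lag_deg``.

    Independent Gaussian noise is added per channel so that the sinusoid
    variance over noise variance equals ``snr`` (``np.inf`` for noiseless).
    """
    if not (0 < f_hz < rate_hz / 2):
        raise ValueError(f"f={f_hz} Hz must lie strictly below Nyquist {rate_hz / 2} Hz")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * rate_hz))) / rate_hz
    ph = 2 * np.pi * f_hz * t
    x = amplitude * np.cos(ph)
    y = amplitude * np.cos(ph - np.deg2rad(lag_deg))
    if np.isfinite(snr):
        sd = amplitude * np.sqrt(0.5 / snr)
        x = x + sd * rng.standard_normal(t.size)
        y = y + sd * rng.standard_normal(t.size)
    return MultiChannelRecording(data=np.vstack([x, y]), rate_hz=rate_hz, labels=labels)


def gen_common_source(
    mixing: np.ndarray,
    source: np.ndarray,
    rate_hz: float,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    labels: Sequence[str] | None = None,
) -> MultiChannelRecording:
    """Zero-lag mixture of source(s) into several channels (volume conduction).

    ``mixing`` is (n_channels, n_sources); ``source`` is (n_sources,
    n_samples) or 1-D for a single source.  Every channel is an
    instantaneous weighted copy plus independent Gaussian noise, so the
    cross-spectrum between channels is purely real: coherence can be
    arbitrarily high while lag-based metrics stay at their null.
    """
    source = np.atleast_2d(np.asarray(source, dtype=float))
    mixing = np.atleast_2d(np.asarray(mixing, dtype=float))
    if not np.all(np.isfinite(mixing)):
        raise ValueError("mixing matrix must be finite")
    if mixing.shape[1] != source.shape[0]:
        raise ValueError(
            f"mixing has {mixing.shape[1]} columns but source has {source.shape[0]} rows"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = mixing @ source
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal(data.shape)
    labels = list(labels) if labels is not None else [f"ch{i}" for i in range(data.shape[0])]
    return MultiChannelRecording(data=data, rate_hz=rate_hz, labels=labels)


def gen_pac_signal(
    f_theta: float,
    f_gamma: float,
    depth: float,
    duration_s: float,
    rate_hz: float,
    seed: int | np.random.Generator = 0,
    phase_offset_deg: float = 0.0,
    noise_sd: float = 0.0,
    gamma_amplitude: float = 0.5,
    labels: Sequence[str] = ("theta_region", "gamma_region"),
) -> MultiChannelRecording:
    """Cross-regional phase-amplitude coupling of known depth.

    Channel A carries the theta oscillation ``cos(2 pi f_theta t)``;
    channel B carries a gamma carrier whose envelope is
    ``1 + depth * cos(theta_phase - phase_offset)`` plus optional noise.
    ``depth`` must lie in [0, 1]; ``f_gamma`` must exceed ``2 f_theta`` so
    phase and amplitude bands do not overlap.
    """
    if not (0.0 <= depth <= 1.0):
        raise ValueError(f"modulation depth must be in [0, 1], got {depth}")
    if f_gamma <= 2 * f_theta:
        raise ValueError("f_gamma must exceed 2 * f_theta")
    if f_gamma >= rate_hz / 2:
        raise ValueError("f_gamma at or above Nyquist")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * rate_hz))) / rate_hz
    theta_phase = 2 * np.pi * f_theta * t
    a = np.cos(theta_phase)
    envelope = 1.0 + depth * np.cos(theta_phase - np.deg2rad(phase_offset_deg))
    b = gamma_amplitude * envelope * np.cos(2 * np.pi * f_gamma * t)
    if noise_sd > 0:
        a = a + noise_sd * rng.standard_normal(t.size)
        b = b + noise_sd * rng.standard_normal(t.size)
    return MultiChannelRecording(data=np.vstack([a, b]), rate_hz=rate_hz, labels=labels)


def gen_locked_spikes(
    phase_deg: np.ndarray,
    rate_hz: float,
    mu_deg: float,
    kappa: float,
    n_spikes: int,
    delay_ms: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Spike times whose phases follow a von Mises law on a phase series.

    ``phase_deg`` is a monotonically ramping (mod 360) phase series, e.g.
    from :func:`connkit.spike_phase.theta_phase_interp`.  Each spike picks
    a random cycle and the moment within it where the phase crosses a von
    Mises(mu, kappa) draw; a common delay is then added in continuous time.
    Spike times are returned sorted (collisions dropped).
    """
    if n_spikes < 1:
        raise ValueError("n_spikes must be >= 1")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    phase_deg = np.asarray(phase_deg, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    wraps = np.flatnonzero(np.diff(phase_deg) < -180.0)  # cycle boundaries
    if wraps.size < 2:
        raise ValueError("phase series too short: fewer than two full cycles")
    cycle_starts = wraps[:-1] + 1
    cycle_ends = wraps[1:] + 1
    target = np.rad2deg(rng.vonmises(np.deg2rad(mu_deg), kappa, size=n_spikes)) % 360.0
    cyc = rng.integers(0, cycle_starts.size, size=n_spikes)
    times = np.empty(n_spikes)
    for s in range(n_spikes):
        a, b = cycle_starts[cyc[s]], cycle_ends[cyc[s]]
        seg = phase_deg[a:b]
        # phase ramps linearly within the cycle; invert by interpolation
        idx = np.interp(target[s], seg, np.arange(seg.size))
        times[s] = (a + idx) / rate_hz
    times = np.unique(times) + delay_ms / 1000.0
    return times


# ----------------------------------------------------------------- cohorts


def gen_cohort(
    n_per_group: tuple[int, int] = (12, 15),
    duration_s: float = 600.0,
    rate_hz: float = 250.0,
    f_hz: float = 8.0,
    lag_deg: float = 60.0,
    base_snr: tuple[float, float] = (1.0, 1.0),
    snr_slope_per_min: tuple[float, float] = (0.0, 0.0),
    subject_jitter: float = 0.1,
    seed: int = 0,
    group_names: tuple[str, str] = ("WT", "KO"),
):
    """Two-group cohort with linearly drifting coupling strength.

    Each subject's recording is a phase-lagged oscillatory pair whose
    band-limited SNR drifts linearly over the session at the group's slope
    (``snr_slope_per_min``), around a subject-jittered baseline.  Returns
    ``(recordings, labels)`` with one group label per recording.  Defaults
    model a typical two-genotype cohort (12 vs 15 subjects, 10-min
    sessions); callers may scale duration down for quick experiments.
    """
    if min(n_per_group) < 2:
        raise ValueError("need >= 2 subjects per group for any group comparison")
    streams = np.random.SeedSequence(seed).spawn(sum(n_per_group))
    t_min = None
    recs, labels = [], []
    k = 0
    for g, (n_sub, name) in enumerate(zip(n_per_group, group_names)):
        for _ in range(n_sub):
            rng = np.random.default_rng(streams[k])
            k += 1
            base = base_snr[g] * (1.0 + subject_jitter * rng.standard_normal())
            slope = snr_slope_per_min[g] * (1.0 + subject_jitter * rng.standard_normal())
            n = int(round(duration_s * rate_hz))
            t = np.arange(n) / rate_hz
            if t_min is None:
                t_min = t / 60.0
            snr_t = np.maximum(base + slope * (t / 60.0), 1e-3)
            ph = 2 * np.pi * f_hz * t + rng.uniform(0, 2 * np.pi)
            # time-varying signal amplitude against unit-variance noise
            amp = np.sqrt(2.0 * snr_t)
            x = amp * np.cos(ph) + rng.standard_normal(n)
            y = amp * np.cos(ph - np.deg2rad(lag_deg)) + rng.standard_normal(n)
            recs.append(
                MultiChannelRecording(data=np.vstack([x, y]), rate_hz=rate_hz, labels=["A", "B"])
            )
            labels.append(name)
    return recs, labels


def gen_redundant_metric_table(
    n_subjects: int = 27,
    latent_sd: float = 1.0,
    noise_sd: float = 0.4,
    connections: Sequence[str] = ("PFC-dHC", "PFC-vHC", "vHC-dHC"),
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Per-connection metric tables with one planted redundancy.

    For each connection, metrics ``m1`` and ``m2`` share a latent driver
    (so they correlate strongly), while ``m3`` is independent noise.  Used
    to validate that the consensus analysis flags exactly the driven pair.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for conn in connections:
        z = latent_sd * rng.standard_normal(n_subjects)
        df = pd.DataFrame(
            {
                "m1": z + noise_sd * rng.standard_normal(n_subjects),
                "m2": z + noise_sd * rng.standard_normal(n_subjects),
                "m3": rng.standard_normal(n_subjects),
            }
        )
        out[conn] = df
    return out


# ------------------------------------------------------------- scenarios


def generate_scenario(spec: ScenarioSpec) -> dict:
    """Materialise a :class:`ScenarioSpec`: one entry per block.

    Returns a dict with ``"recordings"`` (list of MultiChannelRecording,
    one per LFP-producing block) and ``"spike_trains"`` (list of spike-time
    arrays from ``locked_spikes`` blocks, generated against the phase of
    the preceding block's first channel).
    """
    streams = spec.substreams(max(1, len(spec.blocks)))
    recordings, spikes = [], []
    for block, rng in zip(spec.blocks, streams):
        p = dict(block.params)
        if block.kind == "var":
            recordings.append(
                gen_var_lfp(
                    p["coefs"], p["sigma"], spec.duration_s, spec.rate_hz, seed=rng,
                    labels=p.get("labels", spec.regions[: np.asarray(p["coefs"]).shape[1]]),
                )
            )
        elif block.kind == "phase_lag":
            recordings.append(
                gen_phase_lagged_pair(
                    p["f_hz"], p["lag_deg"], p.get("snr", np.inf),
                    spec.duration_s, spec.rate_hz, seed=rng,
                    labels=p.get("labels", spec.regions[:2]),
                )
            )
        elif block.kind == "common_source":
            src = p.get("source")
            if src is None:
                t = np.arange(spec.n_samples) / spec.rate_hz
                src = np.cos(2 * np.pi * p.get("f_hz", 8.0) * t)
            recordings.append(
                gen_common_source(
                    p["mixing"], src, spec.rate_hz, noise_sd=p.get("noise_sd", 0.0),
                    seed=rng, labels=p.get("labels"),
                )
            )
        elif block.kind == "pac":
            recordings.append(
                gen_pac_signal(
                    p.get("f_theta", 8.0), p.get("f_gamma", 40.0), p["depth"],
                    spec.duration_s, spec.rate_hz, seed=rng,
                    noise_sd=p.get("noise_sd", 0.0),
                    labels=p.get("labels", spec.regions[:2]),
                )
            )
        elif block.kind == "locked_spikes":
            if not recordings:
                raise ValueError("locked_spikes block needs a preceding LFP block")
            from .spike_phase import theta_phase_interp

            ref = recordings[-1]
            ps = theta_phase_interp(ref.data[0], ref.rate_hz)
            spikes.append(
                gen_locked_spikes(
                    ps.phase, ref.rate_hz, p["mu_deg"], p["kappa"], p["n_spikes"],
                    delay_ms=p.get("delay_ms", 0.0), seed=rng,
                )
            )
        elif block.kind == "drift":
            recs, labels = gen_cohort(seed=int(rng.integers(2**31)), **p)
            recordings.extend(recs)
    return {"recordings": recordings, "spike_trains": spikes}
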