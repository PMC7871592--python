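"""Directed spectral metrics: parametric and non-parametric Granger
causality, partial directed coherence and the directed transfer function.

Parametric route: a vector autoregression is fit by pooled least squares
over non-overlapping short sections (trial averaging for approximate
stationarity; samples whose lags would straddle a section boundary are
excluded).  The Geweke spectral decomposition then gives the per-frequency
causal influence from the transfer function ``H(f)`` and the residual
covariance ``Sigma``::

    f_{x->y}(f) = ln( S_yy(f) / (S_yy(f) - (Sig_xx - Sig_xy^2/Sig_yy) |H_yx(f)|^2) )

Non-parametric route: the cross-spectral density matrix is factorised by
Wilson's iterative algorithm into a minimum-phase transfer function and a
noise covariance, and the same Geweke formula is applied -- no model order
is involved.

Band values integrate the spectrum over the band (arithmetic mean over
in-band bins by default; trapezoidal rule optionally).  Data intended for
these metrics are used unfiltered and downsampled to 250 Hz by convention
(model order 27 at that rate is the pipeline default for real recordings).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import BandSpec, DEFAULT_BANDS

__all__ = [
    "VarModel",
    "SpectralMatrix",
    "DirectedSpectrum",
    "fit_var",
    "select_order",
    "var_transfer",
    "var_spectral_matrix",
    "gc_spectrum",
    "spectral_matrix",
    "wilson_factorize",
    "np_gc",
    "pdc",
    "dtf",
    "gc_permutation_null",
    "GC_RATE_HZ",
    "DEFAULT_ORDER",
]

#: Working sample rate for autoregressive metrics.
GC_RATE_HZ = 250.0
#: Pipeline default model order at 250 Hz.
DEFAULT_ORDER = 27


@dataclass
class VarModel:
    """Fitted vector autoregression.

    ``coefs`` has shape (order, n, n) with ``coefs[k-1]`` the lag-k matrix
    A_k in ``x_t = sum_k A_k x_{t-k} + e_t``; ``sigma`` is the residual
    covariance (MLE denominator).
    """

    coefs: np.ndarray
    sigma: np.ndarray
    n_obs: int
    loglik: float
    bic: float

    @property
    def order(self) -> int:
        return self.coefs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coefs.shape[1]

    @property
    def spectral_radius(self) -> float:
        p, n, _ = self.coefs.shape
        comp = np.zeros((n * p, n * p))
        comp[:n, :] = np.concatenate(self.coefs, axis=1)
        if p > 1:
            comp[n:, :-n] = np.eye(n * (p - 1))
        return float(np.abs(np.linalg.eigvals(comp)).max())

    @property
    def is_stable(self) -> bool:
        return self.spectral_radius < 1.0


@dataclass
class SpectralMatrix:
    """Cross-spectral density S(f): Hermitian PSD matrices on a uniform grid.

    Convention: ``values[k]`` is an n x n matrix normalised so that the mean
    of S over the full (two-sided) circle equals the process covariance;
    a VAR process then satisfies S(f) = H(f) Sigma H(f)^H exactly.  The grid
    must be uniform and include 0 and Nyquist.
    """

    freqs: np.ndarray
    values: np.ndarray  # (n_freqs, n, n) complex
    rate_hz: float


@dataclass
class DirectedSpectrum:
    """Per-frequency directed influence for every ordered channel pair."""

    freqs: np.ndarray
    values: dict  # (source_idx, target_idx) -> array over freqs
    metric: str
    rate_hz: float

    def band_integral(
        self, source: int, target: int, band: str | BandSpec, how: str = "mean"
    ) -> float:
        """Integrate the directed spectrum over a band (mean or trapezoid)."""
        b = DEFAULT_BANDS[band] if isinstance(band, str) else band
        mask = b.contains(self.freqs)
        if not mask.any():
            raise ValueError(f"no frequency bins inside band {b.name}")
        v = self.values[(source, target)][mask]
        if how == "mean":
            return float(v.mean())
        if how == "trapz":
            return float(np.trapezoid(v, self.freqs[mask]))
        raise ValueError(f"unknown integration rule {how!r}")


# ----------------------------------------------------------------- VAR fit


def _section_starts(n_samples: int, section_len: int):
    n_sec = n_samples // section_len
    return [s * section_len for s in range(n_sec)]


def _build_regression(x: np.ndarray, p: int, section_len: int | None):
    """Stacked lag regression excluding section-boundary lags.

    x: (n_channels, n_samples).  Returns (Y, X) with Y = targets (T x n),
    X = lagged predictors (T x n*p).
    """
    n, total = x.shape
    if section_len is None:
        section_len = total
    ys, xs = [], []
    for s in _section_starts(total, section_len):
        seg = x[:, s : s + section_len]
        if seg.shape[1] <= p:
            continue
        seg = seg - seg.mean(axis=1, keepdims=True)
        T = seg.shape[1] - p
        ys.append(seg[:, p:].T)
        lag_cols = [seg[:, p - k : p - k + T].T for k in range(1, p + 1)]
        xs.append(np.concatenate(lag_cols, axis=1))
    if not ys:
        raise ValueError("no section long enough for the requested order")
    return np.concatenate(ys, axis=0), np.concatenate(xs, axis=0)


def fit_var(
    x: np.ndarray,
    p: int,
    rate_hz: float | None = None,
    section_s: float | None = 10.0,
) -> VarModel:
    """Fit a VAR(p) by pooled least squares over non-overlapping sections.

    Sections (default 10 s when ``rate_hz`` is given) are demeaned
    individually and pooled; lag windows never straddle a boundary.  The
    fit is checked for stability and conditioning.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[0]
    if p < 1:
        raise ValueError("order must be >= 1")
    section_len = None
    if rate_hz is not None and section_s is not None:
        section_len = int(round(section_s * rate_hz))
    Y, X = _build_regression(x, p, section_len)
    T = Y.shape[0]
    if T < 2 * p * n:
        raise ValueError(f"too few usable samples ({T}) for order {p}")
    sol, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"singular lag regression (rank {rank} < {X.shape[1]}); "
            "duplicated or linearly dependent channels?"
        )
    resid = Y - X @ sol
    sigma = resid.T @ resid / T
    coefs = np.stack([sol[k * n : (k + 1) * n].T for k in range(p)])
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError("residual covariance not positive definite")
    loglik = -0.5 * T * (n * np.log(2 * np.pi) + logdet + n)
    bic = logdet + (np.log(T) / T) * p * n * n
    return VarModel(coefs=coefs, sigma=sigma, n_obs=T, loglik=loglik, bic=bic)


def select_order(
    x: np.ndarray,
    p_max: int,
    rate_hz: float | None = None,
    section_s: float | None = 10.0,
) -> int:
    """Bayesian-information-criterion order selection over 1..p_max."""
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    best_p, best_bic = 1, np.inf
    for p in range(1, p_max + 1):
        try:
            m = fit_var(x, p, rate_hz=rate_hz, section_s=section_s)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if m.bic < best_bic:
            best_p, best_bic = p, m.bic
    return best_p


# --------------------------------------------------- spectra from a model


def _freq_grid(rate_hz: float, n_freqs: int) -> np.ndarray:
    return np.linspace(0.0, rate_hz / 2.0, n_freqs)


def var_transfer(model: VarModel, rate_hz: float, freqs: np.ndarray):
    """A-bar(f) = I - sum_k A_k exp(-2 pi i f k / rate) and H = A-bar^{-1}."""
    p, n, _ = model.coefs.shape
    k = np.arange(1, p + 1)
    w = np.exp(-2j * np.pi * np.outer(freqs, k) / rate_hz)  # (F, p)
    abar = np.tile(np.eye(n, dtype=complex), (len(freqs), 1, 1))
    abar -= np.einsum("fk,kij->fij", w, model.coefs.astype(complex))
    H = np.linalg.inv(abar)
    return abar, H


def var_spectral_matrix(model: VarModel, rate_hz: float, n_freqs: int = 256) -> SpectralMatrix:
    """Theoretical CSD of a VAR process: S(f) = H(f) Sigma H(f)^H."""
    freqs = _freq_grid(rate_hz, n_freqs)
    _, H = var_transfer(model, rate_hz, freqs)
    S = H @ model.sigma @ np.conj(np.swapaxes(H, 1, 2))
    return SpectralMatrix(freqs=freqs, values=S, rate_hz=rate_hz)


def _geweke_pairwise(H, sigma, S, freqs, rate_hz) -> DirectedSpectrum:
    """Geweke directional spectra for all ordered pairs from H, Sigma, S."""
    n = sigma.shape[0]
    values = {}
    for i in range(n):  # source
        for j in range(n):  # target
            if i == j:
                continue
            s_jj = np.real(S[:, j, j])
            partial = sigma[i, i] - sigma[i, j] ** 2 / sigma[j, j]
            denom = s_jj - partial * np.abs(H[:, j, i]) ** 2
            denom = np.maximum(denom, np.finfo(float).tiny)
            with np.errstate(divide="ignore"):
                f = np.log(np.maximum(s_jj, np.finfo(float).tiny) / denom)
            values[(i, j)] = np.maximum(f, 0.0)
    return DirectedSpectrum(freqs=freqs, values=values, metric="GC", rate_hz=rate_hz)


def gc_spectrum(model: VarModel, rate_hz: float = GC_RATE_HZ, n_freqs: int = 256) -> DirectedSpectrum:
    """Parametric Geweke spectral Granger causality from a fitted VAR."""
    if not model.is_stable:
        raise ValueError(
            f"unstable VAR (spectral radius {model.spectral_radius:.4f} >= 1)"
        )
    freqs = _freq_grid(rate_hz, n_freqs)
    _, H = var_transfer(model, rate_hz, freqs)
    S = H @ model.sigma @ np.conj(np.swapaxes(H, 1, 2))
    return _geweke_pairwise(H, model.sigma, S, freqs, rate_hz)


# ------------------------------------------------- non-parametric route


def spectral_matrix(
    x: np.ndarray,
    rate_hz: float,
    win_s: float = 2.0,
    section_s: float | None = None,
) -> SpectralMatrix:
    """Averaged-periodogram CSD matrix on a uniform grid incl. 0 and Nyquist.

    Each window is demeaned and Hann tapered; the periodograms are
    normalised so the mean of S over the two-sided circle equals the
    process covariance (the convention Wilson factorization expects).
    """
    from scipy.signal.windows import hann

    x = np.atleast_2d(np.asarray(x, dtype=float))
    n_ch, total = x.shape
    nwin = int(round(win_s * rate_hz))
    if nwin % 2:
        nwin += 1
    starts = range(0, total - nwin + 1, nwin // 2)  # 50% overlap
    taper = hann(nwin, sym=False)
    norm = (taper**2).mean()
    acc = None
    count = 0
    for s in starts:
        seg = x[:, s : s + nwin]
        seg = seg - seg.mean(axis=1, keepdims=True)
        F = np.fft.fft(taper[None, :] * seg, axis=1)  # (n_ch, nfft)
        Sw = np.einsum("if,jf->fij", F, np.conj(F)) / (nwin * norm)
        acc = Sw if acc is None else acc + Sw
        count += 1
    if count == 0:
        raise ValueError("record shorter than one window")
    Sfull = acc / count  # (nfft, n, n) over the full circle
    n_half = nwin // 2 + 1
    freqs = np.fft.rfftfreq(nwin, 1.0 / rate_hz)
    return SpectralMatrix(freqs=freqs, values=Sfull[:n_half], rate_hz=rate_hz)


def _plus_operator(g: np.ndarray) -> np.ndarray:
    """Causal part of a matrix function on the full frequency circle.

    g: (nfft, n, n).  Transform to the lag domain, keep non-negative lags
    (half the zero lag, upper-triangularised), back-transform.
    """
    nfft = g.shape[0]
    gam = np.fft.ifft(g, axis=0)
    beta0 = 0.5 * gam[0]
    gam[0] = np.triu(beta0)
    gam[nfft // 2 + 1 :] = 0.0
    return np.fft.fft(gam, axis=0)


def wilson_factorize(
    S: SpectralMatrix, tol: float = 1e-9, max_iter: int = 100, max_residual: float = 1e-2
):
    """Factorise S(f) = H(f) Sigma H(f)^H by Wilson's iterative algorithm.

    Returns (H, Sigma, psi) on the one-sided grid of ``S``.  The iteration
    stops when the factor stagnates (relative change in psi below ``tol``)
    or the relative factorization error ||psi psi^H - S|| / ||S|| drops
    below ``tol``.  On an exactly factorizable spectrum (e.g. the analytic
    CSD of a finite-order VAR) the residual reaches ~1e-12; an empirical
    windowed-periodogram CSD retains a small truncation floor because the
    exact causal factor has an infinite-order expansion while psi is a
    finite polynomial on the grid.  Non-convergence (final residual above
    ``max_residual``) raises with the residual in the message.
    """
    n_half = S.values.shape[0]
    n = S.values.shape[1]
    nfft = 2 * (n_half - 1)
    # two-sided extension: S(-f) = conj(S(f))
    Sfull = np.empty((nfft, n, n), dtype=complex)
    Sfull[:n_half] = S.values
    Sfull[n_half:] = np.conj(S.values[-2:0:-1])

    # init: Cholesky of the zero-lag covariance
    gam0 = np.real(np.fft.ifft(Sfull, axis=0)[0])
    gam0 = 0.5 * (gam0 + gam0.T)
    try:
        h = np.linalg.cholesky(gam0).T  # upper triangular
    except np.linalg.LinAlgError:
        h = np.linalg.cholesky(gam0 + 1e-12 * np.trace(gam0) * np.eye(n)).T
    psi = np.tile(h.astype(complex), (nfft, 1, 1))

    I = np.eye(n)
    s_norm = np.linalg.norm(Sfull)
    err = np.inf
    for _ in range(max_iter):
        psi_inv = np.linalg.inv(psi)
        g = psi_inv @ Sfull @ np.conj(np.swapaxes(psi_inv, 1, 2)) + I
        gp = _plus_operator(g)
        psi_new = psi @ gp
        delta = np.linalg.norm(psi_new - psi) / np.linalg.norm(psi)
        psi = psi_new
        err = np.linalg.norm(psi @ np.conj(np.swapaxes(psi, 1, 2)) - Sfull) / s_norm
        if err < tol or delta < tol:
            break
    if err > max_residual:
        raise RuntimeError(
            f"Wilson factorization did not converge (residual {err:.3e})"
        )
    A0 = np.real(np.fft.ifft(psi, axis=0)[0])
    sigma = A0 @ A0.T
    H = psi[:n_half] @ np.linalg.inv(A0)
    return H, sigma, psi[:n_half]


def np_gc(S: SpectralMatrix, tol: float = 1e-9, max_iter: int = 100) -> DirectedSpectrum:
    """Non-parametric spectral Granger causality via Wilson factorization."""
    H, sigma, _ = wilson_factorize(S, tol=tol, max_iter=max_iter)
    return _geweke_pairwise(H, sigma, S.values, S.freqs, S.rate_hz)


# --------------------------------------------------------------- PDC/DTF


def pdc(model: VarModel, rate_hz: float = GC_RATE_HZ, n_freqs: int = 256) -> DirectedSpectrum:
    """Partial directed coherence (original column-normalised form).

    ``PDC_{i->j}(f) = |Abar_{ji}(f)| / sqrt(sum_m |Abar_{mi}(f)|^2)``.
    """
    if not model.is_stable:
        raise ValueError("unstable VAR")
    freqs = _freq_grid(rate_hz, n_freqs)
    abar, _ = var_transfer(model, rate_hz, freqs)
    mag2 = np.abs(abar) ** 2
    col_norm = np.sqrt(mag2.sum(axis=1))  # (F, n): sum over rows m, per column i
    n = model.n_channels
    values = {
        (i, j): np.abs(abar[:, j, i]) / col_norm[:, i]
        for i in range(n)
        for j in range(n)
        if i != j
    }
    return DirectedSpectrum(freqs=freqs, values=values, metric="PDC", rate_hz=rate_hz)


def dtf(model: VarModel, rate_hz: float = GC_RATE_HZ, n_freqs: int = 256) -> DirectedSpectrum:
    """Directed transfer function (row-normalised on H = Abar^{-1}).

    ``DTF_{i->j}(f) = |H_{ji}(f)| / sqrt(sum_m |H_{jm}(f)|^2)``.
    """
    if not model.is_stable:
        raise ValueError("unstable VAR")
    freqs = _freq_grid(rate_hz, n_freqs)
    _, H = var_transfer(model, rate_hz, freqs)
    mag2 = np.abs(H) ** 2
    row_norm = np.sqrt(mag2.sum(axis=2))  # (F, n): sum over sources m, per row j
    n = model.n_channels
    values = {
        (i, j): np.abs(H[:, j, i]) / row_norm[:, j]
        for i in range(n)
        for j in range(n)
        if i != j
    }
    return DirectedSpectrum(freqs=freqs, values=values, metric="DTF", rate_hz=rate_hz)


# ----------------------------------------------------------- permutation


def gc_permutation_null(
    x: np.ndarray,
    order: int,
    rate_hz: float,
    band: str | BandSpec = "theta",
    n_perm: int = 99,
    seed: int | None = None,
    section_s: float = 10.0,
    n_freqs: int = 128,
) -> dict:
    """Permutation test of band-integrated GC per direction.

    The source channel's 10-s sections are randomly reassigned across time
    (destroying cross-channel temporal alignment while preserving each
    channel's spectrum) and GC is recomputed; the p-value is
    ``(1 + #{perm >= obs}) / (1 + n_perm)``.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19 to resolve alpha = 0.05")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n_ch, total = x.shape
    section_len = int(round(section_s * rate_hz))
    n_sec = total // section_len
    if n_sec < 6:
        raise ValueError(f"need >= 6 sections to permute, have {n_sec}")
    rng = np.random.default_rng(seed)

    def band_gc(data):
        m = fit_var(data, order, rate_hz=rate_hz, section_s=section_s)
        spec = gc_spectrum(m, rate_hz=rate_hz, n_freqs=n_freqs)
        return {
            k: spec.band_integral(k[0], k[1], band) for k in spec.values
        }

    obs = band_gc(x)
    exceed = {k: 0 for k in obs}
    trimmed = x[:, : n_sec * section_len]
    for _ in range(n_perm):
        perm_vals = {}
        for i in range(n_ch):
            xp = trimmed.copy()
            idx = rng.permutation(n_sec)
            src = trimmed[i].reshape(n_sec, section_len)[idx].ravel()
            xp[i] = src
            g = band_gc(xp)
            for j in range(n_ch):
                if i != j:
                    perm_vals[(i, j)] = g[(i, j)]
        for k in exceed:
            if perm_vals[k] >= obs[k]:
                exceed[k] += 1
    return {
        k: {"gc": obs[k], "p": (1 + exceed[k]) / (1 + n_perm)} for k in obs
    }
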