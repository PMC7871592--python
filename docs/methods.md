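# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `connkit`'s estimators and simulators.

## Signal model and preprocessing

A recording is a channels × samples array of extracellular voltage with one
region label per channel and a declared reference. The LFP path detrends
each trace with a moving-window local linear fit (1 s windows sliding by
0.5 s, overlapping window fits averaged per sample) and downsamples by
polyphase resampling — to 1 kHz for most metrics and to 250 Hz for the
autoregressive (GC/PDC/DTF) branch, which always consumes *unfiltered*
data: band-pass filtering before VAR fitting inflates the required model
order and is deliberately prevented by the pipeline ordering.

Band definitions: delta 1–4, theta 5–12, beta 15–30, low gamma 30–48 Hz.
Band-pass filters are zero-phase two-pass FIR (Hamming-window design); the
length is the larger of 3 cycles of the band's low edge and whatever a
quarter-band transition width requires. The wide transition of a
short filter attenuates sidebands near band edges, which matters for PAC:
an amplitude-modulated carrier at `f_g` carries sidebands at `f_g ± f_θ`,
so the amplitude band must cover them (the validation suite uses 25–55 Hz
around a 40 Hz carrier). Analytic signals come from the Hilbert transform
of the filtered trace; phase 0 sits at the positive peak of a
cosine-aligned oscillation.

## Spectral estimation

Power and coherence use Slepian (dpss) multitapers parameterised by
(half-bandwidth, taper count, window length). Session-long spectra use
(0.2 Hz, 220 tapers) over the full 10-min window — a deliberately
conservative taper count, below the admissible 2TW−1 = 239 — and time courses
use 10-s bins with (1 Hz, 19 tapers). Windows are demeaned before
tapering, which makes coherence invariant to added constants. Power is
reported as 10·log10, with a −300 dB floor (and a warning) for zero
signal; the analysed range is 0.1–48 Hz. Tapers and windows are averaged
in the cross- and auto-spectra *before* normalisation. Coherence phase is
`arg(S_xy)` in degrees and is exactly antisymmetric under argument swap; a
positive phase at frequency f means the second signal lags (y delayed by
Δ gives +360·f·Δ degrees).

## Phase synchronization

wPLI/PLV/PPC all consume per-segment cross-spectra: non-overlapping 1-s
windows, demeaned, single Hann taper, zero-padded to the next power of two
(frequency step 1000/1024 Hz at 1 kHz). A single Hann taper per window is
the default; a dpss multitaper with ±0.5 Hz spectral smoothing is
available behind `taper="dpss"` for users who prefer trading frequency
resolution for variance.

The debiased wPLI-square estimator is computed by the sum trick
`((ΣIm)² − ΣIm²) / ((Σ|Im|)² − ΣIm²)`, algebraically identical to the
pairwise double loop; 0/0 (all imaginary parts zero, e.g. zero-lag
mixing) is defined as 0, and negative values are reported unclipped —
clipping would reintroduce the bias the estimator removes. PPC is computed
through the identity `(n·PLV² − 1)/(n − 1)`, which equals the pairwise
cosine average exactly and has zero mean under the uniform null for any n,
whereas PLV's null mean shrinks only as 1/√n — the bias contrast between
the two estimators. Per-minute wPLI time courses recompute the estimator
per minute rather than averaging spectra.

## Directed spectral metrics

The VAR is fit by pooled least squares over non-overlapping 10-s sections
(each demeaned; lag windows never straddle a section boundary), mirroring
trial-averaged fitting for approximate stationarity. Stability is checked
via the companion-matrix spectral radius; singular lag regressions
(duplicated channels) are rejected. Order selection minimises
`log det Σ̂ + p n² log T / T`; the pipeline default order for real 250 Hz
recordings is 27, kept configurable. Geweke's spectral decomposition gives
per-frequency directed influence from the transfer function and residual
covariance; band values are arithmetic means over in-band frequency bins
(trapezoidal integration available), computed in natural units with log10
applied only for display. Session values average 1-min-bin values, which
also feed the slope metric.

The non-parametric route estimates the cross-spectral density matrix from
Hann-windowed, 50%-overlapping periodograms normalised so the mean of S
over the two-sided circle equals the process covariance, then factorises
`S = H Σ H^H` by Wilson's iterative algorithm (causal-part projection via
FFT to the lag domain, upper-triangular zero-lag). Convergence: the
iteration stops when the factor stagnates or the relative factorization
residual falls below 1e-9. On an analytically generated VAR spectrum the
residual reaches ~1e-12; an empirical CSD retains a small truncation floor
(~1e-3) because the exact causal factor has an infinite-order expansion
while ψ is a finite polynomial on the grid — a final residual above 1e-2
raises an error with the residual reported. Band-integrated npGC agrees
with parametric GC within a few percent (median) on 60-s simulated
systems.

PDC uses the column-normalised Baccalá form on `Ā(f)`; DTF is
row-normalised on `H = Ā⁻¹`. Permutation significance reassigns the
source channel's 10-s sections across time (preserving each channel's
spectrum, destroying alignment) and uses `p = (1 + #{perm ≥ obs})/(1 +
n_perm)`; at least 6 sections and 19 permutations are required.
Section-shuffling is the implemented scheme; phase- or trial-shuffling
alternatives are not.

## Phase–amplitude coupling

Theta phases are binned into eighteen 20° bins (bin 1 spans [−180°, −160°)
in the wrapped convention); the mean gamma amplitude per bin, normalised
to a distribution P, gives `MI = (log 18 − H(P))/log 18`. Empty bins
contribute 0·log 0 := 0; an all-zero amplitude is an error. MI is computed
per 1-min bin and averaged. MI is invariant to positive amplitude scaling
and (up to <2% discretisation error for smooth profiles) to constant phase
rotations, and is monotone in the generator's modulation depth. No
amplitude normalisation or surrogate correction is applied. Direction is
labelled "theta-region → gamma-region" (first-named region contributes the
phase).

## Amplitude cross-correlation

Band-limited envelopes are cut into 1-s windows with 95% overlap; each
window is demeaned and the Pearson-normalised cross-correlation evaluated
over ±100 ms. The Pearson normalisation makes the peak location
scale-free. Ties break
toward the smallest |lag|; windows whose peak reaches the ±100 ms boundary
are excluded (the true peak may lie outside). Pooled window lags are
tested against zero with Wilcoxon's signed-rank test per recording;
cohort-level aggregation uses per-recording medians. Positive lag means
the first-named signal leads; this convention is stamped on every output.

## Spike–phase coupling

MUA extraction: high-pass above 800 Hz (4th-order Butterworth, two-pass),
threshold at 3.5 SD from the mean of the filtered trace on negative
deflections (extracellular spikes are negative; polarity configurable).
Excursions longer than 2 ms are discarded, as is the second of any spike
pair closer than 1 ms; spike time is the first suprathreshold sample. A
flat trace yields an empty train, not an error.

Theta phase is defined by linear interpolation between troughs of
consecutive 5–12 Hz cycles (trough = 0°/360°, peak ≈ 180°), with trough
positions refined to sub-sample precision by parabolic interpolation;
phases at arbitrary (continuous) times are evaluated from the trough grid.
Only periods with theta envelope above mean + 0.25·SD are used (the
alternative absolute gate, envelope > 0.25·SD, is available via
`gate_rule`).

MRL and preferred angle are computed on a seeded uniform-random subsample
of exactly 1000 in-mask spikes, which keeps MRL magnitudes comparable
across recordings with different firing rates; recordings with fewer
eligible spikes are excluded with an explicit status rather than an error.
The offset profile evaluates the MRL of the *same* fixed subsample shifted
by each of 51 offsets from −100 to +100 ms in 4 ms steps. A peak at a positive
offset means spikes lock to the upcoming cycle (spiking leads theta). Note
a genuine resolution limit: for perfectly periodic theta a uniform time
shift rotates all phases equally and the profile is flat — offset recovery
requires cycle-length variability, and with realistic jitter the best
offset still carries ±1–2 grid steps of finite-sample wiggle. The
Watson–Williams two-sample F test compares circular means between groups,
with the standard 1 + 3/(8κ̂) correction and a low-concentration warning
below the usual R̄ < 0.45 validity bound.

## Time courses and slopes

Each metric is evaluated per bin at its native bin size (10 s for
power/coherence, 1 min for wPLI/PAC/GC) and summarised by the OLS slope
over bin midpoints *in minutes*, so slopes are comparable across metrics
with different bin sizes. SPC slopes are not computed: the fixed-count
subsampling requires more spikes than short bins contain.

## Redundancy and group statistics

Per connection, metric columns are correlated pairwise: Spearman's rho for
linear–linear, Jammalamadaka–SenGupta for circular–circular, Mardia for
circular–linear — the standard estimator forms, labelled per cell in the
output. P-values are
deliberately unadjusted. The consensus table averages each pair's rho over
the three connections and flags significance only when present in *every*
connection, at α ∈ {0.01, 0.001}; the flag is monotone in α. Group
comparisons dispatch Welch's t (linear), Watson–Williams (circular), or a
two-factor mixed ANOVA (between group × within direction/reference, via
pingouin) with Sidak-adjusted Welch contrasts gated on a significant group
or interaction effect.

## Synthetic ground truth

The generators emulate the recording conditions the metrics are designed
for:
3-region-style LFP with band-limited oscillations, directed VAR influence
of known strength, fixed-phase-lag oscillatory pairs, zero-lag
common-source mixing (volume conduction), cross-regional theta→gamma
amplitude modulation of known depth, von-Mises-locked spike trains of
known angle/concentration/delay, and two-group cohorts whose coupling
drifts linearly within the session at group-specific slopes. Noise is
Gaussian; SNR is the signal-to-noise variance ratio. VAR simulations
discard a burn-in of 10× the model order. Spike delays are applied in
continuous time. One top-level seed spawns independent per-block
substreams (`numpy.random.SeedSequence`), so identical scenario specs give
bit-identical output.

Cohort defaults model a typical two-genotype design at this scale: 12 vs
15 subjects and 10-min sessions. Effect sizes for the group contrast are
free parameters; the defaults (baseline SNR 1.0, drift slope 0.3/min in
the drifting group, 10% subject jitter) are package choices producing a
realistic but clearly detectable divergence. The validation suite and
acceptance script run cohorts at 5 min and 200 Hz and single recordings at
30–120 s — problem sizes chosen to exercise every code path at desk scale;
the estimators themselves are size-agnostic.

What the simulations do *not* emulate: 1/f background spectra,
non-stationary behaviour-coupled dynamics, volume conduction with
frequency-dependent phase, spike waveform diversity, artifacts. Passing
recovery tests on these generators therefore demonstrates estimator
correctness (the right formula computed correctly, with calibrated nulls),
not robustness to every property of in-vivo data.

## Known limitations

- Wilson factorization on empirical CSDs has a grid-truncation residual
  floor (see above); pathological spectra (near-singular at some
  frequency) can fail with a residual error.
- The shifted-MRL best offset has ±1–2 grid steps of jitter at n = 1000
  spikes; cohort-level inference should use the Wilcoxon test across
  recordings, not single best offsets.
- The circular–circular correlation is undefined for data with vanishing
  resultant (circular mean unstable); such cells are reported as missing.
- Re-referencing is exact linear algebra, but the digital-reference
  contrast can only be as good as the recorded reference trace.
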