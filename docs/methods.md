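# Methods

`slowflow` analyses slow (< 0.25 Hz) oscillatory activity in small networks
of nodes — the setting of resting-state BOLD fMRI, where each node is a
brain region sampled every TR seconds and each region contributes many
voxel time series — and asks three questions: how node power and directed
network flow are distributed over time and frequency, whether the
higher-band directed flow into a node predicts its lower-band power, and
whether net flow reflects anatomical (fiber-count) connectivity.

## Time-frequency estimation

**Morlet transform.** Each realization of each node is transformed with an
analytic Morlet wavelet (ω₀ = 6, the standard trade-off between time and
frequency resolution). The transform is computed in the Fourier domain with
the kernel 2·exp(−(sω−ω₀)²/2) on ω > 0, scale s(f) = ω₀/(2πf), applied to
the even periodic extension [x, reversed x] so the circular convolution
never sees an artificial edge. With this normalization a unit-amplitude
sinusoid at f₀ gives |W(t, f₀)|² = 1 independent of f₀.

**Frequency grid.** 40 log-spaced voices from 0.005 Hz to Nyquist. The
slow bands analysed are slow-5 [0.01, 0.027), slow-4 [0.027, 0.073),
slow-3 [0.073, 0.198) and slow-2 [0.198, 0.25] Hz — half-open on the right
except the last, so the union partitions [0.01, 0.25] exactly. The voices
below 0.01 Hz exist only so that spectral factorization sees the full
frequency axis; they are excluded from every band statistic and from the
causality validation cells.

**Spectral density.** S_lm(t, f) = c(f)·⟨W_l W_m*⟩ with the realization
average ⟨·⟩ (no additional time smoothing) and c(f) = √π·ω₀/(2πf). This
makes S a one-sided spectral density: for stationary input the trapezoid
integral of the diagonal over the grid approximates the sample variance
(normalization constant 1; the grid covers ≈ 98% of the white-noise band,
so the identity is verified at 10%). Coherence is |S_lm|²/(S_ll·S_mm),
clipped into [0, 1] with clip counts logged; with a single realization S is
rank one and coherence degenerates to 1, so at least two realizations are
required for any cross-spectral use (a warning is logged at one).

**Cone of influence.** Cells closer than √2·s(f) seconds to either record
end are flagged and excluded from band averages, peak detection and
time-averaged spectra. At TR = 2 s and 237 samples the slow-5 band loses
roughly the outer quarter of the record; if a band's COI swallows every
time point the band series is NaN and downstream statistics use
available-case analysis.

## Spectral factorization and causal flow

Each spectral matrix slice is factorized as S(f) = H(f) Σ H(f)* by
Wilson's iterative minimum-phase algorithm: the spectrum is placed on a
uniform grid of `n_fact` points spanning [0, Nyquist] (default 65; the
wavelet grid is linearly interpolated with boundary replication at the
ends), extended to the full frequency circle, and iterated with the causal
projection operator. The iteration is initialized from the Cholesky factor
of the frequency-averaged spectrum, with tolerance 1e−7 on the relative
Frobenius reconstruction error and at most 100 iterations; convergence is
quadratic and typically takes 6–10 iterations. Two numerical safeguards
matter:

- spectra of a real process must be real-valued at the self-conjugate
  points f = 0 and Nyquist; the estimated matrices are projected onto that
  constraint (otherwise systematic spurious reverse causality appears at
  the axis edges);
- eigenvalues are floored at 1e−10 of the slice's largest eigenvalue, with
  floored counts logged, so rank-deficient input (e.g. duplicated
  channels) is repaired rather than crashing.

H is evaluated back on the wavelet frequencies exactly, from the causal
Fourier coefficients of ψ (zero-padded FFT evaluation). Non-converged
slices are flagged missing (NaN), never zero-filled.

**Granger causality.** Causality is computed pairwise — each node pair's
2×2 sub-spectral-matrix is factorized independently — because the
bivariate Geweke formula

I_{l→m}(t, f) = ln [ S_mm / (S_mm − (Σ_ll − Σ_lm²/Σ_mm)·|H_ml|²) ]

and the net-flow sum are pairwise constructs; conditional multivariate
causality is out of scope. Negative values (numerically possible) are
clipped at zero with counts logged. The net causal in-out flow

F_m(t, f) = Σ_l (I_{l→m} − I_{m→l}),  I_{m→m} ≡ 0

is positive where a node is a net sink and negative where it is a net
source; flows sum exactly to zero over nodes at every cell. Each time
slice is factorized independently (no temporal regularization); a
`average_time=True` mode factorizes the COI-respecting time-averaged
spectrum once for stationary analyses.

**Significance.** The permutation null shuffles the pairing of
realizations across the two nodes, destroying cross-dependence while
preserving each node's marginals. Time-averaged surrogate cross-spectra
are assembled from a per-frequency realization Gram matrix, so each
permutation costs one 2×2 factorization. The surrogate statistic for a
frequency cell is the per-permutation maximum over the family actually
tested at that cell — both directions of the pair and the ±1 adjacent
voices (adjacent log-grid voices share most of their passband and are one
effective test) — and the threshold is the empirical 95th percentile of
that statistic. This family-wise construction is what makes "below
threshold almost everywhere" a stable property of null data rather than a
coin flip at exactly the nominal level.

**Estimator limits.** The Morlet estimator has constant relative bandwidth
Δf/f ≈ 1/ω₀; the expected value of the estimate is therefore a smoothed
spectrum, and the exact reverse causality of a smoothed unidirectional
spectrum is no longer zero — it grows roughly with the square of the
coupling. Spectral features narrower than ~f/6 are distorted by more than
the 15% diagonal-recovery tolerance. Band-integrated causality is mildly
underestimated (typically −6% ± 8% over random weakly coupled VARs,
within the documented 25% tolerance at moderate couplings; the *relative*
error of very weak couplings is noise-limited and can exceed it); peak
frequencies are accurate to one grid voice.

## Band statistics

Band series are trapezoid-weighted means of power or net flow over the
non-flagged in-band voices, per node and time point (a band must contain
at least two voices on the grid). On top of these:

- **Windowed power ANOVA** — one-way ANOVA of band power grouped by
  consecutive 19-sample (38 s) windows, per node, trailing partial window
  dropped. With 237 samples this gives 12 complete windows and dfs
  (11, 216), reported as computed. A constant series returns F = 0, p = 1.
- **Windowed correlation / change test** — Pearson correlation between
  realization-averaged node series in equal consecutive windows (237 → 3
  windows of 79), and a paired two-sided t-test across participants on a
  pair's correlation in window i vs j. Correlations are Fisher-z
  transformed before the t-test (variance stabilization); the reported sd
  is of the raw correlation differences. All-zero differences return
  t = 0, p = 1; a constant nonzero difference is an error.
- **Peaks and cross-band relation** — a node's peak is the global maximum
  of the band series over non-flagged times, ties broken by earliest time;
  peak location is invariant to positive affine rescaling. The cross-band
  statistic pairs each unit's (participant × node) peak net-flow value in
  a band with its band-integrated power in the next-lower band at the
  same peak time, pooled into one Pearson correlation (n = 68 at 4 nodes ×
  17 participants). Band-integrated power at the peak time is used (not
  the single time-frequency cell) — the band series is the object the
  peaks are defined on.
- **Structure–function** — a node's fiber degree is the row sum of the
  symmetric tract-count table; degrees are correlated with peak slow-3 net
  in-flow across pooled units.

No multiple-testing correction is applied by default; a
Benjamini–Hochberg helper is provided and off by default.

## Synthetic data

The generator produces stable VAR processes at the emulated recording
scale — 4 nodes, 237 samples, TR = 2 s, 20 realizations per node standing
in for averaged voxel series (the realization count is a free parameter
chosen to stabilize spectra). Stability is checked at construction via the
companion matrix; simulation discards a 100 × max-lag burn-in and uses an
independent random sub-stream per realization. Closed forms used as
oracles: the spectral matrix 2·dt·T(f)ΣT(f)*, Yule–Walker autocovariances
via the companion Lyapunov equation, and bivariate Geweke causality
directly from T and Σ (for a pair embedded in a larger network the exact
2×2 marginal is factorized numerically, since the marginal of a VAR has no
finite-order closed form).

The default 4-node spec couples damped AR(2) oscillators (three resonating
in slow-4, one in slow-3) through a unidirectional lag-1/lag-2 chain, with
fiber counts assigned monotone in |coupling| (counts =
round(5 + 120·|coupling|) plus optional integer Poisson-difference
jitter). The seed jitters frequencies (±10%) and couplings (±20%) to
emulate participant variability.

Validation experiments use purpose-built conditions:

- *Causality oracle*: unidirectional 2-node VARs in which a slow-3
  resonant source drives a smooth AR(1) sink through a band-limited FIR
  coupling kernel z(1−z²)/2 (zeros at DC and Nyquist). Couplings are weak
  — forward causality peaks at ~0.01–0.03, the order observed for slow
  hemodynamic signals — because the smoothing-induced reverse-causality
  floor grows with coupling².
- *Chain*: x→y→z with the same kernel at gain 0.25. Ground-truth flow
  signs are checked for the end nodes only (the middle node's in- and
  out-flow nearly cancel, so its sign is not determined by the topology).
- *Participant sampler (end-to-end recovery)*: 4 nodes with smooth AR(1)
  self-dynamics, all-to-all fan-in coupling whose strength into node m is
  a per-(participant, node) latent u_m ~ U(0.6, 1.4), passed through the
  kernel z(1−z)(1+z)³/5.2 whose passband covers slow-4 and lower slow-3
  and whose slow-2 stopband is below 0.05% power — so no slow-2 relation
  is planted (a shallower stopband measurably leaks a weak positive
  slow-2 association through wavelet smoothing).
  After simulation node m's slow-4 band component is scaled by u_m, so
  the latent drives both the slow-3/slow-4 inflow and the lower-band
  power; synthetic fiber counts are monotone in the couplings. This
  plants exactly the relations the pooled statistics are supposed to
  recover, and nothing in slow-2.

What the generator does not emulate: hemodynamic convolution and its
regional variability, scanner and physiological (cardiac/respiratory)
noise, inter-regional delays beyond integer lags, and head-motion
artefacts. Passing these experiments therefore shows the estimators
recover known spectral structure under the stated noise model, not that
the same effect sizes hold in real recordings. The temporal band-pass
filter that fMRI preprocessing pipelines often apply is not replicated
(corner frequencies vary between pipelines); spectra are analysed as
simulated.

## Validation design scales

Oracle comparisons use 4096-sample, 50-realization recordings where
estimator variance is small; statistical calibrations use 500 null
repetitions; recovery experiments use 100 repetitions at the emulated
recording scale, and the chain sign-recovery runs use 1024-sample
recordings (a methods-validation length, about 34 min of TR = 2 s data).
Factorization of the smooth, weakly damped 4-node participant networks
uses a 33-point uniform grid (causal coefficients decay below 1e−4 by lag
32); oracle factorizations use 129 points.

## Known limitations

- Pairwise (not conditional) causality: indirect influence through a
  third node appears as direct flow.
- The permutation null calibrates the no-cross-dependence hypothesis; it
  does not account for the smoothing-induced reverse-causality floor,
  which becomes visible for strong couplings (forward GC ≳ 0.1).
- Wavelet smoothing biases sharp spectral peaks; quantities are reliable
  at the band-integrated level.
- NIfTI ROI extraction truncates unequal ROI sizes to the smallest voxel
  count so realizations align across nodes (logged).
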