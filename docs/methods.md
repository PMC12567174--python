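# Methods

## Problem and signal model

During water decoction of herbal materials, the transition from subcooled
boiling (wall microbubbles that collapse in the bulk) to discrete saturated
boiling (bubbles detaching, rising, bursting at the surface) produces a rapid
rise of acoustic-emission power concentrated in the 75–100 kHz band. The
package detects that transition online from a stream of fixed-length AE
acquisitions — one 10 s waveform at 1 MHz every 30 s in the laboratory
configuration — and compares it with the industrial criterion (tank
temperature reaching 100 °C), which lags the physical onset by several
minutes.

Time base: acquisition index n ≥ 1 occurs at `n × period/60` minutes, i.e.
the first acquisition one full period after heating starts. With the 30 s
period every reported time is a multiple of 0.5 min, which is also the
resolution limit of any trigger time. The temperature crossing of the
100 °C criterion is located by linear interpolation between log samples;
with a plateau-capped trace the crossing is at worst half a period late.

## Spectral preprocessing

Each acquisition is split into `n_segments` (default 80) contiguous blocks of
N = 125 000 samples; each block is mean-centered (DC removal) and transformed
with a Hann-windowed periodogram

    P(f) = (1 / (fs N)) | Σ_n h(n) x(n) e^(−j2πfn/fs) |²,

folded one-sided (interior bins doubled; DC and Nyquist not). The window is
the symmetric Hann `h(n) = 0.5(1 − cos(2πn/(N−1)))`. No window-power
renormalization (1/Σh²) is applied beyond the 1/(fs N) of the formula above:
the constant scale factor this leaves on absolute PSD values cancels in every
monitoring statistic, because columns are autoscaled before PCA. The 80
per-block PSDs are averaged (variance reduction ≈ 1/80 per bin) and
compressed into 1 kHz sub-bands covering [0, Nyquist], each sub-band the
*arithmetic mean* of its fine bins — a mean rather than a sum keeps sub-band
values on the PSD scale (V²/Hz) and independent of segment length. Bands are
half-open `[k, k+1)` kHz with the Nyquist bin assigned to the last band, so
the bands partition the grid with no double counting. The monitored feature
vector is the contiguous slice covering the signature band (75–100 kHz at
full rate; K = 25).

Numerical notes: a tone on a sub-band *edge* splits its (symmetric-Hann)
3-bin leakage across the two adjacent bands — roughly 83 % / 17 % — while a
band-centered tone keeps > 99.99 % of its binned power in one band; off-bin
leakage beyond ±2 bins is below 1e−7 of the peak. The whole pipeline is
verified against a brute-force O(N²) DFT evaluation of the same formula to
1e−6 relative error, and per-block Parseval
(`Σ P(f_k)Δf = (1/N) Σ h²x²`) to 1e−6.

## PCA monitoring model

On a training window X (N × K, N ≥ 4) columns are autoscaled — training mean
0, SD 1 (divisor N−1) — and the sample correlation matrix eigendecomposed.
Autoscaling is a deliberate choice: sub-band magnitudes differ by orders
across bands, and it makes the eigenvalue spectrum that of a correlation
matrix (Σλ = K exactly). Components with explained-variance ratio
λ_a/Σλ > 0.05 are retained, clamped to `1 ≤ A ≤ min(N−2, K)` so the
F-limit's degrees of freedom stay positive (if no eigenvalue passes, A = 1;
if all pass, A = N−2). An explicit `n_components` override is available for
studies that fix A.

For a point x with scores `t = x_std · P`:

    T²  = (t − t̄) diag(λ₁…λ_A)⁻¹ (t − t̄)ᵀ
    SPE = ‖ x_std − t Pᵀ ‖²

with limits at significance α (default 0.01)

    T²_lim  = A(N−1)/(N−A) · F₁₋α(A, N−A)
    SPE_lim = θ₁ [ z_α h₀ √(2θ₂)/θ₁ + 1 + θ₂h₀(h₀−1)/θ₁² ]^{1/h₀},
    θ_i = Σ_{k>A} λ_k^i,  h₀ = 1 − 2θ₁θ₃/(3θ₂²),

`z_α` the upper-α standard-normal quantile (≈ 2.326 at α = 0.01). The SPE
limit is the weighted-chi-square (Jackson–Mudholkar) approximation; when the
residual spectrum is empty (A = K) the limit is 0, and a residual spectrum
with θ₁ > 0 but θ₂ ≈ 0 raises a degenerate-model error.

The N−1 covariance divisor makes two identities exact, both asserted in
tests: mean training T² = A(N−1)/N, and per-row Pythagoras
`‖x_std‖² = ‖t‖² + SPE`.

Degenerate inputs: a training column whose SD is at the rounding level of its
mean (relative tolerance 1e−12) is treated as zero-variance — its scale is
set to 1 with a warning rather than raising, so early all-quiet acquisitions
cannot crash a live stream. A retained eigenvalue ≤ 1e−12 raises on scoring.

### Calibration at finite N

With strongly expressed, well-separated principal components both limits are
accurately calibrated: on multivariate-normal null data with leading
correlation eigenvalues {10, 7, 5} (K = 25, A = 3, N = 200), the marginal
false-exceedance rates over independent training fits match α = 0.01 within
Monte-Carlo error (≈ 0.0103–0.0107 for T², ≈ 0.0102–0.0105 for SPE). Two
finite-sample caveats, both verified by simulation during development:
the exceedance rate *conditional on one* 200-row training fit varies between
fits with SD ≈ 0.003 — calibration statements need averaging over training
replicates — and when the retained components are weak (eigenvalues within a
few times the residual bulk), PCA direction overfitting deflates new-point
scores and the T² limit under-alarms by ~15 % relative at this N/K. Neither
caveat affects the detector's intended use, where the boiling signature
shift is orders of magnitude above the in-control variation.

## Adaptive detector

The growing-window scheme starts once `n_start = 10` acquisitions exist. At
each step M ≥ n_start the model is re-fitted (autoscaling recomputed) on
acquisitions 1…M and the M-th acquisition's T² is compared with that model's
own limit. The evaluated point is deliberately *inside* its training window —
that is what makes the scheme self-starting with no reference batch; the
out-of-window variant is available via `exclude_test_point=True`. Two
consecutive exceedances (`consecutive_required = 2`; each against its own
successive model) trigger the detection; a non-exceeding point resets the
counter. The trigger time t_AE is the time of the second exceeding
acquisition — the moment the decision becomes available online. After the
trigger the detector stops accepting updates. SPE is exposed in the trail at
every step but never drives the decision: T² separates the subcooled and
saturated stages more reliably.

Known limitation (observed in testing): when the onset arrives while the
window is still small (≈ 20 points or fewer), the second elevated point can
be masked, because two large outliers inside a short training window inflate
the leading eigenvalue enough to pull the second point back under its limit.
Under the laboratory schedule onsets occur near index 40, where this does
not arise.

## Synthetic runs

The generator is a stand-in for laboratory streams, emulating only the
three-stage band-power phenomenology: each acquisition is Gaussian broadband
noise (SD 0.003 V) plus band-limited random-phase noise confined to the
signature band, with expected power stepping from `baseline_band_power`
(1e−4 V²) to 10× at the true onset (ramp width 1 acquisition), then to 0.5×
the discrete level with log-normal multiplicative fluctuation (CV 0.3) in
the polymerized stage — reproducing the rise-then-fall statistic trail. The
stage contrast (discrete > polymerized > subcooled band power) holds on
every standard-suite run.

The default profile is rate-scaled so a full run takes seconds: 100 kHz
sampling, 1 s acquisitions, 8 segments, signature band relocated to
15–40 kHz (inside the scaled 50 kHz Nyquist, preserving K = 25); the full
1 MHz laboratory profile is `full_rate_profile()`. The detector is fully
band-parametric, so the relocation exercises the same code paths.

Temperature is Newtonian heating `T(t) = T_med − (T_med − T0)e^{−t/τ}`
capped at the 100 °C plateau, with T0 = 25 °C and T_med = 108 °C; τ is
calibrated so the liquid is at 91 °C at the true onset, which places the
100 °C crossing ≈ 9.5 min after the acoustic onset — matching the observed
gap between saturated-boiling onset (≈ 19–20 min, ≈ 91 °C) and the 100 °C
criterion (≈ 29 min) on practical formulation extractions, and yielding
δtime ≈ 30 %.

What passing synthetic tests do **not** show: performance on herb-specific
spectra (signature frequencies and magnitudes vary with material), robustness
to factory background noise, or any bubble-physics fidelity.

## Problem sizes used in the shipped checks

The standard suite is 9 runs (3 seeds × onsets {30, 40, 50}) of 60 scaled
acquisitions; limit calibration uses 50 training fits × 2000 draws (1e5
total); spectral-oracle comparisons use blocks up to N = 2048 (the O(N²)
oracle bounds this); false-alarm behavior uses 20 null streams of 50
acquisitions. These sizes were chosen so the entire battery completes in
well under a minute while keeping every Monte-Carlo assertion inside its
stated error bars.
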