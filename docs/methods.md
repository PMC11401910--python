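# Methods

## Photon-stream model

The simulator emulates confocal smFRET of a dilute (~pM) solution of doubly
labelled molecules under pulsed interleaved excitation.  Molecular transits
are modelled as rectangular-rate emission windows with exponentially
distributed duration (mean `transit_mean`, default 1 ms) arriving
sequentially at `burst_rate` (default 20 s⁻¹, never overlapping — the pM
regime guarantees one molecule at a time).  A full 3-D diffusion path
through a Gaussian detection volume is deliberately not simulated: the
downstream stages consume only count statistics and timing, which the
rectangular transit preserves at a fraction of the cost.  Consequences:
simulated bursts lack the intensity rise-and-fall and the burst-size/
duration correlation shape of real diffusion data, so tests passing here
validate the estimators' statistics, not robustness to diffusion-profile
effects.

Within a transit the molecule exchanges between two FRET states
(efficiencies `E1`, `E2`) as a continuous-time Markov chain with rates
`k12`, `k21` (Gillespie sampling; `k12 = k21 = 0` gives a static molecule;
initial state drawn from the stationary distribution `k21/(k12+k21)`).

Detected rates are constructed so that the consensus correction chain is
exactly invertible in expectation.  With donor-excitation photon budget
`R = peak_rate` (default 150 kcps) and corrections `(lk, dir, γ, β)`:

| stream  | rate |
|---------|------|
| Dex/D   | `R(1−E)` |
| Dex/A   | `γRE + lk·R(1−E) + dir·rate_AA` |
| Aex/A   | `rate_AA = βγR(1−S_true)/S_true` |

so `F_DA − lk·F_DD − dir·F_AA → γRE`, the corrected `E → E_state` and
`S → S_true`.  Crosstalk composition order: FRET first, leakage added on
donor-emitted photons, direct-excitation photons as an independent Poisson
stream in the A channel during donor excitation, γ as a detection
asymmetry and β as the excitation-rate ratio.

Microtimes: Dex/D photons decay exponentially with `τ_D0(1−E_state)`
(default `τ_D0` 4 ns) plus the IRF mean delay (default 2 ns); acceptor
emission decays with `τ_A` (1.5 ns).  The IRF is a pure delay by default
(the lifetime estimator uses only its mean); a Gaussian width is available.
Background is homogeneous Poisson per channel/excitation slot (defaults
1500/800/1200 cps for Dex/D, Dex/A, Aex/A) with microtimes uniform over the
slot window.  TCSPC bins are converted to times at bin centres.

PIE layout (the instrument's repetition rate and duty cycle are free
choices): 100 ns alternation period — two interleaved 10 MHz pulse
trains — split 50:50 into donor-excitation bins [0, 1000) and
acceptor-excitation bins [1000, 2000) of 50 ps, so a 4 ns donor decay
truncates at the window edge with probability e⁻¹² (negligible bias).
Macrotimes are clock ticks of the 100 ns period.  All randomness flows
from a single `numpy` Generator keyed by the model seed; identical seeds
give bit-identical streams.

## Background estimation and burst search

Background is re-estimated for every 60 s segment (last segment may be
shorter), separately for the Dex/D, Dex/A and Aex/A streams.  The rate is
a maximum-likelihood exponential fit to the inter-photon delays above an
automatic threshold: starting at twice the mean delay, the tail rate
`1/mean(delay − thr | delay > thr)` and the threshold `2/rate` are
iterated until the threshold is stable to 1%, which excludes burst photons
from the fit.  Segments with fewer than 50 photons fall back to the plain
mean rate.

The burst search slides a window of `window_m = 10` consecutive Dex-slot
photons.  The window *starting* at photon *i* is hot when the local donor
rate exceeds `threshold_factor = 3` times the segment's Dex/D background
**and** the local acceptor rate exceeds 3× the Dex/A background (the
dual-channel construction that selects doubly labelled molecules; an
intensity-only single-stream variant, `mode="any"`, thresholds the total
Dex rate against the summed background).  A maximal run of hot start
photons `[a, b]` yields the candidate `[a, b + m − 1]`; overlapping
candidates merge; candidates with fewer than `min_size = 50` Dex photons
are discarded.  Anchoring hotness at window starts makes bursts end at
photon-free gaps (the trailing windows span the gap and are cold).
Near-adjacent but non-overlapping candidates are never merged.  Burst
records carry Dex-slot channel counts, the Aex/A count over the burst's
time span, duration and the background segment for later subtraction.

Degenerate regime worth knowing: with (near-)zero background the
3×-background threshold loses its noise floor — use an explicit nominal
`BackgroundEstimate` (an absolute rate threshold) for background-free
streams, as the validation studies do.

## E, S, ALEX-2CDE and filters

Background-subtracted counts are floored at zero (keeps `E_raw` in [0, 1]);
corrected `E`/`S` are *not* clipped — shot noise legitimately carries them
slightly outside the unit interval.  The ALEX-2CDE score uses the
exponential kernel density `KDE_X(t) = Σ_{j∈X} exp(−|t−t_j|/τ)` with
`τ = 100 µs` (a free choice, recorded in output headers):

```
ALEX-2CDE = 100 − 50·(BR_DA + BR_AD)
BR_DA = (1/N_Dex) Σ_{j∈Aex} KDE_Dex(t_j)/KDE_Aex(t_j)
BR_AD = (1/N_Aex) Σ_{i∈Dex} KDE_Aex(t_i)/KDE_Dex(t_i)
```

Well-mixed bursts score near 0; segregated ones (acceptor bleaching,
blinking, coincident molecules) approach 100; a burst with an empty
excitation slot scores 100 and is flagged.  Filters keep
`0.3 ≤ S ≤ 0.7` and ALEX-2CDE ≤ 95 (inclusive); the S filter acts on
corrected S; every rejection carries a reason code; filters commute.

## BVA

Each burst's Dex photons are cut into consecutive non-overlapping windows
of `window_n = 5`; the remainder is discarded; the per-burst statistic
`s_i` is the *population* standard deviation of the window acceptor
fractions (raw, non-background-subtracted, uncorrected — the shot-noise
null is binomial in raw counts).  The static line is
`σ(E) = √(E(1−E)/window_n)`; binning uses half-open `E_raw` bins of width
0.05 with empty bins emitted.

Finite-sample caveat: over `k = ⌊N/5⌋` windows the population SD has mean
`≈ σ√((k−1)/k)` — about 2.5 % below the line at `k = 20` — so binned means
must be compared against a matched null, not the bare curve.
`bva_null_band` provides it: binomial Monte-Carlo replicates matched per
burst in window count and acceptor fraction give the null mean and SD of
each binned mean.  The validation studies additionally (i) aggregate the
two bins straddling the population's true E (a population centred on a
bin edge is otherwise asymmetrically split) and (ii) draw the null at the
pooled acceptor fraction of the selected bursts (per-burst noisy `E_raw`
plus the concavity of `σ(E)` would bias the null low by ~0.3 SD).

## Burst lifetimes and FRET lines

`τ_D(A)` per burst is the mean Dex/D microtime minus the IRF mean
(≥ 10 donor photons required; negative estimates flagged, never clipped).
`τ_D0` pools the same estimator over bursts with `S > 0.9` (donor-only
molecules).  Static line `E = 1 − τ/τ_D0`; two-state dynamic line
`E(τ̄) = 1 − τ₁τ₂/(τ_D0(τ₁+τ₂−τ̄))`, which passes exactly through both
state points and lies above the static line between them.

This estimator is *not* background-corrected (by design — it mirrors
common practice): uniform background microtimes bias τ upward by roughly
`f_bg·(T_window/2 − τ)`, where `f_bg` is the background fraction among the
burst's donor photons.  Note the floor on `f_bg` is scale-free: a
threshold search always extends burst boundaries by a couple of background
photons per edge (edge windows mix transit photons with background spans,
and the threshold scales with the background rate), so lowering the
background rate does not remove the bias — only background-free streams
do.

## Validation study conditions

Three background/search couplings, all verified analytically and by
simulation, dictate the study designs:

1. **Edge photons.**  ~2–3 background photons attach to each burst
   boundary at *any* background rate (see above), biasing mean-microtime
   lifetimes and inflating BVA variance at extreme E (windows mixing
   E-specific burst photons with uniform-E background photons).
2. **Dual-channel chopping.**  The AND search breaks bursts at stretches
   where the sparse channel has a locally empty window (probability
   `0.9¹⁰ ≈ 0.35` per window at E = 0.1/0.9), selecting against
   high-variance windows and suppressing `s_i`.
3. **Photon-gap leakage of fast dynamics.**  With exponential photon gaps
   the adjacent-photon state correlation is `τ_R/(τ_R + 1/rate)`, not
   `exp(−1/(rate·τ_R))`; microsecond exchange therefore leaves a small but
   real variance excess unless the sampling interval is ≫ the exchange
   correlation time.

Accordingly: the corrected-E recovery study runs under realistic
conditions (full background and corrections, ~5400 accepted bursts from a
360 s stream); the BVA static-line study (nine E values, ~550 bursts each,
60 s streams) and the lifetime-line study (~1400 static bursts, ~700
two-state bursts) run on background-free streams searched with a fixed
nominal threshold and the intensity-only search; the dynamics-contrast
study uses 12.5 kcps detection with 6 ms transits so the 80 µs sampling
interval sits two orders of magnitude above the 0.5 µs fast-exchange
correlation time while 5-photon windows (~400 µs) still resolve 1 ms
dwells.  The static-line assertion uses simultaneous 95 % coverage (every
bin |z| ≤ 3 and Σz² within the χ²₉ bound): nine independent per-bin 2 SD
checks would reject a perfect implementation about a third of the time.
What passing shows: the estimators are unbiased and correctly calibrated
at shot-noise level under their intended conditions.  What it does not
show: robustness to diffusion profiles, photophysics (triplet/blinking),
or background regimes outside those studied.

## NMR perturbation mapping

Intensity ratios `R = Y/X` (apo X, bound Y) carry the
signal-to-noise-derived error `δR = |R|·√(δX/X) + √(δY/Y)` by default;
standard quadrature propagation `δR = |R|·√((δX/X)² + (δY/Y)²)` is a
documented alternative and both are always emitted side by side.  The
default form is dimensionally anomalous (the ratios under the roots are
not squared) but is retained for fidelity to common practice with
SNR-based errors; neither mode is silently preferred.
`CSP = √(ΔH² + (0.251·ΔC)²)` scales ¹³C shifts by the gyromagnetic ratio
factor 0.251.  Z-scores use the population standard deviation over all
included peaks; intensity Z-scores are computed on the loss `1 − R` so
that Z > 0 means stronger perturbation (matching the convention of
colouring perturbed residues by positive Z); `significant` defaults to
`Z > 0` with a configurable threshold and no multiple-testing correction
(deliberately — the mapping is descriptive, not inferential).
Bound-state peaks below the spectrum noise floor (or flagged
`broadened_below_noise` upstream) enter with the floor as effective
intensity and an asterisk mark; the floor is an upper bound on the true
intensity, so the reported loss is a conservative lower bound.
Overlapped/excluded peaks are dropped only on explicit input flags, never
inferred.  Degenerate tables (all values identical) yield Z = 0 rather
than an error at the mapping level.

The synthetic generator plants: lognormal apo intensities (CV ≈ 25 %)
around a unit scale, hotspot attenuation (default 0.4), conformational
shift changes (ΔH, ΔC), and additive Gaussian noise at the noise floor
(default 0.05 = 5 % of scale).  It emulates perturbation *patterns*, not
spectra: no peak overlap, lineshapes or picking errors, so recovery rates
here are upper bounds on real-data performance.

## Hill fits

`S_obs = S_U + (S_B − S_U)/(1 + (K_d,app/[L])^n)`, unweighted least
squares in linear signal space (a weighted option exists).  `K_d,app` and
`n` are fitted as logarithms (positivity by construction) and reported on
the natural scale with delta-method standard errors from the local
curvature — a linearised approximation, labelled as such.  Auto
initialisation: plateaus from the extreme-concentration eighths, `K_d`
from the half-signal crossing (geometric midpoint of the bracketing
concentrations), `n = 1`.  Designs with < 5 points or no data beyond
`K_d` are flagged, never silently accepted.

## File formats

Photon streams use a documented Photon-HDF5-style subset
(`photon_data/{timestamps, nanotimes, detectors}` with unit specs and
alternation windows); unknown groups are ignored with a logged warning,
missing mandatory fields and non-monotone timestamps are hard errors
(first offending index reported).  All tables are TSV with `.` decimals
and a single header row; every writer embeds the active `RunConfig` as
`# key: json` comment lines so results are reproducible from the file
alone.  Ground truth travels as a JSON sidecar next to simulated streams.
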