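# fretkit

Quantitative analysis of chaperone–client binding experiments that combine
three measurement modalities:

* **single-molecule FRET burst analysis** of freely diffusing, doubly
  labelled client chains under pulsed interleaved excitation (PIE/ALEX),
  including burst variance analysis (BVA) and fluorescence-lifetime
  FRET-lines for detecting millisecond and sub-millisecond chain dynamics;
* **methyl-TROSY NMR perturbation mapping** of the chaperone upon client
  binding (intensity ratios, chemical-shift perturbations, Z-scores,
  per-domain hotspot summaries);
* **Hill-equation fits** to binding titrations (e.g. microscale
  thermophoresis), reporting apparent affinity and cooperativity.

Every stage is exercised end to end against a synthetic-data generator with
known ground truth (a two-state photon-stream Monte Carlo, planted NMR
perturbation patterns, noisy Hill curves), so the whole pipeline is testable
without any instrument data.  It is aimed at structural biologists and
single-molecule spectroscopists who want a scriptable, reproducible version
of this analysis chain.

## The quantities computed

For each burst with background-subtracted counts `F_DD`, `F_DA` (donor
excitation, donor/acceptor channel) and `F_AA` (acceptor excitation):

```
E_raw = F_DA / (F_DD + F_DA)                     # proximity ratio
F_DA' = F_DA − lk·F_DD − dir·F_AA                # leakage, direct excitation
E     = F_DA' / (F_DA' + γ·F_DD)                 # corrected FRET efficiency
S     = (F_DA' + γ·F_DD) / (F_DA' + γ·F_DD + F_AA/β)   # stoichiometry
```

with defaults `lk = 0.14`, `dir = 0.14`, `γ = 1.0`, `β = 1.4`.  Bursts are
found by a dual-channel sliding-window search at 3× the per-60-s background
rate with a 50-photon minimum, then filtered to `S ∈ [0.3, 0.7]` and
ALEX-2CDE ≤ 95.

BVA splits each burst's donor-excitation photons into consecutive 5-photon
windows and compares the standard deviation `s_i` of the window acceptor
fractions with the shot-noise expectation `σ = √(E(1−E)/5)`; excess `s_i`
indicates conformational exchange during the burst.  Burst lifetimes
`τ_D(A)` (mean donor microtime − IRF mean) are compared with the static line
`E = 1 − τ/τ_D0` and the two-state dynamic line
`E(τ̄) = 1 − τ₁τ₂ / (τ_D0(τ₁+τ₂−τ̄))`.

For NMR peak pairs: `R = I_bound/I_apo` with signal-to-noise-propagated
error, `CSP = √(ΔH² + (0.251·ΔC)²)`, and Z-scores
`Z_i = (x_i − µ)/σ` over all peaks (intensity Z-scores on the loss `1 − R`,
so Z > 0 means perturbed).  Peaks broadened below the spectrum noise enter
with the noise floor and are marked with an asterisk.  Titrations follow
`S_obs = S_U + (S_B − S_U)/(1 + (K_d,app/[L])^n)`.

## Worked example

```python
import fretkit

model = fretkit.TwoStateModel(E1=0.45, E2=0.45, seed=1)     # static chain, true E = 0.45
stream = fretkit.simulate_photon_stream(model, duration=60.0)
bg = fretkit.estimate_background(stream)                     # per-60-s segments
bursts = fretkit.search_bursts(stream, bg)                   # 3x background, >= 50 photons
metrics = fretkit.filter_bursts(
    fretkit.compute_metrics(stream, bursts, bg, model.corrections))
accepted = metrics[metrics["passed"]]

print(f"photons: {len(stream):,}, bursts: {len(bursts)}, accepted: {len(accepted)}")
print(f"E_raw mean: {accepted['e_raw'].mean():.3f}  "
      f"corrected E mode: {fretkit.histogram_mode(accepted['e_corr'], 0.02):.2f}  "
      f"mean S: {accepted['s_corr'].mean():.3f}")
```

prints

```
photons: 657,850, bursts: 889, accepted: 889
E_raw mean: 0.564  corrected E mode: 0.45  mean S: 0.506
```

The raw proximity ratio (0.564) is inflated by leakage, direct excitation
and the β asymmetry; the correction chain recovers the true efficiency
(mode 0.45) and the doubly-labelled stoichiometry (≈0.5).  The same
stages are available from the shell:

```sh
fretkit simulate --duration 60 --seed 1 --out run.h5
fretkit bursts run.h5 --out bursts.tsv
fretkit bva run.h5 --out bva.tsv
fretkit lifetime run.h5 --out lifetime.tsv
fretkit nmr-map apo.tsv bound.tsv --out perturbations.tsv
fretkit hillfit titration.tsv --out fit.json
```

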