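# neurocov

Circuit-model interpretation of correlated trial-to-trial variability in
neural populations.

Repeated presentations of a stimulus evoke variable population responses, and
that variability is correlated across neurons. The correlations could come
from recurrent connections, from inputs shared by the population, or from a
common multiplicative gain signal — three mechanisms that are hard to tell
apart from a single stimulus condition, but that leave distinct fingerprints
in how the population-averaged covariances depend on the population-averaged
response across a *battery* of stimuli. `neurocov` implements the
linearly-interacting-Poisson (Hawkes) modelling chain that turns those
fingerprints into an analysis: closed-form spike-count statistics for the
three architectures, a point-process simulator that validates them,
population statistics, Fisher-discriminant stimulus decoding, and a
fitting/model-comparison workflow — together with a synthetic-data generator
that emulates trial-resolved population recordings (defaults: 60 neurons,
65 stimuli, 15 trials, 250 ms count windows, baseline-relative responses).

It is aimed at systems neuroscientists who have trial-resolved population
responses to many stimuli and want to ask which circuit architecture is
consistent with the joint response statistics, and at modellers who need a
tested reference implementation of the underlying formulas.

## The model

Spike trains are inhomogeneous Poisson processes whose rates interact
linearly through causal kernels with integrated coupling matrix `G`
(spectral radius < 1). With transfer matrix `B = (I − G)⁻¹`, external drive
`r_ext` and windowed-input variance `V_ext`, the steady-state rates and the
large-window spike-count covariance (normalised by the window length) are

    r = B r_ext
    C = B (D[r + a] + D[V_ext]) Bᵀ            (recurrent)
    C = F D[V_ext] Fᵀ + D[r + a]              (shared feed-forward input)
    C = D[r + a] + (r + a)(r + a)ᵀ V_ext      (shared gain fluctuations)

where `a` is the (unobserved) baseline offset of baseline-relative
recordings and `D[x]` is the diagonal matrix of `x`. Treating the couplings
as a random matrix with mean `⟨B⟩` and relative variability
`ρ = var(B)/⟨B⟩²` yields population-level predictions, e.g. for the
recurrent network

    ⟨C_ii⟩ = N ⟨B²⟩ (⟨r⟩ + a + ⟨V_ext⟩),   ⟨C_ij⟩ = N ⟨B⟩² (⟨r⟩ + a + ⟨V_ext⟩)
    c_N = 1 / (1 + ρ),                     c_S = (1 + (N−1)c_in) / (1 + ρ + (N−1)c_in)

so both moment lines share the intercept/slope ratio `a + ⟨V_ext⟩`, while
the feed-forward covariance line is flat in `⟨r⟩` and the gain covariance
grows quadratically. Stimulus discriminability is measured by the Fisher
signal-to-noise ratio `S = |w̄·(r₁−r₂)| / (σ₁+σ₂)` along the optimal linear
readout `w = (C₁+C₂)⁻¹(r₁−r₂)`, compared before and after removing noise
correlations by trial shuffling (data) or covariance diagonalisation
(models).

## Worked example

```bash
neurocov generate --arch recurrent --seed 7 --out demo
neurocov stats --data demo --out demo/summary.csv
neurocov fit   --data demo --out demo/fit.json
neurocov compare --data demo --out demo/verdict.json
```

The `generate` step samples a random effective network (`⟨B⟩ = 0.15`,
`ρ = 1`), a random stimulus ensemble, and 65 × 15 Gaussian trials matched to
the analytic per-stimulus moments, with a 5 spikes/s baseline subtracted.
The session above prints

```
wrote demo/summary.csv (65 stimuli) and demo/summary_pairs.csv; c_N=0.4935 c_S=0.7137
wrote demo/verdict.json; verdict: recurrent (scores: recurrent=0.367, feedforward=0.4235, gain=3.275)
```

and `demo/fit.json` contains, among others,

```
variance line:  slope 2.105, intercept 21.201, intercept/slope 10.073
covariance line: slope 1.078, intercept 10.707, intercept/slope  9.931
recurrent fit:  rho 1.026, <B> 0.132
```

Read: the average noise correlation `c_N = 0.494` inverts to
`ρ = 1/c_N − 1 = 1.03`, recovering the generating value `ρ = 1`; the
variance- and covariance-line intercept/slope ratios agree (10.07 vs 9.93),
the recurrent signature — both estimate the external-noise strength
`a + ⟨V_ext⟩`, though at 15 trials the ratio is inflated by
errors-in-variables attenuation of the slope (see `docs/methods.md`); and
the ranked comparison puts the true generator first, with the gain model a
distant third because it cannot reproduce the pair-level covariance
structure. In the library, the same analysis is
`fit_population(read_dataset("demo"))` and
`compare_architectures(read_dataset("demo"))`.

The Hawkes simulator is exposed both in the library
(`simulate_population`) and as `neurocov simulate --network G.csv --drive
drive.csv --seed 3 --out sim/`, writing spike times, window counts and the
empirical normalised count covariance.

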