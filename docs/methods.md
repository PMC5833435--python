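# Methods

## Model

Neurons are inhomogeneous Poisson processes whose rates interact linearly:
the rate of neuron *i* is its external drive plus the spike trains of its
presynaptic partners filtered through causal kernels (a multivariate Hawkes
process). Only time-averaged quantities enter the analysis: with integrated
coupling matrix `G` (spectral radius < 1) and transfer matrix
`B = (I − G)⁻¹`, the steady-state rates are `r = B r_ext` and the
spike-count covariance in large windows, normalised by the window length
`Δ`, is `C = B (D[r + a] + D[V_ext]) Bᵀ`. The two noise sources — intrinsic
Poisson spiking (variance = rate) and fluctuating external input (windowed
variance `V_ext`) — are both filtered by the network, which is what makes
recurrent covariances grow with the population rate. The shared-input
feed-forward model (`C = F D[V_ext] Fᵀ + D[r + a]`) correlates only the
input noise, and the shared-gain model
(`C = D[r + a] + (r + a)(r + a)ᵀ V_ext`) makes pairwise covariances
proportional to rate products. The scalar `a` is the baseline offset of
baseline-relative recordings: stored responses may be negative, but the
rates inside the covariance formulas are `r + a`.

Assumptions worth keeping in mind: linear interactions (no transfer
nonlinearity), stationarity within a trial, spike-count coding (temporal
structure inside the window is discarded), and large windows relative to
the kernel timescale. Negative linear rates are tolerated as in the
baseline-relative data; covariances are then not guaranteed positive
semidefinite (see *Degenerate inputs*).

## Ensembles rather than connectomes

No individual connection is fitted. Coupling matrices are drawn i.i.d.
normal with mean `mean_w` and SD `sd_w`; the effective parameter is the
relative variability `ρ = var/mean²` (population variance over all `N²`
entries, diagonal included — excluding autapses changes nothing appreciable
at these sizes). Stimulus drives are normal across neurons and stimuli with
an optional shared component per stimulus producing input signal
correlation `c_in`; input variances follow Poisson statistics,
`V_ext = |r_ext|`. Population-averaged predictions under these ensembles:
`⟨C_ii⟩ = N⟨B²⟩(⟨r⟩ + a + ⟨V_ext⟩)` and `⟨C_ij⟩ = N⟨B⟩²(·)` for the
recurrent network (shared intercept/slope ratio `a + ⟨V_ext⟩`),
`⟨C_ij⟩ = N⟨F⟩²⟨V_ext⟩` (no direct `⟨r⟩` dependence) for shared input,
`⟨C_ij⟩ = V_ext⟨r⟩²` for shared gain, and
`c_N = 1/(1+ρ)`, `c_S = (1+(N−1)c_in)/(1+ρ+(N−1)c_in)`.

## Synthetic-data generator

`GeneratorConfig` defaults emulate the structure of trial-resolved
auditory-cortex population recordings: 60 neurons, 65 stimuli, 15 trials,
250 ms count windows, baseline-relative responses. The ensemble parameters
are pinned to the regime that population-level moment fits to such data
report, rather than chosen freely: population amplification above one
(`⟨B⟩ = 0.15`, so `N⟨B⟩² = 1.35`), coupling variability `ρ = 1` (recurrent)
or `ρ = 2` (feed-forward), input variability well above one
(`ρ_ext = 4`: drive mean 1, variance 4 spikes/s; feed-forward mean 2,
variance 16 — the flat-covariance signature of the shared-input model holds
only at large `ρ_ext`), weak input signal correlation `c_in = 0.05`, a
baseline offset `a = 5` spikes/s putting the external-noise strength
`a + ⟨V_ext⟩ ≈ 6.8` on the same scale as the mean population response
(≈ 9–10 spikes/s), and gain variance `V_ext = 0.53`.

Trials are drawn from a multivariate normal with mean `r` and covariance
`C/Δ` (the moment-matched shortcut; every downstream analysis uses only
first and second moments). The Hawkes sampler is retained as a validation
path for small recurrent networks with a direct coupling matrix,
nonnegative drives and zero offset; there, each count window is one trial.

What the generator does **not** emulate: calcium-indicator dynamics and
deconvolution (including the unknown multiplicative scale of inferred
rates), non-Gaussian trial distributions, temporal correlations between
trials, structured (distance- or type-dependent) connectivity, and mixed
architectures. Passing tests therefore show that the analysis chain is
correct under its own generative assumptions, not that real recordings obey
them.

## Simulator

Discrete-time thinning: per step of `dt = 1 ms`, each neuron fires with
probability `max(0, λ) dt`, where `λ` sums a filtered external input and
kernel-filtered recurrent spikes. The kernel shape is exponential with
`τ_s = 10 ms` and integral `G_ij`; only the integral matters for
large-window statistics. The external drive is itself a filtered Poisson
spike train at rate `r_ext` (unit-integral exponential filter), which
realises `V_ext = r_ext`; a deterministic-drive mode (`V_ext = 0`) exists
for checking the pure-Poisson limit (Fano factor 1). Negative intensities
are rectified at zero and the rectified fraction is reported — above ~1%
the linear formulas become unreliable. Count windows are half-open
`[kΔ, (k+1)Δ)` with the trailing partial window discarded. Finite windows
truncate the integrated covariance by a factor of order `τ_eff/Δ` with
`τ_eff = τ_s/(1 − spectral radius)`; at the default `Δ = 250 ms` and radius
≤ 0.5 this bias is a few percent, below the bootstrap uncertainty of a
400 s run.

## Estimators

Noise covariances use the moment-form divisor (trial count `T`, not
`T − 1`); at `T = 15` this is a uniform 14/15 shrinkage that cancels in
every ratio. Empirical trial covariances are multiplied by `Δ` to sit on
the same normalised-count scale as the analytic `C`. Per-stimulus Pearson
noise correlations exclude stimuli where either neuron's variance vanishes
(the exclusions are counted in a diagnostics field). Projected variances
are `σμ² = r̄ᵀCr̄` (mean-response direction), `σd² = d̄ᵀCd̄` (diagonal),
normalised by `σ_all² = trace C`; `cos(d, r) = r̄·d̄` measures how far the
mean response is from uniform.

Two finite-sample caveats are documented because they are visible at the
default sizes. First, with `V_ext = |r_ext|` and a nonzero drive mean the
per-stimulus mean input variance co-varies with the population rate; the
variance-line slope is inflated by a few percent and, when the mean
response is much larger than `a + ⟨V_ext⟩`, the extrapolated
intercept/slope ratio is biased low (≈ 10% at the default regime; the bias
vanishes for balanced, zero-mean drives). Second, at 15 trials the moment
lines suffer errors-in-variables attenuation (the abscissa `⟨r⟩(s)` is
itself noisy), inflating intercept/slope ratios by tens of percent —
parameter-recovery tolerances on empirical moments are correspondingly
wider than on analytic moments.

## Discrimination

`S = |w̄·(r₁−r₂)|/(σ₁+σ₂)` along `w = (C₁+C₂)⁻¹(r₁−r₂)`; `S` is invariant
under any fixed invertible linear transformation of the population. When
`C₁+C₂` is numerically singular (condition number above 1e12 — generic for
empirical covariances with fewer trials than neurons) a ridge of
`1e-8 · trace/(2N)` is added and the result flagged. Correlations are
removed either by zeroing off-diagonal covariances (model moments) or by
permuting each neuron's trials independently within each stimulus (data);
both preserve means and single-neuron variances. Because near-collinear
stimulus pairs give near-zero `S`, the ratio `S_shuffled/S` is heavy-tailed
across pairs; distribution width is summarised by the interquartile range
alongside the raw standard deviation.

## Fitting and model comparison

The recurrent inversion is exact given the ensemble formulas:
`ρ = 1/c_N − 1`, `⟨B²⟩ = slope/N` from the variance line,
`a + ⟨V_ext⟩ = intercept/slope`. The feed-forward fit is a moment-matching
construction: `ρ` from `(⟨C_ii⟩ − ⟨r⟩)/⟨C_ij⟩ − 1` (offset taken as zero on
baseline-relative data), `c_in` inverted from the average signal
correlation, `ρ_ext` from the across-stimulus variance of `⟨r⟩(s)`
including the `c_in` amplification term, and the overall scale `⟨F⟩` pinned
by the folded-normal mean `⟨|r_ext|⟩` of the implied drive distribution.
The gain-offset search minimises the pair-level residual
`Σ_s Σ_{i≠j} (C_ij − V(s)(r_i+a)(r_j+a))²` with the per-stimulus gain
variance profiled out in closed form, via bounded 1-D minimisation of `a`
over `[−max|r|, 10 max|r|]` (scipy's bounded Brent; the bracket covers
baseline-relative data).

Architecture comparison scores each fitted model on the *pair-level*
off-diagonal covariance structure it predicts, in common relative units:
recurrent — per-pair constant times `(⟨r⟩(s) + β)` with `β` tied to the
variance line (the network model forces the covariance profile to track the
population drive); feed-forward — per-pair constant times the model-implied
input-variance profile `⟨|r_ext|⟩(s)`; gain — pooled
`V (r_i+a)(r_j+a)`. A population variance-curve residual is added for each.
Mean-level scoring alone is insufficient: a gain model with a large fitted
offset reproduces any affine mean-covariance line, but not the pair-level
structure. The resulting verdict and ranking are invariant to a global
rescaling of the responses; the feed-forward and gain *scores* retain a
weak scale dependence because both models pin the Poisson variance to the
absolute rate scale — the same reason an unknown deconvolution scale factor
changes inferred parameters but not functional forms.

Surrogates resample a fresh network and stimulus ensemble from the fitted
moments. The gain surrogate takes its rate ensemble from the feed-forward
fit (the gain model leaves average responses free) and its covariance
parameters from the offset search. An optional low-intercept population
exclusion is not implemented as a default behaviour; populations are
fitted as given.

## Degenerate inputs and numerical choices

Coupling matrices with spectral radius ≥ 0.999 are rejected (the stationary
state diverges at radius 1). Negative diagonal drive entries
(`r_i + a + V_ext,i < 0`) warn and proceed — they are a genuine artifact of
baseline-relative data in a linear model — so analytic covariances are not
guaranteed PSD; the Gaussian trial sampler floors negative eigenvalues at
zero with a warning and errors only when the negative mass exceeds half the
trace (strongly suppressive tail stimuli reach a few tens of percent).
Moment lines are unweighted OLS with non-finite rows dropped; line fits
require at least three distinct abscissa values. All samplers are
deterministic given their seed; the generator derives per-stage child seeds
from a single master seed, so any dataset is reproducible from its
metadata.

## Validation harnesses and problem sizes

The end-to-end checks run at the study's natural sizes: the
simulator-versus-theory oracle on a 3-neuron network for 400 s; ensemble
recoveries of the correlation formulas over 20 networks of 60 neurons with
500 stimuli each; moment-line signatures at 500 stimuli (balanced drives
for the ratio-equality and flat-covariance arms, where the `|r_ext|`
coupling vanishes); projected-variance slopes over 20 seeds per
architecture (the gain arm in the model's own frame, zero offset — the gain
model's slope is near zero with a weak negative tilt, so the discriminative
assertion is one-sided: network slopes are statistically positive, the gain
slope is not); parameter recovery over 10 recurrent and 5 gain replicates;
and classification over 50 replicates per architecture. The shuffling-ratio
structure comparison shares one stimulus ensemble across the two network
ensembles and runs on the bare model (zero offset, no input signal
correlations), where removing correlations has a negligible average effect.

## Known limitations

Mixed architectures are not fitted; the comparison assumes one dominant
mechanism. The feed-forward inversion is a reconstruction by moment
matching and its finite-sample bias has not been characterised beyond the
recovery tests. Covariance formulas are exact only in the large-window
limit. The classifier's accuracy is established on analytic per-stimulus
moments; at 15 trials the empirical moment noise (and the rank deficiency
of `C(s)`) widens all tolerances substantially.
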