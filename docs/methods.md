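# Methods

`simrecall` implements, end to end, the modelling machinery needed to ask
whether the psychophysical similarity structure of a circular feature space
(color, orientation, angular location, shape) predicts the shape of
working-memory recall-error distributions in that space. It covers three
model families, the statistics that compare them, and a synthetic-study
generator that makes the whole chain testable without human data.

All computation happens in a common analysis space: circular values in
[−π, π) radians, with orientation (natively a half circle, period 180°)
doubled before conversion. The wrap convention is half-open: −π is
representable, +π maps to −π.

## Psychophysical similarity (parametric MLDS)

The quad task shows two stimulus pairs and asks which pair is *less*
similar. Perceived similarity is modelled as an exponential decay with
circular distance ψ,

    ω(ψ) = exp(−τψ),

convolved with a zero-mean wrapped normal whose SD equals the perceptual
noise measured in an undelayed reproduction task (pooled across observers,
single-pass ±3 SD exclusion, ML fit of the wrapped-normal SD), then
affinely rescaled to [0, 1] to give the similarity function Ω. The decision
model compares Ω at the two pair distances under additive Gaussian noise of
SD σ: P(pair ab judged less similar) = Φ((Ω(ψ_cd) − Ω(ψ_ab))/σ) — the pair
with the smaller similarity has the larger perceived difference. We fix
similarity (not perceived difference) as the fitted object and define σ on
the normalized [0, 1] similarity scale so it is comparable across observers
and features.

(τ, σ) are estimated per observer by maximizing the Bernoulli likelihood
over (log τ, log σ) with Nelder–Mead simplex search from three starting
points, after excluding practice trials and responses faster than 200 ms.
Bounds: τ ≤ 20, σ ∈ [10⁻³, 10]; boundary estimates clear the convergence
flag.

**Numerical choice.** The circular convolution ω ⊛ WN is evaluated in
closed form: each Gaussian image of the wrapped normal integrates against
the two exponential branches over one period, giving erf-type terms summed
in log space over enough periodic images that the omitted kernel mass is
below 10⁻¹⁰. This is exact to machine precision (a 360-point discrete
convolution would carry ~2×10⁻⁴ discretization error) and lets the MLDS
objective evaluate Ω at the exact trial distances, normalized by the true
extrema Ω(0) = 1, Ω(π) = 0.

## Population-coding recall model

A remembered value θ is encoded by M homogeneous neurons with von Mises
tuning (concentration κ) evenly tiling the circle; neuron i fires at

    r̄_i = γ/(M·N) · exp(κ cos(θ − φ_i)) / I₀(κ),

so the total population activity γ is divided between the N memorized
items (divisive normalization). Spike counts are Poisson over a unit
decoding window (only γ·T/N matters; T = 1, M = 100 by default) and the
recall estimate is the ML decode of the pattern — for uniform dense tiling,
the resultant direction of the spike-weighted preferred values. Zero-spike
trials decode to a uniform random value, so guessing emerges from the model
rather than a mixture parameter. For reporting the model is reparameterized
as peak rate r_max = γ e^κ/I₀(κ) and tuning full width at half maximum
W = 2 cos⁻¹(1 + ln(0.5)/κ), defined for κ ≥ ln 2 ⁄ 2.

Predicted error distributions are tabulated on 360 bins by the
dense-tiling reduction: total count n ~ Poisson(γT/N); given n, the error
is the resultant direction of n i.i.d. von Mises(0, κ) draws (validated
against the explicit M-neuron rates → spikes → decode pipeline at total
variation < 0.01). Because only γT/N enters, the set-size identity
pmf(γ, N=6) = pmf(γ/2, N=3) holds exactly, seed for seed.

**Fitting and identifiability.** Per observer, (γ, κ) are fitted jointly
across set sizes by maximum likelihood. The likelihood is evaluated from
Monte-Carlo tables of the error distribution *conditional on each spike
count* (built in one cumulative pass with a fixed seed — common random
numbers — and a Laplace floor of 0.25 pseudo-counts per bin), mixed with
exact Poisson count weights; the γ dependence is therefore noise-free and
only κ is tabulated stochastically. A coarse geometric (γ, κ) grid scan
(28 × 16 by default) locates candidate basins, the best three are polished
by Nelder–Mead on (log γ, log κ), and the winner is chosen at higher table
resolution (20 000 samples per count level).

This machinery exists because the likelihood surface has a long, nearly
flat ridge: raising γ while broadening tuning (lowering κ) changes the
predicted distribution very little. At 400 trials per observer, points as
far apart as (γ=60, κ=4) and (γ=326, κ=1.3) differ by under one
log-likelihood unit, so the ML point itself wanders the ridge from dataset
to dataset. Simulation (25 seeds at γ=60, κ=4, 200 trials per set size)
gives 10–90% quantiles of roughly 43–280 for γ̂, while the *identifiable*
functionals — the predicted circular SD at each set size — recover within
9.5% worst case (≈3% median). Tests and validation therefore check that
the fit attains the data's maximum likelihood and reproduces the
per-set-size dispersion, not that γ and κ individually match the
generating values. Users should treat per-observer (r_max, W) estimates at
these trial counts as jointly, not marginally, constrained.

## Signal-detection (max-rule) recall models

Recall generates a noisy familiarity signal at 360 equally spaced candidate
values: d_θ′ ~ N(d′·Ω(θ′), 1), and the report is the candidate with the
largest signal, plus wrapped-normal motor noise of SD 2° (interpreted on
the 360-point analysis circle for every feature, i.e. two grid bins). The
report distribution is computed by quadrature over the shared noise axis,

    P(i wins) = ∫ φ(x − d̄_i) ∏_{j≠i} Φ(x − d̄_j) dx,

evaluated once per *unique* signal value (symmetric curves halve the work)
on x ∈ [min d̄ − 8, max d̄ + 8]. The integrand is smooth and rapidly
decaying, so the trapezoid rule is already exact to ~10⁻¹⁵ total variation
at 200 nodes; reporting uses 2000 nodes, fitting 220. Observed errors are
assigned to the nearest of the 360 bins before likelihood evaluation.

Three variants share this engine and differ in the responsiveness curve Ω:

- **empirical** — Ω is the observer's measured similarity function; one d′
  per set size (k = 2 for AIC);
- **synthetic** — Ω from the same exponential ⊛ perceptual-noise family,
  with the exponent fitted to recall data on the grid 0.001:0.0313:10,
  shared across set sizes (k = 3);
- **von Mises** — Ω a unit-peak von Mises parameterized by circular SD on
  the grid 0.03:0.0062:2 (k = 3).

d′ is searched on the grid 0:0.02:5.5. Searches run coarse-to-fine on the
printed grids with warm-started windowed refinement for d′; on unimodal
profile likelihoods this returns the exhaustive-grid argmax (tested), and
`exhaustive=True` forces the full scan.

## Relating the models

Approximating the Poisson channel noise as Gaussian with variance equal to
the response amplitude ξ = γ/(360·N) and rescaling by 1/√ξ yields a
unit-variance signal-detection model with von Mises responsiveness of
concentration κ and peak signal

    d′_N = √(γ/(360·N)) · e^κ/I₀(κ),

whence the sample-size prediction d′₃/d′₆ = √2. The square root is the
scaling that actually produces unit variance. The mapping is validated by
simulating the unit-variance Gaussian population under the max rule
directly (total variation < 0.01 against the quadrature distribution), and
the √2 prediction by refitting per-set-size amplitudes to data generated
from that Gaussian variant.

Two genuine architecture differences keep the *Poisson* population model
from being a relabelled max-rule model, and we document them because they
are measurable: (i) Poisson spiking makes the error distribution a scale
mixture over the spike count, with sharper peaks and heavier tails than
any fixed-d′ max-rule distribution; (ii) zero-count guessing adds a
uniform component the signal-detection fit absorbs by deflating d′ at the
larger set size. Fitting max-rule amplitudes to Poisson-generated data
therefore biases d′₃/d′₆ upward by ~13–33% depending on regime, or
censors d′₃ at the 5.5 grid bound when the data are highly discriminable.
The √2 consistency check accordingly generates from the Gaussian-noise
population variant, which is the model the correspondence concerns.

## Statistics

AIC = 2k − 2 ln L per observer; group comparisons report the mean
per-observer AIC difference (positive favoring the second model). Outliers
are removed iteratively until all values lie within ±3 SD of the mean of
the survivors; correlations remove a pair when either member is outlying;
pooling across features standardizes within feature (after its outlier
pass) before concatenation. Observed correlations are corrected for
attenuation, r′ = r/√(r_xx·r_yy); corrected magnitudes above 1 are
reported with a flag, not clipped. Reliabilities come from a
split-resample bootstrap: per replicate, each observer's trials are
resampled with replacement twice, both resamples refitted, and the two
estimate vectors correlated across observers; the reliability is the mean
correlation over replicates (100 by default; fitter failures skip the
replicate).

## Synthetic studies

The generator reproduces the study designs: per-feature cohort sizes
90/100/104/102 (color/orientation/location/shape), 210/230/240/240
analysed quad trials plus 9 practice, 100 analysed recall trials plus 15
practice with set sizes 3 and 6 interleaved 50/50, 50 analysed perceptual
trials plus 10 practice, and perceptual noise SDs 0.103/0.147/0.022/0.137
radians. Quad stimuli are drawn from the 72-value discretized space (5°
steps; 2.5° for orientation) with the second pair's shorter arc disjoint
from the first's (a config switch relaxes this to distinct endpoints);
response times are log-normal around 900 ms so that ~0.1% fall under the
200 ms analysis filter.

Observer-level latents (τ, σ, γ, κ) are log-normal — medians 1.5, 0.15,
60, 4 with log-SDs 0.35/0.35/0.35/0.25, chosen so simulated cohorts sit in
the plotted ranges of the corresponding human fits; a Gaussian copula
couples σ and γ (default correlation −0.6) to emulate the shared
across-task variability the analysis looks for. Recall data come from the
Poisson population model or, optionally, from the von Mises max-rule model
with amplitudes given by the Gaussian mapping. The generator reproduces
trial tables byte-identically from its seed.

What passing tests on these cohorts do *not* show: the generator contains
no swap/non-target errors, no response-time structure beyond the filter
threshold, no stimulus-dependent (inhomogeneous) encoding, and no lapses
beyond model-intrinsic guessing — properties real observers have and the
models here deliberately omit.

## Problem sizes used in validation

Validation runs are sized for a laptop-class single core: recovery checks
use single observers with 240 quad / 400 recall trials, cohort checks use
20–50 observers, Monte-Carlo oracles use 10⁵–10⁶ draws, and the group
model-recovery comparison uses a 20-observer study at the real per-observer
trial counts. The pipeline exposes the knobs (`nr_mc_samples`,
`tcc_quad_nodes`, `tcc_shape_stride`, grid ranges, bootstrap replicates) to
scale any of this up.

## Known limitations

- (γ, κ) — equivalently (r_max, W) — are close to ridge-unidentified at
  ~100–400 trials per observer; see above.
- The synthetic-TCC exponent search warm-starts between neighbouring grid
  points; a pathologically multimodal profile likelihood could in
  principle defeat the coarse-to-fine scan (use `exhaustive=True` to rule
  this out for a given dataset).
- Bootstrap reliabilities refit every resample; at publication scale (100
  replicates × ~100 observers) the synthetic-exponent reliability is by
  far the most expensive quantity in the pipeline.
- The max-rule quadrature assumes independent channel noise; correlated
  familiarity noise is out of scope.
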