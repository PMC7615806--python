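# simrecall

Modelling tools for a question at the border of psychophysics and visual
working memory: **does the psychological similarity structure of a circular
feature space (color, orientation, angular location, shape) determine the
shape of recall-error distributions in that space?** The package is aimed
at researchers fitting trial-level behavioral data from similarity-scaling
and analogue-report (delayed estimation) tasks, and at anyone who wants a
tested, reusable implementation of the models those studies compare.

It implements three modelling traditions over a single analysis convention
(circular values in [−π, π) radians, orientation doubled):

- **Parametric MLDS.** From quad-task judgments ("which pair is less
  similar?"), fit a similarity function Ω(ψ) — an exponential decay
  exp(−τψ) convolved with perceptual noise and rescaled to [0, 1] — with a
  Gaussian decision-noise parameter σ, by maximum likelihood.
- **Population coding.** Recall errors from a Poisson-spiking neural
  population with von Mises tuning: rate r̄ᵢ = γ/(MN) · e^{κcos(θ−φᵢ)}/I₀(κ)
  (total activity γ divided between N items), ML decoding, and
  reparameterization to peak rate r_max = γe^κ/I₀(κ) and tuning width
  W = 2cos⁻¹(1 + ln(0.5)/κ).
- **Signal detection with a max rule.** A familiarity signal
  d_θ′ ~ N(d′·Ω(θ′), 1) at 360 candidate values; report the argmax plus 2°
  motor noise. Three variants of Ω: the *empirical* similarity function,
  a fitted exponential-family curve (*synthetic*), or a fitted *von Mises*
  curve.

Around these sit the formal correspondence between the last two families
(d′_N = √(γ/(360N))·e^κ/I₀(κ), hence d′₃/d′₆ = √2), AIC model comparison,
iterative ±3 SD outlier handling, standardize-then-pool, partial
correlations, attenuation correction r′ = r/√(r_xx·r_yy) with
split-resample bootstrap reliabilities, and a synthetic-study generator
that reproduces the tasks' designs for parameter-recovery testing.
`docs/methods.md` documents every model, default and numerical choice.

## Worked example

Simulate a small color-study cohort, estimate perceptual noise, fit one
observer's similarity function, then compare recall models on the same
observer's memory data:

```python
from simrecall.synthetic import StudyConfig, generate_study
from simrecall.scaling import (fit_perceptual_noise_sd, fit_mlds,
                               build_similarity_function)
from simrecall.tcc import fit_empirical_tcc, fit_vonmises_tcc
from simrecall.pipeline import add_analysis_errors

tables = generate_study(StudyConfig(feature="color", n_observers=8,
                                    n_quad_trials=210, seed=7))

perc = add_analysis_errors(tables["perceptual"]).query("practice == 0")
noise = fit_perceptual_noise_sd(perc["error"].to_numpy())

quad0 = tables["quad"].query("observer_id == 'obs000'")
mlds = fit_mlds(quad0, noise.sd)

wm0 = add_analysis_errors(tables["wm"]).query(
    "practice == 0 and observer_id == 'obs000'")
omega = build_similarity_function(mlds.tau, noise.sd)
emp = fit_empirical_tcc(wm0, omega)
vm = fit_vonmises_tcc(wm0)
```

Output (values printed from the fits above):

```
pooled perceptual SD: 0.104 rad (n=399)
MLDS fit obs000: tau=1.92 sigma=0.14 logL=-65.7 (n=210)
empirical TCC: d'3=2.82 d'6=2.3 AIC=781.0
von Mises TCC: circ SD=0.59 d'3=4.52 d'6=2.98 AIC=778.2
```

Reading the numbers: the pooled perceptual noise estimate (0.104 rad)
recovers the generator's 0.103; the observer's similarity function decays
with rate τ ≈ 1.9 and their pair judgments carry decision noise σ ≈ 0.14
on the normalized similarity scale. Both recall models show the set-size
effect (the memory-match amplitude d′ falls from set size 3 to 6), and the
fitted von Mises responsiveness achieves the lower AIC — i.e., for this
observer a circular-normal curve describes the recall data slightly better
than their measured similarity function, the comparison at the heart of
the analysis.

The full chain — simulate → perceptual fit → MLDS → population-model fit →
all three max-rule variants → AIC tables → correlation/attenuation report —
runs as a pipeline:

```
simrecall run-all --config config.yaml --seed 3 --outdir results/
```

with a YAML config mirroring `StudyConfig` plus fitter settings (see
`simrecall.pipeline.PipelineConfig`). Stages cache their outputs keyed by
config and input hashes; rerunning with an identical config is a no-op.

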