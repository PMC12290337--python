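# glosstrans

Tools for studying how **gloss and albedo perception survive viewing
through a transparent layer**, aimed at visual psychophysicists who run
paired-comparison and asymmetric-matching experiments.

A transparent layer in front of an object changes the retinal image in a
lawful way. Under the episcotister (Metelli) model, a background pixel of
luminance *b* seen through a layer with transmittance *α* and reflectance
*t* becomes

```
p = α·b + t·(1 − α)
```

The package implements the full analysis chain around that model:

- **`glosstrans.metelli`** — apply the compositing rule to luminance
  images and compute the diagnostics that covary with perceived gloss:
  Michelson contrast `(Lmax − Lmin)/(Lmax + Lmin)`, luminance-histogram
  moments (incl. skewness), and the fraction of pixels darkened by a layer.
- **`glosstrans.mlcm`** — maximum-likelihood conjoint measurement.
  A paired comparison of stimuli (i, j) and (k, l) is decided by
  `Δ = (ψᵍᵢ + ψʳⱼ) − (ψᵍₖ + ψʳₗ) + ε`, `ε ~ N(0, σ²)`, so
  `P(left) = Φ(Δ/σ)`. Three nested observer models — *independent*
  (ψʳ ≡ 0), *additive*, and *full* (with interaction ψᵍʳ) — are fitted by
  probit maximum likelihood (σ ≡ 1, first level of each scale anchored at
  0) and compared with χ² likelihood-ratio tests at a Bonferroni-corrected
  level.
- **`glosstrans.mlds`** — maximum-likelihood difference scaling on
  quadruples, used to place stimulus levels at perceptually equal steps
  (fit the physical→perceptual mapping, then invert it).
- **`glosstrans.matching`** — asymmetric-matching error analysis on a
  7-step material lattice: signed errors (matched − true; overestimation
  positive), error-vs-contrast tables, and an OLS test of whether joint
  (albedo+gloss) matching errors are the Euclidean combination of the
  single-attribute errors (slope tested against 1).
- **`glosstrans.synth`** — simulated observers, balanced trial designs,
  lattice matching simulation, and procedural glossy-object images, so the
  whole chain runs without human data.
- **`glosstrans.pipeline` / CLI `glosstrans`** — end-to-end runs with
  seeded reproducibility and a manifest.

## Worked example

```python
import numpy as np
from glosstrans import synth, mlcm

grid = synth.StimulusGrid(n_gloss=4, n_filter=4)
truth = synth.ObserverModel(psi_g=(0, 1, 2, 3), psi_r=(0, -0.2, -0.4, -0.6), sigma=1.0)
design = synth.build_conjoint_design(grid, repetitions=4, seed=1)   # 480 trials
trials = synth.simulate_conjoint_responses(design, truth, seed=2)

model = mlcm.ConjointModel(trials)
fit = model.fit("additive")
print(fit.summary())
res = mlcm.lr_test(model.fit("independent"), fit)
print(f"LR = {res.statistic:.2f}, df = {res.df}, p = {res.p_value:.2g}")
```

prints

```
Conjoint measurement fit
==============================================
Model:            additive
Trials:           480
Free parameters:  6
Log-likelihood:   -162.1259
Converged:        True
----------------------------------------------
Gloss scale psi_g:   0.000   0.911   2.097   2.813
Filter scale psi_r:  0.000  -0.407  -0.613  -0.749
LR = 29.37, df = 3, p = 1.9e-06
```

The gloss scale recovers the generating values (0, 1, 2, 3) in
decision-noise units, the filter scale recovers the injected negative
contribution of lighter layers, and the likelihood-ratio test rejects the
independent observer — the transparent layer demonstrably contaminates
gloss judgments in this simulated session.

The same flow is available from the shell:

```
glosstrans simulate-conjoint --repetitions 4 --seed 1 --out trials.csv
glosstrans fit-mlcm --trials trials.csv --model additive --out fit.json
glosstrans run-exp1 --seed 1 --out-dir out/exp1
glosstrans run-exp2 --seed 1 --out-dir out/exp2
```

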