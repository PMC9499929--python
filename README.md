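# bearclock

Bayesian hierarchical modelling of circadian activity from GPS telemetry of
brown bears.

Hourly movement rate — the planar distance between successive GPS fixes taken
one hour apart — is a standard proxy for activity in large-carnivore
telemetry. This package models the square-root of that rate for each bear and
hour as

```
y_tk = λ*_tk + ε_tk,          ε_tk ~ N(0, σ²)
```

where the linear predictor `λ*_tk` combines, depending on the model variant:

- an **hour-of-day effect** λ = (λ₁, …, λ₂₄) ~ MN(**0**, Σ), with
  `Σ[i,i'] = exp(−ν · min(|i−i'|, 24−|i−i'|)) / ψ` — the covariance decays
  with *circular* distance in time, so 24:00 and 01:00 are one hour apart and
  the fitted diel curve closes smoothly around the clock. The hour effect can
  be shared (λ_i), season-specific (λ_ir), or season-and-sex-specific (λ_irs);
- an **individual random effect** ω_k ~ N(α, ρ²) per bear;
- **sex/season fixed effects**: additive (μ_s + γ_r), season-only (γ_r), or a
  full interaction (ξ_rs) with female-in-spring as reference category;
- **anthropogenic distance decays** β_j·exp(−φ_j·x_j) for distance (km) to all
  roads (x₁), primary roads (x₂), secondary roads (x₃) and settlements (x₄),
  optionally season-specific (β_jr, φ_jr).

Thirteen structural variants of `λ*` (the registry in
`bearclock.model.MODEL_REGISTRY`) are fitted by an in-house
Metropolis-within-Gibbs sampler — closed-form Gibbs updates for every
Gaussian block and the conjugate-Gamma variance parameters, adaptive
reflected random walks for ν and the φ's — and ranked by DIC
(D̄ + p_D, Spiegelhalter's conditional focus). Priors are weakly
informative: N(0, 1000) on all location parameters, Ga(1, 1) on 1/ρ², 1/σ²
and ψ, ν ~ Unif(3/24, 3) and φ ~ Unif(3/4, 3/0.2) so the practical ranges
(3/ν, 3/φ) span 1–24 h and 0.2–4 km.

Because real telemetry of this kind is typically not redistributable, the
package ships a first-class synthetic-study generator
(`bearclock.synthetic`) that emulates the study design end to end: 18
collared bears (11 F / 7 M), one scheduled fix per hour across a March –
mid-December active period split into four dietary seasons, fix-acquisition
success in the 0.79–0.97 range, isotropic GPS error with 24.7 m mean radial
size, and responses drawn from the generative model itself. Every stage —
preprocessing, fitting, selection, summaries — is exercised and validated
against this generator.

## Worked example

The numbered drivers under `analysis/` run a complete synthetic study
(see also the `bearclock` CLI: `simulate`, `preprocess`, `fit`, `select`,
`summarize`):

```
python analysis/01_simulate_study.py     # 18 bears, hourly fixes, truth sidecar
python analysis/02_preprocess_fixes.py   # raw-fix pipeline demo (GPS error, screening)
python analysis/03_fit_models.py         # fit models 1, 12, 9 (2 chains, desk scale)
python analysis/04_model_selection.py    # DIC ranking
python analysis/05_summaries.py          # curves, active hours, distance responses
```

Representative output (seed 7):

```
study: 18 bears (11 F), 17280 scheduled hourly fixes, acquisition 0.88
emitted 13361 movement records (77.3% of scheduled pairs; misses break pairs)
...
 spec_id  ...  K        dbar        p_d         dic   delta_dic
       9  ...  5 4710.293183 191.232146 4901.525330    0.000000
      12  ...  3 5312.459894 111.947739 5424.407633  522.882303
       1  ...  0 6388.008039  41.442498 6429.450536 1527.925207
...
population curve: peak hours [2, 12], 24-h mean 0.328 km/h
both sexes, all seasons (km/h): 24h: 0.33 +/- 0.09, active: 0.35 +/- 0.10, inactive: 0.30 +/- 0.09
  primary roads   spring        beta=-0.145 CI=(-0.186, -0.109)  YES
```

Reading this: DIC recovers the generating structure (model 9, the full
hour×season×sex model with split season-specific distance effects) by a
margin of ~523 over the nearest alternative; the population activity curve
is the per-draw, back-transformed (squared) hour curve for a 50:50 sex
ratio, its 24-h mean (0.328 km/h here) is the threshold separating active
from inactive hours; and each season × feature amplitude β_jr is flagged
when its 95% credibility interval excludes zero. All curves are summarized
draw-wise on the km/h scale — a posterior mean is never squared.

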