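# Methods

## Problem and model

River consumers integrate carbon from several primary sources — terrestrial
C3 plants, C4 macrophytes (e.g. *Vossia*), algae, and possibly
methane-oxidizing bacteria (MOB). δ13C separates C3 from C4 but overlaps
badly between C3 plants and algae; δ2H separates aquatic from terrestrial
production (aquatic producers are strongly 2H-depleted) but only after two
corrections specific to hydrogen. The package chains those corrections to a
compositional Bayesian mixing model.

### Nonexchangeable δ2H

A fraction *f_ex* of tissue hydrogen exchanges freely with ambient moisture
and carries no dietary signal. Under equilibration with water of known
composition,

    δ²H_total = f_ex · δ²H_water + (1 − f_ex) · δ²H_n.

Equilibrating aliquots with two waters (−435.5‰, +945‰) gives two linear
equations; subtracting cancels δ²H_n, so

    f_ex = (δ_A − δ_B) / (w_A − w_B),  δ²H_n = (δ_A − f_ex·w_A) / (1 − f_ex).

The exchangeable pool is assumed to take exactly the equilibration water's
value — no vapour–liquid fractionation term — which keeps the solve exact
and is the convention for the comparative-equilibration family of methods.
f_ex estimates up to 0.02 outside [0, 1] are attributed to analytical noise
and clipped with a warning; beyond that the run is flagged inconsistent.
f_ex > 0.99 leaves δ²H_n undetermined and raises. For fish muscle, whose
exchangeability matches the keratin references, a two-point affine
calibration through (measured, accepted) CBS/KHS values is used instead;
residuals at the anchors are zero by construction. Both paths are exposed
because either treatment may be applied to a given batch. A batch QA/QC
summary compares the laboratory-standard replicate SD against the expected
±1.0‰; it reports and never blocks.

### Trophic water-compounding

Tissue H also derives partly from environmental water, and that fraction
compounds along the food chain: with per-step water fraction ω and τ
trophic steps above the primary source,

    δ²H_consumer = ω_c·δ²H_water + (1 − ω_c)·δ²H_source,   ω_c = 1 − (1 − ω)^τ.

Defaults: ω = 0.28 (fish), 0.40 (invertebrates), assigned by community
label and configurable. τ = TP − 1 with TP = 1 + (δ¹⁵N − 5.6)/3.4 (per-mil;
baseline 5.6‰ is the primary-producer mean, 3.4‰ the canonical per-step
enrichment). τ is computed per specimen from its own δ15N — the only
reading under which the correction equation applies as written — with a
per-group-mean option as a flag. TP below 1 is clamped to 1 (negative
compounding is physically meaningless). Water δ2H enters as a point value
(default 0.0‰, the long-term monitoring mean; its 4.2‰ SD is not propagated
— the correction is deterministic by design, matching how the correction is
used in practice). ω_c ≥ 0.99 raises rather than amplifying noise without
bound.

### Source end-members

Measured sources are summarized per tracer as mean ± SD over specimens
(n ≥ 2 required). The algal end-member is constructed:
δ13C = DIC mean + photosynthetic offset (default −18‰, configurable within
the literature −17 to −23‰ range, chosen so mainstream DIC of −12.0‰ yields
the −30‰ algal value), with the DIC SD multiplied by 1.5; δ2H = water mean
− 150‰ with SD 27‰. The "variation increased by 50%" rule is interpreted as
SD × 1.5, not variance × 1.5 — per-mil "variation" reads as an SD; this
interpretation is a documented choice. The MOB end-member defaults to δ13C
−47.5 ± 2‰, δ2H −80 ± 20‰ (values propagated from water δ2H, methane δ13C
and fatty-acid fractionations; only the final values are implementable).
The C4 macrophyte δ2H defaults to the pooled terrestrial-plant −50 ± 14‰
since no C4-specific value is available. All constructed sources must carry
strictly positive SDs before entering a fit.

### Mixing-polygon screening

Per iteration (default 1,500) each source's position is drawn from
Normal(μ + λ, √(σ² + τ_λ²)) per tracer (discrimination mean and SD folded
in), the convex hull of the draws is formed, and each consumer scores 1 if
inside or on the hull (half-plane test with 1e-9 tolerance; boundary counts
inside). Collinear draws degrade to an on-segment test, so off-line
consumers count outside. The per-consumer probability is the hit rate; its
Monte Carlo SE is ≤ √(p(1−p)/n).

**Retention threshold.** A consumer is retained when its probability
reaches the threshold, and the default threshold is 0.05: exclusion means
fewer than 5% of the simulated polygons can explain the consumer, i.e. it
falls outside the 95% mixing region. The stricter reading — retain only
consumers inside ≥95% of polygons — is available by passing
`threshold=0.95`, but is not the default because even a consumer located
exactly at the mixture of the source means is inside only ~90–96% of
simulated polygons for realistic source SDs; a 0.95 cut would discard most
genuinely feasible consumers. Screening runs in the same tracer space as
the subsequent fit (δ13C × δ2H for the C+H model; a δ13C interval test for
the C-only model), using source-corrected δ2H. The seed is a required,
logged parameter.

### Bayesian mixing model

One proportion vector per group level (fixed effect = fully independent
Dirichlet(α = 1) composition per level; no pooling). Likelihood per tracer:

    x_t ~ Normal( Σ_k p_k(μ_kt + λ_kt), √( Σ_k p_k²(σ_kt² + τ_kt²) + s_t² ) ).

δ13C discrimination is 0.4 ± 1.3‰ applied once at consumer level (not
multiplied by trophic position; a scalar multiplier is exposed for the
per-trophic-step alternative); δ2H carries no discrimination because the
water compounding is removed upstream. δ15N never enters the likelihood —
its producer values overlap too much to resolve sources and it is already
spent on trophic position.

Error structures: `process_plus_residual` (default) samples a per-tracer
residual SD s_t with a weakly informative half-normal prior whose scale is
the consumers' empirical SD; `process_only` fixes s_t = 0. The default
spans unmodelled consumer-level variability (diet heterogeneity, tissue
turnover) that pure process error understates; every report records which
structure was used.

Sampling: random-walk Metropolis on the isometric-log-ratio (ILR) transform
of **p** (orthonormal Helmert basis) plus log s_t, all chains advanced
simultaneously. The Dirichlet prior is expressed in ILR coordinates with
its Jacobian (√K·Π p_k), verified against deterministic quadrature. Step
size adapts every 100 burn-in iterations toward ~30% acceptance and is
frozen afterwards. Defaults mirror the reference run length — 300,000
iterations, 150,000 burn-in, thinning by 50, 3 chains (the likelihood is
reduced to per-tracer sufficient statistics, so cost is independent of
consumer count) — while tests and the acceptance script use 30,000/15,000/
thin 5, which the grid-integration oracle shows is already well converged
for these problem sizes. Convergence: R-hat (warn > 1.05, flag > 1.1) and
bulk ESS via arviz; flags go to the fit report, never abort. Groups with
fewer than 3 usable consumers are skipped with a warning; specimens missing
a required tracer are excluded at fit time and counted, never silently
dropped earlier.

Sources are canonically ordered by name inside both the screening and the
sampler, making results exactly invariant to the order in which sources are
supplied. Posterior summaries report per-source median, SD and 2.5/97.5%
quantiles of the pooled chains (medians of a composition need not sum
exactly to 1).

The sensitivity sweep refits the model over a list of values for one source
parameter (addressed as `source.tracer.mean|sd`, e.g. `algae.d2H.mean` over
−130…−170‰) and tabulates each group × source median against the swept
value plus the maximum absolute change relative to the unmodified fit;
inputs are never mutated.

## Synthetic data generator

The generator is the exact forward model of the pipeline's inverse. Per
consumer: draw TP ~ Normal(TP_mean, TP_sd) truncated at 1; set δ15N =
5.6 + 3.4(TP − 1) + noise; draw each source's tracer values from its
mean/SD and mix with the group's true proportions (δ13C discrimination
drawn per consumer and added); mix δ2H on the source scale, then apply the
compounding equation forward with the consumer's own τ and community ω; add
analytical noise (0.1‰ δ13C/δ15N, 2.0‰ δ2H — the within-run laboratory
SDs). Defaults encode the study conditions: the three sources above, fish
at TP 2.5 ± 0.35 with true diet (0.50, 0.25, 0.25) over (C3, C4, algae),
aquatic invertebrates at TP 1.7 ± 0.40 with (0.60, 0.20, 0.20), 60
consumers per group, water 0 ± 4.2‰. The invertebrate diet and the TP SDs
(community δ15N SDs ≈ 1.2–1.4‰ divided by 3.4) are the package's own
choices of realistic values. An optional outlier fraction injects pure-C4
feeders (δ13C > −17‰) to exercise polygon exclusion; default 0.

What the generator does **not** emulate: taxon-level diet heterogeneity
within a group (all consumers in a group share one true diet), seasonal and
spatial source variation, covariance between tracers within a source,
isotopic routing/turnover, and size effects. Passing recovery tests
therefore shows the inference chain is self-consistent and well calibrated
under its own assumptions — not that those assumptions hold in any real
river.

## Numerical choices

- Two-water solve and compounding correction are closed-form; tolerances
  are exact round-trip checks at 1e-9.
- Point-in-polygon: hull half-plane equations with 1e-9 slack; on-edge is
  inside.
- ILR/softmax inversion is shift-stabilized; proposals that leave the
  feasible region are rejected naturally through the log-posterior.
- Seeds: every stochastic stage takes an explicit seed; the pipeline logs
  screening and fitting seeds separately, and per-group chains derive from
  `numpy.random.SeedSequence` spawns so group order cannot alias streams.
- Reduced problem sizes used throughout the shipped tests and acceptance
  script: 60 consumers/group, 1,500 polygon iterations, 30,000/15,000/thin 5
  MCMC — sizes at which the quadrature and closed-form oracles confirm
  convergence.

## Known limitations

- Fixed effects only; no hierarchical pooling, covariates, concentration
  dependence, or informative diet priors.
- Water δ2H uncertainty and TP uncertainty are not propagated into the
  δ2H correction (deterministic correction by design).
- The MOB end-member is a literature-propagated point prior; the four-source
  model inherits its uncertainty assumptions.
- The polygon test treats sources as independent normals; correlated
  source draws would change hull geometry.
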