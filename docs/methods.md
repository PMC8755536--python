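# Methods

## Cohorts and ages

Ages are exact day differences divided by 365.25, which keeps the 30-day
birth-precision rule meaningful and makes every age reproducible from the
dates alone. An individual enters the analysis at `max(α, age at window
start)`, where α is the sex-specific age at sexual maturity (max of the two
sexes when sex is unrecorded), and exits at death or at the extraction date
(censored). Individuals dead before the window, maturing after extraction,
dying before maturity, or with birth precision worse than 30 days are
excluded, each with a logged reason, so that included + excluded always
equals the input count. Dead individuals without a necropsy record remain
in the cohort with cause `unknown`: they carry survival information, and the
complete-case design of the cumulative incidence needs them present so they
can be dropped there explicitly. Records with known-dead status but no death
date are rejected rather than imputed.

## Survival with delayed entry

The product-limit estimator uses risk sets `n(t) = #{entry < t ≤ exit}`.
Two tie/boundary conventions are fixed and tested:

* deaths at *t* precede censorings at *t* (the standard convention —
  censored-at-*t* individuals are still in the risk set);
* an individual whose exit equals its entry age (possible when death falls
  exactly on the window start or the maturity date) is explicitly included
  in the risk set at that age. Note that a strictly-before entry rule alone
  would *exclude* such an individual from its own death event; the explicit
  zero-length-interval case is what prevents self-exclusion.

Adult life expectancy is the restricted mean above α — the area under the
survival step function up to the last observed age — with a `truncated`
flag when the curve does not reach zero. No extrapolation beyond the last
observation is attempted: with windowed zoo data there is no principled
tail model, and the flag lets downstream users decide. Greenwood variances
are not computed; no analysis in the chain consumes them.

A species enters cumulative-incidence analyses only if its all-deaths
survival curve falls to 10% within the observed ages (the `q10` rule):
below that, late-life hazards are unidentified and the incidence sum would
silently miss mass. The threshold is a parameter (`survival_floor`).

## Cumulative incidence of cancer mortality

On the complete-case subset (known-cause deaths + censored survivors) the
incidence is

    ICM = Σ over cancer event ages t of  S(t−) · d_c(t)/n(t)

with S the known-cause-deaths product-limit curve and the cancer hazard
carried as exact event-age jumps, not pooled into calendar intervals:
event times in small managed populations are sparse and irregular —
sometimes a large fraction of an adult lifespan apart — and interval
pooling would make species incomparable. S enters at its left limit; this
is the convention under which the cause-specific incidences and the
terminal survival sum *exactly* to one on fully observed cohorts (the
estimator telescopes), and under which ICM reduces to the crude cancer
fraction on complete data. The post-jump alternative is exposed as
`s_convention="post"` for sensitivity. All survival products can be carried
in rational arithmetic (`exact=True`), which is how the additivity and
oracle-equivalence tests assert exact equality rather than float closeness.
The complete-case design assumes cause-of-death missingness is unrelated to
cause; an MNAR stress preset in the generator exists to probe violations.

## Phylogenetic GLS and Pagel's λ

Species covariance is the shared root-to-MRCA path length; λ multiplies the
off-diagonal entries only. The GLS solver whitens through a Cholesky factor
of `D C(λ) D`, where `D = diag(1/√w)` — case weights act as precision
multipliers (heavier-weighted species get proportionally smaller residual
variance, correlations untouched). Weights in the risk models are natural
logs of necropsy counts; the base is a convention (config-exposed) since
only ratios of weights matter up to a global variance scale. λ is profiled
by maximum likelihood (not REML) on [0, 1] with a bounded scalar optimizer
(tolerance 1e-6) and endpoint checks; a profile whose optimum sits at the
lower bound is reported as the λ = 0 refit. ML rather than REML keeps
likelihood-ratio comparisons between nested λ values valid; the λ = 0
boundary makes the nominal χ²(1) reference conservative, and a 50:50
mixture correction is available as an option. The λ engine was
cross-checked against an independent reference implementation during
development and agrees to optimizer precision.

Numerical choices: covariances that are semi-definite to machine precision
(trees with near-zero terminal branches, e.g. right after a sister graft)
receive an escalating diagonal jitter (1e-12…1e-8 × mean diagonal) before
Cholesky; anything still non-PD is an error. Rank-deficient designs raise
an error naming the collinear columns (QR pivot diagnosis) — a pseudo-
inverse fallback would mask data problems. Coefficient SEs use the
unbiased residual variance (RSS/(n−p)) with t(n−p) reference.

## The zero-inflated two-part model

Zeros in species-level cancer risk are informative about detection, not
about magnitude, so the model splits:

1. **Detection** — phylogenetic logistic regression of `risk > 0` on log
   necropsy count, log body mass and log life expectancy, with a
   tree-structured random effect `b ~ N(0, s²C)` fitted by penalized
   quasi-likelihood (working-response iteration; s² refreshed each sweep by
   maximizing the working model's restricted likelihood on [0, 10]). With
   s² fixed at 0 the iteration is exactly IRLS for plain logistic
   regression, which is how it is validated. Coefficients exceeding |15| on
   the logit scale are reported as separation (`converged=False`), not an
   exception. PQL is known to shrink variance components in small samples;
   the parameter-recovery tolerances in the tests reflect that.
2. **Magnitude** — weighted PGLS of logit(risk) on log mass and log life
   expectancy among species with risk strictly inside (0, 1). Splitting at
   zero is precisely what makes the logit well-defined without any
   continuity constant. A risk of exactly 1 (all necropsied deaths
   attributed to cancer — only seen at tiny sample sizes) likewise has no
   logit and is set aside with a note. An optional mass × life-expectancy
   interaction is fitted on request and compared by AIC; an optional
   exclusion list removes named high-leverage species (the packaged default
   names three very short-lived rodent/dasyurid outliers).

Predictions invert the logit of the magnitude part's linear predictor and
report percentages; per-doubling effects are per-ln-unit coefficients
rescaled by ln 2 at the reporting layer. Partial R² is prediction-based:
1 − SSE(full)/SSE(reduced) where each model's predictions are conditional
(kriging-style) — species *i* predicted from the model mean plus the
covariance-weighted residuals of all other species — clipped at zero.

The phylogenetic paired t-test fits an intercept-only λ-GLS to the
within-species differences. The degrees of freedom printed alongside the
statistic are a convention (`n−1`, `n−2`, `n−3` selectable, default `n−2`):
published analyses of this design differ in whether the λ estimate costs a
degree of freedom, and the choice moves P values only marginally at the
sample sizes involved. Calibration under the null (star and structured
trees, 1000 replicates) is asserted in the acceptance suite.

Order differences use ordinary one-way linear models on percentage risk
(orders with ≥ 2 species), with marginal means equal to group means and
pairwise contrasts Tukey-adjusted by default (`none`/`bonferroni`
available). Diet items are recoded never/occasional → 0,
secondary/primary → 1 and tested one item at a time against the
mass + life-expectancy base model.

## Synthetic worlds: what they emulate, and what they do not

The generator reproduces the *structure* of managed-population data: a
2010–2020 window, adults alive at the window start entering left-truncated
(their above-maturity age drawn from the stationary exponential age
distribution, so remaining lifetimes stay exponential — memorylessness
makes the delayed-entry estimator exactly consistent), births during the
window, right-censoring at extraction, ~12% unknown-sex individuals, a
mixture of exact and imprecise birth dates, and per-individual necropsy
missingness (MCAR by default; an MNAR preset couples necropsy probability
to cancer status).

Defaults, chosen once as a realistic-and-verifiable operating point:

| parameter | default | rationale |
|---|---|---|
| species / individuals | 150 / mean 300 | comparative-study scale |
| per-species n dispersion | lognormal σ = 0.5, floor 30 | holdings vary over orders of magnitude; identifies the detection curve |
| β_mass | −0.15 per ln kg (≈ −10%/doubling) | small relative to residual spread yet sign-recoverable at this scale |
| β_lifespan | +0.6 per ln yr (≈ +52%/doubling) | as above |
| λ_true / residual SD | 0.5 / 1.8 logits | residual spread matching the orders-of-magnitude range of observed risks; moderate signal |
| baseline logit β0 | −3.4 | mid-teens mean risk, zeros present but not dominant |
| necropsy probability | 0.9 | routine postmortem examination of recovered bodies |
| maturity | α = 0.2 × life expectancy (♂ ×1.1) | crude allometry; exercises the sex-specific α rule |
| mortality | exponential, rate 1/e_i | closed-form truth for life-expectancy recovery |

A `near_null_effects` preset carries per-doubling effects of −3% and +29%
(the near-null regime that motivates Peto's paradox analyses); by design
such effects are *not* reliably sign-recoverable at the default scale, so
power-style tests use the defaults above or the `strong_effects` preset.
One master seed fans out to named substreams (tree, traits, individuals),
so each stage is independently reproducible; identical seeds give
byte-identical CSVs.

Not emulated: Gompertz senescence (exponential mortality has no age
acceleration — the delayed-entry machinery is age-agnostic, but ages at
death are less realistic), demographic seasonality, inter-institution
heterogeneity in record-keeping, cancer-type structure, and real taxonomic
imbalance (Yule trees are more balanced than the mammal tree). Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated generative model, not robustness to every feature of real data.

## Known limitations

* Binomial sampling noise in per-species risk attenuates λ estimates
  toward zero; the log-count weights only partially compensate. The
  recovery checks compare the median λ̂ across replicate worlds against the
  generative value with a tolerance that acknowledges this attenuation
  plus the sampling variability of ML λ at ~150 species.
* PQL point estimates of the detection part are biased toward zero for
  large |β| and can flag separation on steep detection data.
* The restricted-mean life expectancy is downward-biased for species whose
  survivors dominate the observed window (flagged via `truncated`).
* The cumulative incidence treats the necropsied complete-case subset as
  representative of all deaths; MNAR necropsy assignment violates this and
  is only probed, not corrected.
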