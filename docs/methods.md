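# Methods

This note documents the statistical model, the structural corrections, the
synthetic-data generator, the numerical choices, and the limitations of
`csmf519`.  It is written for a reader deciding whether the package's
assumptions fit their problem.

## Estimation strata and taxonomy

Countries are classified once per run:

* **HQVR** — high-quality vital registration; empirical cause fractions
  pass straight to envelope application.  (Real VR pipelines apply
  garbage-code and completeness adjustments first; those are upstream of
  this package, which treats VR-derived CSMFs as pre-adjusted inputs.)
* **LMM / HMM** — modelled strata, split at a probability of death between
  ages 5 and 19 of 10 per 1000.  The boundary value itself is assigned to
  HMM so the rule is a total deterministic function.

Four age-sex groups are estimated separately (5–9, 10–14, 15–19 female,
15–19 male), each with its own cause list reflecting which causes carry a
non-trivial share of that group's deaths: maternal causes only in 15–19
females, congenital disorders and measles only in 5–9, cardiovascular
disease and self-harm only at 15–19, malaria only at 5–14, and no
lower-respiratory-infection (LRI) category at 15–19.  Causes are either
*modelled* (jointly, by the multinomial model: 11 / 10 / 11 / 10 causes per
group respectively) or *single-cause* (HIV/AIDS, tuberculosis, measles,
and the crisis causes), which arrive as external series and are folded in
afterwards.  Every cause maps to one broad group (CMPN / NCD / injury).

Study inclusion: at least two reported causes and at least 15 deaths.
Studies spanning several years carry one covariate row at the midpoint
year.

## The Bayesian LASSO multinomial-logistic model

For study *i* (total deaths *n<sub>i</sub>*, standardized covariates
*x<sub>i</sub>*, country *j(i)*):

    y_i ~ Multinomial(n_i, p_i)
    p_ic = softmax(η_i)_c
    η_ic = β_0c + x_i·β_c + u_j(i),c      (reference cause: η = 0)

Priors:

* covariate coefficients: double-exponential (Laplace) with rate λ — the
  Bayesian form of the LASSO penalty.  The reference parameterisation of
  the original model is not printed in the source literature; a Laplace
  prior with a cross-validated rate is this package's interpretation.
* intercepts: Normal(0, 5²), excluded from the penalty (standard LASSO
  practice).
* country random effects: u<sub>jc</sub> ~ Normal(0, σ<sub>u</sub>),
  σ<sub>u</sub> = 0.07, fixed rather than estimated (configurable).
  Random effects exist only for countries contributing studies; all other
  countries are predicted with u = 0.

Fits are independent per age-sex group and per stratum (LMM-input vs
HMM-input data).  Model averaging across strata is deliberately not
offered.  When a country's own stratum has no studies at all, the pipeline
borrows the other stratum's fit for prediction and logs it.

**Penalty selection.**  λ minimises the mean out-of-fold RMSE of predicted
vs observed cause fractions, over study-level folds (fold unit = study,
stratified by country when every country has at least as many studies as
folds, plain shuffled folds otherwise; default 10 folds).  RMSE cells are
unweighted (study-size weighting is a defensible alternative; unweighted
was chosen and kept).  Held-out studies from countries absent in training
are predicted with u = 0.  Ties break toward the larger λ (more
shrinkage).  Fold assignment is a deterministic function of the seed.

**Sampling.**  The posterior is explored with a package-authored
Hamiltonian Monte Carlo sampler: leapfrog integration with a diagonal mass
matrix estimated during warmup, dual-averaging step-size adaptation toward
80% acceptance, and trajectory-length jitter.  Gradients are analytic
(multinomial-logit score plus prior terms; the Laplace prior uses its
subgradient at zero, corrected by the Metropolis step).  Defaults: 4
chains × 1000 warmup + 1000 kept draws.  Split-chain R-hat is computed per
parameter (via arviz); values above 1.1 are recorded as warnings in the
run log, not fatal errors, so long multi-fit pipelines complete and the
warning is auditable.  Fits are bit-reproducible for a fixed (seed,
chains) pair.

## Prediction and structural malaria rules

CSMFs are predicted for every country-year from a covariate panel that
must be complete over 2000–2019 (readers enforce this).  Covariates are
standardized on the training studies and the same transform is applied at
prediction time.

Malaria receives three corrections grounded in malaria epidemiology:
no malaria cause exists at ages 15–19; malaria is zero where programme
estimates report zero incidence (the freed mass is redistributed pro rata,
i.e. remaining causes are scaled by 1/(1−m)); and the malaria fraction at
5–14 is capped at the country-year's under-5 malaria share, with the
excess redistributed pro rata.  The degenerate all-malaria draw (m = 1)
redistributes uniformly, since pro-rata ratios are undefined there.
The cap is applied **before** single-cause squeezing (the ordering is a
package decision — the source material fixes the cap as post-hoc relative
to modelling but is silent relative to squeezing; the order is logged).

## Single-cause integration (squeezing)

Per country-year-group, with all quantities as fractions of the envelope:

* **Other-CMPN squeeze.**  Room = modelled other-CMPN − residual floor,
  where the floor is the median other-CMPN fraction across HQVR
  country-years (HQVR countries are assumed to have the minimum plausible
  shares of these nonspecific causes).  HIV, endemic measles and
  extrapulmonary TB pass unchanged if they fit, else all three are scaled
  by room/sum.  The floor is held fixed rather than scaled with the
  singles; scaling it too is a defensible alternative, rejected to keep
  the floor semantics ("minimum plausible share") exact.  If the floor
  exceeds the modelled fraction it is clipped to it.
* **LRI squeeze.**  Pulmonary TB fits into modelled LRI above the residual
  LRI floor, truncated to the available room.  Reported tuberculosis is
  pulmonary + extrapulmonary after scaling.  Age groups without an LRI
  cause (15–19) route pulmonary TB through the other-CMPN squeeze instead
  — a package interpretation, since the source material does not say where
  pulmonary TB goes when no LRI category exists.
* **Crisis capping.**  The raw crisis share is capped at the country-year
  maximum historically reported crisis fraction; the capped share goes to
  the cause matching the crisis nature (collective violence → collective
  violence, natural disaster → natural disasters, epidemic → measles; the
  mapping is a configurable table, and routing epidemic measles to the
  measles cause is an interpretation).  Crises inside the envelope scale
  the other causes by (1−f); crises outside it grow the envelope by the
  crisis deaths instead.
* Missing single-cause series mean zero deaths.  A zero envelope with
  nonzero single-cause deaths is an error for that cell; a zero envelope
  otherwise reports fractions with zero deaths.

Every partition sums exactly (to machine precision) to the composite it
divides, floors hold always, and the final vector is a simplex in every
draw.  Order of operations: malaria rules → other-CMPN squeeze → LRI
squeeze → crisis.

## Uncertainty propagation and aggregation

Three uncertainty sources — posterior draws, envelope draws, and Monte
Carlo draws from single-cause 95% intervals — are aligned by draw index
(envelope draws recycle cyclically if fewer than K; K defaults to 1000).
Single-cause draws use a quantile-matched lognormal when the interval's
lower bound is positive (mortality estimates are right-skewed), and a
normal anchored on (point, upper bound) truncated at zero when the
interval touches zero; a degenerate interval yields constant draws.

Draw k of every output uses draw k of every input, so per-draw
conservation (Σ cause deaths = envelope) is exact and correlations survive
into summaries.  Points are medians of draws and intervals the 2.5/97.5
percentiles, so the point always lies inside its interval.  Regional
deaths sum country draws per draw; regional fractions divide by regional
all-cause deaths (equivalently, the death-weighted mean of country
fractions); regional rates divide by person-years recovered from each
country's deaths/rate pair; the global estimate sums the regions.

Trends are summarised as the annual average rate of reduction,
AARR = 100·ln(rate_t1/rate_t2)/(t2−t1), positive for decline — the
log-ratio convention used for child-mortality reporting; applied to rates,
not counts, with natural disasters excluded for their idiosyncratic
spikes, and per-draw AARRs summarised into intervals.

## The synthetic-data generator

The generator emulates the five input streams under the sparse-data
regime the estimator targets: a default scenario of 30 countries (6 HQVR,
10 LMM, 14 HMM), 12 modelled countries contributing 4 studies per
age-sex group, study sizes Poisson with mean 185 deaths (the order of
magnitude typical of verbal-autopsy compilations at these ages), 20 years
(2000–2019), σ<sub>u</sub> = 0.07, covariates following stationary AR(1)
series (ρ = 0.9, standard-normal marginals), envelopes declining 2% per
year with lognormal draw noise (CV 5%), and single-cause series drawn as
smooth per-country fractions of the envelope.  Crises are injected with a
raw share (0.9) deliberately above the recorded cap (0.3), and a share of
HMM country-years get binding malaria caps, so capping and squeezing are
exercised by construction.

Because the generating CSMF surface is exactly the model's softmax
surface, passing recovery tests demonstrates correctness of inference and
plumbing, **not** robustness to model misspecification.  Real data differ
in ways the generator does not emulate: covariates with real semantics and
measurement error, non-representative study placement, overdispersed
counts, cause-misclassification in verbal autopsies, and envelope biases.
Conclusions about those failure modes require separate sensitivity work.

## Problem sizes for validation runs

Replicate studies use deliberately small scenarios so a full validation
pass runs in minutes on one CPU while leaving the estimand unbiased:

* coefficient coverage: 20 replicates, 8 countries × 4 studies, 4
  covariates at 50% sparsity, 2 chains × 400 warmup + 400 draws;
* CSMF error vs study size: 3 replicate pairs at mean study sizes 185 and
  1850;
* interval coverage: 200 replicates, 6 countries × 3 studies, 2 chains ×
  300 + 300;
* penalty-selection contract: grid {0.1, 1, 10}, 3 folds;
* squeezing oracle: 10 000 random simplexes against an independently
  coded scalar oracle (agreement required to 1e-12; observed at machine
  epsilon).

## Known limitations

* σ<sub>u</sub> is fixed, not estimated; misspecifying it miscalibrates
  the width of country-level intervals.
* HQVR pass-through carries envelope uncertainty only; sampling noise in
  the VR fractions themselves is not propagated.
* The hierarchical structure is a single country level; no time
  correlation in the random effects, so year-to-year CSMF changes within
  a country are driven entirely by covariates.
* Multi-country pooled studies are treated as single-country records.
* Crisis redistribution uses a single nature → cause mapping per run;
  real crisis accounting can split one event across causes.
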