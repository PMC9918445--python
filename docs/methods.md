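# Methods

## The estimand

Population-based stool screening (guaiac FOBT or the fecal
immunochemical test, FIT) detects colorectal cancer in its pre-clinical
detectable phase (PCDP).  Some screen-detected lesions would never have
surfaced clinically — non-progressive lesions, and progressive lesions in
subjects who die of other causes first.  Overdiagnosis is quantified as
the excess proportion

    (S(t) / U(t) − 1) × 100 %

where `S(t)` is the expected number of CRC diagnoses in a *digitally
screened twin* of an unscreened control population over follow-up `t`,
and `U(t)` is the control population's observed (or trend-imputed)
clinical CRC count.  The twin is built by learning the natural-history
parameters from a screened population and virtually re-screening the
control cohort with them.  Because the onset intensity learned from
screened data absorbs the non-progressive excess, `S(t)` exceeds the
control expectation, and the ratio isolates that excess without a
randomised trial.

## Natural-history model

A continuous-time Markov chain: Normal → PCDP → Clinical, with

* `lambda1` — onset intensity Normal → PCDP (per person-year),
* `lambda2` — progression intensity PCDP → Clinical; the mean sojourn
  time (MST) in the progressive PCDP is `1/lambda2`,
* `delta` — competing other-cause death hazard from every alive state
  (constant or piecewise-constant in time),
* an optional non-progressive PCDP state, entered from Normal with
  fraction `nonprog_fraction` of the onset intensity, with no exit other
  than death (its sojourn is by construction infinite),
* optional adenoma variants with a Normal → Adenoma → PCDP pathway
  (`lambda1a`, `lambda1b`), in which screen-detected adenomas are removed
  by polypectomy and the subject returns to Normal.

Intensities are time-homogeneous (single rates; age enters only through
the mortality schedule).  Transition probabilities are closed-form sums
of exponentials for the non-adenoma chains — with an explicit limit
branch when `|lambda2 − lambda1| < 1e-9·max(...)` to avoid the
equal-rate division by zero — and `scipy.linalg.expm` for the adenoma
chains; both routes agree to 1e-10 and are cross-checked in tests.

Subjects enter the study conditionally cancer-free after a `lead_in`
accumulation period (default 30 years; any value ≫ MST is equivalent).
For the progressive model this makes the PCDP prevalence at the first
screen the quasi-stationary `lambda1/lambda2` among the cancer-free, the
quantity a prevalence screen actually samples.  Under a constant death
hazard the lead-in conditioning is unaffected by mortality (the hazard is
uniform across alive states and cancels), so the lead-in is propagated
death-free.

## Screening layer and likelihood

A `ScreeningDesign` holds the screen times, follow-up horizon `T`,
cohort size, all-or-none participation (a subject is a lifelong
participant or refuser), and the probability `confirmation_rate` that a
positive test receives diagnostic confirmation.  Detection is an
independent Bernoulli per screen with probability `sens_crc` for a PCDP
occupant (`sens_adenoma` for an adenoma).  An unconfirmed positive
leaves the screening sequence; the cancer is counted in a dedicated
positive-unconfirmed mode if and when it surfaces clinically within
follow-up.

Detection-mode probabilities are computed exactly by propagating a
sub-distribution over the transient states between screens (matrix
product over mortality pieces) and applying the detection operator at
each screen.  Each participant realises exactly one of: prevalent-screen
detection, repeat-screen detection, interval cancer (clinical surfacing
between screens; by default the final round contributes no interval
window — surfacing after the last screen is booked as post-program,
configurable via `final_interval_years`), positive-unconfirmed cancer,
post-program cancer, or none by `T`.  Refusers realise clinical cancer
or not.  Both partitions sum to one to 1e-9 by construction.

The likelihood over an aggregate count table is the multinomial kernel
`sum(n_m log p_m)` per stratum with an implicit remainder category
(stratum size minus the observed cancer-mode counts).  Negative-screen
cells are not multinomial categories — one subject contributes several
negative screens — but their expectations are reproduced for the
goodness-of-fit table.  Cells absent from a dataset (e.g. the Funen
table has no positive-unconfirmed rows) are treated as missing, never as
zero.

## Estimation

`fit_mle` maximises the likelihood by Nelder–Mead on log-rates and
logit-sensitivities.  `fit_mcmc` is a random-walk Metropolis sampler on
the same transformed scale with inverse-gamma(0.001, 0.001) priors on
the intensities (placed on the rates themselves) and uniform(0, 1)
priors on the sensitivities; per-parameter proposal scales adapt toward
30 % acceptance during burn-in only, preserving detailed balance for the
retained draws.  Chains are bitwise-reproducible under a fixed seed;
equal-tailed credible intervals use linear-interpolation (type-7)
quantiles; effective sample sizes come from ArviZ.  Default chain
settings in the bundled analyses are 8 000 iterations with 3 000
burn-in, enough for stable 95 % quantiles of this 3-parameter posterior;
they are configuration values, not constants.

The sampler is hand-written rather than delegated to an ensemble
sampler because the single-site adaptive random-walk Metropolis with
these priors *is* the estimation algorithm under study.

## Digital twin

`predict_screened_twin` recreates `S(t)` as cohort-weighted sums of the
detection-mode expectations over rounds plus post-round clinical
surfacing: screen-detected (confirmed) + interval + surfaced
positive-unconfirmed + post-program + refuser-equivalent clinical cases.
For adenoma variants a polypectomy-offset component is added: removed
adenomas that would have surfaced as clinical CRC within follow-up
(probability taken from the unscreened chain at the removal time).  The
analytic `S(t)` is validated against the individual-level simulator to
within 3 Monte-Carlo standard errors.

When the control count must be imputed from a pre-screening baseline,
`project_control_incidence` applies a geometric secular trend (default
4.5 %/year, the reported background growth of CRC incidence in the
service-screening setting).

`competing_risk_adjustment` handles the asymmetry between `S` and a
death-free control expectation: screen-detected cases whose other-cause
death precedes their latent surfacing are retained in `S` (they are
overdiagnosed by definition), so `U` is multiplied by the depletion
factor `kappa = P(clinical by T | delta) / P(clinical by T | delta=0)`
from the no-screening chain.  The adjustment is the identity at
`delta ≡ 0` and raises the percentage monotonically in `delta`.  The
published adjustment formula is not available; this definition is the
package's own, satisfies the oracle contracts above, and is flagged in
every report.

Uncertainty: `overdiagnosis_interval` pushes posterior draws through the
twin prediction (control count held fixed by default) and takes
equal-tailed quantiles of the resulting percentages.

## Synthetic cohorts

`synthetic_cohort` draws full latent histories per subject (exponential
waiting times, a non-progressive label with default fraction 0.05, an
independent death time), applies the design (all-or-none participation,
per-screen Bernoulli detection, confirmation, polypectomy with redrawn
downstream history), and tallies the same detection modes the analytic
layer computes.  A subject is labelled overdiagnosed iff screen-detected
and (non-progressive or death precedes latent surfacing).  The default
scenario emulates a biennial FIT service program: participation 0.70,
FIT sensitivity 0.80, `lambda1 = 0.00141`, MST ≈ 2.6 y, `delta = 0.01`
per person-year (a typical all-cause magnitude for ages 50–69; not an
estimate from any dataset), screens offered biennially throughout an
11-year window.

The simulator shares the generative assumptions of the analytic model
(exponential sojourns, homogeneous rates, all-or-none attendance,
independent per-screen misses).  Passing tests therefore demonstrate the
internal consistency and statistical calibration of the pipeline — not
robustness to features real data possess and the model does not:
age-dependent onset, correlated test results for the same lesion,
partial attendance patterns, or stage structure.  The non-progressive
fraction is deliberately unknown to the estimation stage (fits use the
progressive model); recovering the implanted excess through the twin
comparison, rather than through the fraction itself, is exactly the
mechanism the analysis relies on.

## Bundled study inputs and reconstructed designs

The two gFOBT trials (Nottingham/UK, Funen/Denmark) ship as verbatim
observed and published-predicted detection-mode tables, with published
parameter estimates and 95 % intervals.  The trials' exact round
structure, ascertainment windows, and confirmation compliance are not
published; the bundled designs are this package's reconstruction —
UK: three biennial screens, T = 8.5 y, participation 44 865/75 280,
confirmation 0.80; Funen: four biennial screens, T = 10.0 y,
participation 20 672/30 762, confirmation 1.0; `delta = 0` in the trial
fits (the published predicted cells reproduce death-free arithmetic
exactly).  Users can override every element.

Under these reconstructions the refit reproduces the published
parameters only partially (e.g. the UK progression rate falls inside its
published interval; the onset rate sits a few percent above its upper
bound).  The residual is structural: the observed ratio of interval
cancers to repeat-screen detections, combined with independent
per-screen misses, implies a shorter sojourn than the published fit,
suggesting the original likelihood treats repeat-screen detectability
differently.  The refit is therefore reported parameter-by-parameter
against the published intervals rather than asserted wholesale.

## Numerical choices

* Equal-rate degeneracy: analytic limit branch at relative tolerance 1e-9.
* Transition matrices clipped to [0, 1] and row-renormalised before the
  1e-10 row-sum check (guards expm round-off only).
* Pearson chi-square: no cell pooling, no continuity correction;
  degrees of freedom = cells − fitted parameters (reproduces the
  published 6 and 4 d.f. for the 9- and 7-cell tables).
* Quantiles: numpy type-7 (linear interpolation) throughout.
* Mode probabilities outside [0, 1] abort with diagnostics (they signal
  a rate/design inconsistency, not a numerical issue).
* A count on a zero-probability mode yields −inf log-likelihood with a
  warning, so optimisers treat it as a rejected point.

## Known limitations

* Time-homogeneous intensities; age structure only via the mortality
  schedule.
* The twin's mean follow-up is a common fixed horizon per cohort, not
  per-subject censoring.
* The polypectomy offset ignores re-accrual double counting (a subject
  whose removed adenoma is counted as offset may also develop and be
  counted for a second lesion; the overlap is second-order).
* The competing-risk adjustment and the positive-unconfirmed handling
  are this package's definitions of under-specified published
  procedures; both are flagged in outputs.
* The published service-program headline percentages depend on a
  non-public registry and are not desk-reproducible; the synthetic-twin
  recovery experiment is the substitute validity check.
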