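# Methods

## Scope and model

`opeair` models one analysis chain: passive-sampler masses → censored air
concentrations → descriptive statistics per microenvironment → Monte Carlo
daily inhalation intake per age group → hazard-quotient / carcinogenic-risk
screening → contribution-to-variance sensitivity. Only the inhalation route
is modeled; dermal contact, dust ingestion and diet are out of scope, so
the screening indices are a lower bound on aggregate exposure.

Key assumptions:

- **Linear-phase passive sampling.** Accumulated mass divided by
  (rate × duration) gives a time-averaged concentration; uptake kinetics,
  temperature and turbulence corrections are folded into the fixed
  per-congener effective sampling rate. No recovery correction is applied.
- **Static time-activity.** Each age group has fixed day fractions (IEF)
  per microenvironment; within a Monte Carlo trial one (IR, BW) pair is
  shared across congeners and environments because respiration rate and
  body weight belong to the person, not the pollutant.
- **Full absorption.** The absorbed fraction defaults to 1.0 (configurable
  in (0, 1]).

## Synthetic concentration generator

Indoor OPE concentrations are right-skewed in every summary the default
profile carries (mean > median throughout), so site concentrations are
drawn from a lognormal moment-matched to a target (mean, median) pair:
`mu = ln(median)`, `sigma = sqrt(2 ln(mean/median))`. A mean equal to the
median degenerates to a point mass; mean < median is rejected.

Non-detects have two mechanisms, because left-censoring alone cannot push a
detection frequency below the lognormal CDF at the MDL:

1. values drawn below the MDL are flagged `below_mdl` (their true draw is
   retained in the table, as the analysis layer must not rely on it);
2. an independent per-site "absent" probability yields `not_detected`
   records (value 0), modeling congeners genuinely missing from a site's
   materials.

`calibrate_censoring` places the MDL at the lognormal quantile matching the
target undetected fraction, clipped into the plausible MDL band
(0.022–1.21 ng/m³ by default); any censoring shortfall left by clipping is
assigned to the absent probability. Low-detection congeners (detection
frequency below ~10%) are therefore reproduced mostly through absence.

The default profile pools homes, offices and dormitories into one `indoor`
target block (that is how the summary constants are published) and rescales
each environment's per-congener means and medians by the ratio of that
environment's total mean concentration (42.12 / 36.02 / 18.14 ng/m³) to the
pooled total (38.62 ng/m³), keeping the congener mix fixed while the totals
track the per-environment levels. Cars have their own block
(total 264.89 ng/m³). Where a published median sits below the MDL (TBP,
TBEP, TPEP, TCP indoors) the generator target median is set to mean/3, a
strong-skew package default. Site counts default to 46 homes, 12 offices,
6 dormitories, 60 cars.

One global integer seed is expanded into independent per-spec substreams
(`numpy.random.SeedSequence.spawn`), so tables are reproducible as a whole
while congeners and environments stay statistically independent.

**What the generator does not emulate:** temporal/seasonal dynamics,
inter-congener correlation structure (congeners are drawn independently, so
correlation screens on synthetic data hover near zero), spatial clustering
within an environment, and analytical measurement error as a separate noise
layer. Passing tests on synthetic tables therefore validate the pipeline's
arithmetic and statistical conventions, not field behaviour of real
campaigns.

## Censored statistics

- **Substitution policies** (applied before any statistic):
  `nd_zero_half_mdl` (default: `not_detected` → 0, `below_mdl` → MDL/2),
  `zero_all`, `mdl_sqrt2` (both → MDL/√2), `detected_only`. The default
  distinguishes the two non-detect kinds because a below-MDL record is
  evidence of presence at low level while a non-detection is evidence of
  absence; it keeps low-detection congeners from inflating means.
- **Percentile convention:** linear interpolation between closest ranks
  (Hyndman–Fan type 7, numpy default), pinned for reproducibility.
- **Detection frequency:** percent of records flagged `detected`; both
  non-detect kinds count as undetected.
- **Totals and composition:** per-site totals sum substituted congener
  values; composition shares are each congener's mean as a percent of the
  summed means. Congeners enter totals/composition only above a 10%
  detection-frequency threshold — this threshold reproduces the published
  inclusion pattern in both blocks (two congeners dropped indoors at <3%
  detection, only one dropped in cars at 5% while an 11.7% congener stays).
  The correlation screen uses a stricter 25% threshold, since rank
  correlations computed on mostly-substituted vectors reflect the
  substitution constant, not the data.
- **Group comparison:** one-way ANOVA on per-site totals across
  microenvironments plus pairwise Welch t-tests; an optional log transform
  is off by default. Groups with fewer than 2 sites or zero variance are
  flagged degenerate rather than tested.

## Monte Carlo engine

Per trial: draw IR and BW from the group's distributions (normal truncated
at zero by default; point and lognormal kinds available), draw a
concentration per (environment, congener), form
`EDI = Σ_env C · IEF / BW · IR · absorption`. Concentration sampling modes:

- `empirical` (default): resample substituted site-level values with
  replacement — no distributional commitment beyond the observed table;
- `lognormal`: moment-matched parametric fit to the substituted pool, for
  smoother tails at small site counts.

The total-OPE distribution sums congener draws *within* each trial; summary
statistics of the total are computed from those summed draws, which is why
the total's reported mean can differ at the last digit from the sum of
per-congener rounded means. Default 1000 trials, matching common practice
for screening assessments; acceptance-style convergence checks use 10⁵.

## Risk characterization

HQ = EDI/RfD and CR = EDI × 10⁻⁶ × CSF (the 10⁻⁶ bridges ng to mg exactly
once), computed from mean EDIs; per-group totals sum only congeners with
the relevant toxicity value (six carry an RfD, four a CSF in the default
registry). Flags trip above HQ = 1 and CR = 10⁻⁶. Congeners without a
benchmark are reported as unavailable (NaN), never as zero.

One internal inconsistency in the published screening table is worth
noting: the children TCPP cell prints 7.71 × 10⁻⁴ although the published
children mean TCPP intake (7.55 ng/kg/day) over the 10,000 ng/kg/day RfD
gives 7.55 × 10⁻⁴. The package reproduces the equation value.

## Sensitivity

Contribution to variance is the normalized squared Spearman rank
correlation between each input factor's draws (per-environment total
concentration, IR, BW) and the EDI draws — the convention of spreadsheet
Monte Carlo tools. Signs are discarded (BW enters inversely and still
contributes variance); contributions are non-negative and sum to 100. The
metric is invariant under strictly monotone rescaling of any factor. A
zero-variance factor contributes 0 with a warning. The decomposition is
exact only for monotone input–output relations; it is a screening metric,
not a variance-based Sobol analysis, and is swappable behind the same
interface.

On the shipped defaults the home concentration dominates every group's
intake variance (infants/toddlers are home-only by construction; adults
weight home 0.6 vs car 0.05), and IR/BW contribute ~10% for infants. A
car-dominated regime for school-age groups requires in-car levels high
enough that the small in-car time fraction still carries the weighted
variance; the test suite constructs that regime explicitly.

## Exposure parameter defaults

IR/BW distributions and IEF fractions per age group are package defaults —
plausible values for a Chinese urban population with normal spread — **not**
values from any published appendix: infants (IR 7.5 ± 1.0 m³/day,
BW 7.8 ± 1.2 kg) and toddlers are exposed at home only (IEF 0.875);
children and adolescents add a study office and car time; adults weight
home 0.60, office 0.30, car 0.05. Because the published per-group intake
table cannot be reproduced without the original appendix parameters, the
default profile ships those published mean intakes as `reference_edi`
inputs, and risk-table validation runs on them directly.

## Numerical and degenerate-input choices

- Values exactly at the MDL count as detected (inclusive convention).
- Blank MDLs use the sample (n−1) standard deviation; a single blank has
  sd 0; clean blanks fall back to IDL/2.
- Zero or NaN instrument readings are `not_detected`; negative
  concentrations are rejected everywhere.
- Spearman pairs with fewer than 3 complete observations are reported NaN,
  not dropped silently.
- Seeds derived from the user seed stay below 2³¹; identical seed + config
  give byte-identical CSV artifacts (manifests exclude timestamps).

## Problem sizes

The default test and acceptance runs use the campaign-scale site counts
(124 sites), 1000-trial Monte Carlo for end-to-end runs, 10⁵ trials for
convergence and sensitivity properties, and 10⁶ draws for generator
parameter recovery — sizes at which the stochastic checks are stable to
well under their asserted tolerances.

## Known limitations

- Single route (inhalation), single season, static time-activity.
- Congener independence in the generator: correlation-screen results on
  synthetic data are null by construction.
- The lognormal family is an assumption of the generator, chosen for its
  universal mean>median pattern in the shipped constants, not an inference
  about any particular dataset; the generator interface accepts alternative
  laws.
- Registry sampling rates and per-congener detection limits are nominal
  values inside published plausibility bands, not compound-certified
  calibration constants.
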