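# Methods

## Model and assumptions

The package implements the standard chronic dietary exposure model for a
single food commodity:

EDI = CF·IR·EF·ED/(BW·AT), in μg/kg body weight/day,

followed by hazard-quotient (HQ = EDI/RfD), hazard-index (HI = ΣHQ),
carcinogenic-risk (CR = EDI[mg]·SF) and total-carcinogenic-risk
(TCR = ΣCR) characterization. The model is multiplicative and assumes:

* exposure through one commodity only (rice), with no speciation
  adjustment (e.g., total As is treated as the toxicologically relevant
  quantity — conservative for inorganic-As-driven risk);
* linear, no-threshold dose–response for carcinogens (slope factors);
* independence of concentration, intake rate and body weight;
* a single national concentration distribution for all consumer groups,
  so between-group differences are driven entirely by the IR/BW ratio.

Units are μg/kg (food), μg/kg bw/day (doses), kg/day (IR), kg (BW). The
single μg→mg conversion lives inside the CR operation, because slope
factors are conventionally quoted per mg/kg bw/day while reference doses
here are per μg/kg bw/day. The bundled slope factors are As 1.5, Cd 6.1,
Pb 8.5×10⁻³ (mg/kg bw/day)⁻¹: published SF listings for As and Cd vary by
three orders of magnitude across sources depending on an implicit
10⁻³ scaling, and the bundled values are the ones consistent with the
reference mean risks this table is meant to reproduce (0.250 μg/kg bw/day
of As → CR 3.75×10⁻⁴). The discrepancy is flagged here deliberately;
users substituting their own table should check the implied CR magnitude.

## Concentration model and moment matching

Survey concentrations are modelled as lognormal, the empirically standard
shape for contaminant residues. Published summaries give a geometric mean
(GM) with an *arithmetic* SD — SD > GM for several cells rules out a
geometric SD. Moment matching therefore sets

* μ = ln(GM), since the GM of a lognormal equals its median e^μ, and
* σ from sd² = (e^{σ²}−1)·e^{2μ+σ²}. Substituting t = e^{σ²} gives
  t(t−1) = (sd/GM)², a quadratic with the single admissible root
  t = (1+√(1+4(sd/GM)²))/2. The right side of the moment identity is
  strictly increasing in σ, so this closed form is the unique solution
  (the test suite cross-checks it against an independent bisection).
  sd = 0 degenerates to a point mass at the GM.

Optional truncation to the published (min, max) range uses rejection
sampling. It is **off by default**: clipping perturbs the matched moments,
and the documented contract is moment recovery, not range containment.

## Synthetic survey generator

The generator emulates a stratified market survey: for each stratum ×
element cell it draws n iid values from the fitted lognormal, attaching
the stratum label and re-using sample ids across elements (one physical
sample, four measurements). What it deliberately does **not** emulate:
within-sample correlation between elements, spatial structure inside a
province, measurement error, or values censored at detection limits (all
published minima exceed the method detection limits, so no substitution
machinery is provided). Passing tests on synthetic data therefore
demonstrate correctness of the statistical pipeline under the stated
model, not robustness to real-data artefacts such as correlated
contamination or censoring.

Randomness uses numpy's `SeedSequence` with entropy
(seed, crc32(stratum), crc32(element)): one independent stream per cell,
so adding strata to a spec never reshuffles existing draws, and a single
integer seed reproduces the whole dataset.

A note on recovery precision: for heavy-tailed cells (arithmetic CV > 1
the fitted σ reaches 0.83–0.93), the sample SD of 10,000 draws has a
relative standard error of 3–4% (distribution kurtosis 40–70), so
single-seed SD recovery at that draw count is only reproducible to about
±10%; GM recovery, driven by the log-scale mean, is precise to well under
1%. The generator property test therefore checks convergence at 100,000
draws per cell.

## Exposure simulation

`edi_mcs` draws CF, IR and BW on three independent substreams spawned
from (seed, crc32(element|group)) and evaluates the intake ratio per
iteration; 10,000 iterations by default (fewer than 1,000 triggers a
warning because P99.9 then rests on a handful of order statistics).
Two concentration modes exist because published workflows are split on
the point: `fitted` (default) samples the lognormal fitted to the pooled
summary; `resample` bootstraps the observed values uniformly. Percentiles
use sorted draws with linear interpolation between order statistics
(Hyndman–Fan type 7, numpy's default), chosen for cross-implementation
reproducibility; commercial MC tools do not document their rule.

Time constants default to EF = 365 days/yr and AT = ED·365 days, making
EF·ED/AT = 1 — the convention under which chronic intake reduces to
CF·IR/BW — and are configurable per group.

## Population parameters

Per-group intake rates and body weights for Nepal are **assumptions**, not
survey values (the underlying dietary references are not reproduced in the
bundled data): the national adult group uses IR ~ lognormal(mean 0.32
kg/day, CV 0.20) — consistent with ~3.65 Mt of rice consumed annually by
~29 M people — and BW ~ lognormal(mean 62 kg, CV 0.15), giving
E[IR]·E[1/BW] ≈ 5.3×10⁻³ kg/kg bw/day. Province, region and
vulnerable-group entries scale this ratio following the reported exposure
orderings (Madhesh highest among provinces; Terai > Rural > Mountain >
Urban > Hill; preschoolers > toddlers > children > women). IR and BW are
sampled independently; no joint model is claimed. Any real assessment
should replace `population_groups.yaml` with measured distributions.

## Risk characterization conventions

* All threshold comparisons are strict; boundary values (HQ = 1,
  CR = 10⁻⁶ or 10⁻⁴) classify as compliant/acceptable.
* HQ/CR/HI/TCR percentiles are always computed from transformed draw
  vectors. For monotone per-element transforms this equals transforming
  percentiles, but the draw-wise contract is what makes HI/TCR percentiles
  correct (quantiles of sums are not sums of quantiles).
* Contribution shares divide per-element means by the family total and
  sum to 1 by construction.
* MAC screening uses strict ">" against the FAO/WHO limit: "below the
  maximum allowable concentration" treats equality as compliant.
* Elements without a slope factor (Cu here) are excluded from the
  carcinogenic family with a logged notice, never silently.

## Numerical and degenerate-input choices

* σ = 0 (or sd → 0) lognormals are handled as point masses throughout;
  with fully degenerate inputs the MC engine reproduces the closed-form
  intake exactly, percentile columns included.
* Rejection sampling (range truncation, positivity of IR/BW draws) caps
  at 1000 rounds and raises rather than looping forever on pathological
  bounds; truncation bounds are validated to admit nonzero mass.
* Geometric means require strictly positive data; a zero concentration is
  a hard error naming the sample rather than a silent drop or a
  detection-limit substitution.
* Sample SDs use ddof = 1; singleton strata report SD 0.

## Problem sizes

Default analysis sizes — 170 samples × 4 elements per synthetic survey,
10,000 Monte Carlo iterations per element × group, 10,000 draws per cell
for recovery checks, 100,000 for the generator convergence test — were
chosen to match the reference workflow's simulation depth while keeping
the full suite and the acceptance script comfortably fast on one CPU.

## Known limitations

* Lognormality is assumed, not tested, for user-supplied data; the
  summary-fitting path will happily moment-match a distribution that fits
  real data poorly in the tails, and P99.9 estimates inherit that risk.
* The national-concentration convention means province-level risk
  differences reflect diet only; provinces with genuinely hotter rice
  (e.g., a high-As irrigation area) would be understated.
* No sensitivity or variance-decomposition analysis, no correlated-input
  sampling, and no ANOVA-style between-stratum inference are provided.
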