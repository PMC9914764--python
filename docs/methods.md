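# Methods

## The experiment and its model

The package analyses a storage experiment on fresh oyster mushrooms
(*Pleurotus ostreatus*): shelf-life in days as a function of two
factors, **packaging** (none, vented polyethylene bag "PBP",
polypropylene vacuum bag "VBP") and the **rate** of agro-industrial
residue (olive pruning residue, spent coffee grounds, or their
combination) blended into the wheat-straw growing substrate.  The
design is a replicated 3x3 grid: nine distinct factor combinations
plus four extra replicates of the unpacked, zero-residue control, 13
runs in all.  The five control replicates carry the pure-error
information (4 df) that makes a lack-of-fit test possible.

Shelf-life is modelled as a full second-order polynomial in the coded
factors,

    y = b0 + b1*x1 + b2*x2 + b12*x1*x2 + b11*x1^2 + b22*x2^2,

fitted by ordinary least squares (p = 6 parameters, 7 residual df).
The surface is used three ways: diagnostics (ANOVA, lack of fit,
R^2 family, PRESS, adequate precision), prediction at arbitrary
in-range settings, and maximization over the admissible factor box to
recommend storage conditions.

## Factor coding

Both factors are three-level.  Under the default *level* coding the
ordered levels map to -1/0/+1; for the continuous rate factor,
intermediate values interpolate linearly between adjacent levels, so
the coded axis is a monotone piecewise-linear warp of the actual axis
(the rate levels 0/0.3/0.7 are not equally spaced in actual units, but
are on the coded axis).  *Range* coding — the affine map
(v − midrange)/halfrange — is available as an option.

Two deliberate conventions deserve a note:

1. **Packaging level order.**  For a three-level factor the span of
   {1, x1, x1^2} contains every function of the factor, so fitted
   values, all sums of squares, leverages, PRESS and the optima are
   invariant to which level gets which code — except through the
   single interaction column x1*x2.  This package assigns the codes in
   lexicographic label order (NONE, PBP, VBP → -1, 0, +1), the
   ordering convention mainstream design-of-experiments software
   applies to categoric factors.  Under this convention the model
   summaries computed here line up, to print rounding, with the
   reference summaries shipped with the bundled dataset; an ordering
   by physical oxygen availability (VBP, NONE, PBP) changes only the
   interaction-term row and, slightly, the fitted values.
2. **Prediction at unseen rates.**  The model is a quadratic *on the
   coded scale*; predictions between levels go through the coding
   warp rather than through a re-expressed raw-rate polynomial.  The
   two agree exactly at the three levels and differ by at most a few
   hundredths of a day between them; working on the coded scale keeps
   prediction, optimization and the fit itself on one consistent
   axis.  Packaging is never interpolated: a "half-vacuum" bag has no
   physical meaning.

## ANOVA, lack of fit, PRESS

Per-term tests are partial (Type III): SS_term is the increase in
residual SS when that column is dropped from the full model
(sequential/Type I SS are available behind a flag).  The residual is
decomposed into pure error (within-replicate scatter, model-free) and
lack of fit; their mean-square ratio is referred to F(3, 4).  PRESS
uses the leverage shortcut sum(e_i/(1-h_ii))^2, which equals explicit
leave-one-out refitting for linear least squares — the test suite
verifies the identity against brute-force refits.  Predicted R^2 is
1 − PRESS/SS_total; adequate precision is the fitted-value range over
sqrt(p·MS_res/n).

Per-term rows for the linear and interaction terms are
coding-dependent and are reported but not certified against the
reference summaries; the model/residual/lack-of-fit/pure-error rows,
the R^2 family and PRESS are the validated surface.

## Optimization

Packaging is enumerated.  Within each level the response is a 1-D
quadratic in coded rate, maximized in closed form (interior vertex
when curvature is negative and the vertex is in bounds, else the
better endpoint) and verified against a dense grid scan (default step
0.001 in actual rate).  Ties between packaging levels break toward
the level with the larger desirability integral over the rate
interval.  Desirability is the standard Derringer linear ramp scaled
to the surface's span over the admissible box.  Reported rates are
rounded to 3 decimals.

A caveat documented in `reference.py`: the reference optima shipped
with the dataset for the OLPR and SCG schemes (e.g. 9.18 days at rate
0.289 for the ambient OLPR response) exceed the maxima of the
corresponding reference predicted surfaces (~8.82 days) and cannot be
reproduced by any least-squares fit of the shipped tables; the
`reproduce` report compares packaging level only for the optima.  The
combined-residue optima do reproduce (26.30 vs 26.26 days at 4 °C).

## TMC classification

Total microbial count (log10 CFU/g) is classified into four bands:
LOW < 5.0, MEDIUM 5.0–6.5, HIGH 6.5–8.05, VERY_HIGH > 8.05.  The
quoted band definitions leave one-decimal gaps (5.0–5.1, 8.0–8.1);
the edges close them so every stored reading classifies uniquely:
5.0 belongs to MEDIUM (the assignment under which the recomputed
band fractions match the reference percentages — 83.3 % of packed
samples LOW on ambient day 3, 77.8 %/88.9 % on day 4), and the
HIGH/VERY_HIGH edge sits at the 8.0/8.1 midpoint.  Consumability uses
the separate threshold 8.1: a series is consumable through the last
observed day before it first exceeds 8.1 log CFU/g, and a later dip
below the threshold does not reopen the window.

## Quality metrics

Weight loss is 100·(W0−Wt)/W0.  The veil metric is implemented
verbatim as 100·(Vt−Vf)/Vt, which reads as the percentage of veils
still *closed*; because the acceptability rule in the source material
treats readings at or above 70 % as deterioration, records carry a
`veil_metric_convention` flag and expose the complementary
`veil_opened_pct`.  Acceptability: weight loss ≤ 5 % (inclusive,
"around 5 %"), firmness ≥ 3.0 on the 1–9 instrumented score, veil
metric < 70 %.  Firmness is carried as the 1–9 score; the mapping
from raw newton readings to the score is upstream of this package.

## Synthetic generators

`simulate_design` draws responses as a known quadratic surface plus
i.i.d. Gaussian noise; the default noise SD (0.16 days) matches the
replicate scatter of the shipped data (pure-error MS ≈ 0.025 days²).
`simulate_tmc` draws a linear log-CFU trend (defaults: intercept 3.0,
slope 1.0/day, the unpacked-ambient regime) plus noise, then projects
onto non-decreasing sequences by cumulative maximum and rounds to one
decimal — noise before projection, so plateaus appear as in the real
tables.  `simulate_quality` decays weight geometrically (3 %/day, the
unpacked-ambient rate implied by ~26 % loss over 10 days), firmness
linearly (1.35/day, floored at the scale minimum), and opens veils by
binomial increments.  What the generators do *not* emulate: correlated
noise between replicate runs, day-to-day measurement drift, the
saturating late-storage microbial kinetics, or any mechanistic growth
model — so green tests certify the statistical machinery, not the
biology of real storage data.

One seeded `numpy` generator is threaded through all draws; no global
random state.

## Numerical choices

OLS is solved by QR with an explicit rank check that names collinear
columns; the normal-equations solve exists only as a test oracle.
Leverages are squared row norms of thin Q.  p-values come from the F
survival function and render as `<0.0001` below 4-decimal resolution.
A leverage of 1 makes PRESS undefined and raises.  Zero residual MS
flags F as infinite with p = 0.  Designs without replicates omit the
lack-of-fit rows (explicitly flagged) and `lack_of_fit` raises.

Golden-test tolerances live in `src/shelfrsm/reference.py`, each with
a propagation-based rationale: the shipped responses are printed to
0.1 day, which bounds how well residual-scale statistics (residual SS
~0.2 days², PRESS, lack-of-fit F) can be reproduced, while
model-scale quantities reproduce to well under a percent.

## Problem sizes

Everything runs at desk scale: 13-run fits, 27-series TMC tables, a
1000-replicate Monte-Carlo calibration of the lack-of-fit test (null
rejection rate 5 % ± 2 %), and 100–300-replicate parameter-recovery
checks.  The full suite and the reproduction script each finish in
well under a minute.

## Known limitations

* Per-term SS for linear/interaction terms depend on the coding
  convention; only the coding-invariant block is certified.
* The replicated point sits at a corner of the grid, not the centre,
  so pure error is estimated under the control condition only; the
  lack-of-fit test assumes homoscedasticity across the grid.
* Packaging is modelled on a numeric code with 1 df, which imposes an
  ordering assumption; a 2-df nominal parameterization would change
  the per-term table (but not the fitted surface, which saturates the
  factor anyway).
* The quality module carries single records; it does not model
  time-series dependence between storage days.
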