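# shelfrsm

Response-surface shelf-life analysis for fresh mushrooms stored under
different packaging and substrate treatments.

Fresh oyster mushrooms (*Pleurotus ostreatus*) spoil within days:
they lose water, soften, and accumulate microbial load.  Growers and
food scientists probe how long a batch stays marketable as a function
of **packaging** (none, vented polyethylene bag, polypropylene vacuum
bag) and the **substrate** the mushrooms were grown on — here, the
rate of agro-industrial residue (olive pruning residue, spent coffee
grounds, or both) blended into wheat straw.  `shelfrsm` implements the
standard response-surface workflow for such experiments:

* a replicated 3x3 two-factor design (13 runs, pure-error df = 4);
* the second-order polynomial fit by ordinary least squares,

  `y = b0 + b1 x1 + b2 x2 + b12 x1 x2 + b11 x1^2 + b22 x2^2`,

  with coded factors `x1` (packaging) and `x2` (residue rate);
* full ANOVA diagnostics: partial-F per-term tests, the lack-of-fit /
  pure-error decomposition, R^2 / adjusted R^2 / predicted R^2, PRESS
  (via the leave-one-out leverage identity), adequate precision;
* maximization of the fitted surface over the admissible factor box,
  with a Derringer desirability ramp;
* total-microbial-count (TMC) classification into contamination bands
  (low < 5.0 log CFU/g, medium 5.0-6.5, high 6.5-8.05, very high
  above), with per-day summaries and consumability windows at the
  8.1 log CFU/g threshold;
* physicochemical quality metrics (weight loss, veil opening,
  firmness) and consumer-acceptability rules;
* seeded synthetic generators for every data stream, used throughout
  the test suite.

A complete worked dataset — six measured 13-run designs and two
27-series TMC tables from a published storage experiment — ships with
the package, along with its reference summaries.

## Worked example

```python
import shelfrsm as s

design = s.load_shelf_life("OLPR", "ambient")   # wheat straw x olive pruning residue, ~20 C
fit = s.fit_quadratic(design)
report = s.anova_table(design, fit)
print(f"R2={report.r2:.4f} adjR2={report.adj_r2:.4f} predR2={report.pred_r2:.4f}")
print(f"model F={report.row('Model').F:.2f}  lack-of-fit F={report.row('LackOfFit').F:.2f}")
print(f"PRESS={report.press:.2f}  adequate precision={report.adeq_precision:.2f}")

opt = s.optimize_response(fit.model)
print(f"optimum: {opt.packaging}, rate={opt.rate}, predicted {opt.predicted:.2f} days")

packed = s.level_summary(s.load_tmc("ambient"), day=3, packaging=("PBP", "VBP"))
print("day-3 packed LOW fraction:", round(packed["fractions"]["LOW"], 4))
```

prints

```
R2=0.9833 adjR2=0.9713 predR2=0.8742
model F=82.34  lack-of-fit F=15.23
PRESS=9.35  adequate precision=20.31
optimum: PBP, rate=0.329, predicted 8.82 days
day-3 packed LOW fraction: 0.8333
```

Reading the numbers: the quadratic explains 98.3 % of the shelf-life
variation across the 13 runs (97.1 % adjusted for the 6 parameters),
and cross-validation (predicted R^2 0.87 from PRESS 9.35 days^2)
says the surface generalizes beyond the fitted runs.  The overall
model F of 82 on (5, 7) df is overwhelming evidence the factors
matter.  The fitted surface is maximized by the vented plastic bag at
a residue rate of 0.33, predicting 8.8 days of shelf-life — almost
three times the unpacked wheat-straw control (3.0 days).  On storage
day 3, 15 of the 18 packed sample groups (83.3 %) are still in the
low-contamination band, while every unpacked group has already turned
highly contaminated.

The same workflow is available from the shell:

```sh
shelfrsm anova --scheme OLPR --temperature ambient
shelfrsm optimize --scheme OLPR_SCG --temperature cold_4C
shelfrsm tmc-summary --day 3 --packaging PBP --packaging VBP
shelfrsm reproduce          # recompute all six fits vs the pinned reference values
```

## Layout

```
src/shelfrsm/
  design.py     factors, coding, the 13-run layout, replicate groups
  model.py      OLS quadratic fit, prediction, model JSON
  anova.py      ANOVA / lack of fit / PRESS / R2 family
  optimize.py   surface maximization, desirability, grid export
  tmc.py        contamination bands, summaries, consumability
  quality.py    weight loss, veil metric, acceptability
  synthetic.py  seeded generators for designs, TMC, quality series
  datasets.py   bundled dataset loaders (see data/NOTES.md)
  reference.py  pinned reference summaries + tolerance rationale
  io.py         CSV/JSON schemas, pipeline driver, contrasts
  cli.py        `shelfrsm` command-line interface
docs/methods.md   model, conventions, generators, limitations
```
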