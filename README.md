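# ufa — univariate flagging for interpretable risk prediction

`ufa` finds, for each continuous variable in a tabular dataset with a
binary outcome, the cutpoints beyond which the outcome is significantly
enriched or depleted — and turns those cutpoints into simple, readable
risk flags and classifiers. It is aimed at settings (clinical tables,
environmental early-warning data) where practitioners reason about one
measurement at a time, records are riddled with missing values, and a
rule like *"body temperature below 36 °C doubles the death rate"* is
worth more than an opaque score.

## The statistic

For a variable *x* and binary outcome *y*, the baseline group is the
interquartile range of *x* (observations with *x* between the 25th and
75th percentile), with outcome rate *p*<sub>iqr</sub> over
*n*<sub>iqr</sub> observations. For a candidate cut *c* below the
median, the tail group {*x* < *c*} has rate *p*<sub>out</sub> over
*n*<sub>out</sub> observations, and the two rates are compared with a
pooled two-sample binomial-proportion statistic

```
p_wa = (p_iqr·n_iqr + p_out·n_out) / (n_iqr + n_out)
Z    = (p_out − p_iqr) / sqrt( p_wa·(1 − p_wa)·(1/n_iqr + 1/n_out) )
```

Candidate cuts are the interior breakpoints of 50 equal-length segments
between the median and the (trimmed) extremum; the five most extreme
values are trimmed first so every tail keeps a minimum level of
support. The cut maximising |Z| is kept if |Z| ≥ 2.576 (two-sided
p = 0.01). Searching below and above the median independently yields up
to two thresholds per variable; |Z| itself arbitrates the trade-off
between tail purity and tail support. Observations missing a variable
are simply excluded from that variable's search — no imputation.

Each significant threshold becomes a binary flag (raised when a value
lies strictly beyond the cut; never raised for a missing value). On top
of the flags:

* **N-UFA** — each observation is reduced to (n_high, n_low), its counts
  of high-risk and low-risk flags, and classified by a linear boundary
  in that plane (closed-form Fisher discriminant by default, exact
  0-1-loss minimisation optionally).
* **RF-UFA** — the full 0/1 flag matrix feeds a random forest as dummy
  features.
* **Stratification** — conjunctions of flags report support, outcome
  rate and relative risk, for rare-event triage.

## Worked example

```python
from ufa import GeneratorConfig, PlantedThresholdSpec, detect_thresholds, generate

config = GeneratorConfig(
    n=2000, seed=42,
    planted=(PlantedThresholdSpec("temperature", "below",
                                  tail_rate=0.8, cut_quantile=0.2),),
    n_noise=3, base_rate=0.2,
)
data, truth = generate(config)          # planted cut at 0.2000
for t in detect_thresholds(data):
    print(t.variable, t.side, round(t.cut, 4), round(t.z, 2), t.n_out)
    print(t.rule_text("death"))
```

prints

```
temperature below 0.1998 21.42 407
For temperature, a value below 0.1998 is associated with a significantly higher incidence of outcome death
```

The detected cut (0.1998) lies within one candidate-grid spacing
(≈ 0.01) of the planted 0.2; Z = 21.42 far exceeds the 2.576 critical
value because the tail's 80% outcome rate stands against a 20% IQR
baseline with 407 supporting observations. The three noise variables
yield no threshold. The `examples/` directory walks through detection,
flag-count classification, missingness/noise robustness sweeps and
rare-event stratification, each printing and interpreting its numbers.

## Command line

```sh
ufa simulate --out data.csv --n 2000 --seed 3 --planted temp:below:0.8:0.2 --n-noise 2
ufa detect   --input data.csv --target y --out thresholds.csv --rules rules.txt
ufa flags    --input data.csv --target y --thresholds thresholds.csv --out flags.csv
ufa train    --input data.csv --target y --out scatter.csv --boundary boundary.json
ufa evaluate --input data.csv --target y --classifier nufa --out metrics.csv
ufa sweep    --input data.csv --target y --perturbation missing --out sweep.csv
```

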