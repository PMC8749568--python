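# bcsense

Sensitivity and agreement analysis for automated (3D camera) versus visual
body condition scoring of dairy cows.

## The problem

Body condition score (BCS) tracks a dairy cow's subcutaneous fat reserves.
Researchers need to detect changes of a few tenths of a point on the 1–8
scale within weeks — but the traditional instrument is a human panel
scoring each cow once a week, while commercial 3D cameras score every cow
at every milking.  Which method is actually better at detecting real
change, and by how much?  Correlation and Bland–Altman agreement don't
answer that: they compare methods against each other, not against the
biology.

`bcsense` implements the measurement-sensitivity framework for this
comparison.  Each method's data are described by a crossed random-effects
model (weeks W, days D, milkings M, animals A, camera units C or scorers
S, and their interactions), estimated by REML.  The components are
composed into, per cow-by-week mean,

* σa — the SD of the *actual* signal (`σW² + σWA²` for change over time,
  `σA² + σWA²` for differences between animals),
* σm — the standard error of the reported mean (`Σ σi²/nᵢ` over the error
  terms, with nᵢ the number of draws averaged in: 14 camera scores over 7
  days and 2 units, or 3 visual scorers),

and the Mandel–Stiehler sensitivity **Θ = σa/σm** — a dimensionless,
scale-invariant signal-to-noise ratio.  The ratio of two methods'
sensitivities, RS, says how many extra samplers the weaker method would
need (RS²×) to catch up, and `t = 3σm/|β|` converts a method's precision
into days until a body-condition change of detectable size accrues, given
a rate of change β (BCS/month).

The package provides the full chain as tested, reusable modules:

| module | what it does |
|---|---|
| `bcsense.records` | long-format BCS tables, validity filtering, scale conversion, cow-week means, vendor-style trimmed rolling average |
| `bcsense.refine` | per-cow robust loess (span 0.5, symmetric family) + Tukey-fence outlier removal for raw camera series |
| `bcsense.varcomp` | exact AI-REML for the crossed variance-component models, with aliasing diagnosis |
| `bcsense.sensitivity` | σa/σm composition, Θ, RS, equivalent samplers, trend, time-to-detect |
| `bcsense.agreement` | Pearson/Lin concordance and Bland–Altman on paired cow-week means |
| `bcsense.simulate` | synthetic herd generator reproducing the reference study design, with labelled contamination |
| `bcsense.pipeline` / CLI | end-to-end orchestration: simulate → filter → refine → fit → summarise |

## Worked example

Recompute the summary statistics of the reference herd study (32 cows,
7 weeks, camera scored 14×/week on 2 units, 3 visual scorers weekly) from
its published variance components, shipped with the package:

```bash
bcsense summary
```

```text
        method         contrast  sigma_a  sigma_m  theta  rs_vs_reference  beta_per_month  detect_days  equivalent_samplers
    raw_camera change_over_time    0.149    0.041    3.6              2.2           -0.18         21.0                 14.0
refined_camera change_over_time    0.163    0.026    6.2              3.7           -0.19         13.0                 41.0
        visual change_over_time    0.139    0.083    1.7              NaN           -0.17         45.0                  NaN
    raw_camera  between_animals    0.207    0.048    4.3              1.3           -0.18         24.0                  5.0
refined_camera  between_animals    0.232    0.030    7.7              2.4           -0.19         15.0                 17.0
        visual  between_animals    0.288    0.090    3.2              NaN           -0.17         48.0                  NaN
```

Reading the change-over-time block: a
cow-week mean from the refined camera data carries a standard error of
0.026 BCS against 0.083 for the visual panel, so its sensitivity to
within-cow change is 6.2 vs 1.7 — 3.7× the visual method.  Matching that
with humans would take 3.7² × 3 ≈ 41 independent scorers, and at the
observed decline of ~0.19 BCS/month the refined camera detects a change in
about 13 days versus about 45 for weekly visual scoring.

The same analysis runs end-to-end on synthetic data:

```bash
bcsense run-all --seed 7 --out runs/demo     # simulate → refine → fit → summarise
bcsense -v simulate --seed 7 --out runs/sim  # or stage by stage
bcsense refine runs/sim/camera.csv --out runs/refined
```

or from Python:

```python
from bcsense import PipelineConfig, run_full_pipeline
result = run_full_pipeline(PipelineConfig(seed=7))
print(result.summary)          # 3 methods x 2 contrasts
print(result.counts)           # records in / invalid / outliers removed
```

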