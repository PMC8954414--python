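# catbank

Item-bank calibration and computerized adaptive testing (CAT) simulation for
ordinal (Likert-type) questionnaires, aimed at patient-reported experience
and outcome measures: descriptive item screening, ordinal dimensionality
assessment, generalized partial credit model (GPCM) calibration, differential
item functioning (DIF) analysis, EAP scoring, and CAT simulation with
SEM-based stopping rules.

## The problem

Fixed-length patient questionnaires are burdensome, so modern measurement
builds a *calibrated item bank* — items placed on a common latent metric by
an item response theory (IRT) model — and administers only the most
informative items adaptively.  Getting there requires a pipeline of checks:
weeding out redundant or degenerate items, confirming the item pool is
essentially unidimensional, fitting and diagnosing the IRT model, verifying
items behave the same across patient subgroups, and finally demonstrating
that adaptive administration loses little information relative to the full
bank.  `catbank` implements that pipeline end to end, together with a
synthetic-data generator that emulates a realistic survey cohort
(~460 respondents × 24 five-point items with reverse-coded items, redundant
pairs, per-item missingness, an explicit "not applicable" option, and
group structure), so every stage is testable without access to patient data.

## The model

Responses in categories k = 0..K−1 follow the GPCM,

    P_ik(θ) ∝ exp( Σ_{v=1..k} a_i (θ − b_iv) ),

with discrimination a_i and step thresholds b_iv; the partial credit model
(PCM) is the equal-slope special case, compared by likelihood-ratio test and
AIC/BIC.  Calibration is maximum marginal likelihood via EM over a fixed
quadrature grid with an N(0,1) latent density.  Persons are scored by
expected-a-posteriori (EAP) estimation; the posterior SD is the standard
error of measurement (SEM), related to reliability by rel = 1 − SEM² on a
unit-variance trait.  The CAT selects items by maximum Fisher information
(I_i(θ) = a_i²·Var(k|θ)) at the current EAP estimate and stops when
SEM < 0.33 / 0.44 / 0.55 (reliability ≈ 0.89 / 0.81 / 0.70).

## Worked example

```python
from catbank.pipeline import PipelineConfig, run_pipeline
manifest = run_pipeline(PipelineConfig(seed=1), "out/")
```

runs every stage on a synthetic 458-person cohort and logs:

```
simulate: 458 persons x 24 items
screening: retained 21 of 24 items
dimensionality: parallel analysis keeps 1 factor(s)
calibrate: GPCM chosen (LRT chi2=80.38, p=3.4e-09)
dif: 84 tests, 0 flagged
cat:  stop_sem  mean_score  sd_score        r     rmse  mean_items
          0.33   50.186508 12.029457 0.979270 0.200911    9.034934
          0.44   50.155722 11.513994 0.940224 0.337652    4.486900
          0.55   49.926196 11.001672 0.898084 0.436541    2.480349
```

Reading the output: three injected redundant item pairs push exactly three
items over the 0.70 inter-item correlation cutoff, so screening keeps 21 of
24 items (Cronbach's α of the retained set: 0.94).  Parallel analysis keeps
one factor, consistent with the unidimensional generator.  The GPCM beats
the equal-slope PCM (χ² = 80.4 on 20 df).  The 84 DIF tests (21 items × 4
grouping variables) flag nothing on this DIF-free cohort at p < 0.01.  In
the CAT table, the strictest stopping rule (SEM < 0.33) reproduces
full-bank scores almost perfectly (r = 0.98, RMSE = 0.20 on the latent
scale) while administering 9 of 21 items on average; looser rules
administer fewer items at a visible cost in accuracy.

The same stages are available as CLI subcommands
(`catbank simulate | screen | dims | calibrate | score | dif | cat |
report | pipeline`), e.g.

```
catbank cat --bank out/bank.json --responses out/responses.csv \
        --sem 0.33 --sem 0.44 --sem 0.55 --out table.tsv
```

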