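# osdsurvey

Scoring and inference tools for surveys that measure public attitudes to
science alongside both *objective* knowledge and *subjective* (self-assessed)
understanding. The package is built for the analysis pattern in which
attitude items (5-point Likert, coded −2…+2 with +2 most accepting) are
related to:

- **subjective understanding** `S ∈ [0, 1]` — the mean of six ordinal
  self-rating items, each divided by its theoretical maximum (3, 3, 4, 4, 4, 4);
- **objective knowledge** `K ∈ [−1, 1]` — the mean of ±1 scores over twelve
  true/false textbook items (0 = chance guessing);
- the **objective–subjective deficit** `OSD = K − S ∈ [−2, 1]`, negative when
  self-assessment outruns demonstrated knowledge (overconfidence), and its
  sample-relative variant `Z_OSD = z(K) − z(S)`.

Around these scores it implements the full inference battery such studies
use:

- **Curvature test** — OLS fits of `S ~ a + b·x` and `S ~ a + b·x + c·x²` on
  the numeric attitude `x`, adjusted R², and the nested F test for the
  quadratic improvement (a positive `c` is the U shape: both attitude
  extremes report higher understanding than the neutral middle);
- **Balanced resampling** — the improvement test repeated over resamples
  drawing the minimum class size from *every* attitude class without
  replacement, so small extreme classes cannot be swamped; reports the
  fraction of resamples with a significant improvement;
- **Split-half correlations** — Spearman ρ of `S` with `x` separately on the
  `x ≥ 0` and `x ≤ 0` halves (zeros in both);
- **Rank/partial-rank correlation tables** — Spearman ρ above the diagonal,
  pairwise partial correlations (precision-matrix method on average ranks)
  controlling all other listed variables below it;
- **Slope contrast** — on the `x ≤ 0` subset,
  `t = (b_S − b_K) / √(SEM_S² + SEM_K²)` with `df = n₁ + n₂ − 4`, testing
  whether self-assessment rises faster than knowledge as attitudes turn
  negative;
- **Group tests** — one-way ANOVA with Tukey HSD, Mann–Whitney U,
  Pearson χ² sex-ratio heterogeneity, and the Hartigan–Hartigan dip test of
  unimodality with a uniform-reference bootstrap p-value (the dip statistic
  is computed exactly by the classical modal-interval algorithm, validated
  in-tree against a linear-programming formulation of its definition);
- **Intersection randomization** — whether strong rejectors (score −2) of
  different attitude questions overlap more than independent equally sized
  random subsets of the respondent pool would (empirical P and
  `Z = (observed − null mean)/null SD`).

A synthetic respondent generator (`SyntheticConfig`, `generate_respondents`)
emulates the assumed data structure — Gaussian-copula attitude items,
U-shaped confidence link, linear knowledge link, an overconfident subgroup,
correlated covariates — with every generating parameter exposed, so
calibration and parameter-recovery tests can run without survey data.

## Worked example

```python
from osdsurvey import (SyntheticConfig, generate_respondents,
                       score_respondents, fit_linear_quadratic,
                       balanced_resample_test)

records, truth = generate_respondents(SyntheticConfig(n_respondents=2000,
                                                      seed=3))
scored = score_respondents(records)
fit = fit_linear_quadratic(scored.trust, scored.subjective)
bal = balanced_resample_test(scored.trust, scored.subjective,
                             replicates=2000, seed=0)
```

With the default generator this prints (see `examples/02_u_shape_curvature.py`):

```
adjusted R2: linear 0.242, quadratic 0.725
improvement P = 0.00e+00, quadratic coefficient = +0.148
balanced resampling (38 per class, 2000 replicates): quadratic better in 100.0%
split halves: rho = +0.75 (attitude >= 0, n=1716), -0.51 (attitude <= 0, n=977)
```

The quadratic coefficient recovers the generating curvature (0.15); the
opposite-signed half-range correlations are the U signature. The
`examples/` directory holds one short script per capability (scoring,
correlation tables, slope contrast, group tests, intersection
randomization), each printing its numbers with a line on what they mean.

A thin CLI wraps the pipeline: `osdsurvey simulate`, `score`, `analyze`,
`report` (exit codes: 2 validation failure, 3 degenerate analysis).
`analyze` writes every table as CSV plus a `manifest.json` recording seed,
versions and per-analysis N, and reruns with the same seed are
byte-identical.

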