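# Methods

## Scores

Attitude items are 5-point Likert responses coded −2…+2 with +2 the most
accepting position; attitude *strength* is the absolute value (0…2), its
sign the valence. Subjective understanding is the mean of six ordinal
self-ratings each normalised by its **theoretical** maximum (3, 3, 4, 4, 4, 4
in questionnaire order), not the observed maximum, giving `S ∈ [0, 1]`.
Objective knowledge is the mean of ±1 (correct/incorrect) over twelve
true/false items, `K ∈ [−1, 1]`, so 0 is the guessing expectation. The
embedded answer key (T, T, T, F, F, F, T, F, T, T, F, T) encodes the
textbook-consensus truth values of the twelve statements and can be
overridden per call.

The objective–subjective deficit is `OSD = K − S`. Because both scales are
anchored (0 = chance, 1 = full marks; 0 = no confidence, 1 = full
confidence), perfect calibration is the line of slope one through the
origin, and OSD measures signed distance from it; negative values are
overconfidence. `Z_OSD = z(K) − z(S)` (sample-standardised components,
ddof = 1) is the sample-relative variant; it has mean zero by construction
and is undefined for a constant component (raised as a degenerate-data
error rather than silently returning NaN).

Political identity: ten items on −2…+2 raw agreement, items 1–6 negated
(agreement with them is the left-wing pole), items 7–10 kept, mean over
non-missing items divided by 2, giving [−1, +1] with +1 most right-wing;
all-missing yields missing. Religiosity and education are 0/1/2 ordinals.
Missing values are permitted only in political items — the knowledge and
self-rating items are treated as required, mirroring forced-answer survey
designs.

A robustness variant rescoring (`mode="biology_genetics"`) restricts
knowledge to the ten biological items (dropping the radioactivity and
electrons/atoms items, positions 5 and 7) and subjective understanding to
the four genetics-term items (positions 3–6), with unchanged formulas.

## Association

Correlation tables show Spearman ρ (average ranks) above the diagonal and,
below it, the partial correlation of each pair controlling all other listed
variables: every variable is rank-transformed, the correlation matrix of
the ranked data inverted, and `ρ_xy·z = −P_xy/√(P_xx P_yy)` read off the
precision matrix `P`. Two-sided p-values use the t approximation with
`n − k − 2` degrees of freedom. With no controls this reduces exactly to
plain Spearman. Whether the partialling should be rank-based or Pearson is
a genuine choice; rank-based is the default (consistent with the rest of
the battery) with `method="pearson"` available. Rows missing any listed
variable are dropped listwise per table and the per-analysis N recorded.
Significance is flagged at raw (uncorrected) two-sided 0.05; no
multiple-testing correction is applied, by design, so flags must be read as
descriptive.

## Curvature and balanced resampling

Attitude is treated as numeric −2…+2. The linear and quadratic models are
fitted by OLS; adjusted `R² = 1 − (1−R²)(n−1)/(n−p−1)`; the improvement
p-value is the nested F test with 1 numerator and `n − 3` denominator df.
An F test (rather than an information criterion) defines "significantly
better" throughout; the per-replicate threshold defaults to 0.05 and is a
parameter.

Balanced resampling draws, per replicate, the minimum class size `m` from
each of the five attitude classes without replacement (independently across
replicates) and reruns the improvement test on the balanced `5m` rows.
Because the balanced design matrix is the same in every replicate, the
per-replicate F statistics are evaluated against precomputed orthonormal
design bases — algebraically identical to refitting, verified against
direct fits in the tests. The test reports the fraction of replicates
significant at the threshold, the class size, and the seed.

Split-half correlations compute Spearman ρ within the `x ≥ 0` and `x ≤ 0`
subsets; neutral respondents (x = 0) belong to both halves, matching the
"greater/less than or equal" convention.

## Slope contrast

On the attitude ≤ 0 subset, subjective and objective scores are regressed
on attitude separately; the slopes are compared with
`t = (b₁ − b₂)/√(SEM₁² + SEM₂²)`, `df = n₁ + n₂ − 4`. The default
p-value is **one-sided** (lower tail): the published tables this mirrors
print P values that correspond to one-tailed probabilities even though
their methods text says two-tailed, and the package reproduces the printed
convention rather than silently correcting it; `sided="two"` is available.

## Group tests

One-way ANOVA (scipy) with Tukey HSD pairwise adjustment (statsmodels,
studentised-range distribution); for k = 2 the Tukey p equals the omnibus
p, which the tests verify. Mann–Whitney U uses the exact null for small
tie-free samples and the normal approximation otherwise (scipy's choice);
the vaccine contrast follows the acceptor-versus-decliner framing, with
"prefer not to say" kept as a fourth group in omnibus tests only.
Sex-ratio heterogeneity is Pearson χ² on the 2×k contingency table without
continuity correction, df = k − 1.

### Dip test

The dip statistic — the minimal sup-norm distance between the empirical CDF
and any unimodal CDF (convex to a mode, concave after, an atom allowed at
the mode) — is computed exactly by the classical modal-interval algorithm
in count units: the greatest convex minorant touches the lower step corners
`(x_j, j−1)`, the least concave majorant the upper corners `(x_j, j)`; each
cycle finds the largest hull separation on the current interval, shrinks
the interval to it, and accrues the one-sided hull fit errors outside; the
dip is half the final maximum over n. Correctness is established in the
test-suite by agreement with an independent linear-programming formulation
of the defining minimisation (mode swept over data locations and gaps,
convexity/concavity/monotonicity/tube constraints explicit) across random
continuous, tied, and multimodal samples, plus the known exact values
(1/(2n) for equally spaced data, 0.25 for a balanced two-point mixture).

The p-value is the share of `bootstrap_reps` (default 10,000) uniform
samples of the same size with a dip at least as large — the uniform being
the classical least-favourable unimodal reference. The reference
distribution and replicate count are choices, so small p-values should be
read to their order of magnitude.

## Intersection randomization

Strong rejectors are respondents scoring exactly −2 on a question. For the
overlap of two or three such sets, each replicate draws the groups
uniformly without replacement from the pool, independently, and records the
common intersection; empirical `P = #{intersection ≥ observed}/replicates`
(reported as "< 1/replicates" when zero, never as an exact 0), and
`Z = (observed − mean)/SD` of the null vector. Under this null the
pairwise intersection is hypergeometric with mean `n₁n₂/N` (three-way
`n₁n₂n₃/N²`), which the tests use as an analytic cross-check of the
simulation. The pool size is an explicit argument and is never inferred
from the sets: published tables of this kind do not always state the pool,
and back-solving printed null means can imply a pool differing from the
headline N (the bundled printed-input reproduction uses the implied pool of
2,096 for the 29×47 comparison).

## Synthetic respondents

The generator is a minimal chain reproducing the structure the analyses
assume, with one global `numpy.random.default_rng(seed)` so identical
configs give identical tables:

- **Attitudes.** Trust/Hype/GM come from a trivariate Gaussian copula
  (latent Pearson `2·sin(πρ_s/6)` for target Spearman ρ_s; defaults 0.44
  Hype–Trust, 0.20 to GM), discretised by the class probabilities
  (default 0.02/0.12/0.34/0.35/0.17 for −2…+2, putting roughly 2% in the
  strong-rejector class).
- **Confidence → subjective items.** Latent
  `c = 0.30 + curvature·trust² + 0.04·edu_z − 0.01·rel_z +
  0.25·overconfident + N(0, 0.06)`, clipped to [0, 1]; each of the six
  items is Binomial(max_i, c)/…, so the subjective score is conditionally
  unbiased for `c` and the fitted quadratic coefficient recovers
  `curvature` (default 0.15) up to a small clipping bias (≪ 1 SE at
  n = 2,000 under the defaults — the noise scales were chosen to keep the
  latent confidence almost always inside [0, 1]).
- **Accuracy → knowledge items.** Per-item correctness probability
  `0.70 + knowledge_slope/2·trust + covariate terms −
  0.20·overconfident + N(0, 0.12)` plus fixed item-difficulty offsets
  (linspace −0.11…0.11), clipped to [0.02, 0.98]; emitted answers flip the
  answer key on incorrect draws. The ÷2 puts `knowledge_slope` (default
  0.10) on the knowledge-score scale.
- **Overconfident subgroup** (default 5%) gets confidence +0.25 and
  accuracy −0.20, creating the low-knowledge/high-subjective pool that
  drives negative-attitude OSD effects.
- **Covariates.** (education, age, religiosity, politics) from a latent
  Gaussian with plausible cross-correlations (e.g. education–politics
  −0.26, age–politics 0.24); age ∼ N(48, 17²) clipped to 18–95; ten
  political items re-expressed as raw agreement with 3% missingness;
  sex with a mild male-at-the-extremes effect (+0.25 log-odds per unit of
  Trust strength); vaccine stance with decliners younger and more
  overconfident.

What it does **not** emulate: the generator's attitude–confidence signal is
much cleaner than real survey data (synthetic strength–subjective ρ ≈ 0.7
versus ≈ 0.2–0.3 in the field), item-level response styles, acquiescence
bias, differential item functioning, and sampling weights are all absent,
and no attempt is made to match the deposited survey's marginal
distributions. Passing recovery and calibration tests therefore
demonstrates the correctness of the machinery, not field realism; all
noise magnitudes are exposed in `SyntheticConfig` with no claim of
fidelity.

## Numerical and design choices

- Ranks use average ties everywhere.
- `fit_linear_quadratic` clamps `RSS_quad ≤ RSS_lin` (guarding
  least-squares round-off on exact fits) and reports P = 0 for exact
  quadratic fits.
- Degenerate inputs (constant vectors, singular correlation matrices,
  empty classes, zero-variance totals, sub-minimal samples) raise typed
  errors (`ParameterError`, `ValidationError`, `DegenerateDataError`;
  CLI exit codes 2/2/3) rather than propagating NaN.
- Replicated procedures (balanced resampling, intersection nulls, dip
  bootstrap) accept either an integer seed or a `numpy` Generator and are
  bit-reproducible for a given seed.
- Problem sizes in the test-suite and acceptance script (e.g. 200
  calibration meta-replicates with 25 resamples each; 250 null
  generations at n = 1,200; recovery at n = 2,000; bootstrap subsets of
  150–2,000 replicates) were chosen to give tolerances well inside the
  asserted bounds while keeping a full run to a few minutes on one CPU.

## Known limitations

- The balanced-resampling fraction is a descriptive robustness measure,
  not a calibrated p-value; its replicates share the same data.
- The dip bootstrap conditions on sample size only, ignoring ties in the
  observed data (uniform reference draws are tie-free); for heavily
  discretised scores this makes small p-values conservative to an unknown
  degree.
- Partial-correlation p-values use the t approximation, which is liberal
  at very small N.
- The intersection null ignores covariate structure: it answers "more
  overlap than random sets of this size", not "more than demographically
  matched sets".
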