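"""Correlation table with covariate control.

Builds the study-style square table: Spearman rho above the diagonal,
pairwise partial rank correlation controlling all other listed variables
below it, significance starred at raw P < 0.05.
"""

from osdsurvey import (SyntheticConfig, build_correlation_table,
                       generate_respondents, score_respondents)

records, _ = generate_respondents(SyntheticConfig(n_respondents=2000,
                                                  seed=3))
scored = score_respondents(records).assign(
    abs_trust=lambda d: d.trust.abs())

tab = build_correlation_table(
    scored, ["education", "age", "religiosity", "political",
             "subjective", "abs_trust"])
print(f"N = {tab.n} (listwise-complete rows)")
print(tab.formatted())
print("\nUpper triangle: plain rho.  Lower: partial rho given all other "
      "variables.  A starred |Trust|-subjective cell surviving below the "
      "diagonal means attitude strength tracks self-assessed understanding "
      "even after covariate control.")
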