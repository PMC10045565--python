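"""Slope contrast on the rejecting half, plus the printed-input check.

On respondents with attitude <= 0, compares how fast subjective
understanding versus objective knowledge rises as attitudes become more
negative; a significantly more negative subjective slope means rejectors'
self-confidence outruns their knowledge.  The second part re-evaluates the
test from published slope/SEM inputs alone.
"""

from osdsurvey import (SyntheticConfig, compare_slopes,
                       generate_respondents, score_respondents,
                       slope_diff_test)

records, _ = generate_respondents(SyntheticConfig(n_respondents=2000,
                                                  seed=3))
scored = score_respondents(records)

pair = compare_slopes(scored.trust, scored.subjective, scored.knowledge)
print("synthetic study, attitude <= 0:")
print(f"  subjective slope {pair.slope_subjective:+.4f} "
      f"(SEM {pair.sem_subjective:.4f}, n={pair.n_subjective})")
print(f"  objective  slope {pair.slope_objective:+.4f} "
      f"(SEM {pair.sem_objective:.4f})")
print(f"  t = {pair.t:.3f}, df = {pair.df}, one-sided P = {pair.p:.2e}")

# published inputs: slopes -0.0444 +- 0.0090 and -0.0026 +- 0.0150, df 2250
t, df, p = slope_diff_test(-0.0444, 0.0090, 1127, -0.0026, 0.0150, 1127,
                           sided="one")
print(f"\nfrom printed inputs: t = {t:.4f}, df = {df}, "
      f"one-sided P = {p:.4f}")
print("A negative t says the subjective slope is the steeper (more "
      "negative) of the two.")
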