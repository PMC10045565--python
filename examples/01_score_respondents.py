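"""Score a respondent table: subjective understanding, knowledge, OSD.

Generates a small synthetic survey, derives every per-respondent score and
prints the sample summary.  A negative mean OSD (objective minus subjective)
means the average respondent rates their understanding above what the
twelve knowledge items demonstrate - the typical overconfidence pattern.
"""

from osdsurvey import SyntheticConfig, generate_respondents, \
    score_respondents

records, truth = generate_respondents(SyntheticConfig(n_respondents=500,
                                                      seed=7))
scored = score_respondents(records)

print(scored[["subjective", "knowledge", "osd", "z_osd",
              "political"]].describe().loc[["mean", "std", "min", "max"]]
      .round(3))
print(f"\nshare overconfident (OSD < 0): {(scored.osd < 0).mean():.1%}")
print("A negative OSD marks a respondent whose self-assessed understanding"
      " exceeds their demonstrated knowledge.")
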