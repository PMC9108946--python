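"""Harmonize Likert surveys: 7-point responses to the 5-point scale.

A community sample rates perceived 10-year change of its coral reefs on
a 7-point scale; responses are mapped onto the 5-point scale and the
median becomes the comparison score.
"""

from ecoconverge import SurveySample, cp_trend_score, harmonize_sample

sample = SurveySample(
    site="selayar", habitat="coral", direction="past", scale_points=7,
    responses=(3, 2, 2, 1, 1, 1, 0, 0, -1, -1, -2, 1, 2, 0, 1),
)
print("raw 7-point responses: ", list(sample.responses))
print("harmonized to 5-point: ", harmonize_sample(sample))

score = cp_trend_score(sample)
print(f"median {score.raw_median:+.1f} over n={score.n} respondents "
      f"-> CP score {score.score:+d}")
print("\nA CP score of +1 means the community perceives a mild improvement "
      "of the habitat\nover the last decade, directly comparable with the "
      "natural-science trend score.")
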