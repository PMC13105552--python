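"""Calibrate onset/progression probabilities to prevalence targets.

Generates an age-banded prevalence table from a known ("true") parameter
set, then starts the calibrator from the packaged base case and checks that
it recovers the generating transition probabilities.
"""

from crcscreen.natural_history import calibrate_transitions, lesion_prevalence
from crcscreen.parameters import AgeBand, default_parameters

params = default_parameters()
bands = [AgeBand(40, 49), AgeBand(50, 54), AgeBand(55, 59),
         AgeBand(60, 64), AgeBand(65, 69)]

truth = params.with_scaled_bands("p_normal_to_naa", 1.15)
truth = truth.with_scaled_bands("p_naa_to_aa", 0.90)
targets = lesion_prevalence(truth, bands)

result = calibrate_transitions(targets, params)
print(f"objective (sum of squared prevalence errors): "
      f"{result.start_objective:.2e} -> {result.objective:.2e}")
for family in ("p_normal_to_naa", "p_naa_to_aa"):
    fitted = dict((b.lower, v) for b, v in result.params.band_items(family))
    print(f"\n{family} (true vs fitted):")
    for band, true_val in truth.band_items(family):
        if band.lower <= 69:
            print(f"  {band.label}: {true_val:.4f} vs {fitted[band.lower]:.4f}")
print()
print("A near-zero objective and matching values mean the optimizer found "
      "the transition probabilities that generated the targets — the same "
      "procedure a real program applies to its entry-screening prevalence "
      "table.")
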