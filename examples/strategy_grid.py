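"""Compare screening strategies for one entry cohort.

Runs the no-screening baseline and six screening frequencies for a cohort
entering at mean age 52 (the 50-54 initiation band), then ranks them by
QALYs and prints incremental costs and ICERs versus no screening and versus
the next-most-effective strategy.
"""

import crcscreen as cs
from crcscreen.economics import rows_to_frame

params = cs.default_parameters()
grid = cs.run_strategy_grid(params, entry_ages=[52])
outcomes = grid[52]

rows = cs.rank_and_compare(
    [o for freq, o in outcomes.items() if freq != "none"], outcomes["none"]
)
report = cs.classify_against_threshold(rows, cs.ThresholdSet())

print(rows_to_frame(rows).round(0).to_string(index=False))
print()
print(f"max ICER vs no screening: {report.max_icer} USD/QALY")
print(f"all strategies cost-effective at 3x GDP (53,235): "
      f"{report.all_cost_effective['three_gdp']}")
print()
print("Each row is one screening frequency for 100,000 people entering at "
      "age 52; an ICER is the extra cost per QALY gained, so values far "
      "below the 53,235 USD willingness-to-pay threshold mean screening is "
      "clearly worth buying.")
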