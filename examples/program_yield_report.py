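"""Screening-cascade yield and resource metrics of the packaged program.

Loads the aggregate counts of the province-wide screening program
(17.78 million invitees, 2020-2024), recomputes every published resource
metric from its stated formula, and prints the cells that disagree with the
published report.
"""

from crcscreen.program_yield import build_report, pccsp_counts, published_metrics

counts = pccsp_counts()
published = published_metrics()
rates = published[published.metric == "detection_rate_pct"]
detection = {r.lesion: r.value / 100.0 for r in rates.itertuples()}

report = build_report(counts, detection_rates=detection, published=published)

print(f"participation {report.rates.participation_pct}% | "
      f"positivity {report.rates.positivity_pct}% | "
      f"colonoscopy compliance {report.rates.compliance_pct}%")
print()
print(report.table.to_string(index=False))
print()
print("published cells the stated formulas cannot reproduce:")
print(report.discrepancies.to_string(index=False))
print()
print("Colonoscopies/cost per lesion tell a program manager what one "
      "detected adenoma or cancer costs in endoscopy capacity and dollars; "
      "the discrepancy list flags published numbers that are internally "
      "inconsistent rather than silently matching them.")
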