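"""Recompute weighted totals for the packaged top-20 reference panel.

The panel ships with each probe set's eight component scores (0-5); this
recomputes the weighted total — 2x specificity + ave ratio + positive
condition + positive chemical + P value + 0.5x (basal + reverse change +
CV) — and verifies the published ordering is reproduced.
"""

from gtxscore import default_bin_tables, rescore_reference

rr = rescore_reference()
print(rr[["symbol", "recomputed_total", "total_score", "rank"]].to_string())
exact = (rr["recomputed_total"] == rr["total_score"]).all()
print(f"\nAll 20 recomputed totals match the published values: {exact}")
print("Top scorer:", rr.index[0], f"({rr['symbol'].iloc[0]}),",
      "total", rr["recomputed_total"].iloc[0], "of a possible 37.5")

print("\nDefault score-bin tables inferred from the panel:")
for name, tab in default_bin_tables().items():
    print(f"  {name:20s} {tab.direction:13s} edges={tuple(round(e, 3) for e in tab.edges)}")
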