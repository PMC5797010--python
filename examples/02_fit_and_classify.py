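"""Fit Hill curves to a simulated screen and read the qHTS curve classes.

Each concentration-response series is fitted with the four-parameter
logistic model and classified: -1.x = complete cytotoxic curve (both
plateaus seen), -2.x = incomplete (top plateau out of range), -3 = response
at the top concentration only, 4 = inactive.  The AUC column is the
normalized area under the fitted curve (100 = full kill across the whole
tested range) and is the value later used for profile heatmaps.
"""

import qscreen as q

series = q.make_dilution_series(46e-6, 11, 3)
mix = {"complete_full": 0.3, "complete_partial": 0.2, "incomplete": 0.2,
       "single_point": 0.1, "inactive": 0.2}
library = q.generate_library(12, mix, seed=5)
plates = q.simulate_viability_screen(library, ["TC32"], series,
                                     noise_cv=0.05, seed=6)

result = q.analyze_viability_screen(plates)
cols = ["compound_id", "curve_class", "log10_ic50", "hill_slope",
        "max_response", "r2", "auc", "is_active"]
print(result.fits[cols].to_string(index=False,
                                  float_format=lambda v: f"{v:.2f}"))

truth = {r.compound_id: r.archetype for r in library}
print("\nplanted archetypes:")
for cid in result.fits["compound_id"]:
    print(f"  {cid}: {truth[cid]}")
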