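"""Call activity across a cell-line panel and categorize the compounds.

A compound is active in a line when its curve is high quality, a raw well
crossed six neutral-control SDs, IC50 <= 10 uM and maximal response >= 65%.
Panel-level flags follow: pan-active (active in most lines), potent
(IC50 < 100 nM somewhere), selective (confined to one tumor type), and
clean against the fibroblast counter-screen.
"""

from dataclasses import replace

import qscreen as q

series = q.make_dilution_series(46e-6, 11, 3)
panel = {"TC32": "EWS", "A673": "EWS", "SK-N-SH": "NB", "LAN-5": "NB",
         "U-2 OS": "OS", "Saos-2": "OS"}
FIB = "Hh-Wt-fibroblasts"

base = q.generate_library(4, {"complete_full": 1.0}, ic50_range=(2e-8, 2e-7),
                          seed=11)
library = [
    base[0],                                                      # pan-active
    replace(base[1], responsive_lines=frozenset({"TC32", "A673"})),  # EWS-only
    replace(base[2], archetype="inactive", true_ic50=None, true_efficacy=0.0),
    base[3],
]

plates = q.simulate_viability_screen(library, [*panel, FIB], series,
                                     noise_cv=0.05, seed=12)
result = q.analyze_viability_screen(plates)
cats = q.categorize(result.consensus_calls, panel, fibroblast_line=FIB,
                    pan_threshold=6, cpc_members={base[3].compound_id})

for c in cats:
    sel = ",".join(sorted(c.selective_for)) or "-"
    print(f"{c.compound_id}: active in {c.n_active_lines}/6 lines | "
          f"pan={c.pan_active} potent={c.potent} selective_for={sel} "
          f"fibroblast_clean={c.fibroblast_clean} cpc={c.cpc_member}")

n_active = sum(c.n_active_lines > 0 for c in cats)
print(f"\nhit rate: {q.hit_rate_percent(n_active, len(cats))}% of compounds "
      "active in at least one line")
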