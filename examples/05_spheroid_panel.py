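"""Multiparametric 3D-spheroid assay: viability by two readouts + apoptosis.

Simulates a triplicate 384-well spheroid plate with coupled channels, then:
(1) calls activity from CellTiter-Glo with the 2-of-3 replicate rule,
(2) checks that imaging (PI/Hoechst ratio) potencies agree with CTG, and
(3) quantifies caspase-3/7 activation against the staurosporine anchor —
separating apoptotic killers from a planted non-apoptotic one (high PI,
quiet caspase: the niclosamide-like pattern).
"""

from dataclasses import replace

import pandas as pd

import qscreen as q

series = q.make_dilution_series(46e-6, 11, 3)
lib = q.generate_library(6, {"complete_full": 1.0}, ic50_range=(1e-8, 5e-7),
                         seed=31)
lib = [replace(lib[0], apoptotic=False)] + list(lib[1:])

plates = q.simulate_spheroid_plate(lib, "TC32", series, replicates=3,
                                   coupling=q.SpheroidCoupling(noise_cv=0.05),
                                   seed=32)
chans = {}
for p in plates:
    chans.setdefault(p.readout, []).append(p)

fits, rep_calls = q.fit_series_table(q.ctg_viability(chans["luminescence"]))
consensus, _ = q.consensus_table(fits, rep_calls)
print("CTG consensus calls (2-of-3 rule):")
print(consensus[["compound_id", "is_active", "n_replicates_passing",
                 "log10_ic50"]].to_string(index=False,
                                          float_format=lambda v: f"{v:.2f}"))


def potency_table(series_list):
    rows = [{"compound_id": s.compound_id, "cell_line": s.cell_line,
             "replicate": s.replicate_index,
             "log10_ic50": q.fit_hill(s).log10_ic50} for s in series_list]
    return (pd.DataFrame(rows).groupby(["compound_id", "cell_line"])
            ["log10_ic50"].median().reset_index())


corr, _ = q.readout_agreement(
    potency_table(q.ctg_viability(chans["luminescence"])),
    potency_table(q.pi_hoechst_viability(chans["pi_intensity"],
                                         chans["hoechst_intensity"])),
)
print(f"\nCTG vs imaging potency rank correlation: "
      f"{corr.loc[0, 'rank_correlation']:.3f} over {corr.loc[0, 'n_pairs']} compounds")

casp = q.caspase_activation(chans["caspase_intensity"])
peak = casp.groupby("compound_id")["pct_activation"].max()
print("\npeak caspase-3/7 activation (% of staurosporine control):")
for cid, v in peak.items():
    tag = " <- non-apoptotic killer" if cid == lib[0].compound_id else ""
    print(f"  {cid}: {v:.1f}%{tag}")
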