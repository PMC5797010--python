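# qscreen

Analysis pipeline for quantitative high-throughput screening (qHTS) of cell
viability, aimed at drug-repurposing campaigns that titrate large compound
collections (approved drugs and investigational agents) against panels of
cancer cell lines — including pediatric-tumor panels — in 1536-well
monolayer format and 384-well 3D tumor-spheroid format. It is a library:
you import it from Python; the `examples/` scripts are short narrative
walk-throughs of each capability.

Because every compound is screened as a full titration, concentration–
response curves come straight out of the primary screen. `qscreen` covers
the whole analysis path:

* **Plate QC and normalization** — per-plate control statistics, the Z′
  factor `Z′ = 1 − 3(SD₊ + SD₋)/|μ₊ − μ₋|` and signal-to-background,
  then plate-wise percent-activity normalization (DMSO neutral level → 0,
  cytotoxic positive control → −100).
* **Curve fitting and classing** — the four-parameter Hill model
  `r(c) = s₀ + (s∞ − s₀)/(1 + (10^L/c)^h)` fitted by bounded multi-start
  least squares, qHTS curve classes (−1.x complete, −2.x incomplete, −3
  single-point, 4 inactive), and a normalized curve AUC (100 = full kill
  across the tested range).
* **Activity calling** — the 4-criterion rule (high-quality class, six-SD
  signal drop, IC50 ≤ 10 μM, maximal response ≥ 65%), 2-of-3 replicate
  consensus, and panel-level categories: pan-active, potent (< 100 nM),
  tumor-type-selective, fibroblast-counter-screen-clean, and membership in
  a pediatric dosing/safety annotation list (CPC).
* **Profile analysis** — compounds × cell lines AUC or log-IC50 matrices,
  hierarchical clustering with pairwise-complete distances,
  hypergeometric target/indication enrichment with BH correction, and
  2D-vs-3D potency concordance.
* **Spheroid readouts** — CellTiter-Glo, PI/Hoechst-ratio imaging
  viability, and caspase-3/7 percent activation against a staurosporine
  anchor, all feeding the same fitting/calling machinery.
* **Synthetic screens** — a ground-truth generator (response archetypes,
  multiplicative plate noise, coupled spheroid channels) used by the whole
  validation suite.

## Worked example

Simulate a 12-compound screen with known truth on one cell line, fit and
classify every curve, and call activity:

```python
import qscreen as q

series = q.make_dilution_series(top_conc=46e-6, n_points=11, fold=3)
mix = {"complete_full": 0.3, "complete_partial": 0.2, "incomplete": 0.2,
       "single_point": 0.1, "inactive": 0.2}
library = q.generate_library(12, mix, seed=5)
plates = q.simulate_viability_screen(library, ["TC32"], series,
                                     noise_cv=0.05, seed=6)
result = q.analyze_viability_screen(plates)
print(result.fits[["compound_id", "curve_class", "log10_ic50",
                   "max_response", "auc", "is_active"]])
```

prints (abridged):

```
compound_id  curve_class  log10_ic50  max_response    auc  is_active
  CPD-00000        -3.00       -4.36        -47.06   3.57      False
  CPD-00001         4.00       -8.20          2.20   0.00      False
  CPD-00002        -1.10       -5.76        -87.66  26.94       True
  CPD-00005        -1.20       -7.16        -71.27  44.12       True
  CPD-00007        -2.20       -5.06        -66.34  15.30       True
  CPD-00011        -2.20       -4.92        -64.18  10.15      False
```

Reading it: `CPD-00002` is a complete, full-efficacy cytotoxic curve (class
−1.1) with IC50 ≈ 1.7 μM and an 88% maximal kill — active. `CPD-00007` is
incomplete (class −2.2, upper plateau beyond the tested range) but still
passes all four criteria, while `CPD-00011` misses the 65% efficacy cutoff
(max response −64.2%) and is therefore inactive despite a qualifying curve
class. `CPD-00000` responds only at the single top concentration (class
−3), which never qualifies.

The dilution arithmetic matches the screening design: an 11-point 1:3
series from 46 μM ends at 0.78 nM, and an 8-point 1:5 series at 0.59 nM.

See `examples/` for QC gating, panel categorization, clustering +
enrichment, and the multiparametric spheroid assay (including the
high-PI/low-caspase signature of a non-apoptotic killer).

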