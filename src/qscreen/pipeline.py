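"""Screen-level orchestration: plates -> series -> fits -> calls -> summary.

These helpers chain the per-module operations for the common case of a whole
screen: assemble normalized series from raw plates, fit and classify every
series, apply the 4-criterion activity rule per replicate, reduce replicates
by the 2-of-3 consensus, and emit tidy tables ready for matrix building and
clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calls import ActivityCall, ActivityThresholds, call_activity, replicate_consensus
from .hillfit import ClassThresholds, classify_curve, compute_auc, fit_hill
from .qc import NormalizedSeries, assemble_series, qc_report
from .simulate import RawPlate

__all__ = ["ScreenResult", "fit_series_table", "consensus_table", "analyze_viability_screen"]


@dataclass
class ScreenResult:
    """All screen-level tables plus the underlying per-series objects."""

    qc: pd.DataFrame
    fits: pd.DataFrame  # one row per compound x cell line x replicate
    consensus: pd.DataFrame  # one row per compound x cell line
    series: list[NormalizedSeries]
    consensus_calls: list[ActivityCall]


def fit_series_table(
    series_list: list[NormalizedSeries],
    activity: ActivityThresholds | None = None,
    classing: ClassThresholds | None = None,
) -> tuple[pd.DataFrame, list[ActivityCall]]:
    """Fit, classify, integrate and call every series; return the fits table."""
    activity = activity or ActivityThresholds()
    rows = []
    per_replicate_calls = []
    for s in series_list:
        fit = fit_hill(s)
        cls = classify_curve(fit, s, classing)
        auc = compute_auc(fit, (s.concentrations.min(), s.concentrations.max()), cls)
        call = call_activity(fit, cls, s, activity)
        per_replicate_calls.append(call)
        rows.append(
            {
                "compound_id": s.compound_id,
                "cell_line": s.cell_line,
                "replicate_index": s.replicate_index,
                "readout": s.readout,
                "log10_ic50": fit.log10_ic50 if fit.converged else np.nan,
                "ic50_molar": fit.ic50 if fit.converged else np.nan,
                "hill_slope": fit.hill_slope,
                "s0": fit.s0,
                "s_inf": fit.s_inf,
                "max_response": fit.max_response,
                "r2": fit.r2,
                "curve_class": cls.signed,
                "auc": auc,
                "is_active": call.is_active,
                **{f"crit_{k}": v for k, v in call.criteria.items()},
            }
        )
    return pd.DataFrame(rows), per_replicate_calls


def consensus_table(
    fits: pd.DataFrame,
    per_replicate_calls: list[ActivityCall],
    quorum: int = 2,
) -> tuple[pd.DataFrame, list[ActivityCall]]:
    """Reduce per-replicate calls/fits to one row per compound x cell line.

    Activity follows the replicate quorum; the summary potency is the median
    IC50 of passing replicates and the summary AUC is the median replicate AUC
    (0 when the consensus is inactive).
    """
    by_key: dict[tuple[str, str], list[ActivityCall]] = {}
    for c in per_replicate_calls:
        by_key.setdefault((c.compound_id, c.cell_line), []).append(c)

    cons_calls = []
    rows = []
    grouped = fits.groupby(["compound_id", "cell_line"], sort=True)
    for (cid, line), g in grouped:
        cc = replicate_consensus(by_key[(cid, line)], quorum=quorum)
        cons_calls.append(cc)
        auc = float(np.median(g["auc"])) if cc.is_active else 0.0
        rows.append(
            {
                "compound_id": cid,
                "cell_line": line,
                "is_active": cc.is_active,
                "n_replicates": len(g),
                "n_replicates_passing": cc.n_replicates_passing,
                "ic50_molar": cc.ic50 if cc.ic50 is not None else np.nan,
                "log10_ic50": np.log10(cc.ic50) if cc.ic50 is not None else np.nan,
                "auc": auc,
            }
        )
    return pd.DataFrame(rows), cons_calls


def analyze_viability_screen(
    plates: list[RawPlate],
    activity: ActivityThresholds | None = None,
    classing: ClassThresholds | None = None,
    quorum: int = 2,
) -> ScreenResult:
    """Run the full per-plate-to-per-compound analysis on raw plates."""
    qc = qc_report(plates)
    series = assemble_series(plates)
    fits, rep_calls = fit_series_table(series, activity, classing)
    cons, cons_calls = consensus_table(fits, rep_calls, quorum=quorum)
    return ScreenResult(qc=qc, fits=fits, consensus=cons, series=series,
                        consensus_calls=cons_calls)
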