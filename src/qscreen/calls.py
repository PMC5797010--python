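"""Activity calling: the 4-criterion rule, replicate consensus, categorization.

A compound is called active in a cell line when, simultaneously:

1. the curve class is high quality (|class| 1.x or 2.x),
2. at least one raw well crossed six neutral-control SDs toward the
   positive-control level,
3. the fitted IC50 is at or below the potency cutoff (default 10 uM),
4. the maximal response magnitude reaches the efficacy cutoff (default 65%).

For replicated assays (3D spheroids run in triplicate) a compound is active
when at least 2 of 3 replicates individually pass; the summary potency is the
median IC50 of the passing replicates.  Categorization then flags pan-active
compounds (active in >= 17 lines), potent ones (IC50 < 100 nM somewhere),
fibroblast-counter-screen-clean ones, tumor-type-selective ones, and members
of the pediatric-dosing annotation list (CPC).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import SchemaError
from .hillfit import CurveClass, HillFit
from .qc import NormalizedSeries

__all__ = [
    "ActivityThresholds",
    "ActivityCall",
    "CompoundCategory",
    "call_activity",
    "replicate_consensus",
    "categorize",
    "hit_rate_percent",
]

CRITERIA = ("class_ok", "six_sd_ok", "potency_ok", "efficacy_ok")


@dataclass(frozen=True)
class ActivityThresholds:
    """Cutoffs of the 4-criterion rule (inclusive comparisons)."""

    ic50_cutoff: float = 10e-6  # molar
    efficacy_cutoff: float = 65.0  # percent response magnitude
    quorum: int = 2  # replicates that must pass (of however many were run)


@dataclass(frozen=True)
class ActivityCall:
    """One active/inactive decision with per-criterion diagnostics.

    For consensus calls, ``criteria`` holds per-criterion quorum votes,
    ``n_replicates_passing`` counts fully-passing replicates, and ``ic50`` is
    the median IC50 of the passing replicates (None when inactive).
    """

    compound_id: str
    cell_line: str
    is_active: bool
    criteria: Mapping[str, bool]
    n_replicates_passing: int = 0
    ic50: float | None = None
    replicate_index: int | None = None


def call_activity(
    fit: HillFit,
    curve_class: CurveClass,
    series: NormalizedSeries,
    thresholds: ActivityThresholds | None = None,
) -> ActivityCall:
    """Apply the 4-criterion activity rule to one replicate series."""
    t = thresholds or ActivityThresholds()
    class_ok = curve_class.is_high_quality
    six_sd_ok = bool(series.six_sd_crossed)
    ic50 = fit.ic50
    potency_ok = ic50 is not None and ic50 <= t.ic50_cutoff
    efficacy_ok = fit.converged and abs(fit.max_response) >= t.efficacy_cutoff
    criteria = {
        "class_ok": class_ok,
        "six_sd_ok": six_sd_ok,
        "potency_ok": potency_ok,
        "efficacy_ok": efficacy_ok,
    }
    active = all(criteria.values())
    return ActivityCall(
        compound_id=series.compound_id,
        cell_line=series.cell_line,
        is_active=active,
        criteria=criteria,
        n_replicates_passing=int(active),
        ic50=ic50,
        replicate_index=series.replicate_index,
    )


def replicate_consensus(
    calls: Sequence[ActivityCall],
    quorum: int = 2,
) -> ActivityCall:
    """Aggregate replicate calls for one compound x cell line.

    Active iff at least ``min(quorum, n_replicates)`` replicates are
    individually active (so a single-replicate call passes through unchanged,
    and triplicates follow the 2-of-3 rule).  Summary potency is the median
    IC50 of the passing replicates.  Order of replicates is immaterial.
    """
    if not calls:
        raise ValueError("replicate_consensus needs at least one call")
    cid = calls[0].compound_id
    line = calls[0].cell_line
    if any(c.compound_id != cid or c.cell_line != line for c in calls):
        raise SchemaError("replicate calls must share compound and cell line")
    need = min(quorum, len(calls))
    n_pass = sum(c.is_active for c in calls)
    active = n_pass >= need
    criteria = {
        k: sum(bool(c.criteria.get(k, False)) for c in calls) >= need for k in CRITERIA
    }
    passing_ic50 = sorted(
        c.ic50 for c in calls if c.is_active and c.ic50 is not None
    )
    ic50 = statistics.median(passing_ic50) if (active and passing_ic50) else None
    return ActivityCall(
        compound_id=cid,
        cell_line=line,
        is_active=active,
        criteria=criteria,
        n_replicates_passing=n_pass,
        ic50=ic50,
    )


@dataclass(frozen=True)
class CompoundCategory:
    """Screen-level flags for one compound."""

    compound_id: str
    pan_active: bool
    potent: bool
    fibroblast_clean: bool | None
    cpc_member: bool
    selective_for: frozenset[str]
    n_active_lines: int


def categorize(
    consensus_calls: Iterable[ActivityCall],
    tumor_types: Mapping[str, str],
    *,
    cpc_members: set[str] | Mapping[str, bool] | None = None,
    fibroblast_line: str | None = None,
    pan_threshold: int = 17,
    potent_cutoff: float = 100e-9,
) -> list[CompoundCategory]:
    """Categorize compounds from their consensus activity across the panel.

    ``tumor_types`` maps each tumor cell line to its tumor-type label; the
    fibroblast counter-screen line (if any) is excluded from tumor counts.
    Flags: ``pan_active`` (active in >= ``pan_threshold`` tumor lines),
    ``potent`` (active with IC50 strictly below ``potent_cutoff`` in >= 1
    line), ``fibroblast_clean`` (not active in the fibroblast line; None when
    no counter-screen data), ``selective_for {T}`` (active in >= 2 lines of
    tumor type T and in no line of any other type), ``cpc_member`` (from the
    annotation table).

    Raises
    ------
    SchemaError
        If a call references a cell line absent from ``tumor_types`` (and not
        the fibroblast line).
    """
    cpc: set[str]
    if cpc_members is None:
        cpc = set()
    elif isinstance(cpc_members, Mapping):
        cpc = {k for k, v in cpc_members.items() if v}
    else:
        cpc = set(cpc_members)

    by_compound: dict[str, list[ActivityCall]] = {}
    for c in consensus_calls:
        if c.cell_line not in tumor_types and c.cell_line != fibroblast_line:
            raise SchemaError(
                f"cell line {c.cell_line!r} not in the tumor-type map"
            )
        by_compound.setdefault(c.compound_id, []).append(c)

    out = []
    for cid in sorted(by_compound):
        calls = by_compound[cid]
        tumor_calls = [c for c in calls if c.cell_line != fibroblast_line]
        active = [c for c in tumor_calls if c.is_active]
        n_active = len(active)
        active_types = {tumor_types[c.cell_line] for c in active}
        selective: frozenset[str] = frozenset()
        if len(active_types) == 1 and n_active >= 2:
            selective = frozenset(active_types)
        fib_calls = [c for c in calls if c.cell_line == fibroblast_line]
        fibroblast_clean = (
            not any(c.is_active for c in fib_calls) if fib_calls else None
        )
        potent = any(
            c.ic50 is not None and c.ic50 < potent_cutoff for c in active
        )
        out.append(
            CompoundCategory(
                compound_id=cid,
                pan_active=n_active >= pan_threshold,
                potent=potent,
                fibroblast_clean=fibroblast_clean,
                cpc_member=cid in cpc,
                selective_for=selective,
                n_active_lines=n_active,
            )
        )
    return out


def hit_rate_percent(n_active: int, n_tested: int, decimals: int = 1) -> float:
    """Active fraction as a percentage, rounded to ``decimals`` places."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    return round(100.0 * n_active / n_tested, decimals)
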