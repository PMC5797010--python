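"""Activity-profile analysis: matrices, clustering, enrichment, 2D-vs-3D.

The activity matrix holds one row per compound and one column per cell line.
Two value conventions are supported, mirroring how screening heatmaps are
drawn: AUC matrices (joint potency-efficacy summaries; inactive cells are 0)
and log10 IC50 matrices (inactive cells carry no value and stay missing).

Hierarchical clustering uses pairwise-complete distances so potency matrices
with missing cells can still be ordered; target/indication enrichment among a
hit set is the one-sided hypergeometric upper tail with Benjamini-Hochberg
adjustment across categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.stats import hypergeom, spearmanr
from statsmodels.stats.multitest import multipletests

from .errors import DataIntegrityError, InvalidParameterError

__all__ = [
    "build_matrix",
    "ClusterResult",
    "hierarchical_cluster",
    "cut_clusters",
    "EnrichmentResult",
    "enrichment_test",
    "compare_2d_3d",
    "plot_activity_heatmap",
]


def build_matrix(
    summary: pd.DataFrame,
    value_kind: str = "auc",
) -> pd.DataFrame:
    """Pivot a consensus summary table into a compounds x cell lines matrix.

    ``summary`` needs columns ``compound_id, cell_line, is_active`` plus the
    value column (``auc`` or ``log10_ic50``).  For ``value_kind="auc"``
    inactive cells are set to 0; for ``"log_ic50"`` inactive cells are left
    missing (NaN), matching the grey cells of potency heatmaps.

    Raises
    ------
    DataIntegrityError
        On duplicate (compound, cell line) entries.
    """
    if value_kind not in ("auc", "log_ic50"):
        raise InvalidParameterError(f"unknown value_kind {value_kind!r}")
    col = "auc" if value_kind == "auc" else "log10_ic50"
    dup = summary.duplicated(subset=["compound_id", "cell_line"], keep=False)
    if dup.any():
        offenders = (
            summary.loc[dup, ["compound_id", "cell_line"]]
            .drop_duplicates()
            .head(10)
            .to_dict("records")
        )
        raise DataIntegrityError(f"duplicate (compound, cell line) entries: {offenders}")
    values = summary[col].where(summary["is_active"].astype(bool), other=np.nan)
    if value_kind == "auc":
        values = values.fillna(0.0)
    tmp = summary[["compound_id", "cell_line"]].copy()
    tmp["value"] = values
    mat = tmp.pivot(index="compound_id", columns="cell_line", values="value")
    if value_kind == "auc":
        mat = mat.fillna(0.0)
    return mat.sort_index(axis=0).sort_index(axis=1)


def _pairwise_complete_condensed(
    x: np.ndarray, min_overlap: int
) -> np.ndarray:
    """Condensed Euclidean distances with pairwise-complete missing handling.

    Shared-cell squared differences are rescaled to the full dimension
    (d = sqrt(p / m * sum over m shared cells)); pairs with fewer than
    ``min_overlap`` shared finite cells get the maximum observed distance.
    """
    n, p = x.shape
    finite = np.isfinite(x)
    out = np.empty(n * (n - 1) // 2)
    k = 0
    sparse_pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            m = finite[i] & finite[j]
            nm = int(m.sum())
            if nm < min_overlap:
                out[k] = np.nan
                sparse_pairs.append(k)
            else:
                diff = x[i, m] - x[j, m]
                out[k] = np.sqrt(p / nm * float(diff @ diff))
            k += 1
    if sparse_pairs:
        fallback = np.nanmax(out) if np.isfinite(out).any() else 0.0
        out[sparse_pairs] = fallback
    return out


@dataclass(frozen=True)
class ClusterResult:
    """Row/column dendrograms of an activity matrix."""

    row_linkage: np.ndarray
    row_order: list[str]
    col_linkage: np.ndarray | None
    col_order: list[str]
    row_ids: list[str]
    col_ids: list[str]


def hierarchical_cluster(
    matrix: pd.DataFrame,
    distance: str = "euclidean",
    linkage_method: str = "complete",
    *,
    min_overlap: int = 3,
    cluster_columns: bool = True,
) -> ClusterResult:
    """Hierarchically cluster the rows (and columns) of an activity matrix.

    Rows are sorted by id before clustering so leaf order is deterministic and
    invariant to input row permutation (ties broken by id).  All-missing rows
    are excluded with a warning.  Missing cells are handled by
    pairwise-complete distances with a ``min_overlap`` requirement; pairs
    sharing fewer finite cells are assigned the maximum observed distance.
    """
    if distance != "euclidean":
        raise InvalidParameterError("only Euclidean distance is implemented")
    mat = matrix.sort_index(axis=0).sort_index(axis=1)
    all_missing = mat.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"excluding {int(all_missing.sum())} all-missing rows from clustering: "
            f"{list(mat.index[all_missing])[:5]}",
            stacklevel=2,
        )
        mat = mat.loc[~all_missing]
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise InvalidParameterError("need >= 2 rows and >= 2 columns to cluster")

    x = mat.to_numpy(dtype=float)
    d_rows = _pairwise_complete_condensed(x, min_overlap)
    zr = linkage(d_rows, method=linkage_method)
    row_order = [mat.index[i] for i in leaves_list(zr)]

    zc = None
    col_order = list(mat.columns)
    if cluster_columns:
        d_cols = _pairwise_complete_condensed(x.T, min_overlap)
        zc = linkage(d_cols, method=linkage_method)
        col_order = [mat.columns[i] for i in leaves_list(zc)]

    return ClusterResult(
        row_linkage=zr,
        row_order=row_order,
        col_linkage=zc,
        col_order=col_order,
        row_ids=list(mat.index),
        col_ids=list(mat.columns),
    )


def cut_clusters(result: ClusterResult, k: int, axis: str = "rows") -> dict[str, int]:
    """Cut the row (or column) dendrogram into ``k`` flat clusters."""
    if axis == "rows":
        z, ids = result.row_linkage, result.row_ids
    else:
        if result.col_linkage is None:
            raise InvalidParameterError("columns were not clustered")
        z, ids = result.col_linkage, result.col_ids
    labels = fcluster(z, t=k, criterion="maxclust")
    return dict(zip(ids, (int(v) for v in labels)))


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation of one annotation category."""

    category: str
    k: int  # hits in the category
    K: int  # category size in the background
    n: int  # annotated hit-set size
    N: int  # annotated background size
    p_value: float
    q_value: float


def enrichment_test(
    hit_set: Iterable[str],
    background: Iterable[str],
    category_map: Mapping[str, str],
) -> list[EnrichmentResult]:
    """Test each annotation category for over-representation among the hits.

    The background is restricted to compounds with a non-empty annotation in
    ``category_map``; the hit set must be a subset of the background.  For
    each category the p-value is the one-sided hypergeometric upper tail
    P(X >= k), and q-values are Benjamini-Hochberg across the tested
    categories.  Results are sorted by p-value.

    Raises
    ------
    InvalidParameterError
        Empty background, or hits outside the background.
    """
    bg = set(background)
    hits = set(hit_set)
    if not bg:
        raise InvalidParameterError("background must not be empty")
    if not hits <= bg:
        raise InvalidParameterError("hit_set must be a subset of the background")

    annotated_bg = sorted(c for c in bg if category_map.get(c, "") != "")
    annotated_hits = [c for c in annotated_bg if c in hits]
    N, n = len(annotated_bg), len(annotated_hits)
    if N == 0:
        return []

    categories = sorted({category_map[c] for c in annotated_bg})
    rows = []
    for cat in categories:
        members = {c for c in annotated_bg if category_map[c] == cat}
        K = len(members)
        k = sum(1 for c in annotated_hits if c in members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((cat, k, K, p))
    qs = multipletests([r[3] for r in rows], method="fdr_bh")[1]
    results = [
        EnrichmentResult(cat, k, K, n, N, p, float(q))
        for (cat, k, K, p), q in zip(rows, qs)
    ]
    return sorted(results, key=lambda r: (r.p_value, r.category))


def compare_2d_3d(
    pairs: pd.DataFrame,
    *,
    activity_cutoff: float = 10e-6,
    min_pairs: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare monolayer (2D) and spheroid (3D) potencies per cell line.

    ``pairs`` needs columns ``compound_id, cell_line, ic50_2d, ic50_3d``
    (molar; NaN = no potency determined).  A compound counts as active in a
    format when its potency there is finite and at most ``activity_cutoff``
    (the ">10 uM or no effect" inactivity rule).  Returns

    * a per-line table with the Spearman rank correlation of log10 potencies
      over compounds active in both formats (NaN, with a warning, below
      ``min_pairs``), and
    * a per-compound concordance table labeling each pair
      ``concordant_active | concordant_inactive | 2d_only | 3d_only`` with the
      log-potency difference where defined.
    """
    req = {"compound_id", "cell_line", "ic50_2d", "ic50_3d"}
    if not req <= set(pairs.columns):
        raise InvalidParameterError(f"pairs table needs columns {sorted(req)}")

    conc_rows = []
    corr_rows = []
    for line, g in pairs.groupby("cell_line", sort=True):
        a2 = np.isfinite(g["ic50_2d"]) & (g["ic50_2d"] <= activity_cutoff)
        a3 = np.isfinite(g["ic50_3d"]) & (g["ic50_3d"] <= activity_cutoff)
        label = np.select(
            [a2 & a3, ~a2 & ~a3, a2 & ~a3],
            ["concordant_active", "concordant_inactive", "2d_only"],
            default="3d_only",
        )
        dlog = np.where(
            np.isfinite(g["ic50_2d"]) & np.isfinite(g["ic50_3d"]),
            np.log10(g["ic50_3d"]) - np.log10(g["ic50_2d"]),
            np.nan,
        )
        sub = g[["compound_id", "cell_line"]].copy()
        sub["label"] = label
        sub["delta_log10_ic50"] = dlog
        conc_rows.append(sub)

        both = g[a2 & a3]
        if len(both) >= min_pairs:
            rho = float(
                spearmanr(np.log10(both["ic50_2d"]), np.log10(both["ic50_3d"])).statistic
            )
        else:
            warnings.warn(
                f"{line}: only {len(both)} compounds active in both formats; "
                "correlation omitted",
                stacklevel=2,
            )
            rho = float("nan")
        corr_rows.append({"cell_line": line, "rank_correlation": rho, "n_pairs": int(len(both))})

    return pd.DataFrame(corr_rows), pd.concat(conc_rows, ignore_index=True)


def plot_activity_heatmap(matrix: pd.DataFrame, result: ClusterResult, path=None):
    """Render a clustered activity heatmap (missing cells grey); optional save."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = matrix.loc[result.row_order, result.col_order]
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(result.col_order)), max(4, 0.12 * len(result.row_order))))
    cmap = plt.get_cmap("Reds").copy()
    cmap.set_bad("lightgrey")
    im = ax.imshow(np.ma.masked_invalid(ordered.to_numpy()), aspect="auto", cmap=cmap)
    ax.set_xticks(range(len(result.col_order)), result.col_order, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.6)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
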