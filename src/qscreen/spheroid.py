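"""3D-spheroid multiparametric readouts -> normalized dose-response series.

Spheroid plates carry four channels per well: CellTiter-Glo luminescence
(ATP, live cells), propidium-iodide and Hoechst mean intensities (dead cells
and total cells from imaging), and a caspase-3/7 channel (apoptosis).  This
module converts them into the same percent-activity series the monolayer
pipeline uses, so the shared Hill fitting, classing and 2-of-3 replicate
calling apply unchanged:

* CTG viability: plate-wise control normalization of the luminescence channel
  (DMSO -> 0, bortezomib-level -> -100);
* imaging viability: the per-well PI/Hoechst mean-intensity ratio, normalized
  the same way against the control-well ratios;
* caspase activation: percent of the staurosporine positive-control signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import LayoutError, UndefinedMetricError
from .qc import NormalizedSeries, assemble_series, control_stats
from .simulate import ROLE_EMPTY, RawPlate

__all__ = [
    "SpheroidWell",
    "collect_spheroid_wells",
    "pi_hoechst_ratio_plate",
    "pi_hoechst_viability",
    "ctg_viability",
    "caspase_activation",
    "readout_agreement",
    "exclude_failed_spheroids",
]


@dataclass(frozen=True)
class SpheroidWell:
    """Per-well multiparametric record merged across imaging channels."""

    plate_id: str
    row: int
    col: int
    role: str
    compound_id: str | None
    concentration: float
    cell_line: str
    replicate_index: int
    ctg_lum: float
    pi_mean: float
    hoechst_mean: float
    caspase_mean: float | None = None
    diameter: float | None = None


def _channel_map(plates: list[RawPlate]) -> dict[tuple[int, str], RawPlate]:
    out: dict[tuple[int, str], RawPlate] = {}
    for p in plates:
        key = (p.replicate_index, p.readout)
        if key in out:
            raise LayoutError(f"duplicate plate for replicate/readout {key}")
        out[key] = p
    return out


def collect_spheroid_wells(plates: list[RawPlate]) -> list[SpheroidWell]:
    """Merge per-readout plates of one cell line into per-well records."""
    chans = _channel_map(plates)
    reps = sorted({r for r, _ in chans})
    wells: list[SpheroidWell] = []
    for rep in reps:
        lum = chans[(rep, "luminescence")]
        pi = chans[(rep, "pi_intensity")]
        hoe = chans[(rep, "hoechst_intensity")]
        casp = chans.get((rep, "caspase_intensity"))
        w = lum.layout.wells
        for i in range(lum.layout.n_wells):
            if w["role"].iat[i] == ROLE_EMPTY:
                continue
            wells.append(
                SpheroidWell(
                    plate_id=lum.plate_id,
                    row=int(w["row"].iat[i]),
                    col=int(w["col"].iat[i]),
                    role=w["role"].iat[i],
                    compound_id=w["compound_id"].iat[i],
                    concentration=float(w["concentration"].iat[i]),
                    cell_line=lum.cell_line,
                    replicate_index=rep,
                    ctg_lum=float(lum.values[i]),
                    pi_mean=float(pi.values[i]),
                    hoechst_mean=float(hoe.values[i]),
                    caspase_mean=float(casp.values[i]) if casp is not None else None,
                )
            )
    return wells


def exclude_failed_spheroids(
    plate: RawPlate, diameters: np.ndarray, min_diameter: float
) -> RawPlate:
    """Mask wells whose spheroid never formed (diameter below the floor).

    Returns a copy of the plate with failed wells re-rolled as empty so they
    drop out of normalization and series assembly.
    """
    diameters = np.asarray(diameters, dtype=float)
    if diameters.shape != (plate.layout.n_wells,):
        raise LayoutError("diameters must align with the plate's wells")
    failed = diameters < min_diameter
    if not failed.any():
        return plate
    wells = plate.layout.wells.copy()
    wells.loc[failed, "role"] = ROLE_EMPTY
    wells.loc[failed, "compound_id"] = None
    wells.loc[failed, "concentration"] = np.nan
    layout = type(plate.layout)(plate.layout.n_rows, plate.layout.n_cols, wells)
    return RawPlate(
        plate.plate_id, plate.cell_line, plate.readout, layout,
        plate.values, plate.replicate_index,
    )


def pi_hoechst_ratio_plate(pi_plate: RawPlate, hoechst_plate: RawPlate) -> RawPlate:
    """Per-well PI/Hoechst mean-intensity ratio as a derived pseudo-plate.

    Wells with non-positive Hoechst intensity cannot be ratioed and are
    excluded with a warning (re-rolled as empty).
    """
    if pi_plate.layout.n_wells != hoechst_plate.layout.n_wells:
        raise LayoutError("PI and Hoechst plates must share a layout")
    role = pi_plate.layout.wells["role"].to_numpy()
    used = role != ROLE_EMPTY
    bad = used & (hoechst_plate.values <= 0)
    hoechst = np.where(hoechst_plate.values > 0, hoechst_plate.values, 1.0)
    ratio = np.where(used & ~bad, pi_plate.values / hoechst, 0.0)
    wells = pi_plate.layout.wells
    if bad.any():
        warnings.warn(
            f"plate {pi_plate.plate_id}: excluding {int(bad.sum())} wells with "
            "non-positive Hoechst intensity",
            stacklevel=2,
        )
        wells = wells.copy()
        wells.loc[bad, "role"] = ROLE_EMPTY
        wells.loc[bad, "compound_id"] = None
        wells.loc[bad, "concentration"] = np.nan
    layout = type(pi_plate.layout)(pi_plate.layout.n_rows, pi_plate.layout.n_cols, wells)
    return RawPlate(
        f"{pi_plate.plate_id}:pi_hoechst",
        pi_plate.cell_line,
        "pi_hoechst_ratio",
        layout,
        ratio,
        pi_plate.replicate_index,
    )


def pi_hoechst_viability(
    pi_plates: list[RawPlate], hoechst_plates: list[RawPlate]
) -> list[NormalizedSeries]:
    """Imaging-based viability series from paired PI and Hoechst plates.

    The per-well PI/Hoechst ratio is normalized plate-wise against the
    neutral- and positive-control ratios (neutral -> 0, positive -> -100) and
    assembled into fit-ready series.  The six-SD flag is evaluated on the raw
    ratio toward the positive-control level (the ratio rises on cell death).
    """
    by_rep_pi = {p.replicate_index: p for p in pi_plates}
    by_rep_hoe = {p.replicate_index: p for p in hoechst_plates}
    if set(by_rep_pi) != set(by_rep_hoe):
        raise LayoutError("PI and Hoechst plates must cover the same replicates")
    ratio_plates = [
        pi_hoechst_ratio_plate(by_rep_pi[r], by_rep_hoe[r]) for r in sorted(by_rep_pi)
    ]
    series = assemble_series(ratio_plates)
    # percent-activity convention: the ratio increases on death, so responses
    # come out negative toward -100 via the control anchors; flip nothing.
    return series


def ctg_viability(lum_plates: list[RawPlate]) -> list[NormalizedSeries]:
    """CellTiter-Glo viability series (identical contract to 2D normalization)."""
    return assemble_series(lum_plates)


def caspase_activation(caspase_plates: list[RawPlate]) -> pd.DataFrame:
    """Percent caspase-3/7 activation relative to the staurosporine control.

    Per well: ``100 * (caspase - mean_neutral) / (mean_positive -
    mean_neutral)``, where the positive wells carry the staurosporine
    anchor; 0 = basal, 100 = full staurosporine-level activation.  Returns a
    tidy per-well table sorted by compound and concentration.

    Raises
    ------
    UndefinedMetricError
        Equal control means.
    QCError
        Fewer than 2 wells in either control population.
    """
    rows = []
    for p in caspase_plates:
        st = control_stats(p)
        sep = st.mean_positive - st.mean_neutral
        if sep == 0:
            raise UndefinedMetricError(
                f"plate {p.plate_id}: caspase control means are equal"
            )
        w = p.layout.wells
        mask = (w["role"] == "sample").to_numpy()
        pct = 100.0 * (p.values[mask] - st.mean_neutral) / sep
        rows.append(
            pd.DataFrame(
                {
                    "plate_id": p.plate_id,
                    "cell_line": p.cell_line,
                    "replicate_index": p.replicate_index,
                    "compound_id": w.loc[mask, "compound_id"].to_numpy(),
                    "concentration_M": w.loc[mask, "concentration"].to_numpy(),
                    "pct_activation": pct,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(
        ["compound_id", "replicate_index", "concentration_M"], ignore_index=True
    )


def readout_agreement(
    potencies_a: pd.DataFrame,
    potencies_b: pd.DataFrame,
    *,
    labels: tuple[str, str] = ("ctg", "imaging"),
    min_pairs: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank-correlate potencies from two readouts per cell line.

    Each input needs columns ``compound_id, cell_line, log10_ic50`` (NaN for
    no potency).  Returns a per-line correlation table (lines with fewer than
    ``min_pairs`` finite pairs are omitted with a warning) and a per-compound
    table of log-potency differences (b - a).
    """
    a, b = labels
    merged = potencies_a.merge(
        potencies_b,
        on=["compound_id", "cell_line"],
        suffixes=(f"_{a}", f"_{b}"),
    )
    ca, cb = f"log10_ic50_{a}", f"log10_ic50_{b}"
    merged["delta_log10_ic50"] = merged[cb] - merged[ca]
    corr_rows = []
    for line, g in merged.groupby("cell_line", sort=True):
        ok = np.isfinite(g[ca]) & np.isfinite(g[cb])
        if ok.sum() < min_pairs:
            warnings.warn(
                f"{line}: only {int(ok.sum())} compounds with potency in both "
                "readouts; correlation omitted",
                stacklevel=2,
            )
            continue
        rho = float(spearmanr(g.loc[ok, ca], g.loc[ok, cb]).statistic)
        corr_rows.append(
            {"cell_line": line, "rank_correlation": rho, "n_pairs": int(ok.sum())}
        )
    return pd.DataFrame(corr_rows), merged
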