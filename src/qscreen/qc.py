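"""Plate quality control and control-based percent-activity normalization.

Every plate carries its own DMSO neutral and cytotoxic positive control wells;
all sample wells are normalized plate-wise against those intra-plate controls:

    response = 100 * (value - mean_neutral) / (mean_neutral - mean_positive)

so a well at the neutral-control level reads 0 and a well at the
positive-control level reads -100 (percent activity; cytotoxic responses are
negative).  Plate quality is summarized by the Z' factor,

    Z' = 1 - 3 * (SD_positive + SD_neutral) / |Mean_positive - Mean_neutral|,

and by the signal-to-background ratio of the control means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DataIntegrityError, QCError, UndefinedMetricError
from .simulate import ROLE_NEUTRAL, ROLE_POSITIVE, ROLE_SAMPLE, RawPlate

__all__ = [
    "ControlStats",
    "QCMetrics",
    "NormalizedSeries",
    "control_stats",
    "z_prime",
    "signal_to_background",
    "qc_metrics",
    "normalize_values",
    "normalize_plate",
    "assemble_series",
    "qc_report",
]


@dataclass(frozen=True)
class ControlStats:
    """Sample means and SDs (n-1 denominator) of the two control populations."""

    mean_neutral: float
    sd_neutral: float
    mean_positive: float
    sd_positive: float
    n_neutral: int
    n_positive: int


@dataclass(frozen=True)
class QCMetrics:
    z_prime: float
    signal_to_background: float


@dataclass
class NormalizedSeries:
    """One compound x cell line x replicate concentration-response vector.

    ``concentrations`` are molar, sorted ascending; ``responses`` are percent
    activity (0 = neutral control, -100 = positive control).
    ``six_sd_crossed`` records whether any raw well signal lay more than six
    neutral-control SDs from the neutral mean in the direction of the positive
    control (for a luminescence viability readout: six SDs below the neutral
    population).
    """

    compound_id: str
    cell_line: str
    replicate_index: int
    concentrations: np.ndarray
    responses: np.ndarray
    six_sd_crossed: bool
    readout: str = "luminescence"

    def __post_init__(self) -> None:
        order = np.argsort(self.concentrations)
        self.concentrations = np.asarray(self.concentrations, dtype=float)[order]
        self.responses = np.asarray(self.responses, dtype=float)[order]

    @property
    def n_points(self) -> int:
        return len(self.concentrations)


def control_stats(plate: RawPlate, use_median: bool = False) -> ControlStats:
    """Summarize the intra-plate control populations.

    ``use_median`` swaps means for medians (off by default; the Z' formula is
    defined on means).

    Raises
    ------
    QCError
        If the plate has fewer than 2 neutral or 2 positive control wells.
    """
    role = plate.layout.wells["role"].to_numpy()
    neu = plate.values[role == ROLE_NEUTRAL]
    pos = plate.values[role == ROLE_POSITIVE]
    if len(neu) < 2 or len(pos) < 2:
        raise QCError(
            f"plate {plate.plate_id}: need >= 2 neutral and 2 positive control "
            f"wells, got {len(neu)} / {len(pos)}"
        )
    center = np.median if use_median else np.mean
    return ControlStats(
        mean_neutral=float(center(neu)),
        sd_neutral=float(np.std(neu, ddof=1)),
        mean_positive=float(center(pos)),
        sd_positive=float(np.std(pos, ddof=1)),
        n_neutral=len(neu),
        n_positive=len(pos),
    )


def z_prime(stats: ControlStats) -> float:
    """Z' assay-quality index; 1 is ideal, <= 0 unusable.

    Uses the absolute separation of the control means in the denominator so the
    index stays <= 1 for signal-decreasing (cytotoxicity) readouts.
    """
    sep = abs(stats.mean_positive - stats.mean_neutral)
    if sep == 0:
        raise UndefinedMetricError("Z' undefined: control means are equal")
    return 1.0 - 3.0 * (stats.sd_positive + stats.sd_neutral) / sep


def signal_to_background(stats: ControlStats) -> float:
    """Neutral over positive control mean."""
    if stats.mean_positive <= 0:
        raise UndefinedMetricError("S:B undefined: positive control mean is not > 0")
    return stats.mean_neutral / stats.mean_positive


def qc_metrics(stats: ControlStats) -> QCMetrics:
    return QCMetrics(z_prime(stats), signal_to_background(stats))


def normalize_values(values: np.ndarray | float, stats: ControlStats) -> np.ndarray:
    """Map raw signals to percent activity (neutral -> 0, positive -> -100)."""
    sep = stats.mean_neutral - stats.mean_positive
    if sep == 0:
        raise UndefinedMetricError("normalization undefined: control means are equal")
    return 100.0 * (np.asarray(values, dtype=float) - stats.mean_neutral) / sep


def normalize_plate(
    plate: RawPlate,
    stats: ControlStats | None = None,
    *,
    sd_multiplier: float = 6.0,
) -> pd.DataFrame:
    """Normalize the sample wells of one plate to its intra-plate controls.

    Returns a tidy frame with one row per sample well: compound_id,
    concentration_M, raw value, percent-activity response, and a
    ``six_sd_crossed`` flag evaluated on the raw signal against the neutral
    population (see :func:`assemble_series`).
    """
    if stats is None:
        stats = control_stats(plate)
    wells = plate.layout.wells
    mask = (wells["role"] == ROLE_SAMPLE).to_numpy()
    raw = plate.values[mask]
    resp = normalize_values(raw, stats)
    direction = math.copysign(1.0, stats.mean_positive - stats.mean_neutral)
    crossed = (raw - stats.mean_neutral) * direction > sd_multiplier * stats.sd_neutral
    return pd.DataFrame(
        {
            "plate_id": plate.plate_id,
            "cell_line": plate.cell_line,
            "readout": plate.readout,
            "replicate_index": plate.replicate_index,
            "compound_id": wells.loc[mask, "compound_id"].to_numpy(),
            "concentration_M": wells.loc[mask, "concentration"].to_numpy(),
            "raw_value": raw,
            "response": resp,
            "six_sd_crossed": crossed,
        }
    )


def assemble_series(
    plates: Iterable[RawPlate] | pd.DataFrame,
    *,
    sd_multiplier: float = 6.0,
) -> list[NormalizedSeries]:
    """Normalize plates and group wells into per-compound response series.

    Accepts either raw plates or an already-normalized well table (the output
    of :func:`normalize_plate`, concatenated).  Wells are grouped by
    (compound, cell line, replicate, readout); concentrations are sorted
    ascending.  ``six_sd_crossed`` is true when any raw well signal lies more
    than ``sd_multiplier`` neutral SDs from the neutral mean toward the
    positive-control level, evaluated per plate on raw signals.

    Raises
    ------
    DataIntegrityError
        If the same (compound, concentration, replicate, cell line, readout)
        appears more than once.
    """
    if isinstance(plates, pd.DataFrame):
        table = plates
    else:
        frames = [normalize_plate(p, sd_multiplier=sd_multiplier) for p in plates]
        table = pd.concat(frames, ignore_index=True)

    dup_keys = ["compound_id", "concentration_M", "replicate_index", "cell_line", "readout"]
    dups = table.duplicated(subset=dup_keys, keep=False)
    if dups.any():
        offenders = (
            table.loc[dups, dup_keys].drop_duplicates().head(10).to_dict("records")
        )
        raise DataIntegrityError(
            f"duplicate (compound, concentration, replicate, cell line) wells: {offenders}"
        )

    out: list[NormalizedSeries] = []
    group_keys = ["compound_id", "cell_line", "replicate_index", "readout"]
    for (cid, line, rep, readout), g in table.groupby(group_keys, sort=True):
        out.append(
            NormalizedSeries(
                compound_id=cid,
                cell_line=line,
                replicate_index=int(rep),
                concentrations=g["concentration_M"].to_numpy(),
                responses=g["response"].to_numpy(),
                six_sd_crossed=bool(g["six_sd_crossed"].any()),
                readout=readout,
            )
        )
    return out


def qc_report(plates: Iterable[RawPlate]) -> pd.DataFrame:
    """Per-plate QC table: Z', S:B and control-well counts."""
    rows = []
    for p in plates:
        st = control_stats(p)
        rows.append(
            {
                "plate_id": p.plate_id,
                "cell_line": p.cell_line,
                "readout": p.readout,
                "z_prime": z_prime(st),
                "s_b": signal_to_background(st),
                "n_neutral": st.n_neutral,
                "n_positive": st.n_positive,
            }
        )
    return pd.DataFrame(rows)
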