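"""Synthetic quantitative HTS screens with known ground truth.

This module generates compound libraries whose members carry ground-truth
concentration-response parameters, and simulates the two plate formats the
analysis pipeline consumes:

* 1536-well (32 x 48) monolayer viability plates read by an ATP-dependent
  luminescence channel, with DMSO neutral controls and a cytotoxic positive
  control (bortezomib-like, near-complete kill);
* 384-well (16 x 24) spheroid plates with four coupled readouts per well
  (CellTiter-Glo luminescence, propidium-iodide and Hoechst mean intensities,
  and a caspase-3/7 channel), run in replicate.

The viability ground truth is the Hill model

    v(c) = 1 - E * c^h / (c^h + IC50^h),        E = true_efficacy / 100,

and well signals are the cell line's baseline times v(c) with multiplicative
Gaussian noise truncated at zero.  Library members fall into five response
archetypes that map onto the qHTS curve classes by construction:
``complete_full`` (both plateaus in range, efficacy > 80%), ``complete_partial``
(efficacy 30-80%), ``incomplete`` (IC50 within half a decade of the top tested
concentration, so the lower plateau falls outside range), ``single_point``
(steep response at the top concentration only) and ``inactive``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, LayoutError

__all__ = [
    "ARCHETYPES",
    "PLATE_FORMATS",
    "DilutionSeries",
    "make_dilution_series",
    "CompoundRecord",
    "generate_library",
    "largest_remainder_counts",
    "PlateLayout",
    "build_plate_layout",
    "RawPlate",
    "simulate_viability_plate",
    "simulate_viability_screen",
    "SpheroidCoupling",
    "simulate_spheroid_plate",
    "hill_viability",
    "true_response_magnitude",
    "is_truly_active",
    "library_to_table",
]

ARCHETYPES = (
    "complete_full",
    "complete_partial",
    "incomplete",
    "single_point",
    "inactive",
)

#: plate format name -> (n_rows, n_cols)
PLATE_FORMATS = {"1536": (32, 48), "384": (16, 24)}

ROLE_SAMPLE = "sample"
ROLE_NEUTRAL = "neutral_control"
ROLE_POSITIVE = "positive_control"
ROLE_EMPTY = "empty"


# ---------------------------------------------------------------------------
# dilution series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DilutionSeries:
    """A geometric dilution series, top concentration first.

    Attributes
    ----------
    top_conc : float
        Highest tested concentration, molar.
    n_points : int
        Number of concentrations.
    fold : float
        Dilution factor between consecutive points (> 1).
    """

    top_conc: float
    n_points: int
    fold: float

    def concentrations(self) -> np.ndarray:
        """Concentrations in molar, strictly decreasing from ``top_conc``."""
        return self.top_conc / self.fold ** np.arange(self.n_points)

    @property
    def bottom_conc(self) -> float:
        return self.top_conc / self.fold ** (self.n_points - 1)


def make_dilution_series(top_conc: float, n_points: int, fold: float) -> DilutionSeries:
    """Build a geometric dilution series (e.g. 11-point 1:3 from 46 uM).

    Raises
    ------
    InvalidParameterError
        If ``top_conc <= 0``, ``n_points < 2`` or ``fold <= 1``.
    """
    if not (top_conc > 0):
        raise InvalidParameterError(f"top_conc must be positive, got {top_conc}")
    if n_points < 2:
        raise InvalidParameterError(f"n_points must be >= 2, got {n_points}")
    if not (fold > 1):
        raise InvalidParameterError(f"fold must be > 1, got {fold}")
    return DilutionSeries(float(top_conc), int(n_points), float(fold))


# ---------------------------------------------------------------------------
# compound library
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompoundRecord:
    """A library member with annotations and ground-truth response parameters.

    ``true_ic50`` is the base potency (molar); per-cell-line potency is
    ``ic50_for(line)``, which applies the optional ``line_log10_shift`` and
    returns ``None`` for lines outside ``responsive_lines`` (a compound may be
    active in some lines only).  ``true_efficacy`` is the percent viability
    loss at saturation; the ``inactive`` archetype has no IC50 and efficacy 0.
    """

    compound_id: str
    name: str
    indication_category: str
    target_moa: str
    cpc_member: bool
    archetype: str
    true_ic50: float | None
    true_hill: float
    true_efficacy: float
    apoptotic: bool = True
    line_log10_shift: Mapping[str, float] = field(default_factory=dict)
    responsive_lines: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise InvalidParameterError(f"unknown archetype {self.archetype!r}")
        if self.archetype == "inactive":
            if self.true_ic50 is not None or self.true_efficacy != 0:
                raise InvalidParameterError(
                    "inactive archetype must have no IC50 and efficacy 0"
                )
        else:
            if self.true_ic50 is None or not self.true_ic50 > 0:
                raise InvalidParameterError("true_ic50 must be positive when present")
        if not self.true_hill > 0:
            raise InvalidParameterError("true_hill must be positive")
        if not 0 <= self.true_efficacy <= 100:
            raise InvalidParameterError("true_efficacy must lie in [0, 100]")

    def ic50_for(self, cell_line: str) -> float | None:
        """Ground-truth IC50 in ``cell_line`` (molar), or None if unresponsive."""
        if self.true_ic50 is None:
            return None
        if self.responsive_lines is not None and cell_line not in self.responsive_lines:
            return None
        shift = self.line_log10_shift.get(cell_line, 0.0)
        return self.true_ic50 * 10.0 ** shift


def largest_remainder_counts(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Apportion ``n`` items to keys by largest-remainder rounding.

    Quotas ``n * p`` are floored; remaining items go to the largest fractional
    parts, ties broken by key order in ``proportions``.
    """
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise InvalidParameterError(f"proportions must sum to 1, got {total}")
    if any(p < 0 for p in proportions.values()):
        raise InvalidParameterError("proportions must be nonnegative")
    keys = list(proportions)
    quotas = [n * proportions[k] for k in keys]
    counts = {k: int(math.floor(q)) for k, q in zip(keys, quotas)}
    remainder = n - sum(counts.values())
    order = sorted(range(len(keys)), key=lambda i: (-(quotas[i] - math.floor(quotas[i])), i))
    for i in order[:remainder]:
        counts[keys[i]] += 1
    return counts


DEFAULT_ARCHETYPE_MIX = {
    "complete_full": 0.15,
    "complete_partial": 0.10,
    "incomplete": 0.08,
    "single_point": 0.04,
    "inactive": 0.63,
}

DEFAULT_ANNOTATION_MODEL = {
    "indications": {
        "antineoplastic": 0.45,
        "antiinflammatory": 0.10,
        "antiparasitic/protozoal": 0.08,
        "antiviral": 0.07,
        "cardiovascular": 0.08,
        "immunosuppressant": 0.05,
        "other": 0.17,
    },
    "targets": {
        "DNA topoisomerase": 0.08,
        "HDAC": 0.06,
        "proteasome": 0.04,
        "mTOR": 0.05,
        "tubulin polymerization": 0.05,
        "kinase": 0.22,
        "": 0.50,
    },
    "cpc_rate": 0.22,
}


def generate_library(
    n_compounds: int,
    archetype_mix: Mapping[str, float] | None = None,
    annotation_model: Mapping | None = None,
    *,
    cell_lines: Sequence[str] | None = None,
    line_log10_spread: float = 0.0,
    ic50_range: tuple[float, float] = (1e-9, 30e-6),
    top_conc: float = 46e-6,
    bottom_conc: float = 0.78e-9,
    apoptotic_rate: float = 0.8,
    seed: int = 0,
) -> list[CompoundRecord]:
    """Generate a compound library with planted concentration-response truth.

    Archetype counts follow ``archetype_mix`` exactly (largest-remainder
    rounding); which compound gets which archetype is a seeded permutation.
    Base IC50s are log-uniform over ``ic50_range`` for the complete archetypes;
    the ``incomplete`` archetype draws IC50 within half a decade below
    ``top_conc`` so the upper plateau falls outside the tested range, and
    ``single_point`` plants a steep curve centred at ``top_conc``.  When
    ``cell_lines`` is given and ``line_log10_spread > 0``, each responsive line
    receives an independent Normal(0, spread) shift of log10 IC50.

    Deterministic given ``seed``.
    """
    if n_compounds < 1:
        raise InvalidParameterError("n_compounds must be >= 1")
    mix = dict(archetype_mix) if archetype_mix is not None else dict(DEFAULT_ARCHETYPE_MIX)
    unknown = set(mix) - set(ARCHETYPES)
    if unknown:
        raise InvalidParameterError(f"unknown archetypes in mix: {sorted(unknown)}")
    model = dict(DEFAULT_ANNOTATION_MODEL)
    if annotation_model is not None:
        model.update(annotation_model)

    counts = largest_remainder_counts(n_compounds, mix)
    labels = np.array([a for a in mix for _ in range(counts[a])], dtype=object)
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)

    ind_names = list(model["indications"])
    ind_probs = np.array([model["indications"][k] for k in ind_names], dtype=float)
    ind_probs = ind_probs / ind_probs.sum()
    tgt_names = list(model["targets"])
    tgt_probs = np.array([model["targets"][k] for k in tgt_names], dtype=float)
    tgt_probs = tgt_probs / tgt_probs.sum()

    lo, hi = ic50_range
    if not (0 < lo < hi):
        raise InvalidParameterError("ic50_range must satisfy 0 < low < high")

    records: list[CompoundRecord] = []
    for i, arche in enumerate(labels):
        cid = f"CPD-{i:05d}"
        indication = str(rng.choice(ind_names, p=ind_probs))
        target = str(rng.choice(tgt_names, p=tgt_probs))
        cpc = bool(rng.random() < model["cpc_rate"])
        apoptotic = bool(rng.random() < apoptotic_rate)

        if arche == "inactive":
            ic50, hill, eff = None, 1.0, 0.0
        elif arche in ("complete_full", "complete_partial"):
            hill = rng.uniform(0.8, 2.0)
            # both plateaus must sit inside [bottom_conc, top_conc]; clip the
            # configurable potency range to the plateau-observable band for
            # the drawn slope (margin 15x on the concentration ratio)
            margin = 15.0 ** (1.0 / hill)
            band_lo, band_hi = bottom_conc * margin, top_conc / margin
            lo_eff = max(lo, band_lo)
            hi_eff = min(hi, band_hi)
            if not lo_eff < hi_eff:
                lo_eff, hi_eff = band_lo, band_hi
            ic50 = 10.0 ** rng.uniform(math.log10(lo_eff), math.log10(hi_eff))
            eff = (
                rng.uniform(85.0, 100.0)
                if arche == "complete_full"
                else rng.uniform(40.0, 75.0)
            )
        elif arche == "incomplete":
            # IC50 within half a decade of the top tested concentration:
            # >= 2 points beyond the 30% floor, upper plateau out of range.
            ic50 = top_conc * 10.0 ** rng.uniform(-0.5, -0.3)
            hill = rng.uniform(0.8, 1.1)
            eff = rng.uniform(85.0, 100.0)
        else:  # single_point
            ic50 = top_conc
            hill = rng.uniform(6.0, 9.0)
            eff = rng.uniform(85.0, 100.0)

        shifts: dict[str, float] = {}
        if cell_lines is not None and line_log10_spread > 0 and ic50 is not None:
            shifts = {
                line: float(rng.normal(0.0, line_log10_spread)) for line in cell_lines
            }
        records.append(
            CompoundRecord(
                compound_id=cid,
                name=f"compound-{i:05d}",
                indication_category=indication,
                target_moa=target,
                cpc_member=cpc,
                archetype=str(arche),
                true_ic50=ic50,
                true_hill=float(hill),
                true_efficacy=float(eff),
                apoptotic=apoptotic,
                line_log10_shift=shifts,
            )
        )
    return records


def library_to_table(records: Iterable[CompoundRecord]) -> pd.DataFrame:
    """Ground-truth table keyed by compound_id (schema version 1)."""
    rows = []
    for r in records:
        rows.append(
            {
                "compound_id": r.compound_id,
                "name": r.name,
                "indication_category": r.indication_category,
                "target_moa": r.target_moa,
                "cpc_member": r.cpc_member,
                "archetype": r.archetype,
                "true_ic50_M": np.nan if r.true_ic50 is None else r.true_ic50,
                "true_hill": r.true_hill,
                "true_efficacy_pct": r.true_efficacy,
                "apoptotic": r.apoptotic,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plate layout and raw plates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlateLayout:
    """Well-role map for one plate.

    ``wells`` holds one row per well with columns ``row, col, role,
    compound_id, concentration``; sample wells carry exactly one
    (compound_id, concentration) pair, control/empty wells carry NaN.
    """

    n_rows: int
    n_cols: int
    wells: pd.DataFrame

    def __post_init__(self) -> None:
        roles = self.wells["role"]
        n_neu = int((roles == ROLE_NEUTRAL).sum())
        n_pos = int((roles == ROLE_POSITIVE).sum())
        if n_neu < 16 or n_pos < 16:
            raise LayoutError(
                f"layout needs >= 16 neutral and 16 positive control wells for "
                f"stable SD estimates, got {n_neu} neutral / {n_pos} positive"
            )
        samples = self.wells[roles == ROLE_SAMPLE]
        if samples["compound_id"].isna().any() or samples["concentration"].isna().any():
            raise LayoutError("every sample well must map to a (compound, concentration)")

    @property
    def n_wells(self) -> int:
        return len(self.wells)

    def sample_capacity(self) -> int:
        return int((self.wells["role"] == ROLE_SAMPLE).sum())


def build_plate_layout(
    compound_ids: Sequence[str],
    series: DilutionSeries,
    plate_format: str = "1536",
    n_neutral: int = 32,
    n_positive: int = 32,
) -> PlateLayout:
    """Lay out compounds as intact dilution series on one plate.

    Control wells occupy the first columns (row-major fill), then each compound
    gets ``series.n_points`` consecutive sample wells at descending
    concentrations; the remainder is empty.

    Raises
    ------
    LayoutError
        If the series does not fit the plate for the requested library chunk.
    """
    if plate_format not in PLATE_FORMATS:
        raise LayoutError(f"unknown plate format {plate_format!r}")
    n_rows, n_cols = PLATE_FORMATS[plate_format]
    n_wells = n_rows * n_cols
    needed = n_neutral + n_positive + len(compound_ids) * series.n_points
    if needed > n_wells:
        raise LayoutError(
            f"{len(compound_ids)} compounds x {series.n_points} points + "
            f"{n_neutral + n_positive} controls = {needed} wells exceed the "
            f"{plate_format}-well plate ({n_wells} wells)"
        )
    concs = series.concentrations()
    role = np.full(n_wells, ROLE_EMPTY, dtype=object)
    cid = np.full(n_wells, None, dtype=object)
    conc = np.full(n_wells, np.nan)
    role[:n_neutral] = ROLE_NEUTRAL
    role[n_neutral : n_neutral + n_positive] = ROLE_POSITIVE
    pos = n_neutral + n_positive
    for c in compound_ids:
        role[pos : pos + series.n_points] = ROLE_SAMPLE
        cid[pos : pos + series.n_points] = c
        conc[pos : pos + series.n_points] = concs
        pos += series.n_points
    idx = np.arange(n_wells)
    wells = pd.DataFrame(
        {
            "row": idx // n_cols,
            "col": idx % n_cols,
            "role": role,
            "compound_id": cid,
            "concentration": conc,
        }
    )
    return PlateLayout(n_rows, n_cols, wells)


@dataclass
class RawPlate:
    """One plate of one readout: layout plus a value per well (arbitrary units).

    ``values`` is aligned with ``layout.wells`` row order.
    """

    plate_id: str
    cell_line: str
    readout: str
    layout: PlateLayout
    values: np.ndarray
    replicate_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.layout.n_wells,):
            raise LayoutError(
                f"plate {self.plate_id}: {self.values.size} values for "
                f"{self.layout.n_wells} wells"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise InvalidParameterError(
                f"plate {self.plate_id}: well values must be finite and >= 0"
            )

    def to_table(self) -> pd.DataFrame:
        """Long-format table, one row per well (schema version 1)."""
        t = self.layout.wells.copy()
        t.insert(0, "plate_id", self.plate_id)
        t["cell_line"] = self.cell_line
        t["readout"] = self.readout
        t["replicate_index"] = self.replicate_index
        t["value"] = self.values
        t = t.rename(columns={"concentration": "concentration_M"})
        return t[
            [
                "plate_id",
                "row",
                "col",
                "role",
                "compound_id",
                "concentration_M",
                "cell_line",
                "readout",
                "replicate_index",
                "value",
            ]
        ]


# ---------------------------------------------------------------------------
# response model and plate simulation
# ---------------------------------------------------------------------------


def hill_viability(c: np.ndarray | float, ic50: float, hill: float, efficacy_pct: float):
    """Fractional viability v(c) = 1 - E c^h / (c^h + IC50^h), E = efficacy/100."""
    c = np.asarray(c, dtype=float)
    e = efficacy_pct / 100.0
    ch = c ** hill
    return 1.0 - e * ch / (ch + ic50 ** hill)


def _sample_viabilities(
    records_by_id: Mapping[str, CompoundRecord],
    cell_line: str,
    layout: PlateLayout,
    positive_residual_viability: float,
    ic50_key: str = "2d",
    shift_3d: float = 1.0,
) -> np.ndarray:
    """Noise-free fractional viability per well in layout order."""
    v = np.ones(layout.n_wells)
    wells = layout.wells
    role = wells["role"].to_numpy()
    v[role == ROLE_POSITIVE] = positive_residual_viability
    sample_idx = np.flatnonzero(role == ROLE_SAMPLE)
    for i in sample_idx:
        rec = records_by_id[wells["compound_id"].iat[i]]
        ic50 = rec.ic50_for(cell_line)
        if ic50 is None:
            continue
        if ic50_key == "3d":
            ic50 = ic50 * shift_3d
        v[i] = float(
            hill_viability(wells["concentration"].iat[i], ic50, rec.true_hill, rec.true_efficacy)
        )
    return v


def simulate_viability_plate(
    records: Sequence[CompoundRecord],
    cell_line: str,
    series: DilutionSeries,
    layout: PlateLayout | None = None,
    *,
    baseline_signal: float = 3000.0,
    positive_residual_viability: float = 0.05,
    noise_cv: float = 0.05,
    plate_id: str | None = None,
    replicate_index: int = 0,
    seed: int = 0,
) -> RawPlate:
    """Simulate one 1536-well luminescence viability plate.

    Sample-well signal is ``baseline_signal * v(c) * (1 + eps)`` with
    ``eps ~ Normal(0, noise_cv)`` and the product truncated at zero; neutral
    wells use v = 1 and positive-control wells use
    ``positive_residual_viability``.  Deterministic given ``seed``.
    """
    if noise_cv < 0:
        raise InvalidParameterError("noise_cv must be >= 0")
    if not 0 <= positive_residual_viability < 1:
        raise InvalidParameterError("positive_residual_viability must lie in [0, 1)")
    if layout is None:
        layout = build_plate_layout([r.compound_id for r in records], series)
    by_id = {r.compound_id: r for r in records}
    missing = set(layout.wells["compound_id"].dropna()) - set(by_id)
    if missing:
        raise LayoutError(f"layout references compounds not in library: {sorted(missing)[:5]}")
    v = _sample_viabilities(by_id, cell_line, layout, positive_residual_viability)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_cv, layout.n_wells) if noise_cv > 0 else np.zeros(layout.n_wells)
    values = np.maximum(0.0, baseline_signal * v * (1.0 + eps))
    values[layout.wells["role"].to_numpy() == ROLE_EMPTY] = 0.0
    pid = plate_id or f"{cell_line}-viab-r{replicate_index}"
    return RawPlate(pid, cell_line, "luminescence", layout, values, replicate_index)


def simulate_viability_screen(
    records: Sequence[CompoundRecord],
    cell_lines: Sequence[str],
    series: DilutionSeries,
    *,
    replicates: int = 1,
    baseline_signal: float = 3000.0,
    baseline_plate_cv: float = 0.15,
    positive_residual_viability: float = 0.05,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> list[RawPlate]:
    """Simulate a whole screen, chunking the library across 1536-well plates.

    Each physical plate draws its own baseline (log-normal around
    ``baseline_signal`` with CV ``baseline_plate_cv``) to create the
    plate-to-plate variation that plate-wise normalization must remove.
    """
    rng = np.random.default_rng(seed)
    n_rows, n_cols = PLATE_FORMATS["1536"]
    capacity = (n_rows * n_cols - 64) // series.n_points
    chunks = [records[i : i + capacity] for i in range(0, len(records), capacity)]
    plates = []
    for line in cell_lines:
        for rep in range(replicates):
            for k, chunk in enumerate(chunks):
                layout = build_plate_layout([r.compound_id for r in chunk], series)
                base = baseline_signal
                if baseline_plate_cv > 0:
                    sigma = math.sqrt(math.log(1 + baseline_plate_cv**2))
                    base = baseline_signal * float(rng.lognormal(-0.5 * sigma**2, sigma))
                plates.append(
                    simulate_viability_plate(
                        chunk,
                        line,
                        series,
                        layout,
                        baseline_signal=base,
                        positive_residual_viability=positive_residual_viability,
                        noise_cv=noise_cv,
                        plate_id=f"{line}-p{k}-r{rep}",
                        replicate_index=rep,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                )
    return plates


@dataclass(frozen=True)
class SpheroidCoupling:
    """Shared latent-death coupling of the four spheroid readouts.

    The latent dead fraction per well is ``d(c) = E c^h / (c^h + (s*IC50)^h)``
    with ``s = shift_3d`` (3D cultures are typically less sensitive than
    monolayers; default 3x).  Channels:

    * luminescence   ``ctg_baseline * (1 - d)``            (ATP ~ live cells)
    * pi_intensity   ``pi_scale * (pi_floor + d)``         (dead-cell stain)
    * hoechst        ``hoechst_baseline`` (near-constant total-cell stain)
    * caspase        ``basal + scale * a``, where the apoptotic fraction ``a``
      is ``d`` for apoptotic compounds and ``nonapoptotic_caspase_frac * d``
      otherwise; the positive control (staurosporine-like) anchors ``a = 1``.

    Viability positive controls (bortezomib-like) use
    ``d = 1 - positive_residual_viability``.
    """

    shift_3d: float = 3.0
    positive_residual_viability: float = 0.05
    ctg_baseline: float = 5000.0
    pi_scale: float = 1000.0
    pi_floor: float = 0.05
    hoechst_baseline: float = 2000.0
    caspase_basal: float = 100.0
    caspase_scale: float = 900.0
    nonapoptotic_caspase_frac: float = 0.05
    noise_cv: float = 0.05


SPHEROID_READOUTS = ("luminescence", "pi_intensity", "hoechst_intensity", "caspase_intensity")


def simulate_spheroid_plate(
    records: Sequence[CompoundRecord],
    cell_line: str,
    series: DilutionSeries,
    layout: PlateLayout | None = None,
    *,
    replicates: int = 3,
    coupling: SpheroidCoupling | None = None,
    plate_id_prefix: str | None = None,
    seed: int = 0,
) -> list[RawPlate]:
    """Simulate 384-well spheroid plates with coupled multiparametric readouts.

    Returns one :class:`RawPlate` per (replicate, readout); replicate plates
    share the ground truth and differ only in noise.  Deterministic given
    ``seed``.
    """
    if replicates < 1:
        raise InvalidParameterError("replicates must be >= 1")
    cp = coupling or SpheroidCoupling()
    if layout is None:
        layout = build_plate_layout(
            [r.compound_id for r in records], series, plate_format="384",
            n_neutral=16, n_positive=16,
        )
    by_id = {r.compound_id: r for r in records}
    role = layout.wells["role"].to_numpy()
    sample = role == ROLE_SAMPLE
    positive = role == ROLE_POSITIVE

    # latent dead fraction per well (0 for neutral/empty)
    v = _sample_viabilities(
        by_id, cell_line, layout, cp.positive_residual_viability,
        ic50_key="3d", shift_3d=cp.shift_3d,
    )
    d = 1.0 - v
    # apoptotic fraction: scales d down for non-apoptotic killers
    a = np.zeros_like(d)
    a[positive] = 1.0  # staurosporine-like anchor on the caspase channel
    for i in np.flatnonzero(sample):
        rec = by_id[layout.wells["compound_id"].iat[i]]
        a[i] = d[i] if rec.apoptotic else cp.nonapoptotic_caspase_frac * d[i]

    channel_means = {
        "luminescence": cp.ctg_baseline * (1.0 - d),
        "pi_intensity": cp.pi_scale * (cp.pi_floor + d),
        "hoechst_intensity": np.full(layout.n_wells, cp.hoechst_baseline),
        "caspase_intensity": cp.caspase_basal + cp.caspase_scale * a,
    }

    rng = np.random.default_rng(seed)
    prefix = plate_id_prefix or f"{cell_line}-sph"
    plates = []
    for rep in range(replicates):
        for readout in SPHEROID_READOUTS:
            mean = channel_means[readout]
            if cp.noise_cv > 0:
                eps = rng.normal(0.0, cp.noise_cv, layout.n_wells)
            else:
                eps = np.zeros(layout.n_wells)
            values = np.maximum(0.0, mean * (1.0 + eps))
            values[role == ROLE_EMPTY] = 0.0
            plates.append(
                RawPlate(
                    f"{prefix}-r{rep}-{readout}",
                    cell_line,
                    readout,
                    layout,
                    values,
                    replicate_index=rep,
                )
            )
    return plates


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def true_response_magnitude(
    record: CompoundRecord,
    cell_line: str,
    conc: float,
    positive_residual_viability: float = 0.05,
) -> float:
    """Noise-free percent-activity response magnitude at one concentration.

    Percent activity is anchored at the intra-plate controls: 0 at the DMSO
    level and -100 at the positive control, which itself retains
    ``positive_residual_viability`` fractional viability.  A complete kill
    therefore normalizes to ``100 / (1 - residual)`` percent, and the planted
    asymptote magnitude is ``true_efficacy / (1 - residual)``.
    """
    ic50 = record.ic50_for(cell_line)
    if ic50 is None:
        return 0.0
    loss = 1.0 - float(hill_viability(conc, ic50, record.true_hill, record.true_efficacy))
    return 100.0 * loss / (1.0 - positive_residual_viability)


def is_truly_active(
    record: CompoundRecord,
    cell_line: str,
    series: DilutionSeries,
    *,
    ic50_cutoff: float = 10e-6,
    efficacy_cutoff: float = 65.0,
    positive_residual_viability: float = 0.05,
) -> bool:
    """Ground-truth activity of a planted compound under the screen's cutoffs.

    A compound is truly active in a line when its ground-truth IC50 there is
    at most ``ic50_cutoff`` and the noise-free percent-activity response at
    the top tested concentration (see :func:`true_response_magnitude`)
    reaches ``efficacy_cutoff``.
    """
    ic50 = record.ic50_for(cell_line)
    if ic50 is None:
        return False
    max_resp = true_response_magnitude(
        record, cell_line, series.top_conc, positive_residual_viability
    )
    return ic50 <= ic50_cutoff and max_resp >= efficacy_cutoff
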