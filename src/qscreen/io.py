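"""Long-format plate tables on disk (delimited text, schema version 1).

One row per well::

    plate_id,row,col,role,compound_id,concentration_M,cell_line,readout,replicate_index,value

``role`` is one of ``sample | neutral_control | positive_control | empty``;
``compound_id`` and ``concentration_M`` are empty for non-sample wells.  The
companion ground-truth table (see :func:`qscreen.simulate.library_to_table`)
is keyed by ``compound_id``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import SchemaError
from .simulate import PlateLayout, RawPlate

__all__ = ["SCHEMA_VERSION", "PLATE_TABLE_COLUMNS", "plates_to_table",
           "write_plate_table", "read_plate_table"]

SCHEMA_VERSION = 1

PLATE_TABLE_COLUMNS = [
    "plate_id", "row", "col", "role", "compound_id", "concentration_M",
    "cell_line", "readout", "replicate_index", "value",
]


def plates_to_table(plates: Iterable[RawPlate]) -> pd.DataFrame:
    """Concatenate plates into one long-format well table."""
    return pd.concat([p.to_table() for p in plates], ignore_index=True)


def write_plate_table(plates: Iterable[RawPlate], path: str | Path) -> None:
    plates_to_table(plates).to_csv(path, index=False)


def read_plate_table(path: str | Path) -> list[RawPlate]:
    """Rebuild :class:`RawPlate` objects from a long-format well table."""
    table = pd.read_csv(path, dtype={"compound_id": "object"})
    missing = set(PLATE_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"plate table missing columns: {sorted(missing)}")
    plates = []
    keys = ["plate_id", "readout", "replicate_index"]
    for (pid, readout, rep), g in table.groupby(keys, sort=True):
        g = g.sort_values(["row", "col"])
        n_rows = int(g["row"].max()) + 1
        n_cols = int(g["col"].max()) + 1
        wells = g[["row", "col", "role", "compound_id", "concentration_M"]].rename(
            columns={"concentration_M": "concentration"}
        )
        wells["compound_id"] = wells["compound_id"].where(
            wells["compound_id"].notna(), None
        )
        layout = PlateLayout(n_rows, n_cols, wells.reset_index(drop=True))
        plates.append(
            RawPlate(
                plate_id=str(pid),
                cell_line=str(g["cell_line"].iloc[0]),
                readout=str(readout),
                layout=layout,
                values=g["value"].to_numpy(dtype=float),
                replicate_index=int(rep),
            )
        )
    return plates
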