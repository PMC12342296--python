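"""Reading and writing the tabular dataset formats.

Three CSV tables describe a dataset (one observation per row, stable
column order, full float precision so a write→load round trip is exact):

``cells.csv``
    cell_id, animal_id, temperature_C, stage, rpa_count (blank if N/A)
``scs.csv``
    cell_id, sc_rank (blank if unassigned), morphology, length_um,
    centromere_um
``foci.csv``
    cell_id, sc_index, focus_index, position_um

``sc_index`` is the 0-based position of the SC within its cell's scored
list, which keys foci to SCs even before ranking.  An XLSX importer for
supplementary-style workbooks (one sheet per condition, long format, user
supplied header map) is provided by :func:`load_xlsx`.
"""

from __future__ import annotations

import os
from typing import Optional

import pandas as pd

from .model import (
    CellRecord,
    Dataset,
    SCObservation,
    SchemaError,
    validate,
)

__all__ = ["write_dataset", "load_dataset", "load_xlsx", "CELL_COLUMNS", "SC_COLUMNS", "FOCI_COLUMNS"]

CELL_COLUMNS = ["cell_id", "animal_id", "temperature_C", "stage", "rpa_count"]
SC_COLUMNS = ["cell_id", "sc_index", "sc_rank", "morphology", "length_um", "centromere_um"]
FOCI_COLUMNS = ["cell_id", "sc_index", "focus_index", "position_um"]


def _frames(dataset: Dataset):
    cells, scs, foci = [], [], []
    for rec in dataset.records:
        cells.append(
            {
                "cell_id": rec.cell_id,
                "animal_id": rec.animal_id,
                "temperature_C": rec.temperature_C,
                "stage": rec.stage,
                "rpa_count": "" if rec.rpa_count is None else int(rec.rpa_count),
            }
        )
        for i, sc in enumerate(rec.scs):
            scs.append(
                {
                    "cell_id": rec.cell_id,
                    "sc_index": i,
                    "sc_rank": "" if sc.sc_rank is None else int(sc.sc_rank),
                    "morphology": sc.morphology,
                    "length_um": repr(float(sc.length_um)),
                    "centromere_um": repr(float(sc.centromere_um)),
                }
            )
            for j, pos in enumerate(sc.foci_um):
                foci.append(
                    {
                        "cell_id": rec.cell_id,
                        "sc_index": i,
                        "focus_index": j,
                        "position_um": repr(float(pos)),
                    }
                )
    return (
        pd.DataFrame(cells, columns=CELL_COLUMNS),
        pd.DataFrame(scs, columns=SC_COLUMNS),
        pd.DataFrame(foci, columns=FOCI_COLUMNS),
    )


def write_dataset(dataset: Dataset, path: str) -> None:
    """Write ``cells.csv``, ``scs.csv`` and ``foci.csv`` under ``path``.

    Floats are serialized with ``repr`` so reloading reproduces the exact
    double; given identical input the bytes are identical.
    """
    validate(dataset).raise_if_invalid()
    os.makedirs(path, exist_ok=True)
    cells, scs, foci = _frames(dataset)
    cells.to_csv(os.path.join(path, "cells.csv"), index=False, lineterminator="\n")
    scs.to_csv(os.path.join(path, "scs.csv"), index=False, lineterminator="\n")
    foci.to_csv(os.path.join(path, "foci.csv"), index=False, lineterminator="\n")


def _require_columns(df: pd.DataFrame, cols, name: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}")


def _read_csv(path: str, name: str) -> pd.DataFrame:
    full = os.path.join(path, name)
    if not os.path.exists(full):
        raise SchemaError(f"expected {name} in {path}")
    return pd.read_csv(full, comment="#", float_precision="round_trip")


def _assemble(cells: pd.DataFrame, scs: pd.DataFrame, foci: pd.DataFrame, metadata: dict) -> Dataset:
    _require_columns(cells, ["cell_id", "animal_id", "temperature_C", "stage"], "cells")
    _require_columns(scs, ["cell_id", "sc_index", "morphology", "length_um", "centromere_um"], "scs")
    _require_columns(foci, ["cell_id", "sc_index", "position_um"], "foci")

    foci_by_sc: dict = {}
    if len(foci):
        sort_cols = ["cell_id", "sc_index"] + (["focus_index"] if "focus_index" in foci else [])
        for (cid, idx), grp in foci.sort_values(sort_cols).groupby(["cell_id", "sc_index"], sort=False):
            foci_by_sc[(str(cid), int(idx))] = [float(x) for x in grp["position_um"]]

    scs_by_cell: dict = {}
    for _, row in scs.iterrows():
        cid = str(row["cell_id"])
        idx = int(row["sc_index"])
        rank = row.get("sc_rank")
        rank = None if pd.isna(rank) or rank == "" else int(rank)
        sc = SCObservation(
            cell_id=cid,
            length_um=float(row["length_um"]),
            centromere_um=float(row["centromere_um"]),
            morphology=str(row["morphology"]),
            foci_um=sorted(foci_by_sc.get((cid, idx), [])),
            sc_rank=rank,
        )
        scs_by_cell.setdefault(cid, []).append((idx, sc))

    records = []
    for _, row in cells.iterrows():
        cid = str(row["cell_id"])
        rpa = row.get("rpa_count")
        rpa = None if pd.isna(rpa) or rpa == "" else int(rpa)
        cell_scs = [sc for _, sc in sorted(scs_by_cell.get(cid, []), key=lambda t: t[0])]
        records.append(
            CellRecord(
                cell_id=cid,
                animal_id=str(row["animal_id"]),
                temperature_C=float(row["temperature_C"]),
                stage=str(row["stage"]),
                scs=cell_scs,
                rpa_count=rpa,
            )
        )
    return Dataset(records, metadata)


def load_dataset(path: str, format: str = "csv", header_map: Optional[dict] = None, strict: bool = True) -> Dataset:
    """Load and validate a dataset.

    Parameters
    ----------
    path
        For ``format="csv"``: a directory holding the three CSV tables.
        For ``format="xlsx"``: a workbook path (see :func:`load_xlsx`).
    header_map
        Column mapping for the XLSX importer; ignored for CSV.
    strict
        If true (default), invariant violations raise
        :class:`~meioco.model.ValidationError` with row-level locations;
        otherwise the dataset is returned as-is for inspection.
    """
    if format == "csv":
        cells = _read_csv(path, "cells.csv")
        scs = _read_csv(path, "scs.csv")
        foci = _read_csv(path, "foci.csv")
        ds = _assemble(cells, scs, foci, {"source": path, "format": "csv"})
    elif format == "xlsx":
        ds = load_xlsx(path, header_map or {})
    else:
        raise SchemaError(f"unknown format {format!r} (expected 'csv' or 'xlsx')")
    if strict:
        validate(ds).raise_if_invalid()
    return ds


#: Canonical field names the XLSX importer needs.  A header map translates
#: the workbook's actual column headers into these.
XLSX_FIELDS = ("cell_id", "sc_rank", "length_um", "centromere_um", "morphology", "position_um")


def load_xlsx(
    path: str,
    header_map: dict,
    temperature_by_sheet: Optional[dict] = None,
    animal_id: str = "NA",
    metacentric_ranks=(1, 4),
) -> Dataset:
    """Import a supplementary-style workbook.

    The expected layout is long format — one row per MLH1 focus (rows
    with a blank position column contribute an SC with no foci) — with one
    sheet per condition.  Because supplementary header spellings vary,
    ``header_map`` maps canonical names (:data:`XLSX_FIELDS`) to the
    workbook's headers; ``centromere_um`` and ``morphology`` may be
    omitted, in which case morphology is inferred from
    ``metacentric_ranks`` and the centromere defaults to the axis origin
    (acrocentric) or the midpoint (metacentric).
    """
    book = pd.read_excel(path, sheet_name=None, engine="openpyxl")
    records = []
    for sheet, df in book.items():
        inv = {v: k for k, v in header_map.items()}
        df = df.rename(columns=inv)
        _require_columns(df, ["cell_id", "sc_rank", "length_um"], f"sheet {sheet!r}")
        temp = (temperature_by_sheet or {}).get(sheet, float("nan"))
        for cid, cell_df in df.groupby("cell_id", sort=False):
            scs = []
            for rank, sc_df in cell_df.groupby("sc_rank", sort=True):
                rank = int(rank)
                length = float(sc_df["length_um"].iloc[0])
                morph = (
                    str(sc_df["morphology"].iloc[0])
                    if "morphology" in sc_df and not pd.isna(sc_df["morphology"].iloc[0])
                    else ("metacentric" if rank in metacentric_ranks else "acrocentric")
                )
                if "centromere_um" in sc_df and not pd.isna(sc_df["centromere_um"].iloc[0]):
                    cen = float(sc_df["centromere_um"].iloc[0])
                else:
                    cen = 0.0 if morph == "acrocentric" else length / 2.0
                positions = []
                if "position_um" in sc_df:
                    positions = [float(x) for x in sc_df["position_um"].dropna()]
                scs.append(
                    SCObservation(
                        cell_id=str(cid),
                        length_um=length,
                        centromere_um=cen,
                        morphology=morph,
                        foci_um=sorted(positions),
                        sc_rank=rank,
                    )
                )
            records.append(
                CellRecord(
                    cell_id=str(cid),
                    animal_id=animal_id,
                    temperature_C=float(temp),
                    stage="pachytene",
                    scs=scs,
                )
            )
    return Dataset(records, {"source": path, "format": "xlsx"})
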