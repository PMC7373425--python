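"""Reading and writing the pipeline's tabular inputs and outputs.

The canonical on-disk schema is plain CSV with one row per segmented nucleus:

    acinus_id, cell_id, x, y, z, transduced [, diameter, lineage_id]

Coordinates are centers of mass in micrometres; no unit auto-detection is
performed.  Supplementary-style XLSX workbooks (one sheet per acinus) are
supported through an explicit column map, because their internal layout is
not standardised.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import DataError, ParseError, SchemaError

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("acinus_id", "cell_id", "x", "y", "z", "transduced")
OPTIONAL_COLUMNS = ("diameter", "lineage_id")

_TRUTHY = {"1", "true", "TRUE", "True"}
_FALSY = {"0", "false", "FALSE", "False"}


@dataclass(frozen=True)
class CellRecord:
    """One segmented nucleus: 3D centroid (µm) plus identity and labels."""

    cell_id: str
    acinus_id: str
    timepoint: str  # "start" or "end"
    x: float
    y: float
    z: float
    transduced: bool
    diameter: float | None = None
    lineage_id: str | None = None


@dataclass
class CohortTable:
    """A cohort of cells at one timepoint, as a validated DataFrame.

    ``cells`` has the canonical columns plus ``timepoint``; ``provenance``
    records source files, the column mapping used and input checksums.
    """

    cells: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_cells(self.cells)

    @property
    def acinus_ids(self) -> list[str]:
        return sorted(self.cells["acinus_id"].unique())

    def acinus(self, acinus_id: str) -> pd.DataFrame:
        return self.cells[self.cells["acinus_id"] == acinus_id]

    def records(self) -> list[CellRecord]:
        out = []
        for row in self.cells.itertuples(index=False):
            out.append(
                CellRecord(
                    cell_id=row.cell_id,
                    acinus_id=row.acinus_id,
                    timepoint=row.timepoint,
                    x=row.x,
                    y=row.y,
                    z=row.z,
                    transduced=bool(row.transduced),
                    diameter=getattr(row, "diameter", None),
                    lineage_id=getattr(row, "lineage_id", None),
                )
            )
        return out


def validate_cells(df: pd.DataFrame) -> None:
    """Check canonical-schema invariants; raise DataError on violation."""
    for col in MANDATORY_COLUMNS + ("timepoint",):
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column: {col!r}")
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        bad = int(np.where(~np.isfinite(coords).all(axis=1))[0][0])
        raise ParseError(f"non-finite coordinate at row {bad}")
    if "diameter" in df.columns:
        d = pd.to_numeric(df["diameter"], errors="coerce")
        if ((d <= 0) & d.notna()).any():
            raise DataError("diameter must be > 0 where present")
    keys = df[["acinus_id", "timepoint", "cell_id"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].tolist()
        raise DataError(f"duplicate (acinus_id, timepoint, cell_id): {dup}")


def _parse_transduced(values: pd.Series, path: str) -> pd.Series:
    out = np.empty(len(values), dtype=bool)
    for i, v in enumerate(values):
        s = str(v).strip()
        if s in _TRUTHY:
            out[i] = True
        elif s in _FALSY:
            out[i] = False
        else:
            raise ParseError(
                f"{path}: cannot parse transduced value {v!r} at row {i}; "
                "expected one of 0/1/true/false"
            )
    return pd.Series(out, index=values.index)


def read_canonical_csv(path: str | Path, timepoint: str) -> CohortTable:
    """Read a canonical CSV of cell records taken at one timepoint.

    Units are µm.  ``transduced`` accepts 0/1/true/false in any case.
    Raises SchemaError naming the missing column, or ParseError with a
    row index for unparseable values.
    """
    path = Path(path)
    if timepoint not in ("start", "end"):
        raise DataError(f"timepoint must be 'start' or 'end', got {timepoint!r}")
    df = pd.read_csv(path, dtype={"acinus_id": str, "cell_id": str})
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column: {col!r}")
    for col in ("x", "y", "z"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            bad = int(np.where(coerced.isna())[0][0])
            raise ParseError(f"{path}: non-numeric {col} at row {bad}")
        df[col] = coerced
    df["transduced"] = _parse_transduced(df["transduced"], str(path))
    df["timepoint"] = timepoint
    if "lineage_id" in df.columns:
        df["lineage_id"] = df["lineage_id"].astype("string")
    provenance = {
        "source": [str(path)],
        "checksums": {path.name: _sha256(path)},
        "column_map": None,
    }
    return CohortTable(df.reset_index(drop=True), provenance)


def read_supplementary_xlsx(
    path: str | Path,
    column_map: Mapping[str, str],
    timepoint: str,
) -> CohortTable:
    """Read a one-sheet-per-acinus workbook of cell centroids.

    ``column_map`` names which workbook columns hold x, y, z (and optionally
    ``cell_id``, ``transduced``, ``diameter``); the sheet name becomes the
    acinus_id.  Rows without all three coordinates are skipped with a logged
    count; sheets with no parseable rows are omitted with a warning.
    """
    path = Path(path)
    for axis in ("x", "y", "z"):
        if axis not in column_map:
            raise SchemaError(f"column_map must name a column for {axis!r}")
    book = pd.read_excel(path, sheet_name=None, engine="openpyxl")
    if not book:
        raise DataError(f"{path}: workbook has no sheets")
    frames = []
    for sheet, raw in book.items():
        missing = [c for c in ("x", "y", "z") if column_map[c] not in raw.columns]
        if missing:
            raise SchemaError(
                f"{path}[{sheet}]: column_map points at missing column(s): "
                + ", ".join(column_map[c] for c in missing)
            )
        coords = raw[[column_map[a] for a in ("x", "y", "z")]].apply(
            pd.to_numeric, errors="coerce"
        )
        ok = coords.notna().all(axis=1)
        n_skipped = int((~ok).sum())
        if n_skipped:
            logger.info("%s[%s]: skipped %d rows without coordinates", path, sheet, n_skipped)
        if not ok.any():
            logger.warning("%s[%s]: no parseable rows; acinus omitted", path, sheet)
            continue
        sub = raw[ok]
        n = int(ok.sum())
        if "cell_id" in column_map and column_map["cell_id"] in raw.columns:
            cell_ids = sub[column_map["cell_id"]].astype(str).to_numpy()
        else:
            cell_ids = np.array([f"cell_{i:04d}" for i in range(n)])
        df = pd.DataFrame(
            {
                "acinus_id": str(sheet),
                "cell_id": cell_ids,
                "x": coords.loc[ok, column_map["x"]].to_numpy(dtype=float),
                "y": coords.loc[ok, column_map["y"]].to_numpy(dtype=float),
                "z": coords.loc[ok, column_map["z"]].to_numpy(dtype=float),
            }
        )
        if "transduced" in column_map and column_map["transduced"] in raw.columns:
            df["transduced"] = _parse_transduced(
                sub[column_map["transduced"]], f"{path}[{sheet}]"
            ).to_numpy()
        else:
            df["transduced"] = False
        if "diameter" in column_map and column_map["diameter"] in raw.columns:
            df["diameter"] = pd.to_numeric(sub[column_map["diameter"]], errors="coerce").to_numpy()
        frames.append(df)
    if not frames:
        raise DataError(f"{path}: no acinus sheet contained parseable rows")
    cells = pd.concat(frames, ignore_index=True)
    cells["timepoint"] = timepoint
    provenance = {
        "source": [str(path)],
        "checksums": {path.name: _sha256(path)},
        "column_map": dict(column_map),
    }
    return CohortTable(cells, provenance)


def merge_transduced_labels(
    cohort: CohortTable,
    labels: pd.DataFrame,
    mode: str = "exact",
    tolerance: float = 1.0,
) -> tuple[CohortTable, int]:
    """Mark cells as transduced from a label table.

    ``labels`` needs columns (acinus_id, cell_id) in exact mode, or
    (acinus_id, x, y, z) in nearest-centroid mode, where each label is
    matched to the nearest cell centroid within ``tolerance`` µm.

    Returns the relabelled cohort and the number of matched labels.
    """
    cells = cohort.cells.copy()
    cells["transduced"] = False
    matched = 0
    if mode == "exact":
        for col in ("acinus_id", "cell_id"):
            if col not in labels.columns:
                raise SchemaError(f"label table missing column {col!r}")
        key = pd.MultiIndex.from_frame(cells[["acinus_id", "cell_id"]].astype(str))
        lab_key = pd.MultiIndex.from_frame(labels[["acinus_id", "cell_id"]].astype(str))
        unmatched = lab_key.difference(key)
        if len(unmatched):
            raise DataError(
                "labels reference unknown cells: "
                + ", ".join(str(tuple(k)) for k in unmatched[:10])
            )
        cells.loc[key.isin(lab_key), "transduced"] = True
        matched = len(lab_key.unique())
    elif mode == "nearest":
        for col in ("acinus_id", "x", "y", "z"):
            if col not in labels.columns:
                raise SchemaError(f"label table missing column {col!r}")
        for acinus_id, lab in labels.groupby("acinus_id"):
            sub = cells[cells["acinus_id"] == str(acinus_id)]
            if sub.empty:
                raise DataError(f"labels reference unknown acinus {acinus_id!r}")
            tree = cKDTree(sub[["x", "y", "z"]].to_numpy(dtype=float))
            d, idx = tree.query(lab[["x", "y", "z"]].to_numpy(dtype=float))
            hit = d <= tolerance
            cells.loc[sub.index[idx[hit]], "transduced"] = True
            matched += int(hit.sum())
            if (~hit).any():
                logger.warning(
                    "acinus %s: %d labels beyond tolerance %.3g µm left unmatched",
                    acinus_id, int((~hit).sum()), tolerance,
                )
    else:
        raise DataError(f"unknown label-merge mode {mode!r}")
    return CohortTable(cells, dict(cohort.provenance)), matched


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
    input_checksums: Mapping[str, str] | None = None,
) -> dict:
    """Write each table as canonical CSV plus a JSON run manifest.

    Returns the manifest (also written to ``manifest.json``).
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        files[name] = {"path": p.name, "rows": int(len(df)), "sha256": _sha256(p)}
    manifest = {
        "software": {"name": "acini3d", "version": __version__},
        "seed": seed,
        "config": _jsonable(config) if config is not None else None,
        "inputs": dict(input_checksums or {}),
        "outputs": files,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def check_start_end_consistency(start: CohortTable, end: CohortTable) -> None:
    """Every acinus present at the end must also be present at the start."""
    missing = set(end.acinus_ids) - set(start.acinus_ids)
    if missing:
        raise DataError(
            "acini present at end but not at start: " + ", ".join(sorted(missing))
        )
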