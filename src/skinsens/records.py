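"""Data model and CSV I/O for chemical and drug tables.

Two schemas are supported:

* ``chemical`` — columns ``id,cas,name,smiles,label,ec3,split`` plus one
  optional column per quantum descriptor (names from
  :data:`~skinsens.descriptors.DESCRIPTOR_NAMES`), an optional
  ``p_published`` column carrying a literature discriminant score, and an
  optional free-text ``smiles_note`` provenance column.
* ``drug`` — columns ``drugbank_id,name,smiles,adverse_event_flag`` plus
  optional ``epsilon_homo``, ``p_published`` and ``smiles_note``.

Two packaged fixtures transcribe the literature reference set: ``table1``
(30 anilines/phenols with LLNA labels, the 15/15 train/test split, printed
HOMO energies, printed discriminant scores, and EC3 potencies where
measured) and ``table2`` (6 FDA-approved drugs with printed discriminant
scores and allergic-dermatitis adverse-event flags). Structures are curated
SMILES reconstructed from the printed names/CAS numbers — the source prints
no structures — and each row carries a provenance note saying so.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .descriptors import DESCRIPTOR_NAMES, QuantumDescriptors
from .errors import LengthMismatchError, RowParseError, SchemaError, SkinsensError

__all__ = [
    "LABELS",
    "SPLITS",
    "ADVERSE_EVENT_FLAGS",
    "ChemicalRecord",
    "DrugRecord",
    "ChemTable",
    "read_chem_table",
    "write_chem_table",
    "write_predictions",
    "load_fixture",
]

LABELS = ("sensitizer", "non-sensitizer", "unknown")
SPLITS = ("train", "test", "none")
ADVERSE_EVENT_FLAGS = ("reported", "unreported")

_CAS_RE = re.compile(r"^\d{2,7}-\d{2}-\d$")

_CHEMICAL_MANDATORY = ("id", "cas", "name", "label")
_DRUG_MANDATORY = ("drugbank_id", "name", "smiles", "adverse_event_flag")


@dataclass
class ChemicalRecord:
    """One compound: identifiers, structure, class label, EC3, descriptors."""

    id: str
    cas: str
    name: str
    smiles: str | None = None
    label: str = "unknown"
    ec3: float | None = None
    split: str = "none"
    descriptors: QuantumDescriptors | None = None
    p_published: float | None = None
    smiles_note: str | None = None

    def __post_init__(self):
        if self.cas and not _CAS_RE.match(self.cas):
            raise SkinsensError(f"record {self.id!r}: malformed CAS {self.cas!r}")
        if self.label not in LABELS:
            raise SkinsensError(f"record {self.id!r}: unknown label {self.label!r}")
        if self.split not in SPLITS:
            raise SkinsensError(f"record {self.id!r}: unknown split {self.split!r}")
        if self.ec3 is not None and not self.ec3 > 0:
            raise SkinsensError(f"record {self.id!r}: EC3 must be > 0")

    @property
    def epsilon_homo(self) -> float | None:
        return self.descriptors.epsilon_homo if self.descriptors else None


@dataclass
class DrugRecord:
    """One approved drug with its adverse-event flag."""

    drugbank_id: str
    name: str
    smiles: str
    adverse_event_flag: str = "unreported"
    epsilon_homo: float | None = None
    p_published: float | None = None
    prediction_published: str | None = None
    smiles_note: str | None = None

    def __post_init__(self):
        if not self.drugbank_id:
            raise SkinsensError("drug record with empty drugbank_id")
        if self.adverse_event_flag not in ADVERSE_EVENT_FLAGS:
            raise SkinsensError(
                f"drug {self.drugbank_id!r}: unknown adverse_event_flag "
                f"{self.adverse_event_flag!r}"
            )
        if self.prediction_published is not None and self.prediction_published not in LABELS:
            raise SkinsensError(
                f"drug {self.drugbank_id!r}: unknown prediction "
                f"{self.prediction_published!r}"
            )

    @property
    def id(self) -> str:
        return self.drugbank_id


@dataclass
class ChemTable:
    """Ordered collection of chemical or drug records."""

    records: list = field(default_factory=list)
    provenance: str = ""
    schema: Literal["chemical", "drug"] = "chemical"

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SkinsensError(f"duplicate record ids: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, split: str) -> "ChemTable":
        recs = [r for r in self.records if getattr(r, "split", "none") == split]
        return ChemTable(recs, f"{self.provenance}[split={split}]", self.schema)

    def to_frame(self) -> pd.DataFrame:
        return _table_to_frame(self)


def _parse_float(value, column: str, row: int) -> float | None:
    if value is None:
        return None
    s = str(value).strip()
    if s == "" or s.lower() == "nan":
        return None
    try:
        return float(s)
    except ValueError:
        raise RowParseError(row, f"unparseable {column} value {s!r}") from None


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    return pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")


def read_chem_table(path, schema: str = "chemical") -> ChemTable:
    """Read a CSV table into records, preserving row order.

    Missing optional columns leave the corresponding fields unset; a missing
    mandatory column raises :class:`SchemaError` naming the column, and an
    unparseable numeric cell raises :class:`RowParseError` with the 0-based
    data-row index.
    """
    if schema not in ("chemical", "drug"):
        raise SchemaError(f"unknown schema {schema!r}")
    df = _read_csv(path)
    mandatory = _CHEMICAL_MANDATORY if schema == "chemical" else _DRUG_MANDATORY
    for col in mandatory:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")

    records = []
    for row_idx, row in enumerate(df.to_dict("records")):
        get = lambda c: (row.get(c, "") or "").strip() or None  # noqa: E731
        try:
            if schema == "chemical":
                desc_values = {
                    name: _parse_float(row.get(name), name, row_idx)
                    for name in DESCRIPTOR_NAMES
                    if name in df.columns
                }
                desc_values = {k: v for k, v in desc_values.items() if v is not None}
                records.append(
                    ChemicalRecord(
                        id=get("id") or "",
                        cas=get("cas") or "",
                        name=get("name") or "",
                        smiles=get("smiles"),
                        label=get("label") or "unknown",
                        ec3=_parse_float(row.get("ec3"), "ec3", row_idx),
                        split=get("split") or "none",
                        descriptors=QuantumDescriptors(**desc_values)
                        if desc_values
                        else None,
                        p_published=_parse_float(
                            row.get("p_published"), "p_published", row_idx
                        ),
                        smiles_note=get("smiles_note"),
                    )
                )
            else:
                records.append(
                    DrugRecord(
                        drugbank_id=get("drugbank_id") or "",
                        name=get("name") or "",
                        smiles=get("smiles") or "",
                        adverse_event_flag=get("adverse_event_flag") or "unreported",
                        epsilon_homo=_parse_float(
                            row.get("epsilon_homo"), "epsilon_homo", row_idx
                        ),
                        p_published=_parse_float(
                            row.get("p_published"), "p_published", row_idx
                        ),
                        prediction_published=get("prediction_published"),
                        smiles_note=get("smiles_note"),
                    )
                )
        except RowParseError:
            raise
        except SkinsensError as exc:
            raise RowParseError(row_idx, str(exc)) from exc
    return ChemTable(records, provenance=str(path), schema=schema)


def _table_to_frame(table: ChemTable) -> pd.DataFrame:
    rows = []
    if table.schema == "chemical":
        desc_cols = [
            n
            for n in DESCRIPTOR_NAMES
            if any(
                r.descriptors and getattr(r.descriptors, n) is not None
                for r in table.records
            )
        ]
        for r in table.records:
            d = r.descriptors.as_dict() if r.descriptors else {}
            rows.append(
                {
                    "id": r.id,
                    "cas": r.cas,
                    "name": r.name,
                    "smiles": r.smiles,
                    "label": r.label,
                    "ec3": r.ec3,
                    "split": r.split,
                    **{c: d.get(c) for c in desc_cols},
                    "p_published": r.p_published,
                    "smiles_note": r.smiles_note,
                }
            )
        cols = (
            ["id", "cas", "name", "smiles", "label", "ec3", "split"]
            + desc_cols
            + ["p_published", "smiles_note"]
        )
    else:
        for r in table.records:
            rows.append(
                {
                    "drugbank_id": r.drugbank_id,
                    "name": r.name,
                    "smiles": r.smiles,
                    "adverse_event_flag": r.adverse_event_flag,
                    "epsilon_homo": r.epsilon_homo,
                    "p_published": r.p_published,
                    "prediction_published": r.prediction_published,
                    "smiles_note": r.smiles_note,
                }
            )
        cols = [
            "drugbank_id",
            "name",
            "smiles",
            "adverse_event_flag",
            "epsilon_homo",
            "p_published",
            "prediction_published",
            "smiles_note",
        ]
    df = pd.DataFrame(rows, columns=cols)
    # drop fully-empty optional columns so round-trips are clean
    keep = [
        c
        for c in cols
        if c
        in (
            _CHEMICAL_MANDATORY
            if table.schema == "chemical"
            else _DRUG_MANDATORY
        )
        or df[c].notna().any()
    ]
    return df[keep]


def write_chem_table(table: ChemTable, path) -> None:
    """Write a table back to CSV (UTF-8, '.' decimal, deterministic columns)."""
    _table_to_frame(table).to_csv(path, index=False, encoding="utf-8")


def write_predictions(table: ChemTable, predictions: Sequence, path) -> None:
    """Write the table plus ``p`` (4 dp) and ``predicted_class`` columns.

    ``predictions`` must align one-to-one with ``table.records``.
    """
    if len(predictions) != len(table.records):
        raise LengthMismatchError(
            f"{len(table.records)} records but {len(predictions)} predictions"
        )
    df = _table_to_frame(table)
    df["p"] = [
        "" if p.p_score is None or math.isnan(p.p_score) else f"{p.p_score:.4f}"
        for p in predictions
    ]
    df["predicted_class"] = [p.predicted_class for p in predictions]
    df.to_csv(path, index=False, encoding="utf-8")


def load_fixture(name: str) -> ChemTable:
    """Load a packaged fixture: ``table1`` (chemicals) or ``table2`` (drugs)."""
    schemas = {"table1": "chemical", "table2": "drug"}
    if name not in schemas:
        raise SkinsensError(f"unknown fixture {name!r}; choose from {sorted(schemas)}")
    ref = resources.files("skinsens.data").joinpath(f"{name}.csv")
    with resources.as_file(ref) as path:
        table = read_chem_table(path, schema=schemas[name])
    table.provenance = f"fixture:{name}"
    return table
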