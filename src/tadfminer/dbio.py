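"""Serialization of clean records to the published database schema.

Two formats are supported, both UTF-8:

* JSON — an array of nested record objects (the canonical form);
* CSV — RFC-4180 with a header row; nested fields are flattened to dotted
  column names (``compound.names``, ``metadata.doi``) and list fields are
  JSON-encoded inside their cell.

Every record carries the base fields ``doc_id``, ``model_name``,
``compound`` (names/labels, plus ``smiles`` in the subsidiary variant),
``value``, ``units``, ``standard_value``, ``record_method`` and
``metadata``; per-property extras are ``phase``/``atmosphere`` (PLQY),
``phase`` (λ_EM), ``temperature`` (τ_D, kelvin) and ``is_experimental``
(ΔE_ST). Write→read→write round trips are byte-identical.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

from .errors import SchemaValidationError
from .parsers import REGISTERED_PARSERS, CandidateRecord

PROPERTY_IDS = ("lambda_em", "plqy", "delta_e_st", "tau_d")

BASE_FIELDS = ("doc_id", "model_name", "compound", "value", "units",
               "standard_value", "record_method", "metadata")
EXTRA_FIELDS = {
    "plqy": ("phase", "atmosphere"),
    "lambda_em": ("phase",),
    "tau_d": ("temperature",),
    "delta_e_st": ("is_experimental",),
}
#: scalar fields that are numeric in CSV cells (all other scalars are text)
NUMERIC_SCALARS = {"temperature"}


def record_to_dict(record: CandidateRecord, metadata: dict | None = None,
                   include_smiles: bool = False) -> dict:
    """Flatten a candidate record into its database-schema dictionary."""
    compound = {"names": [], "labels": []}
    if record.compound:
        compound = {"names": list(record.compound.names),
                    "labels": list(record.compound.labels)}
    if include_smiles and "smiles" in record.extra:
        compound["smiles"] = record.extra["smiles"]
    out = {
        "doc_id": record.provenance.doc_id,
        "model_name": record.property_id,
        "compound": compound,
        "value": list(record.quantity.values),
        "units": record.quantity.unit,
        "standard_value": list(record.standard_value or []),
        "record_method": record.provenance.parser,
        "metadata": dict(metadata or {}),
    }
    for extra in EXTRA_FIELDS.get(record.property_id, ()):
        if extra in record.extra:
            out[extra] = record.extra[extra]
    return out


def validate_record(rec: dict, subsidiary: bool = False) -> None:
    bad: list[str] = []
    if rec.get("model_name") not in PROPERTY_IDS:
        bad.append("model_name")
    if not isinstance(rec.get("value"), list) or not rec["value"]:
        bad.append("value")
    if not isinstance(rec.get("standard_value"), list):
        bad.append("standard_value")
    if not isinstance(rec.get("units", None), str):
        bad.append("units")
    if rec.get("record_method") not in REGISTERED_PARSERS:
        bad.append("record_method")
    compound = rec.get("compound")
    if not isinstance(compound, dict) or "names" not in compound or "labels" not in compound:
        bad.append("compound")
    elif subsidiary and not compound.get("smiles"):
        bad.append("compound.smiles")
    if bad:
        raise SchemaValidationError("record violates database schema", bad)


def _flatten(rec: dict) -> dict[str, str]:
    flat: dict[str, str] = {}
    for key, value in rec.items():
        if isinstance(value, dict):
            for sub, sval in value.items():
                flat[f"{key}.{sub}"] = (json.dumps(sval, ensure_ascii=False)
                                        if isinstance(sval, (list, dict)) else str(sval))
        elif isinstance(value, list):
            flat[key] = json.dumps(value, ensure_ascii=False)
        else:
            flat[key] = str(value)
    return flat


def _unflatten(row: dict[str, str]) -> dict:
    rec: dict = {}
    for key, raw in row.items():
        if raw == "" and key not in ("units",):
            continue
        target: dict = rec
        name = key
        if "." in key:
            prefix, name = key.split(".", 1)
            target = rec.setdefault(prefix, {})
        if raw.startswith("[") or raw.startswith("{"):
            target[name] = json.loads(raw)
        elif name in NUMERIC_SCALARS:
            target[name] = float(raw)
        else:
            target[name] = raw
    rec.setdefault("compound", {}).setdefault("names", [])
    rec["compound"].setdefault("labels", [])
    rec.setdefault("metadata", {})
    return rec


def _columns(records: list[dict]) -> list[str]:
    # mandatory columns are always present, even for an empty record list
    cols: list[str] = ["doc_id", "model_name", "compound.names",
                       "compound.labels", "value", "units", "standard_value",
                       "record_method"]
    for rec in records:
        for key in _flatten(rec):
            if key not in cols:
                cols.append(key)
    # stable order: base fields first (dotted children follow their parent)
    def rank(col: str) -> tuple[int, str]:
        head = col.split(".")[0]
        try:
            return (BASE_FIELDS.index(head), col)
        except ValueError:
            return (len(BASE_FIELDS), col)
    return sorted(cols, key=rank)


def write_records(records: list[dict], path: str | Path, format: str = "json",
                  subsidiary: bool = False) -> Path:
    """Write schema-validated records to CSV or JSON."""
    for rec in records:
        validate_record(rec, subsidiary=subsidiary)
    path = Path(path)
    if format == "json":
        path.write_text(
            json.dumps(records, ensure_ascii=False, sort_keys=True, indent=1) + "\n",
            encoding="utf-8",
        )
    elif format == "csv":
        cols = _columns(records)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols, extrasaction="ignore")
            writer.writeheader()
            for rec in records:
                writer.writerow({c: _flatten(rec).get(c, "") for c in cols})
    else:
        raise ValueError(f"unknown format {format!r}; expected csv or json")
    return path


def read_records(path: str | Path, format: str = "json") -> list[dict]:
    """Inverse of :func:`write_records`."""
    path = Path(path)
    if format == "json":
        records = json.loads(path.read_text(encoding="utf-8"))
    elif format == "csv":
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "model_name" not in reader.fieldnames:
                raise SchemaValidationError("missing mandatory column", ["model_name"])
            records = [_unflatten(row) for row in reader]
    else:
        raise ValueError(f"unknown format {format!r}; expected csv or json")
    for rec in records:
        validate_record(rec)
    return records
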