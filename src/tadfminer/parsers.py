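"""Candidate-record extraction from sentences and table cells.

Table cells are serialized by joining a cell's column headers (outermost
first) and the cell text with the separator ``🙃🙃🙃🙃`` (U+1F643 ×4) into a
sentence-like string; fields are then sought in that string on a
first-come-first-served basis. Headers come first so specifier lookup is
a prefix scan.

Three special table parsers cover TADF-specific edge cases and claim
their header patterns exclusively, ahead of the generic cell parser:

1. combined singlet/triplet columns headed ``E_S/E_T/ΔE_ST``;
2. fractional PLQY cells (0–1, no ``%`` anywhere);
3. shared lifetime cells where τ_d co-resides with τ_p, λ_em or PLQY.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .document import Table, normalize_name
from .nlp import Sentence
from .ontology import (
    PropertyModel,
    Quantity,
    _NUM,
    _RANGE_SEP,
    _num_to_float,
    normalize_text,
    parse_quantity,
    quantity_regex,
)

CELL_SEPARATOR = "\U0001F643" * 4  # 🙃🙃🙃🙃, bit-exact

REGISTERED_PARSERS = (
    "sentence_parser",
    "table_cell_parser",
    "combined_est_table_parser",
    "fractional_plqy_table_parser",
    "shared_lifetime_table_parser",
)

#: headers whose column supplies the row compound (config list)
COMPOUND_COLUMN_HEADERS = {
    "compound", "compounds", "emitter", "emitters", "molecule", "molecules",
    "material", "materials", "sample", "dye",
}

#: a short identifier is treated as a label rather than a name
MAX_LABEL_LENGTH = 4


@dataclass
class Compound:
    names: list[str] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)

    @classmethod
    def from_surface(cls, surface: str) -> "Compound":
        surface = normalize_name(surface)
        if len(surface) <= MAX_LABEL_LENGTH:
            return cls(labels=[surface])
        return cls(names=[surface])

    def all_identifiers(self) -> list[str]:
        return self.names + self.labels

    def __bool__(self) -> bool:
        return bool(self.names or self.labels)


@dataclass
class Provenance:
    doc_id: str = ""
    element_index: int = -1
    sentence_index: int | None = None
    cell: tuple[int, int] | None = None
    parser: str = ""


@dataclass
class CandidateRecord:
    property_id: str
    quantity: Quantity
    compound: Compound | None = None
    extra: dict = field(default_factory=dict)
    provenance: Provenance = field(default_factory=Provenance)
    standard_value: list[float] | None = None


# ---------------------------------------------------------------------------
# Sentence parsing
# ---------------------------------------------------------------------------

_LINK_WORDS = {
    "of", "for", "is", "was", "were", "at", "being", "be", "to", "as",
    "around", "about", "approximately", "measured", "found", "determined",
    "estimated", "the", "a", "an", "value", "values", "and",
}

_TEMPERATURE_RE = re.compile(r"\bat\s+(\d+(?:\.\d+)?)\s*K\b")
_RT_RE = re.compile(r"\b(?:room[\s-]temperature\b|RT\b|r\.t\.)", re.IGNORECASE)


def _specifier_regex(model: PropertyModel) -> re.Pattern:
    alt = "|".join(
        re.escape(normalize_text(s))
        for s in sorted(model.specifiers, key=len, reverse=True)
    )
    return re.compile(rf"(?<![A-Za-z])(?:{alt})(?![A-Za-z])", re.IGNORECASE)


def _only_link_material(segment: str, cem_intervals: list[tuple[int, int]],
                        offset: int) -> bool:
    """True if a specifier→quantity gap contains only link words/CEMs."""
    masked = list(segment)
    for s, e in cem_intervals:
        s, e = s - offset, e - offset
        for i in range(max(s, 0), min(e, len(masked))):
            masked[i] = " "
    cleaned = "".join(masked)
    cleaned = re.sub(r"[=:~,;()]", " ", cleaned)
    for word in re.findall(r"[^\W\d_][\w.\-]*", cleaned):
        if word.lower().rstrip(".") not in _LINK_WORDS:
            return False
    return True


def _capture_measurement_context(text: str, extra: dict) -> None:
    m = _TEMPERATURE_RE.search(text)
    if m:
        extra["temperature_K"] = float(m.group(1))
    if _RT_RE.search(text):
        extra["rt_flag"] = True


def parse_sentence(sentence: Sentence, model: PropertyModel,
                   doc_id: str = "", element_index: int = -1,
                   sentence_index: int | None = None) -> list[CandidateRecord]:
    """Extract candidate records for one property model from a sentence.

    Relation templates: specifier-of-compound ("The delayed lifetime of
    2CzPN is 3.2 μs"), compound-verb-specifier ("2CzPN exhibits a PLQY of
    68%"), and specifier-value appositive ("λem = 470 nm"). A chemical
    entity between specifier and value in an of-phrase binds as the
    compound; otherwise the nearest tagged entity in the sentence does.
    """
    text = normalize_text(sentence.text)
    records: list[CandidateRecord] = []
    qty_re = quantity_regex(model)
    spec_re = _specifier_regex(model)
    cems = [(s, e, name) for s, e, name in sentence.cem_spans]
    cem_intervals = [(s, e) for s, e, _ in cems]

    for spec_m in spec_re.finditer(text):
        best: tuple[int, Quantity] | None = None
        for qm in qty_re.finditer(text, spec_m.end()):
            gap = text[spec_m.end(): qm.start()]
            if _only_link_material(gap, cem_intervals, spec_m.end()):
                values = [_num_to_float(qm.group("v1"))]
                if qm.group("v2"):
                    values.append(_num_to_float(qm.group("v2")))
                best = (qm.start(), Quantity(values, qm.group("unit"), qm.group(0)))
            break  # only the first following quantity may belong to this specifier
        if best is None:
            continue
        v_start, quantity = best
        compound = _bind_compound(text, cems, spec_m.start(), spec_m.end(), v_start)
        extra: dict = {"source_text": sentence.text}
        _capture_measurement_context(text, extra)
        records.append(CandidateRecord(
            property_id=model.property_id,
            quantity=quantity,
            compound=compound,
            extra=extra,
            provenance=Provenance(doc_id, element_index, sentence_index,
                                  None, "sentence_parser"),
        ))
    return records


def _bind_compound(text: str, cems: list[tuple[int, int, str]],
                   spec_start: int, spec_end: int, value_start: int) -> Compound | None:
    if not cems:
        return None
    # specifier-of-compound: CEM between specifier and value after "of"/"for"
    for s, e, name in cems:
        if spec_end <= s and e <= value_start:
            between = text[spec_end:s]
            if re.search(r"\b(?:of|for)\s*$", between.strip() + " "):
                return Compound.from_surface(name)
    # otherwise: nearest CEM to the specifier by character distance
    def distance(span):
        s, e, _ = span
        if e <= spec_start:
            return spec_start - e
        if s >= spec_end:
            return s - spec_end
        return 0
    s, e, name = min(cems, key=distance)
    return Compound.from_surface(name)


# ---------------------------------------------------------------------------
# Cell serialization and generic cell parsing
# ---------------------------------------------------------------------------

def serialize_cell(table: Table, row: int, col: int) -> str:
    """Join a cell's headers (outer→inner) and its text with 🙃🙃🙃🙃."""
    if not (0 <= row < len(table.body)) or not (0 <= col < table.n_columns):
        raise IndexError(f"cell ({row}, {col}) out of range for "
                         f"{len(table.body)}×{table.n_columns} table")
    headers = table.column_headers[col]
    return CELL_SEPARATOR.join(headers + [table.body[row][col]])


def _split_cell_string(cell_string: str) -> tuple[list[str], str]:
    parts = cell_string.split(CELL_SEPARATOR)
    return parts[:-1], parts[-1]


def _unit_in_text(text: str, model: PropertyModel) -> str | None:
    units = sorted(model.allowed_units, key=len, reverse=True)
    alt = "|".join(re.escape(u) for u in units)
    m = re.search(rf"(?<![A-Za-z])({alt})(?![A-Za-z])", normalize_text(text))
    return m.group(1) if m else None


_BARE_NUMBER_RE = re.compile(rf"(?P<v1>{_NUM})(?:{_RANGE_SEP}(?P<v2>{_NUM}))?")


def parse_cell(cell_string: str, model: PropertyModel,
               row_compound: Compound | None = None) -> list[CandidateRecord]:
    """Generic table-cell parser: first-come-first-served field search.

    The specifier must occur in a header segment. The unit is taken from
    the headers when declared there, otherwise from the cell; the first
    compatible number (or range) in the cell wins. The compound comes from
    the row's compound column when supplied.
    """
    headers, cell = _split_cell_string(cell_string)
    header_text = normalize_text(" ".join(headers))
    if not headers or not _specifier_regex(model).search(header_text):
        return []
    header_unit = _unit_in_text(header_text, model)
    cell_norm = normalize_text(cell)
    quantity: Quantity | None = None
    if header_unit is not None:
        m = _BARE_NUMBER_RE.search(cell_norm)
        if m:
            values = [_num_to_float(m.group("v1"))]
            if m.group("v2"):
                values.append(_num_to_float(m.group("v2")))
            quantity = Quantity(values, header_unit, m.group(0))
    else:
        quantity = parse_quantity(cell_norm, model)
    if quantity is None:
        return []
    return [CandidateRecord(
        property_id=model.property_id,
        quantity=quantity,
        compound=row_compound,
        extra={"source_text": cell_string.replace(CELL_SEPARATOR, " ")},
        provenance=Provenance(parser="table_cell_parser"),
    )]


# ---------------------------------------------------------------------------
# Special table parsers
# ---------------------------------------------------------------------------

_EST_CONSISTENCY_TOL = 0.05  # eV, |E_S − E_T − ΔE_ST| beyond this flags the record

_DELTA_FIELD_RE = re.compile(r"ΔE", re.IGNORECASE)
_ES_FIELD_RE = re.compile(r"^E\s*_?S1?$", re.IGNORECASE)
_ET_FIELD_RE = re.compile(r"^E\s*_?T1?$", re.IGNORECASE)
_PAREN_UNIT_RE = re.compile(r"[(\[]([^()\[\]]*)[)\]]\s*$")


def _strip_paren_unit(header: str) -> tuple[str, str | None]:
    m = _PAREN_UNIT_RE.search(header.strip())
    if m:
        return header[: m.start()].strip(), m.group(1).strip()
    return header.strip(), None


def parse_combined_est_cell(cell_string: str,
                            row_compound: Compound | None = None
                            ) -> list[CandidateRecord] | None:
    """Parser for combined ``E_S/E_T/ΔE_ST`` columns.

    Returns ``None`` when no header matches the slash pattern (the
    dispatcher then tries the next parser); an empty list when applicable
    but the cell's field count disagrees with the header's.
    """
    headers, cell = _split_cell_string(cell_string)
    target = None
    for h in headers:
        base, unit = _strip_paren_unit(normalize_text(h))
        fields = [f.strip() for f in base.split("/")]
        if len(fields) >= 2 and any(_DELTA_FIELD_RE.search(f) for f in fields) and any(
            _ES_FIELD_RE.match(f) or _ET_FIELD_RE.match(f) for f in fields
        ):
            target = (fields, unit or "eV")
            break
    if target is None:
        return None
    fields, unit = target
    cell_fields = [c.strip() for c in normalize_text(cell).split("/")]
    if len(cell_fields) != len(fields):
        return []
    idx = next(i for i, f in enumerate(fields) if _DELTA_FIELD_RE.search(f))
    try:
        value = _num_to_float(cell_fields[idx])
    except ValueError:
        return []
    extra: dict = {"source_text": cell_string.replace(CELL_SEPARATOR, " ")}
    es = et = None
    for i, f in enumerate(fields):
        try:
            if _ES_FIELD_RE.match(f):
                es = _num_to_float(cell_fields[i])
            elif _ET_FIELD_RE.match(f):
                et = _num_to_float(cell_fields[i])
        except ValueError:
            pass
    if es is not None and et is not None and abs(es - et - value) > _EST_CONSISTENCY_TOL:
        extra["consistency_warning"] = True
    return [CandidateRecord(
        property_id="delta_e_st",
        quantity=Quantity([value], unit, cell),
        compound=row_compound,
        extra=extra,
        provenance=Provenance(parser="combined_est_table_parser"),
    )]


def parse_fractional_plqy_cell(cell_string: str, plqy_model: PropertyModel,
                               row_compound: Compound | None = None
                               ) -> list[CandidateRecord] | None:
    """Parser for fractional PLQY table cells (0–1, no ``%`` anywhere).

    The standard value is the fraction ×100 in percent. Cells carrying a
    ``%`` (in header or cell) are deferred to the generic parser.
    """
    headers, cell = _split_cell_string(cell_string)
    header_text = normalize_text(" ".join(headers))
    if not headers or not _specifier_regex(plqy_model).search(header_text):
        return None
    if "%" in header_text or "%" in cell:
        return None
    m = _BARE_NUMBER_RE.search(normalize_text(cell))
    if not m:
        return []
    values = [_num_to_float(m.group("v1"))]
    if m.group("v2"):
        values.append(_num_to_float(m.group("v2")))
    if not all(0.0 <= v <= 1.0 for v in values):
        return None  # not fractional: let the generic parser decide
    return [CandidateRecord(
        property_id="plqy",
        quantity=Quantity(values, "", m.group(0)),
        compound=row_compound,
        extra={"source_text": cell_string.replace(CELL_SEPARATOR, " "),
               "fractional": True},
        provenance=Provenance(parser="fractional_plqy_table_parser"),
        standard_value=[v * 100.0 for v in sorted(values)],
    )]


_TAU_D_FIELD_RE = re.compile(r"^τ\s*_?(?:d|D|del|delayed)$")
_TAU_P_FIELD_RE = re.compile(r"^τ\s*_?(?:p|P|prompt)$")
_SHARED_PARTNER_RE = re.compile(r"^(?:λ|Φ|PLQY)", re.IGNORECASE)


def parse_shared_lifetime_cell(cell_string: str,
                               row_compound: Compound | None = None
                               ) -> list[CandidateRecord] | None:
    """Parser for shared cells combining τ_d with τ_p, λ_em or PLQY.

    Header fields align positionally with cell fields using the header's
    own separator (slash or semicolon); only the τ_d slot is emitted.
    A single header unit applies to all slots.
    """
    headers, cell = _split_cell_string(cell_string)
    target = None
    for h in headers:
        base, unit_part = _strip_paren_unit(normalize_text(h))
        for sep in ("/", ";"):
            fields = [f.strip() for f in base.split(sep)]
            if len(fields) < 2:
                continue
            has_tau_d = any(_TAU_D_FIELD_RE.match(f) for f in fields)
            has_partner = any(
                _TAU_P_FIELD_RE.match(f) or _SHARED_PARTNER_RE.match(f)
                for f in fields if not _TAU_D_FIELD_RE.match(f)
            )
            if has_tau_d and has_partner:
                target = (fields, unit_part, sep)
                break
        if target:
            break
    if target is None:
        return None
    fields, unit_part, sep = target
    cell_fields = [c.strip() for c in normalize_text(cell).split(sep)]
    if len(cell_fields) != len(fields):
        return []
    idx = next(i for i, f in enumerate(fields) if _TAU_D_FIELD_RE.match(f))
    units = [u.strip() for u in unit_part.split(sep)] if unit_part else []
    if len(units) == len(fields):
        unit = units[idx]
    elif len(units) == 1:
        unit = units[0]  # single declared unit applies to every slot
    else:
        unit = "μs"
    try:
        value = _num_to_float(cell_fields[idx])
    except ValueError:
        return []
    return [CandidateRecord(
        property_id="tau_d",
        quantity=Quantity([value], unit, cell),
        compound=row_compound,
        extra={"source_text": cell_string.replace(CELL_SEPARATOR, " ")},
        provenance=Provenance(parser="shared_lifetime_table_parser"),
    )]


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def find_compound_column(table: Table) -> int | None:
    """Index of the column whose header names the row compound, if any."""
    for c, headers in enumerate(table.column_headers):
        for h in headers:
            if normalize_text(h).strip().lower() in COMPOUND_COLUMN_HEADERS:
                return c
    return None


def parse_table_cell(cell_string: str, models: dict[str, PropertyModel],
                     row_compound: Compound | None = None) -> list[CandidateRecord]:
    """Dispatch one serialized cell over the ordered parser list.

    Order: combined-ΔE_ST, shared-lifetime, fractional-PLQY, then the
    generic parser per property — specific before generic, so special
    header patterns are claimed exclusively and never double-emit.
    """
    for special in (
        lambda s: parse_combined_est_cell(s, row_compound),
        lambda s: parse_shared_lifetime_cell(s, row_compound),
        lambda s: parse_fractional_plqy_cell(s, models["plqy"], row_compound)
        if "plqy" in models else None,
    ):
        result = special(cell_string)
        if result is not None:
            return result
    records: list[CandidateRecord] = []
    for model in models.values():
        records.extend(parse_cell(cell_string, model, row_compound))
    return records


def parse_table(table: Table, models: dict[str, PropertyModel],
                doc_id: str = "", element_index: int = -1) -> list[CandidateRecord]:
    """Parse every body cell of a table, attaching row compounds."""
    records: list[CandidateRecord] = []
    comp_col = find_compound_column(table)
    for r, row in enumerate(table.body):
        row_compound = None
        if comp_col is not None and row[comp_col].strip():
            row_compound = Compound.from_surface(row[comp_col])
        for c in range(table.n_columns):
            if c == comp_col:
                continue
            cell_string = serialize_cell(table, r, c)
            if cell_string.endswith(CELL_SEPARATOR) or not table.body[r][c].strip():
                continue  # empty cell: serialized form ends with separator
            for rec in parse_table_cell(cell_string, models, row_compound):
                rec.provenance.doc_id = doc_id
                rec.provenance.element_index = element_index
                rec.provenance.cell = (r, c)
                records.append(rec)
    return records
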