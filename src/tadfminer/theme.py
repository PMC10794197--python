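"""ThemeCompound filtering and forward-looking compound resolution.

A *theme compound* is a focal compound of a paper, as opposed to the
reagents, solvents and comparison compounds that dominate raw chemical
entity mentions (CEMs). Ubiquitous CEMs are blocklisted from a
corpus-level occurrence-frequency table (each CEM counted once per
document); the default cut-off is the fraction 7/1200 of the corpus,
scaled by ceiling to the corpus at hand. Hand-compiled name and label
rules block further artefacts (serializer separators, DOI strings,
"-based"/"part"/"segment" morphology, substituent-fragment suffixes such
as "-o"/"-yl"; date/unit/electronic-state labels, percent labels, labels
longer than 4 characters). An allowlist overrides every block so
well-known emitters that happen to be ubiquitous (e.g. DMAC-TRZ) can be
kept.

Within one document, names and labels of theme compounds are remembered
as soon as they are first seen (forward-looking resolution), including
entries under table headers such as "Compounds" and "Emitters"; the
memory is reset when the document's extraction concludes and is never
shared across documents.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

from .document import Document, normalize_name
from .parsers import CELL_SEPARATOR, CandidateRecord, Compound

DEFAULT_THRESHOLD_FRACTION = 7 / 1200

#: suffixes marking substituent fragments rather than full compounds;
#: "ene" is deliberately absent (it would block e.g. anthracene).
FRAGMENT_SUFFIXES = ("o", "yl", "oxy")

#: morphology immediately following a CEM that marks it as a descriptor
DESCRIPTOR_AFFIXES = ("-based", "-containing", "-type", "part", "segment")

ELECTRONIC_STATES = {f"{s}{i}" for s in "ST" for i in range(10)} | {"S", "T"}

UNIT_STRINGS = {"nm", "μm", "mm", "cm", "m", "ps", "ns", "μs", "ms", "s",
                "eV", "meV", "kJ/mol", "%", "K", "k"}

_DATE_RES = (
    re.compile(r"^\d{4}-\d{2}-\d{2}$"),                      # ISO
    re.compile(r"^(?:January|February|March|April|May|June|July|August|"
               r"September|October|November|December)\s+\d{4}$", re.IGNORECASE),
    re.compile(r"^\d{1,2}/\d{1,2}/\d{2,4}$"),
)

_PERCENT_LABEL_RE = re.compile(r"^\d+(?:\.\d+)?\s*(?:wt\s*)?%$")


@dataclass
class FrequencyTable:
    counts: dict[str, int] = field(default_factory=dict)
    n_documents: int = 0


def build_frequency_table(cem_stream: list[tuple[str, str]]) -> FrequencyTable:
    """Count, per CEM name, the number of distinct documents containing it.

    Multiple occurrences within the same document count once.
    """
    docs_per_name: dict[str, set[str]] = {}
    doc_ids: set[str] = set()
    for doc_id, name in cem_stream:
        name = normalize_name(name)
        doc_ids.add(doc_id)
        docs_per_name.setdefault(name, set()).add(doc_id)
    return FrequencyTable(
        counts={name: len(docs) for name, docs in docs_per_name.items()},
        n_documents=len(doc_ids),
    )


@dataclass
class Blocklist:
    entries: set[str] = field(default_factory=set)
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
    provenance: dict[str, str] = field(default_factory=dict)
    allowlist: set[str] = field(default_factory=set)

    def add(self, name: str, reason: str) -> None:
        name = normalize_name(name)
        self.entries.add(name)
        self.provenance.setdefault(name, reason)

    def blocks(self, name: str) -> bool:
        name = normalize_name(name)
        if name in self.allowlist:
            return False
        return name in self.entries or name.lower() in self.entries

    def to_json(self, path: str | Path) -> None:
        payload = {
            "threshold_fraction": self.threshold_fraction,
            "entries": {e: self.provenance.get(e, "manual") for e in sorted(self.entries)},
            "allowlist": sorted(self.allowlist),
        }
        Path(path).write_text(json.dumps(payload, ensure_ascii=False, indent=1),
                              encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "Blocklist":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        bl = cls(threshold_fraction=payload.get("threshold_fraction",
                                                DEFAULT_THRESHOLD_FRACTION))
        for name, reason in payload.get("entries", {}).items():
            bl.add(name, reason)
        bl.allowlist = {normalize_name(a) for a in payload.get("allowlist", [])}
        return bl


def _name_variants(name: str) -> set[str]:
    """Case/whitespace/hyphenation variants used to enrich the blocklist."""
    base = normalize_name(name)
    return {base, base.lower(), base.upper(), base.capitalize(),
            base.replace("-", " "), base.replace(" ", "-")}


def build_blocklist(freq: FrequencyTable,
                    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
                    allowlist: set[str] | None = None) -> Blocklist:
    """Blocklist every CEM appearing in ≥ ceil(fraction × n_documents) docs.

    The cut-off is stored as a corpus fraction so small corpora scale the
    default (7 documents out of 1200) sensibly.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must lie in (0, 1]")
    cutoff = math.ceil(threshold_fraction * freq.n_documents)
    bl = Blocklist(threshold_fraction=threshold_fraction,
                   allowlist={normalize_name(a) for a in (allowlist or set())})
    for name, count in freq.counts.items():
        if count >= cutoff:
            for variant in _name_variants(name):
                bl.add(variant, "frequency")
    return bl


def blocklist_cutoff(freq: FrequencyTable, threshold_fraction: float) -> int:
    return math.ceil(threshold_fraction * freq.n_documents)


# ---------------------------------------------------------------------------
# Table-style name and label rules
# ---------------------------------------------------------------------------

def apply_name_rules(name: str, doc: Document | None = None,
                     allowlist: set[str] | None = None,
                     following_text: str = "") -> tuple[str, str]:
    """Verdict ("allow"|"block", reason) for a candidate compound name.

    Blocks serializer separators, the current document's DOI, descriptor
    morphology ("-based", "part", "segment"), and substituent-fragment
    suffixes ("-o", "-yl" and configured alike endings). The allowlist
    overrides every rule.
    """
    name = normalize_name(name)
    if allowlist and name in {normalize_name(a) for a in allowlist}:
        return ("allow", "allowlisted")
    if CELL_SEPARATOR[0] in name:
        return ("block", "separator")
    if doc is not None:
        doi = doc.metadata.get("doi", "")
        if doi and doi in name:
            return ("block", "doi-string")
    lowered = name.lower()
    for affix in DESCRIPTOR_AFFIXES:
        if lowered.endswith(affix):
            return ("block", f"descriptor:{affix}")
        if following_text and re.match(rf"\s*{re.escape(affix)}\b",
                                       following_text.lower()):
            return ("block", f"descriptor:{affix}")
    for suffix in FRAGMENT_SUFFIXES:
        if lowered.endswith(suffix) and len(lowered) > len(suffix):
            return ("block", f"fragment-suffix:{suffix}")
    return ("allow", "")


def apply_label_rules(label: str) -> tuple[str, str]:
    """Verdict ("allow"|"block", reason) for a candidate compound label.

    Blocks dates, electronic-state symbols, unit strings, percent labels
    and anything longer than 4 characters.
    """
    label = normalize_name(label)
    if len(label) > 4:
        return ("block", "too-long")
    if any(rx.match(label) for rx in _DATE_RES):
        return ("block", "date")
    if label in ELECTRONIC_STATES:
        return ("block", "electronic-state")
    if label in UNIT_STRINGS:
        return ("block", "unit")
    if _PERCENT_LABEL_RE.match(label):
        return ("block", "percent")
    return ("allow", "")


# ---------------------------------------------------------------------------
# Forward-looking resolution
# ---------------------------------------------------------------------------

@dataclass
class ThemeRegistry:
    """Per-document memory of theme-compound names and labels.

    Populated incrementally while a document is scanned; reset when the
    document's extraction concludes. Never shared across documents.
    """

    doc_id: str = ""
    known_names: list[str] = field(default_factory=list)
    known_labels: list[str] = field(default_factory=list)
    positions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def register(self, surface: str, element_index: int, token_offset: int = 0) -> None:
        surface = normalize_name(surface)
        if not surface:
            return
        is_label = len(surface) <= 4
        store = self.known_labels if is_label else self.known_names
        if surface not in store:
            store.append(surface)
        self.positions.setdefault(surface, []).append((element_index, token_offset))

    def known(self) -> list[str]:
        return self.known_names + self.known_labels

    def reset(self) -> None:
        self.known_names.clear()
        self.known_labels.clear()
        self.positions.clear()


def register_from_table_headers(registry: ThemeRegistry, table, element_index: int,
                                blocklist: Blocklist | None = None) -> None:
    """Auto-register entries of compound columns ("Compounds", "Emitters")."""
    from .parsers import find_compound_column

    col = find_compound_column(table)
    if col is None:
        return
    for r, row in enumerate(table.body):
        surface = normalize_name(row[col])
        if not surface:
            continue
        if blocklist is not None and blocklist.blocks(surface):
            continue
        verdict = (apply_label_rules(surface) if len(surface) <= 4
                   else apply_name_rules(surface))
        if verdict[0] == "allow":
            registry.register(surface, element_index, r)


def resolve_compound(record: CandidateRecord, registry: ThemeRegistry,
                     doc: Document | None = None,
                     element_theme_offsets: dict[str, list[int]] | None = None,
                     record_offset: int = 0) -> CandidateRecord | None:
    """Attach the nearest registered theme compound to a compound-less record.

    Distance is the absolute token-offset difference within the element;
    ties break toward the preceding compound. Records that still lack a
    compound and whose element contains no theme compound are dropped
    (returns ``None``).
    """
    if record.compound:
        return record
    candidates: list[tuple[int, int, str]] = []  # (distance, order, surface)
    offsets = element_theme_offsets or {}
    for surface in registry.known():
        for off in offsets.get(surface, []):
            delta = abs(off - record_offset)
            # preceding mentions win ties: order key 0 before 1
            order = 0 if off <= record_offset else 1
            candidates.append((delta, order, surface))
    if not candidates:
        # fall back to any same-element registered position
        el = record.provenance.element_index
        for surface, pos_list in registry.positions.items():
            for el_idx, tok in pos_list:
                if el_idx == el:
                    candidates.append((abs(tok - record_offset),
                                       0 if tok <= record_offset else 1, surface))
    if not candidates:
        return None
    _, _, surface = min(candidates)
    record.compound = Compound.from_surface(surface)
    return record
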