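"""Record cleaning: physical-range filters, unit and temperature
standardization, phase/atmosphere capture, and the experimental-vs-
theoretical flag for singlet-triplet gaps.

Physically reasonable ranges (standard units):

    300 nm < λ_EM < 1600 nm        (exclusive)
    0 %   ≤ PLQY ≤ 100 %           (inclusive, as printed)
    −1.5 eV < ΔE_ST < 1.5 eV       (exclusive)
    100 ns < τ_D < 10 s            (exclusive; 0.1–1e7 μs)

Room-temperature flags on delayed-lifetime records are replaced by 293 K;
an explicitly extracted temperature wins over the flag on conflict.

ΔE_ST values may come from spectroscopy (onset differences) or from
DFT/TD-DFT calculations. Classification uses a context built from the
section heading, the first sentence of the paragraph, and the record's
own sentence; standalone table records have no such context and stay
unclassified. The default classifier is a keyword heuristic behind a
plugin seam that accepts trained text classifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

from .document import Document
from .nlp import segment_sentences
from .ontology import PropertyModel, to_standard
from .parsers import CandidateRecord

logger = logging.getLogger("tadfminer.postprocess")

ROOM_TEMPERATURE_K = 293.0

#: exclusive/inclusive physical bounds per property, in standard units
PHYSICAL_RANGES: dict[str, tuple[float, float, bool]] = {
    # property: (low, high, inclusive)
    "lambda_em": (300.0, 1600.0, False),      # nm
    "plqy": (0.0, 100.0, True),               # %
    "delta_e_st": (-1.5, 1.5, False),         # eV
    "tau_d": (0.1, 1.0e7, False),             # μs: 100 ns .. 10 s
}

ROOM_TEMPERATURE_FLAGS = ("room temperature", "room-temperature", "rt", "r.t.")

PHASE_KEYWORDS = ("doped film", "neat film", "thin film", "film", "solution",
                  "toluene solution", "neat", "solid", "crystal", "powder")
ATMOSPHERE_KEYWORDS = {
    "nitrogen": ("n2", "nitrogen", "degassed", "inert atmosphere"),
    "air": ("in air", "air-equilibrated", "aerated", "under air"),
}

THEORETICAL_CUES = ("dft", "td-dft", "calculated", "computed", "simulat",
                    "theoretical", "b3lyp", "gaussian")
EXPERIMENTAL_CUES = ("measured", "onset", "phosphorescence spectr",
                     "fluorescence spectr", "experimental", "spectroscop")


def standardize_record(record: CandidateRecord, model: PropertyModel) -> CandidateRecord:
    """Fill ``standard_value`` unless a special parser already did."""
    if record.standard_value is None:
        record.standard_value = to_standard(record.quantity, model)
    return record


def filter_physical_range(record: CandidateRecord) -> tuple[bool, str]:
    """(keep, reason): drop iff any standard value violates its bounds."""
    bounds = PHYSICAL_RANGES.get(record.property_id)
    if bounds is None or record.standard_value is None:
        return (False, "no-standard-value")
    low, high, inclusive = bounds
    for v in record.standard_value:
        ok = (low <= v <= high) if inclusive else (low < v < high)
        if not ok:
            return (False, f"out-of-range:{v}")
    return (True, "")


def standardize_temperature(record: CandidateRecord) -> CandidateRecord | None:
    """Resolve the temperature field of a delayed-lifetime record.

    A room-temperature flag becomes 293 K; an explicit extracted value
    beats the flag on conflict; no information leaves the field absent.
    Non-physical temperatures (≤ 0 K) drop the record (returns ``None``).
    """
    if record.property_id != "tau_d":
        return record
    explicit = record.extra.get("temperature_K")
    flagged = bool(record.extra.get("rt_flag"))
    if explicit is None and flagged:
        source = record.extra.get("source_text", "").lower()
        flagged = flagged or any(f in source for f in ROOM_TEMPERATURE_FLAGS)
    if explicit is not None:
        if explicit <= 0:
            return None
        record.extra["temperature"] = float(explicit)
    elif flagged:
        record.extra["temperature"] = ROOM_TEMPERATURE_K
    return record


def extract_phase_atmosphere(record: CandidateRecord) -> CandidateRecord:
    """Scan the record's sentence/cell for phase and atmosphere keywords."""
    text = record.extra.get("source_text", "").lower()
    if record.property_id in ("plqy", "lambda_em"):
        for kw in PHASE_KEYWORDS:
            if kw in text:
                record.extra.setdefault("phase", kw)
                break
    if record.property_id == "plqy":
        atmosphere = "unknown"
        for label, cues in ATMOSPHERE_KEYWORDS.items():
            if any(c in text for c in cues):
                atmosphere = label
                break
        record.extra["atmosphere"] = atmosphere
    return record


# ---------------------------------------------------------------------------
# is_experimental classification
# ---------------------------------------------------------------------------

def build_classifier_context(record: CandidateRecord, doc: Document) -> str | None:
    """Section heading ⊕ first paragraph sentence ⊕ record sentence.

    Standalone table records have no sentence context and return ``None``
    (they stay unclassified). If the record's sentence *is* the first
    sentence of its paragraph it is included only once.
    """
    if record.provenance.cell is not None:
        return None
    el_index = record.provenance.element_index
    if doc is None or not (0 <= el_index < len(doc.elements)):
        return None
    element = doc.elements[el_index]
    if element.kind != "paragraph":
        return None
    parts: list[str] = []
    if element.section_heading:
        parts.append(element.section_heading)
    sentences = segment_sentences(element.text)
    first = sentences[0].text if sentences else ""
    record_sentence = record.extra.get("source_text", "")
    if first and first != record_sentence:
        parts.append(first)
    if record_sentence:
        parts.append(record_sentence)
    return " ".join(parts) if parts else None


def keyword_classifier(context: str) -> str:
    """Default rule-based classifier: tri-state true/false/unknown."""
    low = context.lower()
    theoretical = any(cue in low for cue in THEORETICAL_CUES)
    experimental = any(cue in low for cue in EXPERIMENTAL_CUES)
    if theoretical and not experimental:
        return "false"
    if experimental and not theoretical:
        return "true"
    return "unknown"


def classify_is_experimental(context: str | None,
                             classifier: Callable[[str], str] = keyword_classifier
                             ) -> str:
    """Tri-state experimental flag; no context ⇒ unknown."""
    if context is None:
        return "unknown"
    verdict = classifier(context)
    if verdict not in ("true", "false", "unknown"):
        raise ValueError(f"classifier returned invalid verdict {verdict!r}")
    return verdict


# ---------------------------------------------------------------------------
# Cleaning driver
# ---------------------------------------------------------------------------

@dataclass
class CleaningReport:
    kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str) -> None:
        key = reason.split(":")[0]
        self.dropped[key] = self.dropped.get(key, 0) + 1


def clean_records(records: list[CandidateRecord],
                  models: dict[str, PropertyModel],
                  doc: Document | None = None,
                  classifier: Callable[[str], str] = keyword_classifier,
                  report: CleaningReport | None = None) -> list[CandidateRecord]:
    """Standardize, range-filter and annotate a document's records."""
    report = report if report is not None else CleaningReport()
    cleaned: list[CandidateRecord] = []
    for record in records:
        model = models[record.property_id]
        standardize_record(record, model)
        keep, reason = filter_physical_range(record)
        if not keep:
            report.drop(f"range:{reason}")
            logger.debug("drop %s: %s", record.property_id, reason)
            continue
        resolved = standardize_temperature(record)
        if resolved is None:
            report.drop("non-physical-temperature")
            continue
        record = extract_phase_atmosphere(resolved)
        if record.property_id == "delta_e_st":
            context = build_classifier_context(record, doc) if doc else None
            record.extra["is_experimental"] = classify_is_experimental(context, classifier)
        cleaned.append(record)
        report.kept += 1
    logger.info("cleaning: kept %d, dropped %s", report.kept, dict(report.dropped))
    return cleaned
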