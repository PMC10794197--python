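"""End-to-end orchestration: corpus → records.

Per document the stages run in order: read → sentence segmentation and
entity tagging → abbreviation detection → sentence and table parsing →
theme-compound resolution (the per-document compound memory is reset
when the document concludes) → post-processing → optional SMILES
subsidiary output. Processing is streaming per document; the only
cross-document state is the pre-built blocklist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import dbio, postprocess, smiles as smiles_mod
from .document import Document, iter_parseable, normalize_name, read_document
from .errors import ConfigurationError, MarkupParseError
from .nlp import (AbbreviationRegistry, LexiconTagger, detect_abbreviations,
                  get_tagger, segment_sentences, tag_cems)
from .ontology import load_default_models
from .parsers import (CandidateRecord, Compound, parse_sentence, parse_table)
from .theme import (Blocklist, ThemeRegistry, apply_label_rules,
                    apply_name_rules, build_blocklist, build_frequency_table,
                    register_from_table_headers, DEFAULT_THRESHOLD_FRACTION)

logger = logging.getLogger("tadfminer.pipeline")


@dataclass
class PipelineConfig:
    dialect: str = "xml-like"
    property_models_path: str | None = None
    lexicon_path: str | None = None
    blocklist_path: str | None = None
    allowlist_path: str | None = None
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
    tagger: str = "lexicon"
    smiles_backend: str | None = None
    smiles_lookup_path: str | None = None
    smiles_filter_conjunctive: bool = True
    output_format: str = "json"
    seed: int = 0
    log_level: str = "WARNING"

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction <= 1:
            raise ConfigurationError("threshold_fraction must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunReport:
    n_documents: int = 0
    n_skipped: int = 0
    stage_counts: dict[str, int] = field(default_factory=dict)
    drop_reasons: dict[str, int] = field(default_factory=dict)

    def bump(self, stage: str, n: int = 1) -> None:
        self.stage_counts[stage] = self.stage_counts.get(stage, 0) + n


def _load_tagger(config: PipelineConfig):
    if config.tagger == "lexicon":
        if config.lexicon_path:
            return LexiconTagger.from_file(config.lexicon_path)
        return LexiconTagger()
    return get_tagger(config.tagger)


def corpus_documents(corpus_dir: str | Path, dialect: str) -> list[Path]:
    corpus_dir = Path(corpus_dir)
    docs_dir = corpus_dir / "docs" if (corpus_dir / "docs").is_dir() else corpus_dir
    return sorted(p for p in docs_dir.iterdir()
                  if p.suffix in (".xml", ".html") and p.is_file())


def collect_cem_stream(corpus_dir: str | Path, config: PipelineConfig
                       ) -> list[tuple[str, str]]:
    """CEM occurrences (doc_id, name) from the corpus's paragraph text."""
    tagger = _load_tagger(config)
    stream: list[tuple[str, str]] = []
    for path in corpus_documents(corpus_dir, config.dialect):
        try:
            doc = read_document(path, config.dialect)
        except MarkupParseError:
            continue
        for element in iter_parseable(doc):
            if element.kind != "paragraph":
                continue
            for sentence in segment_sentences(element.text):
                tag_cems(sentence, tagger)
                stream.extend((doc.doc_id, name) for _, _, name in sentence.cem_spans)
    return stream


def build_corpus_blocklist(corpus_dir: str | Path, config: PipelineConfig,
                           allowlist: set[str] | None = None) -> Blocklist:
    freq = build_frequency_table(collect_cem_stream(corpus_dir, config))
    return build_blocklist(freq, config.threshold_fraction, allowlist=allowlist)


def _load_allowlist(config: PipelineConfig) -> set[str]:
    if not config.allowlist_path:
        return set()
    with open(config.allowlist_path, encoding="utf-8") as fh:
        return {normalize_name(line) for line in fh if line.strip()}


def _compound_allowed(surface: str, doc: Document, blocklist: Blocklist | None) -> bool:
    surface = normalize_name(surface)
    if blocklist is not None and blocklist.blocks(surface):
        return False
    verdict = (apply_label_rules(surface) if len(surface) <= 4
               else apply_name_rules(surface, doc))
    return verdict[0] == "allow"


def extract_document(doc: Document, models, tagger,
                     blocklist: Blocklist | None = None,
                     abbreviations: AbbreviationRegistry | None = None
                     ) -> list[CandidateRecord]:
    """Run the per-document extraction stages; the theme registry lives and
    dies inside this call, so documents never share compound memory."""
    registry = ThemeRegistry(doc_id=doc.doc_id)
    abbreviations = abbreviations or AbbreviationRegistry()
    records: list[CandidateRecord] = []
    try:
        for element in iter_parseable(doc):
            if element.kind == "paragraph":
                sentences = segment_sentences(element.text)
                for s_idx, sentence in enumerate(sentences):
                    tag_cems(sentence, tagger)
                    for pair in detect_abbreviations(sentence):
                        abbreviations.add(pair)
                    for start, end, name in sentence.cem_spans:
                        if _compound_allowed(name, doc, blocklist):
                            registry.register(name, element.index,
                                              sentence.start + start)
                    for model in models.values():
                        for record in parse_sentence(
                                sentence, model, doc.doc_id, element.index, s_idx):
                            record.extra["offset"] = sentence.start
                            records.append(record)
            elif element.kind == "table":
                register_from_table_headers(registry, element.table_payload,
                                            element.index, blocklist)
                records.extend(parse_table(element.table_payload, models,
                                           doc.doc_id, element.index))
        records = _resolve_compounds(records, registry, doc, blocklist, abbreviations)
    finally:
        registry.reset()  # memory never leaks into the next document
    return records


def _resolve_compounds(records, registry: ThemeRegistry, doc: Document,
                       blocklist: Blocklist | None,
                       abbreviations: AbbreviationRegistry) -> list[CandidateRecord]:
    from .theme import resolve_compound

    resolved: list[CandidateRecord] = []
    for record in records:
        # strip blocklisted/rule-breaking compounds before resolution
        if record.compound:
            kept = [n for n in record.compound.all_identifiers()
                    if _compound_allowed(n, doc, blocklist)]
            if not kept:
                record.compound = None
        if not record.compound:
            record = resolve_compound(
                record, registry, doc,
                record_offset=record.extra.get("offset", 0))
            if record is None:
                continue
        # unify names through document-wide abbreviation pairs
        if record.compound and record.compound.names:
            aliases: list[str] = []
            for name in record.compound.names:
                for alias in abbreviations.aliases(name):
                    if alias not in record.compound.names and alias not in aliases:
                        aliases.append(alias)
            record.compound.names.extend(aliases)
        resolved.append(record)
    return resolved


def run_pipeline(corpus_dir: str | Path, config: PipelineConfig,
                 blocklist: Blocklist | None = None
                 ) -> tuple[list[dict], list[dict], RunReport]:
    """Extract, resolve and clean every document of a corpus.

    Returns (master records, subsidiary records with SMILES, run report).
    When no blocklist is supplied one is built from the corpus itself at
    the configured threshold fraction.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 30))
    models = load_default_models(config.property_models_path)
    tagger = _load_tagger(config)
    allowlist = _load_allowlist(config)
    if blocklist is None:
        if config.blocklist_path:
            blocklist = Blocklist.from_json(config.blocklist_path)
            blocklist.allowlist |= allowlist
        else:
            blocklist = build_corpus_blocklist(corpus_dir, config, allowlist)
    report = RunReport()
    master: list[dict] = []
    for path in corpus_documents(corpus_dir, config.dialect):
        try:
            doc = read_document(path, config.dialect)
        except MarkupParseError as exc:
            logger.warning("skipping unreadable document %s: %s", path.name, exc)
            report.n_skipped += 1
            continue
        report.n_documents += 1
        candidates = extract_document(doc, models, tagger, blocklist)
        report.bump("candidates", len(candidates))
        cleaning = postprocess.CleaningReport()
        cleaned = postprocess.clean_records(candidates, models, doc,
                                            report=cleaning)
        report.bump("cleaned", len(cleaned))
        for reason, n in cleaning.dropped.items():
            report.drop_reasons[reason] = report.drop_reasons.get(reason, 0) + n
        master.extend(dbio.record_to_dict(r, doc.metadata) for r in cleaned)
        # re-attach extras needed for the subsidiary pass
        for record, rec_dict in zip(cleaned, master[-len(cleaned):]):
            rec_dict["_record"] = record
    subsidiary = _build_subsidiary(master, config)
    for rec in master:
        rec.pop("_record", None)
    report.bump("master", len(master))
    report.bump("subsidiary", len(subsidiary))
    return master, subsidiary, report


def _build_subsidiary(master: list[dict], config: PipelineConfig) -> list[dict]:
    if not config.smiles_backend:
        return []
    if config.smiles_backend == "lookup":
        if config.smiles_lookup_path:
            backend = smiles_mod.LookupBackend.from_tsv(config.smiles_lookup_path)
        else:
            backend = smiles_mod.LookupBackend()
    else:
        backend = smiles_mod.get_backend(config.smiles_backend)
    records = [rec["_record"] for rec in master if "_record" in rec]
    kept = {id(r) for r in smiles_mod.attach_smiles(
        records, backend, conjunctive=config.smiles_filter_conjunctive)}
    out: list[dict] = []
    for rec_dict in master:
        record = rec_dict.get("_record")
        if record is not None and id(record) in kept:
            sub = {k: v for k, v in rec_dict.items() if k != "_record"}
            sub = dict(sub)
            sub["compound"] = dict(sub["compound"])
            sub["compound"]["smiles"] = record.extra["smiles"]
            out.append(sub)
    return out
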