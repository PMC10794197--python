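"""Synthetic-corpus generator with gold-standard annotations.

Generates dialect-conformant article files that emulate the extraction
targets of the real pipeline — property sentences, property tables with
a compound column, the three special table-cell layouts, abbreviation
definitions, and distractor solvent/atmosphere mentions — together with
the exact gold records planted, the per-name document counts (for
frequency-table oracles), and the lexicon covering every planted entity.

The generator is deterministic: identical spec + seed produce
byte-identical corpora. Phrasing templates live in
``data/templates.yaml`` so new phrasings extend coverage without code
changes.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
import yaml

DEFAULT_SOLVENT_POOL = ("toluene", "nitrogen", "dichloromethane", "chloroform",
                        "tetrahydrofuran")

_COMPOUND_CORES = ("CzIPN", "CzPN", "PXZ-TRZ", "DMeCz", "AcIPN", "BNCz")
_LONG_FRAGMENTS = ("carbazol-9-yl", "dimethylacridin-10-yl", "phenoxazin-10-yl")

# synthetic name→SMILES assignments for generated compounds (large donor-
# acceptor scaffolds that survive the structure filter)
_SMILES_POOL = (
    "N#Cc1c(n2c3ccccc3c3ccccc32)c(n2c3ccccc3c3ccccc32)c(C#N)"
    "c(n2c3ccccc3c3ccccc32)c1n1c2ccccc2c2ccccc21",
    "N#Cc1ccc(n2c3ccccc3c3ccccc32)c(n2c3ccccc3c3ccccc32)c1C#N",
    "c1ccc2cc(-c3ccc4cc(-c5ccc6ccccc6c5)ccc4c3)ccc2c1",
)


@dataclass
class CorpusSpec:
    n_documents: int = 20
    facts_per_property: int = 3        # planted facts per property per document
    n_distractor_solvents: int = 3
    distractor_probability: float = 0.75  # chance a pooled solvent enters a doc
    abbreviation_probability: float = 0.5
    include_special_tables: bool = True
    noise_missing_units: bool = False  # robustness option, off for gold corpora
    threshold_fraction: float = 0.35   # blocklist cut-off used downstream
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_documents < 0 or self.facts_per_property < 0:
            raise ValueError("counts must be non-negative")


def _load_templates() -> dict:
    text = resources.files("tadfminer.data").joinpath("templates.yaml").read_text(
        encoding="utf-8"
    )
    return yaml.safe_load(text)


def _fmt(value: float, decimals: int) -> tuple[str, float]:
    """Format once, then take the parsed float as the planted truth."""
    s = f"{value:.{decimals}f}" if decimals else str(int(round(value)))
    return s, float(s)


def _gold(doc_id: str, pid: str, compound: str, values: list[float], units: str,
          standard: list[float], method: str, temperature: float | None = None) -> dict:
    compound_dict = ({"names": [compound], "labels": []} if len(compound) > 4
                     else {"names": [], "labels": [compound]})
    rec = {
        "doc_id": doc_id,
        "model_name": pid,
        "compound": compound_dict,
        "value": values,
        "units": units,
        "standard_value": standard,
        "record_method": method,
        "metadata": {},
    }
    if pid == "tau_d" and temperature is not None:
        rec["temperature"] = temperature
    return rec


@dataclass
class GeneratedDocument:
    doc_id: str
    markup: str
    gold: list[dict]
    mentioned_names: set[str] = field(default_factory=set)
    lexicon: set[str] = field(default_factory=set)


def _draw_value(pid: str, rng: np.random.Generator) -> tuple[str, float]:
    if pid == "lambda_em":
        return _fmt(float(rng.integers(350, 801)), 0)
    if pid == "plqy":
        return _fmt(float(rng.integers(5, 96)), 0)
    if pid == "delta_e_st":
        return _fmt(float(rng.uniform(0.01, 0.40)), 2)
    return _fmt(float(rng.uniform(0.5, 50.0)), 1)  # tau_d, μs


_STANDARD_UNIT = {"lambda_em": "nm", "plqy": "%", "delta_e_st": "eV", "tau_d": "μs"}


def generate_document(spec: CorpusSpec, doc_index: int) -> GeneratedDocument:
    """Generate one article file (xml-like dialect) plus its gold records."""
    rng = np.random.default_rng([spec.seed % (2**31), doc_index])
    templates = _load_templates()
    doc_id = f"10.0000/synthetic-{doc_index:04d}"
    gold: list[dict] = []
    mentioned: set[str] = set()
    lexicon: set[str] = set()

    # suffix alphabet avoids letters that would trip fragment-suffix rules
    suffixes = "ABCDEFGHIJKLMNPQRSTUVWXZ"
    n_compounds = max(2, min(spec.facts_per_property, len(suffixes)))
    compounds = []
    for k in range(n_compounds):
        core = _COMPOUND_CORES[int(rng.integers(len(_COMPOUND_CORES)))]
        compounds.append(f"{doc_index + 1}{core}-{suffixes[k]}")
    for c in compounds:
        lexicon.add(c)
        mentioned.add(c)

    solvents = [DEFAULT_SOLVENT_POOL[i] for i in range(spec.n_distractor_solvents)]
    doc_solvents = [s for s in solvents if rng.random() < spec.distractor_probability]
    for s in doc_solvents:
        lexicon.add(s)
        mentioned.add(s)

    paragraphs: list[str] = []

    # every compound is introduced in text once, so planted per-name
    # document counts are exactly recoverable from sentence CEMs
    if len(compounds) > 1:
        listing = ", ".join(compounds[:-1]) + " and " + compounds[-1]
    else:
        listing = compounds[0]
    paragraphs.append(f"In this work, the emitters {listing} were investigated.")

    # abbreviation definitions for a configurable fraction of compounds
    for c in compounds:
        if rng.random() < spec.abbreviation_probability:
            frag = _LONG_FRAGMENTS[int(rng.integers(len(_LONG_FRAGMENTS)))]
            long_name = f"bis({frag})-{doc_index + 1}-cyanobenzene-{c[-1]}"
            lexicon.add(long_name)
            mentioned.add(long_name)
            tpl = templates["abbreviation"][int(rng.integers(len(templates["abbreviation"])))]
            paragraphs.append(tpl.format(long=long_name, short=c))

    # distractor mentions
    for s in doc_solvents:
        tpl = templates["distractor"][int(rng.integers(len(templates["distractor"])))]
        paragraphs.append(tpl.format(solvent=s))

    # sentence facts: one property sentence per fact, grouped into paragraphs
    property_ids = ["lambda_em", "plqy", "delta_e_st", "tau_d"]
    n_sentence_facts = max(1, spec.facts_per_property // 2)
    sentence_bits: list[str] = []
    for pid in property_ids:
        for _ in range(n_sentence_facts):
            compound = compounds[int(rng.integers(len(compounds)))]
            value_str, value = _draw_value(pid, rng)
            temp_clause, temperature = "", None
            if pid == "tau_d":
                choice = rng.integers(3)
                if choice == 0:
                    temp_clause, temperature = " at room temperature", 293.0
                elif choice == 1:
                    t = float(rng.choice([77, 100, 200, 300]))
                    temp_clause, temperature = f" at {t:.0f} K", t
            tpl_list = templates["sentence"][pid]
            tpl = tpl_list[int(rng.integers(len(tpl_list)))]
            sentence_bits.append(tpl.format(compound=compound, value=value_str,
                                            temp_clause=temp_clause))
            gold.append(_gold(doc_id, pid, compound, [value], _STANDARD_UNIT[pid],
                              [value], "sentence_parser", temperature))
    for i in range(0, len(sentence_bits), 3):
        paragraphs.append(" ".join(sentence_bits[i:i + 3]))

    # forward-looking resolution paragraph: compound named one sentence earlier
    res_pid = "plqy" if rng.random() < 0.5 else "lambda_em"
    res_compound = compounds[int(rng.integers(len(compounds)))]
    value_str, value = _draw_value(res_pid, rng)
    tpl = templates["resolution"][res_pid][0]
    paragraphs.append(tpl.format(compound=res_compound, value=value_str))
    gold.append(_gold(doc_id, res_pid, res_compound, [value],
                      _STANDARD_UNIT[res_pid], [value], "sentence_parser"))

    # main property table: remaining facts per property
    n_table_facts = spec.facts_per_property - n_sentence_facts
    table_rows: list[list[str]] = []
    headers = ["Compounds", "λem (nm)", "ΦPL (%)", "ΔEST (eV)", "τd (μs)"]
    for _ in range(n_table_facts):
        compound = compounds[int(rng.integers(len(compounds)))]
        row = [compound]
        for pid in property_ids:
            value_str, value = _draw_value(pid, rng)
            row.append(value_str)
            gold.append(_gold(doc_id, pid, compound, [value], _STANDARD_UNIT[pid],
                              [value], "table_cell_parser"))
        table_rows.append(row)

    special_table = None
    if spec.include_special_tables:
        sheaders = ["Emitters", "ES/ET/ΔEST (eV)", "ΦPL", "τp/τd (ns/μs)"]
        srows: list[list[str]] = []
        for compound in compounds[:2]:
            dst_str, dst = _fmt(float(rng.uniform(0.05, 0.30)), 2)
            et_str, et = _fmt(float(rng.uniform(2.4, 3.0)), 2)
            es_str, _ = _fmt(et + dst, 2)
            frac_str, frac = _fmt(float(rng.uniform(0.05, 0.95)), 2)
            tp_str, _ = _fmt(float(rng.uniform(1.0, 50.0)), 1)
            td_str, td = _fmt(float(rng.uniform(0.5, 50.0)), 1)
            srows.append([compound, f"{es_str}/{et_str}/{dst_str}", frac_str,
                          f"{tp_str}/{td_str}"])
            gold.append(_gold(doc_id, "delta_e_st", compound, [dst], "eV", [dst],
                              "combined_est_table_parser"))
            gold.append(_gold(doc_id, "plqy", compound, [frac], "", [frac * 100.0],
                              "fractional_plqy_table_parser"))
            gold.append(_gold(doc_id, "tau_d", compound, [td], "μs", [td],
                              "shared_lifetime_table_parser"))
        special_table = (sheaders, srows)

    markup = _render_xml(doc_id, doc_index, paragraphs,
                         (headers, table_rows) if table_rows else None,
                         special_table)
    return GeneratedDocument(doc_id=doc_id, markup=markup, gold=gold,
                             mentioned_names=mentioned, lexicon=lexicon)


def _render_xml(doc_id: str, doc_index: int, paragraphs: list[str],
                main_table: tuple[list[str], list[list[str]]] | None,
                special_table: tuple[list[str], list[list[str]]] | None) -> str:
    def table_xml(headers: list[str], rows: list[list[str]], caption: str) -> str:
        parts = ["  <table>", f"   <caption>{escape(caption)}</caption>",
                 "   <tr>" + "".join(f"<th>{escape(h)}</th>" for h in headers) + "</tr>"]
        for row in rows:
            parts.append("   <tr>" + "".join(f"<td>{escape(c)}</td>" for c in row) + "</tr>")
        parts.append("  </table>")
        return "\n".join(parts)

    lines = [
        "<article>",
        " <meta>",
        f"  <doi>{escape(doc_id)}</doi>",
        f"  <authors>Synthetic Author {doc_index}</authors>",
        "  <journal>Synthetic Journal of Delayed Fluorescence</journal>",
        "  <year>2023</year>",
        " </meta>",
        f" <title>Synthetic TADF study no. {doc_index}</title>",
        " <section>",
        "  <h>Introduction</h>",
        "  <p>Thermally activated delayed fluorescence enables efficient "
        "triplet harvesting in organic emitters.</p>",
        " </section>",
        " <section>",
        "  <h>Photophysical properties</h>",
    ]
    for p in paragraphs:
        lines.append(f"  <p>{escape(p)}</p>")
    if main_table:
        lines.append(table_xml(*main_table, caption="Photophysical data."))
    if special_table:
        lines.append(table_xml(*special_table, caption="Combined photophysical data."))
    lines += [" </section>", "</article>", ""]
    return "\n".join(lines)


@dataclass
class GeneratedCorpus:
    directory: Path
    doc_paths: list[Path]
    gold: list[dict]
    planted_frequencies: dict[str, int]
    lexicon: list[str]

    @property
    def gold_path(self) -> Path:
        return self.directory / "gold.json"

    @property
    def lexicon_path(self) -> Path:
        return self.directory / "lexicon.txt"

    @property
    def smiles_path(self) -> Path:
        return self.directory / "name_smiles.tsv"


def generate_corpus(spec: CorpusSpec, out_dir: str | Path) -> GeneratedCorpus:
    """Generate ``n_documents`` files plus gold.json, planted_frequencies.json
    and lexicon.txt under ``out_dir``.

    Warns when the blocklist cut-off implied by the spec's threshold
    fraction degenerates (< 2 documents), since then every mention —
    including focal compounds — would be blocklisted.
    """
    out_dir = Path(out_dir)
    docs_dir = out_dir / "docs"
    docs_dir.mkdir(parents=True, exist_ok=True)
    gold: list[dict] = []
    counts: dict[str, int] = {}
    lexicon: set[str] = set()
    doc_paths: list[Path] = []
    for i in range(spec.n_documents):
        gen = generate_document(spec, i)
        path = docs_dir / f"doc-{i:04d}.xml"
        path.write_text(gen.markup, encoding="utf-8")
        doc_paths.append(path)
        gold.extend(gen.gold)
        lexicon |= gen.lexicon
        for name in gen.mentioned_names:
            counts[name] = counts.get(name, 0) + 1
    cutoff = math.ceil(spec.threshold_fraction * spec.n_documents)
    if spec.n_documents and cutoff < 2:
        warnings.warn(
            f"blocklist cut-off {cutoff} over {spec.n_documents} documents is "
            "degenerate: every compound would be blocklisted", stacklevel=2)
    (out_dir / "gold.json").write_text(
        json.dumps(gold, ensure_ascii=False, sort_keys=True, indent=1) + "\n",
        encoding="utf-8")
    (out_dir / "planted_frequencies.json").write_text(
        json.dumps(dict(sorted(counts.items())), ensure_ascii=False, indent=1) + "\n",
        encoding="utf-8")
    (out_dir / "lexicon.txt").write_text(
        "\n".join(sorted(lexicon)) + "\n", encoding="utf-8")
    solvent_set = set(DEFAULT_SOLVENT_POOL)
    compound_names = [n for n in sorted(lexicon) if n not in solvent_set]
    (out_dir / "name_smiles.tsv").write_text(
        "# synthetic name -> SMILES assignments for generated compounds\n"
        + "".join(f"{name}\t{_SMILES_POOL[i % len(_SMILES_POOL)]}\n"
                  for i, name in enumerate(compound_names)),
        encoding="utf-8")
    return GeneratedCorpus(directory=out_dir, doc_paths=doc_paths, gold=gold,
                           planted_frequencies=counts, lexicon=sorted(lexicon))
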