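# Methods

This note documents the models, rules and design choices behind
`tadfminer`, in the spirit of a methods section: what each stage assumes,
which parameters matter, and what the synthetic test bed does and does
not show about real literature data.

## Document model and dialects

Publisher markup varies by journal; rather than emulate any particular
publisher schema (retrieval and publisher-specific scraping are out of
scope), the package defines two minimal dialects with a documented tag
set — `xml-like` (`<article>`, `<meta>`, `<title>`, `<section>`, `<h>`,
`<p>`, `<table>/<tr>/<th>/<td>/<caption>`) and `html-like` (standard
`head`/`body`, `h1`/`h2`, `p`, `table` with optional `thead`). Inline
decoration (`b`, `i`, `sub`, `sup`, `span`) is flattened to text. Files
are UTF-8 throughout; Greek symbols (λ, τ, Δ, Φ) and the astral-plane
cell separator must survive ingestion unmodified. The metadata/citation
block is an element flagged `metadata`, and the iterator used by every
parser skips it, so no property record can originate from citation text.
Nested table headers are flattened to per-column ordered header lists,
outermost first — needed for deterministic cell serialization. Figure
captions are not modelled; whether they should be parsed is an open
question and the fixtures omit them.

Name normalization removes leading/trailing whitespace, collapses runs,
and deletes spaces adjacent to hyphens, commas and brackets. Single
spaces between alphabetic words are kept ("boron nitride"), because
"unnecessary whitespace" is otherwise undefined and removing inner
spaces would destroy multi-word names. The operation is idempotent
(property-tested).

## NLP layer

Sentence segmentation splits on `.`/`!`/`?` followed by whitespace,
except after known non-terminal abbreviations ("Fig.", "approx.",
"et al.") or inside decimals; concatenating sentence texts with their
separators reconstructs the paragraph exactly, so offsets are stable.

Chemical named-entity recognition is a pluggable contract. The default
tagger combines (a) lexicon longest-match — case-insensitive for names,
case-sensitive for short label-like entries (≤ 4 characters) — and
(b) morphology heuristics: tokens mixing digits, uppercase and lowercase
("4CzIPN") and systematic-name fragments with locants and brackets.
This is a deliberate, deterministic stand-in for learned taggers; any
tagger registered under a name can replace it, and every downstream
stage only sees spans.

Abbreviation detection: for each tagged chemical entity, a strictly
shorter entity (fewer characters after name normalization; ties yield no
pair) immediately adjacent in matched brackets `()`/`[]`/`{}` or linked
by `=`/`:` defines a short↔long pair. The letters-in-order
(Schwartz–Hearst-style) test cannot handle organic abbreviations like
"2CzPN", whose letters do not appear in order in the systematic name, so
it is retained only for non-chemical acronym definitions ("TADF"). Pairs
are registered document-wide and unify compound names on emitted records.

## Property ontology

Each property model carries: specifier surface forms (configuration,
seeded with the symbols λem/λEM/λmax(em), ΦPL/PLQY/Φf, ΔEST and
variants, τd/τD/"delayed lifetime"), a dimension, a generated unit
grammar, a fixed standard unit (nm, %, eV, μs) and per-property extra
fields (phase; phase+atmosphere; is_experimental; temperature). The unit
grammar derives from the dimension: SI prefixes for time (ps–s) and
length (nm–m), eV/meV/kJ/mol for energy with 1 eV ≙ 96.485 kJ/mol, and
`%` for the fraction dimension. Homoglyphs that differ across publishers
(micro sign vs Greek mu, minus vs hyphen, em vs en dash) are normalized
before matching. Quantities support decimals, ranges ("450–460", "450 to
460") and ×10^n notation; conversion is linear and invertible to 1e-12
relative tolerance (property-tested). A dimensioned property with a bare
number and no unit yields nothing — fractional PLQY table cells are the
one sanctioned exception, handled by their special parser.

## Sentence and table parsing

Sentence records come from a finite set of relation templates:
specifier-of-compound ("the delayed lifetime of 2CzPN is 3.2 μs"),
compound-verb-specifier ("2CzPN exhibits a PLQY of 68%"), and
specifier-value appositive ("τd = 3.2 μs"). Implementation-wise, a
specifier match is associated with the first following quantity whose
gap contains only link material (copulas, measurement verbs, equality
symbols, tagged entities); an entity inside an of-phrase between
specifier and value binds as the compound, otherwise the nearest tagged
entity does. Temperature phrases ("at 77 K", "at room temperature") are
captured into the record's extras.

Table cells are serialized by joining the cell's column headers
(outermost first) and the cell text with `🙃🙃🙃🙃` (U+1F643 ×4,
bit-exact). Headers-first order makes specifier lookup a prefix scan.
In the generic cell parser the specifier must occur in a header segment;
the unit comes from the header when declared there, otherwise from the
cell; the first compatible number wins (first-come-first-served); the
compound comes from the row's compound column (headers matching a
configurable list: "Compounds", "Emitters", "Molecule", ...).

Dispatch over a cell runs specific parsers before the generic one —
combined ΔE_ST, shared lifetime, fractional PLQY, then generic — so a
special header pattern is claimed exclusively and a fractional value
0.68 is never misread as 0.68 %. The combined parser splits
`E_S/E_T/ΔE_ST` headers and cells positionally and flags records where
|E_S − E_T − ΔE_ST| > 0.05 eV with a consistency warning. The shared
lifetime parser aligns header fields with cell fields on the header's
own separator (slash or semicolon) and emits only the τ_d slot; when
the header declares a single unit for several slots, that unit applies
to all of them (flagged as an interpretation — per-slot units are the
unambiguous case).

## ThemeCompound model

Raw entity mentions are dominated by solvents, reagents and comparison
compounds. The blocklist is built from a corpus frequency table (each
name counted once per document) with cut-off ⌈f × n_documents⌉ where
f defaults to 7/1200 — the fraction form scales the published absolute
cut-off (7 documents in a 1200-document corpus) to corpora of any size,
with a warning when the cut-off degenerates below 2. Frequency entries
are enriched with case/whitespace/hyphenation variants only; synonym
expansion is out of scope.

Hand-compiled rules block further artefacts. Names: the cell separator,
the current document's DOI string, descriptor morphology ("-based",
"-containing", "-type", "part", "segment"), and substituent-fragment
suffixes "o", "yl", "oxy" ("amino", "phenyl", "methoxy"). The suffix
"ene" is deliberately not in the default list — it would block whole
compound classes (anthracene). These rules are suffix tests, matching
their canonical examples. Labels: date strings (ISO, "Month YYYY",
slashed), electronic-state symbols (S0…S9, T0…T9), unit strings,
numbers followed by % or wt %, and anything longer than 4 characters.
An allowlist overrides every block, which is how well-known emitters
that are ubiquitous in the literature (e.g. DMAC-TRZ) stay retrievable.

Forward-looking resolution: names and labels that pass the blocklist and
rules are registered the moment they are first seen, and entries of
table compound columns are registered automatically. A record without a
compound receives the nearest registered compound within its own element
(absolute token-offset distance, ties toward the preceding mention);
records that cannot be resolved are dropped. The registry is created and
reset inside the per-document extraction call, so outputs for a document
are invariant to whichever documents were processed before it
(tested directly).

## Cleaning

Ranges are applied on standard values: 300 nm < λ_EM < 1600 nm,
0 % ≤ PLQY ≤ 100 %, −1.5 eV < ΔE_ST < 1.5 eV, 100 ns < τ_D < 10 s.
PLQY's bounds are inclusive while the others are exclusive — implemented
exactly as printed in the source rules, inclusive ≤ for PLQY only.
Room-temperature flags on τ_D records become 293 K; when both a flag and
an explicit extracted temperature exist the explicit value wins (the
conservative reading of "conflicts were resolved"); non-physical
temperatures drop the record. Phase and atmosphere are keyword scans of
the record's own sentence or cell ("film", "solution", "neat", ...;
"N2"/"nitrogen"/"degassed" vs "in air"/"aerated"), since only the fields
themselves, not an extraction rule, are prescribed.

The ΔE_ST `is_experimental` flag is tri-state (true/false/unknown) so
that unclassifiable records are representable. The classification
context is section heading ⊕ first paragraph sentence ⊕ record sentence
(the record sentence appears once when it *is* the first sentence);
standalone table records have no context and stay unknown. The default
classifier is a keyword heuristic (DFT/TD-DFT/calculated/computed →
theoretical; measured/onset/fluorescence- or phosphorescence-spectra →
experimental; both or neither → unknown) behind a plugin seam that
accepts trained text classifiers; shipping fine-tuned transformer
weights is out of scope, and the seam is the supported path to higher
accuracy.

## SMILES resolution and structure filters

Name→SMILES resolution is a pluggable backend; the built-in backend is a
lookup table (TSV), which keeps the package self-contained; adapters for
systematic-nomenclature parsers can be registered. Carbon counting and
aromatic-ring counting operate directly on the SMILES string with a
purpose-built tokenizer (organic subset, bracket atoms, two-letter
elements, `%nn` ring labels). An aromatic ring is a ring-closure pair
whose both endpoint atoms are aromatic; closure-pair counting equals the
smallest-set ring count for the usual one-closure-per-ring aromatic
writings, which the oracle fixture set is restricted to (kekulized or
multi-closure exotica are outside the supported set). The removal rule
is conjunctive as phrased — drop iff fewer than 24 carbons AND fewer
than five aromatic rings — with a configuration switch for the
disjunctive reading, since the intent of the "and" is genuinely
ambiguous; the conjunctive default keeps, e.g., long-chain molecules
with few rings.

## Evaluation

True positive requires (i) property with correct value and unit —
compared as exact equality of standard values (relative tolerance 1e-9),
which jointly tests value and unit after conversion; (ii) a correct
compound name or label; (iii) the correct temperature for delayed
lifetime records (absent must match absent). Matching is greedy
one-to-one per document in document order; no matching algorithm is
prescribed by the source methodology (which was manual), and greedy
matching is exact on the noiseless corpora used for the oracle.
Accumulative curves permute the per-record (precision) or per-gold
(recall) outcome labels with a seeded generator; the final point of
every order equals the overall metric, and the default protocol
constants (110 records per property, 40 publications, 5 orders) are
configuration mirroring the published evaluation protocol. Because the
published overall precision (82%) matches neither the simple mean
(80.45) nor exactly the record-weighted mean of the per-property values,
both means are reported.

## Synthetic corpus

The generator emulates exactly the phenomena the extractor targets:
property sentences instantiated from data-driven templates, a property
table with a "Compounds"/"Emitters" column, the three special cell
layouts, abbreviation definitions for a configurable fraction of
compounds (default 0.5), a forward-looking-resolution paragraph where
the compound is named one sentence before its property, and distractor
solvent mentions planted in 75% of documents. Values are drawn from
physically sensible grids (λ_EM 350–800 nm, PLQY 5–95 %, ΔE_ST
0.01–0.40 eV, τ_D 0.5–50 μs, temperatures from {77, 100, 200, 300} K or
a room-temperature phrase), always inside the cleaning ranges, and the
planted truth is the parsed form of the printed string, so float
round-tripping is exact. The default study condition is 20 documents ×
3 facts per property (380 gold records including the special cells) with
blocklist fraction 0.35 — at 20 documents this gives cut-off 7, which
separates solvents (planted in ≈15 documents) from focal compounds
(1 document each); the published 7/1200 fraction is kept as the
package-wide default for realistically sized corpora and the generator
warns when it degenerates. Identical spec + seed give byte-identical
corpora.

What the synthetic corpus does *not* contain: flexible free-form
phrasing, nested multi-layer table headers with merged cells, footnote
indirection, OCR noise, or compound names that defeat the lexicon — so a
perfect score here demonstrates the correctness of the machinery (every
rule firing as specified), not the recall one should expect on real
publisher prose, where learned taggers and richer templates carry the
load.

## Numerical choices

- kJ/mol → eV divisor: 96.485 (CODATA-derived, documented constant).
- Combined-cell consistency tolerance: 0.05 eV.
- Value equality in evaluation: relative 1e-9 on standard values.
- Conversion invertibility: relative 1e-12.
- Zero-denominator metrics are 0 by convention.
- Ties in compound-distance resolution break toward the preceding
  mention; ties in abbreviation length (equal lengths) produce no pair.

## Known limitations

- The default tagger cannot discover out-of-lexicon systematic names
  with unusual morphology; the tagger seam exists for that purpose.
- Ring counting is exact only for closure-per-ring SMILES writings.
- Merged table cells and figure captions are not modelled.
- The keyword `is_experimental` classifier trades recall for
  transparency; contexts mixing experimental and theoretical cues are
  deliberately left unknown.
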