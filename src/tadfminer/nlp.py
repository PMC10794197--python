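"""Sentence segmentation, chemical-entity tagging, abbreviation detection.

Chemical named-entity recognition (CNER) is a pluggable contract
(:class:`CemTagger`): the default implementation combines longest-match
lexicon lookup with morphology heuristics for acronym-style emitter names
("4CzIPN") and systematic-name fragments. Neural taggers can be registered
under a name and swapped in through configuration.

Abbreviation detection implements the bracket/equality rule: an
abbreviation is recognised when a tagged chemical name is immediately
preceded or followed by a shorter entity enclosed in matched brackets or
linked by an equality sign. The classic Schwartz–Hearst letters-in-order
test is retained only for acronym definitions whose long form is *not* a
tagged chemical entity (e.g. "thermally activated delayed fluorescence
(TADF)"), where initials genuinely appear in order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .document import normalize_name
from .errors import ConfigurationError

# Tokens that end with "." but do not close a sentence.
_NON_TERMINAL_ABBREVS = {
    "approx.", "fig.", "figs.", "ref.", "refs.", "eq.", "eqs.", "e.g.", "i.e.",
    "et al.", "al.", "vs.", "ca.", "cf.", "no.", "dr.", "prof.", "r.t.", "wt.",
    "max.", "min.", "temp.", "resp.",
}

_TOKEN_RE = re.compile(
    r"[^\W\d_][\w\-()\[\]{},.'′]*[\w)\]}%]"   # word-like (names, incl. locants)
    r"|\d+(?:\.\d+)?"                          # number
    r"|[^\w\s]",                               # single punctuation/symbol
    re.UNICODE,
)


def _token_class(surface: str) -> str:
    if re.fullmatch(r"\d+(?:\.\d+)?", surface):
        return "number"
    if re.search(r"\w", surface, re.UNICODE):
        return "word"
    if surface in ".,;:!?()[]{}\"'":
        return "punctuation"
    return "symbol"


@dataclass
class Sentence:
    text: str
    start: int = 0  # offset within the parent paragraph
    tokens: list[tuple[str, int, int, str]] = field(default_factory=list)
    cem_spans: list[tuple[int, int, str]] = field(default_factory=list)

    def tokenize(self) -> "Sentence":
        self.tokens = [
            (m.group(0), m.start(), m.end(), _token_class(m.group(0)))
            for m in _TOKEN_RE.finditer(self.text)
        ]
        return self


def segment_sentences(paragraph: str) -> list[Sentence]:
    """Split a paragraph into sentences.

    A sentence boundary is ``.``, ``!`` or ``?`` followed by whitespace,
    unless the period belongs to a known non-terminal abbreviation
    ("Fig.", "approx.", "et al.") or to a decimal number. Concatenating
    the sentence texts with their separators reconstructs the paragraph.
    """
    if not paragraph.strip():
        return []
    boundaries: list[int] = []
    for m in re.finditer(r"[.!?](?=\s)", paragraph):
        i = m.start()
        ch = paragraph[i]
        if ch == ".":
            # decimal point or mid-number: never a boundary
            if i + 1 < len(paragraph) and paragraph[i + 1].isdigit():
                continue
            prev = paragraph[max(0, i - 12): i + 1]
            last_word = re.search(r"\S+$", prev)
            if last_word and last_word.group(0).lower() in _NON_TERMINAL_ABBREVS:
                continue
            two_words = re.search(r"\S+\s+\S+$", prev)
            if two_words and two_words.group(0).lower() in _NON_TERMINAL_ABBREVS:
                continue
        boundaries.append(i + 1)
    sentences: list[Sentence] = []
    prev_end = 0
    for b in boundaries + [len(paragraph)]:
        chunk = paragraph[prev_end:b]
        stripped = chunk.strip()
        if stripped:
            start = prev_end + chunk.index(stripped[0])
            sentences.append(Sentence(text=stripped, start=start).tokenize())
        prev_end = b
    return sentences


# ---------------------------------------------------------------------------
# CEM tagging
# ---------------------------------------------------------------------------

class CemTagger:
    """Contract for chemical-entity taggers: deterministic span producers."""

    name = "base"

    def tag(self, text: str) -> list[tuple[int, int, str]]:  # pragma: no cover
        raise NotImplementedError


# Acronym-style emitter names mix digits, uppercase and lowercase: 4CzIPN,
# 2CzPN, DMAC-TRZ (upper + hyphen + upper also accepted).
_MORPH_ACRONYM_RE = re.compile(
    r"^(?=.*\d)(?=.*[A-Z])(?=.*[a-z])[A-Za-z0-9\-]{3,}$"
    r"|^[A-Z]{2,}[A-Za-z0-9]*-[A-Z][A-Za-z0-9]+$"
)
# Systematic-name fragments: locant lists + brackets, e.g.
# 4,5-bis(carbazol-9-yl)-1,2-dicyanobenzene
_MORPH_SYSTEMATIC_RE = re.compile(
    r"^\d+(?:,\d+)*-[\w()\[\]\-,]*\(\S*\)[\w()\[\]\-,]*$"
)


class LexiconTagger(CemTagger):
    """Default tagger: lexicon longest-match plus morphology heuristics.

    Lexicon names match case-insensitively; short label-like entries
    (≤ 4 characters) match case-sensitively so labels such as "3a" do not
    swallow unrelated text.
    """

    name = "lexicon"

    def __init__(self, lexicon: list[str] | None = None):
        entries = [normalize_name(e) for e in (lexicon or []) if e.strip()]
        self._names = sorted({e for e in entries if len(e) > 4}, key=len, reverse=True)
        self._labels = sorted({e for e in entries if 0 < len(e) <= 4}, key=len, reverse=True)

    @classmethod
    def from_file(cls, path) -> "LexiconTagger":
        with open(path, encoding="utf-8") as fh:
            return cls([line.strip() for line in fh if line.strip()])

    def tag(self, text: str) -> list[tuple[int, int, str]]:
        spans: list[tuple[int, int, str]] = []
        taken = [False] * len(text)

        def claim(s: int, e: int, name: str) -> None:
            if e > s and not any(taken[s:e]):
                spans.append((s, e, name))
                for i in range(s, e):
                    taken[i] = True

        for entry in self._names:
            for m in re.finditer(re.escape(entry), text, re.IGNORECASE):
                if _is_word_bounded(text, m.start(), m.end()):
                    claim(m.start(), m.end(), text[m.start():m.end()])
        for entry in self._labels:
            for m in re.finditer(re.escape(entry), text):
                if _is_word_bounded(text, m.start(), m.end()):
                    claim(m.start(), m.end(), entry)
        # morphology pass on raw chemical-token shapes (digit-initial allowed)
        for m in re.finditer(r"[A-Za-z0-9][A-Za-z0-9\-()\[\]{},]*[A-Za-z0-9)\]]", text):
            surface = m.group(0)
            if _MORPH_ACRONYM_RE.match(surface) or _MORPH_SYSTEMATIC_RE.match(surface):
                claim(m.start(), m.end(), surface)
        return sorted(spans)


def _is_word_bounded(text: str, start: int, end: int) -> bool:
    before = text[start - 1] if start > 0 else " "
    after = text[end] if end < len(text) else " "
    return not (before.isalnum() or after.isalnum())


_TAGGER_REGISTRY: dict[str, type[CemTagger]] = {"lexicon": LexiconTagger}


def register_tagger(name: str, cls: type[CemTagger]) -> None:
    _TAGGER_REGISTRY[name] = cls


def get_tagger(name: str, **kwargs) -> CemTagger:
    if name not in _TAGGER_REGISTRY:
        raise ConfigurationError(
            f"unknown tagger {name!r}; registered: {sorted(_TAGGER_REGISTRY)}"
        )
    return _TAGGER_REGISTRY[name](**kwargs)


def tag_cems(sentence: Sentence, tagger: CemTagger) -> Sentence:
    """Populate ``cem_spans`` using the given tagger (non-overlapping, sorted)."""
    sentence.cem_spans = sorted(tagger.tag(sentence.text))
    return sentence


# ---------------------------------------------------------------------------
# Abbreviation detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AbbreviationPair:
    short_form: str
    long_form: str
    evidence: str  # brackets | equality | letters-in-order


_BRACKETS = {"(": ")", "[": "]", "{": "}"}
_EQUALITY = ("=", ":")


def _letters_in_order(short: str, long: str) -> bool:
    """Schwartz–Hearst style check: abbreviation letters appear in order."""
    letters = [c.lower() for c in short if c.isalnum()]
    if not letters:
        return False
    pos = 0
    low = long.lower()
    for ch in letters:
        pos = low.find(ch, pos)
        if pos < 0:
            return False
        pos += 1
    return True


def _shorter(a: str, b: str) -> bool:
    return len(normalize_name(a)) < len(normalize_name(b))


def detect_abbreviations(sentence: Sentence) -> list[AbbreviationPair]:
    """Detect short↔long name definitions within a tagged sentence.

    For each CEM span, a shorter entity in matched brackets immediately
    after (or before) the span, or linked by an equality sign, defines an
    abbreviation. Equal-length candidates produce no pair. Non-CEM acronym
    definitions fall back to the letters-in-order rule.
    """
    text = sentence.text
    pairs: list[AbbreviationPair] = []
    seen: set[tuple[str, str]] = set()

    def emit(short: str, long: str, evidence: str) -> None:
        short, long = normalize_name(short), normalize_name(long)
        if len(short) < len(long) and (short, long) not in seen:
            seen.add((short, long))
            pairs.append(AbbreviationPair(short, long, evidence))

    cem_span_set = {(s, e) for s, e, _ in sentence.cem_spans}
    for start, end, name in sentence.cem_spans:
        # CEM followed by "(SHORT)" / "[SHORT]" / "{SHORT}"
        m = re.match(r"\s*([(\[{])\s*([^()\[\]{}]+?)\s*([)\]}])", text[end:])
        if m and _BRACKETS[m.group(1)] == m.group(3):
            candidate = m.group(2)
            if _shorter(candidate, name):
                emit(candidate, name, "brackets")
            elif _shorter(name, candidate):
                emit(name, candidate, "brackets")
        # equality signs link either direction: SHORT = LONG or LONG = SHORT
        pre = text[:start].rstrip()
        if pre and pre[-1] in _EQUALITY:
            left = pre[:-1].strip()
            m2 = re.search(r"([^\s=:]+)$", left)
            if m2:
                other = m2.group(1)
                if _shorter(other, name):
                    emit(other, name, "equality")
                elif _shorter(name, other):
                    emit(name, other, "equality")
        post = text[end:].lstrip()
        if post and post[0] in _EQUALITY:
            rest = post[1:].strip()
            m3 = re.match(r"([^\s,;]+(?:\s[^\s,;]+)*?)(?:[.,;]|$)", rest)
            if m3:
                other = m3.group(1).rstrip(".")
                if _shorter(other, name):
                    emit(other, name, "equality")
                elif _shorter(name, other):
                    emit(name, other, "equality")

    # Letters-in-order fallback for non-CEM definitions: "long words (ACRO)"
    for m in re.finditer(r"((?:\w[\w\-]*\s+){1,8}\w[\w\-]*)\s*\(([^()]{1,12})\)", text):
        long, short = m.group(1).strip(), m.group(2).strip()
        span = (m.start(1), m.start(1) + len(m.group(1)))
        if span in cem_span_set:
            continue  # CEM long forms are handled by the bracket rule
        if _shorter(short, long) and _letters_in_order(short, long):
            emit(short, long, "letters-in-order")
    return pairs


class AbbreviationRegistry:
    """Document-wide short↔long substitution table."""

    def __init__(self) -> None:
        self.short_to_long: dict[str, str] = {}
        self.long_to_short: dict[str, str] = {}

    def add(self, pair: AbbreviationPair) -> None:
        self.short_to_long.setdefault(pair.short_form, pair.long_form)
        self.long_to_short.setdefault(pair.long_form, pair.short_form)

    def aliases(self, name: str) -> set[str]:
        name = normalize_name(name)
        out = {name}
        if name in self.short_to_long:
            out.add(self.short_to_long[name])
        if name in self.long_to_short:
            out.add(self.long_to_short[name])
        return out
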