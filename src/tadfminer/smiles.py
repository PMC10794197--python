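"""Name→SMILES resolution and SMILES-based structure filters.

Resolution backends are pluggable; the built-in backend is a lookup
table (TSV of name → SMILES) so the package works without external
name-parsing services. Adapters for systematic-nomenclature parsers can
be registered under a name.

The structure filters count carbons and aromatic rings *directly on the
SMILES string* with a purpose-built tokenizer: organic-subset atoms,
bracket atoms, and ring-closure digits (including ``%nn``) are
recognised; an aromatic ring is a ring-closure pair whose both endpoint
atoms are aromatic. Closure-pair counting equals the smallest ring count
for the common one-closure-per-ring writing of fused aromatics; exotic
multi-closure writings are outside the supported fixture set. Molecules
with fewer than 24 carbons *and* fewer than five aromatic rings are
removed (conjunctive reading of the cleaning rule; a switch selects the
disjunctive variant).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

from .document import normalize_name
from .errors import ConfigurationError, SmilesParseError

MIN_CARBONS = 24
MIN_AROMATIC_RINGS = 5


@dataclass(frozen=True)
class SmilesString:
    text: str
    source: str = "backend"  # backend | lookup

    def __post_init__(self) -> None:
        if not self.text:
            raise SmilesParseError("empty SMILES")


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------

class LookupBackend:
    """TSV-backed name→SMILES table; the zero-dependency default."""

    name = "lookup"

    def __init__(self, table: dict[str, str] | None = None):
        if table is None:  # default to the bundled fixture table
            from importlib import resources
            text = resources.files("tadfminer.data").joinpath(
                "name_smiles.tsv").read_text(encoding="utf-8")
            table = {}
            for line in text.splitlines():
                if line.strip() and not line.startswith("#"):
                    name, smi = line.split("\t", 1)
                    table[name.strip()] = smi.strip()
        self._table = {normalize_name(k).lower(): v for k, v in table.items()}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LookupBackend":
        table: dict[str, str] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            name, smiles = line.split("\t", 1)
            table[name.strip()] = smiles.strip()
        return cls(table)

    def resolve(self, name: str) -> str | None:
        return self._table.get(normalize_name(name).lower())


_BACKEND_REGISTRY: dict[str, type] = {"lookup": LookupBackend}


def register_backend(name: str, cls: type) -> None:
    _BACKEND_REGISTRY[name] = cls


def get_backend(name: str, **kwargs):
    if name not in _BACKEND_REGISTRY:
        raise ConfigurationError(
            f"unknown SMILES backend {name!r}; registered: {sorted(_BACKEND_REGISTRY)}"
        )
    return _BACKEND_REGISTRY[name](**kwargs)


def name_to_smiles(name: str, backend) -> SmilesString | None:
    """Resolve a chemical name to SMILES; ``None`` for unparseable names."""
    if backend is None:
        raise ConfigurationError("no SMILES backend configured")
    resolved = backend.resolve(name)
    if resolved is None:
        return None
    return SmilesString(resolved, source=getattr(backend, "name", "backend"))


# ---------------------------------------------------------------------------
# SMILES tokenizer (enough for counting, not full semantics)
# ---------------------------------------------------------------------------

# two-letter organic-subset elements must be tried before one-letter ones
_ORGANIC = ("Cl", "Br", "B", "C", "N", "O", "S", "P", "F", "I",
            "b", "c", "n", "o", "s", "p")

_BRACKET_RE = re.compile(
    r"\[(?P<isotope>\d+)?(?P<element>[A-Z][a-z]?|[a-z]{1,2}|\*)"
    r"(?P<rest>[^\]]*)\]"
)

_TOKEN_RE = re.compile(
    r"\[[^\]]*\]"                    # bracket atom
    r"|Cl|Br"                        # two-letter organic subset
    r"|[BCNOSPFI]|[bcnosp]"          # one-letter organic subset
    r"|%\d{2}|\d"                    # ring-closure labels
    r"|[-=#$:/\\().+]"               # bonds, branches, charge in error
)


@dataclass
class _Atom:
    element: str
    aromatic: bool


def _tokenize(smiles: str) -> list[tuple[str, str]]:
    """Yield (kind, token) pairs; kind ∈ {atom, ring, other}."""
    out: list[tuple[str, str]] = []
    pos = 0
    while pos < len(smiles):
        m = _TOKEN_RE.match(smiles, pos)
        if not m:
            raise SmilesParseError(
                f"unrecognised SMILES syntax at position {pos}: {smiles[pos:pos+8]!r}"
            )
        tok = m.group(0)
        if tok.startswith("["):
            if not tok.endswith("]"):
                raise SmilesParseError(f"unclosed bracket atom in {smiles!r}")
            out.append(("atom", tok))
        elif tok in _ORGANIC:
            out.append(("atom", tok))
        elif tok[0] == "%" or tok.isdigit():
            out.append(("ring", tok))
        else:
            out.append(("other", tok))
        pos = m.end()
    depth = 0
    for kind, tok in out:
        if tok == "(":
            depth += 1
        elif tok == ")":
            depth -= 1
            if depth < 0:
                raise SmilesParseError(f"unbalanced parentheses in {smiles!r}")
    if depth != 0:
        raise SmilesParseError(f"unbalanced parentheses in {smiles!r}")
    return out


def _parse_atoms(smiles: str) -> tuple[list[_Atom], list[tuple[int, int]]]:
    """Return atoms and ring-closure atom-index pairs."""
    atoms: list[_Atom] = []
    open_rings: dict[str, int] = {}
    pairs: list[tuple[int, int]] = []
    current = -1
    for kind, tok in _tokenize(smiles):
        if kind == "atom":
            if tok.startswith("["):
                m = _BRACKET_RE.match(tok)
                if not m:
                    raise SmilesParseError(f"malformed bracket atom {tok!r}")
                element = m.group("element")
            else:
                element = tok
            aromatic = element[0].islower() and element != "*"
            atoms.append(_Atom(element=element.capitalize() if aromatic else element,
                               aromatic=aromatic))
            current = len(atoms) - 1
        elif kind == "ring":
            if current < 0:
                raise SmilesParseError(f"ring closure before any atom in {smiles!r}")
            label = tok.lstrip("%")
            if label in open_rings:
                pairs.append((open_rings.pop(label), current))
            else:
                open_rings[label] = current
    if open_rings:
        raise SmilesParseError(
            f"unpaired ring-closure digit(s) {sorted(open_rings)} in {smiles!r}"
        )
    return atoms, pairs


def count_carbons(smiles: SmilesString | str) -> int:
    """Number of carbon atoms (aromatic ``c`` and aliphatic ``C``, including
    bracket atoms; two-letter elements like Cl are not miscounted)."""
    text = smiles.text if isinstance(smiles, SmilesString) else smiles
    atoms, _ = _parse_atoms(text)
    return sum(1 for a in atoms if a.element == "C")


def count_aromatic_rings(smiles: SmilesString | str) -> int:
    """Number of ring-closure pairs whose both endpoint atoms are aromatic."""
    text = smiles.text if isinstance(smiles, SmilesString) else smiles
    atoms, pairs = _parse_atoms(text)
    return sum(1 for i, j in pairs if atoms[i].aromatic and atoms[j].aromatic)


def passes_structure_filter(smiles: SmilesString | str,
                            conjunctive: bool = True) -> bool:
    """Keep/drop verdict for the small-molecule removal rule.

    Drop iff carbon count < 24 AND aromatic-ring count < 5 (conjunctive,
    as the cleaning rule is phrased); ``conjunctive=False`` selects the
    stricter OR variant.
    """
    carbons = count_carbons(smiles)
    rings = count_aromatic_rings(smiles)
    if conjunctive:
        drop = carbons < MIN_CARBONS and rings < MIN_AROMATIC_RINGS
    else:
        drop = carbons < MIN_CARBONS or rings < MIN_AROMATIC_RINGS
    return not drop


def attach_smiles(records: list, backend,
                  conjunctive: bool = True) -> list:
    """Build the subsidiary record subset: resolve names, filter structures.

    Records whose compound has no resolvable name are excluded; resolved
    molecules failing the structure filter are excluded as well.
    """
    subsidiary = []
    for record in records:
        if not record.compound or not record.compound.names:
            continue
        smiles = None
        for name in record.compound.names:
            smiles = name_to_smiles(name, backend)
            if smiles is not None:
                break
        if smiles is None:
            continue
        if not passes_structure_filter(smiles, conjunctive=conjunctive):
            continue
        record.extra["smiles"] = smiles.text
        subsidiary.append(record)
    return subsidiary
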