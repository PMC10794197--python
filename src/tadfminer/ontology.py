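"""Property ontology: models, specifiers, unit grammars, quantity parsing.

Four photophysical properties are modelled, each with a fixed standard
unit:

====================  =======================  =============
property              dimension                standard unit
====================  =======================  =============
``lambda_em``         length                   nm
``plqy``              dimensionless fraction   %
``delta_e_st``        energy                   eV
``tau_d``             time                     μs
====================  =======================  =============

Specifier surface forms (λem, ΦPL, ΔEST, τd and their common variants)
are configuration, seeded from ``data/property_models.yaml``; the unit
grammar is generated from the dimension (SI prefixes for time and length,
plus kJ/mol for energy with 1 eV = 96.485 kJ/mol). Homoglyphs that vary
across publisher markup (micro sign vs Greek mu, typographic dashes) are
normalized before matching.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .errors import ConfigurationError, UnitError

PROPERTY_IDS = ("lambda_em", "plqy", "delta_e_st", "tau_d")

KJ_PER_MOL_PER_EV = 96.485  # CODATA: 1 eV ≙ 96.485 kJ/mol

# publisher-markup homoglyphs → canonical forms
_HOMOGLYPHS = {
    "µ": "μ",  # micro sign → Greek mu
    "−": "-",  # minus sign → hyphen-minus
    "—": "–",  # em dash → en dash (range separator)
    "Ф": "Φ",  # Cyrillic Ef → Greek Phi
}


def normalize_text(text: str) -> str:
    for src, dst in _HOMOGLYPHS.items():
        text = text.replace(src, dst)
    return text


@dataclass
class PropertyModel:
    property_id: str
    specifiers: list[str]
    dimension: str  # length | dimensionless-fraction | energy | time
    allowed_units: dict[str, float]  # unit symbol -> factor to standard
    standard_unit: str
    extra_fields: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.specifiers:
            raise ConfigurationError(
                f"property {self.property_id!r} has an empty specifier list"
            )
        if any(f <= 0 for f in self.allowed_units.values()):
            raise ConfigurationError(
                f"property {self.property_id!r} has a non-positive unit factor"
            )


@dataclass
class Quantity:
    values: list[float]
    unit: str
    raw_text: str = ""

    def __post_init__(self) -> None:
        if len(self.values) == 2:
            self.values = sorted(self.values)


# ---------------------------------------------------------------------------
# Unit grammars
# ---------------------------------------------------------------------------

_SI_TIME = {"ps": 1e-6, "ns": 1e-3, "μs": 1.0, "ms": 1e3, "s": 1e6}
_SI_LENGTH = {"nm": 1.0, "μm": 1e3, "mm": 1e6, "cm": 1e7, "m": 1e9}
_ENERGY = {"eV": 1.0, "meV": 1e-3, "kJ/mol": 1.0 / KJ_PER_MOL_PER_EV}
_FRACTION = {"%": 1.0}


def units_for_dimension(dimension: str) -> dict[str, float]:
    table = {
        "time": _SI_TIME,
        "length": _SI_LENGTH,
        "energy": _ENERGY,
        "dimensionless-fraction": _FRACTION,
    }
    if dimension not in table:
        raise ConfigurationError(f"unknown dimension {dimension!r}")
    return dict(table[dimension])


def load_default_models(path=None) -> dict[str, PropertyModel]:
    """Load the four property models from the bundled (or given) YAML."""
    if path is None:
        text = resources.files("tadfminer.data").joinpath("property_models.yaml").read_text(
            encoding="utf-8"
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    models: dict[str, PropertyModel] = {}
    for pid, cfg in raw.items():
        units = units_for_dimension(cfg["dimension"])
        units.update(cfg.get("extra_units", {}))
        models[pid] = PropertyModel(
            property_id=pid,
            specifiers=[normalize_text(s) for s in cfg["specifiers"]],
            dimension=cfg["dimension"],
            allowed_units=units,
            standard_unit=normalize_text(cfg["standard_unit"]),
            extra_fields=cfg.get("extra_fields", []),
        )
    return models


# ---------------------------------------------------------------------------
# Quantity grammar
# ---------------------------------------------------------------------------

_NUM = r"[+-]?\d+(?:\.\d+)?(?:\s*[×x]\s*10(?:\^|\*\*)?[+-]?\d+)?"
_RANGE_SEP = r"\s*(?:–|-|to)\s*"


def _num_to_float(s: str) -> float:
    s = s.replace(" ", "")
    m = re.match(r"([+-]?\d+(?:\.\d+)?)(?:[×x]10(?:\^|\*\*)?([+-]?\d+))?$", s)
    if not m:
        raise ValueError(f"not a number: {s!r}")
    base = float(m.group(1))
    if m.group(2):
        base *= 10.0 ** int(m.group(2))
    return base


def _unit_pattern(model: PropertyModel) -> str:
    units = sorted(model.allowed_units, key=len, reverse=True)
    return "|".join(re.escape(u) for u in units)


def quantity_regex(model: PropertyModel) -> re.Pattern:
    """Regex matching a scalar or range with one of the model's units."""
    up = _unit_pattern(model)
    return re.compile(
        rf"(?P<v1>{_NUM})(?:{_RANGE_SEP}(?P<v2>{_NUM}))?\s*(?P<unit>{up})(?![A-Za-z])"
    )


def parse_quantity(text: str, model: PropertyModel) -> Quantity | None:
    """Extract the first number/range with a unit compatible with the model.

    Returns ``None`` when no dimensioned match exists; unitless numbers are
    deliberately not accepted here (fractional PLQY table cells are handled
    by their special parser).
    """
    text = normalize_text(text)
    m = quantity_regex(model).search(text)
    if not m:
        return None
    values = [_num_to_float(m.group("v1"))]
    if m.group("v2"):
        values.append(_num_to_float(m.group("v2")))
    return Quantity(values=values, unit=m.group("unit"), raw_text=m.group(0))


def compile_parse_expressions(model: PropertyModel) -> list[re.Pattern]:
    """Auto-generate sentence patterns "<specifier> <link words> <value> <unit>".

    Link words cover copulas, measurement phrasing, and symbolic links
    (=, :, ~); the value/unit grammar comes from :func:`quantity_regex`.
    """
    if not model.specifiers:
        raise ConfigurationError("cannot compile patterns for empty specifier list")
    spec_alt = "|".join(
        re.escape(normalize_text(s)) for s in sorted(model.specifiers, key=len, reverse=True)
    )
    link = (
        r"(?:\s*[=:~]\s*|\s+(?:of|for|is|was|were|at|being|be|to|as|around|about|"
        r"approximately|measured|found|determined|estimated|peaking|centred|centered|"
        r"reaches?|reached)\b)*\s*"
    )
    up = _unit_pattern(model)
    qty = rf"(?P<v1>{_NUM})(?:{_RANGE_SEP}(?P<v2>{_NUM}))?\s*(?P<unit>{up})(?![A-Za-z])"
    pattern = re.compile(
        rf"(?P<specifier>{spec_alt})(?P<link>{link})(?P<quantity>{qty})",
        re.IGNORECASE,
    )
    return [pattern]


def to_standard(q: Quantity, model: PropertyModel) -> list[float]:
    """Convert a quantity's values to the model's standard unit."""
    unit = normalize_text(q.unit)
    if unit not in model.allowed_units:
        raise UnitError(unit, model.property_id)
    factor = model.allowed_units[unit]
    return [v * factor for v in q.values]


def from_standard(values: list[float], unit: str, model: PropertyModel) -> list[float]:
    """Inverse of :func:`to_standard` (used by round-trip checks)."""
    unit = normalize_text(unit)
    if unit not in model.allowed_units:
        raise UnitError(unit, model.property_id)
    factor = model.allowed_units[unit]
    return [v / factor for v in values]
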