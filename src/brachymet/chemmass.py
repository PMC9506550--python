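"""Exact-mass arithmetic for small-molecule annotation.

Elemental formulas are restricted to the CHNOSP elements that occur in
plant phenylpropanoid/flavonoid chemistry.  All masses are monoisotopic
(most-abundant isotope, IUPAC values); ion m/z uses the proton mass so
that the electron-mass correction is folded in ([M+H]+ adds a proton,
not a hydrogen atom).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ElementalFormula",
    "IonSpecies",
    "MassError",
    "NeutralLossEntry",
    "FormulaError",
    "PROTON_MASS",
    "MONOISOTOPIC",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "ppm_error",
    "match_mz",
    "neutral_loss_table",
]

#: Monoisotopic masses of the most abundant isotope, Da (IUPAC).
MONOISOTOPIC: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}

#: Mass of the proton, Da (i.e. H atom minus one electron).
PROTON_MASS = 1.00727646677

_HILL_TAIL = sorted(set(MONOISOTOPIC) - {"C", "H"})
_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unparsable or chemically invalid formula strings."""


@dataclass(frozen=True)
class ElementalFormula:
    """Parsed chemical formula as element -> count."""

    counts: Mapping[str, int]

    def __post_init__(self):
        counts = {e: int(n) for e, n in self.counts.items() if n}
        if not counts:
            raise FormulaError("formula must contain at least one atom")
        for element, n in counts.items():
            if element not in MONOISOTOPIC:
                raise FormulaError(f"unknown element symbol {element!r}")
            if n < 0:
                raise FormulaError(f"negative count for {element}")
        object.__setattr__(self, "counts", counts)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def hill(self) -> str:
        """Canonical Hill-order text form (C, H, then alphabetical)."""
        parts = []
        for element in ("C", "H", *_HILL_TAIL):
            n = self[element]
            if n:
                parts.append(element if n == 1 else f"{element}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for element, n in other.counts.items():
            merged[element] = merged.get(element, 0) + n
        return ElementalFormula(merged)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


@dataclass(frozen=True)
class IonSpecies:
    """Singly charged protonated/deprotonated molecular ion."""

    kind: str  # "[M+H]+" or "[M-H]-"

    _KINDS = ("[M+H]+", "[M-H]-")

    def __post_init__(self):
        kind = self.kind.replace("−", "-")  # tolerate typeset minus
        if kind not in self._KINDS:
            raise ValueError(f"unsupported ion species {self.kind!r}")
        object.__setattr__(self, "kind", kind)

    @property
    def charge_sign(self) -> int:
        return 1 if self.kind == "[M+H]+" else -1

    @property
    def polarity(self) -> str:
        return "positive" if self.charge_sign > 0 else "negative"


POSITIVE = IonSpecies("[M+H]+")
NEGATIVE = IonSpecies("[M-H]-")


@dataclass(frozen=True)
class MassError:
    measured_mz: float
    theoretical_mz: float

    @property
    def delta_ppm(self) -> float:
        return ppm_error(self.measured_mz, self.theoretical_mz)


def parse_formula(text: str) -> ElementalFormula:
    """Parse a formula string such as ``C17H20O9`` into element counts.

    Repeated element symbols accumulate (``CH3CH3`` == ``C2H6``).
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    s = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if not m or not m.group(0):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        element, digits = m.group(1), m.group(2)
        if element not in MONOISOTOPIC:
            raise FormulaError(f"unknown element symbol {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ElementalFormula(counts)


def monoisotopic_mass(f: ElementalFormula | str) -> float:
    """Neutral monoisotopic mass in Da."""
    if isinstance(f, str):
        f = parse_formula(f)
    return sum(MONOISOTOPIC[e] * n for e, n in f.counts.items())


def ion_mz(f: ElementalFormula | str, ion: IonSpecies | str) -> float:
    """m/z of the singly charged ion of the neutral formula ``f``."""
    if isinstance(f, str):
        f = parse_formula(f)
    if isinstance(ion, str):
        ion = IonSpecies(ion)
    if ion.charge_sign < 0 and f["H"] < 1:
        raise ValueError(f"[M-H]- requested for hydrogen-free formula {f.hill()}")
    return monoisotopic_mass(f) + ion.charge_sign * PROTON_MASS


def ppm_error(measured: float, theoretical: float) -> float:
    """Signed relative error in parts per million.

    The theoretical (calculated) mass is the denominator.
    """
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (measured - theoretical) / theoretical * 1e6


def match_mz(
    observed: float,
    candidates: Iterable[tuple],
    tol_ppm: float = 5.0,
) -> list:
    """All candidates whose ion m/z lies within ``tol_ppm`` of ``observed``.

    ``candidates`` yields ``(record, ion_mz_value)`` pairs where ``record``
    has a ``name`` attribute (or is itself used for tie-breaking).  Returns
    ``(record, MassError)`` pairs sorted by |delta ppm| then name.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    hits = []
    for record, theo in candidates:
        err = MassError(observed, float(theo))
        if abs(err.delta_ppm) <= tol_ppm:
            hits.append((record, err))
    hits.sort(key=lambda h: (abs(h[1].delta_ppm), getattr(h[0], "name", str(h[0]))))
    return hits


@dataclass(frozen=True)
class NeutralLossEntry:
    """One diagnostic neutral loss used by the fragmentation rule layer."""

    name: str
    formula: ElementalFormula
    context: str = ""
    exact_mass: float = field(init=False)
    nominal_mass: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "exact_mass", monoisotopic_mass(self.formula))
        object.__setattr__(self, "nominal_mass", round(self.exact_mass))


# Diagnostic neutral losses / residues of the phenylpropanoid rule layer.
# The exact masses are formula-derived; where the source literature prints a
# slightly different measured figure (e.g. 118.0278 for threonate-H2O vs the
# formula-derived 118.0266) the formula value is stored.
_NEUTRAL_LOSSES: Sequence[tuple[str, str, str]] = (
    ("water", "H2O", "generic"),
    ("CO2", "CO2", "carboxylate"),
    ("dehydrated-hexose", "C6H10O5", "O-hexoside"),
    ("dehydrated-deoxyhexose", "C6H10O4", "O-deoxyhexoside"),
    ("dehydrated-pentose", "C5H8O4", "O-pentoside"),
    ("hexose", "C6H12O6", "2''-O-glycoside"),
    ("deoxyhexose", "C6H12O5", "external deoxyhexose (1->2)"),
    ("hexosyl-deoxyhexose", "C12H20O9", "O-hexosyldeoxyhexoside"),
    ("threonate-H2O", "C4H6O4", "hydroxycinnamoyl threonate ester"),
    ("putrescine", "C4H12N2", "polyamine amide"),
    ("agmatine", "C5H14N4", "polyamine amide"),
    ("spermidine", "C7H19N3", "polyamine amide"),
    ("ammonia", "NH3", "amine"),
    ("formic-acid", "CH2O2", "amino acid"),
    ("caffeoyl-H2O", "C9H6O3", "hydroxycinnamoyl"),
    ("coumaroyl-H2O", "C9H6O2", "hydroxycinnamoyl"),
    ("feruloyl-H2O", "C10H8O3", "hydroxycinnamoyl"),
    ("sinapoyl-H2O", "C11H10O4", "acylated flavonoid"),
    ("sinapoyl-hexose", "C17H20O9", "acylated flavonoid"),
    ("RDA-catechin", "C8H8O3", "retro-Diels-Alder, (epi)catechin"),
    ("RDA-gallocatechin", "C8H8O4", "retro-Diels-Alder, (epi)gallocatechin"),
    ("HRF", "C6H6O3", "heterocyclic ring fission"),
    ("gallate-related", "C7H4O4", "galloylated flavan-3-ol"),
    ("hydroxybenzoate-related", "C7H4O2", "hydroxybenzoylated flavan-3-ol"),
)


def neutral_loss_table() -> dict[str, NeutralLossEntry]:
    """The bundled diagnostic neutral-loss dictionary, keyed by name."""
    table = {}
    for name, formula, context in _NEUTRAL_LOSSES:
        table[name] = NeutralLossEntry(name, parse_formula(formula), context)
    return table
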