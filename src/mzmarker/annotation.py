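"""Mass arithmetic for metabolite annotation.

Monoisotopic masses from molecular formulae, positive-mode adduct m/z
values, signed ppm mass errors, and candidate matching against a local
compound table at a ppm tolerance. All arithmetic is electron-mass
aware: a singly protonated/cationized species weighs the neutral plus
the charge carrier minus one electron.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .exceptions import ConfigError, ParseError

#: Mass of the electron in Da (CODATA).
ELECTRON_MASS = 0.000548579909

#: Most-abundant-isotope atomic masses in Da (AME/IUPAC), extensible.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse ``formula`` into element -> count, e.g. ``"C9H13N5O3"``.

    An empty string parses to an empty composition. Unknown elements or
    malformed text raise :class:`ConfigError`.
    """
    composition: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ConfigError(f"malformed formula {formula!r} at position {pos}")
        element, count = match.group(1), match.group(2)
        if element not in ELEMENT_MASSES:
            raise ConfigError(f"unknown element {element!r} in formula {formula!r}")
        composition[element] = composition.get(element, 0) + (int(count) if count else 1)
        pos = match.end()
    if pos != len(formula):
        raise ConfigError(f"malformed formula {formula!r} at position {pos}")
    return composition


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic (most-abundant-isotope) mass of ``formula`` in Da."""
    return sum(ELEMENT_MASSES[el] * n for el, n in parse_formula(formula).items())


@dataclass(frozen=True)
class AdductSpec:
    """A positive-mode adduct: observed m/z = neutral mass + ``mass_delta``.

    ``mass_delta`` includes the loss of one electron per positive charge.
    """

    name: str
    mass_delta: float
    charge: int = 1


def _delta(formula_gain: str, formula_loss: str = "") -> float:
    gain = monoisotopic_mass(formula_gain) if formula_gain else 0.0
    loss = monoisotopic_mass(formula_loss) if formula_loss else 0.0
    return gain - loss - ELECTRON_MASS


#: Singly charged positive-mode adducts used for annotation.
ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", _delta("H")),
    "[M+Na]+": AdductSpec("[M+Na]+", _delta("Na")),
    "[M+K]+": AdductSpec("[M+K]+", _delta("K")),
    "[M+NH4]+": AdductSpec("[M+NH4]+", _delta("NH4")),
    "[M+H-2H2O]+": AdductSpec("[M+H-2H2O]+", _delta("H", "H4O2")),
}


def adduct_mz(neutral_mass: float, adduct: AdductSpec | str) -> float:
    """m/z of ``adduct`` formed from a neutral of ``neutral_mass`` Da.

    Returned at full precision; round to 4 decimals for display.
    """
    if neutral_mass <= 0:
        raise ConfigError(f"neutral mass must be positive, got {neutral_mass}")
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise ConfigError(f"unknown adduct {adduct!r}") from None
    return neutral_mass + adduct.mass_delta


def ppm_error(measured: float, theoretical: float) -> float:
    """Signed relative mass error, (measured - theoretical)/theoretical * 1e6."""
    if theoretical <= 0:
        raise ConfigError(f"theoretical mass must be positive, got {theoretical}")
    return (measured - theoretical) / theoretical * 1e6


def truncate_ppm(value: float, decimals: int = 2) -> float:
    """Truncate a ppm value toward zero at ``decimals`` places.

    This is the display convention used for reported mass errors
    (1.798 -> 1.79, -1.900 -> -1.90); internal comparisons always use
    the full-precision value.
    """
    scale = 10**decimals
    return math.trunc(value * scale) / scale


@dataclass(frozen=True)
class MassMatch:
    """One (compound, adduct) candidate for a measured m/z."""

    query_mz: float
    compound: str
    formula: str
    adduct: AdductSpec
    theoretical_mz: float
    ppm_error: float
    within_tolerance: bool


def load_compound_table(path: str | Path | None = None) -> list[tuple[str, str]]:
    """Load a compound table of (name, formula) rows from CSV.

    With no ``path``, the packaged table of reference plasma metabolites
    is used. Rows must have non-empty ``name`` and parseable ``formula``.
    """
    if path is None:
        source = resources.files("mzmarker").joinpath("data/compounds.csv")
        text = source.read_text(encoding="utf-8")
        lines = text.splitlines()
    else:
        lines = Path(path).read_text(encoding="utf-8").splitlines()
    reader = csv.DictReader(lines)
    if reader.fieldnames is None or not {"name", "formula"} <= set(reader.fieldnames):
        raise ParseError("compound table must have a 'name,formula' header")
    table: list[tuple[str, str]] = []
    for i, row in enumerate(reader, start=2):
        name = (row.get("name") or "").strip()
        formula = (row.get("formula") or "").strip()
        if not name or not formula:
            raise ParseError(f"compound table row {i}: missing name or formula")
        try:
            parse_formula(formula)
        except ConfigError as exc:
            raise ParseError(f"compound table row {i} ({name}): {exc}") from exc
        table.append((name, formula))
    return table


def match_candidates(
    query_mz: float,
    compound_table: Iterable[tuple[str, str]],
    adduct_set: Sequence[AdductSpec | str] | None = None,
    tolerance_ppm: float = 2.0,
) -> list[MassMatch]:
    """All (compound, adduct) pairs within ``tolerance_ppm`` of ``query_mz``.

    Theoretical masses are carried at the 4-decimal reporting precision
    and ppm errors are computed against them, keeping reported match
    tables self-consistent. Results are sorted by absolute ppm error,
    best first; an empty list means no candidate annotates the ion at
    this mass accuracy.
    """
    if tolerance_ppm <= 0:
        raise ConfigError(f"tolerance_ppm must be positive, got {tolerance_ppm}")
    adducts = [
        ADDUCTS[a] if isinstance(a, str) else a
        for a in (adduct_set if adduct_set is not None else ADDUCTS.values())
    ]
    matches: list[MassMatch] = []
    for name, formula in compound_table:
        neutral = monoisotopic_mass(formula)
        for adduct in adducts:
            theo = round(adduct_mz(neutral, adduct), 4)
            err = ppm_error(query_mz, theo)
            if abs(err) < tolerance_ppm:
                matches.append(
                    MassMatch(query_mz, name, formula, adduct, theo, err, True)
                )
    matches.sort(key=lambda m: abs(m.ppm_error))
    return matches
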