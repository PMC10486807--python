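"""Molecular-formula arithmetic and m/z computation for negative-mode ions.

All species in scope are CHO compounds observed as singly deprotonated
[M - H]- anions, so the mass bookkeeping reduces to element-count maps,
elementwise addition/subtraction (a neutral loss is a subtraction), and two
mass scales: integer nominal masses (C=12, H=1, O=16) matching the values
an analyst reads off a printed spectrum, and IUPAC monoisotopic masses for
high-resolution work.  The element table is shipped as package data
(``data/elements.json``) so further elements can be added without touching
code.
"""

from __future__ import annotations

import json
import re
from collections.abc import Iterator, Mapping
from dataclasses import dataclass
from importlib import resources

__all__ = [
    "FormulaError",
    "MolecularFormula",
    "IonMass",
    "PROTON_MASS",
    "parse_formula",
    "nominal_mass",
    "monoisotopic_mass",
    "mz_deprotonated",
]

#: Mass of a proton in Da.  Deprotonation in negative ESI removes H+ and
#: leaves the electron with the anion, so m/z([M - H]-) = M - PROTON_MASS.
PROTON_MASS = 1.00727646

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed formula string or infeasible element arithmetic."""


def _load_element_masses() -> dict[str, dict[str, float]]:
    with resources.files("flavanms.data").joinpath("elements.json").open() as fh:
        return json.load(fh)


ELEMENT_MASSES: dict[str, dict[str, float]] = _load_element_masses()

# Hill order: carbon, then hydrogen, then the rest alphabetically.
_HILL_ORDER = {"C": 0, "H": 1}


class MolecularFormula(Mapping):
    """Immutable element -> count map with elementwise arithmetic.

    Zero counts are never stored, so equality and hashing are canonical.
    Subtraction raises :class:`FormulaError` when any count would go
    negative — the signal that a neutral-loss rule cannot apply.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None):
        clean: dict[str, int] = {}
        for elem, n in (counts or {}).items():
            if elem not in ELEMENT_MASSES:
                raise FormulaError(f"unknown element symbol: {elem!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"invalid count for {elem}: {n!r}")
            if n:
                clean[elem] = n
        self._counts = clean

    # -- Mapping protocol -------------------------------------------------
    def __getitem__(self, elem: str) -> int:
        return self._counts[elem]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def get(self, elem: str, default: int = 0) -> int:
        return self._counts.get(elem, default)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self._counts)
        for elem, n in other.items():
            merged[elem] = merged.get(elem, 0) + n
        return MolecularFormula(merged)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        out = dict(self._counts)
        for elem, n in other.items():
            left = out.get(elem, 0) - n
            if left < 0:
                raise FormulaError(
                    f"infeasible loss: cannot remove {other.hill()} "
                    f"from {self.hill()} ({elem} would go negative)"
                )
            out[elem] = left
        return MolecularFormula(out)

    def __mul__(self, k: int) -> "MolecularFormula":
        if not isinstance(k, int) or k < 0:
            raise FormulaError(f"formula multiplier must be a non-negative int, got {k!r}")
        return MolecularFormula({e: n * k for e, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if isinstance(other, MolecularFormula):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def hill(self) -> str:
        """Canonical Hill-notation string (C, H, then alphabetical)."""
        ordered = sorted(self._counts, key=lambda e: (_HILL_ORDER.get(e, 2), e))
        return "".join(f"{e}{self._counts[e] if self._counts[e] != 1 else ''}" for e in ordered)

    def __str__(self) -> str:
        return self.hill()

    def __repr__(self) -> str:
        return f"MolecularFormula({self.hill()!r})"


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string such as ``"C15H14O6"``.

    No isotopes, charges or parentheses: nothing in scope needs them.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula {text!r} at {text[pos:]!r}")
        elem, digits = m.group(1), m.group(2)
        if elem not in ELEMENT_MASSES:
            raise FormulaError(f"unknown element symbol {elem!r} in {text!r}")
        counts[elem] = counts.get(elem, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return MolecularFormula(counts)


def nominal_mass(f: MolecularFormula) -> int:
    """Integer nominal mass in Da (C=12, H=1, O=16)."""
    return sum(n * int(ELEMENT_MASSES[e]["nominal"]) for e, n in f.items())


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Monoisotopic mass in Da from IUPAC single-isotope masses."""
    return sum(n * ELEMENT_MASSES[e]["monoisotopic"] for e, n in f.items())


@dataclass(frozen=True)
class IonMass:
    """m/z of a singly charged anion on both mass scales."""

    nominal_mz: int
    monoisotopic_mz: float
    charge: int = -1


def mz_deprotonated(f: MolecularFormula, mode: str = "both") -> IonMass:
    """m/z of the [M - H]- ion of a neutral with formula ``f``.

    ``mode`` is accepted for interface compatibility; the returned
    :class:`IonMass` always carries both the nominal (integer) and
    monoisotopic m/z.
    """
    if f.get("H", 0) < 1:
        raise FormulaError(f"cannot deprotonate {f.hill()}: no hydrogen to remove")
    if mode not in ("both", "nominal", "monoisotopic"):
        raise ValueError(f"unknown mode {mode!r}")
    return IonMass(
        nominal_mz=nominal_mass(f) - 1,
        monoisotopic_mz=monoisotopic_mass(f) - PROTON_MASS,
    )
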