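"""Registry of the eight flavan-3-ol / procyanidin reference standards.

A compound is described structurally as an ordered chain of monomer units
(top extension unit first, bottom terminal unit last).  A unit carries its
B-ring hydroxylation (2 = catechol type, catechin/epicatechin; 3 =
pyrogallol type, epigallocatechin) and whether the C3 hydroxyl is esterified
with gallic acid.  B-type oligomers are joined by single 4->8 / 4->6
interflavan C-C bonds, each of which removes two hydrogens from the summed
unit formulas.  Stereochemistry (catechin vs epicatechin, B1 vs B2) does not
change the formula and therefore not the fragment set either.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .formula import MolecularFormula, mz_deprotonated, parse_formula

__all__ = [
    "MonomerUnit",
    "CompoundSpec",
    "REGISTRY_NAMES",
    "registry_compound",
]

# Building blocks of every in-scope formula.
_FLAVANOL_CORE = parse_formula("C15H14O6")  # catechin/epicatechin skeleton
_O = parse_formula("O")
_GALLIC_ACID = parse_formula("C7H6O5")
_WATER = parse_formula("H2O")
_H2 = parse_formula("H2")


@dataclass(frozen=True)
class MonomerUnit:
    """One flavan-3-ol unit within a (possibly oligomeric) compound."""

    b_ring_oh: int = 2
    galloylated: bool = False

    def __post_init__(self) -> None:
        if self.b_ring_oh not in (2, 3):
            raise ValueError(f"b_ring_oh must be 2 or 3, got {self.b_ring_oh}")

    @property
    def formula(self) -> MolecularFormula:
        f = _FLAVANOL_CORE
        if self.b_ring_oh == 3:
            f = f + _O
        if self.galloylated:
            f = f + _GALLIC_ACID - _WATER  # ester bond condenses out water
        return f


@dataclass(frozen=True)
class CompoundSpec:
    """A flavan-3-ol monomer or B-type oligomer (DP <= 3)."""

    name: str
    units: tuple[MonomerUnit, ...]
    retention_s: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.units) <= 3:
            raise ValueError("degree of polymerization must be 1-3")

    @property
    def dp(self) -> int:
        return len(self.units)

    @property
    def formula(self) -> MolecularFormula:
        total = MolecularFormula()
        for u in self.units:
            total = total + u.formula
        # each B-type interflavan C-C bond removes H2
        return total - (self.dp - 1) * _H2

    @property
    def precursor(self):
        """IonMass of the deprotonated molecular ion [M - H]-."""
        return mz_deprotonated(self.formula)

    @property
    def galloylated(self) -> bool:
        return any(u.galloylated for u in self.units)

    def subchain(self, start: int, stop: int) -> "CompoundSpec":
        """Sub-oligomer made of units[start:stop] (same bond bookkeeping)."""
        units = self.units[start:stop]
        if not units:
            raise ValueError("empty unit chain")
        return CompoundSpec(name=f"{self.name}[{start}:{stop}]", units=units,
                            retention_s=self.retention_s)


def _load_registry() -> dict[str, CompoundSpec]:
    with resources.files("flavanms.data").joinpath("compounds.json").open() as fh:
        raw = json.load(fh)
    specs: dict[str, CompoundSpec] = {}
    alias_map: dict[str, str] = {}
    for name, entry in raw.items():
        units = tuple(MonomerUnit(u["b_ring_oh"], u["galloylated"]) for u in entry["units"])
        specs[name] = CompoundSpec(name=name, units=units, retention_s=entry.get("retention_s"))
        alias_map[name.lower()] = name
        for alias in entry.get("aliases", []):
            alias_map[alias.lower()] = name
            # tolerate the unicode minus sign used for optical rotation
            alias_map[alias.replace("-", "−", 1).lower()] = name
    specs["__aliases__"] = alias_map  # type: ignore[assignment]
    return specs


_REGISTRY = _load_registry()
_ALIASES: dict[str, str] = _REGISTRY.pop("__aliases__")  # type: ignore[assignment]

#: Canonical names of the eight reference standards.
REGISTRY_NAMES: tuple[str, ...] = tuple(_REGISTRY)


def registry_compound(name: str) -> CompoundSpec:
    """Look up a standard by canonical name or common alias."""
    key = _ALIASES.get(name.strip().lower())
    if key is None:
        raise KeyError(
            f"unknown compound {name!r}; known standards: {', '.join(REGISTRY_NAMES)}"
        )
    return _REGISTRY[key]
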