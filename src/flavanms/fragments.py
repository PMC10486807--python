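"""Negative-mode fragmentation rules and MRM transition design.

The engine enumerates the product ions of flavan-3-ols, their gallate
esters, and B-type procyanidin dimers/trimers from a small catalog of
neutral-loss and cleavage rules:

* ``WATER_LOSS`` (-H2O, 18 Da) and ``ETHENOL_LOSS`` (-C2H4O, 44 Da);
* ``C3O2_LOSS`` (-68 Da) and the consecutive ``C3O2_LOSS -> WATER_LOSS``
  chain (-86 Da overall), the unusual carbon-suboxide pathway of the
  flavan-3-ol A ring;
* ``HRF`` — heterocyclic ring fission eliminating the phloroglucinol
  A ring as C6H6O3 (-126 Da);
* ``RDA_152`` / ``RDA_138`` — retro-Diels-Alder fission of ring C losing
  the catechol-containing side (-C8H8O3) or retaining it (-C7H6O3);
* ``GALLOYL_LOSS`` (-C7H4O4, 152 Da) and ``GALLATE_ANION`` (charge
  retention on deprotonated gallic acid, m/z 169) for gallate esters;
* ``QM`` — quinone-methide cleavage of an interflavan bond, producing a
  complementary ion pair: the lower block as an intact deprotonated
  flavan-3-ol and the upper block as its quinone methide, 2 Da lower.

QM cleavage yields ions that behave as fresh precursors: the lower-block
anion of a trimer fragments like a dimer, which is how the dimer-level
ions (451/425/407/299/273/533...) arise in a trimer spectrum.  The
loss-chain budget (``max_chain``) therefore applies per precursor segment,
and an ion's provenance records the full rule history across segments.

Rule compositions and default relative intensities are shipped as package
data (``data/rules.json``); intensities are configuration describing which
ions the instrument method treats as most abundant, not a physical model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from .formula import (
    FormulaError,
    IonMass,
    MolecularFormula,
    mz_deprotonated,
    parse_formula,
)
from .registry import CompoundSpec, registry_compound

__all__ = [
    "RuleNotApplicable",
    "FragmentationRule",
    "FragmentIon",
    "TransitionSet",
    "RULES",
    "apply_loss",
    "qm_cleavage",
    "enumerate_fragments",
    "build_transitions",
]

_H2 = parse_formula("H2")
_GALLIC_ACID = parse_formula("C7H6O5")


class RuleNotApplicable(ValueError):
    """The rule's loss is infeasible or its predicate rejects the precursor."""


def _load_rules() -> dict:
    with resources.files("flavanms.data").joinpath("rules.json").open() as fh:
        return json.load(fh)


_RULE_DATA = _load_rules()
DEFAULT_INTENSITY: dict[str, float] = dict(_RULE_DATA["intensity"])


@dataclass(frozen=True)
class FragmentationRule:
    """A named neutral-loss rule (``loss`` is None for GALLATE_ANION/QM)."""

    rule_id: str
    loss: MolecularFormula | None
    requires_catechol: bool = False
    requires_gallate: bool = False


def _build_catalog() -> dict[str, FragmentationRule]:
    catalog: dict[str, FragmentationRule] = {}
    for rid, loss_text in _RULE_DATA["losses"].items():
        catalog[rid] = FragmentationRule(
            rule_id=rid,
            loss=parse_formula(loss_text),
            requires_catechol=(rid == "RDA_152"),
            requires_gallate=(rid == "GALLOYL_LOSS"),
        )
    catalog["GALLATE_ANION"] = FragmentationRule(
        rule_id="GALLATE_ANION", loss=None, requires_gallate=True
    )
    catalog["QM"] = FragmentationRule(rule_id="QM", loss=None)
    return catalog


RULES: dict[str, FragmentationRule] = _build_catalog()

_MONOMER_CHAINS = [tuple(c) for c in _RULE_DATA["monomer_chains"]]
_OLIGOMER_CHAINS = [tuple(c) for c in _RULE_DATA["oligomer_chains"]]
_GALLATE_CHAINS = [tuple(c) for c in _RULE_DATA["gallate_chains"]]


@dataclass(frozen=True)
class FragmentIon:
    """A product ion, stored as its neutral formula plus [M - H]- m/z.

    ``provenance`` is the ordered chain of rule ids that produced the ion
    from the registry precursor; ``parent_mz`` is the nominal m/z of the
    nearest precursor-like ion (the molecular anion, or the intact-side QM
    ion the fragment descends from).
    """

    formula: MolecularFormula
    mass: IonMass
    provenance: tuple[str, ...]
    parent_mz: int
    retains: str | None = None

    @property
    def nominal_mz(self) -> int:
        return self.mass.nominal_mz


_RETAINS = {
    "HRF": "B_ring_side",
    "RDA_152": "A_ring_side",
    "RDA_138": "B_ring_side",
    "GALLATE_ANION": "gallate",
}


def _make_ion(neutral: MolecularFormula, provenance: tuple[str, ...], parent_mz: int,
              retains: str | None = None) -> FragmentIon:
    return FragmentIon(
        formula=neutral,
        mass=mz_deprotonated(neutral),
        provenance=provenance,
        parent_mz=parent_mz,
        retains=retains,
    )


def _check_predicate(rule: FragmentationRule, compound: CompoundSpec | None) -> None:
    if compound is None:
        return
    if rule.requires_catechol and not any(u.b_ring_oh == 2 for u in compound.units):
        raise RuleNotApplicable(
            f"{rule.rule_id} needs a catechol-type B ring; {compound.name} has none"
        )
    if rule.requires_gallate and not compound.galloylated:
        raise RuleNotApplicable(f"{rule.rule_id} needs a galloyl ester; {compound.name} has none")


def apply_loss(precursor, rule: FragmentationRule | str) -> FragmentIon:
    """Apply one neutral-loss rule to a precursor ion.

    ``precursor`` may be a :class:`FragmentIon`, a :class:`CompoundSpec`
    (meaning its [M - H]- molecular anion) or a bare neutral
    :class:`MolecularFormula`.
    """
    if isinstance(rule, str):
        rule = RULES[rule]
    compound: CompoundSpec | None = None
    if isinstance(precursor, CompoundSpec):
        compound = precursor
        neutral, prov, parent = precursor.formula, (), precursor.precursor.nominal_mz
    elif isinstance(precursor, FragmentIon):
        neutral, prov, parent = precursor.formula, precursor.provenance, precursor.parent_mz
    elif isinstance(precursor, MolecularFormula):
        neutral, prov, parent = precursor, (), mz_deprotonated(precursor).nominal_mz
    else:
        raise TypeError(f"unsupported precursor type: {type(precursor).__name__}")

    _check_predicate(rule, compound)

    if rule.rule_id == "GALLATE_ANION":
        # charge retention on the gallate side: the flavanol part leaves as
        # the neutral; the observed anion is deprotonated gallic acid (169).
        try:
            neutral - _GALLIC_ACID
        except FormulaError as exc:
            raise RuleNotApplicable(str(exc)) from exc
        return _make_ion(_GALLIC_ACID, prov + (rule.rule_id,), parent,
                         retains=_RETAINS["GALLATE_ANION"])
    if rule.loss is None:
        raise RuleNotApplicable(f"{rule.rule_id} is not a simple neutral-loss rule")
    try:
        remainder = neutral - rule.loss
    except FormulaError as exc:
        raise RuleNotApplicable(str(exc)) from exc
    return _make_ion(remainder, prov + (rule.rule_id,), parent,
                     retains=_RETAINS.get(rule.rule_id))


def qm_cleavage(oligomer: CompoundSpec, bond_index: int) -> tuple[FragmentIon, FragmentIon]:
    """Quinone-methide cleavage of interflavan bond ``bond_index`` (1-based).

    Returns ``(intact, qm)``: the lower block leaves with the charge as an
    intact deprotonated flavan-3-ol/oligomer, the upper block as its quinone
    methide anion, 2 nominal Da lower than the intact form of that block.
    """
    if oligomer.dp < 2:
        raise RuleNotApplicable("QM cleavage needs an interflavan bond (DP >= 2)")
    if not 1 <= bond_index <= oligomer.dp - 1:
        raise ValueError(
            f"bond_index must be in 1..{oligomer.dp - 1}, got {bond_index}"
        )
    parent_mz = oligomer.precursor.nominal_mz
    lower = oligomer.subchain(bond_index, oligomer.dp)
    upper = oligomer.subchain(0, bond_index)
    intact = _make_ion(lower.formula, ("QM",), parent_mz, retains="lower_unit")
    qm = _make_ion(upper.formula - _H2, ("QM",), parent_mz, retains="upper_unit_QM")
    return intact, qm


def _chains_for(compound: CompoundSpec, max_chain: int) -> list[tuple[str, ...]]:
    if compound.galloylated:
        chains = _GALLATE_CHAINS
    elif compound.dp == 1:
        chains = _MONOMER_CHAINS
    else:
        chains = _OLIGOMER_CHAINS
    return [c for c in chains if len(c) <= max_chain]


def enumerate_fragments(compound: CompoundSpec | str, max_chain: int = 2) -> list[FragmentIon]:
    """All product ions of ``compound`` reachable under the rule catalog.

    Deduplicated on neutral formula (keeping the shortest provenance) and
    sorted by descending nominal m/z.  ``max_chain`` bounds the number of
    consecutive neutral losses applied to any one precursor segment; QM
    cleavage opens a new segment (its lower-block ion fragments like the
    corresponding monomer/dimer).
    """
    if isinstance(compound, str):
        compound = registry_compound(compound)
    if max_chain not in (1, 2):
        raise ValueError("max_chain must be 1 or 2")

    best: dict[MolecularFormula, FragmentIon] = {}

    def add(ion: FragmentIon) -> None:
        prev = best.get(ion.formula)
        if prev is None or len(ion.provenance) < len(prev.provenance):
            best[ion.formula] = ion

    def walk(spec: CompoundSpec, prefix: tuple[str, ...], parent_mz: int) -> None:
        for chain in _chains_for(spec, max_chain):
            ion: FragmentIon | None = None
            try:
                for rid in chain:
                    src = ion if ion is not None else spec
                    ion = apply_loss(src, RULES[rid])
            except RuleNotApplicable:
                continue
            assert ion is not None
            add(FragmentIon(ion.formula, ion.mass, prefix + ion.provenance,
                            parent_mz, ion.retains))
        if spec.dp >= 2 and not spec.galloylated:
            for bond in range(1, spec.dp):
                intact, qm = qm_cleavage(spec, bond)
                add(FragmentIon(intact.formula, intact.mass, prefix + intact.provenance,
                                parent_mz, intact.retains))
                add(FragmentIon(qm.formula, qm.mass, prefix + qm.provenance,
                                parent_mz, qm.retains))
                walk(spec.subchain(bond, spec.dp), prefix + ("QM",),
                     intact.mass.nominal_mz)

    walk(compound, (), compound.precursor.nominal_mz)
    return sorted(best.values(), key=lambda i: (-i.nominal_mz, i.formula.hill()))


@dataclass(frozen=True)
class TransitionSet:
    """Quantifier/qualifier MRM transitions for one compound."""

    compound: CompoundSpec
    precursor_mz: IonMass
    quantifier: FragmentIon
    qualifiers: tuple[FragmentIon, ...]
    expected_ratios: dict[int, float] = field(default_factory=dict)

    @property
    def product_ions(self) -> tuple[FragmentIon, ...]:
        return (self.quantifier, *self.qualifiers)


def _fragment_intensity(ion: FragmentIon, model: dict[str, float]) -> float:
    x = 1.0
    for rid in ion.provenance:
        x *= model.get(rid, 0.1)
    if ion.retains == "upper_unit_QM":
        x *= model.get("qm_side_factor", 0.8)
    return x


def build_transitions(
    compound: CompoundSpec | str,
    intensity_model: dict[str, float] | None = None,
    n_qualifiers: int | None = None,
    max_chain: int = 2,
) -> TransitionSet:
    """Select quantifier and qualifier ions for MRM-style monitoring.

    The quantifier is the highest-intensity fragment under the (relative)
    intensity model, ties broken toward higher m/z; qualifiers are the next
    fragments down.  Non-galloylated compounds monitor 3 product ions
    (quantifier + 2 qualifiers); gallate esters produce only two diagnostic
    ions, so they monitor 2.
    """
    if isinstance(compound, str):
        compound = registry_compound(compound)
    model = dict(DEFAULT_INTENSITY)
    if intensity_model:
        model.update(intensity_model)
    fragments = enumerate_fragments(compound, max_chain=max_chain)
    if not fragments:
        raise ValueError(f"no fragments enumerable for {compound.name}")
    if n_qualifiers is None:
        n_qualifiers = 1 if compound.galloylated else 2
    ranked = sorted(
        fragments,
        key=lambda i: (-_fragment_intensity(i, model), -i.nominal_mz, i.formula.hill()),
    )
    quantifier = ranked[0]
    qualifiers = tuple(ranked[1 : 1 + n_qualifiers])
    q0 = _fragment_intensity(quantifier, model)
    ratios = {
        q.nominal_mz: _fragment_intensity(q, model) / q0 for q in qualifiers
    }
    return TransitionSet(
        compound=compound,
        precursor_mz=compound.precursor,
        quantifier=quantifier,
        qualifiers=qualifiers,
        expected_ratios=ratios,
    )
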