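"""Readers/writers and run configuration.

Peak tables travel as UTF-8 comma-separated files with a fixed header
(:data:`flavanms.simulate.PEAKTABLE_COLUMNS`, '.' decimal separator);
fragment lists can be exported as MGF via pyteomics; run configuration is
JSON validated by pydantic before any stage runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field
from pyteomics import mgf

from .fragments import FragmentIon, TransitionSet
from .simulate import PEAKTABLE_COLUMNS, SimulationConfig

__all__ = [
    "RunConfig",
    "read_peak_table",
    "write_peak_table",
    "transitions_frame",
    "fragments_frame",
    "write_mgf",
]


class RunConfig(BaseModel):
    """Validated run configuration for the CLI pipeline."""

    seed: int = 0
    dilution_factor: float = Field(default=20.0, gt=0)
    ascorbic_g_L: float = Field(default=5.0, ge=0)  # sample-prep metadata
    tolerance_mDa: float = Field(default=5.0, gt=0)
    ip_threshold: float = Field(default=4.0, ge=0)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    lod_max_level: float = Field(default=0.4, gt=0)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))


def read_peak_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PEAKTABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: peak table missing columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: empty peak table")
    return df


def write_peak_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def transitions_frame(transition_sets: list[TransitionSet]) -> pd.DataFrame:
    """Flat transition table: compound, precursor, product, role, ratio."""
    rows = []
    for ts in transition_sets:
        for role, ion in [("quantifier", ts.quantifier)] + [
            ("qualifier", q) for q in ts.qualifiers
        ]:
            rows.append({
                "compound": ts.compound.name,
                "precursor_mz": ts.precursor_mz.nominal_mz,
                "precursor_mz_mono": round(ts.precursor_mz.monoisotopic_mz, 4),
                "product_mz": ion.nominal_mz,
                "product_mz_mono": round(ion.mass.monoisotopic_mz, 4),
                "role": role,
                "expected_ratio": 1.0 if role == "quantifier"
                else round(ts.expected_ratios[ion.nominal_mz], 4),
                "provenance": ">".join(ion.provenance),
            })
    return pd.DataFrame(rows)


def fragments_frame(compound_name: str, ions: list[FragmentIon]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "compound": compound_name,
            "formula": ion.formula.hill(),
            "nominal_mz": ion.nominal_mz,
            "monoisotopic_mz": round(ion.mass.monoisotopic_mz, 4),
            "parent_mz": ion.parent_mz,
            "provenance": ">".join(ion.provenance),
            "retains": ion.retains or "",
        }
        for ion in ions
    ])


def write_mgf(entries: list[tuple[str, float, list[FragmentIon]]], path: str | Path) -> None:
    """Write fragment lists as MGF; one entry per (title, precursor, ions)."""
    spectra = []
    for title, precursor_mz, ions in entries:
        spectra.append({
            "m/z array": [ion.mass.monoisotopic_mz for ion in ions],
            "intensity array": [1.0] * len(ions),
            "params": {
                "title": title,
                "pepmass": (precursor_mz, None),
                "charge": "1-",
            },
        })
    mgf.write(spectra, output=str(path), file_mode="w")
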