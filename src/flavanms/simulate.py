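"""Synthetic bbCID spectra and peak-area tables for method development.

The generator emulates the measurement structure a targeted wine-phenolics
assay assumes:

* linear detector response, ``area = slope * conc + intercept``, with
  proportional (injection CV) plus additive noise, truncated at zero;
* partial analyte oxidation to the quinone form in untreated samples — a
  fraction ``f_oxidized`` of each analyte is invisible to the assay — fully
  or partially reversed when ascorbic acid is added during sample
  preparation (``ascorbic_reversal``);
* a 20-fold sample dilution separating the instrument (diluted) and wine
  concentration scales;
* day-to-day multiplicative bias (lognormal) creating between-day variance
  on top of within-day injection noise;
* fining-treatment groups whose true concentrations scale the control by
  ``1 - removal``.

All concentrations handled here are on the *diluted* (instrument) scale in
mg/L; quantification converts back to the wine scale with the dilution
factor.  Every stochastic operation takes an explicit numpy Generator or
derives one deterministically from ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .fragments import TransitionSet
from .registry import REGISTRY_NAMES, CompoundSpec, registry_compound

__all__ = [
    "SimulationConfig",
    "SpectrumRecord",
    "PEAKTABLE_COLUMNS",
    "simulate_response",
    "simulate_calibration",
    "simulate_spike_recovery",
    "simulate_precision_series",
    "simulate_fining_trial",
    "simulate_wines",
    "render_spectrum",
]

#: Column contract for every peak table produced here.
PEAKTABLE_COLUMNS = (
    "sample_id",
    "group",
    "compound",
    "level_mg_L",
    "area",
    "replicate",
    "day",
    "ascorbic",
)


def _default_slopes() -> dict[str, float]:
    # Area counts per (mg/L, diluted scale); monomers respond more strongly
    # than the oligomers, as ESI efficiency drops with size.
    return {
        "catechin": 1.20e5,
        "epicatechin": 1.15e5,
        "epigallocatechin": 0.90e5,
        "epicatechin gallate": 0.80e5,
        "epigallocatechin gallate": 0.75e5,
        "procyanidin B1": 0.65e5,
        "procyanidin B2": 0.62e5,
        "procyanidin C1": 0.50e5,
    }


class SimulationConfig(BaseModel):
    """Parameters of the measurement model (defaults = study conditions)."""

    seed: int = 0
    slope_map: dict[str, float] = Field(default_factory=_default_slopes)
    intercept_map: dict[str, float] = Field(default_factory=dict)
    cv_injection: float = Field(default=0.03, ge=0)
    sd_additive: float = Field(default=300.0, ge=0)
    f_oxidized: float = Field(default=0.3, ge=0, lt=1)
    ascorbic_reversal: float = Field(default=1.0, ge=0, le=1)
    dilution_factor: float = Field(default=20.0, gt=0)
    mass_sigma: float = Field(default=0.002, ge=0)
    day_bias_sd: float = Field(default=0.05, ge=0)

    @model_validator(mode="after")
    def _oxidation_bounded(self) -> "SimulationConfig":
        if self.f_oxidized * (1 - self.ascorbic_reversal) >= 1:
            raise ValueError("irreversible oxidized fraction must stay below 1")
        return self

    def slope(self, compound: str) -> float:
        return self.slope_map.get(compound, 1.0e5)

    def intercept(self, compound: str) -> float:
        return self.intercept_map.get(compound, 0.0)

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


@dataclass(frozen=True)
class SpectrumRecord:
    """Two-channel bbCID-style spectrum: MS survey plus fragment channel."""

    sample_id: str
    compound: str
    retention_s: float
    survey: tuple[tuple[float, float], ...]
    fragment: tuple[tuple[float, float], ...]


def mean_response(conc_mg_L: float, compound: str, ascorbic: bool,
                  cfg: SimulationConfig) -> float:
    """Noise-free expected area under the oxidation/reversal model."""
    visible = 1.0 - cfg.f_oxidized * (1.0 - cfg.ascorbic_reversal * (1 if ascorbic else 0))
    return cfg.slope(compound) * conc_mg_L * visible + cfg.intercept(compound)


def simulate_response(conc_mg_L: float, compound: str, ascorbic: bool,
                      cfg: SimulationConfig, rng: np.random.Generator) -> float:
    """One noisy peak area at a diluted-scale concentration."""
    if conc_mg_L < 0:
        raise ValueError(f"negative concentration: {conc_mg_L}")
    mean = mean_response(conc_mg_L, compound, ascorbic, cfg)
    area = mean * (1.0 + rng.normal(0.0, cfg.cv_injection)) + rng.normal(0.0, cfg.sd_additive)
    return max(0.0, area)


def _compound_list(compounds) -> list[str]:
    if compounds is None:
        return list(REGISTRY_NAMES)
    return [registry_compound(c).name for c in compounds]


def _finish(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=list(PEAKTABLE_COLUMNS) + (
        ["flag"] if rows and "flag" in rows[0] else []))
    return df


def simulate_calibration(levels, reps: int = 3, cfg: SimulationConfig | None = None,
                         compounds=None, ascorbic: bool = True) -> pd.DataFrame:
    """Calibration series: one row per compound x level x replicate."""
    cfg = cfg or SimulationConfig()
    levels = list(levels)
    if not levels:
        raise ValueError("empty level list")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = cfg.rng(stream=1)
    rows = []
    for compound in _compound_list(compounds):
        for level in levels:
            for rep in range(1, reps + 1):
                rows.append(dict(
                    sample_id=f"cal_{level:g}_{rep}",
                    group="calibration",
                    compound=compound,
                    level_mg_L=float(level),
                    area=simulate_response(level, compound, ascorbic, cfg, rng),
                    replicate=rep,
                    day=1,
                    ascorbic=ascorbic,
                ))
    return _finish(rows)


def simulate_spike_recovery(base_conc: dict[str, float], spikes, reps: int = 3,
                            cfg: SimulationConfig | None = None,
                            ascorbic: bool = True,
                            calibration_range: tuple[float, float] = (0.1, 1.0),
                            ) -> pd.DataFrame:
    """Standard-addition series: base wine plus increasing spikes.

    ``level_mg_L`` holds the *added* concentration (0 for base rows); rows
    whose spike falls outside the calibration range carry a warning flag.
    """
    cfg = cfg or SimulationConfig()
    spikes = list(spikes)
    rng = cfg.rng(stream=2)
    lo, hi = calibration_range
    rows = []
    for compound, base in base_conc.items():
        compound = registry_compound(compound).name
        for rep in range(1, reps + 1):
            rows.append(dict(
                sample_id=f"base_{rep}", group="base", compound=compound,
                level_mg_L=0.0,
                area=simulate_response(base, compound, ascorbic, cfg, rng),
                replicate=rep, day=1, ascorbic=ascorbic, flag="",
            ))
        for spike in spikes:
            flag = "" if lo <= spike <= hi else "outside_calibration_range"
            for rep in range(1, reps + 1):
                rows.append(dict(
                    sample_id=f"spike_{spike:g}_{rep}", group=f"spike_{spike:g}",
                    compound=compound, level_mg_L=float(spike),
                    area=simulate_response(base + spike, compound, ascorbic, cfg, rng),
                    replicate=rep, day=1, ascorbic=ascorbic, flag=flag,
                ))
    return _finish(rows)


def simulate_precision_series(conc: dict[str, float], days: int = 3, reps: int = 3,
                              cfg: SimulationConfig | None = None,
                              ascorbic: bool = True) -> pd.DataFrame:
    """Triplicates on several days with a lognormal per-day bias."""
    cfg = cfg or SimulationConfig()
    if days < 1 or reps < 1:
        raise ValueError("days and reps must be >= 1")
    rng = cfg.rng(stream=3)
    day_bias = np.exp(rng.normal(0.0, cfg.day_bias_sd, size=days))
    rows = []
    for compound, c in conc.items():
        compound = registry_compound(compound).name
        for day in range(1, days + 1):
            mean = mean_response(c, compound, ascorbic, cfg) * day_bias[day - 1]
            for rep in range(1, reps + 1):
                area = mean * (1.0 + rng.normal(0.0, cfg.cv_injection)) \
                    + rng.normal(0.0, cfg.sd_additive)
                rows.append(dict(
                    sample_id=f"prec_d{day}_{rep}", group="precision",
                    compound=compound, level_mg_L=float(c), area=max(0.0, area),
                    replicate=rep, day=day, ascorbic=ascorbic,
                ))
    return _finish(rows)


def simulate_fining_trial(control_conc: dict[str, float],
                          removal: dict[str, dict[str, float]],
                          reps: int = 3, cfg: SimulationConfig | None = None,
                          ascorbic: bool = True) -> pd.DataFrame:
    """Fining-trial groups: group means scale control by (1 - removal)."""
    cfg = cfg or SimulationConfig()
    if reps < 1:
        raise ValueError("reps must be >= 1")
    for group, fracs in removal.items():
        for compound, r in fracs.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"removal fraction out of [0,1]: {group}/{compound}={r}")
    rng = cfg.rng(stream=4)
    groups = ["control"] + [g for g in removal if g != "control"]
    rows = []
    for compound, c0 in control_conc.items():
        compound = registry_compound(compound).name
        for group in groups:
            frac = removal.get(group, {}).get(compound, 0.0)
            conc = c0 * (1.0 - frac)
            for rep in range(1, reps + 1):
                rows.append(dict(
                    sample_id=f"{group}_{rep}", group=group, compound=compound,
                    level_mg_L=float(conc),
                    area=simulate_response(conc, compound, ascorbic, cfg, rng),
                    replicate=rep, day=1, ascorbic=ascorbic,
                ))
    return _finish(rows)


def simulate_wines(wine_conc: dict[str, dict[str, float]], reps: int = 3,
                   cfg: SimulationConfig | None = None,
                   ascorbic: bool = True) -> pd.DataFrame:
    """Wine samples; ``wine_conc`` maps wine id -> compound -> mg/L on the
    *wine* scale.  ``level_mg_L`` records the true diluted-scale value (a
    ground-truth annotation only synthetic data can carry)."""
    cfg = cfg or SimulationConfig()
    rng = cfg.rng(stream=5)
    rows = []
    for wine, comp_map in wine_conc.items():
        for compound, wine_scale in comp_map.items():
            compound = registry_compound(compound).name
            diluted = wine_scale / cfg.dilution_factor
            for rep in range(1, reps + 1):
                rows.append(dict(
                    sample_id=str(wine), group="wine", compound=compound,
                    level_mg_L=diluted,
                    area=simulate_response(diluted, compound, ascorbic, cfg, rng),
                    replicate=rep, day=1, ascorbic=ascorbic,
                ))
    return _finish(rows)


def render_spectrum(compound: CompoundSpec | str, transitions: TransitionSet,
                    cfg: SimulationConfig, rng: np.random.Generator,
                    sample_id: str = "sim", survey_intensity: float = 1.0e5,
                    conversion_efficiency: float = 0.9) -> SpectrumRecord:
    """bbCID-style spectrum: survey precursor peak plus fragment channel.

    Fragment intensities preserve the transition set's expected quantifier/
    qualifier ratios and sum to ``conversion_efficiency`` times the survey
    precursor intensity (the fragment channel can never out-count the
    precursor it derives from).
    """
    if isinstance(compound, str):
        compound = registry_compound(compound)
    jitter = lambda mz: mz + rng.normal(0.0, cfg.mass_sigma)  # noqa: E731
    survey = ((jitter(compound.precursor.monoisotopic_mz), survey_intensity),)
    rel = [1.0] + [transitions.expected_ratios[q.nominal_mz] for q in transitions.qualifiers]
    scale = conversion_efficiency * survey_intensity / sum(rel)
    frag_peaks = tuple(
        (jitter(ion.mass.monoisotopic_mz), r * scale)
        for ion, r in zip(transitions.product_ions, rel)
    )
    return SpectrumRecord(
        sample_id=sample_id,
        compound=compound.name,
        retention_s=compound.retention_s or 0.0,
        survey=survey,
        fragment=frag_peaks,
    )
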