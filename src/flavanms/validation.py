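"""Calibration, method-validation statistics, quantification and group
comparison for the targeted wine flavan-3-ol assay.

The module follows the model/results idiom: :class:`CalibrationCurve` is a
model built from a peak table whose ``fit()`` returns a
:class:`CalibrationResult` carrying the estimates and diagnostics, and
:class:`MethodValidation` bundles the whole validation study (calibration +
precision + standard-addition series) into a single ``fit()`` producing a
per-compound report table.  Thin module-level functions
(:func:`fit_calibration`, :func:`mandel_test`, ...) expose each statistic
individually.

Statistics implemented:

* unweighted OLS calibration with residual standard error s_y and the
  quality coefficient QCmean = 100 * sqrt(sum(((y - yhat)/ybar)^2) / (n-1));
* Mandel's fitting test comparing linear vs quadratic calibration,
  F = ((n-2) s_y1^2 - (n-3) s_y2^2) / s_y2^2 against F(1, n-3);
* LOD = 3.3 s_y / slope and LOQ = 10 s_y / slope from a low-range
  calibration, scaled to the wine by the dilution factor;
* within-day (repeatability) and between-day (intermediate precision) RSDs
  from a one-way day-variance decomposition, with Horwitz predicted RSDs
  PRSD = 2^(1 - 0.5 log10 C) (C the analyte mass fraction; repeatability
  scale 0.66x) and the HorRat = RSD/PRSD acceptability windows
  (0.3-1.3 for repeatability, 0.5-2.0 for intermediate precision);
* standard-addition recovery: found-minus-base regressed on added, with a
  t-based CI on the slope and a test of slope = 1;
* sample quantification with dilution correction and <LOD / <LOQ flagging;
* one-way ANOVA with Tukey HSD post hoc comparison and a compact letter
  display for fining-trial groups.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "CalibrationCurve",
    "CalibrationResult",
    "MandelResult",
    "SensitivityLimits",
    "PrecisionReport",
    "RecoveryReport",
    "GroupComparison",
    "MethodValidation",
    "ValidationResults",
    "fit_calibration",
    "mandel_test",
    "lod_loq",
    "horwitz_prsd",
    "precision_metrics",
    "recovery_analysis",
    "quantify",
    "compare_treatments",
]

#: HorRat acceptability windows per precision scale.
HORRAT_WINDOW_R = (0.3, 1.3)
HORRAT_WINDOW_IR = (0.5, 2.0)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationResult:
    """OLS calibration fit of area on concentration for one compound."""

    compound: str
    slope: float
    intercept: float
    n: int
    s_y: float
    r2: float
    qc_mean_pct: float
    slope_se: float
    intercept_se: float
    level_min: float
    level_max: float

    def summary(self) -> str:
        lines = [
            f"Calibration: {self.compound}",
            f"  n = {self.n}, levels {self.level_min:g}-{self.level_max:g} mg/L",
            f"  area = {self.slope:.4g} * conc + {self.intercept:.4g}",
            f"  slope SE {self.slope_se:.3g}, intercept SE {self.intercept_se:.3g}",
            f"  s_y = {self.s_y:.4g}, R^2 = {self.r2:.5f}, QCmean = {self.qc_mean_pct:.2f}%",
        ]
        return "\n".join(lines)


class CalibrationCurve:
    """Unweighted straight-line calibration model for one compound."""

    def __init__(self, levels, areas, compound: str = ""):
        self.levels = np.asarray(levels, dtype=float)
        self.areas = np.asarray(areas, dtype=float)
        self.compound = compound
        if self.levels.size != self.areas.size:
            raise ValueError("levels and areas differ in length")
        if np.unique(self.levels).size < 3:
            raise ValueError("calibration needs >= 3 distinct levels")
        if np.ptp(self.levels) == 0:
            raise ValueError("zero variance in calibration levels")

    @classmethod
    def from_peak_table(cls, table: pd.DataFrame, compound: str) -> "CalibrationCurve":
        sub = table[table["compound"] == compound]
        if sub.empty:
            raise ValueError(f"no calibration rows for {compound!r}")
        return cls(sub["level_mg_L"].to_numpy(), sub["area"].to_numpy(), compound)

    def fit(self) -> CalibrationResult:
        x, y = self.levels, self.areas
        n = x.size
        X = sm.add_constant(x)
        res = sm.OLS(y, X).fit()
        intercept, slope = res.params
        yhat = res.fittedvalues
        sse = float(np.sum((y - yhat) ** 2))
        s_y = math.sqrt(sse / (n - 2)) if n > 2 else 0.0
        ybar = float(np.mean(y))
        qc = 100.0 * math.sqrt(float(np.sum(((y - yhat) / ybar) ** 2)) / (n - 1))
        return CalibrationResult(
            compound=self.compound,
            slope=float(slope),
            intercept=float(intercept),
            n=int(n),
            s_y=s_y,
            r2=float(res.rsquared) if np.ptp(y) > 0 else 1.0,
            qc_mean_pct=qc,
            slope_se=float(res.bse[1]),
            intercept_se=float(res.bse[0]),
            level_min=float(x.min()),
            level_max=float(x.max()),
        )


def fit_calibration(table: pd.DataFrame, compound: str) -> CalibrationResult:
    return CalibrationCurve.from_peak_table(table, compound).fit()


# ---------------------------------------------------------------------------
# Mandel's fitting test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MandelResult:
    compound: str
    s_y1: float
    s_y2: float
    f_stat: float
    f_crit: float
    alpha: float
    linear: bool


def mandel_test(table: pd.DataFrame, compound: str, alpha: float = 0.05) -> MandelResult:
    """Linear-vs-quadratic F test on the calibration residual errors."""
    sub = table[table["compound"] == compound]
    x = sub["level_mg_L"].to_numpy(dtype=float)
    y = sub["area"].to_numpy(dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("Mandel test needs >= 5 points (n - 3 >= 2)")
    X1 = sm.add_constant(x)
    X2 = np.column_stack([np.ones_like(x), x, x**2])
    sse1 = float(np.sum(sm.OLS(y, X1).fit().resid ** 2))
    sse2 = float(np.sum(sm.OLS(y, X2).fit().resid ** 2))
    # perfect fits leave only rounding residue; zero them relative to scale
    tiny = 1e-20 * max(1.0, float(np.sum(y**2)))
    sse1 = 0.0 if sse1 < tiny else sse1
    sse2 = 0.0 if sse2 < tiny else sse2
    s1sq = sse1 / (n - 2)
    s2sq = sse2 / (n - 3)
    f_crit = float(st.f.ppf(1 - alpha, 1, n - 3))
    if s2sq == 0.0:
        # degenerate perfect quadratic fit: linear iff the line is perfect too
        linear = s1sq == 0.0
        f_stat = 0.0 if linear else float("inf")
    else:
        f_stat = ((n - 2) * s1sq - (n - 3) * s2sq) / s2sq
        linear = f_stat <= f_crit
    return MandelResult(compound, math.sqrt(s1sq), math.sqrt(s2sq),
                        f_stat, f_crit, alpha, linear)


# ---------------------------------------------------------------------------
# LOD / LOQ
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensitivityLimits:
    compound: str
    lod_diluted: float
    loq_diluted: float
    lod_wine: float
    loq_wine: float
    dilution_factor: float


def lod_loq(model: CalibrationResult, dilution_factor: float = 20.0) -> SensitivityLimits:
    """3.3x / 10x residual-error limits, on both concentration scales."""
    if model.slope <= 0:
        raise ValueError("calibration slope must be positive for LOD/LOQ")
    base = model.s_y / model.slope
    return SensitivityLimits(
        compound=model.compound,
        lod_diluted=3.3 * base,
        loq_diluted=10.0 * base,
        lod_wine=3.3 * base * dilution_factor,
        loq_wine=10.0 * base * dilution_factor,
        dilution_factor=dilution_factor,
    )


# ---------------------------------------------------------------------------
# precision / Horwitz
# ---------------------------------------------------------------------------

def horwitz_prsd(conc_mg_L: float, scale: str = "reproducibility") -> float:
    """Horwitz predicted RSD (percent) at a wine-scale concentration.

    ``C`` is the analyte mass fraction (mg/L -> C = conc * 1e-6 assuming
    unit density); the base curve 2^(1 - 0.5 log10 C) predicts
    between-session RSD, and repeatability is conventionally 0.66 of it.
    """
    if conc_mg_L <= 0:
        raise ValueError("concentration must be > 0")
    c = conc_mg_L * 1e-6
    prsd = 2.0 ** (1.0 - 0.5 * math.log10(c))
    if scale in ("reproducibility", "intermediate"):
        return prsd
    if scale == "repeatability":
        return 0.66 * prsd
    raise ValueError(f"unknown scale {scale!r}")


@dataclass(frozen=True)
class PrecisionReport:
    compound: str
    conc_wine_mg_L: float
    rsd_r_pct: float
    rsd_ir_pct: float
    prsd_r_pct: float
    prsd_ir_pct: float
    horrat_r: float
    horrat_ir: float
    horrat_r_ok: bool
    horrat_ir_ok: bool


def precision_metrics(table: pd.DataFrame, model: CalibrationResult, compound: str,
                      dilution_factor: float = 20.0) -> PrecisionReport:
    """Within-day and between-day RSDs with Horwitz ratios.

    Within-day variance is pooled over days; the between-day component comes
    from the one-way (day) decomposition, and the intermediate-precision
    variance is their sum.
    """
    sub = table[table["compound"] == compound]
    days = sub.groupby("day")["area"]
    n_days = days.ngroups
    reps = days.size()
    if n_days < 2 or (reps < 2).any():
        raise ValueError("precision needs >= 2 replicates on >= 2 days")
    grand = float(sub["area"].mean())

    within_var = float(days.var(ddof=1).mean())  # pooled (balanced design)
    day_means = days.mean()
    n_rep = float(reps.mean())
    ms_between = float(day_means.var(ddof=1)) * n_rep
    between_var = max(0.0, (ms_between - within_var) / n_rep)

    rsd_r = 100.0 * math.sqrt(within_var) / grand if grand > 0 else 0.0
    rsd_ir = 100.0 * math.sqrt(within_var + between_var) / grand if grand > 0 else 0.0

    conc_wine = dilution_factor * (grand - model.intercept) / model.slope
    prsd_r = horwitz_prsd(conc_wine, "repeatability") if conc_wine > 0 else float("nan")
    prsd_ir = horwitz_prsd(conc_wine, "reproducibility") if conc_wine > 0 else float("nan")
    horrat_r = rsd_r / prsd_r if prsd_r and prsd_r > 0 else float("nan")
    horrat_ir = rsd_ir / prsd_ir if prsd_ir and prsd_ir > 0 else float("nan")
    return PrecisionReport(
        compound=compound,
        conc_wine_mg_L=conc_wine,
        rsd_r_pct=rsd_r,
        rsd_ir_pct=rsd_ir,
        prsd_r_pct=prsd_r,
        prsd_ir_pct=prsd_ir,
        horrat_r=horrat_r,
        horrat_ir=horrat_ir,
        horrat_r_ok=bool(HORRAT_WINDOW_R[0] <= horrat_r <= HORRAT_WINDOW_R[1]),
        horrat_ir_ok=bool(HORRAT_WINDOW_IR[0] <= horrat_ir <= HORRAT_WINDOW_IR[1]),
    )


# ---------------------------------------------------------------------------
# standard-addition recovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryReport:
    compound: str
    slope: float
    slope_ci95: tuple[float, float]
    recovery_pct: float
    deviates_from_1: bool
    per_level_recovery: tuple[tuple[float, float], ...]  # (added, found - base)


def recovery_analysis(table: pd.DataFrame, model: CalibrationResult,
                      compound: str | None = None,
                      dilution_factor: float = 20.0,
                      alpha: float = 0.05) -> RecoveryReport:
    """Regress found-minus-base concentration on added concentration."""
    compound = compound or model.compound
    sub = table[table["compound"] == compound]
    if sub.empty:
        raise ValueError(f"no spike rows for {compound!r}")
    found = (sub["area"].to_numpy(dtype=float) - model.intercept) / model.slope
    added = sub["level_mg_L"].to_numpy(dtype=float)
    base_mask = sub["group"].to_numpy() == "base"
    if not base_mask.any():
        raise ValueError("spike table has no base rows")
    base_found = float(found[base_mask].mean())
    spiked = ~base_mask
    x = added[spiked]
    y = found[spiked] - base_found
    if np.unique(x).size < 3:
        raise ValueError("recovery needs >= 3 spike levels")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(res.params[1])
    lo, hi = (float(v) for v in res.conf_int(alpha=alpha)[1])
    per_level = tuple(
        (float(level), float(np.mean(y[x == level]))) for level in np.unique(x)
    )
    return RecoveryReport(
        compound=compound,
        slope=slope,
        slope_ci95=(lo, hi),
        recovery_pct=100.0 * slope,
        deviates_from_1=not (lo <= 1.0 <= hi),
        per_level_recovery=per_level,
    )


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def quantify(table: pd.DataFrame, model: CalibrationResult,
             dilution_factor: float = 20.0,
             limits: SensitivityLimits | None = None) -> pd.DataFrame:
    """Wine-scale concentrations per sample with <LOD / <LOQ flags.

    Sub-limit values are flagged but retained numerically for auditing;
    areas below the intercept floor at 0 with their own flag.
    """
    sub = table[table["compound"] == model.compound].copy()
    conc_diluted = (sub["area"].to_numpy(dtype=float) - model.intercept) / model.slope
    floored = conc_diluted < 0
    conc_wine = np.where(floored, 0.0, conc_diluted) * dilution_factor

    flags = np.where(floored, "below_intercept", "")
    if limits is not None:
        flags = np.where((flags == "") & (conc_wine < limits.loq_wine), "<LOQ", flags)
        flags = np.where((conc_wine < limits.lod_wine) & ~floored, "<LOD", flags)
    out = pd.DataFrame({
        "sample_id": sub["sample_id"].to_numpy(),
        "group": sub["group"].to_numpy(),
        "compound": model.compound,
        "conc_mg_L": conc_wine,
        "flag": flags,
    })
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# group comparison (ANOVA + Tukey + compact letter display)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    compound: str
    f_stat: float
    p_value: float
    group_means: dict[str, float]
    group_letters: dict[str, str]
    n_excluded: int = 0


def _compact_letters(groups: list[str], means: dict[str, float],
                     significant: set[frozenset]) -> dict[str, str]:
    """Compact letter display from the non-significance graph.

    Maximal cliques of mutually non-different groups each receive one
    letter (ordered by descending clique mean); a group's code is the
    sorted union of its cliques' letters.
    """
    g = nx.Graph()
    g.add_nodes_from(groups)
    for a in groups:
        for b in groups:
            if a < b and frozenset((a, b)) not in significant:
                g.add_edge(a, b)
    cliques = sorted(nx.find_cliques(g), key=lambda c: -max(means[m] for m in c))
    letters: dict[str, list[str]] = {grp: [] for grp in groups}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i)
        for grp in clique:
            letters[grp].append(letter)
    return {grp: "".join(sorted(ls)) for grp, ls in letters.items()}


def compare_treatments(conc_table: pd.DataFrame, alpha: float = 0.05,
                       drop_flagged: bool = True) -> dict[str, GroupComparison]:
    """Per-compound one-way ANOVA + Tukey HSD with letter codes.

    ``conc_table`` needs columns compound, group, conc_mg_L (and optionally
    flag; <LOQ/<LOD rows are excluded from the comparison when
    ``drop_flagged`` and counted in ``n_excluded``).
    """
    out: dict[str, GroupComparison] = {}
    for compound, sub in conc_table.groupby("compound"):
        n_total = len(sub)
        if drop_flagged and "flag" in sub.columns:
            sub = sub[~sub["flag"].isin(["<LOQ", "<LOD"])]
        n_excluded = n_total - len(sub)
        groups = sorted(sub["group"].unique())
        if len(groups) < 2:
            raise ValueError(f"{compound}: need >= 2 groups")
        arrays = [sub.loc[sub["group"] == grp, "conc_mg_L"].to_numpy(dtype=float)
                  for grp in groups]
        if any(a.size < 2 for a in arrays):
            raise ValueError(f"{compound}: need >= 2 replicates per group")
        means = {grp: float(a.mean()) for grp, a in zip(groups, arrays)}

        if all(np.ptp(a) == 0 for a in arrays):
            # zero within-group variance: exact-equality shortcut
            distinct = sorted({round(m, 12) for m in means.values()}, reverse=True)
            if len(distinct) == 1:
                f_stat, p, letters = 0.0, 1.0, {grp: "a" for grp in groups}
            else:
                f_stat, p = float("inf"), 0.0
                letters = {grp: chr(ord("a") + distinct.index(round(means[grp], 12)))
                           for grp in groups}
            out[compound] = GroupComparison(compound, f_stat, p, means, letters, n_excluded)
            continue

        f_stat, p = st.f_oneway(*arrays)
        tuk = pairwise_tukeyhsd(
            sub["conc_mg_L"].to_numpy(dtype=float),
            sub["group"].to_numpy(), alpha=alpha,
        )
        significant = set()
        for (g1, g2), reject in zip(
            ((r[0], r[1]) for r in tuk.summary().data[1:]), tuk.reject
        ):
            if reject:
                significant.add(frozenset((str(g1), str(g2))))
        letters = _compact_letters(groups, means, significant)
        out[compound] = GroupComparison(compound, float(f_stat), float(p),
                                        means, letters, n_excluded)
    return out


# ---------------------------------------------------------------------------
# whole-study validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationResults:
    """Per-compound validation report with a Table-style summary."""

    calibration: dict[str, CalibrationResult]
    mandel: dict[str, MandelResult]
    limits: dict[str, SensitivityLimits]
    precision: dict[str, PrecisionReport]
    recovery: dict[str, RecoveryReport]
    dilution_factor: float
    qc_mean_denominator: str = "mean_response"
    table: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        rows = []
        for compound, cal in self.calibration.items():
            man = self.mandel.get(compound)
            lim = self.limits.get(compound)
            pre = self.precision.get(compound)
            rec = self.recovery.get(compound)
            rows.append({
                "compound": compound,
                "linear_range_mg_L": f"{cal.level_min:g}-{cal.level_max:g}",
                "slope": cal.slope,
                "intercept": cal.intercept,
                "r2": cal.r2,
                "qc_mean_pct": cal.qc_mean_pct,
                "mandel_linear": man.linear if man else None,
                "lod_wine_mg_L": lim.lod_wine if lim else None,
                "loq_wine_mg_L": lim.loq_wine if lim else None,
                "lod_diluted_mg_L": lim.lod_diluted if lim else None,
                "loq_diluted_mg_L": lim.loq_diluted if lim else None,
                "rsd_r_pct": pre.rsd_r_pct if pre else None,
                "rsd_ir_pct": pre.rsd_ir_pct if pre else None,
                "horrat_r": pre.horrat_r if pre else None,
                "horrat_ir": pre.horrat_ir if pre else None,
                "horrat_r_ok": pre.horrat_r_ok if pre else None,
                "horrat_ir_ok": pre.horrat_ir_ok if pre else None,
                "recovery_pct": rec.recovery_pct if rec else None,
                "recovery_ci95_lo": rec.slope_ci95[0] if rec else None,
                "recovery_ci95_hi": rec.slope_ci95[1] if rec else None,
                "recovery_deviates_from_1": rec.deviates_from_1 if rec else None,
            })
        self.table = pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        return self.table

    def to_json(self) -> str:
        payload = {
            "dilution_factor": self.dilution_factor,
            "qc_mean_denominator": self.qc_mean_denominator,
            "compounds": {
                c: {
                    "calibration": asdict(self.calibration[c]),
                    "mandel": asdict(self.mandel[c]) if c in self.mandel else None,
                    "limits": asdict(self.limits[c]) if c in self.limits else None,
                    "precision": asdict(self.precision[c]) if c in self.precision else None,
                    "recovery": asdict(self.recovery[c]) if c in self.recovery else None,
                }
                for c in self.calibration
            },
        }
        return json.dumps(payload, indent=2, default=str)


class MethodValidation:
    """Whole validation study for all compounds present in the tables.

    ``lod_max_level`` restricts the LOD/LOQ calibration to the low end of
    the range (default 0.4 mg/L on the diluted scale), mirroring the use of
    a dedicated low-range curve for sensitivity limits.
    """

    def __init__(self, calibration_table: pd.DataFrame,
                 precision_table: pd.DataFrame | None = None,
                 spike_table: pd.DataFrame | None = None,
                 dilution_factor: float = 20.0, alpha: float = 0.05,
                 lod_max_level: float = 0.4):
        self.calibration_table = calibration_table
        self.precision_table = precision_table
        self.spike_table = spike_table
        self.dilution_factor = dilution_factor
        self.alpha = alpha
        self.lod_max_level = lod_max_level

    def fit(self) -> ValidationResults:
        compounds = sorted(self.calibration_table["compound"].unique())
        calibration: dict[str, CalibrationResult] = {}
        mandel: dict[str, MandelResult] = {}
        limits: dict[str, SensitivityLimits] = {}
        precision: dict[str, PrecisionReport] = {}
        recovery: dict[str, RecoveryReport] = {}
        low = self.calibration_table[
            self.calibration_table["level_mg_L"] <= self.lod_max_level + 1e-12
        ]
        for compound in compounds:
            cal = fit_calibration(self.calibration_table, compound)
            calibration[compound] = cal
            mandel[compound] = mandel_test(self.calibration_table, compound, self.alpha)
            low_cal = fit_calibration(low, compound) if not low.empty else cal
            limits[compound] = lod_loq(low_cal, self.dilution_factor)
            if self.precision_table is not None and \
                    (self.precision_table["compound"] == compound).any():
                precision[compound] = precision_metrics(
                    self.precision_table, cal, compound, self.dilution_factor)
            if self.spike_table is not None and \
                    (self.spike_table["compound"] == compound).any():
                recovery[compound] = recovery_analysis(
                    self.spike_table, cal, compound, self.dilution_factor,
                    alpha=self.alpha)
        return ValidationResults(
            calibration=calibration, mandel=mandel, limits=limits,
            precision=precision, recovery=recovery,
            dilution_factor=self.dilution_factor,
        )
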