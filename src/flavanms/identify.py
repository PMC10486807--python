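"""Positive identification of analytes from bbCID spectra.

Confirmatory identification follows the identification-points (IP) system
used in regulatory residue analysis: each high-resolution precursor ion
earns 2.0 IP and each high-resolution product ion 2.5 IP, with IP > 4
required for a positive call.  Monitoring 3 product ions therefore scores
7.5 IP, and the two diagnostic ions of a gallate ester score 5.0 IP.  On
top of the points threshold, each qualifier's intensity ratio to the
quantifier must sit inside a banded tolerance around its reference value
(wider bands for weaker qualifiers), and the peak must fall inside a
retention-time window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fragments import FragmentIon, TransitionSet
from .simulate import SpectrumRecord

__all__ = [
    "MatchResult",
    "IdentificationResult",
    "match_ions",
    "ip_score",
    "ion_ratio_check",
    "identify",
]

#: EU 2002/657-style identification-point weights for high-resolution MS.
W_HR_PRECURSOR = 2.0
W_HR_PRODUCT = 2.5


@dataclass(frozen=True)
class MatchResult:
    compound: str
    matched_ions: tuple[tuple[FragmentIon, float, float], ...]  # (expected, obs mz, err mDa)
    n_product_matched: int
    precursor_matched: bool
    matched_intensity: dict[int, float] = field(default_factory=dict)


@dataclass(frozen=True)
class IdentificationResult:
    compound: str
    ip: float
    ip_threshold: float
    ratio_checks: tuple[tuple[int, float, float, float, bool], ...]
    retention_ok: bool
    identified: bool
    ratio_checks_skipped: bool = False


def match_ions(spectrum: SpectrumRecord, transitions: TransitionSet,
               tol_mDa: float) -> MatchResult:
    """Greedy nearest-neighbour matching of expected ions to observed peaks.

    Candidate (expected, observed) pairs within tolerance are assigned in
    order of increasing mass error; every observed peak and every expected
    ion is used at most once.  An empty spectrum simply yields no matches.
    """
    if tol_mDa <= 0:
        raise ValueError("tol_mDa must be > 0")
    tol = tol_mDa / 1000.0

    expected = list(transitions.product_ions)
    observed = list(spectrum.fragment)
    pairs = []
    for ei, ion in enumerate(expected):
        for oi, (mz, _inten) in enumerate(observed):
            err = mz - ion.mass.monoisotopic_mz
            if abs(err) <= tol:
                pairs.append((abs(err), ei, oi, err))
    pairs.sort()
    used_e: set[int] = set()
    used_o: set[int] = set()
    matched = []
    intensity: dict[int, float] = {}
    for _aerr, ei, oi, err in pairs:
        if ei in used_e or oi in used_o:
            continue
        used_e.add(ei)
        used_o.add(oi)
        matched.append((expected[ei], observed[oi][0], err * 1000.0))
        intensity[expected[ei].nominal_mz] = observed[oi][1]

    prec_ok = any(
        abs(mz - transitions.precursor_mz.monoisotopic_mz) <= tol
        for mz, _ in spectrum.survey
    )
    return MatchResult(
        compound=transitions.compound.name,
        matched_ions=tuple(matched),
        n_product_matched=len(matched),
        precursor_matched=prec_ok,
        matched_intensity=intensity,
    )


def ip_score(n_hr_precursor: int, n_hr_product: int,
             w_precursor: float = W_HR_PRECURSOR,
             w_product: float = W_HR_PRODUCT) -> float:
    """Identification points earned by matched high-resolution ions."""
    if n_hr_precursor < 0 or n_hr_product < 0:
        raise ValueError("ion counts must be non-negative")
    return w_precursor * n_hr_precursor + w_product * n_hr_product


def ion_ratio_tolerance(reference: float) -> float:
    """Maximum permitted relative deviation (fraction) for an ion ratio.

    Banded on the reference ratio (qualifier relative to base peak), with
    exact band boundaries assigned the wider tolerance:
    > 0.5 -> 20%; (0.2, 0.5] -> 25%; (0.1, 0.2] -> 30%; <= 0.1 -> 50%.
    """
    if reference <= 0 or reference > 1:
        raise ValueError(f"reference ratio must be in (0, 1], got {reference}")
    if reference <= 0.1:
        return 0.50
    if reference <= 0.2:
        return 0.30
    if reference <= 0.5:
        return 0.25
    return 0.20


def ion_ratio_check(measured: float, reference: float) -> tuple[float, bool]:
    """(tolerance %, pass) for one qualifier/quantifier intensity ratio."""
    if measured < 0:
        raise ValueError("measured ratio must be >= 0")
    tol = ion_ratio_tolerance(reference)
    return tol * 100.0, abs(measured - reference) <= tol * reference


def identify(spectrum: SpectrumRecord, transitions: TransitionSet,
             tol_mDa: float = 5.0, ip_threshold: float = 4.0,
             retention_window_s: float = 6.0,
             reference_ratios: dict[int, float] | None = None,
             allow_missing_ratios: bool = False) -> IdentificationResult:
    """Full identification: ion matching + IP score + ratio and RT checks.

    ``reference_ratios`` defaults to the transition set's expected ratios;
    if none are available the ratio checks are skipped with an explicit
    flag and identification requires ``allow_missing_ratios=True``.
    """
    match = match_ions(spectrum, transitions, tol_mDa)
    ip = ip_score(0, match.n_product_matched)

    refs = reference_ratios if reference_ratios is not None else transitions.expected_ratios
    checks = []
    skipped = False
    quant_mz = transitions.quantifier.nominal_mz
    quant_int = match.matched_intensity.get(quant_mz)
    if not refs:
        skipped = True
    else:
        for qual in transitions.qualifiers:
            ref = refs.get(qual.nominal_mz)
            if ref is None:
                skipped = True
                continue
            qual_int = match.matched_intensity.get(qual.nominal_mz)
            if quant_int is None or qual_int is None or quant_int <= 0:
                checks.append((qual.nominal_mz, float("nan"), ref,
                               ion_ratio_tolerance(ref) * 100.0, False))
                continue
            measured = qual_int / quant_int
            tol_pct, ok = ion_ratio_check(measured, ref)
            checks.append((qual.nominal_mz, measured, ref, tol_pct, ok))

    rt_ref = transitions.compound.retention_s
    retention_ok = True
    if rt_ref is not None and spectrum.retention_s is not None:
        retention_ok = abs(spectrum.retention_s - rt_ref) <= retention_window_s

    ratios_ok = all(ok for *_x, ok in checks) if checks else (allow_missing_ratios or not skipped)
    if skipped and not allow_missing_ratios:
        ratios_ok = False
    identified = ip >= ip_threshold and ratios_ok and retention_ok
    return IdentificationResult(
        compound=transitions.compound.name,
        ip=ip,
        ip_threshold=ip_threshold,
        ratio_checks=tuple(checks),
        retention_ok=retention_ok,
        identified=identified,
        ratio_checks_skipped=skipped,
    )
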