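# Methods

## Scope and problem

Monomeric flavan-3-ols and low-DP (dimeric/trimeric) B-type
proanthocyanidins are principal contributors to red-wine bitterness.
Quantifying them by LC–MS/MS requires (i) knowing which product ions each
standard yields in negative ESI, so that selective quantifier/qualifier
transitions can be monitored; (ii) a validated calibration with linearity,
sensitivity, precision and accuracy statistics; and (iii) a statistical
comparison of treatment groups when the assay is used to judge fining
agents. This package implements all three layers and a synthetic-data
generator that emulates the measurement structure, so that the statistics
can be exercised end to end without instrument data.

## Mass bookkeeping

All species are CHO compounds observed as singly deprotonated [M−H]⁻
anions. Formulas are element-count maps; a neutral loss is an elementwise
subtraction, which fails loudly when a rule cannot apply. Nominal masses
use integer mass numbers (C=12, H=1, O=16) and match the values printed on
spectra; monoisotopic masses use IUPAC single-isotope masses
(H 1.00782503207, O 15.99491461957) and are reproducible to 1e−4 Da.
Deprotonated m/z subtracts the proton mass 1.00727646 Da, i.e. the electron
stays with the anion — the standard negative-ESI convention; nominal m/z
subtracts 1. Isotope patterns, adducts other than [M−H]⁻ and multiple
charging are out of scope.

## Compound model

A compound is an ordered chain of 1–3 monomer units (top/extension unit
first). A unit records B-ring hydroxylation (2 = catechol type:
catechin/epicatechin; 3 = pyrogallol type: epigallocatechin) and optional
galloylation (gallic acid esterified at C3, condensing out one water).
Each B-type interflavan (4→8 / 4→6) C–C bond removes H₂ from the summed
unit formulas: B1/B2 = C30H26O12 (m/z 577), C1 = C45H38O18 (m/z 865).
Stereochemistry does not enter the formula, so epimers (catechin vs
epicatechin; B1 vs B2) share one fragment set — a structural invariant the
tests assert. Registry retention times are plausible placeholders for a
10-min reversed-phase gradient and carry no chemical claim; they only
exercise the retention-window check.

## Fragmentation rules

Neutral-loss compositions: water H₂O (18), ethenol C₂H₄O (44), carbon
suboxide C₃O₂ (68), combined C₃O₂+H₂O = C₃H₂O₃ (86), HRF C₆H₆O₃ (126,
elimination of the phloroglucinol A ring), RDA_152 C₈H₈O₃ (retro-Diels–
Alder fission of ring C losing the catechol side — applicable only when a
catechol-type B ring is present), RDA_138 C₇H₆O₃ (the B-ring-retaining
counterpart), galloyl loss C₇H₄O₄ (152). The gallate-anion rule retains
the charge on deprotonated gallic acid (m/z 169), the flavanol part leaving
as the neutral. Gallate esters are limited to the galloyl-loss/gallate-anion
pair, the only diagnostic ions they show.

Quinone-methide (QM) cleavage of interflavan bond *i* splits the chain into
an upper block (units 1..i), which leaves as its quinone methide (block
formula − H₂, anion 2 Da below the intact form), and a lower block
(units i+1..DP), which leaves as an intact deprotonated flavan-3-ol or
oligomer. This produces the characteristic doublets: 289/287 at monomer
level, 577/575 at dimer level in the trimer. Complementarity is enforced
through the formulas, never hard-coded masses.

Enumeration applies a whitelist of loss chains (monomer chains include the
two-step C₃O₂ → H₂O route; oligomer chains include RDA→H₂O, HRF→RDA,
RDA→RDA) bounded by `max_chain` (default 2) per precursor segment. A QM
lower-block ion behaves as a fresh precursor and is recursively fragmented
with the same budget — this is how the dimer-level ions (451, 425, 407,
299, 273, 533) arise inside the trimer spectrum. Because of the recursion
an ion's full provenance can hold three rule ids (e.g. QM → RDA_152 →
WATER for m/z 407 of C1) even though no segment exceeds two losses.
Fragments are deduplicated on neutral formula keeping the shortest
provenance, and sorted by descending m/z. The enumeration is a superset of
the ions observed for each standard; extras (e.g. the water-loss ion of
epigallocatechin at 287) are chemically expected even where a printed
spectrum does not list them.

One literature assignment is internally inconsistent — an HRF "loss of
129 Da" giving m/z 456 from the dimer, which neither the arithmetic
(577−129=448) nor the trimer's 739/451 pairs support. The engine fixes
HRF at −126 throughout and never generates 456.

Transition design ranks fragments by a configurable relative-intensity
model (per-rule weights multiplied along the provenance; the QM-side ion
carries an extra factor). The quantifier is the top-ranked ion, ties
broken toward higher m/z; non-galloylated compounds monitor 3 product ions
and gallate esters 2, matching the identification-point budgets below. The
intensity model is configuration describing the instrument method's
abundance ordering, not a physical prediction — bond-energetics intensity
modelling is explicitly out of scope.

## Identification

IP scoring uses the high-resolution weights 2.0 (precursor) / 2.5 (product
ion); the default profile scores product ions only, so 3 ions → 7.5 IP and
2 ions → 5.0 IP, with the acceptance threshold IP > 4. Whether a reported
IP total should also count the precursor is ambiguous in common usage; the
default reproduces the product-ion-only arithmetic and both weights are
arguments. Ion-ratio tolerances are banded on the reference ratio
(qualifier/quantifier): >0.5 → ±20%, (0.2,0.5] → ±25%, (0.1,0.2] → ±30%,
≤0.1 → ±50%, with exact boundary values taking the wider band
(conservative reading). Matching is greedy nearest-neighbour within a mass
tolerance (default 5 mDa), each observed peak used at most once. The
retention window defaults to ±6 s, a typical UPLC peak-to-peak spacing;
no reference states one for this assay.

## Synthetic measurements

The generator's response model is

    area = slope·conc·(1 − f_ox·(1 − r·ascorbic)) + intercept,
    observed = area·(1 + ε_prop) + ε_add,  truncated at 0,

with ε_prop ~ N(0, cv_injection), ε_add ~ N(0, sd_additive). Defaults:
cv_injection 0.03, sd_additive 300 area counts, f_oxidized 0.3,
ascorbic_reversal 1.0, dilution factor 20, m/z jitter 2 mDa. Slopes are
0.5–1.2·10⁵ area per mg/L (monomers respond more strongly than oligomers);
intercepts default to 0 (blank-subtracted areas). The oxidation fraction
is a compound-independent scalar by default (per-compound overrides
possible): the observed phenomenon — peak areas rising, sometimes
doubling, on ascorbic-acid addition as pre-oxidized quinone forms are
reduced — is reported without numbers, so 0.3 was chosen as
order-compatible, not fitted. Day-to-day variation is a lognormal
multiplicative bias (SD 0.05) drawn once per day. Concentrations inside
the generator are on the diluted (instrument) scale; study designs follow
the assay: calibration 0.1–1.0 mg/L, spikes 0.10–1.0 mg/L at 6 levels × 3
replicates (2–20 mg/L on the wine scale), precision in triplicate on three
days, a base wine near 6 mg/L (0.3 diluted) for the standard-addition
series, and fining groups scaling the control by (1 − removal).

What the generator does *not* emulate: chromatographic profiles and
co-elution, ion suppression beyond the dilution-factor bookkeeping,
carry-over, heteroscedasticity structure beyond proportional+additive, and
real between-compound correlation. Passing tests therefore demonstrate
the statistical machinery under the stated model, not instrument-level
performance.

All stochastic operations take an explicit numpy Generator or derive one
from `SimulationConfig.seed` (per-function streams), so identical configs
give bit-identical tables.

## Validation statistics

* **Calibration**: unweighted OLS of area on level (no weighting is part of
  the procedure being modelled); s_y = √(SSE/(n−2));
  QCmean = 100·√(Σ((yᵢ−ŷᵢ)/ȳ)²/(n−1)). The QCmean denominator is the mean
  response ȳ (a per-point-ŷ variant exists; the choice is recorded in the
  report metadata).
* **Mandel**: F = ((n−2)s²_y1 − (n−3)s²_y2)/s²_y2 against F(1, n−3).
  Perfect fits are detected with a scale-relative zero tolerance; a perfect
  quadratic over a non-perfect line is declared nonlinear. Note: with
  purely proportional noise the test runs ~9% type-I error instead of the
  nominal 5% (measured over 1000 seeded linear calibrations) because the F
  test assumes homoscedastic residuals; the nominal rate is recovered under
  additive noise, which is how the type-I property is verified.
* **LOD/LOQ**: 3.3·s_y/slope and 10·s_y/slope from a calibration restricted
  to ≤0.4 mg/L (diluted scale), then ×dilution factor for the wine scale.
  Both scales are always reported together with the factor used, because
  the two scales are easy to conflate when quoting limits.
* **Precision**: within-day variance pooled over days; between-day
  component from the one-way decomposition ((MS_between − MS_within)/n_rep,
  floored at 0); intermediate-precision variance is their sum. Horwitz
  PRSD = 2^(1 − 0.5·log₁₀C) with C the wine-scale mass fraction
  (mg/L × 10⁻⁶, unit density); repeatability scale 0.66×. HorRat windows:
  0.3–1.3 (repeatability), 0.5–2.0 (intermediate precision). With the
  default cv of 3% the true repeatability HorRat at wine-typical
  concentrations is ≈0.4–0.5, and its 6-df estimate scatters widely, so
  individual out-of-window flags at a given seed are expected behaviour,
  not failures.
* **Recovery**: found-minus-base (base = mean of unspiked replicates)
  regressed on added concentration; t-based 95% CI on the slope;
  "deviates from 1" iff 1 ∉ CI. Quantifying a non-ascorbic sample against
  an ascorbic-stabilized calibration yields slope ≈ 1 − f_oxidized,
  reproducing the oxidation anomaly and its reversal.
* **Quantification**: conc_wine = DF·(area − intercept)/slope; values
  below LOQ/LOD are flagged but kept numerically for auditing; areas below
  the intercept floor at 0 with their own flag.
* **Group comparison**: per-compound one-way ANOVA plus Tukey HSD at
  α = 0.05 (no multiplicity correction across compounds — reports are
  per-compound). <LOQ/<LOD rows are excluded with a count. The compact
  letter display assigns one letter per maximal clique of the
  non-significance graph (networkx), ordered by descending clique mean.
  Zero within-group variance short-circuits to exact equality.

## Problem sizes used in tests

The distributional checks run at sizes chosen to give stable Monte-Carlo
estimates at interactive cost: 2000 seeded calibrations for the Mandel
type-I rate (binomial SE ≈ 0.5%), 500/200 seeded studies for the recovery
slope means, 10⁴ draws for response-mean and m/z-jitter checks, 9 wines ×
8 compounds × 3 replicates for end-to-end recovery, and 12 seeded null
fining trials (96 compound×seed ANOVAs) for the familywise null rate.

## Known limitations

* DP > 3, A-type linkages and positive-ion mode are unsupported.
* The intensity model is ordinal configuration; expected ion ratios are
  only as meaningful as the weights supplied.
* The Horwitz mass-fraction convention (wine scale, unit density) is a
  choice; computing it on the diluted scale changes PRSD by 2^(0.5·log₁₀20)
  ≈ 1.7×. The scale used is reported.
* The simulator's oxidation model is a single reversible fraction; real
  wines show compound- and matrix-dependent behaviour.
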