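# Methods

## Scope and data flow

`nampod` derives human-equivalent points of departure (PODs) from
in vitro potency data, fills data gaps by structural read-across, and
ranks chemicals by bioactivity-exposure ratio. The pipeline consumes
six tables (chemicals, fingerprints, assay-level AC50s, toxicokinetic
parameters, exposure estimates, traditional in vivo POD records) and
emits POD, BER, protectiveness and chemotype-enrichment tables plus a
run manifest that accounts for every input chemical in exactly one
terminal status (bioactivity POD, read-across POD, excluded with
reason, or out of coverage).

## Potency summarization

Assay rows are kept when the hit call is active, the assay was run in
multiple-concentration format, the row does not combine ≥ 3 caution
flags with a hit percent below 50 (rows meeting only one of the two
criteria are kept), and the curve-fit category is not 36 or 45 (both
mark AC50s above the tested range). Filter tallies are reported
per reason; reasons may overlap, but kept + removed always reconciles
with the input count. Because the keep predicate is a pure row-wise
conjunction, filtering is idempotent.

Surviving active AC50s are pooled per chemical — duplicates across
endpoints included — and summarized by the 5th percentile. Quantiles
use linear interpolation between order statistics (numpy's default,
"type 7"); this convention is also used for the Monte-Carlo Css
percentile and is recorded here because no single convention is
universal. Tested chemicals with zero surviving actives receive the
maximum tested concentration (`max_tested_conc_uM`, default 100 μM)
with an `is_default` flag; never-tested chemicals are *not* defaulted —
they flow to read-across instead.

## Steady-state toxicokinetic model

The analytic model treats gut, liver and rest-of-body at steady state
under a constant oral dose rate (default 1 mg/kg-bw/day). Plasma
concentration is linear in dose rate:

    Css [μM] = (dose_rate / MW × 1000) / (24 × (GFR·fup + CLh))
    CLh      = Q·fup·CLint_w / (Q + fup·CLint_w)        (well-stirred liver)
    CLint_w  = clint_hep × hepatocellularity × liver_mass_per_bw × 60 × 1e-6

with dose in μmol/kg/day, all clearances in L/h per kg body weight
(hence the ×24 to L/day/kg), and the quotient in μmol/L = μM. The
well-stirred form saturates at the hepatic blood flow Q for large
intrinsic clearance; renal clearance is glomerular filtration of the
unbound fraction. Body weight cancels from the per-kg formulation.

Default physiology (config-overridable, `toxicokinetics.Physiology`):

| parameter | default | units | note |
|---|---|---|---|
| body_weight | 70 | kg | reference adult |
| liver_mass_per_bw | 25.7 | g/kg | 1.8 kg liver / 70 kg |
| hepatocellularity | 110 | 10⁶ cells/g | whole-liver scaling |
| microsomal_protein_per_g_liver | 32 | mg/g | unit-conversion constant |
| microsome_cells_per_g_liver | 99 | 10⁶ cells/g | unit-conversion constant |
| liver_blood_flow | 1.30 | L/h/kg | ~91 L/h for 70 kg |
| gfr | 0.103 | L/h/kg | ~107 mL/min for 70 kg |
| blood_plasma_ratio | 1.0 | — | degenerate default when unmeasured |
| cv | 0.30 | — | population variability |
| n_draws | 1000 | — | Monte-Carlo draws |

Two hepatocellularity constants coexist deliberately: 99×10⁶ cells/g
belongs to the microsomal-to-hepatocyte unit conversion
(clint_hep = clint_hlm × 32/99 per 10⁶ cells), while 110×10⁶ cells/g is
the whole-liver scaling inside Css. Keeping them as separate fields
avoids silently conflating two different conventions.

**Floors.** A fraction unbound of exactly 0 (below the assay limit of
detection) is floored at 0.005; a config switch extends the floor to
all values below 0.005, but the default floors only exact zeros. The
population 95th-percentile Css is floored at 0.1 μM *after* quantile
computation — a conservative cut-off applied uniformly to measured- and
predicted-parameter chemicals, with the flag recorded in provenance.

**Population simulation.** Six parameters (liver mass per BW,
hepatocellularity, hepatic blood flow, body weight, GFR, intrinsic
clearance) are redrawn independently per draw from normals with
sd = cv × nominal, truncated at zero (at cv = 0.30 the truncation point
is 3.3 sd below the mean, so the effective CV stays within a fraction
of a percentage point of nominal). Independence and zero-truncation
are modelling choices: the simulator emulates inter-individual
variability magnitude, not the demographic covariance structure of a
survey-resampling population model, and correlated physiology is a
known omission. With cv = 0 the code returns the analytic value
exactly rather than a degenerate sample quantile.

**Eligibility.** Chemicals whose TK parameters are in silico
predictions are dropped when any of: a Lipinski rule-of-five violation
(strict inequalities — MW > 500, logP > 5, HBD > 5, HBA > 10, so a
value exactly at the bound passes), fraction absorbed < 0.1, fraction
bioavailable < 0.1, or outside the prediction applicability domain.
These filters bound the uncertainty of predictive models trained mainly
on pharmaceutical chemical space; measured parameters bypass them, and
when both exist the measured row wins.

## IVIVE and the POD

AED = concentration / Css × 1 mg/kg-bw/day. One POD per chemical is
emitted: the 5th-percentile potency over the floored 95th-percentile
Css. The full per-assay AED vector is available via
`ivive.per_assay_aeds` for diagnostics. Provenance (defaulted
concentration, floored Css, neighbor identities for read-across) is
carried on every record so a POD can be reproduced exactly from its
stored fields.

## Read-across

Analogs require more than five active assays and more than five
fingerprint on-bits; targets without assay data need only the
structural criterion. Neighbor selection takes the up-to-10 most
similar eligible analogs with Tanimoto similarity at or above the
threshold s. The threshold comparison is inclusive (Sᵢ ≥ s); a strict
mode is available. Ties at the k-th rank break by analog identifier
ascending, making neighbor sets deterministic. The prediction is the
similarity-weighted mean of analog log10 potencies, hence always inside
the analogs' potency range. The default operating point (s = 0.3,
k = 10, dictionary-based fingerprints) follows established read-across
practice; the leave-one-out benchmark (`genra.benchmark_s_grid`) sweeps
s from 0.1 to 0.8 and reports coverage (targets with ≥ 1 neighbor,
non-increasing in s) and the fraction of predictions within 10-fold and
100-fold on the log10 scale. In the leave-one-out protocol the target
is excluded from its own analog list by identifier only; exact
structural duplicates under other identifiers remain eligible analogs.

Externally computed fingerprint dictionaries (ToxPrint- or
PubChem-style) are consumed from wide 0/1 CSV matrices; Morgan
fingerprints are computed internally with RDKit (radius 2, 1024 bits by
default — a documented choice, configurable). Tanimoto similarity of
two all-zero fingerprints is defined as 0 with a warning rather than
NaN; such chemicals can never pass the > 5-on-bits rule, so the value
never drives a prediction. Hydrogen-bond donor/acceptor counts use
RDKit's standard Lipinski SMARTS definitions (recorded as
`chemistry.HBOND_CONVENTION`); note these count an O with exactly one H
as a donor, so e.g. free water counts zero donors.

## Risk metrics

log10 BER = log10 POD − log10 exposure, computed against both the
median and 95th-percentile exposure estimate (the latter is the more
conservative denominator). Bins use the half-open convention
(−∞, 0), [0, 2), [2, 3), [3, ∞) so every finite value maps to exactly
one bin; the boundary placement of exactly-integer values is a
documented convention, not data-derived. TTC values are 30 / 9 /
1.5 μg/kg-bw/day for Cramer classes I/II/III; POD and exposure are
converted to μg/kg-bw/day and compared strictly (>), with exact
equality flagged separately. Genotoxicity-specific TTC tiers are out
of scope.

## Traditional-POD comparison

Response types are harmonized case-insensitively: NOEC, NOAEC, NOEL,
NEL, HNEL → NOAEL; LOEC, LOAEC, LOEL, LEL → LOAEL; NOAEL, LOAEL, BMDL
pass through; everything else is rejected. Units must be an mg/kg or
mg/kg-day dialect (mg/kg, mg/kg-day, mg/kg/day, mg/kg bw/day,
case-insensitive), routes oral or gavage, study types one of
developmental, reproductive, subchronic, chronic, repeat dose (a single
normalized study-class column). The lowest surviving value per
chemical is the traditional POD. Protectiveness means
POD_NAM ≤ POD_traditional; the aggregate fold difference is the median
of the arithmetic ratios POD_traditional / POD_NAM.

Chemotype enrichment among non-protective chemicals tests each
fingerprint bit with nonzero variance in the compared sample (not the
full dictionary) with a one-sided Fisher's exact test in the enrichment
direction, Holm-adjusted; a bit is enriched when the adjusted p < 0.01.
A two-sided alternative is available via the `alternative` argument.

## Synthetic fixtures

The generators produce all six input tables with seeded, byte-stable
output. They emulate: lognormal potencies with a linear
structure-activity link (per-bit effects on log10 potency), clustered
fingerprints so Tanimoto neighborhoods exist, QC-noise injection at
known rates (caution flags, bad fit categories, single-concentration
rows), TK parameters spanning the filter boundaries (exact-zero fup,
both clearance unit systems, absorption fractions straddling 0.1),
exposures with p95 ≥ median by construction, and traditional PODs
offset from a NAM-POD reference by a configurable
log10-normal(mean 2, sd 0.5) distribution with reject-case rows mixed
in. They do *not* emulate: real assay endpoint heterogeneity,
correlated fingerprint bits beyond the block structure, measurement
error models for TK assays, or any real chemical's structure (synthetic
records carry descriptors directly, with CASRN-like placeholder
identifiers and empty SMILES). Passing tests therefore demonstrate
algorithmic correctness and statistical calibration under the stated
generative model, not predictive performance on real inventories.

## Numerical and design choices

- Quantiles: linear interpolation everywhere (potency 5th percentile,
  Css 95th percentile).
- Seeding: one root seed fans out per-chemical via
  `numpy.random.SeedSequence`, so Monte-Carlo results are independent
  of chemical iteration order and stages can be re-run in isolation;
  changing only the seed changes only Monte-Carlo-derived columns.
- Degenerate inputs: empty neighbor sets yield out-of-coverage rather
  than a prediction; empty assay tables yield the 100 μM default only
  for chemicals that were actually tested; two all-zero fingerprints
  compare as 0.
- Problem sizes in the test suite (up to 1,000 chemicals, 10,000 assay
  rows, 250–1,000 Monte-Carlo draws) were chosen as the smallest sizes
  at which the statistical assertions have adequate power.

## Known limitations

- The steady-state model omits absorption kinetics, non-oral routes,
  metabolite tracking and bioaccumulating chemicals that never reach
  steady state; it is a screening-level IVIVE, not PBPK.
- Population variability is magnitude-only (independent 30% CV draws),
  not demographically structured.
- Read-across uncertainty is not quantified; the benchmark reports
  aggregate accuracy, not per-prediction confidence.
- Exposure estimates are consumed as given; no exposure modelling is
  performed.
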