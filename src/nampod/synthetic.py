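"""Seeded synthetic-data generators for every pipeline input table.

The generators emit the exact CSV dialects the readers consume, with
controllable statistical structure:

- chemicals with descriptors drawn to straddle the rule-of-five
  boundaries, plus absorption/bioavailability fractions, applicability
  domain flags and Cramer classes;
- clustered binary fingerprints (blocks of chemicals sharing most of a
  set of "core" bits) so Tanimoto neighborhoods exist by construction;
- a structure-activity link: each chemical's latent log10 potency is a
  linear function of its on-bits plus noise, so read-across has an
  analyzable expectation;
- assay-level AC50 tables with configurable activity, caution-flag and
  bad-fit-category injection rates;
- toxicokinetic parameters spanning the filter boundaries (exact-zero
  fup values, both clearance unit systems, absorption fractions around
  the 0.1 cut-off);
- exposure estimates with p95 >= median by construction; and
- traditional POD records offset from a NAM-POD reference by a
  configurable log10-fold distribution, including reject-case rows
  (wrong units, routes, study types, response types).

Everything is reproducible bit-for-bit from ``FixtureConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .toxicokinetics import (
    Physiology, apply_css_floor, apply_fup_floor, convert_hlm_clint, _css_core,
)


@dataclass
class FixtureConfig:
    n_chemicals: int = 200
    n_assays: int = 40
    seed: int = 0

    # potency / assay structure
    ac50_log10_mean: float = 0.5  # log10 μM, grand mean of latent potency
    ac50_log10_sd: float = 0.5  # sd of the latent chemical potency noise
    assay_noise_sd: float = 0.3  # within-chemical assay-to-assay scatter, log10
    p_active: float = 0.3
    flag_rate: float = 0.1  # fraction of active rows triggering the flag filter
    fit_cat_bad_rate: float = 0.05
    single_conc_rate: float = 0.02
    frac_untested: float = 0.2  # chemicals with no assay rows (read-across targets)

    # fingerprint block structure
    n_bits: int = 128
    cluster_size: int = 10
    n_core_bits: int = 16  # core bits per cluster
    p_core_on: float = 0.9
    p_background_on: float = 0.02
    bit_effect_sd: float = 0.1  # per-bit potency effect sd (log10)

    # toxicokinetics
    fup_zero_rate: float = 0.05
    clint_log10_mean: float = 0.8  # μL/min/10^6 cells
    clint_log10_sd: float = 0.5
    frac_hlm_units: float = 0.5
    frac_measured: float = 0.3
    frac_out_of_domain: float = 0.05
    fabs_low_rate: float = 0.08  # fraction forced below the 0.1 cut-off
    fbio_low_rate: float = 0.08

    # traditional PODs and exposure
    trad_offset_log10_mean: float = 2.0
    trad_offset_log10_sd: float = 0.5
    trad_reject_row_rate: float = 0.2
    trad_coverage: float = 0.8  # fraction of chemicals with any trad record
    exposure_log10_mean: float = -4.0  # mg/kg-bw/day
    exposure_log10_sd: float = 1.0
    exposure_coverage: float = 0.9

    def validate(self) -> None:
        for name in ("p_active", "flag_rate", "fit_cat_bad_rate", "single_conc_rate",
                     "frac_untested", "p_core_on", "p_background_on", "fup_zero_rate",
                     "frac_hlm_units", "frac_measured", "frac_out_of_domain",
                     "fabs_low_rate", "fbio_low_rate", "trad_reject_row_rate",
                     "trad_coverage", "exposure_coverage"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_chemicals < 0 or self.n_assays < 0:
            raise ValueError("n_chemicals and n_assays must be non-negative")
        if self.cluster_size < 1 or self.n_bits < 1:
            raise ValueError("cluster_size and n_bits must be positive")


def _chem_ids(n: int) -> list[str]:
    # CASRN-like synthetic identifiers
    return [f"{100000 + i}-{(i % 89) + 10:02d}-{i % 10}" for i in range(n)]


CHEM_COLUMNS = ["chem_id", "smiles", "mw", "logp", "hbd", "hba",
                "fraction_absorbed", "fraction_bioavailable",
                "in_applicability_domain", "cramer_class",
                "cluster", "true_log10_potency", "tested"]


def generate_universe(config: FixtureConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Chemical records + clustered fingerprint matrix.

    Returns ``(chemicals, fingerprints)``.  The chemicals frame carries
    generator metadata columns (``cluster``, ``true_log10_potency``,
    ``tested``) that the pipeline ignores but tests use as ground truth.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_chemicals
    ids = _chem_ids(n)
    fp_cols = [f"bit_{i}" for i in range(config.n_bits)]
    if n == 0:
        chem = pd.DataFrame(columns=CHEM_COLUMNS)
        fps = pd.DataFrame(columns=fp_cols, dtype=np.uint8)
        fps.index.name = "chem_id"
        return chem, fps

    # descriptors straddling the rule-of-five boundaries
    mw = rng.uniform(100, 700, n).round(2)
    logp = rng.normal(2.5, 1.8, n).round(3)
    hbd = rng.poisson(2.0, n)
    hba = rng.poisson(4.0, n)

    # absorption fractions around the 0.1 eligibility cut-off
    fabs = rng.uniform(0.15, 1.0, n).round(3)
    fbio = rng.uniform(0.15, 1.0, n).round(3)
    low_abs = rng.random(n) < config.fabs_low_rate
    low_bio = rng.random(n) < config.fbio_low_rate
    fabs[low_abs] = rng.uniform(0.01, 0.09, int(low_abs.sum())).round(3)
    fbio[low_bio] = rng.uniform(0.01, 0.09, int(low_bio.sum())).round(3)
    in_ad = rng.random(n) >= config.frac_out_of_domain
    cramer = rng.choice(["I", "II", "III"], size=n, p=[0.4, 0.2, 0.4])

    # clustered fingerprints: each cluster shares a random core-bit set
    cluster = np.arange(n) // config.cluster_size
    n_clusters = int(cluster.max()) + 1
    bits = (rng.random((n, config.n_bits)) < config.p_background_on)
    core_bits_by_cluster = [
        rng.choice(config.n_bits, size=min(config.n_core_bits, config.n_bits), replace=False)
        for _ in range(n_clusters)
    ]
    for i in range(n):
        core = core_bits_by_cluster[cluster[i]]
        on = core[rng.random(len(core)) < config.p_core_on]
        bits[i, on] = True
    fps = pd.DataFrame(bits.astype(np.uint8), index=pd.Index(ids, name="chem_id"),
                       columns=fp_cols)

    # structure-activity link: latent potency linear in on-bits + noise
    bit_effects = rng.normal(0.0, config.bit_effect_sd, config.n_bits)
    potency = (config.ac50_log10_mean
               + bits.astype(float) @ bit_effects
               + rng.normal(0.0, config.ac50_log10_sd, n))

    tested = rng.random(n) >= config.frac_untested
    chem = pd.DataFrame({
        "chem_id": ids,
        "smiles": "",  # synthetic records carry descriptors directly, no structures
        "mw": mw,
        "logp": logp,
        "hbd": hbd,
        "hba": hba,
        "fraction_absorbed": fabs.round(3),
        "fraction_bioavailable": fbio.round(3),
        "in_applicability_domain": in_ad,
        "cramer_class": cramer,
        "cluster": cluster,
        "true_log10_potency": potency.round(6),
        "tested": tested,
    })
    return chem, fps


def generate_assay_table(config: FixtureConfig, chemicals: pd.DataFrame) -> pd.DataFrame:
    """Per chemical x assay activity and AC50 rows with QC-noise injection.

    Active rows draw AC50 = 10^(latent potency + scatter); a configured
    fraction gets >= 3 caution flags with hit percent < 50 (triggering
    the QC filter) and another fraction gets fit category 36 or 45.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    rows = []
    tested = chemicals.loc[chemicals["tested"].astype(bool)]
    for _, chem in tested.iterrows():
        active = rng.random(config.n_assays) < config.p_active
        for j in range(config.n_assays):
            if not active[j]:
                rows.append((chem["chem_id"], f"assay_{j}", np.nan, False, 0, 100.0, 41, True))
                continue
            ac50 = 10.0 ** (chem["true_log10_potency"] + rng.normal(0, config.assay_noise_sd))
            if rng.random() < config.flag_rate:
                n_flags, hit_pct = int(rng.integers(3, 6)), float(rng.uniform(0, 49.9))
            else:
                n_flags, hit_pct = int(rng.integers(0, 3)), float(rng.uniform(50, 100))
            fit_cat = int(rng.choice([36, 45])) if rng.random() < config.fit_cat_bad_rate else 41
            multi = rng.random() >= config.single_conc_rate
            rows.append((chem["chem_id"], f"assay_{j}", round(ac50, 6), True,
                         n_flags, round(hit_pct, 2), fit_cat, multi))
    return pd.DataFrame(rows, columns=["chem_id", "endpoint_id", "ac50_uM", "hit_call",
                                       "n_flags", "hit_percent", "fit_category", "multi_conc"])


def generate_tk_table(config: FixtureConfig, chemicals: pd.DataFrame) -> pd.DataFrame:
    """TK parameters spanning the filter boundaries and both unit systems.

    A configured fraction of fup values is exactly zero (exercising the
    limit-of-detection floor); half the clearances are reported in
    microsomal units chosen so the unit conversion recovers the
    hepatocyte-scale value.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    n = len(chemicals)
    fup = rng.uniform(0.005, 1.0, n).round(4)
    fup[rng.random(n) < config.fup_zero_rate] = 0.0
    clint_hep = 10.0 ** rng.normal(config.clint_log10_mean, config.clint_log10_sd, n)
    as_hlm = rng.random(n) < config.frac_hlm_units
    phys = Physiology()
    hlm_factor = phys.microsome_cells_per_g_liver / phys.microsomal_protein_per_g_liver
    source = np.where(rng.random(n) < config.frac_measured, "measured", "predicted")
    return pd.DataFrame({
        "chem_id": chemicals["chem_id"].to_numpy(),
        "fup": fup,
        "clint_hep_uL_min_1e6": np.where(as_hlm, np.nan, clint_hep.round(4)),
        "clint_hlm_uL_min_mg": np.where(as_hlm, (clint_hep * hlm_factor).round(4), np.nan),
        "source": source,
    })


def generate_exposure_table(config: FixtureConfig, chemicals: pd.DataFrame) -> pd.DataFrame:
    """Lognormal exposure medians with p95 >= median by construction."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    covered = chemicals.loc[rng.random(len(chemicals)) < config.exposure_coverage]
    n = len(covered)
    median = 10.0 ** rng.normal(config.exposure_log10_mean, config.exposure_log10_sd, n)
    p95 = median * 10.0 ** np.abs(rng.normal(0.8, 0.3, n))
    return pd.DataFrame({
        "chem_id": covered["chem_id"].to_numpy(),
        "exposure_median_mgkgday": median,
        "exposure_p95_mgkgday": p95,
    })


def _nominal_nam_pod(config: FixtureConfig, chemicals: pd.DataFrame,
                     tk: pd.DataFrame) -> pd.Series:
    """Closed-form NAM-POD proxy the traditional-POD generator offsets from.

    Uses the latent potency and the analytic (no-variability) Css with
    default physiology, floors included — a deterministic stand-in for
    the pipeline's Monte-Carlo POD.
    """
    phys = Physiology()
    merged = chemicals.merge(tk, on="chem_id")
    clint = merged["clint_hep_uL_min_1e6"].fillna(
        merged["clint_hlm_uL_min_mg"].map(lambda v: convert_hlm_clint(v, phys) if pd.notna(v) else np.nan)
    )
    pods = {}
    for row, cl in zip(merged.itertuples(), clint):
        fup = apply_fup_floor(row.fup)
        css = _css_core(fup=fup, clint_hep=cl, mw=row.mw, dose_rate=1.0,
                        liver_mass_per_bw=phys.liver_mass_per_bw,
                        hepatocellularity=phys.hepatocellularity,
                        liver_blood_flow=phys.liver_blood_flow,
                        gfr=phys.gfr, blood_plasma_ratio=phys.blood_plasma_ratio)
        css, _ = apply_css_floor(css)
        pods[row.chem_id] = 10.0 ** row.true_log10_potency / css
    return pd.Series(pods, name="nam_pod_proxy")


def generate_trad_pod_table(
    config: FixtureConfig,
    chemicals: pd.DataFrame,
    tk: pd.DataFrame | None = None,
    nam_pod_reference: pd.Series | None = None,
) -> pd.DataFrame:
    """ToxValDB-style records offset from a NAM-POD reference.

    Valid rows are the reference x 10^(offset_mean + offset_sd * z) with
    accepted units/routes/study/response types; reject rows (ppm units,
    dermal route, acute studies, LD50 response type) are mixed in at
    ``trad_reject_row_rate``.  ``nam_pod_reference`` (indexed by
    chem_id) overrides the internal closed-form proxy, letting callers
    anchor the offset to pipeline-computed PODs.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    if nam_pod_reference is None:
        if tk is None:
            raise ValueError("need tk table or nam_pod_reference")
        nam_pod_reference = _nominal_nam_pod(config, chemicals, tk)
    valid_types = ["NOAEL", "LOAEL", "BMDL", "NOEC", "LOEL", "NEL"]
    rows = []
    for chem_id in chemicals["chem_id"]:
        if chem_id not in nam_pod_reference.index or rng.random() >= config.trad_coverage:
            continue
        ref = nam_pod_reference[chem_id]
        for _ in range(int(rng.integers(1, 4))):
            offset = config.trad_offset_log10_mean + config.trad_offset_log10_sd * rng.standard_normal()
            value = ref * 10.0 ** offset
            if rng.random() < config.trad_reject_row_rate:
                kind = rng.choice(["units", "route", "study", "type"])
                rows.append((chem_id, value,
                             "ppm" if kind == "units" else "mg/kg-day",
                             "dermal" if kind == "route" else "oral",
                             "acute" if kind == "study" else "chronic",
                             "LD50" if kind == "type" else "NOAEL"))
            else:
                rows.append((chem_id, value,
                             str(rng.choice(["mg/kg", "mg/kg-day", "mg/kg/day"])),
                             str(rng.choice(["oral", "gavage"])),
                             str(rng.choice(["developmental", "reproductive", "subchronic",
                                             "chronic", "repeat dose"])),
                             str(rng.choice(valid_types))))
    return pd.DataFrame(rows, columns=["chem_id", "toxval_numeric", "toxval_units",
                                       "exposure_route", "study_type", "toxval_type"])


def generate_downstream_tables(
    config: FixtureConfig, chemicals: pd.DataFrame,
    nam_pod_reference: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(tk, exposure, traditional-POD) tables for one universe."""
    tk = generate_tk_table(config, chemicals)
    exposure = generate_exposure_table(config, chemicals)
    trad = generate_trad_pod_table(config, chemicals, tk=tk,
                                   nam_pod_reference=nam_pod_reference)
    return tk, exposure, trad


FIXTURE_FILES = {
    "chemicals": "chemicals.csv",
    "fingerprints": "fingerprints.csv",
    "assays": "assays.csv",
    "tk": "tk_parameters.csv",
    "exposure": "exposures.csv",
    "trad": "traditional_pods.csv",
}


def write_fixture_dir(config: FixtureConfig, out_dir) -> dict[str, Path]:
    """Generate every input table and write a self-contained fixture directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chem, fps = generate_universe(config)
    assays = generate_assay_table(config, chem)
    tk, exposure, trad = generate_downstream_tables(config, chem)
    paths = {k: out / v for k, v in FIXTURE_FILES.items()}
    chem.to_csv(paths["chemicals"], index=False)
    fps.to_csv(paths["fingerprints"], index_label="chem_id")
    assays.to_csv(paths["assays"], index=False)
    tk.to_csv(paths["tk"], index=False)
    exposure.to_csv(paths["exposure"], index=False)
    trad.to_csv(paths["trad"], index=False)
    with open(out / "fixture_config.yaml", "w") as fh:
        for k, v in asdict(config).items():
            fh.write(f"{k}: {v}\n")
    return paths
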