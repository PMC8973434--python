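"""Traditional in vivo POD harmonization, protectiveness, chemotype enrichment.

Traditional PODs come from heterogeneous study records (ToxValDB-style
rows).  Response types are harmonized to NOAEL/LOAEL/BMDL via the
standard synonym lists, records are restricted to oral/gavage routes,
mg/kg(-day) dose units and the repeat-dose study classes, and the
lowest surviving value per chemical is the traditional POD.  A NAM POD
is protective when it is lower than or equal to the traditional POD.
Chemotype enrichment among non-protective chemicals uses a one-sided
Fisher's exact test per fingerprint bit with Holm step-down adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

RESPONSE_SYNONYMS = {
    # canonical pass-throughs
    "NOAEL": "NOAEL", "LOAEL": "LOAEL", "BMDL": "BMDL",
    # no-effect synonyms
    "NOEC": "NOAEL", "NOAEC": "NOAEL", "NOEL": "NOAEL", "NEL": "NOAEL", "HNEL": "NOAEL",
    # lowest-effect synonyms
    "LOEC": "LOAEL", "LOAEC": "LOAEL", "LOEL": "LOAEL", "LEL": "LOAEL",
}

#: accepted dose-unit spellings, normalized case-insensitively
UNIT_DIALECTS = {
    "mg/kg": "mg/kg",
    "mg/kg-day": "mg/kg-day",
    "mg/kg/day": "mg/kg-day",
    "mg/kg bw/day": "mg/kg-day",
}

ALLOWED_ROUTES = {"oral", "gavage"}
ALLOWED_STUDY_TYPES = {"developmental", "reproductive", "subchronic", "chronic", "repeat dose"}


def harmonize_response_type(raw: str) -> str | None:
    """Map a raw response-type label to NOAEL/LOAEL/BMDL, or None if rejected."""
    if not isinstance(raw, str):
        return None
    return RESPONSE_SYNONYMS.get(raw.strip().upper())


def select_traditional_pod(records: pd.DataFrame) -> float | None:
    """Lowest acceptable traditional POD for one chemical, or None.

    ``records`` columns: ``toxval_numeric, toxval_units, exposure_route,
    study_type, toxval_type``.  A record survives when its units are an
    mg/kg or mg/kg-day dialect, its route is oral or gavage, its study
    type is one of the five repeat-dose classes, and its response type
    harmonizes to NOAEL/LOAEL/BMDL.
    """
    if len(records) == 0:
        return None
    units_ok = records["toxval_units"].astype(str).str.strip().str.lower().isin(UNIT_DIALECTS)
    route_ok = records["exposure_route"].astype(str).str.strip().str.lower().isin(ALLOWED_ROUTES)
    study_ok = records["study_type"].astype(str).str.strip().str.lower().isin(ALLOWED_STUDY_TYPES)
    type_ok = records["toxval_type"].map(harmonize_response_type).notna()
    value_ok = records["toxval_numeric"] > 0
    surviving = records.loc[units_ok & route_ok & study_ok & type_ok & value_ok]
    if len(surviving) == 0:
        return None
    return float(surviving["toxval_numeric"].min())


@dataclass
class ProtectivenessSummary:
    per_chemical: pd.DataFrame
    fraction_protective: float
    median_fold_difference: float  # median of pod_trad / pod_nam on arithmetic scale
    n_pairs: int


def protectiveness_summary(pod_nam: pd.Series, pod_trad: pd.Series) -> ProtectivenessSummary:
    """Per-chemical protectiveness of NAM PODs against traditional PODs.

    Both series are indexed by chem_id in mg/kg-bw/day; only chemicals
    present in both are compared.  A NAM POD is protective when
    pod_nam <= pod_trad.  The aggregate fold difference is the median of
    the arithmetic ratios pod_trad / pod_nam.
    """
    common = pod_nam.index.intersection(pod_trad.index)
    if len(common) == 0:
        raise ValueError("no paired chemicals to compare")
    nam = pod_nam.loc[common].astype(float)
    trad = pod_trad.loc[common].astype(float)
    log10_ratio = np.log10(trad) - np.log10(nam)
    per_chem = pd.DataFrame({
        "chem_id": common,
        "pod_nam": nam.to_numpy(),
        "pod_trad": trad.to_numpy(),
        "log10_ratio": log10_ratio.to_numpy(),
        "protective": (nam <= trad).to_numpy(),
    })
    return ProtectivenessSummary(
        per_chemical=per_chem,
        fraction_protective=float(per_chem["protective"].mean()),
        median_fold_difference=float((trad / nam).median()),
        n_pairs=len(common),
    )


def chemotype_enrichment(
    nonprotective_ids,
    all_ids,
    fingerprints: pd.DataFrame,
    alpha: float = 0.01,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Fingerprint-bit enrichment among non-protective chemicals.

    For every bit with nonzero variance in the tested sample, a 2x2
    table {non-protective vs rest} x {bit set vs unset} is tested with a
    one-sided Fisher's exact test (enrichment direction); p-values are
    Holm-adjusted across the tested bits and a bit is flagged enriched
    when p_holm < ``alpha``.
    """
    all_ids = pd.Index(all_ids).unique()
    nonprot = pd.Index(nonprotective_ids).unique()
    missing = set(all_ids) - set(fingerprints.index)
    if missing:
        raise ValueError(f"fingerprints missing for {sorted(missing)[:5]}")
    fp = fingerprints.loc[all_ids].astype(bool)
    in_group = fp.index.isin(nonprot)
    rows = []
    for bit in fp.columns:
        col = fp[bit].to_numpy()
        if col.all() or not col.any():
            continue  # zero variance in the tested sample
        a = int((col & in_group).sum())  # non-protective, bit set
        b = int((~col & in_group).sum())
        c = int((col & ~in_group).sum())
        d = int((~col & ~in_group).sum())
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        rows.append({"bit": bit, "a": a, "b": b, "c": c, "d": d, "p": float(p)})
    out = pd.DataFrame(rows, columns=["bit", "a", "b", "c", "d", "p"])
    if len(out):
        _, p_holm, _, _ = multipletests(out["p"], method="holm")
        out["p_holm"] = p_holm
        out["enriched"] = out["p_holm"] < alpha
    else:
        out["p_holm"] = pd.Series(dtype=float)
        out["enriched"] = pd.Series(dtype=bool)
    return out.sort_values("p", kind="stable").reset_index(drop=True)
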