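"""Assay-level AC50 quality filtering and per-chemical potency summarization.

qHTS concentration-response pipelines emit one AC50 (μM) per
chemical x assay-endpoint with QC metadata: an active/inactive hit call,
a count of level-6 caution flags, the hit percent across bootstrap
resamples, and a curve-fit category.  Fit categories 36 and 45 mark hill
and gain-loss fits whose AC50 lies above the highest tested
concentration, so those potencies are unreliable and are dropped.  The
surviving active AC50s are pooled per chemical and summarized as the 5th
percentile concentration; chemicals that were tested but retain no
active result carry the maximum tested concentration forward instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

#: curve-fit categories whose AC50 exceeds the tested concentration range
UNRELIABLE_FIT_CATEGORIES = (36, 45)

#: maximum concentration tested (μM); the default potency for inactive chemicals
MAX_TESTED_CONC_UM = 100.0

ASSAY_COLUMNS = [
    "chem_id",
    "endpoint_id",
    "ac50_uM",
    "hit_call",
    "n_flags",
    "hit_percent",
    "fit_category",
    "multi_conc",
]


@dataclass
class FilterReport:
    """Bookkeeping for one filtering pass; reasons may overlap per row."""

    n_input: int
    n_kept: int
    reason_counts: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_kept


def filter_assay_results(results: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the QC filters to an assay-level AC50 table.

    A row is kept iff all of:

    - the hit call is active,
    - it was tested in multiple-concentration format,
    - NOT (>= 3 caution flags AND hit percent < 50) — a row failing only
      one of the two is kept,
    - its fit category is not 36 or 45.

    Returns the kept rows and a :class:`FilterReport` whose per-reason
    counts overlap (one row can trigger several reasons) but whose
    kept + removed total reconciles exactly with the input size.
    """
    df = results
    inactive = ~df["hit_call"].astype(bool)
    single_conc = ~df["multi_conc"].astype(bool)
    flagged = (df["n_flags"] >= 3) & (df["hit_percent"] < 50)
    bad_fit = df["fit_category"].isin(UNRELIABLE_FIT_CATEGORIES)
    removed = inactive | single_conc | flagged | bad_fit
    report = FilterReport(
        n_input=len(df),
        n_kept=int((~removed).sum()),
        reason_counts={
            "inactive_hit_call": int(inactive.sum()),
            "single_concentration": int(single_conc.sum()),
            "flags_and_low_hit_percent": int(flagged.sum()),
            "unreliable_fit_category": int(bad_fit.sum()),
        },
    )
    return df.loc[~removed].copy(), report


def summarize_bioactivity(
    filtered: pd.DataFrame,
    universe: Iterable[str],
    max_tested_conc_uM: float = MAX_TESTED_CONC_UM,
    quantile: float = 0.05,
) -> pd.DataFrame:
    """Collapse filtered active AC50s to one potency per tested chemical.

    Per chemical the 5th percentile of its pooled active AC50s (linear
    interpolation between order statistics, i.e. the type-7 quantile) is
    reported as ``conc5_uM``.  Chemicals in ``universe`` (the tested
    chemicals) with zero surviving actives receive
    ``max_tested_conc_uM`` with ``is_default=True``.  Chemicals appearing
    in ``filtered`` but not in ``universe`` are a data-integrity error.
    """
    universe = pd.Index(universe, name="chem_id").unique()
    extra = set(filtered["chem_id"]) - set(universe)
    if extra:
        raise ValueError(f"chemicals in filtered results but not in universe: {sorted(extra)[:5]}")
    rows = []
    grouped = {k: v["ac50_uM"].to_numpy(dtype=float) for k, v in filtered.groupby("chem_id")}
    for chem_id in universe:
        ac50s = grouped.get(chem_id)
        if ac50s is None or len(ac50s) == 0:
            rows.append((chem_id, float(max_tested_conc_uM), 0, True))
        else:
            conc5 = float(np.percentile(ac50s, 100 * quantile))
            rows.append((chem_id, conc5, len(ac50s), False))
    return pd.DataFrame(rows, columns=["chem_id", "conc5_uM", "n_active", "is_default"])


def read_assay_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(ASSAY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"assay table {path} missing columns {sorted(missing)}")
    return df
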