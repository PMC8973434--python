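"""Bioactivity-exposure ratios, risk bins and TTC comparisons.

The bioactivity-exposure ratio (BER) is the NAM-based POD divided by a
population exposure estimate; on the log scale,
log10 BER = log10 POD - log10 exposure.  Chemicals are binned by
log10 BER into prioritization tiers (< 0, [0, 2), [2, 3), >= 3); the
lowest bins flag chemicals whose bioactive dose approaches estimated
exposure.  Thresholds of toxicological concern (TTC) by Cramer
structural class provide an independent conservative exposure threshold
for cross-checking: Class I 30, Class II 9, Class III 1.5 μg/kg-bw/day
(genotoxicity-specific tiers are out of scope).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ivive import PODRecord

#: TTC by Cramer class, μg/kg-bw/day
TTC_UG_PER_KG_DAY = {"I": 30.0, "II": 9.0, "III": 1.5}

BER_BINS = ("below_0", "zero_to_two", "two_to_three", "above_three")

MG_TO_UG = 1000.0


@dataclass
class ExposureRecord:
    chem_id: str
    exposure_median: float  # mg/kg-bw/day
    exposure_p95: float  # mg/kg-bw/day

    def __post_init__(self):
        if self.exposure_median <= 0 or self.exposure_p95 <= 0:
            raise ValueError(f"{self.chem_id}: exposures must be positive")
        if self.exposure_p95 < self.exposure_median:
            raise ValueError(f"{self.chem_id}: p95 exposure below median")


@dataclass
class BERRecord:
    chem_id: str
    ber: float
    log10_ber: float
    bin: str
    exposure_basis: str  # "median" or "p95"


def bin_ber(log10_ber: float) -> str:
    """Assign a log10 BER to its prioritization bin.

    Half-open convention: (-inf, 0) / [0, 2) / [2, 3) / [3, inf), so
    every finite value maps to exactly one bin.
    """
    if not math.isfinite(log10_ber):
        raise ValueError(f"non-finite log10 BER {log10_ber}")
    if log10_ber < 0:
        return "below_0"
    if log10_ber < 2:
        return "zero_to_two"
    if log10_ber < 3:
        return "two_to_three"
    return "above_three"


def compute_ber(pod: PODRecord, exposure: ExposureRecord, basis: str = "median") -> BERRecord:
    """BER for one chemical against the chosen exposure percentile."""
    if basis not in ("median", "p95"):
        raise ValueError(f"unknown exposure basis {basis!r}")
    denom = exposure.exposure_median if basis == "median" else exposure.exposure_p95
    if pod.pod <= 0 or denom <= 0:
        raise ValueError("POD and exposure must be positive")
    ber = pod.pod / denom
    log10_ber = math.log10(pod.pod) - math.log10(denom)
    return BERRecord(chem_id=pod.chem_id, ber=ber, log10_ber=log10_ber,
                     bin=bin_ber(log10_ber), exposure_basis=basis)


def ttc_assign_and_compare(
    cramer_class: str,
    pod_mgkgday: float | None = None,
    exposure_mgkgday: float | None = None,
) -> dict:
    """Look up the TTC for a Cramer class and compare POD/exposure against it.

    Comparisons are strict (>) in μg/kg-bw/day; exact equality is flagged
    separately.  Absent POD or exposure yields ``None`` flags.
    """
    if cramer_class not in TTC_UG_PER_KG_DAY:
        raise ValueError(f"unknown Cramer class {cramer_class!r}")
    ttc = TTC_UG_PER_KG_DAY[cramer_class]
    out = {
        "ttc_ugkgday": ttc,
        "pod_above_ttc": None,
        "pod_equals_ttc": None,
        "exposure_above_ttc": None,
        "exposure_equals_ttc": None,
    }
    if pod_mgkgday is not None:
        pod_ug = pod_mgkgday * MG_TO_UG
        out["pod_above_ttc"] = pod_ug > ttc
        out["pod_equals_ttc"] = pod_ug == ttc
    if exposure_mgkgday is not None:
        exp_ug = exposure_mgkgday * MG_TO_UG
        out["exposure_above_ttc"] = exp_ug > ttc
        out["exposure_equals_ttc"] = exp_ug == ttc
    return out
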