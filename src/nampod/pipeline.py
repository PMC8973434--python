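"""End-to-end orchestration: inputs to PODs, BERs and comparison tables.

Stage order: assay QC filtering and potency summarization; toxicokinetic
gap-filling (unit conversion, fraction-unbound floor) with measured
parameters taking precedence over predicted ones; eligibility filtering
of predicted parameters; population Monte-Carlo Css with the 0.1 μM
floor; bioactivity PODs for tested chemicals; similarity-weighted
read-across PODs for untested chemicals; bioactivity-exposure ratios and
TTC comparisons; traditional-POD protectiveness and chemotype
enrichment.  A run manifest accounts for every input chemical in exactly
one terminal status.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bioactivity import filter_assay_results, summarize_bioactivity
from .chemistry import tanimoto_cross
from .comparison import chemotype_enrichment, protectiveness_summary, select_traditional_pod
from .genra import (NeighborSet, ReadAcrossPrediction, derive_pod_read_across,
                    find_neighbors, genra_eligible, genra_predict, MIN_ON_BITS)
from .ivive import derive_pod
from .risk import ExposureRecord, bin_ber, compute_ber, ttc_assign_and_compare
from .toxicokinetics import (CssResult, Physiology, apply_css_floor, apply_fup_floor,
                             convert_hlm_clint, css_population, tk_eligibility_filter)

logger = logging.getLogger("nampod.pipeline")

TERMINAL_STATUSES = ("pod_bioactivity", "pod_read_across", "excluded_no_tk",
                     "excluded_tk_ineligible", "out_of_coverage")


@dataclass
class PipelineConfig:
    seed: int = 0
    physiology: Physiology = field(default_factory=Physiology)
    s: float = 0.3
    k: int = 10
    max_tested_conc_uM: float = 100.0
    css_floor_uM: float = 0.1
    fup_lod: float = 0.005
    fup_floor_all_below: bool = False
    dose_rate: float = 1.0  # mg/kg-bw/day
    enrichment_alpha: float = 0.01

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class PipelineResult:
    pods: pd.DataFrame
    bers: pd.DataFrame
    protectiveness: pd.DataFrame
    enrichment: pd.DataFrame
    manifest: dict


class SchemaError(ValueError):
    """Input table violates the expected schema."""


def _require_columns(df: pd.DataFrame, cols, name: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise SchemaError(f"{name} table missing columns {sorted(missing)}")


def _resolve_tk(tk: pd.DataFrame, phys: Physiology, fup_lod: float,
                floor_all_below: bool) -> pd.DataFrame:
    """One TK row per chemical: measured beats predicted; microsomal
    clearances converted to hepatocyte units; fup floored at the LOD."""
    _require_columns(tk, ["chem_id", "fup", "source"], "tk")
    tk = tk.copy()
    for col in ("clint_hep_uL_min_1e6", "clint_hlm_uL_min_mg"):
        if col not in tk.columns:
            tk[col] = np.nan
    tk["_rank"] = (tk["source"] != "measured").astype(int)
    tk = (tk.sort_values(["chem_id", "_rank"], kind="stable")
            .drop_duplicates("chem_id", keep="first")
            .drop(columns="_rank"))
    clint = tk["clint_hep_uL_min_1e6"].to_numpy(dtype=float)
    hlm = tk["clint_hlm_uL_min_mg"].to_numpy(dtype=float)
    need = np.isnan(clint) & ~np.isnan(hlm)
    clint[need] = [convert_hlm_clint(v, phys) for v in hlm[need]]
    if np.isnan(clint).any():
        bad = tk.loc[np.isnan(clint), "chem_id"].tolist()
        raise SchemaError(f"TK rows without any clearance value: {bad[:5]}")
    tk["clint_hep_resolved"] = clint
    tk["fup_floored"] = [apply_fup_floor(v, lod=fup_lod, floor_all_below=floor_all_below)
                         for v in tk["fup"]]
    return tk.reset_index(drop=True)


def run_pipeline(
    chemicals: pd.DataFrame,
    assays: pd.DataFrame,
    tk: pd.DataFrame,
    fingerprints: pd.DataFrame,
    exposures: pd.DataFrame | None = None,
    trad_pods: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full prioritization workflow on in-memory tables.

    ``chemicals`` needs chem_id (unique) plus descriptor and filter
    columns; ``fingerprints`` is the wide 0/1 matrix indexed by chem_id.
    ``exposures`` and ``trad_pods`` are optional: without them the BER
    and comparison outputs are empty.
    """
    config = config or PipelineConfig()
    phys = config.physiology
    _require_columns(chemicals, ["chem_id", "mw"], "chemicals")
    if chemicals["chem_id"].duplicated().any():
        raise SchemaError("duplicate chem_id in chemicals table")
    chem_index = pd.Index(chemicals["chem_id"])
    chem_by_id = chemicals.set_index("chem_id")
    status: dict[str, str] = {}

    # --- bioactivity: QC filter then per-chemical 5th-percentile potency
    _require_columns(assays, ["chem_id", "ac50_uM", "hit_call", "n_flags",
                              "hit_percent", "fit_category", "multi_conc"], "assays")
    unknown = set(assays["chem_id"]) - set(chem_index)
    if unknown:
        raise SchemaError(f"assay rows for chemicals absent from the universe: {sorted(unknown)[:5]}")
    filtered, filter_report = filter_assay_results(assays)
    tested_ids = pd.Index(assays["chem_id"]).unique()
    summary = summarize_bioactivity(filtered, tested_ids,
                                    max_tested_conc_uM=config.max_tested_conc_uM)
    summary = summary.set_index("chem_id")

    # --- toxicokinetics: resolve parameters, eligibility, population Css
    tk_resolved = _resolve_tk(tk, phys, config.fup_lod, config.fup_floor_all_below)
    tk_by_id = tk_resolved.set_index("chem_id")
    seeds = np.random.SeedSequence(config.seed).generate_state(len(chem_index)) % (2**31)
    css_by_id: dict[str, CssResult] = {}
    tk_exclusions: dict[str, list[str]] = {}
    for i, chem_id in enumerate(chem_index):
        if chem_id not in tk_by_id.index:
            status[chem_id] = "excluded_no_tk"
            continue
        row = tk_by_id.loc[chem_id]
        ok, reasons = tk_eligibility_filter(chem_by_id.loc[chem_id], row["source"])
        if not ok:
            status[chem_id] = "excluded_tk_ineligible"
            tk_exclusions[chem_id] = reasons
            continue
        mw = float(chem_by_id.loc[chem_id, "mw"])
        res = css_population(
            tk=pd.Series({"fup": row["fup_floored"], "clint_hep": row["clint_hep_resolved"],
                          "chem_id": chem_id}),
            phys=phys, mw=mw, dose_rate=config.dose_rate, seed=int(seeds[i]))
        res.chem_id = chem_id
        res.css_p95, res.floored = apply_css_floor(res.css_p95, config.css_floor_uM)
        css_by_id[chem_id] = res

    # --- bioactivity PODs for tested chemicals with a usable Css
    pod_records = []
    for chem_id in tested_ids:
        if chem_id not in css_by_id:
            continue  # already carries an exclusion status
        rec = derive_pod(summary.loc[chem_id].to_dict() | {"chem_id": chem_id},
                         css_by_id[chem_id])
        pod_records.append(rec)
        status[chem_id] = "pod_bioactivity"

    # --- read-across PODs for untested chemicals
    n_on = fingerprints.sum(axis=1)
    analog_ids = [c for c in tested_ids
                  if c in fingerprints.index and c in summary.index
                  and genra_eligible(int(summary.loc[c, "n_active"]), int(n_on[c]))]
    target_ids = [c for c in chem_index
                  if c not in set(tested_ids) and c in css_by_id
                  and c in fingerprints.index]
    analog_log10 = np.log10(summary.loc[analog_ids, "conc5_uM"].astype(float))
    analog_conc5 = summary.loc[analog_ids, "conc5_uM"].astype(float).to_dict()
    if target_ids and analog_ids:
        sims = tanimoto_cross(fingerprints.loc[target_ids], fingerprints.loc[analog_ids])
    for chem_id in target_ids:
        if not genra_eligible(None, int(n_on[chem_id]), as_target=True) or not analog_ids:
            status[chem_id] = "out_of_coverage"
            continue
        ns = find_neighbors(chem_id, sims.loc[chem_id], k=config.k, s=config.s)
        if len(ns) == 0:
            status[chem_id] = "out_of_coverage"
            continue
        pred = ReadAcrossPrediction(target_id=chem_id,
                                    predicted_log10_conc=genra_predict(ns, analog_log10),
                                    neighbor_set=ns)
        pod, analog_aeds = derive_pod_read_across(pred, css_by_id[chem_id].css_p95,
                                                  analog_conc5)
        pod.provenance["analog_aeds"] = analog_aeds
        pod.provenance["css_floored"] = css_by_id[chem_id].floored
        pod_records.append(pod)
        status[chem_id] = "pod_read_across"

    # untested chemicals with a Css but no fingerprint row
    for chem_id in chem_index:
        if chem_id not in status:
            status[chem_id] = "out_of_coverage"

    pods = pd.DataFrame([{
        "chem_id": r.chem_id,
        "pod_mgkgday": r.pod,
        "log10_pod": r.log10_pod,
        "pod_type": r.pod_type,
        "conc_used_uM": r.conc_used,
        "css_used_uM": r.css_used,
        "is_default_conc": r.provenance.get("is_default_conc", False),
        "css_floored": r.provenance.get("css_floored", False),
        "n_neighbors": len(r.provenance.get("neighbor_ids", [])),
        "neighbors": ";".join(
            f"{a}:{s:.4f}" for a, s in zip(r.provenance.get("neighbor_ids", []),
                                           r.provenance.get("neighbor_similarities", []))),
    } for r in pod_records])
    pod_by_id = {r.chem_id: r for r in pod_records}

    # --- bioactivity-exposure ratios and TTC comparison
    ber_rows = []
    if exposures is not None and len(pods):
        _require_columns(exposures, ["chem_id", "exposure_median_mgkgday",
                                     "exposure_p95_mgkgday"], "exposures")
        exp_by_id = exposures.drop_duplicates("chem_id").set_index("chem_id")
        for chem_id, rec in pod_by_id.items():
            if chem_id not in exp_by_id.index:
                continue
            row = exp_by_id.loc[chem_id]
            exp = ExposureRecord(chem_id, float(row["exposure_median_mgkgday"]),
                                 float(row["exposure_p95_mgkgday"]))
            ber_med = compute_ber(rec, exp, basis="median")
            ber_p95 = compute_ber(rec, exp, basis="p95")
            cramer = chem_by_id.loc[chem_id].get("cramer_class")
            ttc = (ttc_assign_and_compare(cramer, rec.pod, exp.exposure_median)
                   if isinstance(cramer, str) and cramer else
                   {"ttc_ugkgday": None, "pod_above_ttc": None, "exposure_above_ttc": None})
            ber_rows.append({
                "chem_id": chem_id,
                "pod_mgkgday": rec.pod,
                "pod_type": rec.pod_type,
                "exposure_median_mgkgday": exp.exposure_median,
                "exposure_p95_mgkgday": exp.exposure_p95,
                "ber_median": ber_med.ber,
                "ber_p95": ber_p95.ber,
                "log10_ber_median": ber_med.log10_ber,
                "log10_ber_p95": ber_p95.log10_ber,
                "bin_median": ber_med.bin,
                "bin_p95": ber_p95.bin,
                "ttc_ugkgday": ttc["ttc_ugkgday"],
                "pod_above_ttc": ttc["pod_above_ttc"],
                "exposure_above_ttc": ttc["exposure_above_ttc"],
            })
    bers = pd.DataFrame(ber_rows)

    # --- traditional-POD comparison
    protectiveness = pd.DataFrame()
    enrichment = pd.DataFrame()
    prot_aggregate = None
    if trad_pods is not None and len(trad_pods) and len(pods):
        _require_columns(trad_pods, ["chem_id", "toxval_numeric", "toxval_units",
                                     "exposure_route", "study_type", "toxval_type"],
                         "trad_pods")
        trad_selected = {}
        for chem_id, grp in trad_pods.groupby("chem_id"):
            val = select_traditional_pod(grp)
            if val is not None:
                trad_selected[chem_id] = val
        nam = pd.Series({r.chem_id: r.pod for r in pod_records})
        trad = pd.Series(trad_selected, dtype=float)
        if len(nam.index.intersection(trad.index)):
            prot = protectiveness_summary(nam, trad)
            protectiveness = prot.per_chemical
            prot_aggregate = {
                "fraction_protective": prot.fraction_protective,
                "median_fold_difference": prot.median_fold_difference,
                "n_pairs": prot.n_pairs,
            }
            nonprot = protectiveness.loc[~protectiveness["protective"], "chem_id"]
            compared = [c for c in protectiveness["chem_id"] if c in fingerprints.index]
            if len(nonprot) and len(compared):
                enrichment = chemotype_enrichment(
                    [c for c in nonprot if c in fingerprints.index],
                    compared, fingerprints, alpha=config.enrichment_alpha)

    status_counts = pd.Series(status).value_counts().to_dict()
    manifest = {
        "software_version": __version__,
        "seed": config.seed,
        "config": config.snapshot(),
        "n_chemicals": int(len(chem_index)),
        "assay_filter": {"n_input": filter_report.n_input,
                         "n_kept": filter_report.n_kept,
                         "reason_counts": filter_report.reason_counts},
        "terminal_status_counts": status_counts,
        "terminal_status": status,
        "tk_exclusion_reasons": tk_exclusions,
        "n_pod_bioactivity": int((pods["pod_type"] == "bioactivity").sum()) if len(pods) else 0,
        "n_pod_read_across": int((pods["pod_type"] == "read_across").sum()) if len(pods) else 0,
        "n_bers": int(len(bers)),
        "protectiveness": prot_aggregate,
    }
    assert sum(status_counts.values()) == len(chem_index)
    return PipelineResult(pods=pods, bers=bers, protectiveness=protectiveness,
                          enrichment=enrichment, manifest=manifest)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline_from_files(
    chemicals_csv, assays_csv, tk_csv, fingerprints_csv,
    exposures_csv=None, trad_pods_csv=None, config: PipelineConfig | None = None,
) -> PipelineResult:
    """File-based front end: read the input CSVs, run, record checksums."""
    from .chemistry import read_fingerprints

    paths = {"chemicals": chemicals_csv, "assays": assays_csv, "tk": tk_csv,
             "fingerprints": fingerprints_csv, "exposures": exposures_csv,
             "trad_pods": trad_pods_csv}
    chemicals = pd.read_csv(chemicals_csv)
    assays = pd.read_csv(assays_csv)
    tk = pd.read_csv(tk_csv)
    fps = read_fingerprints(fingerprints_csv)
    exposures = pd.read_csv(exposures_csv) if exposures_csv else None
    trad = pd.read_csv(trad_pods_csv) if trad_pods_csv else None
    result = run_pipeline(chemicals, assays, tk, fps, exposures, trad, config)
    result.manifest["inputs"] = {
        name: {"path": str(p), "sha256_16": _checksum(Path(p))}
        for name, p in paths.items() if p is not None
    }
    return result


def write_outputs(result: PipelineResult, out_dir) -> dict[str, Path]:
    """Write pods/bers/comparison CSVs and the JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("pods", result.pods), ("bers", result.bers),
                     ("protectiveness", result.protectiveness),
                     ("enrichment", result.enrichment)):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    p = out / "manifest.json"
    with open(p, "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
    paths["manifest"] = p
    return paths
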