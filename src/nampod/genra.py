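"""Similarity-weighted generalized read-across (GenRA) for data-poor chemicals.

A target chemical lacking assay data borrows potency from its nearest
structural analogs: the up-to-k analogs with Tanimoto similarity at or
above a threshold s contribute their log10 5th-percentile bioactivity
concentrations in a similarity-weighted mean,

    predicted log10 conc = sum_i S_i * log10(conc_i) / sum_i S_i .

Analogs must themselves be data-rich (more than five active assays and
more than five fingerprint on-bits); targets need only the structural
criterion.  The leave-one-out benchmark sweeps s over a grid and reports
coverage and the fraction of predictions within 10x / 100x of truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chemistry import tanimoto_matrix
from .ivive import PODRecord

DEFAULT_K = 10
DEFAULT_S = 0.3
MIN_ACTIVE_ASSAYS = 5  # strict: need more than this
MIN_ON_BITS = 5  # strict: need more than this


@dataclass
class NeighborSet:
    """Ranked analogs of one target: (analog_id, similarity) pairs.

    Sorted by similarity descending, ties broken by analog_id ascending;
    never contains the target itself; length <= k.
    """

    target_id: str
    neighbors: list[tuple[str, float]]
    s_threshold: float
    k: int = DEFAULT_K

    def __len__(self):
        return len(self.neighbors)

    @property
    def analog_ids(self) -> list[str]:
        return [a for a, _ in self.neighbors]

    @property
    def similarities(self) -> np.ndarray:
        return np.array([s for _, s in self.neighbors], dtype=float)


@dataclass
class ReadAcrossPrediction:
    target_id: str
    predicted_log10_conc: float  # log10 μM
    neighbor_set: NeighborSet
    analog_aeds: list[float] = field(default_factory=list)


def genra_eligible(n_active_assays: int | None, n_on_bits: int, as_target: bool = False) -> bool:
    """Data-richness rule: analogs need >5 active assays and >5 on-bits.

    Targets without any assay data (``as_target=True``) need only the
    structural criterion of more than five fingerprint on-bits.
    """
    if n_on_bits <= MIN_ON_BITS:
        return False
    if as_target:
        return True
    return n_active_assays is not None and n_active_assays > MIN_ACTIVE_ASSAYS


def find_neighbors(
    target_id: str,
    similarities: pd.Series,
    k: int = DEFAULT_K,
    s: float = DEFAULT_S,
    inclusive: bool = True,
) -> NeighborSet:
    """Select up to k most-similar eligible analogs above the s threshold.

    ``similarities``: Tanimoto coefficients indexed by candidate
    analog_id (eligible analogs only).  The threshold is inclusive
    (S_i >= s) by default; ties at the k-th rank break by analog_id
    ascending so results are deterministic.
    """
    sims = similarities.drop(labels=[target_id], errors="ignore")
    qualified = sims[sims >= s] if inclusive else sims[sims > s]
    order = sorted(qualified.items(), key=lambda kv: (-kv[1], kv[0]))
    return NeighborSet(target_id=target_id, neighbors=[(a, float(v)) for a, v in order[:k]],
                       s_threshold=s, k=k)


def genra_predict(neighbors: NeighborSet, analog_log10_conc: Mapping[str, float]) -> float:
    """Similarity-weighted mean of analog log10 potencies.

    Raises on an empty neighbor set (the chemical is out of coverage)
    or on a missing analog potency.
    """
    if len(neighbors) == 0:
        raise ValueError(f"{neighbors.target_id}: empty neighbor set, no prediction")
    weights = neighbors.similarities
    try:
        values = np.array([analog_log10_conc[a] for a in neighbors.analog_ids], dtype=float)
    except KeyError as err:
        raise KeyError(f"missing potency for analog {err.args[0]!r}") from err
    return float(np.sum(weights * values) / np.sum(weights))


def derive_pod_read_across(
    prediction: ReadAcrossPrediction,
    css_p95_target: float,
    analog_conc5_uM: Mapping[str, float] | None = None,
) -> tuple[PODRecord, list[float]]:
    """Read-across POD: predicted concentration over the target's Css.

    Also returns the per-analog AEDs (each analog's 5th-percentile
    concentration over the *target's* Css), the diagnostic spread shown
    alongside the read-across POD.
    """
    if css_p95_target <= 0:
        raise ValueError("target Css must be positive")
    conc = 10.0 ** prediction.predicted_log10_conc
    analog_aeds = []
    if analog_conc5_uM is not None:
        analog_aeds = [analog_conc5_uM[a] / css_p95_target
                       for a in prediction.neighbor_set.analog_ids if a in analog_conc5_uM]
    pod = PODRecord(
        chem_id=prediction.target_id,
        pod=conc / css_p95_target,
        pod_type="read_across",
        conc_used=conc,
        css_used=css_p95_target,
        provenance={
            "neighbor_ids": prediction.neighbor_set.analog_ids,
            "neighbor_similarities": list(prediction.neighbor_set.similarities),
            "s_threshold": prediction.neighbor_set.s_threshold,
        },
    )
    return pod, analog_aeds


def benchmark_s_grid(
    fingerprints: pd.DataFrame,
    conc5_uM: pd.Series,
    n_active: pd.Series,
    s_grid: Sequence[float] = tuple(np.round(np.arange(0.1, 0.81, 0.1), 2)),
    k: int = DEFAULT_K,
    fingerprint_type: str = "unspecified",
) -> pd.DataFrame:
    """Leave-one-out read-across benchmark over a similarity threshold grid.

    Each eligible chemical in turn plays the data-poor target; its own
    potency is hidden and predicted from the remaining eligible analogs.
    Per s value the table reports coverage (fraction of targets with at
    least one neighbor) and, among covered targets, the fraction whose
    prediction is within 10-fold (|Δlog10| <= 1) and 100-fold
    (|Δlog10| <= 2) of the true value.
    """
    s_grid = list(s_grid)
    if not s_grid:
        raise ValueError("empty s grid")
    n_on = fingerprints.sum(axis=1)
    eligible = [c for c in fingerprints.index
                if genra_eligible(int(n_active.get(c, 0)), int(n_on[c]))
                and c in conc5_uM.index]
    if len(eligible) < 2:
        raise ValueError("need at least two eligible chemicals for leave-one-out")
    fps = fingerprints.loc[eligible]
    sim = tanimoto_matrix(fps)
    log10_true = np.log10(conc5_uM.loc[eligible].astype(float))
    rows = []
    for s in s_grid:
        n_covered = 0
        errors = []
        for target in eligible:
            ns = find_neighbors(target, sim[target], k=k, s=s)
            if len(ns) == 0:
                continue
            n_covered += 1
            pred = genra_predict(ns, log10_true)
            errors.append(abs(pred - log10_true[target]))
        errors = np.array(errors)
        rows.append({
            "fingerprint_type": fingerprint_type,
            "s": s,
            "n_targets": len(eligible),
            "coverage": n_covered / len(eligible),
            "frac_within_10x": float(np.mean(errors <= 1.0)) if len(errors) else np.nan,
            "frac_within_100x": float(np.mean(errors <= 2.0)) if len(errors) else np.nan,
        })
    return pd.DataFrame(rows)
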