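"""Steady-state plasma concentration (Css) modelling at 1 mg/kg-bw/day.

The model is the analytic three-compartment (gut, liver, rest-of-body)
steady state with well-stirred hepatic clearance: at a constant oral
dose rate the plasma concentration is

    Css = molar dose rate / (renal clearance + hepatic clearance)

with renal clearance ``GFR x fup`` (glomerular filtration of the unbound
fraction) and hepatic clearance the well-stirred form
``Q fup CLint_w / (Q + fup CLint_w)``, where Q is hepatic blood flow
(times the blood:plasma ratio) and CLint_w the intrinsic clearance
scaled from per-10^6-hepatocytes to the whole liver.  All clearances are
expressed per kg body weight so body weight cancels from the point
estimate; it is still varied in the population simulation for parity
with the physiological parameter set.

Population variability is emulated by redrawing six parameters (liver
mass, hepatocellularity, hepatic blood flow, body weight, GFR and
intrinsic clearance) from independent normals truncated at zero with a
30% coefficient of variation, computing Css per draw, and reporting the
95th percentile — the conservative (high-Css, low-dose) end of the
population distribution.

Microsomal clearances (μL/min/mg protein) are converted to hepatocyte
units with the standard scaling factors 32 mg microsomal protein per g
liver and 99x10^6 cells per g liver.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import stats

from .chemistry import rule_of_five_violations, MissingDescriptorError

#: default floor for the fraction unbound in plasma (assay limit of detection)
FUP_LOD = 0.005

#: default floor for the population Css used in dose extrapolation (μM)
CSS_FLOOR_UM = 0.1


@dataclass
class TKParameters:
    """Chemical-specific toxicokinetic inputs.

    At least one of ``clint_hep`` (μL/min/10^6 hepatocytes) or
    ``clint_hlm`` (μL/min/mg microsomal protein) must be present; the
    latter is converted via :func:`convert_hlm_clint`.  ``source`` tags
    whether the parameters are measured in vitro or predicted in silico —
    only predicted parameters go through the eligibility filter.
    """

    chem_id: str
    fup: float
    clint_hep: float | None = None
    clint_hlm: float | None = None
    source: str = "measured"

    def __post_init__(self):
        if self.clint_hep is None and self.clint_hlm is None:
            raise ValueError(f"{self.chem_id}: need clint_hep or clint_hlm")
        if not 0 <= self.fup <= 1:
            raise ValueError(f"{self.chem_id}: fup={self.fup} outside [0, 1]")


@dataclass
class Physiology:
    """Human physiological constants of the steady-state model.

    Defaults describe a reference adult (70 kg, 1.8 kg liver, GFR
    ~107 mL/min scaled per kg).  The hepatocellularity used to scale
    intrinsic clearance to the whole liver (110x10^6 cells/g) is kept
    separate from the 99x10^6 cells/g constant of the microsome unit
    conversion so the two conventions are never silently conflated.
    """

    body_weight: float = 70.0  # kg
    liver_mass_per_bw: float = 25.7  # g liver per kg BW (1.8 kg / 70 kg)
    hepatocellularity: float = 110.0  # 10^6 cells per g liver (whole-liver scaling)
    microsomal_protein_per_g_liver: float = 32.0  # mg/g, unit-conversion constant
    microsome_cells_per_g_liver: float = 99.0  # 10^6 cells/g, unit-conversion constant
    liver_blood_flow: float = 1.30  # L/h per kg BW
    gfr: float = 0.103  # L/h per kg BW (~107 mL/min for 70 kg)
    blood_plasma_ratio: float = 1.0
    cv: float = 0.30  # coefficient of variation of the population draws
    n_draws: int = 1000

    #: parameters redrawn by the population simulator
    VARIED: tuple = ("liver_mass_per_bw", "hepatocellularity", "liver_blood_flow",
                     "body_weight", "gfr")


@dataclass
class CssResult:
    chem_id: str
    css_point: float  # μM, analytic value at nominal physiology
    css_p95: float  # μM, 95th percentile over population draws (post-floor)
    floored: bool = False
    n_draws: int = 0
    seed: int | None = None
    clint_draws: np.ndarray | None = None
    css_draws: np.ndarray | None = None


def convert_hlm_clint(clint_hlm: float, phys: Physiology | None = None) -> float:
    """Convert microsomal clearance (μL/min/mg) to μL/min/10^6 hepatocytes.

    clint_hep = clint_hlm x (32 mg microsomal protein / g liver)
                          x (1 g liver / 99x10^6 cells)
    """
    phys = phys or Physiology()
    clint_hlm = np.asarray(clint_hlm, dtype=float)
    if np.any(clint_hlm < 0):
        raise ValueError("microsomal clearance must be non-negative")
    out = clint_hlm * phys.microsomal_protein_per_g_liver / phys.microsome_cells_per_g_liver
    return float(out) if out.ndim == 0 else out


def apply_fup_floor(fup: float, lod: float = FUP_LOD, floor_all_below: bool = False) -> float:
    """Floor the fraction unbound at the assay limit of detection.

    By default only an exact zero is replaced by ``lod``; with
    ``floor_all_below`` any value below the limit is raised to it.
    """
    if not 0 <= fup <= 1:
        raise ValueError(f"fup={fup} outside [0, 1]")
    if fup == 0 or (floor_all_below and fup < lod):
        return lod
    return fup


def hepatic_clearance_well_stirred(fup: float, clint_whole: float, q: float) -> float:
    """Well-stirred liver model: CL_h = Q fup CLint / (Q + fup CLint).

    Bounded above by the blood flow Q (perfusion limit) for any CLint.
    """
    x = fup * clint_whole
    return q * x / (q + x) if np.ndim(x) == 0 else q * x / (q + x)


def css_analytic(tk, phys: Physiology | None = None, mw: float = None,
                 dose_rate: float = 1.0) -> float:
    """Analytic steady-state plasma concentration in μM.

    ``tk`` is a :class:`TKParameters` (fup post-floor, clint in
    hepatocyte units) or any object with ``fup``/``clint_hep``; ``mw`` is
    the molecular weight in Da and ``dose_rate`` the constant oral dose
    rate in mg/kg-bw/day.  Unit chain: dose_rate/mw x 1000 gives
    μmol/kg/day; clearances are converted to L/day/kg, so the quotient is
    μmol/L = μM.
    """
    if mw is None or mw <= 0:
        raise ValueError("molecular weight must be positive")
    fup = tk.fup if hasattr(tk, "fup") else tk["fup"]
    clint = tk.clint_hep if hasattr(tk, "clint_hep") else tk["clint_hep"]
    phys = phys or Physiology()
    return _css_core(
        fup=fup,
        clint_hep=clint,
        mw=mw,
        dose_rate=dose_rate,
        liver_mass_per_bw=phys.liver_mass_per_bw,
        hepatocellularity=phys.hepatocellularity,
        liver_blood_flow=phys.liver_blood_flow,
        gfr=phys.gfr,
        blood_plasma_ratio=phys.blood_plasma_ratio,
    )


def _css_core(fup, clint_hep, mw, dose_rate, liver_mass_per_bw, hepatocellularity,
              liver_blood_flow, gfr, blood_plasma_ratio):
    """Vectorizable steady-state core; all clearance terms per kg BW."""
    # μL/min/10^6 cells -> L/h/kg BW: x cells/g x g/kg x 60 min/h x 1e-6 L/μL
    clint_whole = clint_hep * hepatocellularity * liver_mass_per_bw * 60.0 * 1e-6
    q = liver_blood_flow * blood_plasma_ratio
    cl_hepatic = hepatic_clearance_well_stirred(fup, clint_whole, q)  # L/h/kg
    cl_renal = gfr * fup  # L/h/kg
    cl_total = (cl_hepatic + cl_renal) * 24.0  # L/day/kg
    dose_umol = dose_rate / mw * 1000.0  # μmol/kg/day
    return dose_umol / cl_total


def _truncated_normal(rng, mean, cv, size):
    """Normal(mean, cv*mean) truncated at zero; degenerate when cv == 0."""
    if cv == 0:
        return np.full(size, mean, dtype=float)
    z = stats.truncnorm.rvs(-1.0 / cv, np.inf, loc=1.0, scale=cv, size=size,
                            random_state=rng)
    return mean * z


def css_population(tk, phys: Physiology | None = None, mw: float = None,
                   dose_rate: float = 1.0, seed: int | None = None,
                   keep_draws: bool = False) -> CssResult:
    """Population Monte-Carlo Css: redraw physiology + clearance, report p95.

    Six parameters (liver mass per BW, hepatocellularity, hepatic blood
    flow, body weight, GFR, intrinsic clearance) are sampled
    independently from zero-truncated normals with sd = cv x nominal;
    Css is computed per draw and the 95th percentile (linear
    interpolation) returned alongside the analytic point value.  With
    ``cv = 0`` the distribution is degenerate and css_p95 equals
    css_point exactly.  Reproducible for a given ``seed``.
    """
    phys = phys or Physiology()
    if phys.n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    fup = tk.fup if hasattr(tk, "fup") else tk["fup"]
    clint = tk.clint_hep if hasattr(tk, "clint_hep") else tk["clint_hep"]
    chem_id = getattr(tk, "chem_id", None) or "unknown"
    rng = np.random.default_rng(seed)
    n = phys.n_draws
    varied = {name: _truncated_normal(rng, getattr(phys, name), phys.cv, n)
              for name in Physiology.VARIED}
    clint_draws = _truncated_normal(rng, clint, phys.cv, n) if clint > 0 else np.zeros(n)
    css_draws = _css_core(
        fup=fup,
        clint_hep=clint_draws,
        mw=mw,
        dose_rate=dose_rate,
        liver_mass_per_bw=varied["liver_mass_per_bw"],
        hepatocellularity=varied["hepatocellularity"],
        liver_blood_flow=varied["liver_blood_flow"],
        gfr=varied["gfr"],
        blood_plasma_ratio=phys.blood_plasma_ratio,
    )
    # body_weight draws are generated for parity with the physiological set but
    # cancel from the per-kg formulation
    point = css_analytic(tk, phys, mw=mw, dose_rate=dose_rate)
    p95 = float(np.percentile(css_draws, 95))
    if phys.cv == 0:
        p95 = point
    return CssResult(
        chem_id=chem_id,
        css_point=point,
        css_p95=p95,
        floored=False,
        n_draws=n,
        seed=seed,
        clint_draws=clint_draws if keep_draws else None,
        css_draws=css_draws if keep_draws else None,
    )


def apply_css_floor(css: float, floor: float = CSS_FLOOR_UM) -> tuple[float, bool]:
    """Clamp a Css from below at the conservative cut-off (default 0.1 μM).

    Returns (value, floored); the flag is set only when the input was
    strictly below the floor.
    """
    if css < 0:
        raise ValueError(f"negative Css {css}")
    if css < floor:
        return floor, True
    return float(css), False


def tk_eligibility_filter(record, source: str) -> tuple[bool, list[str]]:
    """Decide whether a chemical's TK parameters are usable for IVIVE.

    Chemicals with *predicted* parameters fail when any of: a Lipinski
    rule-of-five violation, fraction absorbed < 0.1, fraction
    bioavailable < 0.1, or outside the prediction applicability domain
    (the filters bound the uncertainty of the in silico models, which
    were trained mainly on pharmaceutical chemical space).  Measured
    parameters bypass every filter.  All applicable failure reasons are
    reported.
    """
    if source == "measured":
        return True, []
    if source != "predicted":
        raise ValueError(f"unknown TK source {source!r}")
    get = record.get if isinstance(record, Mapping) else lambda f, d=None: getattr(record, f, d)
    reasons: list[str] = []
    try:
        reasons.extend(f"ro5:{v}" for v in rule_of_five_violations(record))
    except MissingDescriptorError as err:
        reasons.append(f"missing_field:{err.field}")
    for fld, tag in (("fraction_absorbed", "fabs<0.1"), ("fraction_bioavailable", "fbio<0.1")):
        v = get(fld)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            reasons.append(f"missing_field:{fld}")
        elif v < 0.1:
            reasons.append(tag)
    in_ad = get("in_applicability_domain")
    if in_ad is None:
        reasons.append("missing_field:in_applicability_domain")
    elif not in_ad:
        reasons.append("out_of_applicability_domain")
    return (len(reasons) == 0), reasons
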