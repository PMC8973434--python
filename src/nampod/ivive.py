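"""In vitro to in vivo extrapolation: concentrations to administered doses.

Under the linear steady-state assumption, the administered equivalent
dose (AED) that produces a plasma concentration equal to an in vitro
bioactivity concentration is

    AED (mg/kg-bw/day) = bioactivity concentration (μM) x 1 mg/kg/day / Css (μM)

with Css the steady-state plasma concentration at a constant dose rate
of 1 mg/kg-bw/day.  The per-chemical point of departure is the AED of
the 5th percentile bioactivity concentration over the 95th percentile
population Css.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .toxicokinetics import CssResult


@dataclass
class PODRecord:
    """One chemical's point of departure with full provenance."""

    chem_id: str
    pod: float  # mg/kg-bw/day
    pod_type: str  # "bioactivity" or "read_across"
    conc_used: float  # μM
    css_used: float  # μM
    provenance: dict = field(default_factory=dict)

    @property
    def log10_pod(self) -> float:
        return float(np.log10(self.pod))


def aed_from_css(conc: float, css: float, dose_rate: float = 1.0) -> float:
    """Administered equivalent dose (mg/kg-bw/day) for one concentration."""
    if conc <= 0 or css <= 0:
        raise ValueError(f"conc and css must be positive (conc={conc}, css={css})")
    return conc / css * dose_rate


def derive_pod(summary, css: CssResult, css_floored_value: float | None = None) -> PODRecord:
    """POD from a bioactivity summary row and a population Css result.

    ``summary`` is a mapping/row with ``chem_id, conc5_uM, is_default``;
    ``css_floored_value`` is the post-floor 95th-percentile Css (defaults
    to ``css.css_p95``, which callers floor beforehand).
    """
    get = summary.get if hasattr(summary, "get") else lambda f: getattr(summary, f)
    css_val = css.css_p95 if css_floored_value is None else css_floored_value
    conc5 = float(get("conc5_uM"))
    return PODRecord(
        chem_id=get("chem_id"),
        pod=aed_from_css(conc5, css_val),
        pod_type="bioactivity",
        conc_used=conc5,
        css_used=css_val,
        provenance={
            "is_default_conc": bool(get("is_default")),
            "css_floored": bool(css.floored),
            "n_draws": css.n_draws,
        },
    )


def per_assay_aeds(ac50s_uM, css_uM: float) -> np.ndarray:
    """Diagnostic AED vector: every surviving AC50 over one Css."""
    ac50s = np.asarray(ac50s_uM, dtype=float)
    if np.any(ac50s <= 0) or css_uM <= 0:
        raise ValueError("AC50s and Css must be positive")
    return ac50s / css_uM
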