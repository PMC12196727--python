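"""Reverse dosimetry: in vitro PODs to oral equivalent doses.

The oral equivalent dose (OED) of an in vitro point of departure (POD, µM)
is the daily oral dose producing a matching steady-state plasma
concentration:

    OED [mg/kg/day] = POD_in vitro / Css,1 mg/kg/day

where Css per unit dose comes from an analytic well-stirred steady state
(renal clearance GFR·fub plus flow-limited hepatic clearance).  The
bioavailability-adjusted variant replaces the nominal in vitro concentration
with the free one and the total plasma concentration with the free one:

    OED_adjusted = OED × fub_media / fub_plasma

The ratio fub_media/fub_plasma is the *correction factor* a
nominal-concentration IVIVE would need.  Media free fractions come from any
of the distribution models; plasma free fractions and clearances are
user-supplied toxicokinetic parameters.

Two internal threshold-of-toxicological-concern (iTTC) constants are
available as built-in constant-POD modes: 0.01 µM (internal NOAEL, i.e.
iTTC before the 100-fold safety factor) and 1 µM (iTTC proper).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PhysiologyConfig
from .errors import ValidationError, VitrodistError
from .evaluation import MetricsResult, compute_metrics

ITTC_NOAEL_UM = 0.01  # internal NOAEL: iTTC prior to the 100-fold safety factor
ITTC_UM = 1.0  # iTTC without safety factors

POD_IN_VITRO = "in_vitro_uM"
POD_IN_VIVO = "in_vivo_mg_kg_day"


@dataclass
class TKParams:
    """Per-chemical toxicokinetic parameters for the steady-state model."""

    chemical_id: str
    fub_plasma: float  # fraction unbound in plasma, (0, 1]
    clint: float = 0.0  # µL/min/10⁶ hepatocytes
    gfr: float | None = None  # L/h; None → physiology default
    q_liver: float | None = None  # L/h
    body_weight: float | None = None  # kg
    hepatocellularity: float | None = None  # 1e6 cells/g liver
    liver_mass: float | None = None  # g
    f_abs: float | None = None

    def __post_init__(self):
        if not (0.0 < self.fub_plasma <= 1.0):
            raise ValidationError("fub_plasma", f"{self.fub_plasma} outside (0, 1]")
        if self.clint < 0:
            raise ValidationError("clint", "must be >= 0")


@dataclass
class PODRecord:
    chemical_id: str
    kind: str  # {in_vitro_uM, in_vivo_mg_kg_day}
    value: float
    ci_lower: float | None = None
    ci_upper: float | None = None

    def __post_init__(self):
        if self.value <= 0:
            raise ValidationError("value", "POD must be positive")
        if self.ci_lower is not None and self.ci_upper is not None:
            if not (self.ci_lower <= self.value <= self.ci_upper):
                raise ValidationError("ci", "value outside [ci_lower, ci_upper]")


@dataclass
class QIVIVEResult:
    chemical_id: str
    css_1mgkg: float  # µM at steady state per 1 mg/kg/day
    oed: float  # mg/kg/day
    oed_adjusted: float  # mg/kg/day
    correction_factor: float  # fub_media / fub_plasma


def _resolve(tk: TKParams, phys: PhysiologyConfig, name: str) -> float:
    value = getattr(tk, name)
    return getattr(phys, name) if value is None else value


def css_steady_state(tk: TKParams, mw: float, phys: PhysiologyConfig | None = None) -> float:
    """Steady-state plasma concentration (µM) under 1 mg/kg/day oral dosing.

    Analytic well-stirred form: dose rate divided by total clearance,
    CL_total = GFR·fub + Q_h·fub·CLint_scaled/(Q_h + fub·CLint_scaled),
    with CLint scaled from µL/min/10⁶ cells by hepatocellularity and liver
    mass.  No empirical adjustment is applied to fub or CLint.
    """
    cfg = phys or PhysiologyConfig()
    if mw <= 0:
        raise ValidationError("mw", "molar mass must be positive")
    bw = _resolve(tk, cfg, "body_weight")
    gfr = _resolve(tk, cfg, "gfr")
    q_liver = _resolve(tk, cfg, "q_liver")
    hep = _resolve(tk, cfg, "hepatocellularity")
    liver = _resolve(tk, cfg, "liver_mass")
    f_abs = _resolve(tk, cfg, "f_abs")

    # 1 mg/kg/day × BW kg = BW mg/day → µmol/h
    dose_rate = f_abs * bw / mw * 1000.0 / 24.0  # µmol/h
    # µL/min/1e6 cells × 1e6 cells/g × g × 60 min/h × 1e-6 L/µL → L/h
    clint_scaled = tk.clint * hep * liver * 60.0 * 1e-6
    fu = tk.fub_plasma
    cl_renal = gfr * fu
    cl_hepatic = (
        q_liver * fu * clint_scaled / (q_liver + fu * clint_scaled)
        if clint_scaled > 0
        else 0.0
    )
    cl_total = cl_renal + cl_hepatic  # L/h
    if cl_total <= 0:
        raise VitrodistError(f"{tk.chemical_id}: zero total clearance, Css undefined")
    return dose_rate / cl_total  # µmol/L = µM


def oed(pod_invitro: float, css: float) -> float:
    """Oral equivalent dose (mg/kg/day) of an in vitro POD (µM)."""
    if pod_invitro <= 0 or css <= 0:
        raise ValidationError("oed", "pod and css must be positive")
    return pod_invitro / css


def oed_adjusted(pod_invitro: float, css: float, fub_media: float, fub_plasma: float) -> float:
    """Bioavailability-adjusted OED: POD·fub_media / (Css·fub_plasma)."""
    for name, value in (("fub_media", fub_media), ("fub_plasma", fub_plasma)):
        if not (0.0 < value <= 1.0):
            raise ValidationError(name, f"{value} outside (0, 1]")
    return oed(pod_invitro, css) * fub_media / fub_plasma


def qivive_chemical(
    chemical_id: str,
    pod_invitro: float,
    tk: TKParams,
    mw: float,
    fub_media: float,
    phys: PhysiologyConfig | None = None,
) -> QIVIVEResult:
    """Full QIVIVE for one chemical: Css, both OED variants, correction factor."""
    css = css_steady_state(tk, mw, phys)
    base = oed(pod_invitro, css)
    adjusted = oed_adjusted(pod_invitro, css, fub_media, tk.fub_plasma)
    return QIVIVEResult(
        chemical_id=chemical_id,
        css_1mgkg=css,
        oed=base,
        oed_adjusted=adjusted,
        correction_factor=fub_media / tk.fub_plasma,
    )


def concordance(oeds: dict, pods_invivo: list[PODRecord]) -> MetricsResult:
    """In vitro–in vivo concordance of OEDs against in vivo PODs.

    Matches chemicals between the two sets and delegates to
    :func:`~vitrodist.evaluation.compute_metrics`.  When every in vivo POD
    carries a confidence interval, statistics are weighted by the inverse
    variance, with SE taken as the log10 CI half-width / 1.96; otherwise
    unweighted.
    """
    in_vivo = {p.chemical_id: p for p in pods_invivo if p.kind == POD_IN_VIVO}
    common = [cid for cid in oeds if cid in in_vivo]
    if not common:
        raise VitrodistError("no overlapping chemicals between OEDs and in vivo PODs")
    pred = np.array([oeds[cid] for cid in common])
    obs = np.array([in_vivo[cid].value for cid in common])
    weights = None
    if all(in_vivo[cid].ci_lower is not None and in_vivo[cid].ci_upper is not None
           for cid in common):
        se = np.array([
            (np.log10(in_vivo[cid].ci_upper) - np.log10(in_vivo[cid].ci_lower)) / 2.0 / 1.96
            for cid in common
        ])
        weights = 1.0 / np.maximum(se, 1e-12) ** 2
    return compute_metrics(pred, obs, weights=weights)
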