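"""Time-dependent distribution models.

Two kinetic flavors complement the equilibrium models:

* ``permeability_metabolism`` — permeability-limited cellular uptake with
  optional first-order intracellular metabolic clearance; applicable to
  neutral and ionizable chemicals.
* ``neutral_fate`` — neutral chemicals only, with optional evaporation,
  abiotic degradation, and cell growth.

Mechanics: the medium (water + serum constituents) is treated as one
well-mixed pool with instantaneous internal equilibrium, so its free
concentration is ``c_free = a_media / κ_media``.  Every other compartment
relaxes first-order toward its partition-equilibrium target,
``da_i/dt = k_i · (c_free·κ_i − a_i)``, with capacities κ_i shared with the
equilibrium models.  Loss processes (metabolism, degradation, evaporation)
drain into explicit ledgers so mass is conserved along the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .chem_param import NEUTRAL, Chemical, resolve_speciation
from .config import Config, KineticConfig
from .equilibrium import (
    FULL_SYSTEM,
    MEDIA_COMPARTMENTS,
    DistributionResult,
    _package,
    capacities,
)
from .errors import ApplicabilityError, VitrodistError
from .test_system import ExposureSystem

PERMEABILITY_METABOLISM = "permeability_metabolism"
NEUTRAL_FATE = "neutral_fate"
KINETIC_FLAVORS = (PERMEABILITY_METABOLISM, NEUTRAL_FATE)

# state vector layout
_MEDIA, _CELL, _PLASTIC, _HEAD, _MET, _DEG, _EVAP = range(7)
LOSS_LABELS = ("metabolized", "degraded", "evaporated")


@dataclass
class TimeCourse:
    """Dense solution of the kinetic mass balance for one well."""

    times: np.ndarray  # h
    states: np.ndarray  # (7, n_times) nmol
    chem: Chemical
    sys: ExposureSystem
    flavor: str
    cfg: KineticConfig
    caps: dict  # equilibrium capacities (mL) at t = 0
    _sol: object = None

    @property
    def dose(self) -> float:
        return self.sys.dose_nmol

    def totals(self) -> np.ndarray:
        """Compartments + loss ledgers at every stored time (nmol)."""
        return self.states.sum(axis=0)


def simulate_timecourse(
    chem: Chemical,
    sys: ExposureSystem,
    flavor: str = PERMEABILITY_METABOLISM,
    cfg: KineticConfig | None = None,
    config: Config | None = None,
    n_times: int = 97,
) -> TimeCourse:
    """Integrate the kinetic mass balance from an all-in-media start.

    The ``neutral_fate`` flavor refuses ionizable chemicals (applicability
    domain).  Returns dense output on a uniform grid of ``n_times`` points
    over [0, t_end].
    """
    kcfg = cfg or KineticConfig()
    conf = config or Config()
    if flavor not in KINETIC_FLAVORS:
        raise ValueError(f"unknown flavor {flavor!r}; choose from {KINETIC_FLAVORS}")

    speciation = resolve_speciation(
        chem.pka_acid, chem.pka_base, sys.medium.ph, conf.chem_param.speciation_window
    )
    if flavor == NEUTRAL_FATE and speciation.ioc_class != NEUTRAL:
        raise ApplicabilityError(
            f"{chem.id}: the neutral-fate flavor is only applicable to neutral "
            f"chemicals (speciation gives {speciation.ioc_class!r})"
        )

    caps = capacities(chem, sys, FULL_SYSTEM, conf)
    kappa_media = sum(caps[c] for c in MEDIA_COMPARTMENTS)
    kappa_cell0 = caps["cell_water"] + caps["cell_lipid"] + caps["cell_protein"]
    kappa_plastic = caps["plastic"]
    kappa_head = caps["headspace"]

    clint = kcfg.clint if flavor == PERMEABILITY_METABOLISM else 0.0
    k_deg = kcfg.k_deg if flavor == NEUTRAL_FATE else 0.0
    k_evap = kcfg.k_evap if (flavor == NEUTRAL_FATE and not sys.labware.sealed) else 0.0
    growth = kcfg.cell_growth_rate if flavor == NEUTRAL_FATE else 0.0

    k_cell = kcfg.k_cell_exchange
    k_plast = kcfg.k_plastic_exchange
    k_air = kcfg.k_air_exchange

    def rhs(t, y):
        a_media, a_cell, a_plastic, a_head = y[_MEDIA], y[_CELL], y[_PLASTIC], y[_HEAD]
        c_free = a_media / kappa_media
        kappa_cell = kappa_cell0 * np.exp(growth * t)
        j_cell = k_cell * (c_free * kappa_cell - a_cell)
        j_plastic = k_plast * (c_free * kappa_plastic - a_plastic)
        j_head = k_air * (c_free * kappa_head - a_head)
        dydt = np.empty(7)
        dydt[_MEDIA] = -j_cell - j_plastic - j_head - k_deg * a_media
        dydt[_CELL] = j_cell - clint * a_cell
        dydt[_PLASTIC] = j_plastic
        dydt[_HEAD] = j_head - k_evap * a_head
        dydt[_MET] = clint * a_cell
        dydt[_DEG] = k_deg * a_media
        dydt[_EVAP] = k_evap * a_head
        return dydt

    y0 = np.zeros(7)
    y0[_MEDIA] = sys.dose_nmol
    times = np.linspace(0.0, kcfg.t_end, n_times)
    sol = solve_ivp(
        rhs,
        (0.0, kcfg.t_end),
        y0,
        method="LSODA",
        t_eval=times,
        dense_output=True,
        rtol=kcfg.solver_rel_tol,
        atol=kcfg.solver_abs_tol,
    )
    if not sol.success:
        raise VitrodistError(f"integration failed for {chem.id}: {sol.message}")
    return TimeCourse(
        times=times, states=sol.y, chem=chem, sys=sys, flavor=flavor, cfg=kcfg,
        caps=caps, _sol=sol.sol,
    )


def distribution_at_time(tc: TimeCourse, t: float) -> DistributionResult:
    """Package the interpolated state at time ``t`` as a DistributionResult.

    The lumped media pool is split into water/serum-protein/serum-lipid in
    proportion to their capacities (internal equilibrium); the cell pool is
    split likewise using the growth-scaled cell capacity.  Loss ledgers are
    reported in ``losses`` and excluded from the compartment sum.
    """
    if not (0.0 <= t <= tc.cfg.t_end):
        raise VitrodistError(f"t={t} outside simulated range [0, {tc.cfg.t_end}]")
    y = tc._sol(t)
    caps = tc.caps
    kappa_media = sum(caps[c] for c in MEDIA_COMPARTMENTS)
    growth = tc.cfg.cell_growth_rate if tc.flavor == NEUTRAL_FATE else 0.0
    cell_caps = {
        name: caps[name] * np.exp(growth * t)
        for name in ("cell_water", "cell_lipid", "cell_protein")
    }
    kappa_cell = sum(cell_caps.values())

    a_media, a_cell = y[_MEDIA], y[_CELL]
    c_free = a_media / kappa_media
    amounts = {name: a_media * caps[name] / kappa_media for name in MEDIA_COMPARTMENTS}
    if kappa_cell > 0:
        amounts.update({name: a_cell * kappa / kappa_cell for name, kappa in cell_caps.items()})
    else:
        amounts.update({name: 0.0 for name in cell_caps})
    amounts["plastic"] = y[_PLASTIC]
    amounts["headspace"] = y[_HEAD]

    result = _package(amounts, c_free, tc.sys, f"kinetic_{tc.flavor}")
    result.losses = dict(zip(LOSS_LABELS, y[[_MET, _DEG, _EVAP]]))
    return result
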