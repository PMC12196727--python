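"""Equilibrium-partitioning distribution models.

Both flavors solve the same scalar mass balance: at equilibrium every
compartment's amount is proportional to the freely dissolved aqueous
concentration, so

    C_free = dose / (V_w + Σ_i K_i · V_i)

with the sum over binding compartments, each contributing a *capacity*
κ_i = K_i·V_i (mL of equivalent aqueous volume).  The two flavors differ
only in which compartments they include:

* ``media_cell_only`` — medium (water + serum protein + serum lipid) and
  cells (water + lipid + protein).
* ``full_system`` — additionally labware plastic (area-based sorption),
  headspace (air–water partitioning, open wells only), and an aqueous
  solubility cap with salting-out adjustment.

Partition coefficients come from the chemical's pH-7.4 distribution ratios
(serum/cell protein ← albumin–water; serum/cell lipid ← liposome–water),
with headspace and plastic restricted to the neutral species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .chem_param import NEUTRAL, Chemical, predict_distribution_ratios, resolve_speciation
from .config import Config
from .errors import ParameterizationError
from .test_system import CompartmentVolumes, ExposureSystem, compartment_volumes

MEDIA_CELL_ONLY = "media_cell_only"
FULL_SYSTEM = "full_system"
EQUILIBRIUM_FLAVORS = (MEDIA_CELL_ONLY, FULL_SYSTEM)

MEDIA_COMPARTMENTS = ("media_water", "serum_protein", "serum_lipid")
CELL_COMPARTMENTS = ("cell_water", "cell_lipid", "cell_protein")
ALL_COMPARTMENTS = MEDIA_COMPARTMENTS + CELL_COMPARTMENTS + ("plastic", "headspace")


@dataclass
class DistributionResult:
    """Predicted distribution of the dose across compartments.

    ``amounts`` are nmol per compartment; ``c_free`` is the freely dissolved
    medium concentration in µM; ``precipitate`` holds any dose exceeding the
    solubility cap (kept so the ledger still sums to the dose).
    """

    amounts: dict
    c_free: float  # µM
    f_free_media: float
    a_media: float  # nmol
    a_cell: float  # nmol
    oversaturated: bool
    model_tag: str
    precipitate: float = 0.0
    losses: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return sum(self.amounts.values()) + self.precipitate + sum(self.losses.values())


def capacities(
    chem: Chemical,
    sys: ExposureSystem,
    flavor: str,
    config: Config | None = None,
    volumes: CompartmentVolumes | None = None,
) -> dict:
    """Per-compartment capacities κ_i (mL) such that amount_i = C_free·κ_i.

    ``media_water`` carries κ = V_w (K = 1 by definition).  Headspace and
    plastic capacities are included only for the full-system flavor, scaled
    by the neutral fraction (ions are non-volatile and assumed not to sorb
    to plastic).
    """
    cfg = config or Config()
    if flavor not in EQUILIBRIUM_FLAVORS:
        raise ValueError(f"unknown flavor {flavor!r}; choose from {EQUILIBRIUM_FLAVORS}")
    vols = volumes or compartment_volumes(sys, cfg.serum)
    ph = sys.medium.ph
    log_bsa, log_lip = predict_distribution_ratios(chem, ph, cfg.chem_param)
    d_bsa = 10.0**log_bsa
    d_lip = 10.0**log_lip
    f_neutral = resolve_speciation(
        chem.pka_acid, chem.pka_base, ph, cfg.chem_param.speciation_window
    ).f_neutral

    uL = 1e-3  # µL → mL
    caps = {
        "media_water": vols.v_water * uL,
        "serum_protein": d_bsa * vols.v_serum_protein * uL,
        "serum_lipid": d_lip * vols.v_serum_lipid * uL,
        "cell_water": vols.v_cell_water * uL,
        "cell_lipid": d_lip * vols.v_cell_lipid * uL,
        "cell_protein": d_bsa * cfg.equilibrium.cell_protein_factor * vols.v_cell_protein * uL,
        "plastic": 0.0,
        "headspace": 0.0,
    }
    if flavor == FULL_SYSTEM:
        # area-based plastic sorption, log10 K [L/m²] regression on logKow;
        # 1 L/m² = 0.1 mL/cm²
        k_plastic = 10.0 ** (
            cfg.equilibrium.plastic_slope * chem.log_kow + cfg.equilibrium.plastic_intercept
        ) * 0.1
        caps["plastic"] = k_plastic * vols.a_plastic * f_neutral
        if not sys.labware.sealed and vols.v_air > 0:
            if chem.log_kaw is None:
                raise ParameterizationError(
                    f"{chem.id}: log_kaw required for open headspace in the full-system flavor"
                )
            caps["headspace"] = 10.0**chem.log_kaw * f_neutral * vols.v_air * uL
    return caps


def predict_equilibrium(
    chem: Chemical,
    sys: ExposureSystem,
    flavor: str = FULL_SYSTEM,
    config: Config | None = None,
    apply_cap: bool | None = None,
) -> DistributionResult:
    """Solve the equilibrium mass balance for one chemical in one well.

    Returns a :class:`DistributionResult` with all compartment amounts, the
    free concentration, F_free,media = C_free/C_nominal, and the media/cell
    totals.  For the full-system flavor the solubility cap is applied unless
    disabled via ``apply_cap`` or the configuration.
    """
    cfg = config or Config()
    caps = capacities(chem, sys, flavor, cfg)
    dose = sys.dose_nmol
    kappa_total = sum(caps.values())
    c_free = dose / kappa_total  # nmol/mL = µM
    amounts = {name: c_free * kappa for name, kappa in caps.items()}
    result = _package(amounts, c_free, sys, flavor)
    do_cap = cfg.equilibrium.apply_solubility_cap if apply_cap is None else apply_cap
    if flavor == FULL_SYSTEM and do_cap:
        result = apply_solubility_cap(chem, sys, result, cfg)
    return result


def _package(amounts: dict, c_free: float, sys: ExposureSystem, tag: str,
             oversaturated: bool = False, precipitate: float = 0.0) -> DistributionResult:
    a_media = sum(amounts[c] for c in MEDIA_COMPARTMENTS)
    a_cell = sum(amounts[c] for c in CELL_COMPARTMENTS)
    # for near-zero binding the excluded volume of serum constituents can
    # push c_free marginally above nominal; the free *fraction* is capped at 1
    return DistributionResult(
        amounts=amounts,
        c_free=c_free,
        f_free_media=min(c_free / sys.nominal_conc, 1.0),
        a_media=a_media,
        a_cell=a_cell,
        oversaturated=oversaturated,
        model_tag=tag,
        precipitate=precipitate,
    )


def solubility_um(chem: Chemical, ionic_strength: float) -> float:
    """Salting-adjusted aqueous solubility in µM.

    S = solubility_w / 10^(K_salt·I), converted from mg/L via the molar
    mass (mg/L ÷ g/mol = mmol/L → ×1000 µM).
    """
    k_salt = chem.k_salt
    if k_salt is None:
        from .chem_param import ksalt_from_logkow

        k_salt = ksalt_from_logkow(chem.log_kow)
    s_mg_l = chem.solubility_w / 10.0 ** (k_salt * ionic_strength)
    return s_mg_l / chem.mw * 1000.0


def apply_solubility_cap(
    chem: Chemical,
    sys: ExposureSystem,
    dist: DistributionResult,
    config: Config | None = None,
) -> DistributionResult:
    """Cap the free concentration at the salting-adjusted solubility.

    If C_free exceeds the solubility the result is re-partitioned at the
    capped concentration (bound compartments stay proportional to their
    capacities) and the excess is booked as ``precipitate`` so the ledger
    still sums to the dose.
    """
    s_um = solubility_um(chem, sys.medium.ionic_strength)
    if dist.c_free <= s_um:
        return dist
    scale = s_um / dist.c_free
    amounts = {name: amt * scale for name, amt in dist.amounts.items()}
    precipitate = sys.dose_nmol - sum(amounts.values())
    out = _package(amounts, s_um, sys, dist.model_tag, oversaturated=True,
                   precipitate=precipitate)
    return out
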