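"""Uniform dispatch over the four model flavors.

The package implements four distribution-model flavors mirroring the
commonly used generations of in vitro mass-balance models:

========================  =====================================================
tag                       structure
========================  =====================================================
``equilibrium_media_cell``  equilibrium; media + cells only (protein/lipid)
``equilibrium_full``        equilibrium; + plastic, headspace, solubility cap
``kinetic_permeability``    time-dependent; permeability-limited uptake,
                            optional metabolism; neutral + ionizable
``kinetic_neutral_fate``    time-dependent; neutral only, optional
                            evaporation/degradation/cell growth
========================  =====================================================

:func:`predict_distribution` runs any flavor to its reported state (kinetic
flavors at 24 h by default) and returns a
:class:`~vitrodist.equilibrium.DistributionResult`.
"""

from __future__ import annotations

from .chem_param import NEUTRAL, Chemical, resolve_speciation
from .config import Config, KineticConfig
from .equilibrium import FULL_SYSTEM, MEDIA_CELL_ONLY, DistributionResult, predict_equilibrium
from .kinetics import (
    NEUTRAL_FATE,
    PERMEABILITY_METABOLISM,
    distribution_at_time,
    simulate_timecourse,
)
from .test_system import ExposureSystem

EQUILIBRIUM_MEDIA_CELL = "equilibrium_media_cell"
EQUILIBRIUM_FULL = "equilibrium_full"
KINETIC_PERMEABILITY = "kinetic_permeability"
KINETIC_NEUTRAL_FATE = "kinetic_neutral_fate"

MODEL_FLAVORS = (
    EQUILIBRIUM_MEDIA_CELL,
    EQUILIBRIUM_FULL,
    KINETIC_PERMEABILITY,
    KINETIC_NEUTRAL_FATE,
)
NEUTRAL_ONLY_FLAVORS = (KINETIC_NEUTRAL_FATE,)


def flavor_applicable(flavor: str, chem: Chemical, config: Config | None = None) -> bool:
    """Whether ``flavor`` covers the chemical's speciation class."""
    if flavor not in NEUTRAL_ONLY_FLAVORS:
        return True
    cfg = config or Config()
    spec = resolve_speciation(
        chem.pka_acid, chem.pka_base, cfg.chem_param.ph, cfg.chem_param.speciation_window
    )
    return spec.ioc_class == NEUTRAL


def predict_distribution(
    chem: Chemical,
    sys: ExposureSystem,
    flavor: str,
    config: Config | None = None,
    kinetic_cfg: KineticConfig | None = None,
    t: float | None = None,
) -> DistributionResult:
    """Run one model flavor and return its distribution prediction.

    Kinetic flavors report the distribution at ``t`` hours (default: the
    configured t_end, 24 h).
    """
    cfg = config or Config()
    if flavor == EQUILIBRIUM_MEDIA_CELL:
        result = predict_equilibrium(chem, sys, MEDIA_CELL_ONLY, cfg)
    elif flavor == EQUILIBRIUM_FULL:
        result = predict_equilibrium(chem, sys, FULL_SYSTEM, cfg)
    elif flavor in (KINETIC_PERMEABILITY, KINETIC_NEUTRAL_FATE):
        kin = {
            KINETIC_PERMEABILITY: PERMEABILITY_METABOLISM,
            KINETIC_NEUTRAL_FATE: NEUTRAL_FATE,
        }[flavor]
        kcfg = kinetic_cfg or cfg.kinetics
        tc = simulate_timecourse(chem, sys, kin, kcfg, cfg)
        result = distribution_at_time(tc, kcfg.t_end if t is None else t)
    else:
        raise ValueError(f"unknown model flavor {flavor!r}; choose from {MODEL_FLAVORS}")
    result.model_tag = flavor
    return result
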