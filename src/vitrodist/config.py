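"""Configuration blocks with documented defaults.

All tunable constants of the package live here, grouped by the module they
feed.  Each block is a plain dataclass so that tests can construct explicit
configurations and YAML files can override individual keys (unknown keys are
rejected).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import SchemaError


@dataclass
class ChemParamConfig:
    """Chemical parameterization constants.

    ph : assay system pH used for speciation (7.4 for standard culture media).
    speciation_window : pKa values further than this many log units on the
        "mostly neutral" side of the pH are ignored.
    bsa_slope/bsa_intercept : linear regression log D_BSA/w = a·logKow + b
        for serum-albumin–water distribution of neutral species.
    lip_slope/lip_intercept : same for liposome(membrane lipid)–water.
    ion_log_offset : optional additive log10 term giving ionic species a fixed
        residual partitioning; None disables ionic-species partitioning
        (neutral-species-only after D_OW correction).
    """

    ph: float = 7.4
    speciation_window: float = 2.0
    bsa_slope: float = 0.71
    bsa_intercept: float = 0.42
    lip_slope: float = 1.01
    lip_intercept: float = 0.12
    ion_log_offset: float | None = None


@dataclass
class SerumConfig:
    """Composition of 100% fetal bovine serum and constituent densities."""

    albumin_conc_serum: float = 23.0  # g/L in 100% FBS
    lipid_conc_serum: float = 2.5  # g/L in 100% FBS
    protein_density: float = 1.0  # g/mL
    lipid_density: float = 1.0  # g/mL
    cell_density: float = 1.0  # g/mL


@dataclass
class WellGeometry:
    """Cylindrical well geometry used for wetted plastic area."""

    total_volume: float  # µL
    diameter: float  # cm


@dataclass
class LabwareGeometryConfig:
    formats: dict = field(
        default_factory=lambda: {
            "96-well": WellGeometry(total_volume=360.0, diameter=0.64),
            "384-well": WellGeometry(total_volume=112.0, diameter=0.33),
        }
    )


@dataclass
class EquilibriumConfig:
    """Equilibrium-model constants.

    cell_protein_factor : scaling applied to the albumin–water ratio when it
        stands in for cell-protein–water partitioning.
    plastic_slope/plastic_intercept : log10 Kplastic [L/m²] = a·logKow + b,
        an area-based polystyrene–water sorption regression.
    apply_solubility_cap : whether the full-system flavor caps the free
        concentration at the salting-adjusted aqueous solubility.
    """

    cell_protein_factor: float = 1.0
    plastic_slope: float = 0.97
    plastic_intercept: float = -6.94
    apply_solubility_cap: bool = True


@dataclass
class KineticConfig:
    """Rates and solver settings for the time-dependent flavors.

    Exchange rates are first-order relaxation constants toward the
    partition-equilibrium target of each compartment.  Defaults are fast
    (10/h) so 24 h predictions sit at equilibrium unless slowed.
    """

    k_cell_exchange: float = 10.0  # 1/h
    k_plastic_exchange: float = 10.0  # 1/h
    k_air_exchange: float = 10.0  # 1/h
    k_evap: float = 0.0  # 1/h, air-side loss from open wells
    clint: float = 0.0  # 1/h intracellular metabolic clearance
    k_deg: float = 0.0  # 1/h abiotic degradation in media
    cell_growth_rate: float = 0.0  # 1/h exponential growth of cell capacity
    t_end: float = 24.0  # h
    solver_rel_tol: float = 1e-8
    solver_abs_tol: float = 1e-10

    def __post_init__(self):
        for name in (
            "k_cell_exchange",
            "k_plastic_exchange",
            "k_air_exchange",
            "k_evap",
            "clint",
            "k_deg",
            "cell_growth_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")


@dataclass
class PhysiologyConfig:
    """Standard-human toxicokinetic constants for steady-state plasma levels."""

    body_weight: float = 70.0  # kg
    gfr: float = 6.7  # L/h glomerular filtration rate
    q_liver: float = 90.0  # L/h hepatic blood flow
    hepatocellularity: float = 110.0  # 1e6 cells per g liver
    liver_mass: float = 1820.0  # g
    f_abs: float = 1.0  # oral absorbed fraction


@dataclass
class EvaluationConfig:
    log_floor: float = 1e-12  # floor for zero/negative values before log10
    r2_material: float = 0.10  # R² above which a residual trend is "material"


@dataclass
class Config:
    chem_param: ChemParamConfig = field(default_factory=ChemParamConfig)
    serum: SerumConfig = field(default_factory=SerumConfig)
    labware_geometry: LabwareGeometryConfig = field(default_factory=LabwareGeometryConfig)
    equilibrium: EquilibriumConfig = field(default_factory=EquilibriumConfig)
    kinetics: KineticConfig = field(default_factory=KineticConfig)
    physiology: PhysiologyConfig = field(default_factory=PhysiologyConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)


def default_config() -> Config:
    return Config()


def _update_block(block, overrides: dict, path: str):
    valid = {f.name for f in dataclasses.fields(block)}
    for key, value in overrides.items():
        if key not in valid:
            raise SchemaError(f"unknown config key '{path}.{key}'")
        setattr(block, key, value)
    return block


def load_config(path: str | None = None, overrides: dict | None = None) -> Config:
    """Build a Config from the defaults plus a YAML file and/or dict overrides.

    Unknown keys at either level raise :class:`SchemaError`.
    """
    cfg = default_config()
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        for key, block in overrides.items():
            data.setdefault(key, {}).update(block)
    blocks = {f.name: getattr(cfg, f.name) for f in dataclasses.fields(cfg)}
    for key, block_overrides in data.items():
        if key not in blocks:
            raise SchemaError(f"unknown config block '{key}'")
        if not isinstance(block_overrides, dict):
            raise SchemaError(f"config block '{key}' must be a mapping")
        if key == "labware_geometry":
            formats = block_overrides.get("formats", {})
            for fmt, geom in formats.items():
                blocks[key].formats[fmt] = WellGeometry(**geom)
            extra = set(block_overrides) - {"formats"}
            if extra:
                raise SchemaError(f"unknown config key 'labware_geometry.{extra.pop()}'")
        else:
            _update_block(blocks[key], block_overrides, key)
    return cfg
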