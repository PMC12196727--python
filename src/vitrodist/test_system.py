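"""The in vitro well: cells, medium, labware, and volume bookkeeping.

An :class:`ExposureSystem` bundles everything that defines one dosed well —
the chemical's nominal concentration, the medium composition (serum-derived
binding protein and lipid), the cell population, and the labware format.
:func:`compartment_volumes` converts this description into volume-equivalent
compartments (µL) for the distribution models, treating protein, lipid and
cells as unit-density phases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .config import Config, LabwareGeometryConfig, SerumConfig
from .errors import ValidationError

PLATE_FORMATS = ("96-well", "384-well")

# seeded cells and media volume per well, standard defaults
PLATE_DEFAULTS = {
    "96-well": {"cell_count": 20_000, "media_volume": 150.0},
    "384-well": {"cell_count": 5_600, "media_volume": 40.0},
}


@dataclass
class CellType:
    """Composition of one cell type (mass fractions of wet mass)."""

    name: str
    species: str = "human"
    mass_per_cell: float = 3.0  # ng/cell
    density: float = 1.0  # g/mL
    f_water: float = 0.7
    f_lipid: float = 0.03
    f_protein: float = 0.2

    def __post_init__(self):
        for name in ("f_water", "f_lipid", "f_protein"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValidationError(name, f"fraction {value} outside [0, 1]")
        if self.f_water + self.f_lipid + self.f_protein > 1.0 + 1e-9:
            raise ValidationError("fractions", "water+lipid+protein fractions exceed 1")
        if self.mass_per_cell <= 0:
            raise ValidationError("mass_per_cell", "must be positive")


@dataclass
class MediumComposition:
    """Culture medium: serum fraction and binding-constituent concentrations.

    Direct ``albumin_conc_media``/``lipid_conc_media`` overrides (g/L in the
    final medium) take precedence over FBS-scaled values; this mirrors the
    use of measured media composition (e.g. 4.19 mg/mL protein, 0.22 mg/mL
    lipid) when available.
    """

    fbs_percent: float = 10.0  # % v/v
    albumin_conc_serum: float = 23.0  # g/L in 100% serum
    lipid_conc_serum: float = 2.5  # g/L in 100% serum
    albumin_conc_media: float | None = None  # g/L direct override
    lipid_conc_media: float | None = None  # g/L direct override
    ph: float = 7.4
    ionic_strength: float = 0.16  # mol/L, isotonic media
    temperature: float = 37.0  # °C

    def __post_init__(self):
        if not (0.0 <= self.fbs_percent <= 100.0):
            raise ValidationError("fbs_percent", f"{self.fbs_percent} outside [0, 100]")
        for name in ("albumin_conc_serum", "lipid_conc_serum"):
            if getattr(self, name) < 0:
                raise ValidationError(name, "concentration must be >= 0")

    def albumin_in_media(self) -> float:
        """Albumin concentration in the final medium (g/L)."""
        if self.albumin_conc_media is not None:
            return self.albumin_conc_media
        return self.fbs_percent / 100.0 * self.albumin_conc_serum

    def lipid_in_media(self) -> float:
        """Lipid concentration in the final medium (g/L)."""
        if self.lipid_conc_media is not None:
            return self.lipid_conc_media
        return self.fbs_percent / 100.0 * self.lipid_conc_serum


@dataclass
class Labware:
    format: str = "96-well"  # {96-well, 384-well, custom}
    well_total_volume: float = 360.0  # µL
    plastic_area: float = 1.5  # cm² in contact with medium
    sealed: bool = False

    def __post_init__(self):
        if self.well_total_volume <= 0:
            raise ValidationError("well_total_volume", "must be positive")
        if self.plastic_area < 0:
            raise ValidationError("plastic_area", "must be >= 0")


@dataclass
class ExposureSystem:
    """One dosed well: chemical dose + medium + cells + labware."""

    chemical_id: str
    nominal_conc: float  # µM
    media_volume: float  # µL
    cell_count: float
    cell_type: CellType
    medium: MediumComposition = field(default_factory=MediumComposition)
    labware: Labware = field(default_factory=Labware)

    def __post_init__(self):
        if self.nominal_conc <= 0:
            raise ValidationError("nominal_conc", "must be positive")
        if self.cell_count < 0:
            raise ValidationError("cell_count", "must be >= 0")
        if self.media_volume > self.labware.well_total_volume + 1e-9:
            raise ValidationError("media_volume", "exceeds well_total_volume")

    @property
    def dose_nmol(self) -> float:
        """Total chemical added (nmol): nominal µM × media volume."""
        return self.nominal_conc * self.media_volume * 1e-3


@dataclass
class CompartmentVolumes:
    """Volume-equivalent compartments in µL (areas in cm²)."""

    v_water: float
    v_serum_protein: float
    v_serum_lipid: float
    v_cell_water: float
    v_cell_lipid: float
    v_cell_protein: float
    v_air: float
    a_plastic: float


def wetted_area(geometry, media_volume: float) -> float:
    """Wetted plastic area (cm²) of a cylindrical well: bottom + wall."""
    radius = geometry.diameter / 2.0
    bottom = math.pi * radius**2
    height = media_volume * 1e-3 / bottom  # µL → cm³ over area
    return bottom + 2.0 * math.pi * radius * height


def default_plate(
    fmt: str, geometry: LabwareGeometryConfig | None = None
) -> tuple[int, float, Labware]:
    """Standard (cell_count, media_volume µL, Labware) for a plate format.

    96-well: 20,000 cells in 150 µL; 384-well: 5600 cells in 40 µL.
    """
    if fmt not in PLATE_FORMATS:
        raise ValidationError(
            "format", f"unknown plate format {fmt!r}; supported: {', '.join(PLATE_FORMATS)}"
        )
    geo = (geometry or LabwareGeometryConfig()).formats[fmt]
    defaults = PLATE_DEFAULTS[fmt]
    labware = Labware(
        format=fmt,
        well_total_volume=geo.total_volume,
        plastic_area=wetted_area(geo, defaults["media_volume"]),
        sealed=False,
    )
    return defaults["cell_count"], defaults["media_volume"], labware


def compartment_volumes(sys: ExposureSystem, serum: SerumConfig | None = None) -> CompartmentVolumes:
    """Split the well into volume-equivalent compartments.

    Serum-constituent volumes come from the medium concentration × media
    volume ÷ constituent density; cell volume from count × mass/cell ÷
    density, split by mass fractions.  Conservation holds by construction:
    v_water + serum constituents = media_volume and the cell sub-volumes sum
    to the (composition-covered part of the) cell volume.
    """
    cfg = serum or SerumConfig()
    v_media = sys.media_volume  # µL
    # g/L == mg/mL; mass_mg = conc * volume_mL; volume_µL = mass_mg / density
    v_protein = sys.medium.albumin_in_media() * v_media / 1000.0 / cfg.protein_density
    v_lipid = sys.medium.lipid_in_media() * v_media / 1000.0 / cfg.lipid_density
    v_water = v_media - v_protein - v_lipid
    if v_water <= 0:
        raise ValidationError("medium", "constituent volumes exceed media volume")

    cell_density = sys.cell_type.density or cfg.cell_density
    # ng / (g/mL) = 1e-6 µL
    v_cell = sys.cell_count * sys.cell_type.mass_per_cell * 1e-6 / cell_density
    v_cell_water = v_cell * sys.cell_type.f_water
    v_cell_lipid = v_cell * sys.cell_type.f_lipid
    v_cell_protein = v_cell * sys.cell_type.f_protein

    v_air = 0.0 if sys.labware.sealed else sys.labware.well_total_volume - v_media
    return CompartmentVolumes(
        v_water=v_water,
        v_serum_protein=v_protein,
        v_serum_lipid=v_lipid,
        v_cell_water=v_cell_water,
        v_cell_lipid=v_cell_lipid,
        v_cell_protein=v_cell_protein,
        v_air=max(v_air, 0.0),
        a_plastic=sys.labware.plastic_area,
    )
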