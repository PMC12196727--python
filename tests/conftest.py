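import pytest

from vitrodist import (
    CellType,
    Chemical,
    Config,
    ExposureSystem,
    MediumComposition,
    default_plate,
    validate_chemical,
)


@pytest.fixture
def config():
    return Config()


@pytest.fixture
def neutral_chem(config):
    """Moderately hydrophobic neutral chemical with full parameterization."""
    return validate_chemical(
        Chemical(
            id="NEU1",
            name="neutral-probe",
            mw=250.0,
            mp=80.0,
            log_kow=3.0,
            log_kaw=-4.0,
            solubility_w=50.0,
        ),
        config.chem_param,
    )


@pytest.fixture
def acid_chem(config):
    """Weak acid retained by the pKa screen (pKa 5.4 at pH 7.4)."""
    return validate_chemical(
        Chemical(
            id="ACI1",
            name="acid-probe",
            mw=300.0,
            mp=120.0,
            log_kow=2.5,
            log_kaw=-6.0,
            solubility_w=200.0,
            pka_acid=5.4,
        ),
        config.chem_param,
    )


@pytest.fixture
def cell_type():
    return CellType(name="hepatocyte-like", species="human", mass_per_cell=3.0,
                    f_water=0.7, f_lipid=0.05, f_protein=0.2)


def make_system(chem, cell_type, fmt="96-well", fbs=10.0, nominal=1.0,
                cell_count=None, sealed=False, **medium_kwargs):
    count, media_volume, labware = default_plate(fmt)
    labware.sealed = sealed
    return ExposureSystem(
        chemical_id=chem.id,
        nominal_conc=nominal,
        media_volume=media_volume,
        cell_count=count if cell_count is None else cell_count,
        cell_type=cell_type,
        medium=MediumComposition(fbs_percent=fbs, **medium_kwargs),
        labware=labware,
    )


@pytest.fixture
def system(neutral_chem, cell_type):
    return make_system(neutral_chem, cell_type)
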