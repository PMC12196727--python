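"""CSV readers/writers and table validation.

Conventions: UTF-8 CSV with a mandatory header row and "." decimal; empty
cells denote absent optional fields; censored bound-% observations carry the
verbatim markers ``"<10"`` / ``">99"`` in the value column.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict

import pandas as pd

from .chem_param import Chemical, validate_chemical
from .config import Config
from .errors import SchemaError, ValidationError
from .evaluation import (
    CENSOR_ABOVE,
    CENSOR_BELOW,
    CENSOR_NONE,
    ObservationRecord,
    decensor_bound_fraction,
)
from .qivive import PODRecord, TKParams
from .test_system import CellType

CHEMICAL_REQUIRED = ["id", "name", "mw", "mp", "log_kow", "solubility_w"]
CHEMICAL_OPTIONAL = [
    "log_kaw", "k_salt", "pka_acid", "pka_base", "ioc_class", "h37", "vb",
    "log_d_bsa_w", "log_d_lip_w",
]
CELL_REQUIRED = ["name", "species", "mass_per_cell", "f_water", "f_lipid", "f_protein"]
OBS_REQUIRED = ["chemical_id", "endpoint", "value"]
POD_REQUIRED = ["chemical_id", "kind", "value"]
TK_REQUIRED = ["chemical_id", "fub_plasma"]


def read_table(path, required: list[str]) -> pd.DataFrame:
    """Read a CSV and check required columns are present."""
    try:
        table = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise SchemaError(f"input file not found: {path}")
    missing = [col for col in required if col not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    return table


def _cell(row, name, cast=float, default=None):
    raw = row.get(name, "")
    if raw is None or str(raw).strip() == "":
        return default
    try:
        return cast(raw)
    except (TypeError, ValueError):
        raise SchemaError(f"unparseable {name!r} value {raw!r}")


def _collect(rows, build, path):
    out, errors = [], []
    for line, row in enumerate(rows, start=2):  # header is line 1
        try:
            out.append(build(row))
        except (SchemaError, ValidationError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise SchemaError(f"{path}: {len(errors)} invalid row(s):\n  " + "\n  ".join(errors))
    return out


def read_chemicals(path, config: Config | None = None) -> list[Chemical]:
    cfg = config or Config()
    table = read_table(path, CHEMICAL_REQUIRED)

    def build(row):
        chem = Chemical(
            id=str(row["id"]),
            name=str(row["name"]),
            mw=_cell(row, "mw"),
            mp=_cell(row, "mp"),
            log_kow=_cell(row, "log_kow"),
            solubility_w=_cell(row, "solubility_w"),
            log_kaw=_cell(row, "log_kaw"),
            k_salt=_cell(row, "k_salt"),
            pka_acid=_cell(row, "pka_acid"),
            pka_base=_cell(row, "pka_base"),
            ioc_class=_cell(row, "ioc_class", cast=str),
            h37=_cell(row, "h37"),
            vb=_cell(row, "vb"),
            log_d_bsa_w=_cell(row, "log_d_bsa_w"),
            log_d_lip_w=_cell(row, "log_d_lip_w"),
        )
        return validate_chemical(chem, cfg.chem_param)

    return _collect(table.to_dict("records"), build, path)


def write_chemicals(chemicals: list[Chemical], path) -> None:
    rows = []
    for chem in chemicals:
        row = asdict(chem)
        row.pop("provenance", None)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cell_types(path) -> list[CellType]:
    table = read_table(path, CELL_REQUIRED)

    def build(row):
        return CellType(
            name=str(row["name"]),
            species=str(row["species"]),
            mass_per_cell=_cell(row, "mass_per_cell"),
            density=_cell(row, "density", default=1.0),
            f_water=_cell(row, "f_water"),
            f_lipid=_cell(row, "f_lipid"),
            f_protein=_cell(row, "f_protein"),
        )

    return _collect(table.to_dict("records"), build, path)


def write_cell_types(cells: list[CellType], path) -> None:
    pd.DataFrame([asdict(c) for c in cells]).to_csv(path, index=False)


def read_observations(path) -> list[ObservationRecord]:
    """Observation CSV; censor markers "<10"/">99" in the value column are
    parsed into censor flags with midpoint-decensored unbound fractions."""
    table = read_table(path, OBS_REQUIRED)

    def build(row):
        raw = str(row["value"]).strip()
        censor = str(row.get("censor", "") or CENSOR_NONE).strip() or CENSOR_NONE
        if raw in ("<10", ">99"):
            value = decensor_bound_fraction(raw)
            censor = CENSOR_BELOW if raw == "<10" else CENSOR_ABOVE
        else:
            value = _cell(row, "value")
        return ObservationRecord(
            chemical_id=str(row["chemical_id"]),
            endpoint=str(row["endpoint"]),
            value=value,
            censor=censor,
            timepoint=_cell(row, "timepoint", default=24.0),
            system_id=str(row.get("system_id", "")),
            source=str(row.get("source", "")),
        )

    return _collect(table.to_dict("records"), build, path)


def write_observations(records: list[ObservationRecord], path) -> None:
    """Censored bound-fraction records are written back as verbatim markers."""
    rows = []
    for rec in records:
        row = asdict(rec)
        if rec.endpoint == "f_free_media" and rec.censor == CENSOR_BELOW:
            row["value"] = "<10"
        elif rec.endpoint == "f_free_media" and rec.censor == CENSOR_ABOVE:
            row["value"] = ">99"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_pods(path) -> list[PODRecord]:
    table = read_table(path, POD_REQUIRED)

    def build(row):
        return PODRecord(
            chemical_id=str(row["chemical_id"]),
            kind=str(row["kind"]),
            value=_cell(row, "value"),
            ci_lower=_cell(row, "ci_lower"),
            ci_upper=_cell(row, "ci_upper"),
        )

    return _collect(table.to_dict("records"), build, path)


def write_pods(records: list[PODRecord], path) -> None:
    pd.DataFrame([asdict(r) for r in records]).to_csv(path, index=False)


def read_tk_params(path) -> dict[str, TKParams]:
    table = read_table(path, TK_REQUIRED)

    def build(row):
        return TKParams(
            chemical_id=str(row["chemical_id"]),
            fub_plasma=_cell(row, "fub_plasma"),
            clint=_cell(row, "clint", default=0.0),
            gfr=_cell(row, "gfr"),
            q_liver=_cell(row, "q_liver"),
            body_weight=_cell(row, "body_weight"),
            hepatocellularity=_cell(row, "hepatocellularity"),
            liver_mass=_cell(row, "liver_mass"),
            f_abs=_cell(row, "f_abs"),
        )

    records = _collect(table.to_dict("records"), build, path)
    return {tk.chemical_id: tk for tk in records}


def file_sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(path, *, workflow: str, seed: int | None, inputs: dict,
                   config_echo: dict | None = None, status: str = "ok") -> None:
    """Machine-readable run manifest: input hashes, seed, versions, status."""
    from . import __version__

    manifest = {
        "workflow": workflow,
        "status": status,
        "seed": seed,
        "inputs": {name: file_sha256(p) for name, p in inputs.items()},
        "config": config_echo or {},
        "versions": {"vitrodist": __version__, "pandas": pd.__version__},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
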