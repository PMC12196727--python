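"""Factorial sensitivity analysis with ANOVA η² variance attribution.

The design crosses chemicals × cell types × plate formats × serum levels ×
model flavors at a fixed 1 µM nominal dose, runs every prediction, and
attributes the variance of the (log10-transformed) response to each input
category via η² = SS_factor / SS_total from a main-effects ANOVA.  Input
categories are deliberately lumped: chemical identity is one factor that
absorbs all chemical-related parameters, and likewise cell type.

Unbalanced designs (rows dropped because a neutral-only flavor cannot be
applied to an ionizable chemical) use type-I sequential sums of squares in
the fixed order chemical, cell, FBS, labware, model; balanced designs are
order-invariant.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .chem_param import Chemical
from .config import Config, KineticConfig
from .errors import VitrodistError
from .models import MODEL_FLAVORS, flavor_applicable, predict_distribution
from .test_system import CellType, ExposureSystem, MediumComposition, default_plate

FACTOR_ORDER = ("chemical", "cell_type", "fbs_percent", "labware", "model")


@dataclass
class FactorialDesign:
    factors: dict  # factor name → level list
    rows: pd.DataFrame  # one row per run with factor labels
    chemicals: dict  # id → Chemical
    cell_types: dict  # name → CellType

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class SensitivityResult:
    response: str
    ss: dict  # factor → sum of squares (includes "residual")
    eta_squared: dict  # factor → η²
    residual_share: float
    n: int


def build_design(
    chemicals: list[Chemical],
    cell_types: list[CellType],
    plate_formats=("96-well", "384-well"),
    fbs_levels=(2.0, 20.0),
    models=MODEL_FLAVORS,
    mode: str = "all",
    nominal_conc: float = 1.0,
    config: Config | None = None,
) -> FactorialDesign:
    """Cross the factor levels into a runnable design at 1 µM dosing.

    ``mode="all"`` keeps every chemical and drops rows pairing a neutral-only
    flavor with an ionizable chemical (unbalanced design);
    ``mode="neutral_only"`` restricts the chemical factor to neutrals so all
    flavors apply everywhere (balanced design).
    """
    cfg = config or Config()
    if mode not in ("all", "neutral_only"):
        raise VitrodistError(f"unknown mode {mode!r}")
    for name, levels in (
        ("chemicals", chemicals), ("cell_types", cell_types),
        ("plate_formats", plate_formats), ("fbs_levels", fbs_levels), ("models", models),
    ):
        if not levels:
            raise VitrodistError(f"empty factor: {name}")
    for fmt in plate_formats:
        default_plate(fmt, cfg.labware_geometry)  # validates format early

    if mode == "neutral_only":
        chemicals = [c for c in chemicals
                     if all(flavor_applicable(m, c, cfg) for m in models)]
        if not chemicals:
            raise VitrodistError("no neutral chemicals available for neutral_only mode")

    records = []
    for chem, cell, fmt, fbs, model in itertools.product(
        chemicals, cell_types, plate_formats, fbs_levels, models
    ):
        if mode == "all" and not flavor_applicable(model, chem, cfg):
            continue
        records.append(
            {
                "chemical": chem.id,
                "cell_type": cell.name,
                "labware": fmt,
                "fbs_percent": fbs,
                "model": model,
                "nominal_conc": nominal_conc,
            }
        )
    rows = pd.DataFrame.from_records(records)
    factors = {
        "chemical": [c.id for c in chemicals],
        "cell_type": [c.name for c in cell_types],
        "labware": list(plate_formats),
        "fbs_percent": list(fbs_levels),
        "model": list(models),
    }
    return FactorialDesign(
        factors=factors,
        rows=rows,
        chemicals={c.id: c for c in chemicals},
        cell_types={c.name: c for c in cell_types},
    )


def run_design(
    design: FactorialDesign,
    config: Config | None = None,
    kinetic_cfg: KineticConfig | None = None,
) -> pd.DataFrame:
    """Run every design row; adds ``f_free_media`` and ``f_cell`` columns.

    ``f_cell`` is the predicted fraction of the dose residing in cells.
    """
    cfg = config or Config()
    out = design.rows.copy()
    f_free = np.empty(len(out))
    f_cell = np.empty(len(out))
    for i, row in enumerate(out.itertuples(index=False)):
        chem = design.chemicals[row.chemical]
        cell = design.cell_types[row.cell_type]
        cell_count, media_volume, labware = default_plate(row.labware, cfg.labware_geometry)
        sys = ExposureSystem(
            chemical_id=chem.id,
            nominal_conc=row.nominal_conc,
            media_volume=media_volume,
            cell_count=cell_count,
            cell_type=cell,
            medium=MediumComposition(fbs_percent=row.fbs_percent),
            labware=labware,
        )
        dist = predict_distribution(chem, sys, row.model, cfg, kinetic_cfg)
        f_free[i] = dist.f_free_media
        f_cell[i] = dist.a_cell / sys.dose_nmol
    out["f_free_media"] = f_free
    out["f_cell"] = f_cell
    return out


def eta_squared(
    table: pd.DataFrame,
    response: str,
    factors=FACTOR_ORDER,
    log_transform: bool = True,
    floor: float = 1e-12,
) -> SensitivityResult:
    """Main-effects ANOVA variance decomposition of ``response``.

    η² = SS_factor / SS_total per factor from type-I sequential sums of
    squares in the given factor order (order-invariant for balanced
    designs); the residual share is SS_residual / SS_total.  The response is
    log10-transformed by default since predictions span orders of magnitude.
    """
    if len(table) < 2:
        raise VitrodistError("need at least 2 rows")
    factors = [f for f in factors if f in table.columns and table[f].nunique() > 1]
    data = table.copy()
    y = data[response].astype(float)
    if log_transform:
        y = np.log10(np.maximum(y, floor))
    data["_y"] = y
    if np.allclose(y, y.iloc[0]):
        warnings.warn("constant response: all eta-squared set to 0", stacklevel=2)
        ss = {f: 0.0 for f in factors}
        ss["residual"] = 0.0
        return SensitivityResult(response=response, ss=ss,
                                 eta_squared={f: 0.0 for f in factors},
                                 residual_share=0.0, n=len(table))
    formula = "_y ~ " + " + ".join(f"C({f})" for f in factors)
    fit = smf.ols(formula, data=data).fit()
    anova = sm.stats.anova_lm(fit, typ=1)
    ss = {}
    for factor in factors:
        ss[factor] = float(anova.loc[f"C({factor})", "sum_sq"])
    ss["residual"] = float(anova.loc["Residual", "sum_sq"])
    ss_total = sum(ss.values())
    eta = {f: ss[f] / ss_total for f in factors}
    return SensitivityResult(
        response=response,
        ss=ss,
        eta_squared=eta,
        residual_share=ss["residual"] / ss_total,
        n=len(table),
    )
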