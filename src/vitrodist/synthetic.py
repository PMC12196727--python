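"""Synthetic chemicals, cell types, observations, and POD pairs.

The generators emulate the statistical structure the analysis stages assume
— a chemical set spanning log Kow ≈ −2…8 with solubility and volatility
correlated to hydrophobicity and a neutral/acid/base mixture; a panel of
cell types with varying mass and composition including one extreme-lipid and
one low-mass type; observations drawn from a chosen truth model with
multiplicative lognormal noise and interval censoring of bound fractions;
and POD pairs whose in vivo values derive from the bioavailability-adjusted
OED of a known truth — so every stage of the package runs and is testable
without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_param import ACID, BASE, NEUTRAL, Chemical, validate_chemical
from .config import Config
from .errors import VitrodistError
from .evaluation import CENSOR_ABOVE, CENSOR_BELOW, CENSOR_NONE, ObservationRecord
from .models import predict_distribution
from .qivive import PODRecord, TKParams, css_steady_state, oed_adjusted
from .test_system import CellType, ExposureSystem

R_GAS = 8.314  # Pa·m³/(mol·K)
T_ASSAY = 310.15  # K (37 °C)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic chemical universe and observation process.

    Defaults define the generator's standing study conditions: log Kow
    uniform on [−2, 8]; log10 solubility decreasing linearly in log Kow with
    Gaussian scatter; a 70/15/15 neutral/acid/base mixture; bound-% reporting
    limits at 10 and 99; multiplicative lognormal observation noise of 0.3
    log10 units.
    """

    n_chemicals: int = 116
    ioc_mix: tuple = (0.70, 0.15, 0.15)  # P(neutral), P(acid), P(base)
    log_kow_range: tuple = (-2.0, 8.0)
    # log10 S[mg/L] = sol_intercept + sol_slope·logKow + N(0, sol_sd)
    sol_slope: float = -0.7
    sol_intercept: float = 3.5
    sol_sd: float = 0.6
    # log Kaw = kaw_intercept + kaw_slope·logKow + N(0, kaw_sd)
    kaw_slope: float = 0.4
    kaw_intercept: float = -5.0
    kaw_sd: float = 1.2
    pka_acid_range: tuple = (2.0, 10.0)
    pka_base_range: tuple = (3.0, 11.0)
    mw_log_mean: float = np.log(250.0)
    mw_log_sd: float = 0.35
    mp_range: tuple = (-30.0, 250.0)
    noise_sd_log10: float = 0.3
    censor_bounds: tuple = (10.0, 99.0)  # bound-% reporting limits
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.ioc_mix) - 1.0) > 1e-9:
            raise VitrodistError("ioc_mix probabilities must sum to 1")
        if self.noise_sd_log10 < 0:
            raise VitrodistError("noise_sd_log10 must be >= 0")


def generate_chemicals(spec: SyntheticSpec, config: Config | None = None) -> list[Chemical]:
    """Draw a reproducible set of validated synthetic chemicals."""
    cfg = config or Config()
    rng = np.random.default_rng(spec.seed)
    chemicals = []
    classes = rng.choice([NEUTRAL, ACID, BASE], size=spec.n_chemicals, p=list(spec.ioc_mix))
    for i in range(spec.n_chemicals):
        log_kow = rng.uniform(*spec.log_kow_range)
        log_sol = spec.sol_intercept + spec.sol_slope * log_kow + rng.normal(0, spec.sol_sd)
        log_kaw = spec.kaw_intercept + spec.kaw_slope * log_kow + rng.normal(0, spec.kaw_sd)
        mw = float(np.exp(rng.normal(spec.mw_log_mean, spec.mw_log_sd)))
        pka_acid = pka_base = None
        # draw the retained pKa inside the non-ignorable window for its class
        if classes[i] == ACID:
            pka_acid = rng.uniform(spec.pka_acid_range[0],
                                   min(spec.pka_acid_range[1], cfg.chem_param.ph + cfg.chem_param.speciation_window - 0.05))
        elif classes[i] == BASE:
            pka_base = rng.uniform(max(spec.pka_base_range[0], cfg.chem_param.ph - cfg.chem_param.speciation_window + 0.05),
                                   spec.pka_base_range[1])
        chem = Chemical(
            id=f"SYN{i:04d}",
            name=f"synthetic-{i:04d}",
            mw=mw,
            mp=float(rng.uniform(*spec.mp_range)),
            log_kow=log_kow,
            log_kaw=log_kaw,
            solubility_w=float(10.0**log_sol),
            pka_acid=pka_acid,
            pka_base=pka_base,
            h37=float(10.0**log_kaw * R_GAS * T_ASSAY),
            vb=float(mw / 1.2),
        )
        chemicals.append(validate_chemical(chem, cfg.chem_param))
    return chemicals


def generate_cell_types(
    n: int = 13,
    seed: int = 0,
    include_extremes: bool = True,
) -> list[CellType]:
    """Cell-type panel with one extreme-lipid and one low-mass member.

    The extremes exercise the outlier behavior seen with lipid-rich neuronal
    cells (lipid fraction > 0.9) and very small fish-gill cells.
    """
    if n < 1:
        raise VitrodistError("need at least one cell type")
    rng = np.random.default_rng(seed)
    species_pool = ("human", "rat", "mouse", "fish")
    cells = []
    for i in range(n):
        f_lipid = float(rng.uniform(0.005, 0.15))
        f_protein = float(rng.uniform(0.1, 0.25))
        f_water = float(rng.uniform(0.6, min(0.85, 1.0 - f_lipid - f_protein)))
        cells.append(
            CellType(
                name=f"cell{i:02d}",
                species=species_pool[int(rng.integers(len(species_pool)))],
                mass_per_cell=float(np.exp(rng.normal(np.log(3.0), 0.5))),
                f_water=f_water,
                f_lipid=f_lipid,
                f_protein=f_protein,
            )
        )
    if include_extremes and n >= 2:
        cells[0] = CellType(
            name="extreme_lipid",
            species="rat",
            mass_per_cell=3.0,
            f_water=0.03,
            f_lipid=0.953,
            f_protein=0.015,
        )
        cells[1] = CellType(
            name="low_mass",
            species="fish",
            mass_per_cell=0.05,
            f_water=0.75,
            f_lipid=0.03,
            f_protein=0.2,
        )
    return cells


def _bound_percent(f_free: float) -> float:
    return 100.0 * (1.0 - min(f_free, 1.0))


def generate_observations(
    chemicals: list[Chemical],
    system_for,
    truth_flavor: str,
    spec: SyntheticSpec,
    config: Config | None = None,
    endpoints=("f_free_media", "a_media", "a_cell"),
) -> tuple[list[ObservationRecord], pd.DataFrame]:
    """Observations = truth-model predictions × lognormal noise, censored.

    ``system_for`` maps a Chemical to its ExposureSystem (a callable), so
    callers control dosing and test-system layout.  Bound-% values outside
    the reporting limits are emitted as interval-censored records carrying
    the limit value; everything else is uncensored.  Returns the records and
    a tidy truth table for oracle checks.
    """
    cfg = config or Config()
    rng = np.random.default_rng(spec.seed + 1)
    lo, hi = spec.censor_bounds
    records = []
    truth_rows = []
    for chem in chemicals:
        sys = system_for(chem)
        dist = predict_distribution(chem, sys, truth_flavor, cfg)
        truth = {
            "f_free_media": dist.f_free_media,
            "a_media": dist.a_media,
            "a_cell": dist.a_cell,
        }
        truth_rows.append({"chemical_id": chem.id, **truth})
        for endpoint in endpoints:
            value = truth[endpoint]
            if value <= 0:
                continue
            noisy = value * 10.0 ** rng.normal(0.0, spec.noise_sd_log10)
            censor = CENSOR_NONE
            if endpoint == "f_free_media":
                noisy = min(noisy, 1.0)
                bound = _bound_percent(noisy)
                if bound < lo:
                    # bound below the lower reporting limit → "<10"
                    censor = CENSOR_BELOW
                    noisy = (100.0 - lo / 2.0) / 100.0  # decensored midpoint convention
                elif bound > hi:
                    censor = CENSOR_ABOVE
                    noisy = (100.0 - (hi + 100.0) / 2.0) / 100.0
            records.append(
                ObservationRecord(
                    chemical_id=chem.id,
                    endpoint=endpoint,
                    value=float(noisy),
                    censor=censor,
                    timepoint=24.0,
                    system_id=sys.chemical_id,
                    source="synthetic",
                )
            )
    return records, pd.DataFrame(truth_rows).set_index("chemical_id")


def generate_tk_params(
    chemicals: list[Chemical], seed: int = 0
) -> dict[str, TKParams]:
    """Synthetic plasma-binding/clearance table (fub lognormal, CLint mixed)."""
    rng = np.random.default_rng(seed + 2)
    tk = {}
    for chem in chemicals:
        fub = float(np.clip(10.0 ** rng.uniform(-3.0, 0.0), 1e-4, 1.0))
        clint = float(rng.choice([0.0, 10.0 ** rng.uniform(-1, 2)], p=[0.3, 0.7]))
        tk[chem.id] = TKParams(chemical_id=chem.id, fub_plasma=fub, clint=clint)
    return tk


def generate_pod_pairs(
    chemicals: list[Chemical],
    tk_params: dict[str, TKParams],
    fub_media: dict[str, float],
    scatter_sd: float = 0.0,
    seed: int = 0,
    pod_invitro: float = 1.0,
    ci_log_halfwidth: float = 0.3,
    config: Config | None = None,
) -> tuple[list[PODRecord], list[PODRecord]]:
    """Paired in vitro / in vivo PODs around a known adjusted-OED truth.

    The in vivo POD is the bioavailability-adjusted OED of the in vitro POD
    times 10^ε with ε ~ N(0, scatter_sd); confidence intervals have a
    configurable log10 half-width.  At ``scatter_sd = 0`` adjusted-OED
    concordance is exact and unadjusted concordance is off by exactly the
    correction-factor spread.
    """
    if scatter_sd < 0:
        raise VitrodistError("scatter_sd must be >= 0")
    cfg = config or Config()
    rng = np.random.default_rng(seed + 3)
    invitro, invivo = [], []
    for chem in chemicals:
        tk = tk_params[chem.id]
        css = css_steady_state(tk, chem.mw, cfg.physiology)
        truth = oed_adjusted(pod_invitro, css, fub_media[chem.id], tk.fub_plasma)
        observed = truth * 10.0 ** rng.normal(0.0, scatter_sd)
        invitro.append(PODRecord(chemical_id=chem.id, kind="in_vitro_uM", value=pod_invitro))
        invivo.append(
            PODRecord(
                chemical_id=chem.id,
                kind="in_vivo_mg_kg_day",
                value=observed,
                ci_lower=observed * 10.0**-ci_log_halfwidth,
                ci_upper=observed * 10.0**ci_log_halfwidth,
            )
        )
    return invitro, invivo
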