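"""Equilibrium-partitioning models: closed form vs bisection oracle, conservation."""

import numpy as np
import pytest

from vitrodist import (
    CellType,
    Chemical,
    Config,
    apply_solubility_cap,
    predict_equilibrium,
    solubility_um,
    validate_chemical,
)
from vitrodist.equilibrium import FULL_SYSTEM, MEDIA_CELL_ONLY, capacities
from vitrodist.errors import ParameterizationError

from conftest import make_system


def bisection_c_free(dose_nmol, caps, lo=0.0, hi=None, tol=1e-15):
    """Independent oracle: solve c·Σκ_i = dose for c by pure bisection.

    Never uses the package's closed form; only the total-mass equation.
    """
    kappa_total = sum(caps.values())
    if hi is None:
        hi = dose_nmol / caps["media_water"] + 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mid * kappa_total > dose_nmol:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol * max(hi, 1.0):
            break
    return 0.5 * (lo + hi)


def random_chem(rng, neutral=False):
    pka_acid = pka_base = None
    if not neutral and rng.random() < 0.4:
        if rng.random() < 0.5:
            pka_acid = rng.uniform(3.0, 9.0)
        else:
            pka_base = rng.uniform(5.5, 11.0)
    return validate_chemical(
        Chemical(
            id="R", name="r",
            mw=rng.uniform(80, 600),
            mp=rng.uniform(-20, 250),
            log_kow=rng.uniform(-2, 8),
            log_kaw=rng.uniform(-9, 1),
            solubility_w=10 ** rng.uniform(-2, 5),
            pka_acid=pka_acid,
            pka_base=pka_base,
        )
    )


def random_system(rng, chem):
    cell = CellType(
        name="rc",
        mass_per_cell=rng.uniform(0.1, 10.0),
        f_water=0.6,
        f_lipid=rng.uniform(0.005, 0.2),
        f_protein=rng.uniform(0.05, 0.19),
    )
    return make_system(
        chem, cell,
        fmt=rng.choice(["96-well", "384-well"]),
        fbs=rng.uniform(0.0, 20.0),
        nominal=10 ** rng.uniform(-2, 2),
        cell_count=int(rng.uniform(0, 50_000)),
        sealed=bool(rng.random() < 0.5),
    )


class TestTrivialMassBalances:
    def test_nothing_to_bind_gives_f_free_one(self, neutral_chem, cell_type):
        sys = make_system(neutral_chem, cell_type, fbs=0.0, cell_count=0, sealed=True)
        dist = predict_equilibrium(neutral_chem, sys, MEDIA_CELL_ONLY)
        assert dist.f_free_media == pytest.approx(1.0, rel=1e-12)
        assert dist.amounts["media_water"] == pytest.approx(sys.dose_nmol, rel=1e-12)

    def test_single_sink_with_unit_capacity_ratio(self, cell_type):
        """One binding compartment with K·V = V_w halves the free fraction."""
        # high-affinity sink of negligible volume: D = 1e6 with
        # V_p = V_media/(D+1) gives D·V_p = V_w while V_p ≪ V_media
        chem = validate_chemical(
            Chemical(id="k", name="k", mw=100, mp=0, log_kow=0.0, solubility_w=1e6,
                     log_d_bsa_w=6.0),
        )
        d_bsa = 10 ** chem.log_d_bsa_w
        sys = make_system(chem, cell_type, fbs=0.0, cell_count=0, sealed=True,
                          albumin_conc_media=1000.0 / (d_bsa + 1.0))
        dist = predict_equilibrium(chem, sys, MEDIA_CELL_ONLY)
        assert dist.f_free_media == pytest.approx(0.5, rel=2e-6)
        assert dist.a_media == pytest.approx(sys.dose_nmol, rel=1e-12)

    def test_cell_sink_with_ninefold_capacity(self, cell_type):
        """K_cell·V_cell/V_w = 9 puts 90% of the dose into cells."""
        chem = validate_chemical(
            Chemical(id="c", name="c", mw=100, mp=0, log_kow=0.0, solubility_w=1e6)
        )
        cell = CellType(name="pure-water-cell", mass_per_cell=5.0,
                        f_water=1.0, f_lipid=0.0, f_protein=0.0)
        sys = make_system(chem, cell, fbs=0.0, sealed=True, cell_count=0)
        caps = capacities(chem, sys, MEDIA_CELL_ONLY)
        v_w_uL = caps["media_water"] * 1000
        sys.cell_count = 9.0 * v_w_uL / (cell.mass_per_cell * 1e-6)
        dist = predict_equilibrium(chem, sys, MEDIA_CELL_ONLY)
        assert dist.a_cell / sys.dose_nmol == pytest.approx(0.9, rel=1e-9)


class TestOracleEquivalence:
    def test_closed_form_matches_bisection_on_random_systems(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            chem = random_chem(rng)
            sys = random_system(rng, chem)
            for flavor in (MEDIA_CELL_ONLY, FULL_SYSTEM):
                dist = predict_equilibrium(chem, sys, flavor, apply_cap=False)
                caps = capacities(chem, sys, flavor)
                oracle = bisection_c_free(sys.dose_nmol, caps)
                assert dist.c_free == pytest.approx(oracle, rel=1e-9)

    def test_mass_conserved_on_random_systems(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            chem = random_chem(rng)
            sys = random_system(rng, chem)
            dist = predict_equilibrium(chem, sys, FULL_SYSTEM)
            assert dist.total == pytest.approx(sys.dose_nmol, rel=1e-9)
            assert all(v >= 0 for v in dist.amounts.values())


class TestProperties:
    def test_f_free_non_increasing_in_serum_cells_and_hydrophobicity(self, cell_type):
        base = validate_chemical(
            Chemical(id="m", name="m", mw=200, mp=50, log_kow=2.0, solubility_w=1e5)
        )
        f_prev = None
        for fbs in (0.0, 5.0, 10.0, 20.0):
            f = predict_equilibrium(base, make_system(base, cell_type, fbs=fbs, sealed=True),
                                    MEDIA_CELL_ONLY).f_free_media
            if f_prev is not None:
                assert f <= f_prev + 1e-12
            f_prev = f
        f_prev = None
        for count in (0, 10_000, 40_000):
            f = predict_equilibrium(base, make_system(base, cell_type, cell_count=count, sealed=True),
                                    MEDIA_CELL_ONLY).f_free_media
            if f_prev is not None:
                assert f <= f_prev + 1e-12
            f_prev = f
        f_prev = None
        for log_kow in (-1.0, 1.0, 3.0, 5.0):
            chem = validate_chemical(
                Chemical(id="m", name="m", mw=200, mp=50, log_kow=log_kow, solubility_w=1e5)
            )
            f = predict_equilibrium(chem, make_system(chem, cell_type, sealed=True),
                                    MEDIA_CELL_ONLY).f_free_media
            if f_prev is not None:
                assert f <= f_prev + 1e-12
            f_prev = f

    def test_full_system_reduces_to_media_cell_when_extras_removed(self, neutral_chem, cell_type):
        sys = make_system(neutral_chem, cell_type, sealed=True)
        sys.labware.plastic_area = 0.0
        a = predict_equilibrium(neutral_chem, sys, MEDIA_CELL_ONLY)
        b = predict_equilibrium(neutral_chem, sys, FULL_SYSTEM, apply_cap=False)
        assert b.c_free == pytest.approx(a.c_free, rel=1e-12)

    def test_ionization_limit_approaches_neutral_prediction(self, cell_type):
        """As the acid pKa rises toward the screen threshold, predictions
        converge to the neutral-chemical ones."""
        neutral = validate_chemical(
            Chemical(id="n", name="n", mw=200, mp=50, log_kow=2.0, solubility_w=1e5)
        )
        f_neutral_pred = predict_equilibrium(
            neutral, make_system(neutral, cell_type, sealed=True), MEDIA_CELL_ONLY
        ).f_free_media
        diffs = []
        for pka in (7.4, 8.4, 9.35):
            acid = validate_chemical(
                Chemical(id="a", name="a", mw=200, mp=50, log_kow=2.0, solubility_w=1e5,
                         pka_acid=pka)
            )
            f = predict_equilibrium(acid, make_system(acid, cell_type, sealed=True),
                                    MEDIA_CELL_ONLY).f_free_media
            diffs.append(abs(f - f_neutral_pred))
        assert diffs[0] > diffs[1] > diffs[2]
        assert diffs[-1] < 0.05 * f_neutral_pred

    def test_open_headspace_requires_log_kaw(self, cell_type):
        chem = validate_chemical(
            Chemical(id="v", name="v", mw=100, mp=0, log_kow=1.0, solubility_w=1e4)
        )
        sys = make_system(chem, cell_type, sealed=False)
        with pytest.raises(ParameterizationError, match="log_kaw"):
            predict_equilibrium(chem, sys, FULL_SYSTEM)


class TestSolubilityCap:
    def test_below_solubility_is_identity(self, neutral_chem, cell_type):
        sys = make_system(neutral_chem, cell_type, nominal=0.01)
        dist = predict_equilibrium(neutral_chem, sys, FULL_SYSTEM, apply_cap=False)
        capped = apply_solubility_cap(neutral_chem, sys, dist)
        assert capped is dist
        assert not capped.oversaturated

    def test_zero_ionic_strength_solubility_is_plain_conversion(self):
        chem = validate_chemical(
            Chemical(id="s", name="s", mw=200.0, mp=0, log_kow=1.0, solubility_w=20.0)
        )
        # 20 mg/L ÷ 200 g/mol = 0.1 mmol/L = 100 µM
        assert solubility_um(chem, ionic_strength=0.0) == pytest.approx(100.0)

    def test_oversaturation_caps_c_free_and_conserves_dose(self, cell_type):
        chem = validate_chemical(
            Chemical(id="s", name="s", mw=200.0, mp=0, log_kow=2.0, log_kaw=-5.0,
                     solubility_w=0.2)
        )
        sys = make_system(chem, cell_type, nominal=100.0)
        dist = predict_equilibrium(chem, sys, FULL_SYSTEM)
        s_um = solubility_um(chem, sys.medium.ionic_strength)
        assert dist.oversaturated
        assert dist.c_free == pytest.approx(s_um, rel=1e-12)
        assert dist.precipitate > 0
        assert dist.total == pytest.approx(sys.dose_nmol, rel=1e-9)
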