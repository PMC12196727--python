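"""Synthetic data generators: determinism, statistical structure, recovery."""

import numpy as np
import pandas as pd
import pytest

from vitrodist import (
    Config,
    SyntheticSpec,
    compute_metrics,
    generate_cell_types,
    generate_chemicals,
    generate_observations,
    generate_pod_pairs,
    generate_tk_params,
    predict_distribution,
)
from vitrodist.evaluation import CENSOR_ABOVE, CENSOR_NONE
from vitrodist.models import MODEL_FLAVORS, flavor_applicable
from vitrodist.qivive import concordance

from conftest import make_system


class TestGenerateChemicals:
    def test_same_seed_identical_tables(self):
        spec = SyntheticSpec(n_chemicals=20, seed=5)
        a = generate_chemicals(spec)
        b = generate_chemicals(spec)
        assert [(c.id, c.mw, c.log_kow, c.solubility_w) for c in a] == [
            (c.id, c.mw, c.log_kow, c.solubility_w) for c in b
        ]

    def test_zero_chemicals_empty(self):
        assert generate_chemicals(SyntheticSpec(n_chemicals=0)) == []

    def test_all_records_pass_validation_with_filled_fields(self):
        chems = generate_chemicals(SyntheticSpec(n_chemicals=30, seed=2))
        for c in chems:
            assert c.k_salt is not None
            assert c.log_d_bsa_w is not None
            assert c.ioc_class in ("neutral", "acid", "base")

    def test_kow_solubility_correlation_matches_spec(self):
        """Empirical logKow–logS correlation reflects the configured linear
        dependence within 0.05."""
        spec = SyntheticSpec(n_chemicals=4000, seed=7)
        chems = generate_chemicals(spec)
        kow = np.array([c.log_kow for c in chems])
        logs = np.log10([c.solubility_w for c in chems])
        # implied correlation of S = a + b·K + ε with K ~ U(range), ε ~ N(0, sd)
        var_k = (spec.log_kow_range[1] - spec.log_kow_range[0]) ** 2 / 12.0
        implied = spec.sol_slope * np.sqrt(var_k) / np.sqrt(
            spec.sol_slope**2 * var_k + spec.sol_sd**2
        )
        assert np.corrcoef(kow, logs)[0, 1] == pytest.approx(implied, abs=0.05)

    def test_ioc_mixture_proportions(self):
        chems = generate_chemicals(SyntheticSpec(n_chemicals=3000, seed=9))
        share_neutral = sum(c.ioc_class == "neutral" for c in chems) / len(chems)
        assert share_neutral == pytest.approx(0.70, abs=0.03)


class TestGenerateCellTypes:
    def test_all_rows_satisfy_invariants(self):
        for cell in generate_cell_types(13, seed=3):
            assert 0 <= cell.f_water <= 1
            assert cell.f_water + cell.f_lipid + cell.f_protein <= 1 + 1e-9
            assert cell.mass_per_cell > 0

    def test_extremes_present(self):
        cells = generate_cell_types(13, seed=3)
        assert max(c.f_lipid for c in cells) > 0.9
        assert min(c.mass_per_cell for c in cells) < 0.1

    def test_seed_reproducibility(self):
        a = generate_cell_types(5, seed=11)
        b = generate_cell_types(5, seed=11)
        assert [(c.name, c.mass_per_cell, c.f_lipid) for c in a] == [
            (c.name, c.mass_per_cell, c.f_lipid) for c in b
        ]


class TestGenerateObservations:
    def _setup(self, noise, n=12, seed=21):
        spec = SyntheticSpec(n_chemicals=n, seed=seed, noise_sd_log10=noise)
        chems = generate_chemicals(spec)
        cells = generate_cell_types(3, seed=seed, include_extremes=False)

        def system_for(chem):
            return make_system(chem, cells[0])

        return spec, chems, system_for

    def test_zero_noise_observations_equal_truth(self):
        spec, chems, system_for = self._setup(noise=0.0)
        records, truth = generate_observations(chems, system_for, "equilibrium_full", spec)
        free = [r for r in records if r.endpoint == "f_free_media" and r.censor == CENSOR_NONE]
        pred = [truth.loc[r.chemical_id, "f_free_media"] for r in free]
        obs = [r.value for r in free]
        m = compute_metrics(pred, obs)
        assert m.mae == pytest.approx(0.0, abs=1e-12)

    def test_expected_mae_matches_folded_normal_mean(self):
        """With lognormal noise sd s the MAE of log residuals approaches
        s·√(2/π), the mean of a folded normal."""
        s = 0.4
        spec = SyntheticSpec(n_chemicals=800, seed=33, noise_sd_log10=s)
        chems = generate_chemicals(spec)
        cells = generate_cell_types(1, seed=1, include_extremes=False)
        records, truth = generate_observations(
            chems, lambda c: make_system(c, cells[0]), "equilibrium_full", spec,
            endpoints=("a_media",),  # uncensored endpoint isolates the noise law
        )
        pred = [truth.loc[r.chemical_id, "a_media"] for r in records]
        obs = [r.value for r in records]
        m = compute_metrics(pred, obs)
        assert m.mae == pytest.approx(s * np.sqrt(2 / np.pi), rel=0.1)

    def test_heavy_binding_truth_emits_above_censor_marker(self, cell_type):
        """A chemical whose true bound fraction exceeds 99% is censored."""
        spec = SyntheticSpec(n_chemicals=1, seed=1, noise_sd_log10=0.0)
        chems = generate_chemicals(SyntheticSpec(n_chemicals=40, seed=13))
        strong = [c for c in chems if c.log_kow > 6][:3]
        assert strong
        records, truth = generate_observations(
            strong, lambda c: make_system(c, cell_type, fbs=20.0), "equilibrium_full",
            SyntheticSpec(n_chemicals=1, seed=1, noise_sd_log10=0.0),
            endpoints=("f_free_media",),
        )
        censored = [r for r in records if truth.loc[r.chemical_id, "f_free_media"] < 0.01]
        assert censored
        for rec in censored:
            assert rec.censor == CENSOR_ABOVE
            assert rec.value == pytest.approx(0.005)

    def test_censoring_rate_monotone_in_noise(self, cell_type):
        """For truths inside the reporting limits, noise can only push
        observations into the censored zones, so the rate grows with sd."""
        spec0, chems, system_for = self._setup(noise=0.0, n=200, seed=29)
        _, truth = generate_observations(chems, system_for, "equilibrium_full", spec0,
                                         endpoints=("f_free_media",))
        mid = [c for c in chems if 0.2 < truth.loc[c.id, "f_free_media"] < 0.8]
        assert len(mid) > 20
        rates = []
        for s in (0.0, 0.5, 1.5):
            spec = SyntheticSpec(n_chemicals=len(mid), seed=29, noise_sd_log10=s)
            records, _ = generate_observations(mid, system_for, "equilibrium_full", spec,
                                               endpoints=("f_free_media",))
            rates.append(np.mean([r.censor != CENSOR_NONE for r in records]))
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > rates[0]


class TestPodPairs:
    def _fub_media(self, chems, cells, cfg):
        out = {}
        for chem in chems:
            dist = predict_distribution(chem, make_system(chem, cells[0]), "equilibrium_full", cfg)
            out[chem.id] = dist.f_free_media
        return out

    def test_zero_scatter_adjusted_concordance_is_exact(self):
        cfg = Config()
        chems = generate_chemicals(SyntheticSpec(n_chemicals=15, seed=41))
        cells = generate_cell_types(1, seed=41, include_extremes=False)
        tk = generate_tk_params(chems, seed=41)
        fub_media = self._fub_media(chems, cells, cfg)
        invitro, invivo = generate_pod_pairs(chems, tk, fub_media, scatter_sd=0.0, seed=41)
        from vitrodist.qivive import css_steady_state, oed, oed_adjusted

        adjusted, unadjusted, cfs = {}, {}, {}
        for chem, pod in zip(chems, invitro):
            css = css_steady_state(tk[chem.id], chem.mw, cfg.physiology)
            adjusted[chem.id] = oed_adjusted(pod.value, css, fub_media[chem.id],
                                             tk[chem.id].fub_plasma)
            unadjusted[chem.id] = oed(pod.value, css)
            cfs[chem.id] = fub_media[chem.id] / tk[chem.id].fub_plasma
        m_adj = concordance(adjusted, invivo)
        assert m_adj.mae == pytest.approx(0.0, abs=1e-9)
        # unadjusted error equals the correction-factor spread exactly
        m_unadj = concordance(unadjusted, invivo)
        se = np.array([(np.log10(p.ci_upper) - np.log10(p.ci_lower)) / 2 / 1.96 for p in invivo])
        w = (1 / se**2)
        w = w / w.sum()
        expected_mae = float(w @ np.abs(np.log10([cfs[p.chemical_id] for p in invivo])))
        assert m_unadj.mae == pytest.approx(expected_mae, rel=1e-9)

    def test_seed_reproducibility(self):
        cfg = Config()
        chems = generate_chemicals(SyntheticSpec(n_chemicals=5, seed=51))
        cells = generate_cell_types(1, seed=51, include_extremes=False)
        tk = generate_tk_params(chems, seed=51)
        fub = self._fub_media(chems, cells, cfg)
        a = generate_pod_pairs(chems, tk, fub, scatter_sd=0.3, seed=51)
        b = generate_pod_pairs(chems, tk, fub, scatter_sd=0.3, seed=51)
        assert [p.value for p in a[1]] == [p.value for p in b[1]]


class TestEndToEndRecovery:
    def test_truth_flavor_ranks_best_without_noise(self, cell_type):
        """With noise-free observations generated by the full-system
        equilibrium model, evaluation ranks that flavor lowest-MAE among all
        applicable flavors."""
        cfg = Config()
        spec = SyntheticSpec(n_chemicals=10, seed=61, noise_sd_log10=0.0)
        chems = generate_chemicals(spec)

        def system_for(chem):
            return make_system(chem, cell_type)

        records, _ = generate_observations(chems, system_for, "equilibrium_full", spec,
                                           endpoints=("a_media",))
        obs = {r.chemical_id: r.value for r in records}
        maes = {}
        for flavor in MODEL_FLAVORS:
            usable = [c for c in chems if flavor_applicable(flavor, c, cfg)]
            pred = [predict_distribution(c, system_for(c), flavor, cfg).a_media for c in usable]
            maes[flavor] = compute_metrics(pred, [obs[c.id] for c in usable]).mae
        assert min(maes, key=maes.get) == "equilibrium_full"
        assert maes["equilibrium_full"] == pytest.approx(0.0, abs=1e-9)
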