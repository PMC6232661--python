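"""Ground-truth calibration and respondent sampling."""

import numpy as np
import pandas as pd
import pytest

from hfacsbn.inference import posterior
from hfacsbn.network import build_hfacs_structure, build_variable_catalog
from hfacsbn.questionnaire import SCALE_ITEMS, cronbach_alpha, discretize
from hfacsbn.simulate import (
    GeneratorConfig,
    goodness_ranks,
    make_ground_truth,
    make_study,
    sample_respondents,
)


class TestCalibration:
    def test_target_marginals_hit(self, ground_truth):
        m = ground_truth.model
        assert 0.274 <= posterior(m, "nsi")["yes"] <= 0.284
        assert posterior(m, "safety_motivation")["good"] == pytest.approx(0.432, abs=0.005)
        staffing = posterior(m, "staffing")
        assert staffing["moderate"] + staffing["good"] == pytest.approx(0.554, abs=0.005)
        assert posterior(m, "safe_procedures")["yes"] == pytest.approx(0.758, abs=1e-9)

    def test_zero_effects_decouple_outcome(self):
        config = GeneratorConfig(
            effect_strength={"l4_to_l3": 0.0, "l3_to_l2": 0.0, "l2_to_nsi": 0.0}
        )
        gt = make_ground_truth(config)
        from hfacsbn.sensitivity import mutual_information

        for name in gt.model.structure.names:
            if name == "nsi":
                continue
            mi, _ = mutual_information(gt.model, name)
            assert mi == pytest.approx(0.0, abs=1e-12)

    def test_infeasible_target_reported(self):
        config = GeneratorConfig(
            target_marginals={
                "nsi_yes": 0.999,  # unreachable given theta clipping
                "staffing_moderate_or_good": 0.554,
                "procedures_available": 0.758,
                "motivation_good": 0.432,
            }
        )
        with pytest.raises(ValueError, match="infeasible"):
            make_ground_truth(config)

    def test_monotone_in_every_parent(self, ground_truth):
        """Flipping any single parent toward a better state never lowers the
        child's probability of its most favorable state (exhaustive)."""
        st = ground_truth.model.structure
        for name in st.names:
            pars = st.parents[name]
            if not pars:
                continue
            tab = ground_truth.model.cpts[name]
            g_child = goodness_ranks(st[name])
            fav = int(np.argmax(g_child))
            n_cfg = tab.shape[0]
            for cfg in range(n_cfg):
                states = st.parent_config_states(name, cfg)
                for i, p in enumerate(pars):
                    gp = goodness_ranks(st[p])
                    for s2 in range(st[p].n_states):
                        if gp[s2] <= gp[states[i]]:
                            continue
                        other = list(states)
                        other[i] = s2
                        cfg2 = st.parent_config_index(name, other)
                        assert tab[cfg2, fav] >= tab[cfg, fav] - 1e-12


class TestSampling:
    def test_same_seed_identical_csv(self, ground_truth):
        config = GeneratorConfig(seed=42, n_respondents=60)
        a = sample_respondents(make_ground_truth(config), config).to_csv(index=False)
        b = sample_respondents(make_ground_truth(config), config).to_csv(index=False)
        assert a == b

    def test_latents_recorded(self, ground_truth):
        config = GeneratorConfig(seed=1, n_respondents=25)
        gt = make_ground_truth(config)
        raw = sample_respondents(gt, config)
        assert len(raw) == 25
        assert len(gt.latent_states) == 25
        assert gt.latent_states["straightliner"].sum() == round(25 * 14 / 408)

    def test_direct_answers_respect_state_intervals(self):
        config = GeneratorConfig(seed=2, n_respondents=500, direct_missing_rate=0.0)
        gt = make_ground_truth(config)
        raw = sample_respondents(gt, config)
        st = gt.model.structure
        by_name = {v.name: v for v in st.variables}
        hours = raw["working_hours"].astype(float)
        for h, latent in zip(hours, gt.latent_states["working_hours"]):
            assert discretize(by_name["working_hours"], h) == latent
        nights = raw["night_shifts"].astype(float)
        for x, latent in zip(nights, gt.latent_states["night_shifts"]):
            assert discretize(by_name["night_shifts"], int(x)) == latent

    def test_empirical_marginals_match_exact(self, ground_truth):
        config = GeneratorConfig(seed=3, n_respondents=10_000)
        gt = make_ground_truth(config)
        sample_respondents(gt, config)
        latents = gt.latent_states
        for name in ("nsi", "staffing", "safety_motivation", "fatigue"):
            exact = posterior(gt.model, name)
            for state in gt.model.structure[name].states:
                p = exact[state]
                se = np.sqrt(p * (1 - p) / len(latents))
                emp = (latents[name] == state).mean()
                assert abs(emp - p) <= 3 * se + 1e-12, (name, state)

    def test_scale_state_recovery_from_items(self):
        """Re-discretized item means agree with the latent state >= 90% of
        the time at the default noise level (non-straight-liners)."""
        config = GeneratorConfig(seed=4, n_respondents=10_000, item_missing_rate=0.0)
        gt = make_ground_truth(config)
        raw = sample_respondents(gt, config)
        ok = ~gt.latent_states["straightliner"].to_numpy()
        catalog = {v.name: v for v in gt.model.structure.variables}
        agreements = []
        for scale, k in SCALE_ITEMS.items():
            cols = [f"{scale}_i{j}" for j in range(1, k + 1)]
            means = raw[cols].astype(float).mean(axis=1).to_numpy()[ok]
            latent = gt.latent_states[scale].to_numpy()[ok]
            states = [discretize(catalog[scale], m) for m in means]
            agreements.append(np.mean(np.array(states) == latent))
        assert np.mean(agreements) >= 0.90

    def test_more_item_noise_lowers_alpha(self):
        """Mean Cronbach alpha strictly decreases over a 3-point noise grid."""
        means = []
        for sd in (0.4, 0.8, 1.2):
            alphas = []
            for seed in (11, 12, 13):
                config = GeneratorConfig(seed=seed, n_respondents=2000,
                                         item_noise_sd=sd, item_missing_rate=0.0,
                                         straightliner_fraction=0.0)
                gt = make_ground_truth(config)
                raw = sample_respondents(gt, config)
                for scale, k in SCALE_ITEMS.items():
                    cols = [f"{scale}_i{j}" for j in range(1, k + 1)]
                    alphas.append(cronbach_alpha(raw[cols].astype(float).to_numpy()))
            means.append(np.mean(alphas))
        assert means[0] > means[1] > means[2]


class TestMakeStudy:
    def test_default_sizes(self, default_study):
        train, test, _, report = default_study
        assert (len(train), len(test)) == (343, 50)
        assert report.n_retained == 394

    def test_proportional_small_study(self):
        config = GeneratorConfig(seed=5, n_respondents=100, straightliner_fraction=0.0,
                                 direct_missing_rate=0.0)
        train, test, _, _ = make_study(config)
        assert (len(train), len(test)) == (87, 13)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_respondents=0)
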