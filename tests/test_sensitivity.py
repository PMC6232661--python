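"""Mutual information, predictive-reasoning scans, and interventions."""

import numpy as np
import pytest

from hfacsbn.inference import FullJoint, ImpossibleEvidenceError, posterior
from hfacsbn.network import BayesianNetworkModel
from hfacsbn.sensitivity import (
    best_worst_scan,
    evaluate_intervention,
    mutual_information,
    rank_predictors,
    sensitivity_index,
    sensitivity_report_csv,
)
from hfacsbn.simulate import GeneratorConfig, make_ground_truth

# published worst/best posteriors of P(NSI=no) and the sensitivity column
# they imply (relative percent gain, one decimal)
PUBLISHED_ROWS = [
    ("safety motivation", 62.8, 79.5, 26.6),
    ("fatigue", 65.3, 78.6, 20.4),
    ("teamwork", 67.2, 75.3, 12.1),
    ("physical environment", 66.7, 79.4, 19.0),
    ("supervisors' attitude", 59.6, 77.7, 30.4),
    ("safety training", 66.5, 74.8, 12.5),
    ("working hours per week", 63.8, 78.8, 23.5),
    ("night shifts", 64.9, 75.7, 16.6),
    ("staffing", 65.2, 76.0, 16.6),
    ("management commitment", 66.0, 75.8, 14.8),
    ("availability of safety procedures", 71.9, 72.2, 0.4),
]


@pytest.mark.parametrize("name, worst, best, expected", PUBLISHED_ROWS)
def test_sensitivity_index_reproduces_published_table(name, worst, best, expected):
    assert sensitivity_index(worst, best) == pytest.approx(expected)


def test_sensitivity_index_edge_cases():
    assert sensitivity_index(50.0, 50.0) == 0.0
    with pytest.raises(ZeroDivisionError):
        sensitivity_index(0.0, 10.0)
    with pytest.raises(ValueError):
        sensitivity_index(60.0, 50.0)


class TestMutualInformation:
    def test_independent_predictor_zero_bits(self, uniform_model):
        mi, pct = mutual_information(uniform_model, "safety_motivation")
        assert mi == pytest.approx(0.0, abs=1e-12)
        assert pct == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_copy_one_bit(self, structure, uniform_model):
        # NSI deterministically copies a uniform binary split of motivation
        # (poor vs good, each 0.5) -> I = H(NSI) = 1 bit, 100% of entropy
        cpts = uniform_model.cpts.copy()
        nsi_tab = np.zeros_like(cpts["nsi"])
        for cfg in range(nsi_tab.shape[0]):
            motivation = structure.parent_config_states("nsi", cfg)[3]
            nsi_tab[cfg] = [1.0, 0.0] if motivation == 0 else [0.0, 1.0]
        cpts["nsi"] = nsi_tab
        mot = np.zeros_like(cpts["safety_motivation"])
        mot[:, 0] = 0.5
        mot[:, 2] = 0.5
        cpts["safety_motivation"] = mot
        model = BayesianNetworkModel(structure, cpts)
        mi, pct = mutual_information(model, "safety_motivation")
        assert mi == pytest.approx(1.0, abs=1e-9)
        assert pct == pytest.approx(100.0, abs=1e-6)

    def test_matches_enumeration_oracle(self, random_model):
        model = random_model(31)
        mi, _ = mutual_information(model, "fatigue")
        # brute-force over the enumerated pairwise joint
        pxy = FullJoint(model).marginal(["fatigue", "nsi"])
        px, py = pxy.sum(axis=1), pxy.sum(axis=0)
        expected = sum(
            pxy[i, j] * np.log2(pxy[i, j] / (px[i] * py[j]))
            for i in range(3) for j in range(2) if pxy[i, j] > 0
        )
        assert mi == pytest.approx(expected, abs=1e-9)

    def test_bounded_by_entropies(self, ground_truth):
        fj = FullJoint(ground_truth.model)
        for name in ground_truth.model.structure.names:
            if name == "nsi":
                continue
            mi, _ = mutual_information(ground_truth.model, name)
            px = fj.marginal([name])
            py = fj.marginal(["nsi"])
            h = lambda p: -(p[p > 0] * np.log2(p[p > 0])).sum()
            assert -1e-12 <= mi <= min(h(px), h(py)) + 1e-9


class TestBestWorstScan:
    def test_brackets_baseline(self, ground_truth):
        model = ground_truth.model
        baseline = 100.0 * posterior(model, "nsi")["no"]
        for name in model.structure.names:
            if name == "nsi":
                continue
            _, worst, _, best = best_worst_scan(model, name)
            assert worst - 1e-9 <= baseline <= best + 1e-9

    def test_independent_predictor_flat(self, uniform_model):
        _, worst, _, best = best_worst_scan(uniform_model, "teamwork")
        assert worst == pytest.approx(best) == pytest.approx(50.0)

    def test_forced_outcome_state(self, structure, uniform_model):
        cpts = uniform_model.cpts.copy()
        tab = np.ones_like(cpts["nsi"]) * 0.5
        for cfg in range(tab.shape[0]):
            if structure.parent_config_states("nsi", cfg)[0] == 2:  # fatigue high
                tab[cfg] = [1.0, 0.0]
        cpts["nsi"] = tab
        model = BayesianNetworkModel(structure, cpts)
        worst_state, worst, _, _ = best_worst_scan(model, "fatigue")
        assert worst_state == "high"
        assert worst == pytest.approx(0.0)


class TestRanking:
    def test_grouped_layout(self, ground_truth):
        grouped = rank_predictors(ground_truth.model)
        sizes = {g: len(rows) for g, rows in grouped.items()}
        assert sizes == {
            "preconditions for unsafe acts": 4,
            "unsafe supervision": 4,
            "organizational influences": 3,
        }
        for rows in grouped.values():
            sens = [r.sensitivity_pct for r in rows]
            assert sens == sorted(sens, reverse=True)
            for r in rows:
                assert r.best_posterior_pct >= r.worst_posterior_pct
                assert r.mutual_information_bits >= 0

    def test_strong_predictor_ranks_first(self, structure, uniform_model):
        cpts = uniform_model.cpts.copy()
        tab = np.empty_like(cpts["nsi"])
        for cfg in range(tab.shape[0]):
            fatigue = structure.parent_config_states("nsi", cfg)[0]
            p_yes = (0.1, 0.5, 0.9)[fatigue]
            tab[cfg] = [p_yes, 1 - p_yes]
        cpts["nsi"] = tab
        model = BayesianNetworkModel(structure, cpts)
        rows = rank_predictors(model)["preconditions for unsafe acts"]
        assert rows[0].predictor == "fatigue"
        for r in rows[1:]:
            assert r.sensitivity_pct == pytest.approx(0.0, abs=1e-6)

    def test_all_null_model(self, uniform_model):
        grouped = rank_predictors(uniform_model)
        for rows in grouped.values():
            for r in rows:
                assert r.sensitivity_pct == pytest.approx(0.0, abs=1e-6)

    def test_mi_and_sensitivity_rankings_agree_on_dominant_level(self, ground_truth):
        """Both orderings put the outcome's direct parents (preconditions)
        above every level-3/4 predictor; within the preconditions the two
        orderings are near-ties by construction, so the level-dominance is
        the stable shared signal."""
        grouped = rank_predictors(ground_truth.model)
        rows = [r for rows in grouped.values() for r in rows]
        level2 = [r for r in rows if r.hfacs_level == 2]
        others = [r for r in rows if r.hfacs_level != 2]
        for metric in (lambda r: r.sensitivity_pct,
                       lambda r: r.mutual_information_bits):
            assert min(metric(r) for r in level2) > max(metric(r) for r in others)

    def test_csv_report_has_eleven_rows(self, ground_truth):
        text = sensitivity_report_csv(rank_predictors(ground_truth.model))
        lines = text.strip().splitlines()
        assert len(lines) == 12  # header + 11 predictors


class TestIntervention:
    def test_complement_identity(self, ground_truth):
        res = evaluate_intervention(ground_truth.model, {"safety_motivation": "good"})
        assert res.posterior_no_pct + res.nsi_rate_pct == pytest.approx(100.0)

    def test_published_complement_arithmetic(self):
        # a best-state posterior of 79.5% "no" is an NSI rate of 20.5%,
        # and 78.6% corresponds to 21.4%
        for no_pct, rate in [(79.5, 20.5), (78.6, 21.4)]:
            assert 100.0 - no_pct == pytest.approx(rate)

    def test_empty_evidence_is_baseline(self, ground_truth):
        res = evaluate_intervention(ground_truth.model, {})
        assert res.change_pct_points == pytest.approx(0.0)
        assert res.posterior_no_pct == pytest.approx(res.baseline_no_pct)

    def test_outcome_evidence_rejected(self, ground_truth):
        with pytest.raises(ValueError, match="outcome"):
            evaluate_intervention(ground_truth.model, {"nsi": "no"})

    def test_impossible_evidence_signalled(self, structure, uniform_model):
        cpts = uniform_model.cpts.copy()
        cpts["safe_procedures"] = np.array([[1.0, 0.0]])
        model = BayesianNetworkModel(structure, cpts)
        with pytest.raises(ImpossibleEvidenceError):
            evaluate_intervention(model, {"safe_procedures": "no"})

    def test_joint_beats_every_single(self, ground_truth):
        joint_evidence = {
            "management_commitment": "good",
            "staffing": "good",
            "supervisor_attitude": "good",
            "working_hours": "normal",
        }
        joint = evaluate_intervention(ground_truth.model, joint_evidence)
        for name, state in joint_evidence.items():
            single = evaluate_intervention(ground_truth.model, {name: state})
            assert joint.nsi_rate_pct <= single.nsi_rate_pct + 1e-9

    def test_do_operator_equals_conditioning_on_root(self, ground_truth):
        obs = evaluate_intervention(ground_truth.model, {"staffing": "good"})
        do = evaluate_intervention(
            ground_truth.model, {"staffing": "good"}, do_operator=True
        )
        assert do.nsi_rate_pct == pytest.approx(obs.nsi_rate_pct, abs=1e-9)

    def test_dseparated_intervention_no_effect(self, uniform_model):
        res = evaluate_intervention(uniform_model, {"management_commitment": "good"})
        assert res.change_pct_points == pytest.approx(0.0, abs=1e-9)
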