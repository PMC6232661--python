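"""Predictor ranking by mutual information and predictive reasoning;
what-if intervention evaluation on the injury outcome.

Predictive reasoning sets a predictor to each of its states in turn and
reads off the posterior of "no injury". The sensitivity index is the
relative percent gain of P(NSI = no) from the predictor's worst state to
its best state, 100 * (best - worst) / worst. Mutual information
I(X; NSI) = sum_xy P(x, y) log2 [P(x, y) / (P(x) P(y))] measures, in bits,
the expected reduction in outcome uncertainty from observing the predictor;
it is also reported as a percent of the outcome entropy H(NSI).

An intervention is an evidence set (simple: one variable at its best state;
joint: several at once); its effect is the conditional NSI rate under that
evidence. This is observational conditioning — the reading of "predictive
reasoning" used throughout — not graph surgery; a truncated-product
do-operator mode is available behind a flag for comparison.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .inference import joint_marginal, posterior
from .network import BayesianNetworkModel, LEVEL_NAMES

__all__ = [
    "SensitivityRow",
    "InterventionResult",
    "mutual_information",
    "best_worst_scan",
    "sensitivity_index",
    "rank_predictors",
    "sensitivity_report_csv",
    "evaluate_intervention",
]

OUTCOME = "nsi"
FAVORABLE_OUTCOME = "no"


@dataclass(frozen=True)
class SensitivityRow:
    predictor: str
    hfacs_level: int
    worst_state: str
    worst_posterior_pct: float  # P(NSI = no | worst state), percent
    best_state: str
    best_posterior_pct: float
    sensitivity_pct: float
    mutual_information_bits: float
    mi_pct_of_outcome_entropy: float


@dataclass(frozen=True)
class InterventionResult:
    evidence: dict[str, str]
    posterior_no_pct: float  # P(NSI = no | evidence), percent
    nsi_rate_pct: float      # complement: predicted injury rate, percent
    baseline_no_pct: float   # P(NSI = no) with no evidence
    change_pct_points: float  # posterior_no_pct - baseline_no_pct


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mutual_information(
    model: BayesianNetworkModel, predictor: str, outcome: str = OUTCOME
) -> tuple[float, float]:
    """I(predictor; outcome) in bits, and as a percent of H(outcome).

    The pairwise joint is obtained by exact inference on the network.
    """
    if predictor == outcome:
        raise ValueError("mutual information requires two distinct variables")
    pxy = joint_marginal(model, [predictor, outcome])
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    mi = float((pxy[mask] * np.log2(pxy[mask] / (px @ py)[mask])).sum())
    mi = max(mi, 0.0)  # clip tiny negative rounding residue
    h_outcome = _entropy_bits(py.ravel())
    pct = 100.0 * mi / h_outcome if h_outcome > 0 else 0.0
    return mi, pct


def best_worst_scan(
    model: BayesianNetworkModel, predictor: str, outcome: str = OUTCOME,
    favorable: str = FAVORABLE_OUTCOME,
) -> tuple[str, float, str, float]:
    """Scan a predictor's states for the worst and best outcome posterior.

    Returns (worst state, worst %, best state, best %) where each percent is
    100 * P(outcome = favorable | predictor = state). Ties keep the earliest
    state in the variable's declared order.
    """
    if predictor == outcome:
        raise ValueError("predictor must differ from the outcome")
    spec = model.structure[predictor]
    percents = [
        100.0 * posterior(model, outcome, {predictor: s})[favorable]
        for s in spec.states
    ]
    worst_i = int(np.argmin(percents))
    best_i = int(np.argmax(percents))
    return spec.states[worst_i], percents[worst_i], spec.states[best_i], percents[best_i]


def sensitivity_index(worst_pct: float, best_pct: float) -> float:
    """Relative percent gain from worst to best state, to one decimal.

    100 * (best - worst) / worst; undefined when the worst-state posterior
    is zero.
    """
    if worst_pct == 0:
        raise ZeroDivisionError("sensitivity index undefined: worst-state posterior is 0")
    if best_pct < worst_pct:
        raise ValueError("best posterior must be >= worst posterior")
    return round(100.0 * (best_pct - worst_pct) / worst_pct, 1)


def rank_predictors(
    model: BayesianNetworkModel, outcome: str = OUTCOME
) -> dict[str, list[SensitivityRow]]:
    """Sensitivity table: predictors grouped by HFACS level, strongest first.

    Groups follow the causal distance from the outcome (preconditions, then
    unsafe supervision, then organizational influences); within a group rows
    sort by sensitivity index descending.
    """
    rows = []
    for v in model.structure.variables:
        if v.name == outcome:
            continue
        worst_s, worst, best_s, best = best_worst_scan(model, v.name, outcome)
        mi, mi_pct = mutual_information(model, v.name, outcome)
        rows.append(
            SensitivityRow(
                predictor=v.name,
                hfacs_level=v.hfacs_level,
                worst_state=worst_s,
                worst_posterior_pct=worst,
                best_state=best_s,
                best_posterior_pct=best,
                sensitivity_pct=sensitivity_index(worst, best) if worst > 0 else float("nan"),
                mutual_information_bits=mi,
                mi_pct_of_outcome_entropy=mi_pct,
            )
        )
    grouped: dict[str, list[SensitivityRow]] = {}
    for level in (2, 3, 4):
        level_rows = [r for r in rows if r.hfacs_level == level]
        level_rows.sort(key=lambda r: -r.sensitivity_pct)
        grouped[LEVEL_NAMES[level]] = level_rows
    return grouped


def sensitivity_report_csv(grouped: Mapping[str, Sequence[SensitivityRow]]) -> str:
    """Render the grouped sensitivity table as CSV."""
    buf = io.StringIO()
    buf.write(
        "group,predictor,worst_state,worst_posterior_no_pct,best_state,"
        "best_posterior_no_pct,sensitivity_pct,mutual_information_bits,"
        "mi_pct_of_outcome_entropy\n"
    )
    for group, rows in grouped.items():
        for r in rows:
            buf.write(
                f"{group},{r.predictor},{r.worst_state},{r.worst_posterior_pct:.1f},"
                f"{r.best_state},{r.best_posterior_pct:.1f},{r.sensitivity_pct:.1f},"
                f"{r.mutual_information_bits:.3f},{r.mi_pct_of_outcome_entropy:.1f}\n"
            )
    return buf.getvalue()


def evaluate_intervention(
    model: BayesianNetworkModel,
    evidence: Mapping[str, str],
    outcome: str = OUTCOME,
    favorable: str = FAVORABLE_OUTCOME,
    *,
    do_operator: bool = False,
) -> InterventionResult:
    """Predicted injury rate when the evidence set is imposed.

    The reported ``nsi_rate_pct`` is 100 - P(outcome = favorable | evidence)
    in percent. With ``do_operator=True`` the intervened variables' CPTs are
    replaced by point masses before conditioning (truncated factorization),
    which differs from evidence-setting whenever intervened variables have
    parents; the default observational mode is what predictive reasoning on
    this network denotes.
    """
    if outcome in evidence:
        raise ValueError("intervention evidence must not include the outcome")
    work = model
    if do_operator and evidence:
        st = model.structure
        cpts = model.cpts.copy()
        for name, state in evidence.items():
            idx = st[name].state_index(state)
            tab = np.zeros(st.cpt_shape(name))
            tab[:, idx] = 1.0
            cpts[name] = tab
        work = BayesianNetworkModel(st, cpts)
    post = posterior(work, outcome, dict(evidence))
    baseline = posterior(model, outcome, {})
    no_pct = 100.0 * post[favorable]
    base_pct = 100.0 * baseline[favorable]
    return InterventionResult(
        evidence=dict(evidence),
        posterior_no_pct=no_pct,
        nsi_rate_pct=100.0 - no_pct,
        baseline_no_pct=base_pct,
        change_pct_points=no_pct - base_pct,
    )
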