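"""Held-out model scoring: confusion matrix, error rate, and proper scoring rules.

For each test case the model emits a predicted distribution (P_1..P_n) over
the outcome states; P_c denotes the probability assigned to the state that
actually occurred. All four indices are means over cases (MOAC):

* error rate (%) — argmax classification, 100 * (FP + FN) / n; ties go to
  "yes" as the conservative call for an injury outcome;
* logarithmic loss — mean of -log(P_c), natural log by default (0 = perfect);
* quadratic (Brier) loss — mean of 1 - 2 P_c + sum_j P_j^2, in [0, 2],
  lower better;
* spherical payoff — mean of P_c / sqrt(sum_j P_j^2), in [0, 1], higher
  better.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .inference import predict_case
from .network import BayesianNetworkModel
from .questionnaire import DiscreteDataset

__all__ = [
    "PredictionRecord",
    "PerformanceReport",
    "confusion_and_error_rate",
    "logarithmic_loss",
    "quadratic_loss",
    "spherical_payoff",
    "evaluate",
]


@dataclass(frozen=True)
class PredictionRecord:
    """One scored test case: predicted distribution plus the realized state."""

    states: tuple[str, ...]
    probabilities: tuple[float, ...]
    actual: str

    def __post_init__(self):
        if abs(sum(self.probabilities) - 1.0) > 1e-9:
            raise ValueError("predicted probabilities must sum to 1")
        if self.actual not in self.states:
            raise ValueError(f"actual state {self.actual!r} not among {self.states}")

    @property
    def p_correct(self) -> float:
        """P_c, the predicted probability of the state that occurred."""
        return self.probabilities[self.states.index(self.actual)]

    @property
    def predicted(self) -> str:
        """Argmax state; ties resolve to 'yes' when present, else first state."""
        probs = np.asarray(self.probabilities)
        best = probs.max()
        tied = [s for s, p in zip(self.states, probs) if p == best]
        return "yes" if "yes" in tied else tied[0]


@dataclass
class PerformanceReport:
    confusion: dict[str, dict[str, int]]  # actual -> predicted -> count
    error_rate_pct: float
    logarithmic_loss: float
    quadratic_loss: float
    spherical_payoff: float
    n_cases: int
    n_skipped: int = 0

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.__dict__, indent=indent)

    def to_table(self) -> str:
        """Plain-text summary table of the four indices."""
        lines = [
            f"{'Index':<24}{'Value':>8}  Range",
            f"{'Total error rate (%)':<24}{self.error_rate_pct:>8.2f}  0-100 (lower better)",
            f"{'Logarithmic loss':<24}{self.logarithmic_loss:>8.2f}  0-inf (lower better)",
            f"{'Quadratic loss':<24}{self.quadratic_loss:>8.2f}  0-2 (lower better)",
            f"{'Spherical payoff':<24}{self.spherical_payoff:>8.2f}  0-1 (higher better)",
            f"(n = {self.n_cases} test cases)",
        ]
        return "\n".join(lines)


def _require(predictions: Sequence[PredictionRecord]):
    if not predictions:
        raise ValueError("no predictions to score")


def confusion_and_error_rate(
    predictions: Sequence[PredictionRecord],
) -> tuple[dict[str, dict[str, int]], float]:
    """Confusion matrix (actual x predicted) and total error rate in percent."""
    _require(predictions)
    states = predictions[0].states
    confusion = {a: {p: 0 for p in states} for a in states}
    wrong = 0
    for rec in predictions:
        confusion[rec.actual][rec.predicted] += 1
        wrong += rec.predicted != rec.actual
    return confusion, 100.0 * wrong / len(predictions)


def logarithmic_loss(predictions: Sequence[PredictionRecord], base: float | None = None) -> float:
    """Mean of -log(P_c); natural log unless ``base`` is given."""
    _require(predictions)
    pcs = np.array([r.p_correct for r in predictions])
    if (pcs <= 0).any():
        raise ValueError(
            "a case received probability 0 for its realized state; "
            "fit with a positive pseudocount to avoid degenerate CPT entries"
        )
    losses = -np.log(pcs)
    if base is not None:
        losses /= math.log(base)
    return float(losses.mean())


def quadratic_loss(predictions: Sequence[PredictionRecord]) -> float:
    """Mean of 1 - 2 P_c + sum_j P_j^2; for binary outcomes this equals twice
    the mean Brier score of the predicted 'yes' probability."""
    _require(predictions)
    return float(
        np.mean([1.0 - 2.0 * r.p_correct + sum(p * p for p in r.probabilities)
                 for r in predictions])
    )


def spherical_payoff(predictions: Sequence[PredictionRecord]) -> float:
    """Mean of P_c / sqrt(sum_j P_j^2)."""
    _require(predictions)
    return float(
        np.mean([r.p_correct / math.sqrt(sum(p * p for p in r.probabilities))
                 for r in predictions])
    )


def evaluate(
    model: BayesianNetworkModel,
    test: DiscreteDataset,
    outcome: str = "nsi",
) -> PerformanceReport:
    """Score a trained model on held-out cases.

    Each record's non-missing predictor states are entered as evidence, the
    posterior of the outcome is the prediction, and all four indices are
    computed over the cases with an observed outcome (records missing the
    outcome are skipped and counted in ``n_skipped``).
    """
    predictions = []
    skipped = 0
    for rec in test.records():
        actual = rec.pop(outcome, None)
        if actual is None:
            skipped += 1
            continue
        post = predict_case(model, rec, outcome=outcome)
        predictions.append(PredictionRecord(post.states, post.probabilities, actual))
    if not predictions:
        raise ValueError("test set has no records with an observed outcome")
    confusion, err = confusion_and_error_rate(predictions)
    return PerformanceReport(
        confusion=confusion,
        error_rate_pct=err,
        logarithmic_loss=logarithmic_loss(predictions),
        quadratic_loss=quadratic_loss(predictions),
        spherical_payoff=spherical_payoff(predictions),
        n_cases=len(predictions),
        n_skipped=skipped,
    )
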