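"""Questionnaire ingestion: quality filtering, scale scoring, discretization.

The survey instrument measures eight constructs with multi-item 5-point
Likert scales (5 items for management commitment, 4 for each of the others;
33 items in total), and four quantities with single direct questions (night
shifts per month, working hours per week, availability of safe work
procedures, NSI in the last 3 months). A scale's score is the mean of its
answered items; scores and direct answers are then discretized into the
model's ordered states.

CSV dialect: one row per respondent, UTF-8, missing answers as empty cells.
Scale items are named ``<scale>_i<j>`` (1-based); direct questions use the
variable name (``night_shifts``, ``working_hours``, ``safe_procedures``,
``nsi``). An optional ``respondent_id`` and ``hospital_id`` column are
carried through unmodified.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import VariableSpec, build_variable_catalog

__all__ = [
    "SCALE_ITEMS",
    "DIRECT_COLUMNS",
    "RespondentRecord",
    "DiscreteDataset",
    "QualityReport",
    "ZeroVarianceError",
    "score_scale",
    "discretize",
    "cronbach_alpha",
    "detect_systematic_pattern",
    "parse_records",
    "preprocess",
    "train_test_split",
]

#: Multi-item scales and their item counts.
SCALE_ITEMS: dict[str, int] = {
    "management_commitment": 5,
    "staffing": 4,
    "supervisor_attitude": 4,
    "safety_training": 4,
    "fatigue": 4,
    "teamwork": 4,
    "physical_environment": 4,
    "safety_motivation": 4,
}

#: Directly asked variables (single question each).
DIRECT_COLUMNS = ("night_shifts", "working_hours", "safe_procedures", "nsi")

#: Study design constants: 343 training and 50 test cases out of 393 usable.
TRAIN_SIZE, TEST_SIZE = 343, 50
REFERENCE_TOTAL = TRAIN_SIZE + TEST_SIZE


class ZeroVarianceError(ValueError):
    """Cronbach's alpha is undefined when the item-sum variance is zero."""


@dataclass
class RespondentRecord:
    """Raw item-level answers of one respondent. ``None`` marks a missing answer."""

    respondent_id: str
    items: dict[str, list[int | None]]
    night_shifts: int | None = None
    working_hours: float | None = None
    safe_procedures: str | None = None
    nsi: str | None = None

    def all_items(self) -> list[int | None]:
        """Every Likert item in fixed scale order (straight-lining check)."""
        return [x for scale in SCALE_ITEMS for x in self.items[scale]]


@dataclass
class QualityReport:
    n_received: int
    n_malformed: int
    n_flagged: int
    n_retained: int
    alphas: dict[str, float]
    warnings: list[str] = field(default_factory=list)


@dataclass
class DiscreteDataset:
    """Respondent-level discretized states, one column per model variable.

    ``frame`` holds state labels (``None``/NaN = missing after preprocessing;
    EM handles residual missingness). ``kept`` records provenance for every
    received row, including those the quality filter discarded.
    """

    frame: pd.DataFrame
    kept: pd.Series | None = None

    def __len__(self) -> int:
        return len(self.frame)

    def records(self) -> Iterable[dict[str, str | None]]:
        for _, row in self.frame.iterrows():
            yield {k: (None if pd.isna(v) else v) for k, v in row.items()}

    def subset(self, index) -> "DiscreteDataset":
        return DiscreteDataset(self.frame.loc[index])

    def to_csv(self, path_or_buf=None):
        return self.frame.to_csv(path_or_buf, index_label="respondent_id")

    @classmethod
    def from_csv(cls, path_or_buf) -> "DiscreteDataset":
        frame = pd.read_csv(path_or_buf, index_col="respondent_id", dtype=object)
        return cls(frame)


def score_scale(item_responses: Sequence[int | None]) -> float | None:
    """Scale score = arithmetic mean of the answered items, in [1, 5].

    Returns ``None`` (missing) when fewer than half of the items were
    answered; residual missingness is left to EM downstream.
    """
    answered = [x for x in item_responses if x is not None]
    for x in answered:
        if not (isinstance(x, (int, np.integer)) and 1 <= x <= 5):
            raise ValueError(f"Likert item out of range 1-5: {x!r}")
    if len(answered) < len(item_responses) / 2 or not answered:
        return None
    return float(np.mean(answered))


# interval edges for the three equal parts of the 1-5 score range
_SCORE_EDGES = (7.0 / 3.0, 11.0 / 3.0)


def discretize(variable: VariableSpec, raw) -> str:
    """Map a raw value onto one of the variable's ordered states.

    Scale scores split the 1-5 range into three equal intervals, closed on
    the left: [1, 7/3) / [7/3, 11/3) / [11/3, 5]. Working hours per week:
    normal (<45), high (45-55), very high (>55). Night shifts per month:
    normal (<=8), high (9-11), very high (>=12). Binary answers pass
    through. State labels are not accepted as input for graded rules:
    discretization is a one-way mapping from measurements.
    """
    rule = variable.discretization_rule
    if rule == "binary_passthrough":
        if raw not in variable.states:
            raise ValueError(f"{variable.name}: expected one of {variable.states}, got {raw!r}")
        return raw
    if isinstance(raw, str):
        raise TypeError(f"{variable.name}: got a label {raw!r}; expected a measurement")
    if rule == "scale_score_terciles":
        if not (1.0 <= raw <= 5.0):
            raise ValueError(f"{variable.name}: score {raw!r} outside [1, 5]")
        if raw < _SCORE_EDGES[0]:
            return variable.states[0]
        if raw < _SCORE_EDGES[1]:
            return variable.states[1]
        return variable.states[2]
    if rule == "working_hour_intervals":
        if raw < 0:
            raise ValueError(f"working hours must be non-negative, got {raw!r}")
        return "normal" if raw < 45 else ("high" if raw <= 55 else "very_high")
    if rule == "night_shift_intervals":
        if raw < 0 or raw != int(raw):
            raise ValueError(f"night shifts must be a non-negative integer, got {raw!r}")
        return "normal" if raw <= 8 else ("high" if raw <= 11 else "very_high")
    raise KeyError(f"unknown discretization rule {rule!r}")


def cronbach_alpha(items: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha of an n x k item matrix (complete rows only).

    alpha = k/(k-1) * (1 - sum of item variances / variance of item sums),
    with sample variances (ddof=1). Rows with any missing item are dropped
    (listwise deletion for this computation only).
    """
    arr = np.asarray(items, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected an n x k matrix")
    arr = arr[~np.isnan(arr).any(axis=1)]
    n, k = arr.shape
    if k < 2 or n < 2:
        raise ValueError(f"need at least 2 items and 2 complete rows, got {arr.shape}")
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ZeroVarianceError("zero variance of item sums; alpha undefined")
    item_var = arr.var(axis=0, ddof=1).sum()
    return k / (k - 1) * (1.0 - item_var / total_var)


def detect_systematic_pattern(record: RespondentRecord) -> bool:
    """Flag straight-lining: every Likert item answered with one same value.

    Zero variance across the whole questionnaire is the telltale of
    responding by pattern rather than reading the items; such records are
    discarded before training.
    """
    items = record.all_items()
    if any(x is None for x in items):
        return False
    return len(set(items)) == 1


# ---------------------------------------------------------------------------
# CSV parsing and the full preprocessing pipeline


def _parse_cell(val):
    if val is None:
        return None
    if pd.api.types.is_scalar(val) and pd.isna(val):
        return None
    if isinstance(val, str) and val.strip() == "":
        return None
    return val


def parse_records(frame: pd.DataFrame) -> tuple[list[RespondentRecord], list[str]]:
    """Parse a raw questionnaire table into records; malformed rows reported."""
    records, malformed = [], []
    id_col = frame["respondent_id"] if "respondent_id" in frame else pd.Series(
        [str(i) for i in frame.index], index=frame.index
    )
    for idx, row in frame.iterrows():
        rid = str(id_col.loc[idx])
        try:
            items = {}
            for scale, k in SCALE_ITEMS.items():
                vals = []
                for j in range(1, k + 1):
                    cell = _parse_cell(row.get(f"{scale}_i{j}"))
                    if cell is None:
                        vals.append(None)
                    else:
                        v = float(cell)
                        if v != int(v) or not (1 <= v <= 5):
                            raise ValueError(f"{scale}_i{j}={cell!r}")
                        vals.append(int(v))
                items[scale] = vals
            ns = _parse_cell(row.get("night_shifts"))
            wh = _parse_cell(row.get("working_hours"))
            sp = _parse_cell(row.get("safe_procedures"))
            nsi = _parse_cell(row.get("nsi"))
            for label, v in (("safe_procedures", sp), ("nsi", nsi)):
                if v is not None and v not in ("yes", "no"):
                    raise ValueError(f"{label}={v!r}")
            records.append(
                RespondentRecord(
                    rid, items,
                    night_shifts=None if ns is None else int(float(ns)),
                    working_hours=None if wh is None else float(wh),
                    safe_procedures=sp, nsi=nsi,
                )
            )
        except (ValueError, TypeError) as exc:
            malformed.append(f"row {rid}: {exc}")
    return records, malformed


def preprocess(
    raw: pd.DataFrame | str | io.IOBase,
    catalog: Sequence[VariableSpec] | None = None,
) -> tuple[DiscreteDataset, QualityReport]:
    """Run the full pretreatment pipeline on raw questionnaire data.

    Steps: parse rows (malformed rows reported and dropped), discard
    straight-lining respondents, average each scale's answered items into a
    score, discretize every variable into its states, and compute per-scale
    Cronbach alphas on the retained records. Missing values survive as
    missing — the EM trainer consumes them directly.
    """
    if not isinstance(raw, pd.DataFrame):
        raw = pd.read_csv(raw, dtype=object)
    catalog = list(catalog) if catalog is not None else build_variable_catalog()
    by_name = {v.name: v for v in catalog}

    records, malformed = parse_records(raw)
    warnings = list(malformed)
    if not records:
        warnings.append("empty input: no parsable records")

    flags = [detect_systematic_pattern(r) for r in records]
    kept_records = [r for r, f in zip(records, flags) if not f]

    rows, ids = [], []
    for r in kept_records:
        row: dict[str, str | None] = {}
        for scale in SCALE_ITEMS:
            score = score_scale(r.items[scale])
            row[scale] = None if score is None else discretize(by_name[scale], score)
        for name in ("night_shifts", "working_hours", "safe_procedures", "nsi"):
            value = getattr(r, name)
            row[name] = None if value is None else discretize(by_name[name], value)
        rows.append(row)
        ids.append(r.respondent_id)

    columns = [v.name for v in catalog]
    frame = pd.DataFrame(rows, index=pd.Index(ids, name="respondent_id"), columns=columns)
    kept = pd.Series(
        [not f for f in flags],
        index=pd.Index([r.respondent_id for r in records], name="respondent_id"),
        name="kept",
    )

    alphas = {}
    for scale, k in SCALE_ITEMS.items():
        mat = np.array(
            [[np.nan if x is None else x for x in r.items[scale]] for r in kept_records],
            dtype=float,
        ).reshape(-1, k)
        try:
            alphas[scale] = cronbach_alpha(mat)
        except (ValueError, ZeroVarianceError) as exc:
            alphas[scale] = float("nan")
            warnings.append(f"alpha undefined for {scale}: {exc}")

    report = QualityReport(
        n_received=len(raw),
        n_malformed=len(malformed),
        n_flagged=int(sum(flags)),
        n_retained=len(kept_records),
        alphas=alphas,
        warnings=warnings,
    )
    return DiscreteDataset(frame, kept), report


def train_test_split(
    dataset: DiscreteDataset, seed: int
) -> tuple[DiscreteDataset, DiscreteDataset]:
    """Deterministic train/test split mirroring the study design.

    With at least 393 usable records the study's exact sizes are used
    (343 train / 50 test; any excess is left unassigned); with fewer, sizes
    scale proportionally (test = round(n * 50/393)). Test cases are drawn
    only from records with an observed NSI outcome, since held-out scoring
    needs the true label; records missing the outcome remain available to
    EM in the training set.
    """
    n = len(dataset)
    if n >= REFERENCE_TOTAL:
        n_train, n_test = TRAIN_SIZE, TEST_SIZE
    else:
        n_test = round(n * TEST_SIZE / REFERENCE_TOTAL)
        n_train = n - n_test
    rng = np.random.default_rng(seed)
    index = dataset.frame.index
    eligible = index[dataset.frame["nsi"].notna()]
    if len(eligible) < n_test:
        raise ValueError(
            f"only {len(eligible)} records with observed outcome; need {n_test} test cases"
        )
    test_ids = rng.choice(eligible, size=n_test, replace=False)
    remaining = index.difference(test_ids, sort=False)
    train_ids = rng.choice(remaining, size=min(n_train, len(remaining)), replace=False)
    return dataset.subset(sorted(train_ids)), dataset.subset(sorted(test_ids))
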