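"""Prognostic evaluation: recency split, k-fold CV, and the quotient metric.

A prognosis is judged by the quotient Q = actual / predicted life
expectancy: it is *accurate* when Q lies in [0.67, 1.33] (a 33%
proportional margin, the criterion of the hospice study on physicians'
prognoses), *overly optimistic* when Q < 0.67 (the patient died sooner
than predicted) and *overly pessimistic* when Q > 1.33. The proportional
band is more tolerant for long-horizon predictions than for short ones.

Deviation statistics use the convention ``predicted - actual``, so a
positive mean deviation means life expectancy was overestimated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .emr_data import Cohort

__all__ = [
    "PrognosisOutcome",
    "MetricsReport",
    "split_recent",
    "kfold",
    "quotient_class",
    "deviation_stats",
    "accuracy_breakdown",
    "certainty_analyses",
    "prediction_histogram",
    "chance_accuracy",
    "HOSPICE_HUMAN_BASELINE",
]

MAX_MONTH = 50

#: Physicians' reference performance from the hospice study
#: (accuracy, overly pessimistic, overly optimistic, in %).
HOSPICE_HUMAN_BASELINE = {"accuracy": 20.0, "pessimistic": 17.0, "optimistic": 63.0}


@dataclass(frozen=True)
class PrognosisOutcome:
    patient_id: str
    actual: int
    predicted: int
    quotient: float
    klass: str  # accurate | optimistic | pessimistic
    certainty: float


@dataclass
class MetricsReport:
    rmse: float
    mean_deviation: float
    accuracy_pct: float
    pessimistic_pct: float
    optimistic_pct: float
    n_outcomes: int
    predicted_histogram: list[int]  # counts per predicted month 1..50
    actual_histogram: list[int]
    correlations: list[tuple[str, float, float]] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "rmse": round(self.rmse, 6),
            "mean_deviation": round(self.mean_deviation, 6),
            "accuracy_pct": round(self.accuracy_pct, 6),
            "pessimistic_pct": round(self.pessimistic_pct, 6),
            "optimistic_pct": round(self.optimistic_pct, 6),
            "n_outcomes": self.n_outcomes,
            "predicted_histogram": self.predicted_histogram,
            "actual_histogram": self.actual_histogram,
            "correlations": [
                {"name": n, "r": round(r, 6), "p": float(f"{p:.3e}")}
                for n, r, p in self.correlations
            ],
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    def to_text(self) -> str:
        lines = [
            "Deviation between actual and predicted life expectancy (months)",
            f"  Root mean square : {self.rmse:6.1f}",
            f"  Mean deviation   : {self.mean_deviation:+6.1f}",
            "",
            "Quality of the predictions (quotient margin 0.67..1.33)",
            f"  {'Assessor':<22}{'Accuracy':>10}{'Overly pess.':>14}{'Overly opt.':>13}",
            f"  {'Human (hospice ref.)':<22}{HOSPICE_HUMAN_BASELINE['accuracy']:>9.0f}%"
            f"{HOSPICE_HUMAN_BASELINE['pessimistic']:>13.0f}%"
            f"{HOSPICE_HUMAN_BASELINE['optimistic']:>12.0f}%",
            f"  {'This model':<22}{self.accuracy_pct:>9.1f}%"
            f"{self.pessimistic_pct:>13.1f}%{self.optimistic_pct:>12.1f}%",
        ]
        if self.correlations:
            lines += ["", "Correlations (Pearson r, two-sided p)"]
            for name, r, p in self.correlations:
                lines.append(f"  {name:<55} r={r:+.2f}  p={p:.3g}")
        return "\n".join(lines)


def split_recent(cohort: Cohort, test_fraction: float = 0.10) -> tuple[Cohort, Cohort]:
    """Hold out the most recently deceased patients as the test set.

    The latest ``ceil(test_fraction * N)`` deaths (date ties broken by
    patient_id) form the test cohort, mimicking deployment on new
    patients whose records never entered cross-validation.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie in (0, 1)")
    ordered = sorted(cohort.patients, key=lambda r: (r.death_date, r.patient_id))
    n_test = math.ceil(test_fraction * len(ordered))
    return Cohort(ordered[:-n_test]), Cohort(ordered[-n_test:])


def kfold(dev: Cohort, k: int = 10, seed: int = 0) -> list[tuple[list[str], list[str]]]:
    """Random k-fold patient-id partitions (validation folds disjoint,
    sizes differing by at most one, seeded shuffle)."""
    ids = sorted(r.patient_id for r in dev)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the {len(ids)} development patients")
    rng = np.random.default_rng(seed)
    ids = [ids[i] for i in rng.permutation(len(ids))]
    folds = [sorted(ids[i::k]) for i in range(k)]
    out = []
    for i in range(k):
        val = folds[i]
        train = sorted(pid for j, f in enumerate(folds) if j != i for pid in f)
        out.append((train, val))
    return out


def quotient_class(actual: int, predicted: int, lower: float = 0.67, upper: float = 1.33) -> tuple[float, str]:
    """Quotient Q = actual/predicted and its class under the 33% margin.

    Boundaries are inclusive: 0.67 <= Q <= 1.33 is accurate, Q < 0.67
    overly optimistic (death sooner than predicted), Q > 1.33 overly
    pessimistic.
    """
    if actual <= 0 or predicted <= 0:
        raise ValueError("actual and predicted must be positive months")
    q = actual / predicted
    if q < lower:
        klass = "optimistic"
    elif q > upper:
        klass = "pessimistic"
    else:
        klass = "accurate"
    return q, klass


def make_outcome(patient_id: str, actual: int, predicted: int, certainty: float) -> PrognosisOutcome:
    q, klass = quotient_class(actual, predicted)
    return PrognosisOutcome(patient_id, actual, predicted, q, klass, certainty)


def deviation_stats(outcomes: list[PrognosisOutcome]) -> tuple[float, float]:
    """(RMSE, mean deviation); deviation = predicted - actual (positive =
    overestimated life expectancy)."""
    if not outcomes:
        raise ValueError("no outcomes")
    dev = np.array([o.predicted - o.actual for o in outcomes], dtype=float)
    return float(np.sqrt(np.mean(dev**2))), float(np.mean(dev))


def accuracy_breakdown(outcomes: list[PrognosisOutcome]) -> tuple[float, float, float]:
    """(accurate, pessimistic, optimistic) percentages; sums to 100."""
    if not outcomes:
        raise ValueError("no outcomes")
    n = len(outcomes)
    acc = 100.0 * sum(o.klass == "accurate" for o in outcomes) / n
    pess = 100.0 * sum(o.klass == "pessimistic" for o in outcomes) / n
    opt = 100.0 * sum(o.klass == "optimistic" for o in outcomes) / n
    return acc, pess, opt


def certainty_analyses(outcomes: list[PrognosisOutcome]) -> list[tuple[str, float, float]]:
    """Pearson r and two-sided p for the four relations of interest:
    actual vs predicted, certainty vs actual, certainty vs predicted,
    and certainty vs |actual - predicted|."""
    if len(outcomes) < 3:
        raise ValueError("need at least 3 outcomes")
    actual = np.array([o.actual for o in outcomes], dtype=float)
    predicted = np.array([o.predicted for o in outcomes], dtype=float)
    certainty = np.array([o.certainty for o in outcomes], dtype=float)
    for name, series in (("actual", actual), ("predicted", predicted), ("certainty", certainty)):
        if np.ptp(series) == 0:
            raise ValueError(f"correlation undefined for constant series {name!r}")
    absdiff = np.abs(actual - predicted)
    pairs = [
        ("actual vs. predicted life expectancy", actual, predicted),
        ("certainty vs. actual life expectancy", certainty, actual),
        ("certainty vs. predicted life expectancy", certainty, predicted),
        ("certainty vs. |actual - predicted|", certainty, absdiff),
    ]
    out = []
    for name, x, y in pairs:
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            # derived series can degenerate (e.g. perfect predictions make
            # |actual - predicted| constant); report NaN for that row only
            out.append((name, float("nan"), float("nan")))
            continue
        res = stats.pearsonr(x, y)
        out.append((name, float(res.statistic), float(res.pvalue)))
    return out


def prediction_histogram(outcomes: list[PrognosisOutcome]) -> tuple[list[int], list[int]]:
    """(predicted, actual) frequency counts per month 1..50."""
    pred = [0] * MAX_MONTH
    act = [0] * MAX_MONTH
    for o in outcomes:
        pred[o.predicted - 1] += 1
        act[o.actual - 1] += 1
    return pred, act


def chance_accuracy(max_month: int = MAX_MONTH) -> float:
    """Quotient-accuracy of a uniform random predictor against uniform
    labels, by exhaustive enumeration of all (actual, predicted) pairs."""
    hits = sum(
        quotient_class(a, p)[1] == "accurate"
        for a in range(1, max_month + 1)
        for p in range(1, max_month + 1)
    )
    return hits / (max_month * max_month)


def build_report(outcomes: list[PrognosisOutcome], with_correlations: bool = True) -> MetricsReport:
    rmse, mean_dev = deviation_stats(outcomes)
    acc, pess, opt = accuracy_breakdown(outcomes)
    pred_hist, act_hist = prediction_histogram(outcomes)
    corrs: list[tuple[str, float, float]] = []
    if with_correlations:
        try:
            corrs = certainty_analyses(outcomes)
        except ValueError:
            corrs = []
    return MetricsReport(
        rmse=rmse,
        mean_deviation=mean_dev,
        accuracy_pct=acc,
        pessimistic_pct=pess,
        optimistic_pct=opt,
        n_outcomes=len(outcomes),
        predicted_histogram=pred_hist,
        actual_histogram=act_hist,
        correlations=corrs,
    )
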