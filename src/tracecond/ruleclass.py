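"""One-R rule induction, stratified cross-validation, confusion-matrix
metrics, and prognostic evaluation of the conditioned-response flag.

One-R (Holte) discretises each numeric attribute into class-labelled bins
and keeps the single attribute whose rule misclassifies fewest training
instances.  Despite its simplicity it is a strong baseline on small
clinical tables and yields directly interpretable threshold rules such as
"NOC* magnitude < 0.05 µS → no conditioned response".

The prognostic question is separate from classifier validation: does the
conditioned-response flag measured at the bedside predict evolution to a
minimally conscious state within the four-week observation window?
Patients who evolved only months later count as negative outcomes for
that window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OneRRule",
    "OneRModel",
    "ConfusionMetrics",
    "CohortRecord",
    "oner_discretize",
    "oner_fit",
    "oner_predict",
    "cross_validate",
    "metrics_from_confusion",
    "read_cohort",
    "cohort_fixture_path",
    "load_cohort_fixture",
    "cohort_summary",
    "evaluate_prognosis",
]

DEFAULT_MIN_BUCKET = 6
DEFAULT_CV_SEED = 1


@dataclass(frozen=True)
class OneRRule:
    """A single-attribute threshold rule: strictly increasing cut points
    and one predicted class per bin (boundary values fall in the lower
    bin, i.e. rules read "attribute < cut -> class")."""

    attribute: str
    cut_points: tuple[float, ...]
    bin_classes: tuple
    training_error: int

    def predict_value(self, value: float):
        idx = int(np.searchsorted(self.cut_points, value, side="left"))
        return self.bin_classes[idx]


@dataclass
class OneRModel:
    rules: dict[str, OneRRule]
    selected: OneRRule
    classes: tuple


def oner_discretize(values, labels, min_bucket: int = DEFAULT_MIN_BUCKET):
    """Holte's 1R discretisation of one numeric attribute.

    Sort by value; grow a bin until its majority class has ``min_bucket``
    members; keep extending while the next instance carries that majority
    class (and never cut between equal values); merge adjacent bins with
    equal majority class; cuts at midpoints between adjacent bin edges.

    Returns ``(cut_points, bin_classes)``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels must be aligned")
    if min_bucket < 1:
        raise ValueError("min_bucket must be >= 1")
    order = np.argsort(values, kind="stable")
    v = values[order]
    lab = labels[order]
    n = len(v)
    if n == 0:
        raise ValueError("cannot discretize an empty attribute")

    # Build bins as (first_index, last_index, majority_class).
    bins: list[tuple[int, int, object]] = []
    i = 0
    while i < n:
        counts: dict = {}
        j = i
        majority = lab[i]
        while j < n:
            counts[lab[j]] = counts.get(lab[j], 0) + 1
            majority = max(counts, key=lambda c: (counts[c],))
            j += 1
            if counts[majority] >= min_bucket:
                break
        # Extend while the next value's class equals the majority, or the
        # next value ties the current boundary value (no cut between equal
        # values).
        while j < n and (lab[j] == majority or v[j] == v[j - 1]):
            counts[lab[j]] = counts.get(lab[j], 0) + 1
            majority = max(counts, key=lambda c: (counts[c],))
            j += 1
        bins.append((i, j - 1, majority))
        i = j

    # Merge adjacent bins sharing a majority class.
    merged: list[tuple[int, int, object]] = []
    for b in bins:
        if merged and merged[-1][2] == b[2]:
            merged[-1] = (merged[-1][0], b[1], b[2])
        else:
            merged.append(b)

    cuts = tuple(
        (v[merged[k][1]] + v[merged[k + 1][0]]) / 2.0 for k in range(len(merged) - 1)
    )
    classes = tuple(b[2] for b in merged)
    return cuts, classes


def _rule_for_attribute(name, values, labels, min_bucket) -> OneRRule:
    cuts, classes = oner_discretize(values, labels, min_bucket)
    rule = OneRRule(attribute=name, cut_points=cuts, bin_classes=classes, training_error=0)
    preds = [rule.predict_value(x) for x in np.asarray(values, dtype=float)]
    err = int(sum(p != y for p, y in zip(preds, np.asarray(labels))))
    return OneRRule(attribute=name, cut_points=cuts, bin_classes=classes, training_error=err)


def oner_fit(
    table: pd.DataFrame,
    class_col: str,
    attributes: list[str] | None = None,
    min_bucket: int = DEFAULT_MIN_BUCKET,
) -> OneRModel:
    """One rule per numeric attribute; the selected rule minimises training
    misclassifications, ties broken by column order."""
    if len(table) == 0:
        raise ValueError("empty training table")
    if attributes is None:
        attributes = [
            c for c in table.columns
            if c != class_col and pd.api.types.is_numeric_dtype(table[c])
        ]
    if not attributes:
        raise ValueError("no numeric attributes to fit")
    labels = table[class_col].to_numpy()
    rules = {
        a: _rule_for_attribute(a, table[a].to_numpy(dtype=float), labels, min_bucket)
        for a in attributes
    }
    selected = min(rules.values(), key=lambda r: (r.training_error, attributes.index(r.attribute)))
    return OneRModel(rules=rules, selected=selected, classes=tuple(pd.unique(labels)))


def oner_predict(model: OneRModel | OneRRule, instance) -> object:
    """Predict one instance (a mapping / Series with the rule's attribute)."""
    rule = model.selected if isinstance(model, OneRModel) else model
    try:
        value = float(instance[rule.attribute])
    except (KeyError, IndexError) as exc:
        raise KeyError(f"instance lacks attribute {rule.attribute!r}") from exc
    return rule.predict_value(value)


def _stratified_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Fold assignment per instance: within each class, shuffle that
    class's instances with a seed-derived generator and deal them
    round-robin.  Sorting by label first makes the assignment invariant to
    the original instance order."""
    rng = np.random.default_rng(seed)
    fold = np.empty(len(labels), dtype=int)
    for cls in sorted(pd.unique(labels), key=str):
        idx = np.nonzero(labels == cls)[0]
        idx = idx[np.argsort(idx)]  # deterministic base order
        perm = rng.permutation(len(idx))
        fold[idx[perm]] = np.arange(len(idx)) % k
    return fold


def cross_validate(
    table: pd.DataFrame,
    class_col: str,
    positive_label,
    k: int = 10,
    seed: int = DEFAULT_CV_SEED,
    attributes: list[str] | None = None,
    min_bucket: int = DEFAULT_MIN_BUCKET,
) -> "ConfusionMetrics":
    """Stratified k-fold cross-validation of One-R; metrics on the pooled
    held-out confusion matrix."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(table):
        raise ValueError(f"k={k} exceeds table size {len(table)}")
    labels = table[class_col].to_numpy()
    class_sizes = pd.Series(labels).value_counts()
    if k > class_sizes.min():
        raise ValueError(
            f"k={k} exceeds smallest class size {class_sizes.min()}; "
            "stratification impossible"
        )
    folds = _stratified_folds(labels, k, seed)
    tp = fp = tn = fn = 0
    for f in range(k):
        train = table.iloc[folds != f]
        test = table.iloc[folds == f]
        model = oner_fit(train, class_col, attributes=attributes, min_bucket=min_bucket)
        for _, row in test.iterrows():
            pred = oner_predict(model, row)
            actual = row[class_col]
            if actual == positive_label:
                if pred == positive_label:
                    tp += 1
                else:
                    fn += 1
            else:
                if pred == positive_label:
                    fp += 1
                else:
                    tn += 1
    return metrics_from_confusion(tp, fp, tn, fn)


# Confusion metrics ----------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMetrics:
    """Diagnostic-test metrics; rates in percent, F1 on the 0-1 scale.

    ``rounded`` carries the half-up integer presentation of each rate;
    undefined rates (empty margin) are NaN and flagged."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    fpr: float
    fnr: float
    f1: float
    rounded: dict = field(default_factory=dict)
    undefined: tuple = ()


def metrics_from_confusion(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    undefined = []

    def rate(num, den, name):
        if den == 0:
            undefined.append(name)
            return math.nan
        return 100.0 * num / den

    sens = rate(tp, tp + fn, "sensitivity")
    spec = rate(tn, tn + fp, "specificity")
    prec = rate(tp, tp + fp, "precision")
    acc = 100.0 * (tp + tn) / total
    fpr = 100.0 - spec if not math.isnan(spec) else math.nan
    fnr = 100.0 - sens if not math.isnan(sens) else math.nan
    if math.isnan(spec):
        undefined.append("fpr")
    if math.isnan(sens):
        undefined.append("fnr")
    if math.isnan(prec) or math.isnan(sens) or (prec + sens) == 0:
        f1 = math.nan
        undefined.append("f1")
    else:
        f1 = round(2 * (prec / 100) * (sens / 100) / (prec / 100 + sens / 100), 2)
    rounded = {
        name: (_round_half_up(v) if not math.isnan(v) else None)
        for name, v in [
            ("sensitivity", sens), ("specificity", spec), ("precision", prec),
            ("accuracy", acc), ("fpr", fpr), ("fnr", fnr),
        ]
    }
    return ConfusionMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec, precision=prec, accuracy=acc,
        fpr=fpr, fnr=fnr, f1=f1, rounded=rounded, undefined=tuple(undefined),
    )


# Cohort table ---------------------------------------------------------------

COHORT_COLUMNS = [
    "patient_id", "entry_diagnosis", "age_band", "etiology",
    "days_from_event", "cr_response",
    "crsr_w1", "ncs_w1", "crsr_w2", "ncs_w2",
    "crsr_w3", "ncs_w3", "crsr_w4", "ncs_w4", "final_diagnosis",
]
_FINAL_DIAGNOSES = {"MCS", "UWS", "UWS_LATE"}
_ETIOLOGIES = {"TBI", "HEM", "ANOX"}


@dataclass(frozen=True)
class CohortRecord:
    """One patient row of the cohort table: bedside conditioned-response
    flag, weekly CRS-R/NCS score pairs, and the final diagnosis within the
    observation window (UWS_LATE marks evolution only after ~6 months)."""

    patient_id: int
    entry_diagnosis: str
    age_band: str
    etiology: str
    days_from_event: int
    cr_response: int
    weekly_scores: tuple  # four (crsr, ncs) pairs
    final_diagnosis: str


def read_cohort(path) -> list[CohortRecord]:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path}: missing column(s) {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        if row.cr_response not in (0, 1):
            raise ValueError(
                f"cohort file {path}: row {i}: cr_response must be 0/1, got {row.cr_response!r}"
            )
        if row.final_diagnosis not in _FINAL_DIAGNOSES:
            raise ValueError(
                f"cohort file {path}: row {i}: unknown final_diagnosis {row.final_diagnosis!r}"
            )
        if row.etiology not in _ETIOLOGIES:
            raise ValueError(
                f"cohort file {path}: row {i}: unknown etiology {row.etiology!r}"
            )
        scores = []
        for w in range(1, 5):
            crsr = getattr(row, f"crsr_w{w}")
            ncs = getattr(row, f"ncs_w{w}")
            if crsr < 0 or ncs < 0 or crsr != int(crsr) or ncs != int(ncs):
                raise ValueError(
                    f"cohort file {path}: row {i}: week-{w} scores must be "
                    f"nonnegative integers"
                )
            scores.append((int(crsr), int(ncs)))
        records.append(
            CohortRecord(
                patient_id=int(row.patient_id),
                entry_diagnosis=str(row.entry_diagnosis),
                age_band=str(row.age_band),
                etiology=str(row.etiology),
                days_from_event=int(row.days_from_event),
                cr_response=int(row.cr_response),
                weekly_scores=tuple(scores),
                final_diagnosis=str(row.final_diagnosis),
            )
        )
    return records


def cohort_fixture_path() -> Path:
    """Path of the packaged 30-patient cohort table."""
    return Path(resources.files("tracecond") / "data" / "cohort_table1.csv")


def load_cohort_fixture() -> list[CohortRecord]:
    return read_cohort(cohort_fixture_path())


def cohort_summary(records: list[CohortRecord]) -> dict:
    n = len(records)
    n_cr = sum(r.cr_response == 1 for r in records)
    n_mcs = sum(r.final_diagnosis == "MCS" for r in records)
    n_cr_mcs = sum(r.cr_response == 1 and r.final_diagnosis == "MCS" for r in records)
    n_late = sum(r.final_diagnosis == "UWS_LATE" for r in records)
    return {
        "n_patients": n,
        "n_cr_positive": n_cr,
        "pct_cr_positive": 100.0 * n_cr / n if n else math.nan,
        "n_final_mcs": n_mcs,
        "n_cr_positive_mcs": n_cr_mcs,
        "pct_cr_positive_mcs": 100.0 * n_cr_mcs / n_cr if n_cr else math.nan,
        "n_late_evolvers": n_late,
    }


def evaluate_prognosis(
    records: list[CohortRecord], late_as_positive: bool = False
) -> ConfusionMetrics:
    """Prognostic value of the conditioned-response flag.

    Predictor: ``cr_response``.  Positive outcome: final diagnosis MCS
    within the four-week window; UWS and UWS_LATE are negatives unless
    ``late_as_positive`` widens the outcome window.
    """
    if not records:
        raise ValueError("empty cohort")
    positive = {"MCS", "UWS_LATE"} if late_as_positive else {"MCS"}
    tp = fp = tn = fn = 0
    for r in records:
        outcome = r.final_diagnosis in positive
        if r.cr_response == 1:
            if outcome:
                tp += 1
            else:
                fp += 1
        else:
            if outcome:
                fn += 1
            else:
                tn += 1
    return metrics_from_confusion(tp, fp, tn, fn)
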