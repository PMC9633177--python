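"""Cross-validation, Cooper statistics, ROC and cross-model consensus.

Model validation follows the repeated leave-many-out scheme: the training set
is stratified into 10% folds, each fold is predicted by a model whose weights
are refit on the remaining 90% (the feature vocabulary stays fixed from the
full-set fit), the whole partition is repeated ten times, and per-compound
probabilities are averaged over repeats before classification.

Performance is summarised by the Cooper statistics family computed on the
2x2 confusion table after excluding equivocal and out-of-domain compounds:
sensitivity TP/(TP+FN), specificity TN/(TN+FP), positive predictivity
TP/(TP+FP), negative predictivity TN/(TN+FN), accuracy, plus Matthews
correlation, Pearson chi-squared, and coverage (the fraction of screened
compounds receiving any prediction; equivocal counts as a prediction,
out-of-domain does not).

Consensus between two models favours sensitivity: any positive wins, then
any equivocal, and a lone out-of-domain verdict is disregarded in favour of
the other model's call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .features import FeatureMatrix
from .qsar_model import (
    Call,
    CallValue,
    CUConfig,
    CUModel,
    LSConfig,
    _sigmoid,
    classify,
    fit_cu_style,
    fit_ls_style,
    molecule_path_labels,
    select_threshold,
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    n_equivocal: int = 0
    n_ood: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn, self.n_equivocal, self.n_ood) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_screened(self) -> int:
        return self.tp + self.fp + self.tn + self.fn + self.n_equivocal + self.n_ood


@dataclass(frozen=True)
class CooperStats:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    coverage: float
    mcc: float
    chi_squared: float
    undefined: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "positive_predictivity": self.ppv,
            "negative_predictivity": self.npv,
            "accuracy": self.accuracy,
            "coverage": self.coverage,
            "mcc": self.mcc,
            "chi_squared": self.chi_squared,
        }


def _ratio(num: float, den: float, name: str, undefined: set[str]) -> float:
    if den == 0:
        undefined.add(name)
        return float("nan")
    return num / den


def cooper_statistics(counts: ConfusionCounts, *, continuity_correction: bool = False) -> CooperStats:
    """Cooper statistics from a confusion table (equivocal/OOD pre-excluded).

    Statistics with a zero denominator are returned as NaN and named in
    ``undefined`` instead of raising.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    undefined: set[str] = set()
    sens = _ratio(tp, tp + fn, "sensitivity", undefined)
    spec = _ratio(tn, tn + fp, "specificity", undefined)
    ppv = _ratio(tp, tp + fp, "ppv", undefined)
    npv = _ratio(tn, tn + fn, "npv", undefined)
    acc = _ratio(tp + tn, tp + tn + fp + fn, "accuracy", undefined)
    n_screened = counts.n_screened
    cov = _ratio(n_screened - counts.n_ood, n_screened, "coverage", undefined)

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        undefined.add("mcc")
        mcc = float("nan")
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(float(denom))

    table = np.array([[tp, fn], [fp, tn]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        undefined.add("chi_squared")
        chi2 = float("nan")
    else:
        chi2 = float(
            scipy_stats.chi2_contingency(table, correction=continuity_correction)[0]
        )

    return CooperStats(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        accuracy=acc,
        coverage=cov,
        mcc=float(mcc),
        chi_squared=chi2,
        undefined=frozenset(undefined),
    )


def confusion_from_calls(labels: Sequence[int], calls: Sequence[Call | CallValue]) -> ConfusionCounts:
    """Tally a per-compound (label, call) list into a confusion table."""
    if len(labels) != len(calls):
        raise ValueError("labels and calls must align")
    tp = fp = tn = fn = neq = nood = 0
    for y, call in zip(labels, calls):
        value = call.value if isinstance(call, Call) else call
        if value is CallValue.OUT_OF_DOMAIN:
            nood += 1
        elif value is CallValue.EQUIVOCAL:
            neq += 1
        elif value is CallValue.POSITIVE:
            tp, fp = (tp + 1, fp) if y == 1 else (tp, fp + 1)
        elif value is CallValue.NEGATIVE:
            tn, fn = (tn + 1, fn) if y == 0 else (tn, fn + 1)
        else:
            raise ValueError(f"unknown call {value!r}")
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, n_equivocal=neq, n_ood=nood)


# ---------------------------------------------------------------------------
# consensus


def combine_calls(call_a: Call, call_b: Call) -> Call:
    """Sensitivity-favouring consensus of two model calls.

    Any positive wins; otherwise any equivocal; a lone out-of-domain verdict
    is disregarded in favour of the other model's prediction; two negatives
    stay negative; two out-of-domain verdicts stay out of domain.  The
    operation is commutative.
    """
    a, b = call_a, call_b

    def pick(value: CallValue) -> Call:
        contributors = [c for c in (a, b) if c.value is value]
        prob = max((c.probability for c in contributors if c.probability is not None), default=None)
        if value is CallValue.OUT_OF_DOMAIN:
            return Call(value=value, probability=None, reason="both models out of domain")
        return Call(value=value, probability=prob, reason=f"consensus {value.value}")

    values = {a.value, b.value}
    if CallValue.POSITIVE in values:
        return pick(CallValue.POSITIVE)
    if CallValue.EQUIVOCAL in values:
        return pick(CallValue.EQUIVOCAL)
    if CallValue.NEGATIVE in values:
        return pick(CallValue.NEGATIVE)
    return pick(CallValue.OUT_OF_DOMAIN)


# ---------------------------------------------------------------------------
# ROC


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """(fpr, tpr) points thresholding at every unique score, (0,0) to (1,1)."""
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes required for a ROC curve")
    fpr, tpr, _ = _sk_roc_curve(y, np.asarray(scores, dtype=float), drop_intermediate=False)
    return fpr, tpr


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    fpr, tpr = roc_curve(scores, labels)
    return float(np.trapezoid(tpr, fpr))


# ---------------------------------------------------------------------------
# repeated leave-many-out cross-validation


@dataclass
class CVResult:
    """Per-compound outcome of repeated LMO cross-validation."""

    avg_probability: np.ndarray  # NaN where the compound was OOD in every repeat
    n_held_out: np.ndarray
    n_ood: np.ndarray
    calls: list[Call]
    threshold: float | None = None

    def cooper(self, labels: Sequence[int]) -> CooperStats:
        return cooper_statistics(confusion_from_calls(labels, self.calls))


FoldPredictor = Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]


def _lmo_engine(
    labels: np.ndarray,
    fold_predict: FoldPredictor,
    repeats: int,
    fold_fraction: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the repeated stratified partition; returns (prob_sum basis)."""
    n = labels.shape[0]
    if n < 30:
        raise ValueError("need at least 30 compounds for leave-many-out CV")
    n_splits = int(round(1.0 / fold_fraction))
    prob_sum = np.zeros(n)
    n_pred = np.zeros(n, dtype=int)
    n_held = np.zeros(n, dtype=int)
    n_ood = np.zeros(n, dtype=int)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=(seed + 9973 * r) % (2**31 - 1))
        for train_idx, test_idx in skf.split(np.zeros(n), labels):
            if len(set(labels[train_idx].tolist())) < 2:
                raise ValueError("stratification failure: single-class training fold")
            probs, ood = fold_predict(train_idx, test_idx)
            n_held[test_idx] += 1
            keep = ~ood
            prob_sum[test_idx[keep]] += probs[keep]
            n_pred[test_idx[keep]] += 1
            n_ood[test_idx[ood]] += 1
    with np.errstate(invalid="ignore"):
        avg = np.where(n_pred > 0, prob_sum / np.maximum(n_pred, 1), np.nan)
    return avg, n_held, n_ood


def ls_lmo_cv(
    matrix: FeatureMatrix,
    descriptors: np.ndarray,
    labels: Sequence[int],
    config: LSConfig | None = None,
    repeats: int = 10,
    fold_fraction: float = 0.1,
    seed: int = 0,
) -> CVResult:
    """Repeated LMO CV of the LS style.

    The feature vocabulary (matrix columns) is fixed; descriptor scaling and
    all weights are refit on each fold's training portion.  The LS style
    predicts every held-out compound (no domain exclusion inside CV), so
    averaged probabilities are defined for all compounds.
    """
    config = config or LSConfig()
    y = np.asarray(labels, dtype=int)
    D = np.asarray(descriptors, dtype=float)

    def fold_predict(train_idx: np.ndarray, test_idx: np.ndarray):
        sub = FeatureMatrix(
            compound_ids=[matrix.compound_ids[i] for i in train_idx],
            fragments=list(matrix.fragments),
            values=matrix.values[train_idx],
        )
        model = fit_ls_style(sub, D[train_idx], y[train_idx], config)
        probs = np.array(
            [model.probability(matrix.values[i], D[i]) for i in test_idx], dtype=float
        )
        return probs, np.zeros(len(test_idx), dtype=bool)

    avg, n_held, n_ood = _lmo_engine(y, fold_predict, repeats, fold_fraction, seed)
    calls = [
        Call(value=classify(p, config.pos_cutoff, config.neg_cutoff), probability=float(p))
        for p in avg
    ]
    return CVResult(avg_probability=avg, n_held_out=n_held, n_ood=n_ood, calls=calls)


def cu_lmo_cv(
    molecules: Sequence,
    labels: Sequence[int],
    config: CUConfig | None = None,
    repeats: int = 10,
    fold_fraction: float = 0.1,
    seed: int = 0,
    full_model: CUModel | None = None,
) -> CVResult:
    """Repeated LMO CV of the CU style.

    The alert/deactivator vocabulary comes from the full-set fit; the
    logistic weights are refit per fold.  Domain analysis runs inside CV: a
    held-out compound with three-atom fragments unseen in the fold's training
    portion (and no positive-strength score) contributes no prediction for
    that fold, and a compound out of domain in every repeat is called OOD.
    The classification threshold is chosen on the ROC curve of the averaged
    probabilities unless the config pins it.
    """
    config = config or CUConfig()
    y = np.asarray(labels, dtype=int)
    model = full_model if full_model is not None else fit_cu_style(molecules, y, config)

    from .features import molecule_feature_bits  # local to avoid cycle at import

    bits = np.array([molecule_feature_bits(m, model.fragments) for m in molecules], dtype=float)
    triplets = [molecule_path_labels(m, 3, 3) for m in molecules]

    def fold_predict(train_idx: np.ndarray, test_idx: np.ndarray):
        lr = LogisticRegression(C=1.0, max_iter=5000, random_state=config.seed)
        lr.fit(bits[train_idx], y[train_idx])
        raw = _sigmoid(bits[test_idx] @ lr.coef_[0] + lr.intercept_[0])
        known: set[str] = set()
        for i in train_idx:
            known.update(triplets[i])
        ood = np.array(
            [
                bool(triplets[i] - known) and raw[j] <= model.pos_cutoff
                for j, i in enumerate(test_idx)
            ],
            dtype=bool,
        )
        return np.asarray(raw, dtype=float), ood

    avg, n_held, n_ood = _lmo_engine(y, fold_predict, repeats, fold_fraction, seed)
    covered = ~np.isnan(avg)
    if config.threshold is not None:
        threshold = config.threshold
    else:
        threshold = select_threshold(avg[covered], y[covered])
    pos_cut = threshold + config.equivocal_halfwidth
    neg_cut = threshold - config.equivocal_halfwidth
    calls = []
    for p in avg:
        if np.isnan(p):
            calls.append(Call(value=CallValue.OUT_OF_DOMAIN, probability=None, reason="OOD in every repeat"))
        else:
            calls.append(Call(value=classify(float(p), pos_cut, neg_cut), probability=float(p)))
    return CVResult(avg_probability=avg, n_held_out=n_held, n_ood=n_ood, calls=calls, threshold=float(threshold))


# ---------------------------------------------------------------------------
# prediction-table interface (CSV in, Table-2-style report out)

_CALL_NAMES = {
    "positive": CallValue.POSITIVE,
    "negative": CallValue.NEGATIVE,
    "equivocal": CallValue.EQUIVOCAL,
    "ood": CallValue.OUT_OF_DOMAIN,
    "out_of_domain": CallValue.OUT_OF_DOMAIN,
}


def _parse_call(name: str) -> Call:
    value = _CALL_NAMES[str(name).strip().lower()]
    prob = None if value is CallValue.OUT_OF_DOMAIN else 1.0 if value is CallValue.POSITIVE else 0.0 if value is CallValue.NEGATIVE else 0.5
    return Call(value=value, probability=prob)


def evaluate_prediction_table(df: pd.DataFrame) -> dict[str, CooperStats]:
    """Cooper statistics per model call column and for their consensus.

    Expects columns compound_id, label, call_model_a, call_model_b (the call
    vocabulary is positive|negative|equivocal|ood).
    """
    labels = df["label"].astype(int).tolist()
    out: dict[str, CooperStats] = {}
    call_cols = [c for c in df.columns if c.startswith("call_")]
    parsed = {c: [_parse_call(v) for v in df[c]] for c in call_cols}
    for c in call_cols:
        out[c.removeprefix("call_")] = cooper_statistics(confusion_from_calls(labels, parsed[c]))
    if len(call_cols) == 2:
        a, b = call_cols
        combined = [combine_calls(x, y) for x, y in zip(parsed[a], parsed[b])]
        out["consensus"] = cooper_statistics(confusion_from_calls(labels, combined))
    return out


def stats_report_frame(stats: dict[str, CooperStats]) -> pd.DataFrame:
    """Statistics-by-model report mirroring the usual validation table rows."""
    rows = [
        "sensitivity", "specificity", "positive_predictivity",
        "negative_predictivity", "accuracy", "coverage", "chi_squared", "mcc",
    ]
    return pd.DataFrame({name: s.as_dict() for name, s in stats.items()}).reindex(rows)
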