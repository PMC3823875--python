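"""Evaluation protocols: k-fold CV, leave-one-drug-out CV, metrics.

Two complementary protocols:

* **k-fold CV over labeled pairs** -- gold-standard positives plus an
  equal number of sampled negatives are split into stratified folds;
  each fold is held out in turn, the penalty C is re-selected by inner
  cross-validation on the training folds only, and the held-out fold is
  scored.  Measures interpolation over the known interaction network.
* **Leave-one-drug-out (LODO)** -- each drug and all its associations
  are removed from training; the model then ranks that drug's diseases.
  Measures the cold-start case of a novel drug.

Metrics: ROC AUC (midrank tie handling, i.e. the Mann-Whitney
statistic), area under the precision-recall step curve (AUPR), and
thresholded accuracy / sensitivity / specificity / precision /
F-measure reported at the threshold that maximizes F.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .containers import AssociationTable, SequenceStore, TargetMap, ValidationError
from .kernel import PairKernel
from .similarity import AlignmentParams, target_set_similarity_matrix
from .svm import (
    C_GRID_DEFAULT,
    PairDataset,
    decision_scores,
    sample_negatives,
    select_C,
    train_svm,
)

__all__ = [
    "roc_auc",
    "aupr",
    "threshold_metrics",
    "ThresholdMetrics",
    "EvalReport",
    "LodoReport",
    "kfold_cv",
    "leave_one_drug_out",
    "filter_trivial_positives",
]

Pair = tuple[str, str]


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    classes = set(np.unique(labels))
    if not classes <= {-1, 1}:
        raise ValidationError(f"labels must be +/-1, got {sorted(classes)}")
    if len(classes) < 2:
        raise ValidationError("need both classes to compute ranking metrics")
    return labels


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve with midrank tie handling.

    Equals the Mann-Whitney U statistic divided by n_pos * n_neg.
    """
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def aupr(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall step curve.

    Precision is not linearly interpolated between recall levels (that
    would be optimistic); the area is the recall-weighted sum of
    precisions, which for random scores approaches the positive
    fraction.
    """
    labels = _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


class ThresholdMetrics(NamedTuple):
    acc: float
    sn: float
    sp: float
    pre: float
    f: float
    threshold: float


def threshold_metrics(
    scores: Sequence[float], labels: Sequence[int]
) -> ThresholdMetrics:
    """Confusion-matrix metrics at the F-measure-maximizing threshold.

    Scans every unique score value as a cut (predict positive when
    score >= threshold):

        Acc = (TP + TN) / all     Sn = TP / (TP + FN)
        Sp  = TN / (TN + FP)      Pre = TP / (TP + FP)
        F   = 2 * Pre * Sn / (Pre + Sn)

    Ties in F are broken toward higher sensitivity (recall is what
    repositioning screens care about); thresholds where precision is
    undefined (no predicted positives) are skipped.
    """
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == -1).sum())
    # cumulative TP/FP when thresholding at each sorted score
    tp_cum = np.cumsum(y_sorted == 1)
    fp_cum = np.cumsum(y_sorted == -1)
    # last index of each unique score = counts at threshold == that score
    is_last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp = tp_cum[is_last].astype(float)
    fp = fp_cum[is_last].astype(float)
    thr = s_sorted[is_last]
    fn = n_pos - tp
    tn = n_neg - fp
    valid = (tp + fp) > 0
    tp, fp, fn, tn, thr = tp[valid], fp[valid], fn[valid], tn[valid], thr[valid]
    pre = tp / (tp + fp)
    sn = tp / n_pos
    with np.errstate(invalid="ignore"):
        f = np.where(pre + sn > 0, 2 * pre * sn / (pre + sn), 0.0)
    best_f = f.max()
    cand = np.flatnonzero(f >= best_f - 1e-12)
    best = cand[np.argmax(sn[cand])]
    return ThresholdMetrics(
        acc=float((tp[best] + tn[best]) / (n_pos + n_neg)),
        sn=float(sn[best]),
        sp=float(tn[best] / n_neg) if n_neg else 0.0,
        pre=float(pre[best]),
        f=float(f[best]),
        threshold=float(thr[best]),
    )


def _all_metrics(scores: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    tm = threshold_metrics(scores, labels)
    return {
        "auc": roc_auc(scores, labels),
        "aupr": aupr(scores, labels),
        "acc": tm.acc,
        "sn": tm.sn,
        "sp": tm.sp,
        "pre": tm.pre,
        "f": tm.f,
        "threshold": tm.threshold,
    }


@dataclass
class EvalReport:
    """Per-fold and aggregate results of a cross-validation run."""

    fold_rows: list[dict]
    pooled: dict[str, float]
    fold_assignment: dict[Pair, int]
    seed: int
    k: int
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)

    def per_fold(self) -> pd.DataFrame:
        return pd.DataFrame(self.fold_rows).set_index("fold")

    @property
    def mean(self) -> dict[str, float]:
        df = self.per_fold()
        cols = ["auc", "aupr", "acc", "sn", "sp", "pre", "f"]
        return {c: float(df[c].mean()) for c in cols}

    def summary_frame(self) -> pd.DataFrame:
        rows = {"mean": self.mean, "pooled": {k: v for k, v in self.pooled.items()
                                              if k != "threshold"}}
        return pd.DataFrame(rows).T


def _derive_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def kfold_cv(
    a: AssociationTable,
    kernel: PairKernel,
    k: int = 10,
    seed: int = 0,
    c_grid: Sequence[float] = C_GRID_DEFAULT,
    inner_folds: int = 3,
    resample_per_fold: bool = True,
    max_retries: int = 5,
) -> EvalReport:
    """Stratified k-fold cross-validation over labeled pairs.

    The labeled set is the gold-standard positives plus an equal-sized
    global negative sample; its k stratified folds partition it, so
    every labeled pair is tested exactly once.  Per fold, C is chosen
    by inner CV on the training portion only.  With
    ``resample_per_fold`` (default) the training negatives are redrawn
    per fold from the unlabeled pairs, excluding the held-out fold's
    pairs so nothing tested was ever trained on.
    """
    positives = sorted(a.edges)
    if len(positives) < k:
        raise ValidationError(f"need at least k={k} positives, got {len(positives)}")
    seeds = _derive_seeds(seed, 3 + 2 * k)
    negatives = sample_negatives(a, len(positives), int(seeds[0]))
    pairs = positives + negatives
    y = np.concatenate([np.ones(len(positives), int), -np.ones(len(negatives), int)])

    splits = None
    for attempt in range(max_retries):
        skf = StratifiedKFold(
            n_splits=k, shuffle=True, random_state=int(seeds[1] + attempt) % 2**31
        )
        cand = list(skf.split(np.zeros(len(y)), y))
        if all(len(set(y[te])) == 2 for _, te in cand):
            splits = cand
            break
    if splits is None:
        raise ValidationError("could not form folds with both classes")

    fold_rows = []
    fold_assignment: dict[Pair, int] = {}
    all_scores, all_labels = [], []
    for f, (tr, te) in enumerate(splits):
        test_pairs = [pairs[i] for i in te]
        for p in test_pairs:
            fold_assignment[p] = f
        train_pos = [pairs[i] for i in tr if y[i] == 1]
        if resample_per_fold:
            train_neg = sample_negatives(
                a, len(train_pos), int(seeds[3 + 2 * f]), exclude=test_pairs
            )
        else:
            train_neg = [pairs[i] for i in tr if y[i] == -1]
        ds = PairDataset(
            tuple(train_pos + train_neg),
            np.concatenate(
                [np.ones(len(train_pos), int), -np.ones(len(train_neg), int)]
            ),
        )
        C = select_C(ds, kernel, c_grid, inner_folds, int(seeds[4 + 2 * f]))
        model = train_svm(ds, kernel, C)
        scores = decision_scores(model, kernel, test_pairs)
        row = {"fold": f, "C": C, "n_test": len(te), **_all_metrics(scores, y[te])}
        fold_rows.append(row)
        all_scores.append(scores)
        all_labels.append(y[te])

    pooled_scores = np.concatenate(all_scores)
    pooled_labels = np.concatenate(all_labels)
    return EvalReport(
        fold_rows=fold_rows,
        pooled=_all_metrics(pooled_scores, pooled_labels),
        fold_assignment=fold_assignment,
        seed=seed,
        k=k,
        scores=pooled_scores,
        labels=pooled_labels,
    )


@dataclass
class LodoReport:
    """Leave-one-drug-out results: per-drug AUC plus aggregates."""

    per_drug_auc: dict[str, float]
    skipped: list[str]
    C: float
    seed: int
    pooled_auc: float

    @property
    def mean_auc(self) -> float:
        return float(np.mean(list(self.per_drug_auc.values())))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"auc": pd.Series(self.per_drug_auc)}
        ).rename_axis("drug_id")


def leave_one_drug_out(
    a: AssociationTable,
    kernel: PairKernel,
    seed: int = 0,
    C: float | None = None,
    c_grid: Sequence[float] = C_GRID_DEFAULT,
) -> LodoReport:
    """Leave-one-drug-out cross-validation.

    For each drug with at least one association: every pair involving
    that drug is excluded from training (positives and candidate
    negatives alike), the model is trained on the rest, and the held-out
    drug's diseases are ranked (its known associations vs. the rest).
    Reports per-drug AUC, their macro average, and the pooled
    (micro) AUC over all held-out scores.  If ``C`` is not given it is
    selected once by inner CV on the full labeled set.
    """
    drugs_with_pos = sorted({d for d, _ in a.edges})
    if len(drugs_with_pos) < 2:
        raise ValidationError("need at least 2 drugs with positives")
    seeds = _derive_seeds(seed, 2 + len(drugs_with_pos))
    if C is None:
        ds_full = PairDataset.balanced(a, int(seeds[0]))
        C = select_C(ds_full, kernel, c_grid, seed=int(seeds[1]))

    per_drug: dict[str, float] = {}
    skipped: list[str] = []
    all_scores, all_labels = [], []
    for i, drug in enumerate(drugs_with_pos):
        test_pairs = [(drug, q) for q in a.disease_ids]
        test_labels = np.array(
            [1 if (drug, q) in a.edges else -1 for _, q in test_pairs], int
        )
        if len(set(test_labels)) < 2:
            skipped.append(drug)
            warnings.warn(
                f"drug {drug!r} skipped: its positives cover every disease",
                stacklevel=2,
            )
            continue
        reduced = a.without_drug(drug)
        train_pos = sorted(reduced.edges)
        train_neg = sample_negatives(
            reduced, len(train_pos), int(seeds[2 + i]), exclude=test_pairs
        )
        ds = PairDataset(
            tuple(train_pos + train_neg),
            np.concatenate(
                [np.ones(len(train_pos), int), -np.ones(len(train_neg), int)]
            ),
        )
        model = train_svm(ds, kernel, C)
        scores = decision_scores(model, kernel, test_pairs)
        per_drug[drug] = roc_auc(scores, test_labels)
        all_scores.append(scores)
        all_labels.append(test_labels)

    pooled = roc_auc(np.concatenate(all_scores), np.concatenate(all_labels))
    return LodoReport(per_drug, skipped, float(C), seed, pooled)


def filter_trivial_positives(
    a: AssociationTable,
    t: TargetMap,
    s: SequenceStore,
    p: AlignmentParams | None = None,
    cutoff: float = 0.8,
) -> tuple[AssociationTable, list[dict]]:
    """Remove gold-standard positives explainable by near-identical targets.

    A positive (d, q) is "trivial" when another positive (d', q) exists
    whose drug has a target with normalized Smith-Waterman similarity
    >= ``cutoff`` (default 0.8) to one of d's targets: such pairs are
    predictable from shared targets alone.  On a mutually trivial drug
    pair the lexicographically smaller drug's edge is retained, so
    removal is deterministic and minimal: (d, q) is removed exactly
    when a conflicting positive with a smaller drug id exists.

    Returns the filtered table plus a removal log.
    """
    if not (0 < cutoff <= 1):
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    if p is None:
        p = AlignmentParams()
    # raw best-match target similarity, no diagonal rescaling
    sim = target_set_similarity_matrix(t, s, p, aggregator="max", normalize=False)
    idx = sim.index()

    removed: list[dict] = []
    kept_edges = set()
    for q in sorted({q for _, q in a.edges}):
        drugs = sorted(a.drugs_of(q))
        for j, d in enumerate(drugs):
            conflict = None
            for d2 in drugs[:j]:
                if d in idx and d2 in idx and sim.values[idx[d], idx[d2]] >= cutoff:
                    conflict = d2
                    break
            if conflict is None:
                kept_edges.add((d, q))
            else:
                removed.append(
                    {
                        "drug_id": d,
                        "disease_id": q,
                        "conflicting_drug": conflict,
                        "target_similarity": float(
                            sim.values[idx[d], idx[conflict]]
                        ),
                    }
                )
    filtered = AssociationTable(frozenset(kept_edges), a.drug_ids, a.disease_ids)
    return filtered, removed
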