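"""SVM training on drug-disease pairs with balanced negative sampling.

The interaction-prediction task is a binary classification over
(drug, disease) pairs: gold-standard associations are the positives
and, because unlabeled pairs vastly outnumber them, an equally sized
negative set is drawn uniformly at random from the unlabeled pairs to
keep the classes balanced.  The SVM consumes the precomputed pair-
kernel Gram matrix; the penalty parameter C is chosen by grid search
with inner 3-fold cross-validation on AUC.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .containers import AssociationTable, ValidationError
from .kernel import PairKernel

__all__ = [
    "C_GRID_DEFAULT",
    "PairDataset",
    "TrainedModel",
    "sample_negatives",
    "select_C",
    "train_svm",
    "decision_scores",
]

Pair = tuple[str, str]

#: default penalty grid: odd powers of two from 2^-5 to 2^15
C_GRID_DEFAULT: tuple[float, ...] = tuple(2.0**p for p in range(-5, 16, 2))


def sample_negatives(
    a: AssociationTable,
    n: int | None = None,
    seed: int = 0,
    exclude: Iterable[Pair] = (),
) -> list[Pair]:
    """Draw ``n`` distinct unlabeled pairs uniformly without replacement.

    Candidates are (drug x disease) minus the gold-standard positives
    minus ``exclude``.  ``n`` defaults to the number of positives
    (balanced sampling).  Deterministic given ``seed``; the result is
    returned in sorted order.
    """
    if n is None:
        n = a.n_edges
    excl = set(map(tuple, exclude)) | set(a.edges)
    candidates = [
        (d, q) for d in a.drug_ids for q in a.disease_ids if (d, q) not in excl
    ]
    if len(candidates) < n:
        raise ValidationError(
            f"cannot sample {n} negatives: only {len(candidates)} unlabeled "
            "pairs available"
        )
    candidates.sort()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n, replace=False)
    return sorted(candidates[i] for i in idx)


@dataclass(frozen=True)
class PairDataset:
    """Labeled (drug, disease) pairs: positives +1, sampled negatives -1."""

    pairs: tuple[Pair, ...]
    labels: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        if labels.shape != (len(self.pairs),):
            raise ValidationError("labels length does not match pairs")
        if not np.isin(labels, (-1, 1)).all():
            raise ValidationError("labels must be +/-1")
        pos = {p for p, y in zip(self.pairs, labels) if y == 1}
        neg = {p for p, y in zip(self.pairs, labels) if y == -1}
        if pos & neg:
            raise ValidationError(f"pairs labeled both ways: {sorted(pos & neg)}")
        object.__setattr__(self, "pairs", tuple(map(tuple, self.pairs)))
        object.__setattr__(self, "labels", labels)

    @classmethod
    def balanced(
        cls,
        a: AssociationTable,
        seed: int = 0,
        exclude: Iterable[Pair] = (),
    ) -> "PairDataset":
        """All positives plus an equal number of sampled negatives."""
        pos = sorted(a.edges)
        neg = sample_negatives(a, len(pos), seed, exclude)
        return cls(
            tuple(pos + neg),
            np.concatenate([np.ones(len(pos), int), -np.ones(len(neg), int)]),
            seed,
        )

    @property
    def n_positive(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.labels == -1).sum())


@dataclass(frozen=True)
class TrainedModel:
    """Dual SVM solution over the precomputed pair kernel.

    ``dual_coef`` holds y_i * alpha_i for each support pair, so the
    decision function is  f(p) = sum_i dual_coef_i * k(p, support_i) + b.
    """

    support_pairs: tuple[Pair, ...]
    dual_coef: np.ndarray
    intercept: float
    C: float
    kernel_descriptor: str = ""

    def __post_init__(self) -> None:
        dc = np.asarray(self.dual_coef, dtype=float)
        if dc.shape != (len(self.support_pairs),):
            raise ValidationError("dual coefficients do not match support pairs")
        if np.abs(dc).max(initial=0.0) > self.C * (1 + 1e-8):
            raise ValidationError("dual coefficients exceed the box constraint C")
        object.__setattr__(self, "dual_coef", dc)

    def save(self, path: str | os.PathLike) -> None:
        """Serialize to a self-describing text archive."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# predr trained model\n")
            fh.write(f"C\t{self.C!r}\n")
            fh.write(f"intercept\t{self.intercept!r}\n")
            fh.write(f"kernel\t{self.kernel_descriptor}\n")
            fh.write("# drug_id\tdisease_id\tdual_coef\n")
            for (d, q), c in zip(self.support_pairs, self.dual_coef):
                fh.write(f"{d}\t{q}\t{float(c)!r}\n")

    @classmethod
    def load(cls, path: str | os.PathLike) -> "TrainedModel":
        header: dict[str, str] = {}
        pairs: list[Pair] = []
        coefs: list[float] = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) == 2:
                    header[parts[0]] = parts[1]
                elif len(parts) == 3:
                    pairs.append((parts[0], parts[1]))
                    coefs.append(float(parts[2]))
                else:
                    raise ValidationError(f"{path}: malformed line {line!r}")
        return cls(
            tuple(pairs),
            np.array(coefs),
            float(header["intercept"]),
            float(header["C"]),
            header.get("kernel", ""),
        )


def train_svm(
    ds: PairDataset,
    k: PairKernel,
    C: float,
    check_psd: bool = False,
    psd_tol: float = 1e-6,
) -> TrainedModel:
    """Fit a soft-margin SVM on the precomputed pair-kernel Gram."""
    if C <= 0:
        raise ValueError(f"penalty C must be positive, got {C}")
    if len(set(ds.labels)) < 2:
        raise ValidationError("training labels are single-class")
    G = k.gram(ds.pairs)
    if check_psd:
        min_eig = float(np.linalg.eigvalsh(G).min())
        if min_eig < -psd_tol * max(1.0, np.abs(G).max()):
            raise ValidationError(
                f"training Gram is not PSD (min eigenvalue {min_eig:g}); "
                "apply psd_repair to the kernel factors"
            )
    svc = SVC(C=C, kernel="precomputed")
    svc.fit(G, ds.labels)
    support = tuple(ds.pairs[i] for i in svc.support_)
    # sklearn's dual_coef_ is alpha_i * y_i already
    return TrainedModel(
        support,
        svc.dual_coef_[0].copy(),
        float(svc.intercept_[0]),
        float(C),
    )


def decision_scores(
    m: TrainedModel, k: PairKernel, test_pairs: Sequence[Pair]
) -> np.ndarray:
    """Continuous margin scores; their ranking is what metrics consume."""
    G = k.gram(list(test_pairs), list(m.support_pairs))
    return G @ m.dual_coef + m.intercept


def select_C(
    ds: PairDataset,
    k: PairKernel,
    grid: Sequence[float] = C_GRID_DEFAULT,
    folds: int = 3,
    seed: int = 0,
    max_retries: int = 5,
) -> float:
    """Grid search for the SVM penalty by inner stratified CV on AUC.

    Returns the grid value with the highest mean inner-fold AUC, ties
    broken toward smaller C.
    """
    if not grid:
        raise ValueError("empty C grid")
    grid = sorted(float(c) for c in grid)
    if len(grid) == 1:
        return grid[0]
    if folds < 2:
        raise ValueError("need at least 2 inner folds")
    y = ds.labels
    G = k.gram(ds.pairs)
    splits = None
    for attempt in range(max_retries):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=(seed + attempt) % 2**31
        )
        cand = list(skf.split(np.zeros(len(y)), y))
        if all(
            len(set(y[tr])) == 2 and len(set(y[te])) == 2 for tr, te in cand
        ):
            splits = cand
            break
    if splits is None:
        raise ValidationError(
            "could not build inner folds with both classes after "
            f"{max_retries} reshuffles"
        )
    mean_aucs = []
    for C in grid:
        aucs = []
        for tr, te in splits:
            svc = SVC(C=C, kernel="precomputed")
            svc.fit(G[np.ix_(tr, tr)], y[tr])
            scores = svc.decision_function(G[np.ix_(te, tr)])
            aucs.append(roc_auc_score(y[te], scores))
        mean_aucs.append(float(np.mean(aucs)))
    best = int(np.argmax(mean_aucs))  # argmax returns first (smallest C) on ties
    return grid[best]
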