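"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity by the most direct method available
(quadratic DP, exhaustive enumeration, explicit materialization) and is
deliberately written without reference to the package's own
implementations.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices


def smith_waterman_dp(a: str, b: str, matrix_name: str = "BLOSUM50",
                      gap_open: float = 8.0, gap_extend: float = 8.0) -> float:
    """Quadratic-space Gotoh local alignment score.

    A gap of length L costs gap_open + (L-1) * gap_extend (the first
    gapped position pays the open penalty).
    """
    sub = substitution_matrices.load(matrix_name)
    n, m = len(a), len(b)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + sub[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def auc_by_pair_counting(scores, labels) -> float:
    """AUC as the fraction of concordant positive/negative pairs,
    counting ties as one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    total = len(pos) * len(neg)
    conc = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                conc += 1.0
            elif p == q:
                conc += 0.5
    return conc / total


def threshold_scan_brute(scores, labels):
    """Best-F confusion metrics by scanning every cut explicitly.

    Returns (acc, sn, sp, pre, f, threshold) with F ties broken toward
    higher sensitivity, mirroring the documented contract.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == -1).sum())
    best = None
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == -1)).sum())
        if tp + fp == 0:
            continue
        fn = n_pos - tp
        tn = n_neg - fp
        pre = tp / (tp + fp)
        sn = tp / n_pos
        f = 2 * pre * sn / (pre + sn) if pre + sn > 0 else 0.0
        key = (f, sn)
        if best is None or key > (best[4], best[1]):
            best = (
                (tp + tn) / (n_pos + n_neg),
                sn,
                tn / n_neg if n_neg else 0.0,
                pre,
                f,
                float(t),
            )
    return best


def aupr_step_curve(scores, labels) -> float:
    """Area under the PR step curve: sum over positives, in score order,
    of precision at each recall increment."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = int((labels == 1).sum())
    area = 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == -1)).sum())
        pred_prev = scores > t
        tp_prev = int((pred_prev & (labels == 1)).sum())
        if tp + fp:
            area += (tp - tp_prev) / n_pos * (tp / (tp + fp))
    return area


def kron_gram(K_dr: np.ndarray, K_di: np.ndarray) -> np.ndarray:
    """Explicit Kronecker product over the row-major drug x disease grid."""
    return np.kron(K_dr, K_di)
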