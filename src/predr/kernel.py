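"""The drug-disease pair kernel.

A (drug, disease) pair kernel is the Kronecker product of a drug
kernel and a disease kernel:

    k((d, q), (d', q')) = K_dr(d, d') * K_di(q, q')

so two pairs are similar only when the drugs AND the diseases are
simultaneously similar.  The full Kronecker Gram over every drug x
disease pair is never materialized (it grows as (n_drugs *
n_diseases)^2); Gram blocks are built lazily for the requested pair
lists only.

The drug kernel can be a single similarity source ("chem", "inter",
"side-effect") or their fused combination ("comb", an unweighted mean
by default).  Both factors are spectrally repaired to positive
semidefiniteness, which the product kernel inherits and which the SVM
dual requires for convexity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import SimilarityMatrix, ValidationError

__all__ = ["PairKernel", "combine_drug_kernels", "psd_repair", "pair_gram"]

Pair = tuple[str, str]


def combine_drug_kernels(
    mats: Sequence[SimilarityMatrix],
    weights: Sequence[float] | None = None,
) -> SimilarityMatrix:
    """Weighted arithmetic mean of similarity matrices over one id set.

    The "comb" fusion is the unweighted mean of the chemical, target
    and side-effect kernels; weights allow re-balancing the sources.
    """
    if not mats:
        raise ValidationError("no matrices to combine")
    ids = mats[0].ids
    for m in mats[1:]:
        if m.ids != ids:
            raise ValidationError("similarity matrices have mismatched id sets")
    if weights is None:
        weights = [1.0] * len(mats)
    w = np.asarray(list(weights), dtype=float)
    if w.shape != (len(mats),) or (w < 0).any() or w.sum() <= 0:
        raise ValidationError("weights must be nonnegative with positive sum")
    vals = sum(wi * m.values for wi, m in zip(w, mats)) / w.sum()
    vals = (vals + vals.T) / 2.0
    return SimilarityMatrix(ids, vals)


def psd_repair(K: SimilarityMatrix, tol: float = 1e-8) -> SimilarityMatrix:
    """Clip negative eigenvalues to restore positive semidefiniteness.

    If the smallest eigenvalue is already >= -tol the input is returned
    unchanged.  Otherwise negative eigenvalues are set to zero and the
    matrix reconstructed -- the closest PSD matrix in Frobenius norm,
    at distance sqrt(sum of squared negative eigenvalues).
    """
    evals, evecs = np.linalg.eigh(K.values)
    if evals.min() >= -tol:
        return K
    clipped = np.clip(evals, 0.0, None)
    vals = (evecs * clipped) @ evecs.T
    vals = (vals + vals.T) / 2.0
    return SimilarityMatrix(K.ids, vals)


@dataclass(frozen=True)
class PairKernel:
    """Factored Kronecker kernel over (drug, disease) pairs."""

    drug_kernel: SimilarityMatrix
    disease_kernel: SimilarityMatrix

    def _indices(self, pairs: Sequence[Pair]) -> tuple[np.ndarray, np.ndarray]:
        didx = self.drug_kernel.index()
        qidx = self.disease_kernel.index()
        try:
            di = np.array([didx[d] for d, _ in pairs], dtype=int)
        except KeyError as e:
            raise ValidationError(f"unknown drug id {e.args[0]!r}") from None
        try:
            qi = np.array([qidx[q] for _, q in pairs], dtype=int)
        except KeyError as e:
            raise ValidationError(f"unknown disease id {e.args[0]!r}") from None
        return di, qi

    def gram(self, rows: Sequence[Pair], cols: Sequence[Pair] | None = None) -> np.ndarray:
        """Gram block G[i, j] = K_dr(d_i, d_j) * K_di(q_i, q_j)."""
        ri, rq = self._indices(rows)
        if cols is None:
            ci, cq = ri, rq
        else:
            ci, cq = self._indices(cols)
        return (
            self.drug_kernel.values[np.ix_(ri, ci)]
            * self.disease_kernel.values[np.ix_(rq, cq)]
        )

    def value(self, a: Pair, b: Pair) -> float:
        return float(self.gram([a], [b])[0, 0])

    def all_pairs(self) -> list[Pair]:
        """Row-major grid of every drug x disease pair."""
        return [
            (d, q)
            for d in self.drug_kernel.ids
            for q in self.disease_kernel.ids
        ]


def pair_gram(
    k: PairKernel, rows: Sequence[Pair], cols: Sequence[Pair] | None = None
) -> np.ndarray:
    """Functional alias for :meth:`PairKernel.gram`."""
    return k.gram(rows, cols)
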