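"""Drug-drug and disease-derived similarity builders.

Four similarity matrices feed the pair kernel:

* ``S_chem`` and ``S_se`` -- weighted cosine similarity over binary
  profiles (chemical substructure fingerprints, side-effect terms),
  with per-feature weights that down-weight frequent features: rare
  substructures are more informative for specific function than common
  ones.
* ``S_target`` -- target-set sequence similarity: the best (or mean)
  normalized Smith-Waterman score over all cross pairs of the two
  drugs' target proteins, followed by diagonal normalization because
  the raw aggregate need not be positive semidefinite.
* the disease-profile drug similarity used in the correlation analysis:
  best (or mean) phenotype similarity over the diseases the two drugs
  are known to treat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .containers import (
    AssociationTable,
    FingerprintMatrix,
    SequenceStore,
    SimilarityMatrix,
    TargetMap,
    ValidationError,
)

__all__ = [
    "WeightVector",
    "AlignmentParams",
    "compute_feature_weights",
    "weighted_cosine_matrix",
    "profile_similarity",
    "sw_raw_score",
    "normalized_sw_score",
    "pairwise_sw_matrix",
    "target_set_similarity_matrix",
    "diagonal_normalize",
    "disease_profile_drug_similarity",
]

#: default smoothing parameter d of the feature-weight function
DEFAULT_D = 10.0


@dataclass(frozen=True)
class WeightVector:
    """Per-feature weights w_k = exp(-h_k^2 / (d * sigma_h^2)).

    h_k is the number of drugs carrying feature k, sigma_h the
    population standard deviation of the h vector, and d a smoothing
    parameter (default 10).  Weights decrease strictly in h_k, so rare
    features dominate the cosine; when all features are equally
    frequent (sigma_h = 0) every weight is 1 and the measure reduces to
    the plain cosine.
    """

    feature_ids: tuple[str, ...]
    weights: np.ndarray
    d: float = DEFAULT_D
    h: np.ndarray = field(default=None, compare=False)
    sigma_h: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.feature_ids),):
            raise ValidationError("weight length does not match feature ids")
        if not (w > 0).all():
            raise ValidationError("weights must be strictly positive")
        object.__setattr__(self, "weights", w)

    @classmethod
    def uniform(cls, feature_ids, d: float = DEFAULT_D) -> "WeightVector":
        n = len(tuple(feature_ids))
        return cls(tuple(feature_ids), np.ones(n), d, np.zeros(n), 0.0)


def compute_feature_weights(F: FingerprintMatrix, d: float = DEFAULT_D) -> WeightVector:
    """Frequency-based feature weights for a binary profile matrix.

    ``h_k`` is the column sum of F (how many drugs carry feature k) and
    ``w_k = exp(-h_k^2 / (d * sigma_h^2))`` with sigma_h the population
    standard deviation of h.  Degenerate case sigma_h = 0 (all features
    equally frequent, including a single-feature matrix) yields uniform
    weights 1.
    """
    if d <= 0:
        raise ValueError(f"smoothing parameter d must be positive, got {d}")
    if F.n_drugs == 0 or F.n_features == 0:
        raise ValidationError("empty fingerprint matrix")
    h = F.values.sum(axis=0).astype(float)
    sigma = float(h.std())  # population std
    if sigma == 0.0:
        w = np.ones_like(h)
    else:
        w = np.exp(-(h**2) / (d * sigma**2))
    return WeightVector(F.feature_ids, w, float(d), h, sigma)


def weighted_cosine_matrix(
    F: FingerprintMatrix, w: WeightVector | None = None
) -> SimilarityMatrix:
    """Weighted cosine similarity between all pairs of drug profiles.

    S(d, d') = sum_k w_k x_k x'_k /
               (sqrt(sum_k w_k x_k^2) * sqrt(sum_k w_k x'_k^2)).

    Equivalent to the Gram matrix of the rows rescaled by sqrt(w_k) and
    normalized to unit length, hence symmetric, PSD, with values in
    [0, 1] for binary profiles and unit diagonal.  All-zero profiles
    have no direction: by convention they get similarity 0 to every
    other drug and 1 to themselves, with a warning.
    """
    if w is None:
        w = compute_feature_weights(F)
    if tuple(w.feature_ids) != tuple(F.feature_ids):
        raise ValidationError("weight vector features do not match matrix features")
    X = F.values.astype(float) * np.sqrt(w.weights)
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0.0
    if zero.any():
        names = [F.drug_ids[i] for i in np.flatnonzero(zero)]
        warnings.warn(
            f"all-zero profiles for drugs {names}; similarity set to 0 "
            "off-diagonal by convention",
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, norms)
    Xn = X / safe[:, None]
    S = Xn @ Xn.T
    np.clip(S, 0.0, 1.0, out=S)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(F.drug_ids, S)


def profile_similarity(F: FingerprintMatrix, d: float = DEFAULT_D) -> SimilarityMatrix:
    """Convenience: frequency weights at parameter ``d``, then weighted
    cosine.  This is the one-call builder for S_chem / S_se."""
    return weighted_cosine_matrix(F, compute_feature_weights(F, d))


# ---------------------------------------------------------------------------
# Smith-Waterman sequence similarity


@dataclass(frozen=True)
class AlignmentParams:
    """Local-alignment scoring: substitution matrix plus gap penalties.

    Defaults (BLOSUM50, gap open 8, gap extend 8) follow the common
    protein-alignment toolbox convention.  A gap of length L costs
    ``gap_open + (L - 1) * gap_extend``.
    """

    substitution_matrix_name: str = "BLOSUM50"
    gap_open: float = 8.0
    gap_extend: float = 8.0

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValidationError(
                f"need gap_open >= gap_extend >= 0, got "
                f"({self.gap_open}, {self.gap_extend})"
            )

    def aligner(self) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.substitution_matrix = substitution_matrices.load(
            self.substitution_matrix_name
        )
        al.open_gap_score = -float(self.gap_open)
        al.extend_gap_score = -float(self.gap_extend)
        return al


_DEFAULT_PARAMS = AlignmentParams()


def _check_sequence(seq: str, alphabet: str) -> str:
    seq = str(seq).upper()
    if not seq:
        raise ValidationError("empty sequence")
    bad = set(seq) - (set(alphabet) - {"*"})
    if bad:
        raise ValidationError(f"invalid residues {sorted(bad)}")
    return seq


def sw_raw_score(
    a: str, b: str, p: AlignmentParams = _DEFAULT_PARAMS
) -> float:
    """Raw (un-normalized) Smith-Waterman local alignment score."""
    al = p.aligner()
    a = _check_sequence(a, al.substitution_matrix.alphabet)
    b = _check_sequence(b, al.substitution_matrix.alphabet)
    return float(al.score(a, b))


def normalized_sw_score(
    a: str, b: str, p: AlignmentParams = _DEFAULT_PARAMS
) -> float:
    """Self-score-normalized Smith-Waterman similarity in [0, 1].

    sw(a, b) / sqrt(sw(a, a) * sw(b, b)); symmetric, and 1 for
    identical sequences.
    """
    al = p.aligner()
    a = _check_sequence(a, al.substitution_matrix.alphabet)
    b = _check_sequence(b, al.substitution_matrix.alphabet)
    saa = float(al.score(a, a))
    sbb = float(al.score(b, b))
    if saa <= 0 or sbb <= 0:
        raise ValidationError("nonpositive self-alignment score")
    return float(al.score(a, b)) / np.sqrt(saa * sbb)


def pairwise_sw_matrix(
    store: SequenceStore,
    p: AlignmentParams = _DEFAULT_PARAMS,
    protein_ids: tuple[str, ...] | None = None,
) -> SimilarityMatrix:
    """All-pairs normalized Smith-Waterman matrix over a sequence store."""
    ids = tuple(protein_ids) if protein_ids is not None else store.protein_ids
    al = p.aligner()
    alphabet = al.substitution_matrix.alphabet
    seqs = [_check_sequence(store[pid], alphabet) for pid in ids]
    n = len(ids)
    self_scores = np.array([al.score(s, s) for s in seqs], dtype=float)
    if (self_scores <= 0).any():
        bad = [ids[i] for i in np.flatnonzero(self_scores <= 0)]
        raise ValidationError(f"nonpositive self-alignment score for {bad}")
    S = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = al.score(seqs[i], seqs[j]) / np.sqrt(
                self_scores[i] * self_scores[j]
            )
    return SimilarityMatrix(ids, S)


def _aggregate(values: np.ndarray, aggregator: str) -> float:
    if aggregator == "max":
        return float(values.max())
    if aggregator == "mean":
        return float(values.mean())
    raise ValueError(f"unknown aggregator {aggregator!r}; use 'max' or 'mean'")


def target_set_similarity_matrix(
    t: TargetMap,
    s: SequenceStore,
    p: AlignmentParams = _DEFAULT_PARAMS,
    aggregator: str = "max",
    normalize: bool = True,
) -> SimilarityMatrix:
    """Drug-drug similarity from target-protein sequence similarity.

    S(d, d') aggregates (max by default, best cross-pair match) the
    normalized Smith-Waterman scores over all pairs of d's and d's
    targets.  Drugs without targets get 0 off-diagonal (warning) and 1
    on the diagonal.  With ``normalize`` the aggregated matrix is
    re-scaled to unit diagonal via :func:`diagonal_normalize`, since
    the raw aggregate need not be positive semidefinite nor have unit
    self-similarity under the mean aggregator.
    """
    drugs = t.drug_ids
    prot_ids = t.protein_ids
    missing = [p_ for p_ in prot_ids if p_ not in s]
    if missing:
        raise ValidationError(f"targets without sequence: {missing}")
    psim = pairwise_sw_matrix(s, p, prot_ids)
    pidx = psim.index()

    empty = [d for d in drugs if not t.targets(d)]
    if empty:
        warnings.warn(
            f"drugs with no targets {empty}: similarity 0 off-diagonal",
            stacklevel=2,
        )
    n = len(drugs)
    S = np.zeros((n, n))
    tsets = [sorted(t.targets(d)) for d in drugs]
    tind = [np.array([pidx[p_] for p_ in ts], dtype=int) for ts in tsets]
    for i in range(n):
        if len(tind[i]) == 0:
            continue
        for j in range(i, n):
            if len(tind[j]) == 0:
                continue
            block = psim.values[np.ix_(tind[i], tind[j])]
            S[i, j] = S[j, i] = _aggregate(block, aggregator)
    np.fill_diagonal(S, np.where([len(ti) == 0 for ti in tind], 1.0, S.diagonal()))
    out = SimilarityMatrix(drugs, S)
    if normalize:
        out = diagonal_normalize(out)
    else:
        vals = out.values.copy()
        np.fill_diagonal(vals, 1.0)
        out = SimilarityMatrix(drugs, vals)
    return out


def diagonal_normalize(K: SimilarityMatrix) -> SimilarityMatrix:
    """Rescale to unit diagonal: K'_ij = K_ij / sqrt(K_ii * K_jj).

    Equivalent to D^{-1/2} K D^{-1/2} with D = diag(K); idempotent, and
    the identity on matrices that already have a unit diagonal.
    """
    diag = K.values.diagonal()
    if (diag <= 0).any():
        bad = [K.ids[i] for i in np.flatnonzero(diag <= 0)]
        raise ValidationError(f"nonpositive diagonal entries for ids {bad}")
    inv = 1.0 / np.sqrt(diag)
    vals = K.values * np.outer(inv, inv)
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 1.0)
    return SimilarityMatrix(K.ids, vals)


def disease_profile_drug_similarity(
    a: AssociationTable,
    pheno: SimilarityMatrix,
    aggregator: str = "max",
) -> SimilarityMatrix:
    """Drug similarity through the diseases the drugs are known to treat.

    S(d, d') aggregates pheno(q, q') over q in Dis(d), q' in Dis(d'),
    where Dis(d) is d's gold-standard disease set.  Drugs without any
    association are excluded (with a warning) since they have no
    disease profile.  Diagonal is forced to 1.
    """
    pidx = pheno.index()
    kept, dsets = [], []
    dropped = []
    for d in a.drug_ids:
        qs = [q for q in sorted(a.diseases_of(d)) if q in pidx]
        if qs:
            kept.append(d)
            dsets.append(np.array([pidx[q] for q in qs], dtype=int))
        else:
            dropped.append(d)
    if dropped:
        warnings.warn(
            f"drugs without phenotype-covered diseases excluded: {dropped}",
            stacklevel=2,
        )
    n = len(kept)
    S = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            block = pheno.values[np.ix_(dsets[i], dsets[j])]
            S[i, j] = S[j, i] = _aggregate(block, aggregator)
    return SimilarityMatrix(tuple(kept), S)
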