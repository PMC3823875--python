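"""Core labeled containers shared by all stages.

Everything downstream (similarity builders, the pair kernel, the SVM,
evaluation protocols) consumes these five types.  They are thin wrappers
around numpy arrays / plain mappings whose job is to carry identifier
labels alongside the numbers and to enforce the structural invariants
once, at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "FingerprintMatrix",
    "SimilarityMatrix",
    "AssociationTable",
    "TargetMap",
    "SequenceStore",
    "ValidationError",
]

#: internal symmetry tolerance for similarity matrices
SYMMETRY_TOL = 1e-10

# 20 standard amino acids plus the BLOSUM ambiguity codes B/Z/X
AMINO_ALPHABET = frozenset("ARNDCQEGHILKMFPSTWYVBZX")


class ValidationError(ValueError):
    """Raised when a container's structural invariants are violated."""


def _check_unique(labels: Iterable[str], what: str) -> tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    if len(set(labels)) != len(labels):
        seen, dups = set(), []
        for x in labels:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))}")
    return labels


@dataclass(frozen=True)
class FingerprintMatrix:
    """Binary drug-by-feature profile matrix.

    Rows are drugs, columns are named binary features -- chemical
    substructure keys (PubChem-style fingerprints) or side-effect
    annotation terms (SIDER-style).  Entry 1 marks feature presence.
    """

    drug_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug_ids", _check_unique(self.drug_ids, "drug ids"))
        object.__setattr__(
            self, "feature_ids", _check_unique(self.feature_ids, "feature ids")
        )
        vals = np.asarray(self.values)
        if vals.ndim != 2 or vals.shape != (len(self.drug_ids), len(self.feature_ids)):
            raise ValidationError(
                f"fingerprint matrix shape {vals.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.feature_ids)} features"
            )
        if not np.isin(vals, (0, 1)).all():
            bad = np.argwhere(~np.isin(vals, (0, 1)))[0]
            raise ValidationError(
                f"non-binary entry at drug {self.drug_ids[bad[0]]!r}, "
                f"feature {self.feature_ids[bad[1]]!r}: {vals[tuple(bad)]!r}"
            )
        object.__setattr__(self, "values", vals.astype(np.int8))

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Labeled square symmetric similarity matrix.

    Carrier of every pairwise-similarity object in the pipeline:
    S_chem, S_target, S_se (drug side), S_pheno (disease side), and the
    fused drug kernel.
    """

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", _check_unique(self.ids, "ids"))
        vals = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if vals.shape != (n, n):
            raise ValidationError(f"matrix shape {vals.shape} is not ({n}, {n})")
        if not np.isfinite(vals).all():
            raise ValidationError("similarity matrix contains non-finite entries")
        asym = np.abs(vals - vals.T).max() if n else 0.0
        if asym > SYMMETRY_TOL:
            raise ValidationError(
                f"matrix asymmetric beyond tolerance: max |M - M^T| = {asym:g}"
            )
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self) -> dict[str, int]:
        return {x: i for i, x in enumerate(self.ids)}

    def value(self, a: str, b: str) -> float:
        idx = self.index()
        return float(self.values[idx[a], idx[b]])

    def reorder(self, ids: Iterable[str]) -> "SimilarityMatrix":
        """Restrict/permute to the given id order."""
        idx = self.index()
        try:
            sel = [idx[x] for x in ids]
        except KeyError as e:
            raise ValidationError(f"unknown id {e.args[0]!r}") from None
        return SimilarityMatrix(tuple(self.ids[i] for i in sel),
                                self.values[np.ix_(sel, sel)])


@dataclass(frozen=True)
class AssociationTable:
    """Gold-standard bipartite drug-disease association set.

    ``edges`` holds known (drug, disease) treatment associations; the id
    universes may contain isolated entities (drugs or diseases without
    any known association).
    """

    edges: frozenset[tuple[str, str]]
    drug_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))
        object.__setattr__(self, "drug_ids", _check_unique(self.drug_ids, "drug ids"))
        object.__setattr__(
            self, "disease_ids", _check_unique(self.disease_ids, "disease ids")
        )
        drugs, dis = set(self.drug_ids), set(self.disease_ids)
        for d, q in self.edges:
            if d not in drugs:
                raise ValidationError(f"edge drug {d!r} not in drug universe")
            if q not in dis:
                raise ValidationError(f"edge disease {q!r} not in disease universe")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        drug_ids: Iterable[str] | None = None,
        disease_ids: Iterable[str] | None = None,
    ) -> "AssociationTable":
        """Build from an edge list; universes default to observed labels
        in first-seen order."""
        edges = [(str(d), str(q)) for d, q in edges]
        if drug_ids is None:
            drug_ids = list(dict.fromkeys(d for d, _ in edges))
        if disease_ids is None:
            disease_ids = list(dict.fromkeys(q for _, q in edges))
        return cls(frozenset(edges), tuple(drug_ids), tuple(disease_ids))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def diseases_of(self, drug: str) -> frozenset[str]:
        return frozenset(q for d, q in self.edges if d == drug)

    def drugs_of(self, disease: str) -> frozenset[str]:
        return frozenset(d for d, q in self.edges if q == disease)

    def without_drug(self, drug: str) -> "AssociationTable":
        """Copy with every edge of ``drug`` removed (universes kept)."""
        return AssociationTable(
            frozenset(e for e in self.edges if e[0] != drug),
            self.drug_ids,
            self.disease_ids,
        )


@dataclass(frozen=True)
class SequenceStore:
    """Protein id -> amino-acid sequence (uppercase standard alphabet)."""

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        seqs = {}
        for pid, seq in dict(self.sequences).items():
            seq = str(seq).upper()
            if not seq:
                raise ValidationError(f"empty sequence for protein {pid!r}")
            bad = set(seq) - AMINO_ALPHABET
            if bad:
                raise ValidationError(
                    f"invalid residues {sorted(bad)} in protein {pid!r}"
                )
            seqs[str(pid)] = seq
        object.__setattr__(self, "sequences", seqs)

    def __getitem__(self, pid: str) -> str:
        return self.sequences[pid]

    def __contains__(self, pid: str) -> bool:
        return pid in self.sequences

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def protein_ids(self) -> tuple[str, ...]:
        return tuple(self.sequences)


@dataclass(frozen=True)
class TargetMap:
    """Drug id -> set of target protein ids."""

    drug_to_targets: Mapping[str, frozenset[str]]
    store: SequenceStore | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        mapping = {
            str(d): frozenset(str(p) for p in ps)
            for d, ps in dict(self.drug_to_targets).items()
        }
        object.__setattr__(self, "drug_to_targets", mapping)
        if self.store is not None:
            missing = sorted(
                p for ps in mapping.values() for p in ps if p not in self.store
            )
            if missing:
                raise ValidationError(
                    f"targets without sequence: {sorted(set(missing))}"
                )

    def targets(self, drug: str) -> frozenset[str]:
        return self.drug_to_targets.get(drug, frozenset())

    @property
    def drug_ids(self) -> tuple[str, ...]:
        return tuple(self.drug_to_targets)

    @property
    def protein_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for ps in self.drug_to_targets.values():
            for p in sorted(ps):
                seen.setdefault(p, None)
        return tuple(seen)
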