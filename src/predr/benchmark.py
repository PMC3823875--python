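"""Synthetic benchmark generator with planted class structure.

The generator encodes the premise the whole method rests on -- similar
drugs treat similar diseases -- as planted latent classes: drugs and
diseases each belong to one of ``n_classes`` classes; same-class drugs
share noisy copies of a class prototype fingerprint, side-effect
profile and target-protein sequence; the disease phenotype matrix is a
noisy block matrix over disease classes; and associations are dense
within matching classes and sparse across.  Every input the pipeline
consumes (both fingerprint matrices, target map + FASTA, phenotype
matrix, gold-standard edges) is produced, fully determined by the
seed, so the complete method is exercisable offline.

What this emulates -- and what it does not -- is discussed in the
package's methods documentation: real fingerprints are sparser, real
class structure is soft and overlapping, and real association networks
have heavy-tailed degrees.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    AssociationTable,
    FingerprintMatrix,
    SequenceStore,
    SimilarityMatrix,
    TargetMap,
)
from . import io as pio
from .similarity import profile_similarity, target_set_similarity_matrix

__all__ = ["BenchmarkParams", "SyntheticBenchmark", "generate_benchmark",
           "generate_trivial_target_benchmark", "benchmark_summary",
           "write_benchmark"]

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class BenchmarkParams:
    """Knobs of the planted-structure generator.

    Defaults are sized so a full cross-validation run completes in
    minutes on one CPU while leaving enough pairs for stable metrics.
    """

    n_drugs: int = 60
    n_diseases: int = 40
    n_classes: int = 4
    n_chem_features: int = 200
    n_se_features: int = 100
    bit_noise: float = 0.1          # per-bit flip probability
    prototype_density: float = 0.3  # P(bit set) in a class prototype
    seq_length: int = 120           # residues per target protein
    mutation_rate: float = 0.05     # per-site substitution probability
    targets_per_drug: tuple[int, int] = (1, 3)
    assoc_prob_within: float = 0.5
    assoc_prob_between: float = 0.02
    pheno_within: float = 0.7
    pheno_between: float = 0.2
    pheno_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "bit_noise": self.bit_noise,
            "prototype_density": self.prototype_density,
            "mutation_rate": self.mutation_rate,
            "assoc_prob_within": self.assoc_prob_within,
            "assoc_prob_between": self.assoc_prob_between,
        }
        for name, v in probs.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_classes > min(self.n_drugs, self.n_diseases):
            raise ValueError("n_classes exceeds the number of drugs or diseases")
        if self.assoc_prob_within <= self.assoc_prob_between:
            raise ValueError("assoc_prob_within must exceed assoc_prob_between")
        if self.pheno_within <= self.pheno_between:
            raise ValueError("pheno_within must exceed pheno_between")
        lo, hi = self.targets_per_drug
        if not (1 <= lo <= hi):
            raise ValueError("targets_per_drug must be a range with 1 <= lo <= hi")

    def with_seed(self, seed: int) -> "BenchmarkParams":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SyntheticBenchmark:
    """Complete generated input bundle plus the planted truth labels."""

    chem: FingerprintMatrix
    se: FingerprintMatrix
    targets: TargetMap
    sequences: SequenceStore
    pheno: SimilarityMatrix
    associations: AssociationTable
    drug_class: dict[str, int]
    disease_class: dict[str, int]
    params: BenchmarkParams = field(compare=False, default=None)


def _class_of(i: int, n: int, n_classes: int) -> int:
    # contiguous, near-equal blocks
    return min(i * n_classes // n, n_classes - 1)


def _noisy_profiles(
    prototypes: np.ndarray, classes: np.ndarray, noise: float, rng
) -> np.ndarray:
    profiles = prototypes[classes].astype(np.int8)
    flips = rng.random(profiles.shape) < noise
    return np.where(flips, 1 - profiles, profiles).astype(np.int8)


def _mutate(seq: str, rate: float, rng) -> str:
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            alt = AA20.replace(chars[i], "")
            chars[i] = alt[rng.integers(len(alt))]
    return "".join(chars)


def generate_benchmark(p: BenchmarkParams | None = None) -> SyntheticBenchmark:
    """Generate the full synthetic input bundle for given parameters."""
    if p is None:
        p = BenchmarkParams()
    rng = np.random.default_rng(p.seed)

    drug_ids = tuple(f"D{i:03d}" for i in range(p.n_drugs))
    disease_ids = tuple(f"Q{i:03d}" for i in range(p.n_diseases))
    dclass = np.array(
        [_class_of(i, p.n_drugs, p.n_classes) for i in range(p.n_drugs)]
    )
    qclass = np.array(
        [_class_of(i, p.n_diseases, p.n_classes) for i in range(p.n_diseases)]
    )

    # binary profiles: per-class prototypes + independent bit flips
    chem_proto = (rng.random((p.n_classes, p.n_chem_features))
                  < p.prototype_density).astype(np.int8)
    se_proto = (rng.random((p.n_classes, p.n_se_features))
                < p.prototype_density).astype(np.int8)
    chem = FingerprintMatrix(
        drug_ids,
        tuple(f"chem_{k}" for k in range(p.n_chem_features)),
        _noisy_profiles(chem_proto, dclass, p.bit_noise, rng),
    )
    se = FingerprintMatrix(
        drug_ids,
        tuple(f"se_{k}" for k in range(p.n_se_features)),
        _noisy_profiles(se_proto, dclass, p.bit_noise, rng),
    )

    # target proteins: point-mutated copies of a class prototype sequence
    proto_seqs = [
        "".join(AA20[j] for j in rng.integers(len(AA20), size=p.seq_length))
        for _ in range(p.n_classes)
    ]
    sequences: dict[str, str] = {}
    mapping: dict[str, frozenset[str]] = {}
    lo, hi = p.targets_per_drug
    for i, d in enumerate(drug_ids):
        n_t = int(rng.integers(lo, hi + 1))
        pids = []
        for j in range(n_t):
            pid = f"P_{d}_{j}"
            sequences[pid] = _mutate(proto_seqs[dclass[i]], p.mutation_rate, rng)
            pids.append(pid)
        mapping[d] = frozenset(pids)
    store = SequenceStore(sequences)
    tmap = TargetMap(mapping, store)

    # phenotype matrix: block structure + symmetric noise, unit diagonal
    block = np.where(
        qclass[:, None] == qclass[None, :], p.pheno_within, p.pheno_between
    )
    noise = rng.normal(0.0, p.pheno_noise, size=block.shape)
    noise = (noise + noise.T) / 2.0
    pheno_vals = np.clip(block + noise, 0.0, 1.0)
    np.fill_diagonal(pheno_vals, 1.0)
    pheno = SimilarityMatrix(disease_ids, pheno_vals)

    # associations: dense within matching classes, sparse across
    prob = np.where(
        dclass[:, None] == qclass[None, :],
        p.assoc_prob_within,
        p.assoc_prob_between,
    )
    hit = rng.random(prob.shape) < prob
    edges = frozenset(
        (drug_ids[i], disease_ids[j]) for i, j in zip(*np.nonzero(hit))
    )
    assoc = AssociationTable(edges, drug_ids, disease_ids)

    return SyntheticBenchmark(
        chem=chem,
        se=se,
        targets=tmap,
        sequences=store,
        pheno=pheno,
        associations=assoc,
        drug_class={d: int(c) for d, c in zip(drug_ids, dclass)},
        disease_class={q: int(c) for q, c in zip(disease_ids, qclass)},
        params=p,
    )


def generate_trivial_target_benchmark(
    p: BenchmarkParams | None = None,
    nontrivial_mutation: float = 0.4,
) -> tuple[SyntheticBenchmark, frozenset[str]]:
    """Benchmark variant where half the drugs share identical targets.

    Exercises the trivial-prediction filter: within each class,
    alternating drugs ("trivial" drugs) all target one shared protein
    -- their pairwise target similarity is exactly 1, so any disease
    they co-treat is predictable from the shared target alone.  The
    remaining drugs get private targets mutated heavily
    (``nontrivial_mutation`` per site) from the class prototype: still
    class-informative but well below the similarity cutoff of the
    filter.

    Returns the benchmark and the set of trivial drug ids.
    """
    if p is None:
        p = BenchmarkParams()
    base = generate_benchmark(p)
    rng = np.random.default_rng(p.seed + 1)
    proto_seqs = {
        c: "".join(AA20[j] for j in rng.integers(len(AA20), size=p.seq_length))
        for c in range(p.n_classes)
    }
    sequences: dict[str, str] = {
        f"T_class{c}": seq for c, seq in proto_seqs.items()
    }
    mapping: dict[str, frozenset[str]] = {}
    trivial: set[str] = set()
    per_class_rank: dict[int, int] = {}
    for d in base.associations.drug_ids:
        c = base.drug_class[d]
        rank = per_class_rank.get(c, 0)
        per_class_rank[c] = rank + 1
        if rank % 2 == 0:
            trivial.add(d)
            mapping[d] = frozenset({f"T_class{c}"})
        else:
            pid = f"P_{d}_0"
            sequences[pid] = _mutate(proto_seqs[c], nontrivial_mutation, rng)
            mapping[d] = frozenset({pid})
    store = SequenceStore(sequences)
    bench = SyntheticBenchmark(
        chem=base.chem,
        se=base.se,
        targets=TargetMap(mapping, store),
        sequences=store,
        pheno=base.pheno,
        associations=base.associations,
        drug_class=base.drug_class,
        disease_class=base.disease_class,
        params=p,
    )
    return bench, frozenset(trivial)


def _within_between(S: SimilarityMatrix, classes: dict[str, int]) -> tuple[float, float]:
    labels = np.array([classes[d] for d in S.ids])
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    vals = S.values[iu]
    mask = same[iu]
    within = float(vals[mask].mean()) if mask.any() else np.nan
    between = float(vals[~mask].mean()) if (~mask).any() else np.nan
    return within, between


def benchmark_summary(b: SyntheticBenchmark) -> pd.DataFrame:
    """Counts, density, and within/between-class mean similarity per source."""
    rows = {
        "n_drugs": len(b.associations.drug_ids),
        "n_diseases": len(b.associations.disease_ids),
        "n_edges": b.associations.n_edges,
        "density": b.associations.n_edges
        / (len(b.associations.drug_ids) * len(b.associations.disease_ids)),
    }
    sources = {
        "chem": profile_similarity(b.chem),
        "side_effect": profile_similarity(b.se),
        "target": target_set_similarity_matrix(b.targets, b.sequences),
    }
    for name, S in sources.items():
        w, bt = _within_between(S, b.drug_class)
        rows[f"{name}_within_mean"] = w
        rows[f"{name}_between_mean"] = bt
    w, bt = _within_between(b.pheno, b.disease_class)
    rows["pheno_within_mean"] = w
    rows["pheno_between_mean"] = bt
    return pd.DataFrame([rows])


def write_benchmark(b: SyntheticBenchmark, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write the bundle in the canonical formats plus a truth table."""
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    paths = {
        "chem": os.path.join(out, "chem_fingerprints.tsv"),
        "se": os.path.join(out, "side_effects.tsv"),
        "targets": os.path.join(out, "drug_targets.tsv"),
        "fasta": os.path.join(out, "target_sequences.fasta"),
        "pheno": os.path.join(out, "phenotype_similarity.tsv"),
        "associations": os.path.join(out, "associations.tsv"),
        "truth": os.path.join(out, "truth_classes.tsv"),
    }
    pio.write_fingerprints(b.chem, paths["chem"])
    pio.write_fingerprints(b.se, paths["se"])
    pio.write_target_map(b.targets, paths["targets"])
    pio.write_fasta(b.sequences, paths["fasta"])
    pio.write_similarity_matrix(b.pheno, paths["pheno"])
    pio.write_associations(b.associations, paths["associations"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("# entity\tid\tclass\n")
        for d, c in b.drug_class.items():
            fh.write(f"drug\t{d}\t{c}\n")
        for q, c in b.disease_class.items():
            fh.write(f"disease\t{q}\t{c}\n")
    return paths
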