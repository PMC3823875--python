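"""Readers and writers for the canonical on-disk formats.

The repository convention is plain TSV (tab-separated, UTF-8, ``#``
comment lines) for matrices and edge lists, and FASTA for protein
sequences.  Readers validate strictly and preserve file order; writers
mirror readers bit-exactly for integer content and use ``%.6g`` for
reals, so read-after-write is the identity.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import (
    AssociationTable,
    FingerprintMatrix,
    SequenceStore,
    SimilarityMatrix,
    TargetMap,
    ValidationError,
)

__all__ = [
    "read_fingerprints",
    "write_fingerprints",
    "read_associations",
    "write_associations",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_target_data",
    "write_target_map",
    "write_fasta",
    "FormatError",
]

#: asymmetry absorbed (by averaging) when reading similarity matrices
READ_SYMMETRY_TOL = 1e-6


class FormatError(ValueError):
    """Raised for malformed input files."""


def _read_table(path: str | os.PathLike) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_fingerprints(path: str | os.PathLike) -> FingerprintMatrix:
    """Read a binary drug x feature matrix.

    Expected layout: header row of feature ids, first column of drug
    ids, body strictly 0/1.
    """
    df = _read_table(path)
    raw = np.char.strip(df.to_numpy(dtype=str))
    ok = (raw == "0") | (raw == "1")
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise FormatError(
            f"{path}: non-binary value {raw[i, j]!r} at drug "
            f"{df.index[i]!r}, feature {df.columns[j]!r}"
        )
    values = (raw == "1").astype(np.int8)
    try:
        return FingerprintMatrix(tuple(df.index), tuple(df.columns), values)
    except ValidationError as e:
        raise FormatError(f"{path}: {e}") from None


def write_fingerprints(fp: FingerprintMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(fp.values, index=list(fp.drug_ids), columns=list(fp.feature_ids))
    df.to_csv(path, sep="\t")


def read_associations(
    path: str | os.PathLike,
    drug_ids: Iterable[str] | None = None,
    disease_ids: Iterable[str] | None = None,
) -> AssociationTable:
    """Read a two-column (drug, disease) edge list; duplicates collapse.

    Universes default to the observed labels in file order; pass
    explicit ``drug_ids`` / ``disease_ids`` to include isolated
    entities.
    """
    edges: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise FormatError(
                    f"{path}:{lineno}: expected two tab-separated columns, "
                    f"got {line!r}"
                )
            edges.append((parts[0].strip(), parts[1].strip()))
    if not edges:
        raise FormatError(f"{path}: no association edges found")
    return AssociationTable.from_edges(edges, drug_ids, disease_ids)


def write_associations(a: AssociationTable, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# drug_id\tdisease_id\n")
        for d, q in sorted(a.edges):
            fh.write(f"{d}\t{q}\n")


def read_similarity_matrix(path: str | os.PathLike) -> SimilarityMatrix:
    """Read a square labeled similarity matrix.

    Header-row and first-column labels must match.  Asymmetry up to
    1e-6 (text-format rounding) is absorbed by averaging (M + M^T)/2;
    anything larger is an error.
    """
    df = _read_table(path)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"{path}: matrix is {df.shape[0]}x{df.shape[1]}, not square")
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row labels do not match column labels")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as e:
        raise FormatError(f"{path}: non-numeric entry ({e})") from None
    if not np.isfinite(values).all():
        raise FormatError(f"{path}: non-finite entries")
    asym = np.abs(values - values.T).max() if len(df) else 0.0
    if asym > READ_SYMMETRY_TOL:
        raise FormatError(
            f"{path}: asymmetry {asym:g} exceeds tolerance {READ_SYMMETRY_TOL:g}"
        )
    values = (values + values.T) / 2.0
    return SimilarityMatrix(tuple(df.index), values)


def write_similarity_matrix(s: SimilarityMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(s.values, index=list(s.ids), columns=list(s.ids))
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_target_data(
    map_path: str | os.PathLike, fasta_path: str | os.PathLike
) -> tuple[TargetMap, SequenceStore]:
    """Read a drug -> target-protein map plus the protein FASTA.

    Every protein referenced in the map must have a FASTA record.
    """
    store = SequenceStore(
        {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    )
    mapping: dict[str, set[str]] = {}
    with open(map_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise FormatError(
                    f"{map_path}:{lineno}: expected two tab-separated columns, "
                    f"got {line!r}"
                )
            mapping.setdefault(parts[0].strip(), set()).add(parts[1].strip())
    missing = sorted(
        {p for ps in mapping.values() for p in ps if p not in store}
    )
    if missing:
        raise FormatError(
            f"{map_path}: proteins missing from {fasta_path}: {missing}"
        )
    tmap = TargetMap({d: frozenset(ps) for d, ps in mapping.items()}, store)
    return tmap, store


def write_target_map(t: TargetMap, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# drug_id\tprotein_id\n")
        for d in t.drug_ids:
            for p in sorted(t.targets(d)):
                fh.write(f"{d}\t{p}\n")


def write_fasta(store: SequenceStore, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="")
        for pid, seq in store.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
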