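"""Descriptive analyses around the predictor.

* Drug-drug shortest-path distances in the bipartite association
  network (distance 2 = the drugs share a disease, 4 = connected
  through one intermediate drug, ... even by construction).
* Correlation between a drug-similarity source and the drugs'
  disease-profile similarity, overall and restricted to increasingly
  similar drug pairs -- the sanity check that drugs similar in
  structure / targets / side-effects tend to treat similar diseases.
* Ranked novel predictions: scores for every unlabeled pair, top-N.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import AssociationTable, SimilarityMatrix, ValidationError
from .kernel import PairKernel
from .svm import TrainedModel, decision_scores

__all__ = [
    "DistanceTable",
    "drug_network_distances",
    "similarity_profile_correlation",
    "rank_novel_predictions",
]

DEFAULT_BINS = (0.0, 0.2, 0.4, 0.6, 0.8)


@dataclass(frozen=True)
class DistanceTable:
    """Symmetric drug-drug shortest-path lengths; inf when disconnected."""

    drug_ids: tuple[str, ...]
    values: np.ndarray  # float matrix, even entries or inf off-diagonal

    def distance(self, a: str, b: str) -> float:
        idx = {d: i for i, d in enumerate(self.drug_ids)}
        return float(self.values[idx[a], idx[b]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.drug_ids), columns=list(self.drug_ids)
        )


def drug_network_distances(a: AssociationTable) -> DistanceTable:
    """All-pairs drug distances in the bipartite drug-disease graph.

    Breadth-first search from each drug; drug-drug path lengths are
    even (drug -> disease -> drug alternation), distance 2 meaning the
    two drugs share at least one disease.
    """
    if not a.edges:
        raise ValidationError("empty association table")
    g = nx.Graph()
    g.add_nodes_from(("drug", d) for d in a.drug_ids)
    g.add_nodes_from(("disease", q) for q in a.disease_ids)
    g.add_edges_from((("drug", d), ("disease", q)) for d, q in a.edges)
    n = len(a.drug_ids)
    vals = np.full((n, n), np.inf)
    np.fill_diagonal(vals, 0.0)
    idx = {d: i for i, d in enumerate(a.drug_ids)}
    for d in a.drug_ids:
        lengths = nx.single_source_shortest_path_length(g, ("drug", d))
        i = idx[d]
        for (kind, other), dist in lengths.items():
            if kind == "drug":
                vals[i, idx[other]] = float(dist)
    return DistanceTable(a.drug_ids, vals)


def similarity_profile_correlation(
    s: SimilarityMatrix,
    dp: SimilarityMatrix,
    min_similarity_bins: Sequence[float] = DEFAULT_BINS,
) -> pd.DataFrame:
    """Pearson correlation between two drug-similarity matrices.

    Uses each unordered off-diagonal drug pair once.  Besides the
    overall correlation, the PCC is recomputed on the cumulative tails
    s >= cutoff for each bin cutoff -- the expectation being that the
    correlation strengthens among more similar drugs.  Two-sided
    p-values come from the exact t-transform of r with n-2 degrees of
    freedom.  Bins with fewer than 3 pairs are reported as undefined
    (NaN).
    """
    common = [d for d in s.ids if d in set(dp.ids)]
    if len(common) < 3:
        raise ValidationError("need at least 3 drugs common to both matrices")
    sv = s.reorder(common).values
    dv = dp.reorder(common).values
    iu = np.triu_indices(len(common), k=1)
    x = sv[iu]
    y = dv[iu]

    rows = []
    for cutoff in min_similarity_bins:
        mask = x >= cutoff
        n = int(mask.sum())
        if n < 3 or np.std(x[mask]) == 0 or np.std(y[mask]) == 0:
            rows.append(
                {"min_similarity": cutoff, "n_pairs": n, "pcc": np.nan, "p_value": np.nan}
            )
            continue
        r, p = stats.pearsonr(x[mask], y[mask])
        rows.append(
            {"min_similarity": cutoff, "n_pairs": n, "pcc": float(r), "p_value": float(p)}
        )
    out = pd.DataFrame(rows)
    out.attrs["binning"] = "cumulative-tail"
    return out


def rank_novel_predictions(
    m: TrainedModel,
    k: PairKernel,
    a: AssociationTable,
    top_n: int = 100,
) -> pd.DataFrame:
    """Score every non-gold-standard pair and return the top-N.

    Candidates are all drug x disease pairs absent from the gold
    standard; ties in score break deterministically by (drug_id,
    disease_id).
    """
    candidates = [
        (d, q) for d in a.drug_ids for q in a.disease_ids if (d, q) not in a.edges
    ]
    if not candidates:
        raise ValidationError("no unlabeled pairs to score")
    if top_n > len(candidates):
        warnings.warn(
            f"top_n={top_n} exceeds {len(candidates)} candidates; truncating",
            stacklevel=2,
        )
        top_n = len(candidates)
    scores = decision_scores(m, k, candidates)
    order = sorted(range(len(candidates)), key=lambda i: (-scores[i], candidates[i]))
    top = order[:top_n]
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(top) + 1),
            "drug_id": [candidates[i][0] for i in top],
            "disease_id": [candidates[i][1] for i in top],
            "score": [float(scores[i]) for i in top],
        }
    )
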