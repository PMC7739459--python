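"""Multispecies RSCU matrix and hierarchical (average-linkage) clustering.

Species are described by their 59-codon RSCU vectors (the 61 sense
codons minus the non-degenerate ATG and TGG) and clustered
agglomeratively with Euclidean distance and average linkage (UPGMA).
Rows and columns can be clustered independently for a biclustered
heat-map layout.  Dendrograms serialise to Newick with ultrametric
branch lengths (leaf-to-node path length equals the merge height).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .genetic_code import RSCU_CODON_ORDER
from .metrics import RscuTable, SpeciesSummary


@dataclass
class Dendrogram:
    """An agglomerative merge sequence over labelled leaves.

    ``linkage`` is a scipy-format linkage matrix: row i merges clusters
    ``linkage[i, 0]`` and ``linkage[i, 1]`` (ids < n are leaves) at
    height ``linkage[i, 2]`` into new cluster id ``n + i``.
    """

    linkage: np.ndarray
    labels: list[str]

    def merges(self) -> list[tuple[int, int, float, int]]:
        """(cluster_a, cluster_b, height, new_id) in merge order."""
        n = len(self.labels)
        return [
            (int(row[0]), int(row[1]), float(row[2]), n + i)
            for i, row in enumerate(self.linkage)
        ]

    def to_newick(self) -> str:
        """Newick string; branch length = parent height - child height."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}

        def render(node: int, parent_height: float) -> str:
            if node < n:
                label = self.labels[node].replace(" ", "_")
                return f"{label}:{parent_height:.10g}"
            row = self.linkage[node - n]
            h = float(row[2])
            left = render(int(row[0]), h)
            right = render(int(row[1]), h)
            return f"({left},{right}):{parent_height - h:.10g}"

        root = n + len(self.linkage) - 1
        row = self.linkage[-1]
        h = float(row[2])
        heights[root] = h
        left = render(int(row[0]), h)
        right = render(int(row[1]), h)
        return f"({left},{right}):0;"


def build_rscu_matrix(
    tables: dict[str, RscuTable],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stack per-species RSCU tables into a species x 59-codon matrix.

    Codon columns are in the fixed family order (amino acids
    alphabetical, codons alphabetical within each).  Codons of families
    a species never used are imputed as 0; the returned boolean mask
    marks those imputed cells.
    """
    species = list(tables)
    values = np.zeros((len(species), len(RSCU_CODON_ORDER)))
    imputed = np.zeros_like(values, dtype=bool)
    for i, sp in enumerate(species):
        t = tables[sp]
        for j, codon in enumerate(RSCU_CODON_ORDER):
            if codon in t.rscu:
                values[i, j] = t.rscu[codon]
            else:
                imputed[i, j] = True
    matrix = pd.DataFrame(values, index=species, columns=list(RSCU_CODON_ORDER))
    mask = pd.DataFrame(imputed, index=species, columns=list(RSCU_CODON_ORDER))
    return matrix, mask


def _linkage(matrix: np.ndarray, metric: str, method: str) -> np.ndarray:
    # scipy's agglomeration is deterministic: equal distances resolve to
    # the earliest (smallest-index) pair in condensed order.
    dist = pdist(matrix, metric=metric)
    return hierarchy.linkage(dist, method=method)


def hierarchical_cluster(
    matrix: pd.DataFrame,
    metric: str = "euclidean",
    linkage: str = "average",
    axis: str = "rows",
) -> dict[str, Dendrogram]:
    """Cluster matrix rows, or rows and columns independently.

    ``axis`` is ``"rows"``, ``"columns"`` or ``"both"``.  Each
    clustered axis needs at least 2 entries.
    """
    if axis not in ("rows", "columns", "both"):
        raise ValueError(f"unknown axis {axis!r}")
    out: dict[str, Dendrogram] = {}
    if axis in ("rows", "both"):
        if matrix.shape[0] < 2:
            raise ValueError("row clustering needs at least 2 rows")
        out["rows"] = Dendrogram(
            _linkage(matrix.to_numpy(), metric, linkage),
            [str(i) for i in matrix.index],
        )
    if axis in ("columns", "both"):
        if matrix.shape[1] < 2:
            raise ValueError("column clustering needs at least 2 columns")
        out["columns"] = Dendrogram(
            _linkage(matrix.to_numpy().T, metric, linkage),
            [str(c) for c in matrix.columns],
        )
    return out


def gc_gc3_distribution(summaries: list[SpeciesSummary]) -> pd.DataFrame:
    """Per-species GC and GC3 fractions (heat-map side table).

    Rows follow input order; values are fractions in [0, 1].
    """
    if not summaries:
        raise ValueError("no species summaries")
    return pd.DataFrame(
        [
            {
                "species": s.species,
                "gc": s.gc / 100.0,
                "gc3": s.gc3 / 100.0,
            }
            for s in summaries
        ]
    )
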