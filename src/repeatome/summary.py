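"""Cross-species comparative repeat statistics.

Given per-species repeat abundances (genome proportion %, by cluster,
lineage or superfamily), this module computes the comparative quantities a
multi-species repeatome survey reports: the clustered-read genome
proportion, the Gypsy/Copia abundance ratio per species, the maximum
difference of each repeat category across species (a variability measure),
agglomerative clustering of abundance profiles, and a sharing
classification (shared-by-all / shared-subset / species-specific).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io_core import RepeatomeError


def genome_proportion_table(counts: Mapping[str, tuple[int, int]]) -> pd.DataFrame:
    """Per-species clustered-read summary.

    ``counts`` maps species -> (total_reads, clustered_reads); the genome
    proportion is clustered/total*100 rounded to 2 decimals.
    """
    rows = []
    for species, (total, clustered) in counts.items():
        if total <= 0:
            raise RepeatomeError(f"{species}: total read count must be > 0")
        rows.append({
            "species": species,
            "total_reads": total,
            "clustered_reads": clustered,
            "genome_proportion_pct": round(100.0 * clustered / total, 2),
        })
    return pd.DataFrame(rows).set_index("species")


def gypsy_copia_ratio(matrix: pd.DataFrame,
                      gypsy_row: str = "Gypsy",
                      copia_row: str = "Copia") -> pd.Series:
    """Per-species ratio of Gypsy to Copia genome proportion (2 decimals).

    A zero Copia total makes the ratio undefined; it is reported as NA.
    """
    gypsy = matrix.loc[gypsy_row]
    copia = matrix.loc[copia_row]
    out = {}
    for sp in matrix.columns:
        out[sp] = round(gypsy[sp] / copia[sp], 2) if copia[sp] > 0 else float("nan")
    return pd.Series(out, name="gypsy_copia_ratio")


def max_difference(matrix: pd.DataFrame) -> pd.Series:
    """Per-row max - min across species, rounded to 2 decimals."""
    if matrix.shape[1] < 2:
        raise RepeatomeError("need at least 2 species columns")
    return (matrix.max(axis=1) - matrix.min(axis=1)).round(2) \
        .rename("max_difference")


@dataclass
class Dendrogram:
    linkage_matrix: np.ndarray
    labels: tuple[str, ...]

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def newick(self) -> str:
        root = hierarchy.to_tree(self.linkage_matrix)

        def fmt(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:.6f}"
            inner = ",".join(fmt(c, node.dist) for c in
                             (node.get_left(), node.get_right()))
            return f"({inner}):{length:.6f}"

        left, right = root.get_left(), root.get_right()
        inner = ",".join(fmt(c, root.dist) for c in (left, right))
        return f"({inner});"

    def merge_order(self) -> list[tuple[frozenset, frozenset, float]]:
        """(group A labels, group B labels, height) per merge, in order."""
        n = len(self.labels)
        groups: dict[int, frozenset] = {i: frozenset([self.labels[i]])
                                        for i in range(n)}
        out = []
        for m, (a, b, h, _) in enumerate(self.linkage_matrix):
            ga, gb = groups[int(a)], groups[int(b)]
            out.append((ga, gb, float(h)))
            groups[n + m] = ga | gb
        return out


def hierarchical_cluster(matrix: pd.DataFrame, axis: str = "rows",
                         linkage: str = "average",
                         distance: str = "euclidean") -> Dendrogram:
    """Agglomerative clustering of abundance profiles.

    Default average linkage on Euclidean distance; ``axis`` chooses whether
    rows (repeat categories) or columns (species) are clustered.  Ties are
    broken deterministically by input order (scipy's convention).
    """
    data = matrix.to_numpy(dtype=float) if axis == "rows" \
        else matrix.to_numpy(dtype=float).T
    labels = tuple(matrix.index) if axis == "rows" else tuple(matrix.columns)
    if data.shape[0] < 2:
        raise RepeatomeError("need at least 2 profiles to cluster")
    Z = hierarchy.linkage(pdist(data, metric=distance), method=linkage)
    return Dendrogram(Z, labels)


def sharing_report(matrix: pd.DataFrame,
                   presence_threshold: float = 0.01) -> pd.DataFrame:
    """Classify each repeat category by the species it is present in.

    A category counts as present in a species when its abundance is at least
    ``presence_threshold``; rows are labeled shared-by-all, shared-subset
    (with the species list) or species-specific.  Every row receives exactly
    one label.
    """
    if presence_threshold <= 0:
        raise RepeatomeError("presence threshold must be > 0")
    rows = []
    n_species = matrix.shape[1]
    for name, row in matrix.iterrows():
        present = [sp for sp in matrix.columns if row[sp] >= presence_threshold]
        if len(present) == n_species:
            label = "shared-by-all"
        elif len(present) == 1:
            label = "species-specific"
        elif len(present) == 0:
            label = "absent"
        else:
            label = "shared-subset"
        rows.append({"category": name, "label": label,
                     "n_species": len(present),
                     "species": ",".join(present)})
    return pd.DataFrame(rows).set_index("category")


def lineage_abundance_matrix(tables: Mapping[str, pd.DataFrame],
                             category_col: str = "annotation",
                             value_col: str = "genome_proportion") -> pd.DataFrame:
    """Stack per-species cluster/lineage tables into a category x species
    abundance matrix (absent categories filled with 0)."""
    series = {}
    for species, table in tables.items():
        series[species] = table.groupby(category_col)[value_col].sum()
    out = pd.DataFrame(series).fillna(0.0)
    return out
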