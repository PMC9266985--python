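"""Signed co-mutation scores, gene clustering, and subtype assignment.

For every gene pair the 2x2 cross-table of mutation indicators is tested
with a two-sided Fisher exact test; the score is ``-log10(p)`` signed
positive for co-occurrence (sample odds ratio > 1) and negative for mutual
exclusivity. Genes are then clustered hierarchically (Euclidean distance
between score-matrix rows, Ward minimum-variance agglomeration) and each
patient is flagged for every cluster in which they carry at least one
mutated gene — the cluster-defined subtypes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import fisher_exact

from comutsig.cohort_io import MutationMatrix

logger = logging.getLogger(__name__)

DEFAULT_P_FLOOR = 1e-300


@dataclass(frozen=True)
class PairTest:
    """A Fisher exact test of one gene pair's 2x2 co-occurrence table."""

    gene_a: str
    gene_b: str
    n11: int  # both mutated
    n10: int  # a only
    n01: int  # b only
    n00: int  # neither
    p: float
    odds_ratio: float  # sample OR, may be inf or nan (0/0)
    direction: str  # "co_occurring" / "exclusive" / "neutral"


@dataclass
class CoMutationScoreMatrix:
    """Symmetric gene x gene matrix of signed -log10(p) co-mutation scores."""

    genes: list[str]
    scores: np.ndarray
    diagonal_policy: str = "zero"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.scores, index=self.genes, columns=self.genes)


@dataclass
class GeneClusterSet:
    """A flat cut of the gene dendrogram into ``k`` clusters.

    Labels run 1..k ordered left-to-right by dendrogram leaf position, so
    cluster numbering matches a plotted heatmap. ``linkage`` is the scipy
    merge matrix.
    """

    k: int
    assignment: dict[str, int]
    linkage: np.ndarray

    def genes_in(self, label: int) -> list[str]:
        return sorted(g for g, c in self.assignment.items() if c == label)

    def labels_for(self, genes: list[str]) -> np.ndarray:
        return np.array([self.assignment[g] for g in genes])


def fisher_pair(
    n11: int, n10: int, n01: int, n00: int,
    gene_a: str = "a", gene_b: str = "b",
) -> PairTest:
    """Two-sided Fisher exact test of a 2x2 co-occurrence table.

    Direction is read off the sample odds ratio ``(n11*n00)/(n10*n01)``:
    co-occurring when the cross product ``n11*n00`` exceeds ``n10*n01``,
    exclusive when smaller, neutral on equality (including the degenerate
    0/0 case).
    """
    counts = (n11, n10, n01, n00)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative count in table {counts}")
    if sum(counts) < 1:
        raise ValueError("empty table")
    p = float(fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")[1])
    cross_co, cross_ex = n11 * n00, n10 * n01
    if cross_ex == 0:
        odds_ratio = math.nan if cross_co == 0 else math.inf
    else:
        odds_ratio = cross_co / cross_ex
    if cross_co > cross_ex:
        direction = "co_occurring"
    elif cross_co < cross_ex:
        direction = "exclusive"
    else:
        direction = "neutral"
    return PairTest(gene_a, gene_b, n11, n10, n01, n00, p, odds_ratio, direction)


def comutation_score(test: PairTest, p_floor: float = DEFAULT_P_FLOOR) -> float:
    """Signed -log10(p): positive for co-occurrence, negative for exclusivity.

    ``p`` is floored at ``p_floor`` before the log so scores stay finite.
    """
    if not 0 < test.p <= 1:
        raise ValueError(f"p-value {test.p} outside (0, 1]")
    if test.direction == "neutral":
        return 0.0
    p = test.p
    if p < p_floor:
        logger.info("p floored at %g for pair (%s, %s)", p_floor, test.gene_a,
                    test.gene_b)
        p = p_floor
    magnitude = -math.log10(p)
    return magnitude if test.direction == "co_occurring" else -magnitude


def pair_table(row_a: np.ndarray, row_b: np.ndarray) -> tuple[int, int, int, int]:
    """2x2 cross-table (n11, n10, n01, n00) of two binary indicator rows."""
    a = np.asarray(row_a, dtype=bool)
    b = np.asarray(row_b, dtype=bool)
    n11 = int(np.sum(a & b))
    n10 = int(np.sum(a & ~b))
    n01 = int(np.sum(~a & b))
    n00 = int(np.sum(~a & ~b))
    return n11, n10, n01, n00


def score_matrix(
    m: MutationMatrix,
    p_floor: float = DEFAULT_P_FLOOR,
    diagonal_policy: str = "zero",
) -> CoMutationScoreMatrix:
    """Signed co-mutation score for every gene pair of the mutation matrix.

    Each unordered pair is tested once, so the matrix is symmetric by
    construction. The diagonal is 0 by default (self-pairs are not tests);
    ``diagonal_policy="row_max"`` sets it to the row maximum for heatmap
    display.
    """
    n = len(m.genes)
    if n < 2:
        raise ValueError("need at least 2 genes to score pairs")
    if diagonal_policy not in ("zero", "row_max"):
        raise ValueError(f"unknown diagonal policy {diagonal_policy!r}")
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            t = fisher_pair(*pair_table(m.values[i], m.values[j]),
                            gene_a=m.genes[i], gene_b=m.genes[j])
            s = comutation_score(t, p_floor=p_floor)
            scores[i, j] = scores[j, i] = s
    if diagonal_policy == "row_max":
        np.fill_diagonal(scores, scores.max(axis=1))
    return CoMutationScoreMatrix(list(m.genes), scores, diagonal_policy)


def cluster_genes(s: CoMutationScoreMatrix, k: int) -> GeneClusterSet:
    """Hierarchical gene clustering on score-matrix rows, cut into k clusters.

    Euclidean distances between rows, Ward minimum-variance agglomeration
    (the criterion operating on unsquared Euclidean input distances, i.e.
    the "Ward.D2" convention). Output is deterministic for a fixed matrix:
    rows enter in lexicographic gene order, and labels 1..k follow
    dendrogram leaf order left to right.
    """
    n = len(s.genes)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    order = np.argsort(np.asarray(s.genes, dtype=object))
    genes = [s.genes[i] for i in order]
    rows = s.scores[np.ix_(order, order)]
    Z = hierarchy.linkage(pdist(rows, metric="euclidean"), method="ward")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # relabel 1..k by first appearance along the dendrogram leaf order
    leaf_order = hierarchy.leaves_list(Z)
    relabel: dict[int, int] = {}
    for leaf in leaf_order:
        relabel.setdefault(raw[leaf], len(relabel) + 1)
    assignment = {g: relabel[c] for g, c in zip(genes, raw)}
    return GeneClusterSet(k=k, assignment=assignment, linkage=Z)


def assign_subtypes(m: MutationMatrix, clusters: GeneClusterSet):
    """Flag each sample for each cluster it carries a mutation in.

    Returns a boolean DataFrame (cluster label x sample); a sample is
    positive for a cluster iff any of the cluster's genes is mutated in it.
    Subtypes are not exclusive.
    """
    import pandas as pd

    missing = set(clusters.assignment) - set(m.genes)
    if missing:
        raise ValueError(
            "cluster gene(s) absent from matrix: " + ", ".join(sorted(missing))
        )
    gene_index = {g: i for i, g in enumerate(m.genes)}
    labels = sorted(set(clusters.assignment.values()))
    rows = np.zeros((len(labels), len(m.samples)), dtype=bool)
    for li, label in enumerate(labels):
        idx = [gene_index[g] for g in clusters.genes_in(label)]
        rows[li] = m.values[idx].any(axis=0)
    return pd.DataFrame(rows, index=labels, columns=m.samples)


def silhouette_scan(s: CoMutationScoreMatrix, k_range=range(2, 13)):
    """Mean silhouette width of the Ward cut for each candidate k.

    Guidance for choosing the number of gene clusters, not an automatic
    selection. Returns a DataFrame (k, mean_silhouette).
    """
    import pandas as pd
    from sklearn.metrics import silhouette_score

    out = []
    for k in k_range:
        if not 2 <= k < len(s.genes):
            continue
        cs = cluster_genes(s, k)
        labels = cs.labels_for(s.genes)
        out.append({"k": k, "mean_silhouette": silhouette_score(s.scores, labels)})
    return pd.DataFrame(out)
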