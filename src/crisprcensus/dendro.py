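"""Profile-similarity dendrograms and the iterative profile-merge loop.

Profile-vs-profile scores (HHsearch-style, self-scores included) are turned
into distances by normalizing each cross-score to the smaller self-score and
taking the negative log:

    d(A, B) = -ln( clamp( S_AB / min(S_AA, S_BB), eps, 1 ) )

so identical profiles sit at distance 0 and unrelated ones at -ln(eps).
UPGMA (average linkage) is implemented here with an explicit lexicographic
tie rule so that clustering, depth cutting and the merge loop are all
deterministic; node heights are half the merge distance, making the
dendrogram ultrametric.

The merge loop repeatedly proposes the closest pair of cluster profiles and
asks an external oracle (in production: a fresh profile build + search) how
the merged profile behaves.  A merge is accepted only when the merged
profile retains more than ``retention_min`` (default 0.98) of the original
member sequences and gains at most ``new_fp_max`` (default 10) new false
positives.  Rejected pairs are marked unmergeable and the loop runs to
convergence.  Despite the field name "neighbour-joining" for this procedure,
it is closest-pair agglomeration with profile re-computation, not canonical
NJ tree building.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import dendropy
import numpy as np
import pandas as pd

REL_SCORE_EPS = 1e-9


@dataclass
class SimilarityMatrix:
    labels: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.labels)
        if self.S.shape != (n, n):
            raise ValueError("similarity matrix shape does not match labels")
        if not np.allclose(self.S, self.S.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if np.any(np.diag(self.S) <= 0):
            raise ValueError("self-scores must be positive")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SimilarityMatrix":
        return cls(list(df.index), df.to_numpy(dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.labels, columns=self.labels)


@dataclass
class DistanceMatrix:
    labels: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if np.any(self.D < 0) or np.any(np.abs(np.diag(self.D)) > 1e-12):
            raise ValueError("distances must be non-negative with zero diagonal")
        if not np.allclose(self.D, self.D.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")


@dataclass
class Node:
    """Dendrogram node; leaves carry a label, internal nodes a merge height."""
    height: float = 0.0
    label: str | None = None
    children: tuple["Node", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return [l for c in self.children for l in c.leaves()]

    def to_newick(self) -> str:
        def render(node: Node, parent_height: float) -> str:
            blen = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{blen:.6g}"
            inner = ",".join(render(c, node.height) for c in node.children)
            return f"({inner}):{blen:.6g}"
        if self.is_leaf:
            return f"{self.label};"
        inner = ",".join(render(c, self.height) for c in self.children)
        return f"({inner});"


Dendrogram = Node


# ---------------------------------------------------------------------------

def to_distance(sim: SimilarityMatrix, eps: float = REL_SCORE_EPS) -> DistanceMatrix:
    """Negative-log transform of self-score-normalized similarities."""
    self_scores = np.diag(sim.S)
    denom = np.minimum.outer(self_scores, self_scores)
    rel = np.clip(sim.S / denom, eps, 1.0)
    D = -np.log(rel)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(list(sim.labels), D)


def upgma(dist: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomeration with lexicographic tie-breaking.

    At each step the pair of clusters at minimal distance merges (ties break
    on the lexicographically smallest pair of cluster name-sets); the new
    node's height is half the merge distance and inter-cluster distances
    update by the size-weighted average (Lance-Williams for UPGMA).
    """
    n = len(dist.labels)
    if n < 2:
        raise ValueError("UPGMA needs at least two items")
    clusters: dict[int, Node] = {i: Node(0.0, dist.labels[i]) for i in range(n)}
    names: dict[int, tuple[str, ...]] = {i: (dist.labels[i],) for i in range(n)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    D = {(min(i, j), max(i, j)): dist.D[i, j]
         for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(clusters) > 1:
        best = min(D.items(),
                   key=lambda kv: (kv[1], min(names[kv[0][0]], names[kv[0][1]]),
                                   max(names[kv[0][0]], names[kv[0][1]])))
        (i, j), dij = best
        a, b = ((i, j) if names[i] <= names[j] else (j, i))
        node = Node(dij / 2.0, None, (clusters[a], clusters[b]))
        for k in list(clusters):
            if k in (i, j):
                continue
            dik = D.pop((min(i, k), max(i, k)))
            djk = D.pop((min(j, k), max(j, k)))
            dnew = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            D[(min(next_id, k), max(next_id, k))] = dnew
        del D[(i, j)]
        clusters[next_id] = node
        names[next_id] = tuple(sorted(names[i] + names[j]))
        sizes[next_id] = sizes[i] + sizes[j]
        for k in (i, j):
            del clusters[k], names[k], sizes[k]
        next_id += 1
    return next(iter(clusters.values()))


def cut_at_depth(dendro: Dendrogram, depth: float = 0.8) -> list[list[str]]:
    """Partition leaves into maximal subtrees whose root height <= depth."""
    if depth < 0:
        raise ValueError("depth must be non-negative")
    clusters: list[list[str]] = []

    def walk(node: Node) -> None:
        if node.height <= depth:
            clusters.append(sorted(node.leaves()))
        else:
            for c in node.children:
                walk(c)

    walk(dendro)
    return sorted(clusters)


# ---------------------------------------------------------------------------
# hybrid trees

def graft(backbone: dendropy.Tree,
          tip_subtrees: dict[str, dendropy.Tree]) -> dendropy.Tree:
    """Replace backbone tips by per-cluster subtrees (hybrid dendrogram).

    Every key of *tip_subtrees* must name a backbone tip; after grafting all
    leaf labels must be globally unique.  Unmapped tips are left unchanged.
    """
    tree = backbone.clone(depth=1)
    tips = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    for label in tip_subtrees:
        if label not in tips:
            raise KeyError(f"unknown backbone tip {label!r}")
    for label, subtree in tip_subtrees.items():
        sub = subtree.clone(depth=1)
        tip = tips[label]
        sub_root = sub.seed_node
        # carry the tip's pendant edge length over to the grafted subtree root
        sub_root.edge.length = tip.edge.length
        parent = tip.parent_node
        if parent is None:  # single-tip backbone
            tree.seed_node = sub_root
        else:
            parent.remove_child(tip)
            parent.add_child(sub_root)
    tree.migrate_taxon_namespace(dendropy.TaxonNamespace())
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dup = {l for l in labels if labels.count(l) > 1}
    if dup:
        raise ValueError(f"duplicate leaf labels after grafting: {sorted(dup)}")
    return tree


def dendrogram_to_dendropy(dendro: Dendrogram) -> dendropy.Tree:
    return dendropy.Tree.get(data=dendro.to_newick(), schema="newick")


# ---------------------------------------------------------------------------
# profile-merge loop

MergeOracle = Callable[[tuple[str, ...]], tuple[float, int]]
# candidate merged cluster (tuple of member cluster labels) ->
#   (retained fraction of original sequences, count of new false positives)


@dataclass
class MergeDecision:
    pair: tuple[str, str]
    distance: float
    retention: float
    new_fp: int
    accepted: bool


@dataclass
class MergeResult:
    clusters: dict[str, tuple[str, ...]]  # cluster label -> original member labels
    similarity: SimilarityMatrix
    log: list[MergeDecision] = field(default_factory=list)


def nj_merge(sim: SimilarityMatrix, oracle: MergeOracle,
             retention_min: float = 0.98, new_fp_max: int = 10,
             cluster_sizes: dict[str, int] | None = None) -> MergeResult:
    """Closest-pair profile merging under the retention / false-positive rule.

    Each iteration proposes the pair of current clusters at minimal
    transformed distance among pairs not yet marked unmergeable, queries the
    oracle for the merged profile's behaviour, and accepts the merge only if
    retention > *retention_min* (strict) and new false positives <=
    *new_fp_max* (inclusive).  On acceptance the merged cluster replaces the
    pair; its similarity row is the size-weighted average of the pair's rows
    (standing in for a profile re-computation, which the oracle abstracts).
    Terminates when every remaining pair is marked.
    """
    labels = list(sim.labels)
    S = sim.S.copy()
    members: dict[str, tuple[str, ...]] = {l: (l,) for l in labels}
    sizes = {l: (cluster_sizes or {}).get(l, 1) for l in labels}
    blocked: set[frozenset[str]] = set()
    log: list[MergeDecision] = []

    while len(labels) > 1:
        dist = to_distance(SimilarityMatrix(labels, S))
        candidates = [
            (dist.D[i, j], tuple(sorted((labels[i], labels[j]))), i, j)
            for i in range(len(labels)) for j in range(i + 1, len(labels))
            if frozenset((labels[i], labels[j])) not in blocked
        ]
        if not candidates:
            break
        d, (la, lb), i, j = min(candidates, key=lambda c: (c[0], c[1]))
        i, j = labels.index(la), labels.index(lb)
        candidate = tuple(sorted(members[la] + members[lb]))
        retention, new_fp = oracle(candidate)
        accept = retention > retention_min and new_fp <= new_fp_max
        log.append(MergeDecision((la, lb), float(d), float(retention),
                                 int(new_fp), accept))
        if not accept:
            blocked.add(frozenset((la, lb)))
            continue
        merged_label = f"({la}+{lb})"
        wa, wb = sizes[la], sizes[lb]
        row = (wa * S[i, :] + wb * S[j, :]) / (wa + wb)
        self_score = (wa * S[i, i] + wb * S[j, j]) / (wa + wb)
        keep = [k for k in range(len(labels)) if k not in (i, j)]
        S = S[np.ix_(keep, keep)]
        row = row[keep]
        S = np.block([[S, row[:, None]], [row[None, :], np.array([[self_score]])]])
        blocked = {b for b in blocked if not b & {la, lb}}
        new_labels = [labels[k] for k in keep] + [merged_label]
        members[merged_label] = candidate
        sizes[merged_label] = wa + wb
        for l in (la, lb):
            del members[l], sizes[l]
        labels = new_labels

    return MergeResult({l: members[l] for l in labels},
                       SimilarityMatrix(labels, S), log)
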