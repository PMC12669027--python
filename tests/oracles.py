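"""Independent reference implementations used to check the package.

Everything here is deliberately naive (quadratic scans, recomputation from
the original matrix, exhaustive enumeration) and shares no code with the
implementations under test.
"""

from __future__ import annotations

import itertools


# -- greedy non-overlapping hit selection -------------------------------------

def greedy_selection_oracle(hits, tolerance=0):
    """hits: list of dicts with score, evalue, p_from, p_to, profile_id."""
    order = sorted(hits, key=lambda h: (-h["score"], h["evalue"],
                                        -(h["p_to"] - h["p_from"] + 1),
                                        h["profile_id"]))
    kept = []
    for h in order:
        ok = True
        for k in kept:
            ov = min(h["p_to"], k["p_to"]) - max(h["p_from"], k["p_from"]) + 1
            if ov > tolerance:
                ok = False
                break
        if ok:
            kept.append(h)
    return sorted((k["p_from"], k["p_to"], k["profile_id"]) for k in kept)


# -- UPGMA ---------------------------------------------------------------------

def upgma_heights_oracle(labels, D):
    """Reference agglomeration recomputing every cluster-pair distance as the
    plain mean over the *original* matrix (no Lance-Williams update); returns
    cophenetic merge heights for all leaf pairs."""
    idx = {l: i for i, l in enumerate(labels)}
    clusters = [frozenset([l]) for l in labels]
    heights = {}
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = sum(D[idx[x]][idx[y]] for x in a for y in b) / (len(a) * len(b))
            key = (d, tuple(sorted(min(sorted(a), sorted(b)))),
                   tuple(sorted(max(sorted(a), sorted(b)))))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _, _), a, b = best
        for x in a:
            for y in b:
                heights[frozenset((x, y))] = d / 2.0
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return heights


def cophenetic_heights(node, out=None):
    """Leaf-pair merge heights from a dendrogram Node."""
    if out is None:
        out = {}
    if node.is_leaf:
        return out
    child_leaf_sets = [c.leaves() for c in node.children]
    for i in range(len(child_leaf_sets)):
        for j in range(i + 1, len(child_leaf_sets)):
            for x in child_leaf_sets[i]:
                for y in child_leaf_sets[j]:
                    out[frozenset((x, y))] = node.height
    for c in node.children:
        cophenetic_heights(c, out)
    return out


# -- module-swap counting --------------------------------------------------------

def swaps_oracle(pairs):
    """pairs: iterable of (cas1_cluster, effector_cluster) tuples.

    Count distinct co-occurrence edges minus the number of cas1 clusters with
    at least one edge (an independent formulation of the
    distinct-effector-clusters-minus-one tally)."""
    edges = {(c1, e) for c1, e in pairs}
    cas1 = {c1 for c1, _ in edges}
    return len(edges) - len(cas1)
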