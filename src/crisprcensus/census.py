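"""Phylogenetically weighted census statistics.

Complete-genome collections oversample a few clades (thousands of near-
identical isolates of model species), so raw fractions of genomes carrying a
CRISPR-Cas system are dominated by sampling depth.  The census therefore
weights genomes by a tree-based scheme before computing prevalence: each
branch of the genome phylogeny is apportioned among its descendant leaves
and a leaf's weight is the total length apportioned to it, normalized to sum
to 1.  The default scheme is Gerstein-Sonnhammer-Chothia (GSC) apportionment
— edge length divided among descendant leaves in proportion to their
weights accumulated so far (equally at zero) — which halves the weight of a
genome duplicated at the tips and leaves everything else untouched.  An
"equal" scheme (every edge split equally among its descendant leaves) is
available for comparison.

On these weights the module computes the prevalence of systems per taxon or
per growth-temperature class (fraction of genome weight carried by genomes
with a qualifying locus) and the taxon x subtype fraction matrix, where each
complete locus contributes its genome's weight and rows normalize to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: growth-temperature classes by optimal growth temperature (degrees C).
DEFAULT_TEMPERATURE_CLASSES = (
    ("psychrophile", -float("inf"), 20.0),
    ("mesophile", 20.0, 45.0),
    ("thermophile", 45.0, 80.0),
    ("hyperthermophile", 80.0, float("inf")),
)


def temperature_class(ogt: float,
                      classes=DEFAULT_TEMPERATURE_CLASSES) -> str:
    for name, lo, hi in classes:
        if lo <= ogt < hi:
            return name
    raise ValueError(f"OGT {ogt} outside all classes")


# ---------------------------------------------------------------------------
# genome weights

def compute_weights(tree: dendropy.Tree, scheme: str = "gsc") -> dict[str, float]:
    """Per-leaf genome weights from a rooted phylogeny, summing to 1.

    ``scheme="gsc"``: branch lengths are apportioned bottom-up to descendant
    leaves proportionally to the weights the leaves have accumulated from
    their own subtrees (equal split where all are zero).  ``scheme="equal"``:
    each edge splits equally among its descendant leaves.
    """
    leaves = [lf for lf in tree.leaf_node_iter()]
    if not leaves:
        raise ValueError("tree has no leaves")
    labels = [lf.taxon.label for lf in leaves]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels")
    if len(leaves) == 1:
        return {labels[0]: 1.0}
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length")

    acc: dict[int, dict[str, float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            w = {node.taxon.label: 0.0}
        else:
            w = {}
            for c in node.child_nodes():
                w.update(acc.pop(id(c)))
        length = node.edge.length or 0.0
        if node.parent_node is not None and length > 0:
            if scheme == "equal":
                share = length / len(w)
                for k in w:
                    w[k] += share
            elif scheme == "gsc":
                total = sum(w.values())
                if total == 0:
                    share = length / len(w)
                    for k in w:
                        w[k] += share
                else:
                    for k in w:
                        w[k] += length * w[k] / total
            else:
                raise ValueError(f"unknown weighting scheme {scheme!r}")
        acc[id(node)] = w
    weights = acc[id(tree.seed_node)]
    total = sum(weights.values())
    if total == 0:  # star of zero branch lengths: fall back to uniform
        return {k: 1.0 / len(weights) for k in weights}
    return {k: v / total for k, v in weights.items()}


# ---------------------------------------------------------------------------
# census table

@dataclass
class CensusRow:
    genome_id: str
    taxon: str
    metadata: dict
    loci: list  # classified loci: anything with .subtype/.cas_type/.complete


def build_census(loci_df: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Join a locus report with genome metadata into one census table.

    Genomes present in the metadata but without loci appear with empty locus
    fields (they count in denominators).
    """
    df = metadata.merge(loci_df, on="genome_id", how="left")
    return df


# ---------------------------------------------------------------------------
# weighted statistics

def weighted_prevalence(census: pd.DataFrame, weights: Mapping[str, float],
                        group_by: str,
                        predicate: Callable[[pd.DataFrame], bool]
                        ) -> dict[str, float]:
    """Per group: weight of genomes whose loci satisfy *predicate* over the
    group's total weight.

    *census* holds one row per locus (or a lone row with NaN locus fields for
    a locus-less genome); *predicate* receives a genome's locus rows.
    """
    missing = set(census["genome_id"]) - set(weights)
    if missing:
        raise KeyError(f"genomes missing from weights: {sorted(missing)[:5]}")
    out: dict[str, float] = {}
    for group, gdf in census.groupby(group_by, sort=True):
        genome_groups = gdf.groupby("genome_id", sort=True)
        total = sum(weights[g] for g in genome_groups.groups)
        if total == 0:
            logger.info("group %r has zero total weight; omitted", group)
            continue
        carrier = sum(weights[g] for g, rows in genome_groups
                      if predicate(rows))
        out[group] = carrier / total
    return out


def has_complete_system(rows: pd.DataFrame) -> bool:
    """Default carrier predicate: any complete classified locus."""
    if "complete" not in rows:
        return False
    comp = rows["complete"].eq(True)
    sub = rows.get("subtype")
    ok = sub.notna() & (sub != "unclassified") if sub is not None else True
    return bool((comp & ok).any())


def subtype_fraction_matrix(census: pd.DataFrame,
                            weights: Mapping[str, float]) -> pd.DataFrame:
    """Taxon x subtype matrix of weighted complete-locus fractions.

    Every complete locus contributes the weight of its genome (a genome with
    two I-B loci contributes twice); rows normalize to the taxon's total
    complete-locus weight, so each row with any complete locus sums to 1.
    """
    rows = census[census.get("complete").eq(True)
                  & census.get("subtype").notna()
                  & (census.get("subtype") != "unclassified")]
    cells: dict[tuple[str, str], float] = {}
    for r in rows.itertuples():
        cells[(r.taxon, r.subtype)] = cells.get((r.taxon, r.subtype), 0.0) \
            + weights[r.genome_id]
    taxa = sorted({t for t, _ in cells})
    subtypes = sorted({s for _, s in cells})
    mat = pd.DataFrame(0.0, index=taxa, columns=subtypes)
    for (t, s), w in cells.items():
        mat.loc[t, s] = w
    row_sums = mat.sum(axis=1)
    return mat.div(row_sums.replace(0.0, np.nan), axis=0).fillna(0.0)


def prevalence_by_temperature(census: pd.DataFrame,
                              weights: Mapping[str, float],
                              ogt_column: str = "ogt",
                              classes=DEFAULT_TEMPERATURE_CLASSES,
                              predicate=has_complete_system
                              ) -> dict[str, float]:
    """Weighted prevalence grouped by growth-temperature class.

    Genomes without an OGT are excluded (and counted in the log); weights
    should be recomputed on the analysed subset's subtree by the caller.
    """
    known = census[census[ogt_column].notna()].copy()
    n_dropped = census["genome_id"].nunique() - known["genome_id"].nunique()
    if n_dropped:
        logger.info("%d genomes without OGT excluded", n_dropped)
    known["temp_class"] = known[ogt_column].map(
        lambda t: temperature_class(float(t), classes))
    return weighted_prevalence(known, weights, "temp_class", predicate)
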