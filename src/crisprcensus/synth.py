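"""Synthetic genomes, hit tables, arrays, trees and similarity matrices.

The generator emulates the inputs the toolkit consumes — per-genome gene
tables, profile-hit tables, CRISPR-array calls, genome phylogenies and
profile-similarity matrices — with planted ground truth, so the whole
pipeline is testable without any external data.

Each planted locus emits the gene inventory its registry subtype prescribes
(required families, one member of each alternative group, the adaptation
module and a CRISPR array where the subtype requires them), laid out on one
directon and flanked by decoy genes on both sides.  Loci flagged incomplete
drop one required element (a non-signature required family where one exists,
otherwise the adaptation module or the array).  True hits draw e-values
log-uniformly from [1e-30, 1e-5] and profile coverage from Beta(8, 2), so
they always pass the 1e-4 filter; decoy hits draw from [1e-3, 1] and are
removed by it.  Under the default noise model cas genes also receive a
weaker overlapping hit from a random wrong family, exercising the
best-scoring culling step.  Coordinates use fixed 300-bp genes with 50-bp
gaps — assembly is rank-driven, so this is purely cosmetic.

Everything is a pure function of (spec, seed): the same spec yields
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .locus import CrisprArray
from .registry import Registry

GENE_LEN = 300
GENE_GAP = 50
STEP = GENE_LEN + GENE_GAP

#: a varied default: ten subtypes spanning both classes and all seven types,
#: including the adaptation-less type VII, the cas10-less III-E and the
#:  array-less III-G.
DEFAULT_SUBTYPE_POOL = ("I-E", "I-B", "II-A", "III-A", "III-E", "III-G",
                        "IV-A", "V-A", "VI-B", "VII")


@dataclass(frozen=True)
class SimSpec:
    seed: int = 0
    n_genomes: int = 50
    taxa: tuple[str, ...] = ("Taxon_A", "Taxon_B")
    subtype_pool: tuple[str, ...] = DEFAULT_SUBTYPE_POOL
    carrier_fraction: float = 1.0
    loci_per_carrier: int = 1
    incomplete_fraction: float = 0.0
    noise: bool = True
    decoy_genes_per_side: int = 12
    decoy_hit_rate: float = 0.5
    wrong_family_hit_rate: float = 0.3
    tree_shape: str = "coalescent"  # star | caterpillar | coalescent
    ogt_range: tuple[float, float] = (5.0, 95.0)


@dataclass
class SimResult:
    genes: pd.DataFrame
    hits: pd.DataFrame
    arrays: list[CrisprArray]
    truth: pd.DataFrame
    metadata: pd.DataFrame

    def arrays_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"genome_id": a.genome_id, "contig": a.contig, "start": a.start,
              "end": a.end, "repeat_len": a.repeat_len,
              "n_spacers": a.n_spacers} for a in self.arrays],
            columns=["genome_id", "contig", "start", "end", "repeat_len",
                     "n_spacers"])


# ---------------------------------------------------------------------------

def _locus_genes(subtype_id: str, registry: Registry, complete: bool,
                 rng: np.random.Generator) -> tuple[list[str], bool]:
    """Gene family list and has-array flag for one planted locus."""
    s = registry.subtype(subtype_id)
    sig = s.signature_families(registry)
    families = sorted(s.required_all)
    for alt in s.required_any:
        families.append(sorted(alt)[0])
    if not s.adaptation_optional:
        families += ["cas1", "cas2"]
    if subtype_id == "VII":
        families.append("cas6")  # frequently present, never required
    has_array = not s.array_optional
    if not complete:
        # drop an element whose absence cannot flip the winning subtype:
        # prefer the adaptation module, then a non-signature required family,
        # then the array
        droppable = [f for f in sorted(s.required_all) if f not in sig]
        if not s.adaptation_optional:
            families.remove("cas2")
        elif droppable:
            families.remove(droppable[int(rng.integers(len(droppable)))])
        elif has_array:
            has_array = False
        else:  # nothing removable without losing the signature: drop an alt
            for alt in s.required_any:
                families.remove(sorted(alt)[0])
                break
    # fixed gene order for determinism; biology does not order genes for us
    return families, has_array


def _true_hit(rng: np.random.Generator, noise: bool) -> tuple[float, float, float]:
    """(evalue, score, qcov) for a genuine profile hit."""
    if noise:
        evalue = 10 ** rng.uniform(-30, -5)
        score = float(rng.uniform(100, 400))
        qcov = float(rng.beta(8, 2))
    else:
        evalue, score, qcov = 1e-10, 200.0, 0.95
    return evalue, score, qcov


def simulate_genomes(spec: SimSpec, registry: Registry) -> SimResult:
    """Generate gene/hit/array tables with planted, fully known loci."""
    for sid in spec.subtype_pool:
        if sid not in registry.subtypes:
            raise KeyError(f"subtype {sid!r} unknown to the registry")
    rng = np.random.default_rng(spec.seed)
    all_families = sorted(registry.families)
    gene_rows, hit_rows, arrays, truth_rows, meta_rows = [], [], [], [], []
    subtype_cycle = 0
    for g in range(spec.n_genomes):
        genome_id = f"G{g:04d}"
        taxon = spec.taxa[g % len(spec.taxa)]
        ogt = float(rng.uniform(*spec.ogt_range))
        meta_rows.append({"genome_id": genome_id, "taxon": taxon,
                          "ogt": round(ogt, 1)})
        contig = "ctg1"
        is_carrier = rng.random() < spec.carrier_fraction
        idx = 0  # gene index on the contig

        def add_gene(strand: str) -> tuple[str, int, int, int]:
            nonlocal idx
            idx += 1
            start = 1 + (idx - 1) * STEP
            end = start + GENE_LEN - 1
            pid = f"{genome_id}_p{idx:03d}"
            gene_rows.append({"protein_id": pid, "genome_id": genome_id,
                              "contig": contig, "start": start, "end": end,
                              "strand": strand, "rank": idx})
            return pid, start, end, idx

        def add_decoys(n: int) -> None:
            for _ in range(n):
                pid, *_ = add_gene("+" if rng.random() < 0.5 else "-")
                if spec.noise and rng.random() < spec.decoy_hit_rate:
                    hit_rows.append({
                        "protein_id": pid, "profile_id": "decoy_profile",
                        "evalue": 10 ** rng.uniform(-3, 0),
                        "bitscore": float(rng.uniform(20, 40)),
                        "qcov": float(rng.uniform(0.1, 0.9)),
                        "pstart": 1, "pend": 80})

        add_decoys(spec.decoy_genes_per_side)
        n_loci = spec.loci_per_carrier if is_carrier else 0
        for li in range(n_loci):
            subtype = spec.subtype_pool[subtype_cycle % len(spec.subtype_pool)]
            subtype_cycle += 1
            complete = rng.random() >= spec.incomplete_fraction
            families, has_array = _locus_genes(subtype, registry, complete, rng)
            span_lo = None
            for fam in families:
                pid, start, end, _ = add_gene("+")
                span_lo = span_lo if span_lo is not None else start
                evalue, score, qcov = _true_hit(rng, spec.noise)
                hit_rows.append({"protein_id": pid, "profile_id": fam,
                                 "evalue": evalue, "bitscore": score,
                                 "qcov": qcov, "pstart": 1, "pend": 90})
                if spec.noise and rng.random() < spec.wrong_family_hit_rate:
                    wrong = all_families[int(rng.integers(len(all_families)))]
                    if wrong != fam:  # weaker, fully overlapping: culled
                        hit_rows.append({
                            "protein_id": pid, "profile_id": wrong,
                            "evalue": evalue * 10, "bitscore": score - 50,
                            "qcov": qcov, "pstart": 1, "pend": 90})
                span_hi = end
            if has_array:
                a_start = span_hi + 10
                arrays.append(CrisprArray(contig, a_start, a_start + 200,
                                          repeat_len=30, n_spacers=5,
                                          genome_id=genome_id))
                span_hi = a_start + 200
            truth_rows.append({"genome_id": genome_id, "contig": contig,
                               "subtype": subtype,
                               "cas_type": registry.subtype(subtype).cas_type,
                               "complete": complete,
                               "span_start": span_lo, "span_end": span_hi})
            # wide decoy separator keeps planted loci from merging
            add_decoys(2 * 10 + 5 if li < n_loci - 1 else 0)
        add_decoys(spec.decoy_genes_per_side)

    genes = pd.DataFrame(gene_rows)
    hits = pd.DataFrame(hit_rows, columns=["protein_id", "profile_id", "evalue",
                                           "bitscore", "qcov", "pstart", "pend"])
    truth = pd.DataFrame(truth_rows, columns=["genome_id", "contig", "subtype",
                                              "cas_type", "complete",
                                              "span_start", "span_end"])
    metadata = pd.DataFrame(meta_rows)
    return SimResult(genes, hits, arrays, truth, metadata)


# ---------------------------------------------------------------------------

def simulate_tree(spec: SimSpec, genome_ids: list[str] | None = None
                  ) -> dendropy.Tree:
    """Deterministic genome phylogeny with positive branch lengths."""
    if genome_ids is None:
        genome_ids = [f"G{g:04d}" for g in range(spec.n_genomes)]
    n = len(genome_ids)
    if n < 1:
        raise ValueError("need at least one genome")
    rng = np.random.default_rng(spec.seed + 1)
    if spec.tree_shape == "star":
        newick = "(" + ",".join(f"{g}:1.0" for g in genome_ids) + ");"
    elif spec.tree_shape == "caterpillar":
        if n == 1:
            newick = f"({genome_ids[0]}:1.0);"
        else:
            tree_str = f"({genome_ids[0]}:1,{genome_ids[1]}:1)"
            height = 1
            for g in genome_ids[2:]:
                height += 1
                tree_str = f"({tree_str}:1,{g}:{height})"
            newick = tree_str + ";"
    elif spec.tree_shape == "coalescent":
        if n == 1:
            newick = f"({genome_ids[0]}:1.0);"
        else:
            nodes = [(g, 0.0, f"{g}") for g in genome_ids]
            height = 0.0
            while len(nodes) > 1:
                k = len(nodes)
                height += float(rng.exponential(2.0 / (k * (k - 1))))
                i, j = sorted(rng.choice(k, size=2, replace=False))
                (la, ha, sa), (lb, hb, sb) = nodes[i], nodes[j]
                s = f"({sa}:{height - ha:.6f},{sb}:{height - hb:.6f})"
                nodes = [nodes[m] for m in range(k) if m not in (i, j)]
                nodes.append((la, height, s))
            newick = nodes[0][2] + ";"
    else:
        raise ValueError(f"unknown tree shape {spec.tree_shape!r}")
    return dendropy.Tree.get(data=newick, schema="newick")


def simulate_similarity(n_clusters: int, cluster_size: int = 3,
                        seed: int = 0,
                        within: tuple[float, float] = (60.0, 80.0),
                        between: tuple[float, float] = (5.0, 15.0),
                        self_scores: tuple[float, float] = (90.0, 110.0)):
    """Similarity matrix with planted block structure.

    Within-block cross-scores stochastically exceed between-block scores and
    every self-score is the row maximum, so the negative-log transform and a
    UPGMA depth cut recover the planted blocks.  Returns (SimilarityMatrix,
    list of planted blocks as label lists).
    """
    from .dendro import SimilarityMatrix
    rng = np.random.default_rng(seed)
    labels, blocks = [], []
    for b in range(n_clusters):
        block = [f"p{b}_{i}" for i in range(cluster_size)]
        blocks.append(block)
        labels.extend(block)
    n = len(labels)
    block_of = {lab: b for b, blk in enumerate(blocks) for lab in blk}
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            lo, hi = within if block_of[labels[i]] == block_of[labels[j]] else between
            S[i, j] = S[j, i] = rng.uniform(lo, hi)
    for i in range(n):
        S[i, i] = rng.uniform(*self_scores)
    return SimilarityMatrix(labels, S), blocks
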