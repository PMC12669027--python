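"""Assembly and classification of CRISPR-cas genomic loci.

Loci are built outward from seed genes — genes annotated with a core cas
family (the cas1-cas14 superfamilies and their lettered descendants) — by
taking up to ``flank`` genes on each side, merging neighbourhoods that touch
on a contig, and attaching CRISPR arrays lying within the same gene
distance.  Margins are then adjusted to directon boundaries: the maximal run
of co-oriented genes containing the outermost cas element on each side, a
standard operon proxy.

Classification scores every subtype of the registry against the gene
families present in the locus: a matched signature family counts 2, any
other matched required family counts 1, a forbidden family disqualifies, and
at least one signature match is demanded.  Ties break on the fraction of
required families matched, then on the number matched; residual ties are
reported as conflicts (never silently resolved) with a lexicographic winner.

A classified locus is *complete* when every required effector-module family
is present, plus the adaptation module (cas1 and cas2) and a CRISPR array
where the subtype does not mark them optional.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .annotation import AnnotatedProtein, ProfileMap, ProteinRecord
from .registry import Registry, SubtypeDef


@dataclass(frozen=True)
class CrisprArray:
    contig: str
    start: int
    end: int
    repeat_len: int
    n_spacers: int
    genome_id: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("array start > end")
        if self.n_spacers < 1:
            raise ValueError("array must have at least one spacer")


@dataclass
class Locus:
    genome_id: str
    contig: str
    span: tuple[int, int]
    members: list[AnnotatedProtein]
    arrays: list[CrisprArray] = field(default_factory=list)
    seeds: list[str] = field(default_factory=list)

    @property
    def rank_range(self) -> tuple[int, int]:
        ranks = [m.protein.rank for m in self.members]
        return min(ranks), max(ranks)

    def families(self, profile_map: ProfileMap) -> dict[str, list]:
        """Evidence map: gene family -> supporting assigned hits."""
        ev: dict[str, list] = {}
        for m in self.members:
            for h in m.assigned_hits:
                fam = profile_map.family(h.profile_id)
                if fam is not None:
                    ev.setdefault(fam, []).append(h)
        return ev


@dataclass
class LocusClassification:
    cas_type: str = "unclassified"
    subtype: str = "unclassified"
    variant: str | None = None
    complete: bool = False
    evidence: dict[str, list] = field(default_factory=dict)
    conflicts: list[tuple[str, float]] = field(default_factory=list)
    reason: str = ""


# ---------------------------------------------------------------------------
# assembly

def assemble_neighborhoods(genes: pd.DataFrame,
                           annotations: dict[str, AnnotatedProtein],
                           arrays: list[CrisprArray],
                           registry: Registry,
                           profile_map: ProfileMap,
                           flank: int = 10) -> list[Locus]:
    """One merged locus per run of overlapping seed neighbourhoods.

    *genes* must carry the standard columns (protein_id, genome_id, contig,
    start, end, strand, rank); *annotations* maps protein_id to its assigned
    hits.  Seeds are annotated proteins carrying a core cas family.
    """
    core = registry.core_families()
    gene_index = {r.protein_id for r in genes.itertuples()}
    seeds_by_contig: dict[tuple[str, str], list[int]] = {}
    seed_ids_by_contig: dict[tuple[str, str], set[str]] = {}
    for pid, ann in annotations.items():
        fams = {profile_map.family(h.profile_id) for h in ann.assigned_hits}
        if not (fams & core):
            continue
        if pid not in gene_index:
            raise KeyError(f"seed protein {pid!r} absent from the gene table")
        p = ann.protein
        key = (p.genome_id, p.contig)
        seeds_by_contig.setdefault(key, []).append(p.rank)
        seed_ids_by_contig.setdefault(key, set()).add(pid)

    loci: list[Locus] = []
    for (genome_id, contig), seed_ranks in sorted(seeds_by_contig.items()):
        sub = genes[(genes["genome_id"] == genome_id)
                    & (genes["contig"] == contig)].sort_values("rank")
        lo_rank, hi_rank = int(sub["rank"].min()), int(sub["rank"].max())
        # flank windows around each seed, clipped at contig ends
        windows = sorted((max(lo_rank, r - flank), min(hi_rank, r + flank))
                         for r in seed_ranks)
        merged: list[list[int]] = []
        for a, b in windows:
            if merged and a <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        contig_arrays = [ar for ar in arrays
                         if ar.contig == contig
                         and (not ar.genome_id or ar.genome_id == genome_id)]
        for a, b in merged:
            members_df = sub[(sub["rank"] >= a) & (sub["rank"] <= b)]
            members = [
                annotations.get(r.protein_id) or AnnotatedProtein(
                    ProteinRecord(r.protein_id, genome_id, contig, int(r.start),
                                  int(r.end), r.strand, int(r.rank)))
                for r in members_df.itertuples()
            ]
            members.sort(key=lambda m: m.protein.rank)
            locus_arrays = [ar for ar in contig_arrays
                            if _array_gene_distance(ar, sub, a, b) <= flank]
            span_lo = min([int(members_df["start"].min())]
                          + [ar.start for ar in locus_arrays])
            span_hi = max([int(members_df["end"].max())]
                          + [ar.end for ar in locus_arrays])
            seed_ids = sorted(pid for pid in seed_ids_by_contig[(genome_id, contig)]
                              if any(m.protein.protein_id == pid for m in members))
            loci.append(Locus(genome_id, contig, (span_lo, span_hi), members,
                              locus_arrays, seed_ids))
    return loci


def _array_gene_distance(array: CrisprArray, contig_genes: pd.DataFrame,
                         lo_rank: int, hi_rank: int) -> int:
    """Number of genes strictly between the array and the locus rank window."""
    left = contig_genes[contig_genes["end"] < array.start]["rank"]
    right = contig_genes[contig_genes["start"] > array.end]["rank"]
    # ranks flanking the array's intergenic position
    left_rank = int(left.max()) if len(left) else lo_rank - 10**9
    right_rank = int(right.min()) if len(right) else hi_rank + 10**9
    if right_rank >= lo_rank and left_rank <= hi_rank:
        return 0  # inside or immediately adjacent to the window
    if left_rank > hi_rank:  # array lies right of the window
        return left_rank - hi_rank
    return lo_rank - right_rank  # array lies left of the window


# ---------------------------------------------------------------------------
# directon trimming

def trim_boundaries(locus: Locus, genes: pd.DataFrame,
                    profile_map: ProfileMap) -> Locus:
    """Extend/trim locus margins to the directon of the outermost cas element.

    A directon is a maximal run of consecutive co-oriented genes on the
    contig.  Interior unannotated genes are retained; flanking genes beyond
    the strand switch that bounds the outermost annotated gene are dropped,
    and the margin is extended when that directon continues past the current
    locus edge.  Attached arrays always stay within the span.
    """
    annotated_ranks = [m.protein.rank for m in locus.members
                       if any(profile_map.family(h.profile_id) is not None
                              for h in m.assigned_hits)]
    if not annotated_ranks:
        return locus
    sub = genes[(genes["genome_id"] == locus.genome_id)
                & (genes["contig"] == locus.contig)].sort_values("rank")
    strand_of = dict(zip(sub["rank"].astype(int), sub["strand"]))
    ranks_sorted = sorted(strand_of)

    def directon_bounds(rank: int) -> tuple[int, int]:
        s = strand_of[rank]
        i = ranks_sorted.index(rank)
        lo = i
        while lo > 0 and ranks_sorted[lo - 1] == ranks_sorted[lo] - 1 \
                and strand_of[ranks_sorted[lo - 1]] == s:
            lo -= 1
        hi = i
        while hi + 1 < len(ranks_sorted) and ranks_sorted[hi + 1] == ranks_sorted[hi] + 1 \
                and strand_of[ranks_sorted[hi + 1]] == s:
            hi += 1
        return ranks_sorted[lo], ranks_sorted[hi]

    new_lo = directon_bounds(min(annotated_ranks))[0]
    new_hi = directon_bounds(max(annotated_ranks))[1]
    ann_by_pid = {m.protein.protein_id: m for m in locus.members}
    members = []
    for r in sub[(sub["rank"] >= new_lo) & (sub["rank"] <= new_hi)].itertuples():
        members.append(ann_by_pid.get(r.protein_id) or AnnotatedProtein(
            ProteinRecord(r.protein_id, locus.genome_id, locus.contig,
                          int(r.start), int(r.end), r.strand, int(r.rank))))
    members.sort(key=lambda m: m.protein.rank)
    span_lo = min([m.protein.start for m in members]
                  + [a.start for a in locus.arrays])
    span_hi = max([m.protein.end for m in members]
                  + [a.end for a in locus.arrays])
    seeds = [s for s in locus.seeds
             if any(m.protein.protein_id == s for m in members)]
    return replace(locus, span=(span_lo, span_hi), members=members, seeds=seeds)


# ---------------------------------------------------------------------------
# classification

SIGNATURE_WEIGHT = 2.0
CORE_WEIGHT = 1.0


def _score_subtype(s: SubtypeDef, present: set[str], reg: Registry
                   ) -> tuple[float, float, int] | None:
    """(score, fraction of required matched, n matched), or None if disqualified."""
    if present & s.forbidden:
        return None
    sig = s.signature_families(reg)
    matched_all = s.required_all & present
    n_req = len(s.required_all) + len(s.required_any)
    matched = len(matched_all)
    score = sum(SIGNATURE_WEIGHT if f in sig else CORE_WEIGHT for f in matched_all)
    for alt in s.required_any:
        hit = alt & present
        if hit:
            matched += 1
            score += (SIGNATURE_WEIGHT if hit & sig else CORE_WEIGHT)
    if not (matched_all | {f for alt in s.required_any for f in alt & present}) & sig:
        return None  # min_evidence: at least one signature family
    frac = matched / n_req if n_req else 0.0
    return score, frac, matched


def classify_locus(locus: Locus, registry: Registry,
                   profile_map: ProfileMap) -> LocusClassification:
    evidence = locus.families(profile_map)
    present = set(evidence)
    scored: list[tuple[tuple[float, float, int], str]] = []
    for s in registry.subtypes.values():
        res = _score_subtype(s, present, registry)
        if res is not None:
            scored.append((res, s.id))
    if not scored:
        return LocusClassification(evidence=evidence,
                                   reason="no subtype-specific signature evidence")
    scored.sort(key=lambda t: (-t[0][0], -t[0][1], -t[0][2], t[1]))
    best = scored[0]
    ties = [sid for res, sid in scored[1:] if res == best[0]]
    winner = registry.subtype(best[1])
    return LocusClassification(
        cas_type=winner.cas_type, subtype=winner.id,
        evidence=evidence,
        conflicts=[(sid, scored[0][0][0]) for sid in ties],
    )


def is_complete(locus: Locus, classification: LocusClassification,
                registry: Registry, profile_map: ProfileMap
                ) -> tuple[bool, str]:
    """Completeness call: all effector-module required genes present, plus
    adaptation module and array unless the subtype marks them optional."""
    if classification.subtype == "unclassified":
        return False, "locus is unclassified"
    s = registry.subtype(classification.subtype)
    present = set(locus.families(profile_map))
    missing = sorted(s.required_all - present)
    if missing:
        return False, f"missing required families: {missing}"
    for alt in s.required_any:
        if not alt & present:
            return False, f"none of the alternatives present: {sorted(alt)}"
    if not s.adaptation_optional and not {"cas1", "cas2"} <= present:
        return False, "adaptation module (cas1+cas2) required but absent"
    if not s.array_optional and not locus.arrays:
        return False, "CRISPR array required but absent"
    return True, ""


def classify_all(loci: list[Locus], registry: Registry,
                 profile_map: ProfileMap) -> list[LocusClassification]:
    out = []
    for locus in loci:
        c = classify_locus(locus, registry, profile_map)
        c.complete, reason = is_complete(locus, c, registry, profile_map)
        if not c.complete and not c.reason:
            c.reason = reason
        out.append(c)
    return out


def locus_report(loci: list[Locus],
                 classifications: list[LocusClassification]) -> pd.DataFrame:
    rows = []
    for locus, c in zip(loci, classifications):
        rows.append({
            "genome_id": locus.genome_id, "contig": locus.contig,
            "span_start": locus.span[0], "span_end": locus.span[1],
            "cas_type": c.cas_type, "subtype": c.subtype,
            "variant": c.variant or "", "complete": c.complete,
            "n_arrays": len(locus.arrays),
            "genes": ",".join(m.protein.protein_id for m in locus.members),
            "conflicts": ";".join(sid for sid, _ in c.conflicts),
        })
    return pd.DataFrame(rows)
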