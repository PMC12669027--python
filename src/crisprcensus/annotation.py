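"""Per-protein Cas family assignment from profile-hit tables.

A protein is annotated by the non-overlapping set of best-scoring profile
hits that survive the e-value filter: hits are swept in descending bitscore
order and accepted unless they overlap an already-accepted hit by more than
``overlap_tolerance`` residues (greedy culling, the standard reading of
"best-scoring non-overlapping").  Score ties break on lower e-value, then
longer interval, then profile id, so the assignment is deterministic.

The same machinery backs the abundance-counting mode, where hits of
subtype-attributed query profiles against a clustered protein database are
coverage-filtered (>= 0.75 of the query length), de-overlapped per target
and tallied by the subtype of the query.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .registry import Registry


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    genome_id: str
    contig: str
    start: int
    end: int
    strand: str
    rank: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.protein_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"{self.protein_id}: strand must be + or -")


@dataclass(frozen=True)
class ProfileHit:
    protein_id: str
    profile_id: str
    evalue: float
    score: float
    q_cov: float
    p_from: int
    p_to: int

    def __post_init__(self) -> None:
        if self.p_from > self.p_to:
            raise ValueError(f"hit {self.profile_id}@{self.protein_id}: p_from > p_to")
        if not 0.0 <= self.q_cov <= 1.0:
            raise ValueError(f"hit {self.profile_id}@{self.protein_id}: q_cov outside [0,1]")

    def overlap(self, other: "ProfileHit") -> int:
        """Number of shared residues (1-based inclusive intervals)."""
        return max(0, min(self.p_to, other.p_to) - max(self.p_from, other.p_from) + 1)


@dataclass
class AnnotatedProtein:
    protein: ProteinRecord | None
    assigned_hits: list[ProfileHit] = field(default_factory=list)

    @property
    def protein_id(self) -> str:
        if self.protein is not None:
            return self.protein.protein_id
        return self.assigned_hits[0].protein_id


class ProfileMap:
    """Maps profile ids to (gene family, optional subtype of provenance)."""

    def __init__(self, family_of: dict[str, str],
                 subtype_of: dict[str, str] | None = None):
        self.family_of = dict(family_of)
        self.subtype_of = dict(subtype_of or {})

    def family(self, profile_id: str) -> str | None:
        return self.family_of.get(profile_id)

    def subtype(self, profile_id: str) -> str | None:
        return self.subtype_of.get(profile_id)

    @classmethod
    def from_registry(cls, reg: Registry) -> "ProfileMap":
        """One profile per gene family; a profile carries a subtype when its
        family is the signature of exactly one subtype."""
        family_of = {name: name for name in reg.families}
        owners: dict[str, list[str]] = {}
        for s in reg.subtypes.values():
            for f in s.signature_families(reg):
                owners.setdefault(f, []).append(s.id)
        subtype_of = {f: sids[0] for f, sids in owners.items() if len(sids) == 1}
        return cls(family_of, subtype_of)


# ---------------------------------------------------------------------------

def filter_hits(hits: list[ProfileHit], evalue_max: float = 1e-4) -> list[ProfileHit]:
    """Keep hits with e-value <= *evalue_max* (order preserved)."""
    for h in hits:
        if h.evalue < 0:
            raise ValueError(f"hit {h.profile_id}@{h.protein_id}: negative e-value")
    return [h for h in hits if h.evalue <= evalue_max]


def coverage_filter(hits: list[ProfileHit], min_cov: float = 0.75) -> list[ProfileHit]:
    """Keep hits covering at least *min_cov* of the query profile length."""
    return [h for h in hits if h.q_cov >= min_cov]


def _sweep_key(h: ProfileHit) -> tuple:
    # best first: high score, low e-value, long interval, lexicographic id
    return (-h.score, h.evalue, -(h.p_to - h.p_from + 1), h.profile_id)


def select_nonoverlapping(hits: list[ProfileHit],
                          protein: ProteinRecord | None = None,
                          overlap_tolerance: int = 0) -> AnnotatedProtein:
    """Greedy best-scoring non-overlapping hit selection for one protein."""
    if hits:
        pids = {h.protein_id for h in hits}
        if len(pids) > 1:
            raise ValueError(f"hits span multiple proteins: {sorted(pids)}")
    accepted: list[ProfileHit] = []
    for h in sorted(hits, key=_sweep_key):
        if all(h.overlap(a) <= overlap_tolerance for a in accepted):
            accepted.append(h)
    accepted.sort(key=lambda h: (h.p_from, h.p_to, h.profile_id))
    return AnnotatedProtein(protein=protein, assigned_hits=accepted)


def annotate_proteins(hits_df: pd.DataFrame, genes_df: pd.DataFrame,
                      evalue_max: float = 1e-4,
                      overlap_tolerance: int = 0) -> dict[str, AnnotatedProtein]:
    """Full annotation pass: e-value filter then per-protein hit culling.

    Returns a map protein_id -> AnnotatedProtein for every protein with at
    least one surviving hit.
    """
    proteins = {
        r.protein_id: ProteinRecord(r.protein_id, r.genome_id, str(r.contig),
                                    int(r.start), int(r.end), r.strand, int(r.rank))
        for r in genes_df.itertuples()
    }
    hits = [ProfileHit(r.protein_id, r.profile_id, float(r.evalue),
                       float(r.bitscore), float(r.qcov), int(r.pstart), int(r.pend))
            for r in hits_df.itertuples()]
    hits = filter_hits(hits, evalue_max)
    by_protein: dict[str, list[ProfileHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    out: dict[str, AnnotatedProtein] = {}
    for pid, phits in by_protein.items():
        ann = select_nonoverlapping(phits, proteins.get(pid), overlap_tolerance)
        if ann.assigned_hits:
            out[pid] = ann
    return out


def count_abundance(hits: list[ProfileHit], profile_map: ProfileMap,
                    min_cov: float = 0.75, evalue_max: float = 1e-4,
                    overlap_tolerance: int = 0) -> dict[str, Counter]:
    """Tally filtered, de-overlapped hits by the subtype of the query profile.

    Here ``protein_id`` is the *target* (database) protein and the profile is
    the query, so the coverage filter applies to the query length and the
    non-overlap selection runs per target.  Profiles with no subtype mapping
    are tallied under ``"unassigned"``.

    Returns ``{"per_subtype": Counter, "per_type": Counter}``.
    """
    hits = coverage_filter(filter_hits(hits, evalue_max), min_cov)
    by_target: dict[str, list[ProfileHit]] = {}
    for h in hits:
        by_target.setdefault(h.protein_id, []).append(h)
    per_subtype: Counter = Counter()
    per_type: Counter = Counter()
    for pid, thits in by_target.items():
        ann = select_nonoverlapping(thits, overlap_tolerance=overlap_tolerance)
        for h in ann.assigned_hits:
            st = profile_map.subtype(h.profile_id)
            if st is None:
                per_subtype["unassigned"] += 1
                per_type["unassigned"] += 1
            else:
                per_subtype[st] += 1
                per_type[st.split("-")[0]] += 1
    return {"per_subtype": per_subtype, "per_type": per_type}
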