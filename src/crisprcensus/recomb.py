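"""Adaptation/effector module-swap (recombination) estimation.

The adaptation module travels with its locus, so if near-identical Cas1
proteins (one strict sequence cluster, 0.9 identity / 0.9 coverage) are
found next to clearly different effectors (distinct permissive clusters, 0.5
identity / 0.33 coverage of cas8, cas9, cas10 or cas12), at least one
module swap must have occurred.  For each strict cas1 cluster the number of
registered events is the count of distinct permissive effector clusters it
co-occurs with minus one — a conservative, spanning-tree-like lower bound on
the number of swaps.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: effector genes whose co-occurrence with cas1 is tallied by default.
DEFAULT_EFFECTOR_FAMILIES = ("cas8", "cas9", "cas10", "cas12")


@dataclass(frozen=True)
class ClusterAssignment:
    """A total map protein_id -> cluster_id at one clustering level."""
    assignment: Mapping[str, str]
    level: str  # "strict" (0.9/0.9) or "permissive" (0.5/0.33)

    def __getitem__(self, protein_id: str) -> str:
        return self.assignment[protein_id]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.assignment


@dataclass(frozen=True)
class ModulePair:
    locus_id: str
    cas1_strict_cluster: str
    effector_gene: str
    effector_permissive_cluster: str


# ---------------------------------------------------------------------------

def greedy_cluster(pairs: pd.DataFrame, lengths: Mapping[str, int],
                   id_threshold: float, cov_threshold: float,
                   level: str = "strict") -> ClusterAssignment:
    """Greedy incremental clustering against cluster representatives.

    *pairs* carries columns (protein_a, protein_b, identity, cov_a, cov_b)
    with coverage of the alignment on each sequence.  Proteins are processed
    longest-first (ties lexicographic); each joins the first-founded cluster
    whose representative it matches at >= *id_threshold* identity and
    >= *cov_threshold* coverage on the representative (target-side coverage),
    otherwise it founds a new cluster named after itself.
    """
    if len(pairs) and (pairs["identity"].lt(0).any() or pairs["identity"].gt(1).any()):
        raise ValueError("identity outside [0, 1]")
    sim: dict[tuple[str, str], tuple[float, float]] = {}
    for r in pairs.itertuples():
        # store (identity, coverage-on-second) for both orientations
        sim[(r.protein_a, r.protein_b)] = (float(r.identity), float(r.cov_b))
        sim[(r.protein_b, r.protein_a)] = (float(r.identity), float(r.cov_a))
    proteins = sorted(lengths, key=lambda p: (-lengths[p], p))
    reps: list[str] = []
    assignment: dict[str, str] = {}
    for p in proteins:
        for rep in reps:
            ident, cov_on_rep = sim.get((p, rep), (0.0, 0.0))
            if ident >= id_threshold and cov_on_rep >= cov_threshold:
                assignment[p] = rep
                break
        else:
            reps.append(p)
            assignment[p] = p
    return ClusterAssignment(assignment, level)


def extract_module_pairs(loci: Iterable, strict: ClusterAssignment,
                         permissive: ClusterAssignment,
                         profile_map,
                         effector_families: Sequence[str] = DEFAULT_EFFECTOR_FAMILIES
                         ) -> tuple[list[ModulePair], int]:
    """One ModulePair per (locus, effector gene) with both cas1 and effector.

    Effector family matching is by prefix (cas8 covers cas8a..cas8u, cas12
    covers cas12a..cas12p).  Loci with a cas1 but no listed effector, or vice
    versa, are skipped; the count of skipped loci is returned.  A locus with
    several distinct effector genes (hybrid) yields one pair per effector.
    """
    out: list[ModulePair] = []
    skipped = 0
    for idx, locus in enumerate(loci):
        locus_id = f"{locus.genome_id}:{locus.contig}:{idx}"
        cas1_pid = None
        effectors: list[tuple[str, str]] = []  # (family, protein_id)
        for m in locus.members:
            for h in m.assigned_hits:
                fam = profile_map.family(h.profile_id)
                if fam is None:
                    continue
                if fam == "cas1" and cas1_pid is None:
                    cas1_pid = m.protein.protein_id
                for eff in effector_families:
                    if fam == eff or fam.startswith(eff):
                        effectors.append((eff, m.protein.protein_id))
        if cas1_pid is None or not effectors or cas1_pid not in strict:
            skipped += 1
            continue
        seen = set()
        for eff_gene, pid in effectors:
            if pid not in permissive or (eff_gene, pid) in seen:
                continue
            seen.add((eff_gene, pid))
            out.append(ModulePair(locus_id, strict[cas1_pid], eff_gene,
                                  permissive[pid]))
    return out, skipped


def count_module_swaps(pairs: Iterable[ModulePair]) -> tuple[int, pd.DataFrame]:
    """Conservative swap count: distinct effector clusters per strict cas1
    cluster, minus one, floored at zero, summed."""
    effectors_of: dict[str, set[str]] = {}
    n_pairs: Counter = Counter()
    for p in pairs:
        effectors_of.setdefault(p.cas1_strict_cluster, set()).add(
            p.effector_permissive_cluster)
        n_pairs[p.cas1_strict_cluster] += 1
    detail = pd.DataFrame(
        [{"cas1_strict_cluster": c,
          "n_pairs": n_pairs[c],
          "n_effector_clusters": len(effs),
          "n_events": max(0, len(effs) - 1)}
         for c, effs in sorted(effectors_of.items())])
    n_events = int(detail["n_events"].sum()) if len(detail) else 0
    return n_events, detail
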