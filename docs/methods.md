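# Methods

This note records what each component of `crisprcensus` computes, the
assumptions behind it, the parameter defaults and why, and what the
synthetic-data tests do and do not demonstrate.

## The classification registry

The registry encodes the CRISPR–Cas taxonomy as data: 2 classes, 7 types,
46 subtypes in the current ("2025") scheme; 6 types and 33 subtypes in the
previous ("2020") scheme. Each subtype carries `required_all` (the effector
module core plus its signature genes), `required_any` (alternative gene
sets, e.g. the III-D csx19/csx25 markers), `forbidden` (e.g. cas10 for
III-E, which is defined by its absence; csn2/cas4 for the minimal II-C),
and flags saying whether the adaptation module (cas1+cas2) and the CRISPR
array are dispensable (type VII, III-G/H and most class-2 V/VI subtypes
lack adaptation modules; III-G and type IV loci may lack arrays).

Where the published taxonomy leaves the exact subtype inventory open, we
made the following editorial choices (they are data, editable in the JSON):

- The former single I-F subtype is split into I-F1 and I-F2, with I-F3
  (the Tn7 CAST) and I-F4 remaining variants of I-F1; the legacy map
  `I-F → I-F1` makes the two registries diffable without a spurious
  remove+add pair.
- Type V holds 15 subtypes: the ten of the previous scheme (V-A…V-I, V-K)
  plus V-L…V-P. The letters V-J and V-Q are kept as named candidate
  variants, not counted: the running literature names more type-V letters
  than a 15-subtype partition can contain, so two must remain unpromoted,
  and we chose to promote the five with the broadest experimental support.
- Variants (I-F3 CAST, IV-A2, II-C2, III-A2, V-B3, VI-B3, …) are children
  of subtypes and never counted in the 46.

With these choices the 2020→2025 diff is exactly 13 additions (I-F2, II-D,
III-G/H/I, V-L/M/N/O/P, VI-E/F, VII) and zero removals, and the class-1
partition is 8 (I) + 9 (III) + 3 (IV) + 1 (VII) = 21.

The Crf1–Crf11 CARF-domain sensor families and Crn1–Crn5 ring-nuclease
families are registry gene families (roles `sensor` and `ring-nuclease`);
they participate in locus evidence but are never classification signatures.

## Annotation

Profile hits are filtered at e-value ≤ 1e-4 (the operating point of
PSSM-based *cas* gene searches; the boundary is inclusive). Filtering runs
*before* non-overlap selection — the order is not dictated by the protocol,
but filtering first means a high-scoring junk hit above the threshold can
never displace a genuine one. Per protein, hits are then accepted greedily
in order of (bitscore desc, e-value asc, interval length desc, profile id):
a hit is kept iff it overlaps every already-kept hit by at most
`overlap_tolerance` residues (default 0). Greedy culling — rather than
maximum-weight interval scheduling — is the standard reading of
"best-scoring non-overlapping" and matches rpsblast-style culling. The tie
rule makes the assignment deterministic.

Abundance counting applies the same machinery with roles reversed: query
profiles carry subtype provenance, targets are database proteins, hits are
kept at ≥ 0.75 query coverage (inclusive), de-overlapped per target, and
tallied by the query's subtype ("unassigned" when a profile maps to no
single subtype).

## Locus assembly, trimming, classification, completeness

Seeds are genes annotated with a core *cas* family (roles adaptation,
effector-core or signature-effector — i.e. the cas1–cas14 superfamilies and
their lettered descendants, not sensors/ring nucleases/transposon genes).
Each seed opens a window of ± 10 genes (ranks, not base pairs), truncated
at contig ends; windows that overlap or abut on a contig merge into one
locus, so assembly is independent of seed order and output loci never
overlap. Arrays attach to a locus when at most `flank` genes separate them
from the locus window. Merged windows are not re-extended (single pass).

"Margins ending at their respective directions" is interpreted as directon
trimming: each margin is moved to the boundary of the maximal run of
consecutive co-oriented genes containing the outermost annotated *cas*
element on that side. This both drops unannotated flank genes beyond a
strand switch and extends the margin when the directon continues past the
window; interior unannotated genes are retained. The literal alternative
(no trimming) loses the operon-proxy rationale, so the directon reading is
used and is a fixpoint on already-bounded loci.

Classification scores every subtype: matched signature family (role
`signature-effector` among the subtype's required genes) = 2, any other
matched required family = 1, a `required_any` group counts once via its
best member, any forbidden family disqualifies, and at least one signature
match is required at all (otherwise the locus is `unclassified`). Ties
break on the fraction of required families matched — so a minimal
cas9+cas1+cas2 locus classifies as II-C rather than as an incomplete
II-A/II-B — then on the match count; residual exact ties are reported in
`conflicts` with a lexicographic winner, never silently resolved. Because
scoring sees only the set of families present, classification is invariant
under gene-order reversal (strand flip).

Completeness of a classified locus requires: all `required_all` families,
one member of each `required_any` group, cas1+cas2 unless
`adaptation_optional`, and ≥ 1 attached array unless `array_optional`.
Weights (2/1), the minimum-evidence rule and the flank are configurable
through `PipelineConfig`.

## Dendrograms and the profile-merge loop

Similarity scores become distances via
`d(A,B) = −ln(clamp(S_AB / min(S_AA, S_BB), ε, 1))` with ε = 1e-9: cross
scores occasionally exceed a self-score in practice, so relative scores are
clamped to 1 (distance floor 0), and non-positive scores hit the −ln ε
ceiling (~20.7). The transform is monotone decreasing in S_AB.

UPGMA is implemented directly (not via scipy, which is instead used as an
independent cross-check in the tests) so that ties break lexicographically
on cluster name-sets and the whole downstream machinery is deterministic:
node height = half the merge distance (ultrametric), inter-cluster
distances update by the size-weighted Lance–Williams rule. `cut_at_depth`
returns the maximal subtrees of height ≤ depth; cuts at increasing depth
are nested. The default cut of 0.8 is in −ln(relative score) units, i.e.
clusters retain ≥ e^-1.6 ≈ 20 % pairwise relative similarity at the 2×
height. Hybrid dendrograms replace backbone tips with externally inferred
per-cluster trees (Newick in, via dendropy), preserving the tip's pendant
edge length and refusing duplicate leaf labels.

The profile-merge loop ("neighbour-joining" in the field's usage, though it
is closest-pair agglomeration, not NJ tree building) repeatedly proposes
the closest current pair, consults a `MergeOracle` — the abstraction of
rebuilding the merged profile and re-searching — and accepts only when
retention > 0.98 (strict, per "more than 98 %") and new false positives
≤ 10 (inclusive, per "no more than ten"). Rejected pairs are marked
unmergeable; marks involving a cluster disappear when that cluster merges
into a new one (the new profile deserves a fresh query). Because the oracle
returns only (retention, new_fp), the merged cluster's similarity row is
recomputed internally as the member-count-weighted average of the pair's
rows (self-score likewise) — the best available stand-in for a true profile
re-computation under this interface. Every decision is logged; the loop
performs at most n−1 accepted merges and terminates because each iteration
either merges or permanently marks a pair.

## Genome weights and census statistics

Weights use Gerstein–Sonnhammer–Chothia apportionment: processing edges
bottom-up, each edge's length is distributed among its descendant leaves in
proportion to the weights they have accumulated so far (equally where all
are zero, e.g. at zero-length cherries), and the result is normalized to
sum to 1. This is the canonical tree-based correction for uneven sampling:
a clade of near-identical genomes shares the weight one genome would have
had, and duplicating a leaf with zero-length pendant edges halves exactly
that leaf's weight while every other genome's weight is unchanged. A
strictly equal-split scheme is available (`scheme="equal"`) but does not
have that locality property. A star tree with equal branches gives uniform
weights; an all-zero-length tree falls back to uniform.

Weighted prevalence of a predicate (default: carries ≥ 1 complete
classified system) is, per group, the weight of satisfying genomes over the
group's weight; with uniform weights it reduces to the plain fraction.
The taxon × subtype matrix gives every *complete locus* the weight of its
genome — a genome with two I-B loci contributes twice, following the
occurrence-based definition — and normalizes each row to the taxon's total
complete-locus weight, so rows with any complete locus sum to 1.
Temperature classes default to psychrophile < 20 °C ≤ mesophile < 45 °C ≤
thermophile < 80 °C ≤ hyperthermophile (the literature names the classes
but not the bounds; these are the conventional ones and are configurable).
Genomes without a known OGT are excluded from the temperature analysis and
counted in the log; callers should recompute weights on the analysed
subset's subtree.

## Recombination estimate

Proteins cluster by greedy incremental clustering: candidates are processed
longest-first (ties lexicographic) and join the first-founded cluster whose
representative they match at both thresholds, with coverage evaluated on
the representative (target-side coverage); otherwise they found a cluster.
Strict level = 0.9 identity / 0.9 coverage, permissive = 0.5 / 0.33.
Module pairs are (strict cas1 cluster, permissive effector cluster) per
locus containing both cas1 and an effector gene (cas8, cas9, cas10, cas12
by default, lettered variants matched by prefix; cas13/cas14 excludable
effectors can be added via the `effector_families` argument). The event
count per strict cas1 cluster is (distinct permissive effector clusters
co-occurring with it) − 1, floored at zero — a spanning-tree lower bound:
k distinct effector contexts for one near-identical adaptation module imply
at least k−1 swaps. Counting is deliberately conservative and monotone
(adding a pair never decreases the count); identical loci in near-identical
genomes are *not* deduplicated.

## Synthetic data: what it does and does not show

The generator plants loci whose gene content follows the registry rules
exactly, embeds them in a single directon flanked by decoy genes (default
12 per side, 25 between tandem loci so windows never merge), assigns taxa
round-robin and OGTs uniformly in 5–95 °C, and emits hit tables with:
true hits at e-value ∈ log-uniform[1e-30, 1e-5], bitscore ∈ U[100, 400],
coverage ∈ Beta(8, 2); decoy hits at e-value ∈ log-uniform[1e-3, 1]
(removed by the 1e-4 filter); and, with probability 0.3 per cas gene, a
weaker fully-overlapping wrong-family hit (removed by greedy culling).
Incomplete loci drop the adaptation module where it is required, else one
non-signature required gene, else the array — elements whose absence cannot
flip the winning subtype, so the planted label stays recoverable. Trees
come in star, caterpillar (unit-step ultrametric) and random-coalescent
shapes; similarity matrices have planted blocks with within-block scores
stochastically above between-block scores and maximal self-scores.
All generators are pure functions of (spec, seed).

What passing closed-loop tests shows: the assembly/trim/classify/census
chain is internally consistent and recovers planted truth under the stated
noise. What it does not show: performance on real genomes, where profiles
cross-react between related families, loci overlap and tandem systems
share neighbourhoods, gene order varies, pseudogenes and fragments abound,
and arrays are miscalled — none of which the generator emulates. Real
fractional identities between family profiles (rather than the clean
block/decoy split), tracrRNAs and V-U/TnpB discrimination are out of scope.

## Problem sizes and numeric choices

The test suite and acceptance script run at desk scale: 20–60 genomes for
closed-loop checks (500 for the prevalence recovery check), 100–500
random instances for the oracle-equivalence checks, trees of ≤ 30 leaves —
sizes at which the brute-force oracles are exact and the whole suite
completes in seconds. Tolerances: weights and matrix rows sum to 1 within
1e-9; UPGMA heights match oracles within 1e-9 relative; the distance
transform's ε is 1e-9. Degenerate inputs are defined: single-leaf tree →
weight 1; all-zero branch lengths → uniform weights; single cluster →
merge loop is a no-op; empty hit list → empty annotation; taxa with no
complete locus → zero row, excluded from normalization.
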