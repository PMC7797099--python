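# Methods

## The model: a functional hierarchy for read classification

Taxonomic read classifiers (Kraken-family, Kaiju) resolve ambiguous
matches by assigning a read to the lowest common ancestor (LCA) of all
candidate taxa in a rooted tree. `lcftools` transplants that mechanism
to function: the Gene Ontology molecular-function domain, rooted at
`GO:0003674`, plays the role of the taxonomy, and a read is assigned to
its lowest common function (LCF) — the most specific molecular function
consistent with all of its sequence evidence.

The obstacle is that GO is a DAG, not a tree: a term may have several
`is_a` parents. Only `is_a` relations are used here (`part_of` and
other relationship types are ignored); `is_a` is the subsumption
backbone of GO, and an LCA over mixed relation semantics would not be a
specificity statement. Obsolete terms and terms that cannot reach the
root through non-obsolete terms are excluded, with the excluded
identifiers reported.

## DAG → tree transformation

A spanning arborescence is built by placing nodes in topological order
(parents always placed, with final depths, before their children;
lexicographic tie-break for determinism) and giving each multi-parent
node exactly one parent:

* **DFS** (default): the first-discovery parent of a depth-first
  traversal with lexicographic child order, realised as the deepest
  already-placed parent. This maximises mean node depth, hence the
  specificity of downstream LCF assignments.
* **BFS**: the shallowest parent, making every depth a shortest-path
  distance from the root. This is the natural lower bound: no
  arborescence can place a node shallower than its DAG shortest path, so
  `depth_BFS(v) ≤ depth_S(v)` for every strategy `S`, and DFS mean depth
  ≥ BFS mean depth.
* **RND**: a uniform seeded choice, used as replicates (seeds
  `base..base+n−1`) to show the spread between the two extremes.

For a node with exactly two parents where one parent is an ancestor of
the other, the child attaches to the **deeper** parent under the
depth-maximising strategies (DFS, RND). This is the single
non-redundant attachment point — the shallower parent is already implied
by the deeper one — and it is what DFS first-discovery produces anyway.
The shallower reading is available via `two_parent_rule="shallower"` for
sensitivity analysis. BFS ignores the rule, because applying it would
break the shortest-path property that defines BFS depths. Nodes with
more than two parents fall straight through to the strategy rule.

Root depth is 0; "levels" are reported as maximum depth.

## Taxonomy export

Downstream classifier binaries require NCBI taxonomy dump files
bit-exactly, so `nodes.dmp` rows are
`taxid\t|\tparent_taxid\t|\tno rank\t|` with the root self-parented, and
`names.dmp` uses the `scientific name` class. Taxids are the numeric GO
accession (`GO:0003674` → 3674): collision-free within GO and
auditable by eye; non-GO fixture identifiers get sequential ids above
the maximum. Reading the dump back reconstructs term identifiers by
re-formatting taxids as 7-digit GO accessions (a caller-supplied mapping
overrides this for non-GO trees, where only the taxid-space parent
relation is recoverable).

## Reference databases and the k-mer index

A sequence annotated with several GO terms gets one representative term:
the deepest (most specific) in the tree, ties broken lexicographically.
Redundancy collapse removes byte-identical duplicates (keeping the first
seen); the stronger `containment` mode also removes sequences fully
contained in a longer kept sequence, keeping the longest — redundant
near-identical references otherwise push shared k-mers toward the root.

Reverse translation maps each residue to a fixed codon from a bundled
most-frequent-codon table (E. coli K-12 usage; swappable per call), so
`translate(reverse_translate(p)) == p` always holds and the DNA output
is deterministic.

The k-mer index maps every reference k-mer to the LCA of the
representative terms of all sequences containing it, built incrementally
(pairwise LCA is associative). DNA k-mers are canonicalised over
strands (lexicographic minimum of k-mer and reverse complement);
protein k-mers are not. K-mers containing ambiguity symbols are
skipped, as are sequences shorter than k (logged). Defaults: k = 31
for DNA (the Kraken-family convention), k = 10 for protein (a larger
alphabet saturates specificity sooner, and translated fragments of
125 bp reads are short).

## Classification

**k-mer path-weight mode.** Hits per node are counted from the read's
k-mers (for protein indexes, from its six-frame translation split at
stop codons, dropping fragments shorter than k). Each node `v` is
scored by the sum of hits on the root-to-`v` path, and the read is
assigned to the maximal-score node; ties among maximal nodes resolve to
their LCA, which preserves the lowest-common-function reading of
ambiguous evidence. Zero hits mean unclassified. Only hit nodes need
scoring: the maximum is always achieved at a hit node, and every tied
non-hit node is a descendant of a tied hit node, leaving the tied set's
LCA unchanged.

**MEM mode.** The longest exact amino-acid match between any translated
fragment and any reference decides the call: if it reaches `min_match`
(default 11 residues, the Kaiju default) the read is assigned to the LCA
of the representative terms of all references achieving that best
length; otherwise unclassified. The production search seeds on exact
`min_match`-mers and extends greedily — exhaustive for all matches that
can affect the decision, since any shorter match leaves the read
unclassified either way. The quadratic-DP longest-common-substring
computation is retained in the test suite as the independent oracle.

**Pairs.** Mates of a pair are pooled before the decision: k-mer hit
counts are summed, MEM takes the maximum over mates (unioning the
references that achieve it). A missing mate degrades to single-read
classification. Whether mates should be pooled or classified
independently is a genuinely open choice; pooling matches the
one-fragment-one-call accounting used in the evaluation.

Ambiguous bases are never expanded: any k-mer containing a non-ACGT
symbol is ignored, and ambiguous codons translate to `X`, which no
reference k-mer contains.

## Read simulation

The simulator emulates the wgsim-style benchmark setting: paired 125 bp
reads, uniform fragment starts, mate 2 the reverse complement of the
fragment end, and independent per-base substitution to one of the three
other bases at rates 0.05 / 0.10 / 0.20 (low / medium / high divergence
from the reference). No indels, no quality-dependent errors, constant
`I` quality strings — classification ignores qualities and divergence is
modelled purely as a substitution rate. Pair count per sequence is
`max(1, round(coverage × length / (2 × read_length)))`. Sequences
shorter than the read length are skipped, as are sequences with more
than 10% ambiguous bases (the "high proportion of Ns" filter,
quantified here at 10% since only the qualitative rule is prescribed).
Read ids follow `<seqid>|go:<TERM>|<serial>/<mate>` so every read's true
origin term travels with it. The fragment's start coordinate is kept on
each pair, making error-rate calibration alignment-free.

## Evaluation

Five mutually exclusive categories per read: `unclassified`; `exact`
(assigned = origin); `root` (assigned = tree root — classified, but
uninformative); `related` (a proper non-root ancestor of the origin:
higher up on the same path); `incorrect` (everything else).
Assignments to a *descendant* of the origin count as incorrect by
default — the related category is explicitly ancestor-only — with a
`descendant_as_related` flag for the permissive reading. Summary
percentages follow the benchmark-table convention: unclassified and
classified are percentages of all reads; root, exact-or-related and
incorrect are percentages of classified reads. An optional flag remaps
explicit root calls to unclassified (some tools emit root for
no-evidence reads); the default keeps them classified. Rollups sum a
group term and all its descendants; level-2 groups (depth-1 nodes,
e.g. binding, catalytic activity, antioxidant activity in real GO) are
disjoint by tree structure, and per-sample 0–1 normalisation makes
cross-sample profiles comparable.

## Synthetic fixtures

The fixture generator emits GO-shaped ontologies: a backbone chain
realising the depth target, uniform attachment for the remaining terms,
and extra parents (drawn from strictly shallower nodes, preserving
acyclicity) for a configurable fraction of terms — 16% in the
acceptance runs, matching the observed share of two-parent terms in the
real molecular-function domain (~1820 of 11,684). Sequences are
i.i.d. uniform over their alphabet; `disjoint_kmers` mode rejects (and
regenerates) any sequence sharing a k-mer with another term's
sequences, guaranteeing single-term index entries so exact recovery of
noise-free reads is provable rather than probable. Labels cover every
term uniformly (`per_term` sequences each); real annotation corpora are
leaf-biased, which the `terms` argument can emulate by restricting to
deep nodes.

What the synthetic setting deliberately lacks: homology between
references of different terms, shared domains, codon-usage structure,
sequencing-platform error profiles, and the leaf-biased, heavy-tailed
annotation distribution of real databases. Passing tests therefore
demonstrate the correctness of the machinery (tree derivation, index
semantics, decision rules, bookkeeping) and the qualitative
rate-degradation behaviour — not the absolute classification rates one
would obtain against a real 40-million-sequence reference, where
inter-term sequence similarity drives reads toward ancestors and the
root.

## Problem sizes and numerical choices

The acceptance script uses a 120-term ontology, 2 proteins of 120–200
residues per term (360–600 bp after back-translation), 2× coverage
(~900 read pairs per substitution rate), k = 31 (DNA), k = 10
(protein), `min_match` = 11 — sizes chosen so the whole pipeline
re-runs from scratch in seconds while every rate/mode cell still holds
hundreds of reads. All randomness flows from explicit integer seeds
(Python `random.Random` for discrete choices, NumPy `default_rng` for
base-level mutation); identical seeds give byte-identical FASTQ output.
Tie-breaks are lexicographic throughout (child visitation order, equal
depth representatives, equal-depth parent choices) so every result is
reproducible across platforms.

## Known limitations

* Only `is_a` edges define the hierarchy; regulatory/`part_of`
  relations are out of scope.
* The MEM engine reports no match shorter than `min_match` (by design);
  its `hit_counts` are therefore empty for unclassified reads.
* Reverse translation reproduces protein-level behaviour exactly, but
  DNA-level reproduction depends on the codon-usage table chosen.
* `read_taxonomy` recovers GO-style term identifiers only for taxids
  that follow the numeric-accession scheme; other trees round-trip in
  taxid space.
* No minimizers, compact hashing or probabilistic structures: indexes
  are plain dictionaries, sized for reference sets that fit in memory.
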