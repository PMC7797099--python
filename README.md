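# lcftools

Direct **functional** classification of microbiome sequencing reads by
re-purposing the machinery of taxonomic read classifiers. Instead of
assigning reads to the lowest common ancestor (LCA) in a phylogenetic
taxonomy, `lcftools` assigns them to their **lowest common function
(LCF)** in a rooted hierarchy derived from the Gene Ontology (GO)
molecular-function domain.

Intended users: microbiome researchers who want a one-step, community-level
functional profile of shotgun metagenome reads without a separate
taxonomic-then-functional pipeline, and tool developers who want to feed a
functional hierarchy into existing Kraken/Kraken 2/Kaiju-style software.

## What it does

1. **Ontology → tree.** The GO molecular-function domain is a DAG rooted
   at `GO:0003674` (terms may have several `is_a` parents). `lcftools`
   derives a spanning tree: every multi-parent term keeps one parent,
   chosen by depth-first (DFS), breadth-first (BFS) or seeded random
   (RND) strategy. DFS maximises the mean distance of terms from the
   root, i.e. annotation specificity. Two-parent terms where one parent
   is an ancestor of the other attach to the deeper parent.
2. **Tree → taxonomy.** The tree is exported as NCBI-dialect
   `nodes.dmp` / `names.dmp` (taxid = numeric GO accession) plus
   Kraken-style labelled FASTA or `seqid2taxid` maps, so existing
   classifier binaries can consume it unchanged.
3. **Reference database.** GO-labelled protein or DNA sequences get a
   representative term (the deepest annotation), optional redundancy
   collapse, optional reverse translation to DNA, and a k-mer index
   mapping every reference k-mer *w* to
   `LCF(w) = LCA({term(s) : s contains w})`.
4. **Classification.** Kraken-style scoring — each read k-mer votes for a
   tree node, each root-to-leaf path is scored by the sum of votes on it,
   and the read is assigned to the deepest maximal-score node (ties
   resolve to their LCA) — over DNA k-mers or six-frame translations; or
   Kaiju-MEM-style assignment by the longest exact amino-acid match
   (default minimum 11 residues). Paired mates are pooled.
5. **Benchmarking.** A wgsim-like simulator emits 125 bp paired reads at
   configurable per-base substitution rates (0.05 / 0.10 / 0.20 in the
   benchmark setting) with the origin GO term encoded in the read id, and
   the evaluator scores each read as exact / related (non-root ancestor
   on the origin's path) / root / incorrect / unclassified, plus level-2
   group rollups with 0–1 normalisation.

## Worked example

```python
import lcftools as L

# synthetic molecular-function ontology: 30 terms, ~20% multi-parent
_, graph = L.make_ontology(L.FixtureSpec(terms=30, seed=5, multi_parent_fraction=0.2))
sub = L.extract_subontology(graph, graph.root, "molecular_function")
tree = L.build_tree(sub, "DFS")
print(len(tree.nodes), max(tree.depth.values()))        # 30 8

# reference DB with pairwise-disjoint 31-mers, one sequence per term
records = L.make_sequences(tree, length_range=(200, 400), seed=5,
                           disjoint_kmers=True, k=31)
index = L.build_kmer_index(records, tree, k=31, alphabet="dna")

# simulate noise-free 125 bp pairs and classify them
readset = L.simulate_reads(records, substitution_rate=0.0, coverage=2.0,
                           insert_size=250, seed=100)
cats = []
for p in readset.pairs:
    res = L.classify_pair(p.seq1, p.seq2, "kmer_dna", index, tree)
    cats.append(L.categorize(res.assigned if res.classified else None,
                             p.origin_term, tree))
s = L.summarize(cats)
print(f"{s.pct_classified:.1f} {s.pct_exact:.1f} {s.pct_incorrect:.1f}")
# 100.0 100.0 0.0
```

Noise-free reads from a disjoint-k-mer reference are all classified and
all land on their exact term of origin; raising the substitution rate
lowers both numbers (the same example at a 0.10 rate classifies 62.3% of
pairs, still with no incorrect calls).

The same pipeline is available from the shell:

```bash
lcftools fixtures --terms 50 --seed 3 -o fx/
lcftools build-tree fx/fixture.obo --strategy dfs --seed 1 --out tree.tsv
lcftools export-taxonomy tree.tsv --out-dir taxdump/
lcftools build-db --fasta fx/ref.fasta --labels fx/labels.tsv --tree tree.tsv -k 31 --alphabet dna --out db.tsv
lcftools simulate --fasta fx/ref.fasta --labels fx/labels.tsv --rate 0.05 -o sim/
lcftools classify --index db.tsv --tree tree.tsv -1 sim/sim_1.fastq -2 sim/sim_2.fastq -o calls.tsv
lcftools evaluate calls.tsv --tree tree.tsv
```

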