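"""k-mer path-weight and maximal-exact-match classification."""

import random

import pytest

import lcftools as L
from lcftools.classifier import MemIndex

from conftest import (
    oracle_longest_common_substring,
    oracle_path_score_assign,
)


@pytest.fixture
def ptree() -> L.FunctionTree:
    return L.FunctionTree(
        root="R",
        parent={"P": "R", "A": "P", "B": "P", "C": "R"},
        depth={"R": 0, "P": 1, "A": 2, "B": 2, "C": 1},
    )


def _index_from_hits(tree, kmer_terms, k=4):
    """Build a KmerIndex with prescribed entries (protein alphabet so no
    canonicalisation interferes)."""
    idx = L.KmerIndex(k=k, alphabet="protein", tree=tree)
    idx.entries.update(kmer_terms)
    return idx


class TestSixFrameTranslate:
    def test_forward_frame_one(self):
        assert L.six_frame_translate("ATGAAA")[0] == "MK"

    def test_reverse_frame_one(self):
        # revcomp of ATGAAA is TTTCAT -> FH
        assert L.six_frame_translate("ATGAAA")[3] == "FH"

    @pytest.mark.parametrize("length", [0, 1, 5, 10, 33])
    def test_always_six_frames_with_expected_lengths(self, length):
        read = "ACGT" * 9
        frames = L.six_frame_translate(read[:length])
        assert len(frames) == 6
        for f in range(3):
            assert len(frames[f]) == (length - f) // 3 if length >= f else True

    def test_stop_codons_emitted_as_star(self):
        assert L.six_frame_translate("TAA")[0] == "*"

    def test_fully_ambiguous_codon_is_x(self):
        assert L.six_frame_translate("NNN")[0] == "X"

    def test_non_iupac_symbol_rejected(self):
        with pytest.raises(ValueError):
            L.six_frame_translate("AC!T")


class TestSplitFragments:
    def test_split_at_stops_and_drop_short(self):
        assert L.split_fragments(["MKV*AA*LONGER"], min_len=4) == ["LONGER"]
        assert L.split_fragments(["MKV*AA*LONGER"], min_len=3) == [
            "MKV", "LONGER",
        ]

    def test_no_stop_keeps_frame(self):
        assert L.split_fragments(["MKVA"], min_len=2) == ["MKVA"]


class TestClassifyKmerDecision:
    """Path-weight decisions checked against the exhaustive oracle."""

    def _assign(self, hits, tree):
        from lcftools.classifier import _assign_from_hits
        from collections import Counter

        return _assign_from_hits(Counter(hits), tree)[0]

    def test_leaf_with_all_hits_wins(self, ptree):
        assert self._assign({"A": 2}, ptree) == "A"

    def test_sibling_tie_resolves_to_lca(self, ptree):
        assert self._assign({"A": 1, "B": 1}, ptree) == "P"

    def test_deeper_path_beats_ancestor_hits(self, ptree):
        # score(A) = 1 + 2 = 3 > score(P) = 1
        assert self._assign({"P": 1, "A": 2}, ptree) == "A"

    def test_zero_hits_unclassified(self, ptree):
        assert self._assign({}, ptree) is None

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_path_score_oracle(self, seed):
        graph = L.make_ontology(
            L.FixtureSpec(terms=15, seed=seed, multi_parent_fraction=0.3)
        )[1]
        tree = L.build_tree(L.extract_subontology(graph, graph.root), "DFS")
        rng = random.Random(seed)
        nodes = sorted(tree.nodes)
        hits = {
            n: rng.randint(1, 5)
            for n in rng.sample(nodes, rng.randint(1, 6))
        }
        assert self._assign(hits, tree) == oracle_path_score_assign(hits, tree)

    def test_monotonicity_adding_hits(self, ptree):
        """Adding hits to the assigned node never moves the call to a
        node with a strictly lower path score."""
        hits = {"A": 1, "B": 1}
        base = self._assign(hits, ptree)  # P
        boosted = dict(hits, **{base: 3})
        new = self._assign(boosted, ptree)
        score = lambda h, v: sum(
            h.get(n, 0) for n in ptree.path_to_root(v)
        )
        assert score(boosted, new) >= score(boosted, base)


class TestClassifyKmerReads:
    def test_read_with_no_index_kmers_unclassified(self, ptree):
        idx = L.KmerIndex(k=5, alphabet="dna", tree=ptree)
        res = L.classify_kmer("ACGTACGTAC", idx, ptree)
        assert res.status == "unclassified" and res.assigned is None

    def test_reverse_complement_invariance(self, small_tree):
        recs = L.make_sequences(
            small_tree, per_term=1, length_range=(60, 80), seed=6,
            disjoint_kmers=True, k=11,
        )
        idx = L.build_kmer_index(recs, small_tree, k=11)
        read = recs[0].sequence[10:50]
        fwd = L.classify_kmer(read, idx, small_tree)
        rev = L.classify_kmer(L.reverse_complement(read), idx, small_tree)
        assert fwd.assigned == rev.assigned == recs[0].representative

    def test_translated_mode_recovers_protein_origin(self, small_tree):
        prots = L.make_sequences(
            small_tree, per_term=1, length_range=(60, 90),
            alphabet="protein", seed=8, disjoint_kmers=True, k=8,
        )
        idx = L.build_kmer_index(prots, small_tree, k=8, alphabet="protein")
        dna = L.reverse_translate(prots[0].sequence[:40])
        res = L.classify_kmer(dna, idx, small_tree)
        assert res.classified
        assert res.assigned == prots[0].representative
        assert res.mode == "kmer_translated"

    def test_alphabet_mismatch_is_error(self, ptree):
        idx = L.KmerIndex(k=5, alphabet="dna", tree=ptree)
        with pytest.raises(ValueError):
            L.classify_kmer(["MKVLL"], idx, ptree)


class TestClassifyMem:
    def _refs(self, tree):
        rng = random.Random(3)
        seqs = {
            "A": "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(50)),
            "B": "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(50)),
        }
        return [
            L.SequenceRecord(f"ref{t}", s, [t], t) for t, s in seqs.items()
        ]

    def test_long_match_assigns_its_term(self, ptree):
        refs = self._refs(ptree)
        read = L.reverse_translate(refs[0].sequence[5:20])  # 15 residues
        res = L.classify_mem(read, refs, ptree, min_match=11)
        assert res.classified and res.assigned == "A"
        assert res.hit_counts["A"] >= 15

    def test_equal_best_matches_resolve_to_lca(self, ptree):
        motif = "WWWWWWWWWWWWW"  # 13 residues, shared by A and B
        refs = self._refs(ptree)
        refs[0].sequence = motif + refs[0].sequence[13:]
        refs[1].sequence = motif + refs[1].sequence[13:]
        res = L.classify_mem(
            L.reverse_translate(motif), refs, ptree, min_match=11
        )
        assert res.assigned == "P"

    def test_below_threshold_unclassified(self, ptree):
        refs = self._refs(ptree)
        read = L.reverse_translate(refs[0].sequence[5:13])  # 8 residues
        res = L.classify_mem(read, refs, ptree, min_match=11)
        assert res.status == "unclassified"

    @pytest.mark.parametrize("seed", range(10))
    def test_best_length_matches_lcs_oracle(self, ptree, seed):
        """Seed-and-extend best match equals the quadratic DP longest
        common substring, for every translated fragment/reference pair."""
        rng = random.Random(seed)
        refs = self._refs(ptree)
        # half the time embed a genuine reference substring in the read
        if seed % 2 == 0:
            start = rng.randint(0, 30)
            peptide = refs[0].sequence[start : start + rng.randint(12, 18)]
            read = L.reverse_translate(peptide)
        else:
            read = "".join(rng.choice("ACGT") for _ in range(60))
        index = MemIndex(refs, min_match=11)
        frags = L.split_fragments(L.six_frame_translate(read), min_len=11)
        for ref_i, ref in enumerate(refs):
            oracle_best = max(
                (
                    oracle_longest_common_substring(f, ref.sequence)
                    for f in frags
                ),
                default=0,
            )
            impl_best = max(
                (
                    index.best_matches(f).get(ref_i, 0)
                    for f in frags
                ),
                default=0,
            )
            if oracle_best >= 11:
                assert impl_best == oracle_best
            else:
                assert impl_best == 0


class TestClassifyPair:
    def test_pooled_hits_assign_like_their_sum(self, small_tree):
        recs = L.make_sequences(
            small_tree, per_term=1, length_range=(120, 160), seed=9,
            disjoint_kmers=True, k=11,
        )
        idx = L.build_kmer_index(recs, small_tree, k=11)
        seq = recs[0].sequence
        res = L.classify_pair(
            seq[:50], L.reverse_complement(seq[-50:]), "kmer_dna", idx,
            small_tree,
        )
        assert res.assigned == recs[0].representative

    def test_mates_hitting_siblings_meet_at_parent(self, ptree):
        idx = _index_from_hits(ptree, {"MMMM": "A", "WWWW": "B"})
        res = L.classify_pair(
            L.reverse_translate("MMMM"), L.reverse_translate("WWWW"),
            "kmer_translated", idx, ptree,
        )
        assert res.assigned == "P"

    def test_empty_mate2_is_neutral(self, ptree):
        idx = _index_from_hits(ptree, {"AAAA": "A"})
        solo = L.classify_kmer(["AAAA"], idx, ptree)
        res = L.classify_pair(
            L.reverse_translate("AAAA"), None, "kmer_translated", idx, ptree
        )
        assert res.assigned == solo.assigned

    def test_mem_pair_takes_maximum_over_mates(self, ptree):
        rng = random.Random(5)
        refs = [
            L.SequenceRecord(
                "refA",
                "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(60)),
                ["A"], "A",
            )
        ]
        good = L.reverse_translate(refs[0].sequence[10:25])
        junk = "ACGT" * 10
        res = L.classify_pair(junk, good, "mem", refs, ptree)
        assert res.classified and res.assigned == "A"

    def test_unknown_mode_is_error(self, ptree):
        with pytest.raises(ValueError):
            L.classify_pair("ACGT", None, "bowtie", None, ptree)


class TestOutput:
    def test_per_read_tsv_shape(self, ptree, tmp_path):
        results = [
            L.ClassificationResult("r1", "classified", "A", {"A": 3}),
            L.ClassificationResult("r2", "unclassified"),
        ]
        mapping = L.TaxidMap()
        for i, t in enumerate(sorted(ptree.nodes), 1):
            mapping.add(t, i)
        out = tmp_path / "calls.tsv"
        L.write_classifications(results, out, mapping)
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == [
            "r1", "C", "A", str(mapping.to_taxid["A"]), "A:3",
        ]
        assert lines[1].split("\t")[:3] == ["r2", "U", "-"]
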