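"""Link graph, greedy scaffolder, N50, combination sweep, truth scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mpscaffold as mp
from mpscaffold.scaffold import build_link_graph, greedy_scaffold, prepare_library


def brute_force_n50(lengths):
    total = sum(lengths)
    best = 0
    for L in sorted(set(lengths)):
        if sum(x for x in lengths if x >= L) >= total / 2:
            best = max(best, L)
    return best


def mapped_frame(rows):
    """Rows: (fwd_contig, fwd_cpos, fwd_strand, rev_contig, rev_cpos,
    rev_strand)."""
    recs = []
    for i, (fc, fp, fs, rc, rp, rs) in enumerate(rows):
        recs.append({"pair_id": i, "fwd_contig": fc, "fwd_cpos": fp,
                     "fwd_strand": fs, "rev_contig": rc, "rev_cpos": rp,
                     "rev_strand": rs, "pair_class": "consistent"})
    return pd.DataFrame(recs)


class TestN50:
    @pytest.mark.parametrize("lengths,expected", [
        ([10, 6, 4, 2], 6),   # 10+6=16 >= 11, 10 alone < 11
        ([5], 5),
        ([7, 7, 7], 7),
        ([1, 1, 1, 1, 100], 100),
    ])
    def test_examples(self, lengths, expected):
        assert mp.n50(lengths) == expected

    def test_matches_brute_force_on_random_lists(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            lengths = list(rng.integers(1, 1000, size=rng.integers(1, 21)))
            assert mp.n50(lengths) == brute_force_n50(lengths)

    @given(st.lists(st.integers(1, 10 ** 6), min_size=1, max_size=20))
    @settings(deadline=None, max_examples=150, derandomize=True)
    def test_property_half_of_bases_in_large_pieces(self, lengths):
        v = mp.n50(lengths)
        assert v in lengths
        assert sum(x for x in lengths if x >= v) * 2 >= sum(lengths)
        assert v == brute_force_n50(lengths)

    def test_rejects_empty_and_nonpositive(self):
        with pytest.raises(ValueError):
            mp.n50([])
        with pytest.raises(ValueError):
            mp.n50([10, 0])


class TestBuildLinkGraph:
    def test_consistent_links_aggregate_into_one_edge(self):
        rows = [("A", 900, "+", "B", 50, "-")] * 10
        g = build_link_graph([("lib", 3000, mapped_frame(rows))],
                             {"A": 1000, "B": 1000}, min_support=5)
        assert g.n_edges == 1
        e = g.edges.iloc[0]
        assert (e["contig_a"], e["end_a"], e["contig_b"], e["end_b"]) == \
            ("A", "R", "B", "L")
        assert e["support"] == 10
        # gap = insert - dist_a - dist_b = 3000 - 100 - 100
        assert e["raw_gap"] == 2800

    def test_negative_gap_floored_but_raw_retained(self):
        rows = [("A", 100, "+", "B", 800, "-")] * 6
        g = build_link_graph([("lib", 1000, mapped_frame(rows))],
                             {"A": 1000, "B": 1000}, min_support=5,
                             read_length=50)
        e = g.edges.iloc[0]
        assert e["raw_gap"] < 0
        assert e["gap_estimate"] == 1

    def test_weak_edges_kept_separately(self):
        rows = [("A", 900, "+", "B", 50, "-")]
        g = build_link_graph([("lib", 3000, mapped_frame(rows))],
                             {"A": 1000, "B": 1000}, min_support=5)
        assert g.n_edges == 0
        assert len(g.weak_edges) == 1

    def test_unknown_contig_raises(self):
        rows = [("A", 900, "+", "Z", 50, "-")] * 6
        with pytest.raises(ValueError, match="absent"):
            build_link_graph([("lib", 3000, mapped_frame(rows))],
                             {"A": 1000, "B": 1000})

    def test_clonal_and_ambiguous_pairs_excluded(self):
        df = mapped_frame([("A", 900, "+", "B", 50, "-")] * 8)
        df.loc[:3, "pair_class"] = "clonal"
        df.loc[4:5, "pair_class"] = "ambiguous"
        g = build_link_graph([("lib", 3000, df)], {"A": 1000, "B": 1000},
                             min_support=2)
        assert g.edges.iloc[0]["support"] == 2


class TestMapPairsToContigs:
    def test_tags_in_gaps_are_dropped(self, plain_genome):
        layout = mp.fragment_into_contigs(plain_genome, 20,
                                          gap_model={"mean_gap": 2000}, seed=3)
        spec = mp.LibrarySpec("8kb", 8000, 800, n_pairs=5000, seed=4)
        ps = mp.simulate_library(plain_genome, spec)
        cset = mp.classify_pairs(ps, (6000, 10_000))
        mapped = mp.map_pairs_to_contigs(cset, layout)
        assert 0 < len(mapped) < len(cset.pairs)
        c = layout.contigs.set_index("contig_id")
        starts = c.loc[mapped["fwd_contig"], "start"].to_numpy()
        np.testing.assert_array_equal(
            mapped["fwd_pos"].to_numpy(), starts + mapped["fwd_cpos"].to_numpy())


def path_graph(n_contigs=10, support=50, contig_len=10_000, lib="lib",
               insert=3000):
    """Edges linking a clean contig path ctg0 -R..L- ctg1 ... in order."""
    rows = []
    for i in range(n_contigs - 1):
        rows += [(f"c{i:02d}", contig_len - 200, "+",
                  f"c{i + 1:02d}", 150, "-")] * support
    lengths = {f"c{i:02d}": contig_len for i in range(n_contigs)}
    return build_link_graph([(lib, insert, mapped_frame(rows))], lengths), \
        lengths


class TestGreedyScaffold:
    def test_clean_path_reconstructed(self):
        graph, lengths = path_graph()
        sset = greedy_scaffold(graph)
        assert sset.n_scaffolds == 1
        chain = sset.scaffolds[0]
        ids = [c for c, _, _ in chain]
        orients = {o for _, o, _ in chain}
        assert ids == sorted(lengths) or ids == sorted(lengths)[::-1]
        assert len(orients) == 1  # single consistent orientation

    def test_no_edges_means_no_joins(self):
        g = build_link_graph([], {"A": 1000, "B": 2000})
        sset = greedy_scaffold(g)
        assert sset.n_scaffolds == 2
        assert sset.n50 == 2000

    def test_chimeric_edge_loses_to_supported_edge(self):
        rows = [("A", 900, "+", "B", 50, "-")] * 50 + \
               [("A", 950, "+", "C", 60, "-")] * 2
        g = build_link_graph([("lib", 3000, mapped_frame(rows))],
                             {"A": 1000, "B": 1000, "C": 1000}, min_support=2)
        sset = greedy_scaffold(g, ratio=0.7)
        joined = {frozenset((a, b)) for a, _, b, _ in sset.joins()}
        assert frozenset(("A", "B")) in joined
        assert frozenset(("A", "C")) not in joined

    def test_balanced_conflict_is_ambiguous(self):
        rows = [("A", 900, "+", "B", 50, "-")] * 10 + \
               [("A", 950, "+", "C", 60, "-")] * 9
        g = build_link_graph([("lib", 3000, mapped_frame(rows))],
                             {"A": 1000, "B": 1000, "C": 1000}, min_support=2)
        sset = greedy_scaffold(g, ratio=0.7)
        assert sset.joins() == []

    def test_contig_conservation(self):
        graph, lengths = path_graph(n_contigs=8)
        sset = greedy_scaffold(graph)
        seen = [c for chain in sset.scaffolds for c, _, _ in chain]
        assert sorted(seen) == sorted(lengths)

    def test_orientation_flip_resolved(self):
        # B's left end faces A's right end via B's reverse-strand geometry:
        # tag on '+' strand in B links B's right end, so B must be flipped
        rows = [("A", 900, "+", "B", 900, "+")] * 20
        g = build_link_graph([("lib", 3000, mapped_frame(rows))],
                             {"A": 1000, "B": 1000}, min_support=5)
        sset = greedy_scaffold(g)
        chain = sset.scaffolds[0]
        orients = {c: o for c, o, _ in chain}
        assert orients["A"] != orients["B"]


class TestEvaluateAgainstTruth:
    def _layout(self, n, contig_len=1000):
        contigs = pd.DataFrame({
            "contig_id": [f"c{i:02d}" for i in range(n)],
            "chrom": "chr1",
            "start": [i * (contig_len + 10) for i in range(n)],
            "end": [i * (contig_len + 10) + contig_len for i in range(n)],
            "orientation": "+", "rank": range(n)})
        return mp.ContigLayout(contigs=contigs,
                               gaps=np.full(n - 1, 10, dtype=np.int64),
                               genome_length=n * (contig_len + 10) - 10)

    def _scaffold(self, chains, contig_len=1000):
        lengths = pd.Series({c: contig_len for ch in chains for c, _, _ in ch})
        return mp.ScaffoldSet(scaffolds=[list(ch) for ch in chains],
                              contig_lengths=lengths)

    def test_perfect_reconstruction(self):
        layout = self._layout(4)
        ss = self._scaffold([[("c00", 1, 10), ("c01", 1, 10),
                              ("c02", 1, 10), ("c03", 1, 0)]])
        ev = mp.evaluate_against_truth(ss, layout)
        assert (ev.correct_joins, ev.misjoins, ev.orientation_errors,
                ev.missed_joins) == (3, 0, 0, 0)

    def test_mirrored_scaffold_is_still_correct(self):
        layout = self._layout(3)
        ss = self._scaffold([[("c02", -1, 10), ("c01", -1, 10), ("c00", -1, 0)]])
        ev = mp.evaluate_against_truth(ss, layout)
        assert ev.correct_joins == 2 and ev.misjoins == 0

    def test_random_pairing_counts_as_misjoins(self):
        layout = self._layout(6)
        ss = self._scaffold([[("c00", 1, 10), ("c03", 1, 10), ("c01", 1, 0)],
                             [("c05", 1, 10), ("c02", 1, 0)], [("c04", 1, 0)]])
        ev = mp.evaluate_against_truth(ss, layout)
        assert ev.correct_joins == 0
        assert ev.misjoins == 3
        assert ev.missed_joins == 5

    def test_single_terminal_flip_is_one_orientation_error(self):
        layout = self._layout(3)
        ss = self._scaffold([[("c00", 1, 10), ("c01", 1, 10), ("c02", -1, 0)]])
        ev = mp.evaluate_against_truth(ss, layout)
        assert ev.orientation_errors == 1 and ev.correct_joins == 1

    def test_unknown_contig_rejected(self):
        layout = self._layout(2)
        ss = self._scaffold([[("c00", 1, 10), ("zz", 1, 0)]])
        with pytest.raises(ValueError):
            mp.evaluate_against_truth(ss, layout)


class TestErrorFreeRecovery:
    def test_twenty_random_layouts_no_misjoins(self):
        """With abundant error-free links and gaps below the insert p99, the
        greedy scaffolder reconstructs the true order with zero misjoins and
        zero orientation errors."""
        g = mp.simulate_genome(400_000, seed=80)
        spec = mp.LibrarySpec("3kb", 3000, 200, n_pairs=2000, seed=81)
        for trial in range(20):
            layout = mp.fragment_into_contigs(
                g, 25, gap_model={"mean_gap": 300}, seed=trial,
                min_contig=4000)
            ps = mp.simulate_library(g, mp.LibrarySpec(
                "3kb", 3000, 200, n_pairs=2000, seed=200 + trial))
            lib = prepare_library(ps, layout)
            graph = build_link_graph([lib], layout.contig_lengths(),
                                     min_support=3)
            sset = greedy_scaffold(graph)
            ev = mp.evaluate_against_truth(sset, layout)
            assert ev.misjoins == 0, trial
            assert ev.orientation_errors == 0, trial


@pytest.fixture(scope="module")
def small_world():
    g = mp.simulate_genome(2_000_000, seed=90)
    layout = mp.fragment_into_contigs(g, 150, gap_model={"mean_gap": 200},
                                      seed=91, min_contig=4000)
    libs = []
    for i, (name, insert) in enumerate([("3kb", 3000), ("8kb", 8000),
                                        ("20kb", 20_000)]):
        spec = mp.LibrarySpec(name, insert, 0.1 * insert,
                              n_pairs=int(12 * 2e6 / insert),
                              seed=92 + i)
        libs.append(mp.simulate_library(g, spec))
    return g, layout, libs


class TestCombinationSweep:
    def test_combination_with_itself_is_idempotent(self, small_world):
        _, layout, libs = small_world
        single = mp.combination_sweep(libs[:1], layout, target_coverage=8.5,
                                      subsets=[["3kb"]], seed=1)
        doubled = mp.combination_sweep(libs[:1], layout, target_coverage=8.5,
                                       subsets=[["3kb", "3kb"]], seed=1)
        assert single.loc[0, "n_scaffolds"] == doubled.loc[0, "n_scaffolds"]
        assert single.loc[0, "n50"] == doubled.loc[0, "n50"]

    def test_adding_a_larger_library_never_hurts(self, small_world):
        """Joining is monotone: appending a larger-insert library can only
        merge chains, so N50 never decreases."""
        _, layout, libs = small_world
        table = mp.combination_sweep(
            libs, layout, target_coverage=8.5,
            subsets=[["3kb"], ["3kb", "8kb"], ["3kb", "8kb", "20kb"]], seed=2)
        t = table.set_index("combination")
        assert t.loc["3kb+8kb", "n50"] >= t.loc["3kb", "n50"]
        assert t.loc["3kb+8kb+20kb", "n50"] >= t.loc["3kb+8kb", "n50"]
        assert t.loc["3kb+8kb+20kb", "n_scaffolds"] <= t.loc["3kb", "n_scaffolds"]

    def test_coverage_escalation_table(self, small_world):
        _, layout, libs = small_world
        table = mp.coverage_escalation(libs[1], layout, [4.0, 8.0], seed=3)
        assert list(table["target_coverage"]) == [4.0, 8.0]
        assert (table["n_scaffolds"] > 0).all()


class TestScaffoldSequences:
    def test_sequences_concatenate_with_gaps_and_revcomp(self):
        lengths = pd.Series({"A": 4, "B": 3})
        ss = mp.ScaffoldSet(scaffolds=[[("A", 1, 2), ("B", -1, 0)]],
                            contig_lengths=lengths)
        seqs = ss.sequences({"A": "ACGT", "B": "AAC"})
        assert seqs == ["ACGTNNGTT"]
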