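"""Contig-link graph construction and greedy scaffolding.

The scaffolder emulates the SSPACE-style workflow the study relied on:
inter-contig read pairs from coverage-normalized libraries define weighted
links between contig ends; libraries are processed from the smallest to the
largest insert size; within a library, links are taken by descending support
and a join is made only when both contig ends are free, the orientations are
compatible, and no competing link of comparable support (support ratio rule)
makes the end ambiguous.  Gap sizes are estimated from the insert median
minus the tag-to-contig-end distances of the supporting pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ClassifiedPairSet, classify_pairs
from .qc import estimate_insert_distribution, normalize_to_coverage
from .synthetic import ContigLayout, PairSet


# ---------------------------------------------------------------------------
# N50
# ---------------------------------------------------------------------------

def n50(lengths: Sequence[float]) -> float:
    """Largest L such that pieces of length >= L hold at least half the bases."""
    arr = np.sort(np.asarray(list(lengths), dtype=float))[::-1]
    if arr.size == 0:
        raise ValueError("n50 of an empty length list is undefined")
    if np.any(arr <= 0):
        raise ValueError("lengths must be positive")
    csum = np.cumsum(arr)
    return float(arr[np.searchsorted(csum, csum[-1] / 2.0)])


# ---------------------------------------------------------------------------
# mapping genome-coordinate pairs onto contigs
# ---------------------------------------------------------------------------

def map_pairs_to_contigs(cset: ClassifiedPairSet, layout: ContigLayout) -> pd.DataFrame:
    """Assign each tag to the contig containing it (contig-local coordinates).

    Tags falling in gaps or overhanging a contig edge are unmapped; pairs
    with any unmapped tag are dropped (their fragment end is invisible to a
    contig-based mapper).  Adds fwd_contig/fwd_cpos/rev_contig/rev_cpos.
    """
    df = cset.pairs
    starts = layout.contigs["start"].to_numpy()
    ends = layout.contigs["end"].to_numpy()
    ids = layout.contigs["contig_id"].to_numpy()
    r = cset.read_length

    out = df.copy()
    keep = np.ones(len(df), dtype=bool)
    for side in ("fwd", "rev"):
        pos = df[f"{side}_pos"].to_numpy()
        i = np.searchsorted(starts, pos, side="right") - 1
        ic = np.clip(i, 0, len(starts) - 1)
        inside = (i >= 0) & (pos >= starts[ic]) & (pos + r <= ends[ic])
        keep &= inside
        out[f"{side}_contig"] = np.where(inside, ids[ic], "")
        out[f"{side}_cpos"] = np.where(inside, pos - starts[ic], -1)
    return out.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# link graph
# ---------------------------------------------------------------------------

@dataclass
class ScaffoldGraph:
    """Weighted links between contig ends.

    ``edges`` columns: contig_a, end_a, contig_b, end_b ('L'/'R'), library,
    support, gap_estimate (floored at ``min_gap``), raw_gap (unfloored
    median, possibly negative -- overlap candidates).  ``weak_edges`` holds
    the links below ``min_support``: they never make a join, but their raw
    tallies still take part in the best/second-best ambiguity rule, the way
    SSPACE evaluates its ratio on raw link counts before applying the
    min-links threshold.
    """

    edges: pd.DataFrame
    contig_lengths: pd.Series
    library_inserts: dict[str, float] = field(default_factory=dict)
    weak_edges: pd.DataFrame | None = None

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_link_graph(libraries: Iterable[tuple[str, float, pd.DataFrame]],
                     contig_lengths: Mapping[str, int] | pd.Series,
                     min_support: int = 5, read_length: int = 50,
                     min_gap: int = 1) -> ScaffoldGraph:
    """Aggregate inter-contig pairs into a contig-end link graph.

    ``libraries`` yields (name, insert_median, mapped_pairs) where
    mapped_pairs carries the contig columns of :func:`map_pairs_to_contigs`.
    Clonal and ambiguous pairs are excluded; each surviving pair with tags on
    two different contigs votes for one (contig end, contig end) link.  A
    tag on the forward strand points out of its contig's right end, a
    reverse-strand tag out of the left end.  One edge is kept per (contig
    pair, end pair, library) with the pair count as support; edges below
    ``min_support`` are dropped.
    """
    lengths = pd.Series(contig_lengths)
    all_edges = []
    inserts: dict[str, float] = {}
    for name, insert_median, df in libraries:
        inserts[name] = float(insert_median)
        ok = (~df["pair_class"].isin(["clonal", "ambiguous"])
              & (df["fwd_contig"] != df["rev_contig"])
              & (df["fwd_contig"] != "") & (df["rev_contig"] != ""))
        sub = df.loc[ok]
        if len(sub) == 0:
            continue
        for side in ("fwd", "rev"):
            missing = set(sub[f"{side}_contig"]) - set(lengths.index)
            if missing:
                raise ValueError(f"pairs reference contigs absent from the "
                                 f"layout: {sorted(missing)[:5]}")
        fl = lengths.loc[sub["fwd_contig"]].to_numpy()
        rl = lengths.loc[sub["rev_contig"]].to_numpy()
        f_plus = (sub["fwd_strand"] == "+").to_numpy()
        r_plus = (sub["rev_strand"] == "+").to_numpy()
        f_end = np.where(f_plus, "R", "L")
        r_end = np.where(r_plus, "R", "L")
        f_cpos = sub["fwd_cpos"].to_numpy()
        r_cpos = sub["rev_cpos"].to_numpy()
        f_dist = np.where(f_plus, fl - f_cpos, f_cpos + read_length)
        r_dist = np.where(r_plus, rl - r_cpos, r_cpos + read_length)
        gap = insert_median - f_dist - r_dist

        a = sub["fwd_contig"].to_numpy()
        b = sub["rev_contig"].to_numpy()
        swap = a > b
        edges = pd.DataFrame({
            "contig_a": np.where(swap, b, a),
            "end_a": np.where(swap, r_end, f_end),
            "contig_b": np.where(swap, a, b),
            "end_b": np.where(swap, f_end, r_end),
            "gap": gap,
        })
        agg = edges.groupby(["contig_a", "end_a", "contig_b", "end_b"],
                            observed=True).agg(
            support=("gap", "size"), raw_gap=("gap", "median")).reset_index()
        agg["library"] = name
        all_edges.append(agg)

    cols = ["contig_a", "end_a", "contig_b", "end_b", "support", "raw_gap",
            "library", "gap_estimate"]
    if all_edges:
        edges = pd.concat(all_edges, ignore_index=True)
        edges["gap_estimate"] = np.maximum(min_gap, np.round(edges["raw_gap"])
                                           ).astype(np.int64)
        strong = edges["support"] >= min_support
        weak = edges.loc[~strong].reset_index(drop=True)
        edges = edges.loc[strong].reset_index(drop=True)
    else:
        edges = pd.DataFrame(columns=cols)
        weak = pd.DataFrame(columns=cols)
    return ScaffoldGraph(edges=edges, contig_lengths=lengths,
                         library_inserts=inserts, weak_edges=weak)


# ---------------------------------------------------------------------------
# greedy scaffolding
# ---------------------------------------------------------------------------

@dataclass
class ScaffoldSet:
    """Ordered, oriented contigs with estimated gaps.

    ``scaffolds`` is a list of chains; each chain element is
    (contig_id, orientation (+1/-1), gap_after) with gap_after = 0 for the
    last contig of a chain.
    """

    scaffolds: list[list[tuple[str, int, int]]]
    contig_lengths: pd.Series

    @property
    def n_scaffolds(self) -> int:
        return len(self.scaffolds)

    def spans(self) -> np.ndarray:
        out = []
        for chain in self.scaffolds:
            s = sum(int(self.contig_lengths[c]) for c, _, _ in chain)
            s += sum(g for _, _, g in chain[:-1])
            out.append(s)
        return np.asarray(out, dtype=np.int64)

    @property
    def total_span(self) -> int:
        return int(self.spans().sum())

    @property
    def n50(self) -> float:
        return n50(self.spans())

    def joins(self) -> list[tuple[str, int, str, int]]:
        """All adjacent (contig, orient, contig, orient) junctions made."""
        out = []
        for chain in self.scaffolds:
            for (c1, o1, _), (c2, o2, _) in zip(chain, chain[1:]):
                out.append((c1, o1, c2, o2))
        return out

    def sequences(self, contig_seqs: Mapping[str, str]) -> list[str]:
        """Scaffold sequences with estimated gaps filled with N."""
        comp = str.maketrans("ACGTN", "TGCAN")
        seqs = []
        for chain in self.scaffolds:
            parts = []
            for i, (c, o, gap) in enumerate(chain):
                s = contig_seqs[c]
                parts.append(s if o == 1 else s.translate(comp)[::-1])
                if i < len(chain) - 1:
                    parts.append("N" * gap)
            seqs.append("".join(parts))
        return seqs

    def write_agp(self, path) -> None:
        rows = []
        for si, chain in enumerate(self.scaffolds):
            pos = 0
            for i, (c, o, gap) in enumerate(chain):
                ln = int(self.contig_lengths[c])
                rows.append((f"scaffold{si:05d}", pos, pos + ln, c,
                             "+" if o == 1 else "-", i))
                pos += ln + (gap if i < len(chain) - 1 else 0)
        pd.DataFrame(rows, columns=["scaffold_id", "start", "end", "contig_id",
                                    "orientation", "rank"]
                     ).to_csv(path, sep="\t", index=False)


class _Chains:
    """Mutable scaffold chains with end bookkeeping."""

    def __init__(self, contigs: Iterable[str]):
        self.chain_of: dict[str, int] = {}
        self.chains: dict[int, list[list]] = {}  # [contig, orient, gap_after]
        for i, c in enumerate(contigs):
            self.chain_of[c] = i
            self.chains[i] = [[c, 1, 0]]

    def outer_end(self, chain: list, left: bool) -> tuple[str, str]:
        c, o, _ = chain[0] if left else chain[-1]
        if left:
            return c, ("L" if o == 1 else "R")
        return c, ("R" if o == 1 else "L")

    def _reverse(self, chain: list) -> list:
        rev = []
        for i in range(len(chain) - 1, -1, -1):
            c, o, _ = chain[i]
            gap = chain[i - 1][2] if i > 0 else 0
            rev.append([c, -o, gap])
        return rev

    def join(self, ca: str, ea: str, cb: str, eb: str, gap: int) -> None:
        ia, ib = self.chain_of[ca], self.chain_of[cb]
        A, B = self.chains[ia], self.chains[ib]
        # orient A so that (ca, ea) is its right outer end
        if self.outer_end(A, left=False) != (ca, ea):
            A = self._reverse(A)
            assert self.outer_end(A, left=False) == (ca, ea)
        if self.outer_end(B, left=True) != (cb, eb):
            B = self._reverse(B)
            assert self.outer_end(B, left=True) == (cb, eb)
        A[-1][2] = gap
        merged = A + B
        self.chains[ia] = merged
        del self.chains[ib]
        for c, _, _ in B:
            self.chain_of[c] = ia

    def free_end(self, c: str, e: str) -> bool:
        chain = self.chains[self.chain_of[c]]
        return self.outer_end(chain, True) == (c, e) or \
            self.outer_end(chain, False) == (c, e)


def greedy_scaffold(graph: ScaffoldGraph,
                    library_order: Sequence[str] | None = None,
                    ratio: float = 0.7) -> ScaffoldSet:
    """Greedy end-joining over libraries from smallest to largest insert.

    Within a library, edges are processed by descending support (ties broken
    lexicographically on contig ids/ends, so the output is deterministic).
    An edge joins two chains iff both of its contig ends are currently free
    outer ends of different chains; an edge is skipped as ambiguous when a
    competing link at either of its ends, leading to a different partner
    end, has raw support >= ratio * the candidate's support (the
    SSPACE-style best/second-best rule that keeps repeat-induced chimeric
    links out).  Competing tallies are aggregated over the current and all
    smaller-insert libraries, and include sub-threshold links: several
    libraries agreeing weakly on an adjacency are enough to veto a
    long-range link that would leapfrog it.
    """
    if library_order is None:
        library_order = sorted(graph.library_inserts,
                               key=lambda k: graph.library_inserts[k])
    chains = _Chains(graph.contig_lengths.index)
    used_ends: set[tuple[str, str]] = set()
    # cumulative raw link tallies per (end, partner end), grown library by
    # library so a pass only sees itself and the smaller inserts
    tally: dict[tuple[str, str], dict[tuple[str, str], int]] = {}

    def _accumulate(frame: pd.DataFrame) -> None:
        for row in frame.itertuples(index=False):
            ka, kb = (row.contig_a, row.end_a), (row.contig_b, row.end_b)
            s = int(row.support)
            tally.setdefault(ka, {})[kb] = tally.get(ka, {}).get(kb, 0) + s
            tally.setdefault(kb, {})[ka] = tally.get(kb, {}).get(ka, 0) + s

    for lib in library_order:
        edges = graph.edges[graph.edges["library"] == lib]
        _accumulate(edges)
        if graph.weak_edges is not None and len(graph.weak_edges):
            _accumulate(graph.weak_edges[graph.weak_edges["library"] == lib])
        if len(edges) == 0:
            continue
        edges = edges.sort_values(["support", "contig_a", "end_a",
                                   "contig_b", "end_b"],
                                  ascending=[False, True, True, True, True])

        for row in edges.itertuples(index=False):
            ka, kb = (row.contig_a, row.end_a), (row.contig_b, row.end_b)
            if ka == kb:
                continue
            if ka in used_ends or kb in used_ends:
                continue
            if chains.chain_of[row.contig_a] == chains.chain_of[row.contig_b]:
                continue  # would close a cycle
            if not (chains.free_end(*ka) and chains.free_end(*kb)):
                continue
            support = int(row.support)
            ambiguous = False
            for this_end, partner in ((ka, kb), (kb, ka)):
                for other_partner, other_support in tally.get(this_end, {}).items():
                    if other_partner != partner and \
                            other_support >= ratio * support:
                        ambiguous = True
                        break
                if ambiguous:
                    break
            if ambiguous:
                continue
            chains.join(row.contig_a, row.end_a, row.contig_b, row.end_b,
                        int(row.gap_estimate))
            used_ends.add(ka)
            used_ends.add(kb)

    scaffolds = [[(c, o, g) for c, o, g in chain]
                 for _, chain in sorted(chains.chains.items())]
    return ScaffoldSet(scaffolds=scaffolds, contig_lengths=graph.contig_lengths)


# ---------------------------------------------------------------------------
# truth evaluation
# ---------------------------------------------------------------------------

@dataclass
class TruthEvaluation:
    correct_joins: int
    misjoins: int
    orientation_errors: int
    missed_joins: int


def evaluate_against_truth(scaffolds: ScaffoldSet,
                           layout: ContigLayout) -> TruthEvaluation:
    """Score made joins against the true contig order of the layout.

    A join is correct iff its two contigs are adjacent in truth order and
    traversed with compatible orientations; adjacency with incompatible
    orientations is an orientation error; anything else is a misjoin.
    Missed joins are true adjacencies realized by no scaffold.
    """
    rank = dict(zip(layout.contigs["contig_id"], layout.contigs["rank"]))
    correct = misjoin = orient_err = 0
    realized = set()
    for c1, o1, c2, o2 in scaffolds.joins():
        if c1 not in rank or c2 not in rank:
            raise ValueError("scaffold contig not present in truth layout")
        r1, r2 = rank[c1], rank[c2]
        if abs(r1 - r2) != 1:
            misjoin += 1
            continue
        # truth orientation is '+', so a forward traversal needs o1 == o2 ==
        # +1 with r2 == r1 + 1, and the mirrored traversal o1 == o2 == -1
        if o1 == o2 and ((o1 == 1 and r2 == r1 + 1) or (o1 == -1 and r2 == r1 - 1)):
            correct += 1
            realized.add(frozenset((c1, c2)))
        else:
            orient_err += 1
    missed = (layout.n_contigs - 1) - len(realized)
    return TruthEvaluation(correct_joins=correct, misjoins=misjoin,
                           orientation_errors=orient_err, missed_joins=missed)


# ---------------------------------------------------------------------------
# combination sweep
# ---------------------------------------------------------------------------

def prepare_library(pairset: PairSet, layout: ContigLayout,
                    target_coverage: float | None = None,
                    seed: int = 0) -> tuple[str, float, pd.DataFrame]:
    """Classify, optionally normalize, and map one library onto contigs."""
    stats = estimate_insert_distribution(pairset)
    cset = classify_pairs(pairset, stats.bounds)
    if target_coverage is not None:
        cset = normalize_to_coverage(cset, target_coverage, seed=seed,
                                     insert_stats=stats)
    mapped = map_pairs_to_contigs(cset, layout)
    insert = pairset.spec.insert_median if pairset.spec else stats.median
    return (pairset.name, float(insert), mapped)


def combination_sweep(libraries: Sequence[PairSet], layout: ContigLayout,
                      target_coverage: float = 8.5,
                      subsets: Sequence[Sequence[str]] | None = None,
                      seed: int = 0, min_support: int = 5, ratio: float = 0.7
                      ) -> pd.DataFrame:
    """Scaffold every requested library combination from the same contig set.

    Each library is independently normalized to ``target_coverage`` before
    use, so combinations compare information content at equal physical
    coverage.  ``subsets`` defaults to all non-empty combinations of the
    library names.  Returns a table (combination, n_libraries, n_scaffolds,
    n50) sorted by N50 descending.
    """
    prepared = {}
    for i, ps in enumerate(libraries):
        prepared[ps.name] = prepare_library(ps, layout, target_coverage,
                                            seed=seed + i)
    names = list(prepared)
    if subsets is None:
        subsets = [combo for k in range(1, len(names) + 1)
                   for combo in itertools.combinations(names, k)]
    lengths = layout.contig_lengths()
    rows = []
    for combo in subsets:
        combo = list(dict.fromkeys(combo))  # dedupe, keep order
        graph = build_link_graph([prepared[n] for n in combo], lengths,
                                 min_support=min_support)
        sset = greedy_scaffold(graph, ratio=ratio)
        rows.append(("+".join(combo), len(combo), sset.n_scaffolds, sset.n50))
    return pd.DataFrame(rows, columns=["combination", "n_libraries",
                                       "n_scaffolds", "n50"]
                        ).sort_values("n50", ascending=False,
                                      ignore_index=True)


def coverage_escalation(pairset: PairSet, layout: ContigLayout,
                        coverages: Sequence[float], seed: int = 0,
                        min_support: int = 5, ratio: float = 0.7) -> pd.DataFrame:
    """Single-library scaffolding at rising physical coverage."""
    lengths = layout.contig_lengths()
    rows = []
    for i, cov in enumerate(coverages):
        lib = prepare_library(pairset, layout, cov, seed=seed + i)
        graph = build_link_graph([lib], lengths, min_support=min_support)
        sset = greedy_scaffold(graph, ratio=ratio)
        rows.append((pairset.name, cov, sset.n_scaffolds, sset.n50))
    return pd.DataFrame(rows, columns=["library", "target_coverage",
                                       "n_scaffolds", "n50"])
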