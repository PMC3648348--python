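"""Restriction-map concordance: in-silico digests vs optical-map-like data.

Optical mapping measures the ordered SwaI restriction-fragment lengths of
stretched genomic DNA molecules; comparing them with the in-silico digest of
an assembly validates (or refutes) the assembly's long-range structure.
This module digests sequences in silico, simulates the noise of an optical
measurement (missed cuts, false cuts, sizing error, small-fragment loss),
aligns two ordered fragment-length maps by dynamic programming, and tallies
windowed inconsistencies between two scaffold arrangements of the same
contigs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scaffold import ScaffoldSet

#: SwaI recognition site; palindromic and blunt-cutting at its center
#: (ATTT^AAAT), so the cut coordinate is site_start + 4 on either strand.
SWAI_SITE = "ATTTAAAT"


@dataclass
class RestrictionMap:
    """Ordered fragment lengths of one digested sequence."""

    fragments: np.ndarray
    source: str = "in_silico"  # or "simulated_optical"
    site: str = SWAI_SITE

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def total(self) -> int:
        return int(np.sum(self.fragments))

    def write_tsv(self, path) -> None:
        pd.DataFrame({"index": np.arange(len(self.fragments)),
                      "length": self.fragments}).to_csv(path, sep="\t",
                                                        index=False)

    @classmethod
    def read_tsv(cls, path, source: str = "in_silico") -> "RestrictionMap":
        df = pd.read_csv(path, sep="\t")
        return cls(fragments=df["length"].to_numpy(dtype=np.int64),
                   source=source)


_COMP = str.maketrans("ACGTN", "TGCAN")


def _site_cut_positions(sequence: str, site: str) -> np.ndarray:
    """Cut coordinates (center of the site) on both strands; N never matches."""
    cuts = set()
    offset = len(site) // 2
    for probe in {site.upper(), site.upper().translate(_COMP)[::-1]}:
        start = sequence.find(probe)
        while start != -1:
            cuts.add(start + offset)
            start = sequence.find(probe, start + 1)
    return np.array(sorted(cuts), dtype=np.int64)


def in_silico_digest(sequence: str, site: str = SWAI_SITE) -> RestrictionMap:
    """Digest a nucleotide sequence, fragments between successive cut sites.

    The cut position is the blunt center of the recognition site; both
    strands are searched (a no-op for palindromic sites such as SwaI).
    Fragment lengths always sum to the sequence length.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    seq = sequence.upper()
    cuts = _site_cut_positions(seq, site)
    bounds = np.concatenate(([0], cuts, [len(seq)]))
    frags = np.diff(bounds)
    return RestrictionMap(fragments=frags[frags > 0], source="in_silico",
                          site=site)


def simulate_optical_map(rmap: RestrictionMap, sizing_cv: float = 0.05,
                         miss_rate: float = 0.10, false_cut_rate: float = 0.0,
                         min_detectable: int = 2000,
                         seed: int = 0) -> RestrictionMap:
    """Add optical-measurement noise to a restriction map.

    Each true cut is retained with probability 1 - ``miss_rate`` (a missed
    cut merges neighbouring fragments); false cuts arrive as a Poisson
    process with ``false_cut_rate`` per bp; fragment sizes are perturbed by a
    multiplicative Normal(1, ``sizing_cv``) factor; fragments below
    ``min_detectable`` bp are not resolved and are dropped.
    """
    for name, rate in (("miss_rate", miss_rate),
                       ("false_cut_rate", false_cut_rate)):
        if not 0 <= rate < 1:
            raise ValueError(f"{name} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    total = rmap.total
    cuts = np.cumsum(rmap.fragments)[:-1]
    cuts = cuts[rng.random(len(cuts)) >= miss_rate]
    n_false = rng.poisson(false_cut_rate * total)
    if n_false:
        cuts = np.concatenate([cuts, rng.integers(1, total, size=n_false)])
    cuts = np.unique(cuts)
    frags = np.diff(np.concatenate(([0], cuts, [total]))).astype(float)
    frags = frags[frags > 0]
    if sizing_cv > 0:
        frags = frags * rng.normal(1.0, sizing_cv, size=len(frags))
    frags = np.maximum(1, np.round(frags)).astype(np.int64)
    frags = frags[frags >= min_detectable]
    return RestrictionMap(fragments=frags, source="simulated_optical",
                          site=rmap.site)


# ---------------------------------------------------------------------------
# ordered map alignment
# ---------------------------------------------------------------------------

@dataclass
class MapAlignment:
    """Blocks of matched consecutive fragments between two ordered maps.

    Each block is (a_start, a_end, b_start, b_end, size_difference) in
    fragment indices (half-open).  ``concordant_fraction`` is the matched
    fragment bp of map A over A's total bp.
    """

    blocks: list[tuple[int, int, int, int, int]]
    score: float
    matched_bp_a: int
    total_bp_a: int

    @property
    def concordant_fraction(self) -> float:
        return self.matched_bp_a / self.total_bp_a if self.total_bp_a else 0.0


def align_maps(a: RestrictionMap, b: RestrictionMap,
               size_tolerance_rel: float = 0.05, max_merge: int = 3,
               skip_penalty: float = 0.5) -> MapAlignment:
    """Global ordered alignment of two restriction maps.

    Dynamic programming where a block matches k <= ``max_merge`` consecutive
    fragments of A against m <= ``max_merge`` of B iff their summed lengths
    agree within ``size_tolerance_rel`` (relative to the larger sum) --
    merged blocks absorb missed/extra cuts.  The score is the matched bp of A
    minus ``skip_penalty`` per skipped bp on either map; the traceback yields
    the matched blocks.
    """
    fa = np.asarray(a.fragments, dtype=np.int64)
    fb = np.asarray(b.fragments, dtype=np.int64)
    if len(fa) == 0 or len(fb) == 0:
        raise ValueError("cannot align an empty restriction map")
    pa = np.concatenate(([0], np.cumsum(fa)))
    pb = np.concatenate(([0], np.cumsum(fb)))
    n, m = len(fa), len(fb)

    NEG = -1e18
    dp = np.full((n + 1, m + 1), NEG)
    dp[0, 0] = 0.0
    move = {}
    for i in range(n + 1):
        for j in range(m + 1):
            if i == j == 0:
                continue
            best = NEG
            arg = None
            if i > 0 and dp[i - 1, j] - skip_penalty * fa[i - 1] > best:
                best = dp[i - 1, j] - skip_penalty * fa[i - 1]
                arg = ("skip_a", 1, 0)
            if j > 0 and dp[i, j - 1] - skip_penalty * fb[j - 1] > best:
                best = dp[i, j - 1] - skip_penalty * fb[j - 1]
                arg = ("skip_b", 0, 1)
            for k in range(1, min(max_merge, i) + 1):
                sa = pa[i] - pa[i - k]
                for mm in range(1, min(max_merge, j) + 1):
                    sb = pb[j] - pb[j - mm]
                    if abs(int(sa) - int(sb)) <= size_tolerance_rel * max(sa, sb):
                        cand = dp[i - k, j - mm] + sa
                        if cand > best:
                            best = cand
                            arg = ("match", k, mm)
            dp[i, j] = best
            move[(i, j)] = arg

    blocks = []
    matched = 0
    i, j = n, m
    while (i, j) != (0, 0):
        kind, di, dj = move[(i, j)]
        if kind == "match":
            sa = int(pa[i] - pa[i - di])
            sb = int(pb[j] - pb[j - dj])
            blocks.append((i - di, i, j - dj, j, sa - sb))
            matched += sa
        i, j = i - di, j - dj
    blocks.reverse()
    return MapAlignment(blocks=blocks, score=float(dp[n, m]),
                        matched_bp_a=matched, total_bp_a=int(pa[-1]))


# ---------------------------------------------------------------------------
# windowed inconsistency between two scaffold arrangements
# ---------------------------------------------------------------------------

@dataclass
class WindowInconsistencyReport:
    """Per-window counts of inconsistent contig links between arrangements."""

    window: int
    per_window: pd.DataFrame  # window_start, within_scaffold, between_scaffold
    within_total: int
    between_total: int

    @property
    def affected_windows(self) -> int:
        pw = self.per_window
        return int(((pw["within_scaffold"] > 0) | (pw["between_scaffold"] > 0)).sum())


def window_inconsistency(arrangement_a: ScaffoldSet, arrangement_b: ScaffoldSet,
                         window: int = 100_000) -> WindowInconsistencyReport:
    """Classify every contig junction of arrangement B against arrangement A.

    Arrangement A provides the reference coordinate frame (its scaffolds laid
    end to end).  A junction of B is consistent when its two contigs are also
    adjacent in A, in the same order and relative orientation; otherwise it
    is an inconsistent link, attributed to the reference window containing
    the junction midpoint and split by whether both contigs share one
    A-scaffold (within) or not (between).  A link is counted once globally
    even if the pair of contigs meets twice.
    """
    set_a = {c for ch in arrangement_a.scaffolds for c, _, _ in ch}
    set_b = {c for ch in arrangement_b.scaffolds for c, _, _ in ch}
    if set_a != set_b:
        raise ValueError("arrangements cover different contig sets")

    # reference frame from A
    ref_start: dict[str, int] = {}
    ref_orient: dict[str, int] = {}
    ref_scaffold: dict[str, int] = {}
    succ: dict[str, tuple[str, int, int]] = {}  # contig -> (next, o_self, o_next)
    pos = 0
    for si, chain in enumerate(arrangement_a.scaffolds):
        for i, (c, o, gap) in enumerate(chain):
            ref_start[c] = pos
            ref_orient[c] = o
            ref_scaffold[c] = si
            pos += int(arrangement_a.contig_lengths[c])
            if i < len(chain) - 1:
                succ[c] = (chain[i + 1][0], o, chain[i + 1][1])
                pos += gap

    length_of = arrangement_a.contig_lengths
    total = pos
    n_windows = max(1, -(-total // window))
    within = np.zeros(n_windows, dtype=np.int64)
    between = np.zeros(n_windows, dtype=np.int64)
    seen: set[frozenset] = set()

    for c1, o1, c2, o2 in arrangement_b.joins():
        # is this junction present in A with the same relative geometry?
        consistent = False
        if c1 in succ and succ[c1][0] == c2:
            oa1, oa2 = succ[c1][1], succ[c1][2]
            consistent = (o1 * oa1 == o2 * oa2) and (o1 * oa1 == 1)
        if c2 in succ and succ[c2][0] == c1:
            oa2, oa1 = succ[c2][1], succ[c2][2]
            consistent = consistent or ((o1 * oa1 == o2 * oa2) and (o1 * oa1 == -1))
        if consistent:
            continue
        key = frozenset((c1, c2))
        if key in seen:
            continue
        seen.add(key)
        # junction midpoint in reference coordinates: the two facing contig
        # ends of the B-junction, each mapped through A's frame
        e1 = "R" if o1 == 1 else "L"
        e2 = "L" if o2 == 1 else "R"

        def _ref_pos(c, e):
            local = int(length_of[c]) if (e == "R") == (ref_orient[c] == 1) else 0
            return ref_start[c] + local

        mid = (_ref_pos(c1, e1) + _ref_pos(c2, e2)) // 2
        w = min(n_windows - 1, mid // window)
        if ref_scaffold[c1] == ref_scaffold[c2]:
            within[w] += 1
        else:
            between[w] += 1

    per_window = pd.DataFrame({
        "window_start": np.arange(n_windows, dtype=np.int64) * window,
        "within_scaffold": within,
        "between_scaffold": between,
    })
    return WindowInconsistencyReport(window=window, per_window=per_window,
                                     within_total=int(within.sum()),
                                     between_total=int(between.sum()))
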