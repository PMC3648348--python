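"""Read-pair filtering: duplicate marking, uniqueness, orientation classes.

The classification mirrors the standard mate-pair QC cascade: pairs with
identical mapping coordinates of both tags are clonal (PCR duplicates) and
one representative per coordinate signature is kept; pairs with a non-unique
tag are ambiguous and never enter coverage or scaffolding; the remainder are
classified by tag orientation and distance into consistent, remote, inverted
or everted.  Inconsistent pairs can be clustered to separate recurrent
signals (misassemblies, structural differences) from stochastic chimeras,
which are supported by a single pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import MAX_SPAN, PairSet

PAIR_CLASSES = ("consistent", "clonal", "remote", "inverted", "everted", "ambiguous")

_SIGNATURE = ["fwd_chrom", "fwd_pos", "fwd_strand", "rev_chrom", "rev_pos", "rev_strand"]


@dataclass
class ClassifiedPairSet:
    """Pairs with a ``pair_class`` column and the bounds used for consistency."""

    pairs: pd.DataFrame
    insert_bounds: tuple[float, float] | None
    genome_length: int
    read_length: int
    name: str = "library"

    def __len__(self) -> int:
        return len(self.pairs)

    def counts(self) -> dict[str, int]:
        c = self.pairs["pair_class"].value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in PAIR_CLASSES}

    def fraction(self, pair_class: str) -> float:
        return self.counts()[pair_class] / max(1, len(self.pairs))

    def subset(self, mask: np.ndarray) -> "ClassifiedPairSet":
        return ClassifiedPairSet(pairs=self.pairs.loc[mask].reset_index(drop=True),
                                 insert_bounds=self.insert_bounds,
                                 genome_length=self.genome_length,
                                 read_length=self.read_length, name=self.name)

    def write_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)


def _as_frame(pairs) -> tuple[pd.DataFrame, int, int, str]:
    if isinstance(pairs, ClassifiedPairSet):
        return pairs.pairs.copy(), pairs.genome_length, pairs.read_length, pairs.name
    if isinstance(pairs, PairSet):
        return pairs.pairs.copy(), pairs.genome_length, pairs.read_length, pairs.name
    return pairs.copy(), 0, 50, "library"


def pair_geometry(df: pd.DataFrame, read_length: int) -> pd.DataFrame:
    """Outer span and left/right tag layout of each pair (same-chrom only).

    Adds columns: same_chrom, left_pos, right_pos, left_strand, right_strand,
    span (outer extent: rightmost tag end minus leftmost tag start).
    """
    out = pd.DataFrame(index=df.index)
    out["same_chrom"] = (df["fwd_chrom"] == df["rev_chrom"]).to_numpy()
    fwd_first = df["fwd_pos"].to_numpy() <= df["rev_pos"].to_numpy()
    out["left_pos"] = np.where(fwd_first, df["fwd_pos"], df["rev_pos"])
    out["right_pos"] = np.where(fwd_first, df["rev_pos"], df["fwd_pos"])
    out["left_strand"] = np.where(fwd_first, df["fwd_strand"], df["rev_strand"])
    out["right_strand"] = np.where(fwd_first, df["rev_strand"], df["fwd_strand"])
    out["span"] = out["right_pos"] + read_length - out["left_pos"]
    return out


def mark_duplicates(pairs) -> ClassifiedPairSet:
    """Mark clonal pairs, keeping one representative per coordinate signature.

    A pair is clonal when another pair has exactly the same mapping
    coordinates and strands of both tags.  Which physical record survives is
    irrelevant (they are coordinate-identical); exactly one per signature is
    left unmarked regardless of input order.
    """
    df, genome_length, read_length, name = _as_frame(pairs)
    dup = df.duplicated(subset=_SIGNATURE, keep="first").to_numpy()
    df["pair_class"] = np.where(dup, "clonal", "unclassified")
    return ClassifiedPairSet(pairs=df, insert_bounds=None,
                             genome_length=genome_length,
                             read_length=read_length, name=name)


def classify_pairs(pairs, insert_bounds: tuple[float, float],
                   max_distance: int = MAX_SPAN) -> ClassifiedPairSet:
    """Assign each pair to one of the six mutually exclusive classes.

    Order of precedence: clonal (duplicate coordinates), then ambiguous (any
    non-unique tag), then the orientation/distance classes.  A consistent
    pair has facing-in tags on the same chromosome with an outer span inside
    ``insert_bounds``; a facing-in pair violating span or chromosome is
    remote; one flipped tag is inverted; facing-out tags (wrong tag order)
    are everted.
    """
    low, high = insert_bounds
    if not low < high:
        raise ValueError("insert_bounds must satisfy low < high")
    if high > max_distance:
        raise ValueError(
            f"insert_bounds ({low}, {high}) wider than max_distance {max_distance}")

    cset = pairs if isinstance(pairs, ClassifiedPairSet) and \
        "pair_class" in pairs.pairs.columns else mark_duplicates(pairs)
    df = cset.pairs.copy()
    r = cset.read_length

    geo = pair_geometry(df, r)
    clonal = (df["pair_class"] == "clonal").to_numpy()
    ambiguous = ~(df["fwd_unique"].to_numpy() & df["rev_unique"].to_numpy())

    same = geo["same_chrom"].to_numpy()
    ls = geo["left_strand"].to_numpy()
    rs = geo["right_strand"].to_numpy()
    span = geo["span"].to_numpy()
    # same-chromosome orientation patterns (left tag, right tag)
    facing_in = (ls == "+") & (rs == "-")
    facing_out = (ls == "-") & (rs == "+")
    # across chromosomes tag order is undefined; use the expected fwd/rev
    # strand convention instead
    fs = df["fwd_strand"].to_numpy()
    vs = df["rev_strand"].to_numpy()
    diff_expected = (fs == "+") & (vs == "-")
    diff_everted = (fs == "-") & (vs == "+")

    in_bounds = (span >= low) & (span <= high)
    cls = np.full(len(df), "remote", dtype=object)
    cls[same & facing_in & in_bounds] = "consistent"
    cls[same & facing_out] = "everted"
    cls[same & ~facing_in & ~facing_out] = "inverted"
    cls[~same & diff_everted] = "everted"
    cls[~same & ~diff_expected & ~diff_everted] = "inverted"
    cls[ambiguous] = "ambiguous"
    cls[clonal] = "clonal"

    df["pair_class"] = cls
    df["span"] = np.where(same, span, -1)
    return ClassifiedPairSet(pairs=df, insert_bounds=(float(low), float(high)),
                             genome_length=cset.genome_length,
                             read_length=r, name=cset.name)


# ---------------------------------------------------------------------------
# clustering of inconsistent pairs
# ---------------------------------------------------------------------------

@dataclass
class InconsistentCluster:
    pair_ids: list[int]
    type: str
    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    inter_chromosomal: bool

    @property
    def support(self) -> int:
        return len(self.pair_ids)


@dataclass
class ClusterResult:
    clusters: list[InconsistentCluster]
    n_inconsistent: int
    clustered_fraction: float
    interchromosomal_clustered_fraction: float

    def write_bedpe(self, path) -> None:
        rows = [(c.chrom1, c.start1, c.end1, c.chrom2, c.start2, c.end2,
                 c.type, c.support) for c in self.clusters]
        pd.DataFrame(rows, columns=["chrom1", "start1", "end1", "chrom2",
                                    "start2", "end2", "type", "support"]
                     ).to_csv(path, sep="\t", index=False)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def cluster_inconsistent(cset: ClassifiedPairSet, min_support: int = 2,
                         max_gap: int | None = None) -> ClusterResult:
    """Single-linkage clustering of remote/inverted/everted pairs.

    Two pairs belong to one cluster iff they have the same type and both
    their forward-tag intervals and their reverse-tag intervals lie within
    ``max_gap`` of each other (single linkage on both breakpoint sides).
    ``max_gap`` defaults to the library insert median, approximated by the
    midpoint of the consistency bounds.  Clusters below ``min_support``
    members are dropped.
    """
    if min_support < 2:
        raise ValueError("min_support must be >= 2")
    if max_gap is None:
        if cset.insert_bounds is None:
            raise ValueError("max_gap required when insert_bounds are unknown")
        max_gap = int((cset.insert_bounds[0] + cset.insert_bounds[1]) / 2)

    r = cset.read_length
    df = cset.pairs
    inco = df[df["pair_class"].isin(["remote", "inverted", "everted"])]
    clusters: list[InconsistentCluster] = []
    n_clustered = 0
    n_clustered_inter = 0

    for (ptype, c1, c2), grp in inco.groupby(
            ["pair_class", "fwd_chrom", "rev_chrom"], observed=True, sort=True):
        g = grp.sort_values("fwd_pos")
        f = g["fwd_pos"].to_numpy()
        v = g["rev_pos"].to_numpy()
        ids = g["pair_id"].to_numpy()
        k = len(g)
        uf = _UnionFind(k)
        for i in range(k):
            j = i + 1
            while j < k and f[j] - f[i] <= max_gap:
                if abs(int(v[j]) - int(v[i])) <= max_gap:
                    uf.union(i, j)
                j += 1
        members: dict[int, list[int]] = {}
        for i in range(k):
            members.setdefault(uf.find(i), []).append(i)
        for idxs in members.values():
            if len(idxs) < min_support:
                continue
            fi = f[idxs]
            vi = v[idxs]
            inter = c1 != c2
            clusters.append(InconsistentCluster(
                pair_ids=[int(ids[i]) for i in idxs], type=str(ptype),
                chrom1=str(c1), start1=int(fi.min()), end1=int(fi.max()) + r,
                chrom2=str(c2), start2=int(vi.min()), end2=int(vi.max()) + r,
                inter_chromosomal=inter))
            n_clustered += len(idxs)
            if inter:
                n_clustered_inter += len(idxs)

    n_inco = len(inco)
    return ClusterResult(
        clusters=sorted(clusters, key=lambda c: (-c.support, c.chrom1, c.start1)),
        n_inconsistent=n_inco,
        clustered_fraction=n_clustered / n_inco if n_inco else 0.0,
        interchromosomal_clustered_fraction=(n_clustered_inter / n_inco
                                             if n_inco else 0.0))
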