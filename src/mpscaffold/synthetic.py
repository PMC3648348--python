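"""Synthetic genomes, assembly-like contig layouts and paired-read libraries.

This module generates the ground-truth inputs for the rest of the pipeline:
a genome with a mammalian-like interspersed-repeat landscape, a fragmentation
of that genome into contigs with known order and orientation, and simulated
paired-end (PE) / mate-pair (MP) libraries carrying the artifact classes seen
in real sequencing data (PCR duplicates, chimeric "remote" pairs, inverted
and everted pairs).

Reads carry mapped coordinates directly -- no base-level read sequences,
qualities or alignment are modelled.  Coordinates are 0-based half-open
(BED convention); SAM output converts to 1-based on write.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd
import pysam
from scipy import stats

MAX_SPAN = 100_000  # tags further apart than this are never "consistent"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

REPEAT_CLASSES = ("LINE", "LTR", "SINE", "DNA", "Other")

#: Repeat landscape emulating a rat-like mammalian genome: ~49% repetitive,
#: with LINEs the largest class (18.9% of the genome) followed by LTRs, and
#: LINE elements reaching ~8 kb.  Fractions are of total genome length.
MAMMALIAN_REPEAT_CONFIG: dict[str, dict] = {
    "LINE": {"fraction": 0.189, "length_range": (500, 8000), "divergence": 0.02},
    "LTR": {"fraction": 0.088, "length_range": (300, 5000), "divergence": 0.02},
    "SINE": {"fraction": 0.100, "length_range": (80, 400), "divergence": 0.02},
    "DNA": {"fraction": 0.050, "length_range": (200, 3000), "divergence": 0.02},
    "Other": {"fraction": 0.067, "length_range": (100, 2000), "divergence": 0.02},
}


class RepeatElement(NamedTuple):
    element_class: str
    start: int
    length: int
    identity_group: int


# ---------------------------------------------------------------------------
# genome model
# ---------------------------------------------------------------------------

@dataclass
class GenomeModel:
    """A synthetic reference sequence with its repeat annotation.

    ``repeats`` is a table with one row per repeat copy: element_class, start,
    end, length, identity_group (family label), family_copies (number of
    copies sharing the family) and divergence (per-copy substitution rate
    from the family consensus).  Repeat intervals never overlap.
    """

    name: str
    sequence: str
    repeats: pd.DataFrame

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def repeat_fraction(self) -> float:
        if len(self.repeats) == 0:
            return 0.0
        return float(self.repeats["length"].sum()) / self.length

    def repeat_elements(self) -> Iterator[RepeatElement]:
        for row in self.repeats.itertuples():
            yield RepeatElement(row.element_class, int(row.start),
                                int(row.length), int(row.identity_group))

    def class_bp(self) -> dict[str, int]:
        """Total bp per repeat class, from the annotation."""
        if len(self.repeats) == 0:
            return {}
        return self.repeats.groupby("element_class", observed=True)["length"].sum().to_dict()

    def ambiguous_intervals(self, read_length: int) -> tuple[np.ndarray, np.ndarray]:
        """Intervals in which a tag of ``read_length`` cannot map uniquely.

        A tag is ambiguous when it lies entirely inside a repeat copy whose
        family has >= 2 copies and whose divergence leaves less than one
        expected mismatch over the tag (the copies are indistinguishable at
        tag resolution).  Returns sorted (starts, ends) arrays.
        """
        if len(self.repeats) == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        amb = self.repeats[
            (self.repeats["family_copies"] >= 2)
            & (self.repeats["divergence"] * read_length < 1.0)
        ]
        starts = amb["start"].to_numpy(dtype=np.int64)
        ends = amb["end"].to_numpy(dtype=np.int64)
        order = np.argsort(starts)
        return starts[order], ends[order]

    def write_fasta(self, path, line_width: int = 80) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            for i in range(0, len(self.sequence), line_width):
                fh.write(self.sequence[i:i + line_width] + "\n")

    def write_repeats_bed(self, path) -> None:
        """BED6: name = element class, score = identity group."""
        bed = pd.DataFrame({
            "chrom": self.name,
            "start": self.repeats["start"],
            "end": self.repeats["end"],
            "name": self.repeats["element_class"],
            "score": self.repeats["identity_group"],
            "strand": "+",
        })
        bed.to_csv(path, sep="\t", header=False, index=False)


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _resolve_repeat_config(length: int, repeat_config: Mapping[str, Mapping]) -> list[dict]:
    """Normalize per-class configs to concrete counts/length params."""
    classes = []
    for name, cfg in repeat_config.items():
        lo, hi = cfg.get("length_range", (500, 5000))
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid length_range for class {name!r}: {(lo, hi)}")
        mean_len = (lo + hi) / 2
        if "count" in cfg:
            count = int(cfg["count"])
        elif "fraction" in cfg:
            count = int(round(cfg["fraction"] * length / mean_len))
        else:
            raise ValueError(f"repeat class {name!r} needs 'count' or 'fraction'")
        classes.append({
            "name": name,
            "count": count,
            "lo": lo,
            "hi": hi,
            "divergence": float(cfg.get("divergence", 0.02)),
            "n_families": int(cfg["n_families"]) if "n_families" in cfg
            else max(1, count // 5),
        })
    return classes


def simulate_genome(length: int, repeat_config: Mapping[str, Mapping] | None = None,
                    seed: int = 0, name: str = "chr1", gc: float = 0.42,
                    max_place_tries: int = 500) -> GenomeModel:
    """Generate a genome with an interspersed-repeat landscape.

    ``repeat_config`` maps class name -> {count | fraction, length_range,
    divergence, n_families}.  Copies of one family share a consensus sequence
    (lengths drawn uniformly from ``length_range`` per family) and each copy
    diverges from it by independent substitutions at the configured rate.
    Copies are placed uniformly at random without overlap by rejection
    sampling; the largest families are placed first.
    """
    length = int(length)
    if length < 10_000:
        raise ValueError("genome length must be >= 10 kb")
    if repeat_config is None:
        repeat_config = {}
    classes = _resolve_repeat_config(length, repeat_config)

    requested_bp = sum(c["count"] * (c["lo"] + c["hi"]) / 2 for c in classes)
    if requested_bp > 0.95 * length:
        raise ValueError(
            f"repeat configuration infeasible: requested ~{requested_bp:.0f} bp "
            f"of repeats on a {length} bp genome (> 95%)")

    rng = np.random.default_rng(seed)
    seq = _random_sequence(rng, length, gc)

    # draw families: (class, consensus length, divergence, copy count)
    families = []
    group = 0
    for c in classes:
        counts = np.bincount(rng.integers(0, c["n_families"], size=c["count"]),
                             minlength=c["n_families"])
        lens = rng.integers(c["lo"], c["hi"] + 1, size=c["n_families"])
        for fam in range(c["n_families"]):
            if counts[fam] == 0:
                continue
            families.append((c["name"], int(lens[fam]), c["divergence"],
                             int(counts[fam]), group))
            group += 1

    occupied = np.zeros(length, dtype=bool)
    rows: list[tuple] = []
    # place longest elements first to keep rejection sampling cheap
    families.sort(key=lambda f: -f[1])
    for cls, flen, div, ncopies, grp in families:
        consensus = _random_sequence(rng, flen, gc)
        for _ in range(ncopies):
            placed = False
            for _try in range(max_place_tries):
                start = int(rng.integers(0, length - flen + 1))
                if not occupied[start:start + flen].any():
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"could not place a {flen} bp {cls} element after "
                    f"{max_place_tries} tries; lower the repeat density")
            occupied[start:start + flen] = True
            copy = consensus.copy()
            if div > 0:
                nmut = rng.binomial(flen, div)
                if nmut:
                    pos = rng.choice(flen, size=nmut, replace=False)
                    copy[pos] = _BASES[(np.searchsorted(_BASES, copy[pos])
                                        + rng.integers(1, 4, size=nmut)) % 4]
            seq[start:start + flen] = copy
            rows.append((cls, start, start + flen, flen, grp, ncopies, div))

    repeats = pd.DataFrame(rows, columns=["element_class", "start", "end",
                                          "length", "identity_group",
                                          "family_copies", "divergence"])
    repeats = repeats.sort_values("start", ignore_index=True)
    return GenomeModel(name=name, sequence=seq.tobytes().decode("ascii"),
                       repeats=repeats)


# ---------------------------------------------------------------------------
# contig layout
# ---------------------------------------------------------------------------

@dataclass
class ContigLayout:
    """True positions of assembly contigs on the genome.

    ``contigs`` columns: contig_id, chrom, start, end, orientation, rank
    (rank is the true left-to-right order).  Every genome base belongs to
    exactly one contig or one gap.
    """

    contigs: pd.DataFrame
    gaps: np.ndarray
    genome_length: int
    chrom: str = "chr1"

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    @property
    def truth_order(self) -> list[str]:
        return list(self.contigs.sort_values("rank")["contig_id"])

    def contig_lengths(self) -> pd.Series:
        lengths = self.contigs["end"] - self.contigs["start"]
        return pd.Series(lengths.to_numpy(), index=self.contigs["contig_id"].to_numpy())

    def write_agp(self, path) -> None:
        df = self.contigs[["contig_id", "chrom", "start", "end", "orientation", "rank"]]
        df.to_csv(path, sep="\t", index=False)

    def contig_sequences(self, genome: GenomeModel) -> dict[str, str]:
        return {row.contig_id: genome.sequence[row.start:row.end]
                for row in self.contigs.itertuples()}


def fragment_into_contigs(genome: GenomeModel | int, n_contigs: int,
                          gap_model: Mapping[str, float] | None = None,
                          seed: int = 0, min_contig: int = 1000,
                          chrom: str | None = None) -> ContigLayout:
    """Split a genome into ``n_contigs`` contigs separated by random gaps.

    Gap sizes are exponential with mean ``gap_model['mean_gap']`` (default
    500 bp, minimum 1 bp); contig lengths are ``min_contig`` plus a uniform
    random partition of the remaining sequence, so contig bp + gap bp always
    equals the genome length exactly.
    """
    if isinstance(genome, GenomeModel):
        length = genome.length
        chrom = chrom or genome.name
    else:
        length = int(genome)
        chrom = chrom or "chr1"
    n_contigs = int(n_contigs)
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    gap_model = dict(gap_model or {})
    mean_gap = float(gap_model.get("mean_gap", 500.0))

    rng = np.random.default_rng(seed)
    n_gaps = n_contigs - 1
    if n_gaps:
        gaps = np.maximum(1, np.round(rng.exponential(mean_gap, size=n_gaps))).astype(np.int64)
    else:
        gaps = np.empty(0, dtype=np.int64)
    spare = length - int(gaps.sum()) - n_contigs * min_contig
    if spare < 0:
        raise ValueError(
            f"cannot place {n_contigs} contigs of >= {min_contig} bp plus "
            f"{int(gaps.sum())} bp of gaps on a {length} bp genome")
    if n_contigs > 1:
        cuts = np.sort(rng.integers(0, spare + 1, size=n_contigs - 1))
        extra = np.diff(np.concatenate(([0], cuts, [spare])))
    else:
        extra = np.array([spare], dtype=np.int64)
    contig_lens = min_contig + extra

    starts = np.zeros(n_contigs, dtype=np.int64)
    pos = 0
    rows = []
    width = max(5, len(str(n_contigs)))
    for i in range(n_contigs):
        starts[i] = pos
        end = pos + int(contig_lens[i])
        rows.append((f"ctg{i:0{width}d}", chrom, pos, end, "+", i))
        pos = end + (int(gaps[i]) if i < n_gaps else 0)
    assert pos == length
    contigs = pd.DataFrame(rows, columns=["contig_id", "chrom", "start", "end",
                                          "orientation", "rank"])
    return ContigLayout(contigs=contigs, gaps=gaps, genome_length=length, chrom=chrom)


# ---------------------------------------------------------------------------
# library specification and simulation
# ---------------------------------------------------------------------------

@dataclass
class LibrarySpec:
    """Parameters of one paired-read library.

    ``insert_median``/``insert_spread`` parameterize a truncated-normal
    (default) or lognormal outer-span distribution, truncated to
    [2*read_length, 100 kb].  The artifact fractions are the probabilities
    that an emitted pair is a PCR duplicate (exact coordinate clone of an
    earlier pair), a chimeric "remote" pair (one tag repositioned >= 100 kb
    away), or has one (inverted) or both (everted) tags in the wrong
    orientation.
    """

    name: str
    insert_median: int
    insert_spread: float
    n_pairs: int
    read_length: int = 50
    distribution_shape: str = "normal"
    duplicate_fraction: float = 0.0
    remote_fraction: float = 0.0
    inverted_fraction: float = 0.0
    everted_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.insert_median < 2 * self.read_length:
            raise ValueError("insert_median must be >= 2 * read_length")
        fracs = (self.duplicate_fraction, self.remote_fraction,
                 self.inverted_fraction, self.everted_fraction)
        if any(f < 0 for f in fracs) or sum(fracs) >= 1:
            raise ValueError("artifact fractions must be >= 0 and sum to < 1")
        if self.insert_spread < 0:
            raise ValueError("insert_spread must be >= 0")
        if self.distribution_shape not in ("normal", "lognormal"):
            raise ValueError("distribution_shape must be 'normal' or 'lognormal'")


#: The seven library profiles of the rat study: median insert sizes of
#: 170 bp (PE) and 3/5/8/15/20/25 kb MPs, with per-insert duplicate levels
#: taken from the observed non-duplicate fractions (duplicate libraries of
#: one insert size pooled), ~10% remote pairs and <1% inverted/everted.
PAPER_LIBRARY_PROFILES: tuple[dict, ...] = (
    {"name": "PE", "insert_median": 170, "duplicate_fraction": 0.05},
    {"name": "3kb", "insert_median": 3000, "duplicate_fraction": 0.08},
    {"name": "5kb", "insert_median": 5000, "duplicate_fraction": 0.28},
    {"name": "8kb", "insert_median": 8000, "duplicate_fraction": 0.39},
    {"name": "15kb", "insert_median": 15000, "duplicate_fraction": 0.92},
    {"name": "20kb", "insert_median": 20000, "duplicate_fraction": 0.49},
    {"name": "25kb", "insert_median": 25000, "duplicate_fraction": 0.96},
)


def paper_library_specs(genome_length: int, target_coverage: float = 10.0,
                        read_length: int = 50, spread_cv: float = 0.10,
                        remote_fraction: float = 0.10,
                        inverted_fraction: float = 0.005,
                        everted_fraction: float = 0.004,
                        duplicate_fractions: Mapping[str, float] | None = None,
                        seed: int = 0) -> list[LibrarySpec]:
    """Seven study-profile :class:`LibrarySpec` scaled to a genome.

    ``n_pairs`` per library is chosen so the non-clonal, consistently mapped
    subset yields roughly ``target_coverage`` x physical coverage (with a 25%
    safety margin), mirroring the study design where every library exceeded
    the 8.5x normalization target.  ``spread_cv`` is the insert-distribution
    scale as a fraction of the median (the study reports only medians).
    """
    specs = []
    for i, prof in enumerate(PAPER_LIBRARY_PROFILES):
        dup = prof["duplicate_fraction"]
        if duplicate_fractions and prof["name"] in duplicate_fractions:
            dup = duplicate_fractions[prof["name"]]
        insert = prof["insert_median"]
        usable = (1 - dup) * (1 - remote_fraction - inverted_fraction - everted_fraction)
        n_pairs = int(math.ceil(1.25 * target_coverage * genome_length
                                / insert / usable))
        # the study's remote/inverted/everted rates describe the non-duplicate
        # pairs; LibrarySpec fractions are per emitted pair, so scale by 1-dup
        specs.append(LibrarySpec(
            name=prof["name"], insert_median=insert,
            insert_spread=spread_cv * insert, n_pairs=n_pairs,
            read_length=read_length, duplicate_fraction=dup,
            remote_fraction=remote_fraction * (1 - dup),
            inverted_fraction=inverted_fraction * (1 - dup),
            everted_fraction=everted_fraction * (1 - dup),
            seed=seed + i,
        ))
    return specs


@dataclass
class PairSet:
    """Simulated (or imported) mapped read pairs of one library.

    ``pairs`` columns: pair_id, fwd_chrom, fwd_pos, fwd_strand, rev_chrom,
    rev_pos, rev_strand, truth_category, fwd_unique, rev_unique.  Positions
    are the 0-based leftmost base of each tag on the reference.
    """

    pairs: pd.DataFrame
    spec: LibrarySpec | None
    genome_length: int
    read_length: int

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def name(self) -> str:
        return self.spec.name if self.spec is not None else "library"


PAIR_COLUMNS = ["pair_id", "fwd_chrom", "fwd_pos", "fwd_strand",
                "rev_chrom", "rev_pos", "rev_strand",
                "truth_category", "fwd_unique", "rev_unique"]


def _draw_spans(spec: LibrarySpec, n: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = 2 * spec.read_length, MAX_SPAN
    if spec.insert_spread == 0:
        return np.full(n, spec.insert_median, dtype=np.int64)
    if spec.distribution_shape == "normal":
        a = (lo - spec.insert_median) / spec.insert_spread
        b = (hi - spec.insert_median) / spec.insert_spread
        draws = stats.truncnorm.rvs(a, b, loc=spec.insert_median,
                                    scale=spec.insert_spread, size=n,
                                    random_state=rng)
    else:  # lognormal with the configured median; spread is a CV-like scale
        sigma = spec.insert_spread / spec.insert_median
        draws = spec.insert_median * np.exp(sigma * rng.standard_normal(n))
        draws = np.clip(draws, lo, hi)
    return np.round(draws).astype(np.int64)


def _remote_positions(fwd_pos: np.ndarray, genome_length: int, read_length: int,
                      rng: np.random.Generator, min_dist: int = 100_000) -> np.ndarray:
    """Uniform positions >= min_dist away from the forward tag."""
    hi = genome_length - read_length
    left = np.maximum(0, fwd_pos - min_dist)            # allowed: [0, left)
    right_start = np.minimum(hi, fwd_pos + min_dist)    # allowed: [right_start, hi]
    right = np.maximum(0, hi - right_start + 1)
    total = left + right
    if np.any(total <= 0):
        raise ValueError("genome too short to place a remote tag >= 100 kb away")
    u = (rng.random(len(fwd_pos)) * total).astype(np.int64)
    return np.where(u < left, u, right_start + (u - left))


def simulate_library(genome: GenomeModel, spec: LibrarySpec) -> PairSet:
    """Simulate ``spec.n_pairs`` mapped read pairs from ``genome``.

    Consistent pairs have facing-in tags (forward tag on '+', reverse on '-')
    with the outer span drawn from the insert distribution; mate-pair tag
    orientation after circularization is normalized to this same convention
    so PE and MP libraries share one consistency rule.  Duplicates are exact
    coordinate clones of previously emitted pairs.  Tag uniqueness flags
    reflect the repeat annotation (see GenomeModel.ambiguous_intervals).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pairs
    r = spec.read_length
    G = genome.length

    n_dup = rng.binomial(n, spec.duplicate_fraction)
    m = n - n_dup  # original (non-clone) pairs
    spans = _draw_spans(spec, m, rng)
    spans = np.minimum(spans, G - 1)
    fwd_pos = rng.integers(0, G - spans + 1)
    rev_pos = fwd_pos + spans - r
    fwd_strand = np.full(m, "+", dtype=object)
    rev_strand = np.full(m, "-", dtype=object)
    category = np.full(m, "consistent", dtype=object)

    # assign artifact categories among the originals
    other = spec.remote_fraction + spec.inverted_fraction + spec.everted_fraction
    if other > 0 and spec.duplicate_fraction < 1:
        p = np.array([spec.remote_fraction, spec.inverted_fraction,
                      spec.everted_fraction]) / (1 - spec.duplicate_fraction)
        u = rng.random(m)
        remote = u < p[0]
        inverted = (u >= p[0]) & (u < p[0] + p[1])
        everted = (u >= p[0] + p[1]) & (u < p.sum())
        if remote.any():
            rev_pos[remote] = _remote_positions(fwd_pos[remote], G, r, rng)
            category[remote] = "remote"
            # a chimeric junction joins two fragments in proper orientation:
            # the pair keeps the expected facing-in pattern (left tag '+'),
            # whichever side the repositioned tag lands on
            flipped = remote & (rev_pos < fwd_pos)
            fwd_strand[flipped] = "-"
            rev_strand[flipped] = "+"
        if inverted.any():
            rev_strand[inverted] = "+"
            category[inverted] = "inverted"
        if everted.any():
            fwd_strand[everted] = "-"
            rev_strand[everted] = "+"
            category[everted] = "everted"

    df = pd.DataFrame({
        "pair_id": np.arange(m, dtype=np.int64),
        "fwd_chrom": genome.name, "fwd_pos": fwd_pos, "fwd_strand": fwd_strand,
        "rev_chrom": genome.name, "rev_pos": rev_pos, "rev_strand": rev_strand,
        "truth_category": category,
    })

    if n_dup:
        src = rng.integers(0, m, size=n_dup)
        dup = df.iloc[src].copy()
        dup["pair_id"] = np.arange(m, m + n_dup, dtype=np.int64)
        dup["truth_category"] = [f"duplicate_of:{s}" for s in src]
        df = pd.concat([df, dup], ignore_index=True)

    starts, ends = genome.ambiguous_intervals(r)
    for side in ("fwd", "rev"):
        pos = df[f"{side}_pos"].to_numpy()
        if len(starts):
            idx = np.searchsorted(starts, pos, side="right") - 1
            idx_c = np.clip(idx, 0, len(starts) - 1)
            inside = (idx >= 0) & (pos >= starts[idx_c]) & (pos + r <= ends[idx_c])
            df[f"{side}_unique"] = ~inside
        else:
            df[f"{side}_unique"] = True

    df = df.sample(frac=1.0, random_state=np.random.RandomState(spec.seed)
                   ).reset_index(drop=True)
    return PairSet(pairs=df[PAIR_COLUMNS], spec=spec, genome_length=G, read_length=r)


# ---------------------------------------------------------------------------
# pair set I/O
# ---------------------------------------------------------------------------

def write_pairset(pairset: PairSet, path, format: str = "tsv") -> None:
    """Write a pair set as a 10-column TSV or as SAM (1-based, standard flags).

    SAM encodes strands in the REVERSE/MATE_REVERSE flag bits, the truth
    category in the ZT tag and the two uniqueness flags in the ZU tag, so the
    round trip through :func:`read_pairset` is lossless.
    """
    df = pairset.pairs
    if len(df) == 0:
        warnings.warn("writing an empty pair set (header-only file)")
    fmt = format.lower()
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
        return
    if fmt != "sam":
        raise ValueError(f"unknown pair set format: {format!r}")

    chroms = pd.unique(pd.concat([df["fwd_chrom"], df["rev_chrom"]])) if len(df) \
        else np.array(["chr1"])
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": str(c), "LN": int(pairset.genome_length)} for c in chroms]}
    r = pairset.read_length
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {str(c): i for i, c in enumerate(chroms)}
        for row in df.itertuples(index=False):
            for first in (True, False):
                a = pysam.AlignedSegment(out.header)
                a.query_name = str(row.pair_id)
                this_rev = (row.fwd_strand if first else row.rev_strand) == "-"
                mate_rev = (row.rev_strand if first else row.fwd_strand) == "-"
                a.flag = (0x1  # paired; properness is left to the classifier
                          | (0x10 if this_rev else 0) | (0x20 if mate_rev else 0)
                          | (0x40 if first else 0x80))
                a.reference_id = tid[str(row.fwd_chrom if first else row.rev_chrom)]
                a.reference_start = int(row.fwd_pos if first else row.rev_pos)
                a.next_reference_id = tid[str(row.rev_chrom if first else row.fwd_chrom)]
                a.next_reference_start = int(row.rev_pos if first else row.fwd_pos)
                a.query_sequence = None
                a.cigarstring = f"{r}M"
                a.mapping_quality = 60
                a.set_tag("ZT", str(row.truth_category))
                a.set_tag("ZU", f"{int(row.fwd_unique)}{int(row.rev_unique)}")
                out.write(a)


def read_pairset(path, format: str = "tsv", genome_length: int | None = None,
                 read_length: int = 50, spec: LibrarySpec | None = None) -> PairSet:
    """Read a pair set written by :func:`write_pairset`."""
    fmt = format.lower()
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"fwd_chrom": str, "rev_chrom": str})
        if genome_length is None:
            genome_length = int(max(df["fwd_pos"].max(), df["rev_pos"].max())
                                + read_length) if len(df) else 0
        return PairSet(pairs=df[PAIR_COLUMNS], spec=spec,
                       genome_length=genome_length, read_length=read_length)
    if fmt != "sam":
        raise ValueError(f"unknown pair set format: {format!r}")
    rows = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        lengths = {sq["SN"]: sq["LN"] for sq in sam.header.to_dict().get("SQ", [])}
        rlen = read_length
        for a in sam:
            pid = int(a.query_name)
            rec = rows.setdefault(pid, {"pair_id": pid})
            side = "fwd" if a.is_read1 else "rev"
            rec[f"{side}_chrom"] = a.reference_name
            rec[f"{side}_pos"] = a.reference_start
            rec[f"{side}_strand"] = "-" if a.is_reverse else "+"
            rec["truth_category"] = a.get_tag("ZT")
            zu = a.get_tag("ZU")
            rec["fwd_unique"] = bool(int(zu[0]))
            rec["rev_unique"] = bool(int(zu[1]))
            if a.cigartuples:
                rlen = a.cigartuples[0][1]
    df = pd.DataFrame(list(rows.values()), columns=PAIR_COLUMNS)
    if genome_length is None:
        genome_length = max(lengths.values()) if lengths else 0
    return PairSet(pairs=df, spec=spec, genome_length=int(genome_length),
                   read_length=rlen)
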