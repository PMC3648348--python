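"""Library QC: insert sizes, complexity saturation, physical coverage.

Physical coverage is the clone-coverage notion of Lander-Waterman statistics:
the summed outer spans of qualifying pairs divided by the genome length, so a
20 kb mate-pair "covers" 20 kb of genome structure with only two short tags.
Complexity is measured by subsampling a library and counting non-clonal
pairs; the saturation of that curve bounds the number of distinct template
molecules the library can ever yield.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .classify import ClassifiedPairSet, mark_duplicates, pair_geometry
from .synthetic import MAX_SPAN, PairSet

#: Mappable (chromosome-anchored) genome length used for the expected-
#: coverage arithmetic of the rat study, and the full assembly length used
#: for repeat accounting.  The two differ because ~40 Mb of the assembly is
#: unplaced; both are exposed and configurable per call.
RAT_EFFECTIVE_GENOME_BP = 2.47e9
RAT_ASSEMBLY_BP = 2.51e9
RAT_REPEAT_BP = 1.24e9
RAT_LINE_BP = 474.6e6
RAT_LTR_BP = 220.9e6


@dataclass(frozen=True)
class StudyLibrary:
    """One row of the rat study's per-library sequencing statistics."""

    name: str
    nominal_insert: int          # bp, the library's class (170 bp .. 25 kb)
    median_insert: int           # bp, fitted from the mapped pairs
    sequenced_pairs: float       # raw pairs sequenced
    nonduplicate_fraction: float
    consistent_fraction: float   # unique, consistently mapped / non-duplicate
    physical_coverage: float     # x-fold, from the qualifying pairs
    is_mate_pair: bool


#: The ten libraries of the rat study (duplicate preparations kept separate).
STUDY_LIBRARIES: tuple[StudyLibrary, ...] = (
    StudyLibrary("PE", 170, 166, 160e6, 0.95, 0.87, 8.5, False),
    StudyLibrary("3kb", 3000, 3208, 17.7e6, 0.92, 0.93, 50.0, True),
    StudyLibrary("5kb_a", 5000, 5696, 11.9e6, 0.51, 0.92, 11.0, True),
    StudyLibrary("5kb_b", 5000, 5811, 16.7e6, 0.88, 0.95, 28.0, True),
    StudyLibrary("8kb_a", 8000, 8293, 20.8e6, 0.41, 0.91, 25.0, True),
    StudyLibrary("8kb_b", 8000, 8160, 11.8e6, 0.95, 0.95, 34.0, True),
    StudyLibrary("15kb_a", 15000, 14561, 31.7e6, 0.05, 0.60, 6.0, True),
    StudyLibrary("15kb_b", 15000, 13556, 11.6e6, 0.14, 0.73, 7.0, True),
    StudyLibrary("20kb", 20000, 19375, 13.3e6, 0.51, 0.87, 48.0, True),
    StudyLibrary("25kb", 25000, 25871, 56.9e6, 0.04, 0.49, 11.0, True),
)


# ---------------------------------------------------------------------------
# insert-size estimation
# ---------------------------------------------------------------------------

@dataclass
class InsertStats:
    median: float
    percentile_1: float
    percentile_99: float
    n_pairs: int
    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.percentile_1, self.percentile_99)

    def write_histogram_tsv(self, path) -> None:
        pd.DataFrame({"bin_start": self.bin_edges[:-1].astype(int),
                      "bin_end": self.bin_edges[1:].astype(int),
                      "count": self.counts}).to_csv(path, sep="\t", index=False)


def _qualifying_spans(pairs, max_span: int) -> tuple[np.ndarray, int]:
    """Spans of non-clonal, facing-in, same-chromosome pairs below max_span."""
    cset = pairs if isinstance(pairs, ClassifiedPairSet) else mark_duplicates(pairs)
    df = cset.pairs
    geo = pair_geometry(df, cset.read_length)
    ok = ((df["pair_class"] != "clonal").to_numpy()
          & geo["same_chrom"].to_numpy()
          & (geo["left_strand"].to_numpy() == "+")
          & (geo["right_strand"].to_numpy() == "-"))
    spans = geo["span"].to_numpy()[ok]
    return spans[spans < max_span], cset.read_length


def estimate_insert_distribution(pairs, max_span: int = MAX_SPAN,
                                 min_pairs: int = 100,
                                 n_bins: int = 100) -> InsertStats:
    """Empirical insert distribution of a library.

    Uses only non-clonal pairs with proper (facing-in) orientation on one
    chromosome and tag distance below ``max_span``; remote, inverted and
    everted pairs never influence the estimate.  The 1st/99th percentiles of
    this distribution are the default consistency bounds downstream.
    """
    spans, _ = _qualifying_spans(pairs, max_span)
    if len(spans) < min_pairs:
        raise ValueError(
            f"only {len(spans)} qualifying pairs (need >= {min_pairs}) "
            "for insert-size estimation")
    counts, edges = np.histogram(spans, bins=n_bins)
    return InsertStats(median=float(np.median(spans)),
                       percentile_1=float(np.percentile(spans, 1)),
                       percentile_99=float(np.percentile(spans, 99)),
                       n_pairs=len(spans), bin_edges=edges, counts=counts)


# ---------------------------------------------------------------------------
# complexity / saturation
# ---------------------------------------------------------------------------

@dataclass
class ComplexityEstimate:
    value: float
    is_lower_bound: bool

    def __str__(self) -> str:
        return f"{'>' if self.is_lower_bound else ''}{self.value:.0f}"


@dataclass
class ComplexityCurve:
    """Unique (non-clonal) pairs as a function of sampled sequencing depth."""

    points: pd.DataFrame  # columns: n_sampled, unique_mean, unique_se
    estimate: ComplexityEstimate | None = None


def complexity_curve(pairs, grid: Sequence[int], replicates: int = 3,
                     seed: int = 0) -> ComplexityCurve:
    """Subsample the library at each grid depth and count non-clonal pairs.

    Each point averages ``replicates`` random subsamples (without
    replacement, emulating resampling reads from the run) and reports the
    Monte-Carlo standard error over replicates.
    """
    df = pairs.pairs if isinstance(pairs, (PairSet, ClassifiedPairSet)) else pairs
    grid = [int(g) for g in grid]
    if sorted(grid) != grid:
        raise ValueError("grid must be sorted ascending")
    if grid and grid[-1] > len(df):
        raise ValueError(f"grid max {grid[-1]} exceeds library size {len(df)}")
    # integer signature per coordinate-identical group
    sig = df.groupby(["fwd_chrom", "fwd_pos", "fwd_strand",
                      "rev_chrom", "rev_pos", "rev_strand"],
                     observed=True, sort=False).ngroup().to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for g in grid:
        uniq = [len(np.unique(sig[rng.choice(len(sig), size=g, replace=False)]))
                for _ in range(replicates)]
        rows.append((g, float(np.mean(uniq)),
                     float(np.std(uniq, ddof=1) / np.sqrt(replicates))
                     if replicates > 1 else 0.0))
    return ComplexityCurve(points=pd.DataFrame(
        rows, columns=["n_sampled", "unique_mean", "unique_se"]))


def estimate_max_unique(curve: ComplexityCurve,
                        plateau_tolerance: float = 0.10) -> ComplexityEstimate:
    """Saturation estimate of the number of distinct library molecules.

    Fits unique(n) = C * (1 - exp(-n / C)) by least squares.  If the deepest
    observed point is within ``plateau_tolerance`` of the fitted plateau the
    library is saturated and C is returned; otherwise the observed unique
    count is returned flagged as a lower bound (">"), mirroring the study's
    ">131 M"-style entries for unsaturated libraries.
    """
    pts = curve.points
    if len(pts) < 3:
        raise ValueError("need >= 3 grid points to estimate library complexity")
    n = pts["n_sampled"].to_numpy(dtype=float)
    u = pts["unique_mean"].to_numpy(dtype=float)
    if np.any(np.diff(u) < -3 * (pts["unique_se"].to_numpy()[1:] + 1e-9)):
        warnings.warn("complexity curve is not concave/monotone within noise; "
                      "fit may be unreliable")

    def model(x, c):
        return c * (1.0 - np.exp(-x / c))

    u_max = float(u[-1])
    try:
        popt, _ = curve_fit(model, n, u, p0=[max(u_max, 1.0) * 2],
                            bounds=(u_max * (1 - 1e-9), np.inf), maxfev=10000)
        c_hat = float(popt[0])
    except RuntimeError:
        c_hat = np.inf
    if np.isfinite(c_hat) and u_max >= (1 - plateau_tolerance) * c_hat:
        est = ComplexityEstimate(value=c_hat, is_lower_bound=False)
    else:
        est = ComplexityEstimate(value=u_max, is_lower_bound=True)
    curve.estimate = est
    return est


# ---------------------------------------------------------------------------
# physical coverage and normalization
# ---------------------------------------------------------------------------

@dataclass
class CoverageProfile:
    physical_coverage: float
    pairs_used: int
    genome_length: int


def _coverage_qualifying(cset: ClassifiedPairSet,
                         insert_stats: InsertStats | None) -> np.ndarray:
    """Mask of pairs entering physical coverage: consistent class (non-clonal,
    unique, proper orientation, span within the consistency bounds) with span
    additionally inside the library's own 1st-99th percentile band."""
    df = cset.pairs
    ok = (df["pair_class"] == "consistent").to_numpy()
    if insert_stats is None:
        insert_stats = estimate_insert_distribution(cset)
    span = df["span"].to_numpy()
    return ok & (span >= insert_stats.percentile_1) & (span <= insert_stats.percentile_99)


def physical_coverage(cset: ClassifiedPairSet, genome_length: int | None = None,
                      insert_stats: InsertStats | None = None) -> CoverageProfile:
    """Physical (clone) coverage of the genome by qualifying pairs."""
    G = int(genome_length or cset.genome_length)
    if G <= 0:
        raise ValueError("genome_length must be > 0")
    if len(cset.pairs) == 0 or not (cset.pairs["pair_class"] == "consistent").any():
        return CoverageProfile(0.0, 0, G)
    mask = _coverage_qualifying(cset, insert_stats)
    spans = cset.pairs["span"].to_numpy()[mask]
    return CoverageProfile(physical_coverage=float(spans.sum()) / G,
                           pairs_used=int(mask.sum()), genome_length=G)


def expected_coverage(n_pairs: float, nominal_insert: float,
                      effective_genome: float = RAT_EFFECTIVE_GENOME_BP) -> float:
    """Closed-form expected physical coverage: n_pairs * insert / genome."""
    if n_pairs <= 0 or nominal_insert <= 0 or effective_genome <= 0:
        raise ValueError("all arguments must be > 0")
    return n_pairs * nominal_insert / effective_genome


def normalize_to_coverage(cset: ClassifiedPairSet, target: float, seed: int = 0,
                          genome_length: int | None = None,
                          insert_stats: InsertStats | None = None
                          ) -> ClassifiedPairSet:
    """Random qualifying subset reaching ``target`` x physical coverage.

    Pairs are added in random order until the cumulative span first reaches
    the target, so the resulting coverage overshoots by at most one pair
    span.  Deterministic under ``seed``.  Raises if the full set cannot
    reach the target, reporting the attainable maximum.
    """
    G = int(genome_length or cset.genome_length)
    if G <= 0:
        raise ValueError("genome_length must be > 0")
    mask = _coverage_qualifying(cset, insert_stats)
    idx = np.flatnonzero(mask)
    spans = cset.pairs["span"].to_numpy()[idx]
    total = float(spans.sum()) / G
    if total < target:
        raise ValueError(
            f"insufficient data: full-set coverage {total:.3f}x < target "
            f"{target}x")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(idx))
    csum = np.cumsum(spans[order], dtype=np.float64)
    k = int(np.searchsorted(csum, target * G)) + 1
    chosen = idx[order[:k]]
    return cset.subset(np.isin(np.arange(len(cset.pairs)), chosen))


# ---------------------------------------------------------------------------
# per-library report
# ---------------------------------------------------------------------------

def qc_report(cset: ClassifiedPairSet, insert_stats: InsertStats,
              coverage: CoverageProfile,
              complexity: ComplexityCurve | None = None) -> dict:
    """Assemble the per-library QC summary (JSON-serializable)."""
    counts = cset.counts()
    n = len(cset.pairs)
    rep = {
        "library": cset.name,
        "n_pairs": n,
        "median_insert": insert_stats.median,
        "percentile_1": insert_stats.percentile_1,
        "percentile_99": insert_stats.percentile_99,
        "nonduplicate_fraction": 1 - counts["clonal"] / max(1, n),
        "consistent_fraction": counts["consistent"] / max(1, n),
        "class_counts": counts,
        "physical_coverage": coverage.physical_coverage,
        "pairs_used_for_coverage": coverage.pairs_used,
        "genome_length": coverage.genome_length,
    }
    if complexity is not None:
        rep["complexity_points"] = complexity.points.to_dict(orient="records")
        if complexity.estimate is not None:
            rep["estimated_max_unique"] = complexity.estimate.value
            rep["max_unique_is_lower_bound"] = complexity.estimate.is_lower_bound
    return rep


def write_qc_report(report: dict, json_path, tsv_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    if tsv_path is not None:
        flat = {k: v for k, v in report.items()
                if not isinstance(v, (dict, list))}
        pd.DataFrame([flat]).to_csv(tsv_path, sep="\t", index=False)
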