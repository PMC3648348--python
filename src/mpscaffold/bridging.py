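"""Repeat-element bridging by paired reads.

A repeat element is *bridged* when at least one qualifying pair fully
contains it within its outer span, with both tags mapped in the flanking
sequence (left tag ending at or before the element start, right tag starting
at or after the element end).  Qualifying pairs are unambiguously mapped,
properly oriented and no longer than the 99th percentile of the library's
fragment-size distribution.  Bridging fractions are aggregated in 500-bp
element-size windows per repeat class, which is how libraries of different
insert size are compared across the repeat-size spectrum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import ClassifiedPairSet


@dataclass
class BridgingProfile:
    """Per-class bridged fractions in element-size windows."""

    table: pd.DataFrame  # element_class, bin_start, bin_end, n_elements, n_bridged, fraction
    library: str = "library"
    coverage: float | None = None

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _repeat_frame(repeats) -> pd.DataFrame:
    if hasattr(repeats, "repeats"):  # GenomeModel
        repeats = repeats.repeats
    df = repeats
    if "end" not in df.columns:
        df = df.assign(end=df["start"] + df["length"])
    if "length" not in df.columns:
        df = df.assign(length=df["end"] - df["start"])
    return df


def bridged_elements(cset: ClassifiedPairSet, repeats,
                     insert_p99: float | None = None) -> np.ndarray:
    """Boolean per repeat element: bridged by at least one qualifying pair.

    Implemented by a sorted sweep rather than an all-pairs scan: pairs are
    sorted by the end of their left tag and a running maximum of right-tag
    starts answers "does any pair with left tag ending before this element
    also reach past its end?" in O(log n) per element.
    """
    rep = _repeat_frame(repeats)
    df = cset.pairs
    r = cset.read_length
    if insert_p99 is None:
        insert_p99 = cset.insert_bounds[1] if cset.insert_bounds else np.inf

    ok = (df["pair_class"] == "consistent").to_numpy()
    span = df["span"].to_numpy()
    ok &= span <= insert_p99
    if not ok.any():
        return np.zeros(len(rep), dtype=bool)

    left = np.minimum(df["fwd_pos"].to_numpy()[ok], df["rev_pos"].to_numpy()[ok])
    right = np.maximum(df["fwd_pos"].to_numpy()[ok], df["rev_pos"].to_numpy()[ok])
    left_end = left + r          # end of the left tag interval
    right_start = right         # start of the right tag interval

    order = np.argsort(left_end, kind="stable")
    left_end = left_end[order]
    reach = np.maximum.accumulate(right_start[order])

    starts = rep["start"].to_numpy()
    ends = rep["end"].to_numpy()
    idx = np.searchsorted(left_end, starts, side="right") - 1
    bridged = np.zeros(len(rep), dtype=bool)
    has = idx >= 0
    bridged[has] = reach[idx[has]] >= ends[has]
    return bridged


def bridging_profile(flags: np.ndarray, repeats, window: int = 500,
                     library: str = "library",
                     coverage: float | None = None) -> BridgingProfile:
    """Bin elements by their own length into contiguous ``window``-bp bins.

    Elements are binned by instance length (annotation sizes, not family
    consensus length); empty classes/bins are omitted.
    """
    rep = _repeat_frame(repeats)
    cls = rep["element_class"] if "element_class" in rep.columns \
        else pd.Series("all", index=rep.index)
    lengths = (rep["end"] - rep["start"]).to_numpy()
    bins = lengths // window
    g = pd.DataFrame({"element_class": cls.to_numpy(), "bin": bins,
                      "bridged": np.asarray(flags, dtype=bool)})
    agg = g.groupby(["element_class", "bin"], observed=True).agg(
        n_elements=("bridged", "size"), n_bridged=("bridged", "sum")).reset_index()
    agg["bin_start"] = agg.pop("bin") * window
    agg["bin_end"] = agg["bin_start"] + window
    agg["fraction"] = agg["n_bridged"] / agg["n_elements"]
    table = agg[["element_class", "bin_start", "bin_end",
                 "n_elements", "n_bridged", "fraction"]]
    return BridgingProfile(table=table.sort_values(
        ["element_class", "bin_start"], ignore_index=True),
        library=library, coverage=coverage)


def theoretical_bridging_prob(n_pairs: float, insert: float, element_length: float,
                              read_length: float, genome: float) -> float:
    """Closed-form bridging probability for an isolated element.

    A fragment of size ``insert`` with tags of ``read_length`` bridges an
    element of length L iff its start falls in a window of
    max(0, insert - L - 2*read_length + 1) positions; with n fragments placed
    uniformly on the genome the element is bridged with probability
    1 - exp(-n * window / genome) (Lander-Waterman-style Poisson
    approximation).
    """
    if min(n_pairs, insert, element_length, read_length, genome) <= 0:
        raise ValueError("all arguments must be > 0")
    window = max(0.0, insert - element_length - 2 * read_length + 1)
    return 1.0 - math.exp(-n_pairs * window / genome)
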