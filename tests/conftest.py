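import numpy as np
import pandas as pd
import pytest

import mpscaffold as mp
from mpscaffold.synthetic import PAIR_COLUMNS


@pytest.fixture(scope="session")
def plain_genome():
    """1 Mb repeat-free genome."""
    return mp.simulate_genome(1_000_000, seed=101)


@pytest.fixture(scope="session")
def repeat_genome():
    """1 Mb genome with a two-copy, zero-divergence repeat family (tags
    inside those copies are ambiguous) and a single-copy family."""
    cfg = {
        "LINE": {"count": 6, "length_range": (4000, 4000), "n_families": 3,
                 "divergence": 0.0},
        "LTR": {"count": 1, "length_range": (3000, 3000), "n_families": 1,
                "divergence": 0.0},
    }
    return mp.simulate_genome(1_000_000, cfg, seed=102)


@pytest.fixture(scope="session")
def library_3kb(plain_genome):
    spec = mp.LibrarySpec("3kb", 3000, 300, n_pairs=20_000, read_length=50,
                          duplicate_fraction=0.2, remote_fraction=0.05,
                          inverted_fraction=0.01, everted_fraction=0.01,
                          seed=7)
    return mp.simulate_library(plain_genome, spec)


def make_pairs(rows, genome_length=1_000_000, read_length=50, spec=None):
    """Build a PairSet from (fwd_pos, fwd_strand, rev_pos, rev_strand[, extras])
    tuples or full dicts."""
    recs = []
    for i, row in enumerate(rows):
        if isinstance(row, dict):
            rec = dict(row)
        else:
            fp, fs, rp, rs = row
            rec = {"fwd_pos": fp, "fwd_strand": fs, "rev_pos": rp,
                   "rev_strand": rs}
        rec.setdefault("pair_id", i)
        rec.setdefault("fwd_chrom", "chr1")
        rec.setdefault("rev_chrom", "chr1")
        rec.setdefault("truth_category", "consistent")
        rec.setdefault("fwd_unique", True)
        rec.setdefault("rev_unique", True)
        recs.append(rec)
    if recs:
        df = pd.DataFrame(recs)[PAIR_COLUMNS]
    else:
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in PAIR_COLUMNS})
    return mp.PairSet(pairs=df, spec=spec, genome_length=genome_length,
                      read_length=read_length)
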