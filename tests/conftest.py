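import numpy as np
import pandas as pd
import pytest

from irisgradient import (
    CutoffSet,
    ExpressionTable,
    LibraryCounts,
    PlantedSet,
    SimulationSpec,
    TranscriptCatalog,
    simulate_dataset,
)

#: detection thresholds the original study derived from its array data,
#: used when re-running the published fold-change tables
STUDY_CUTOFFS = CutoffSet(
    cutoffs={"4dv": 0.64, "4dd": 1.14, "8dv": 1.13, "8dd": 1.1},
    null_transcripts=frozenset(),
)


@pytest.fixture(scope="session")
def dataset():
    """Default-scale synthetic dataset (5,000 transcripts), fixed seed."""
    return simulate_dataset(SimulationSpec(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale dataset for IO/CLI round trips."""
    spec = SimulationSpec(
        seed=7,
        n_transcripts=400,
        library_sizes={c: 200_000 for c in ("4dv", "4dd", "8dv", "8dd")},
        planted_sets=(
            PlantedSet("dorsal_up_8x", 30, "dorsal", 8.0, 8.0),
            PlantedSet("ventral_up_8x", 30, "ventral", 8.0, 8.0),
            PlantedSet("dorsal_exclusive", 3, "dorsal", exclusive=True),
        ),
        n_null_pool=30,
        n_null_spots=60,
    )
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def study_cutoffs():
    return STUDY_CUTOFFS


def make_catalog(lengths: dict, go_terms=None) -> TranscriptCatalog:
    """Catalog from a {transcript_id: length} mapping."""
    return TranscriptCatalog.from_entries(
        (tid, length, "", (go_terms or {}).get(tid, ()))
        for tid, length in lengths.items()
    )


def make_expression(rpkm: dict, counts: dict | None = None) -> ExpressionTable:
    """ExpressionTable from {tid: (v4, d4, v8, d8)} RPKM quadruples.

    Counts default to 1 where RPKM > 0 and 0 where RPKM == 0, preserving
    the RPKM-zero-iff-count-zero contract.
    """
    conds = ("4dv", "4dd", "8dv", "8dd")
    rp = pd.DataFrame.from_dict(rpkm, orient="index", columns=conds)
    rp.index.name = "transcript_id"
    if counts is None:
        ct = (rp > 0).astype(int)
    else:
        ct = pd.DataFrame.from_dict(counts, orient="index", columns=conds)
        ct.index.name = "transcript_id"
    return ExpressionTable(rpkm=rp, counts=ct)


def make_library(condition, counts: dict, total=1_000_000) -> LibraryCounts:
    series = pd.Series(counts, dtype=int)
    series.index.name = "transcript_id"
    return LibraryCounts(condition=condition, counts=series, total_mapped_reads=total)
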