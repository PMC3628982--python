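"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates the four-library design (dorsal/ventral iris at 4
and 8 days post-lentectomy) so every stage can be exercised and scored
against known ground truth without any external download:

* a transcript catalog with log-normal lengths and GO labels;
* negative-binomial-like unique-read counts per library: per-transcript
  relative abundance is log-normal, multiplied per library by a gamma
  overdispersion factor (variance = ``dispersion`` around mean 1), and
  reads are allocated multinomially so each library totals exactly its
  requested size — marginally each transcript's count is gamma-Poisson
  (negative binomial) to an excellent approximation;
* planted transcript sets with known dorsal/ventral folds per day,
  side-exclusive sets (zero reads on the opposite side), and a planted GO
  term enriched in the dorsal-up set;
* a pool of low-abundance transcripts backing simulated null microarray
  spots (structurally valid, signal-free) together with decoy spots that
  must fail each quality filter;
* qPCR dilution-series standards and triplicate sample Cts with known
  relative levels and a constant reference gene.

Every draw descends from ``SimulationSpec.seed`` through fixed-order
substreams, so a spec reproduces its dataset exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .cutoffs import MicroarraySpot
from .errors import SimulationSpecError
from .qpcr import PERFECT_SLOPE
from .quantify import CONDITIONS, LibraryCounts, TranscriptCatalog

_DORSAL = ("4dd", "8dd")
_VENTRAL = ("4dv", "8dv")


@dataclass(frozen=True)
class PlantedSet:
    """A set of transcripts with a known dorsoventral expression pattern.

    ``fold4``/``fold8`` are the true dorsal/ventral expression ratios at 4
    and 8 dpl for ``side == "dorsal"`` (ventral/dorsal for ``"ventral"``).
    Exclusive sets have zero expression on the opposite side.
    """

    name: str
    size: int
    side: str  # "dorsal" | "ventral"
    fold4: float = 8.0
    fold8: float = 8.0
    exclusive: bool = False

    def __post_init__(self):
        if self.side not in ("dorsal", "ventral"):
            raise SimulationSpecError(f"side must be dorsal/ventral, got {self.side!r}")
        if not self.exclusive and (self.fold4 <= 1 or self.fold8 <= 1):
            raise SimulationSpecError("planted folds must exceed 1")


@dataclass(frozen=True)
class QpcrGene:
    """True relative template amounts of one gene per (side, day)."""

    name: str
    levels: dict  # (side, day) -> amount


def _default_planted_sets() -> tuple:
    return (
        PlantedSet("dorsal_up_8x", 100, "dorsal", 8.0, 8.0),
        PlantedSet("ventral_up_8x", 100, "ventral", 8.0, 8.0),
        PlantedSet("dorsal_exclusive", 5, "dorsal", exclusive=True),
        PlantedSet("ventral_exclusive", 5, "ventral", exclusive=True),
    )


def _default_qpcr_genes() -> tuple:
    # a TBX5-like dorsal marker (8:1 dorsal/ventral, stronger at 8 dpl) and
    # an NTN1-like ventral marker (1:8)
    return (
        QpcrGene(
            "TBX5",
            {
                ("dorsal", 4): 8.0,
                ("ventral", 4): 1.0,
                ("dorsal", 8): 12.0,
                ("ventral", 8): 1.5,
            },
        ),
        QpcrGene(
            "NTN1",
            {
                ("dorsal", 4): 0.5,
                ("ventral", 4): 4.0,
                ("dorsal", 8): 0.4,
                ("ventral", 8): 3.2,
            },
        ),
    )


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic dataset.

    Defaults are the desk-scale study conditions: 5,000 transcripts, four
    libraries of 2 million mapped reads, negative-binomial dispersion 0.2,
    fold-8 planted gradient sets and triplicate qPCR with 0.15-cycle Ct
    noise.
    """

    seed: int = 0
    n_transcripts: int = 5000
    mean_length_bp: float = 1500.0
    length_sigma: float = 0.6
    min_length_bp: int = 200
    abundance_sigma: float = 1.2
    library_sizes: dict = field(
        default_factory=lambda: {cond: 2_000_000 for cond in CONDITIONS}
    )
    dispersion: float = 0.2
    planted_sets: tuple = field(default_factory=_default_planted_sets)
    # low-abundance pool backing the null microarray spots
    n_null_pool: int = 60
    null_abundance_factor: float = 0.02
    n_null_spots: int = 120
    # GO vocabulary
    n_go_terms: int = 40
    go_freq_range: tuple = (0.01, 0.06)
    planted_go_term: str = "GO:0007049"  # cell cycle, the hallmark dorsal theme
    planted_go_prob: float = 0.8
    planted_go_set: str = "dorsal_up_8x"
    # qPCR block
    qpcr_genes: tuple = field(default_factory=_default_qpcr_genes)
    reference_gene: str = "RPL27"
    curve_slope: float = PERFECT_SLOPE
    curve_intercept: float = 30.0
    ct_noise_sd: float = 0.15
    standards_noise_sd: float = 0.0
    n_replicates: int = 3

    def validate(self) -> None:
        planted_total = sum(s.size for s in self.planted_sets)
        if planted_total + self.n_null_pool > self.n_transcripts:
            raise SimulationSpecError(
                "planted sets plus null pool exceed n_transcripts"
            )
        if self.dispersion <= 0:
            raise SimulationSpecError("dispersion must be positive")
        for cond in CONDITIONS:
            if self.library_sizes.get(cond, 0) <= 0:
                raise SimulationSpecError(f"library size for {cond} must be positive")

    def with_seed(self, seed: int) -> "SimulationSpec":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SimulatedDataset:
    """Everything the pipeline consumes, plus the planted truth."""

    catalog: TranscriptCatalog
    libraries: dict
    truth: pd.DataFrame
    spots: list
    spot_truth: pd.DataFrame
    standards: pd.DataFrame
    samples: pd.DataFrame
    qpcr_truth: pd.DataFrame


def _rngs(spec: SimulationSpec) -> dict:
    children = np.random.SeedSequence(spec.seed).spawn(3)
    return {
        "counts": np.random.default_rng(children[0]),
        "spots": np.random.default_rng(children[1]),
        "qpcr": np.random.default_rng(children[2]),
    }


def simulate_counts(
    spec: SimulationSpec, rng: Optional[np.random.Generator] = None
):
    """Catalog, four count libraries and the planted-truth table.

    The truth table is indexed by transcript id with columns ``set_name``
    (``baseline`` / ``null_pool`` / a planted-set name), ``side``,
    ``fold4``, ``fold8`` and ``exclusive`` — enough to score sensitivity
    and specificity of every downstream call.
    """
    spec.validate()
    if rng is None:
        rng = _rngs(spec)["counts"]
    n = spec.n_transcripts
    ids = pd.Index(
        [f"transcript{i:05d}" for i in range(1, n + 1)], name="transcript_id"
    )
    lengths = np.maximum(
        rng.lognormal(math.log(spec.mean_length_bp), spec.length_sigma, n),
        spec.min_length_bp,
    ).astype(int)
    base = rng.lognormal(0.0, spec.abundance_sigma, n)

    truth = pd.DataFrame(
        {
            "set_name": "baseline",
            "side": "none",
            "fold4": 1.0,
            "fold8": 1.0,
            "exclusive": False,
        },
        index=ids,
    )

    # assign planted sets and the null pool to disjoint id blocks
    cursor = 0
    members: dict[str, np.ndarray] = {}
    for planted in spec.planted_sets:
        block = np.arange(cursor, cursor + planted.size)
        members[planted.name] = block
        cursor += planted.size
        truth.iloc[block, truth.columns.get_loc("set_name")] = planted.name
        truth.iloc[block, truth.columns.get_loc("side")] = planted.side
        truth.iloc[block, truth.columns.get_loc("fold4")] = planted.fold4
        truth.iloc[block, truth.columns.get_loc("fold8")] = planted.fold8
        truth.iloc[block, truth.columns.get_loc("exclusive")] = planted.exclusive
    null_block = np.arange(cursor, cursor + spec.n_null_pool)
    truth.iloc[null_block, truth.columns.get_loc("set_name")] = "null_pool"
    base[null_block] *= spec.null_abundance_factor
    # planted transcripts sit in the expressed range: no extreme-low baselines
    for planted in spec.planted_sets:
        block = members[planted.name]
        base[block] = np.maximum(base[block], np.median(base))

    abundance = {cond: base.copy() for cond in CONDITIONS}
    for planted in spec.planted_sets:
        block = members[planted.name]
        down = _VENTRAL if planted.side == "dorsal" else _DORSAL
        if planted.exclusive:
            for cond in down:
                abundance[cond][block] = 0.0
        else:
            abundance[down[0]][block] = base[block] / planted.fold4
            abundance[down[1]][block] = base[block] / planted.fold8

    libraries = {}
    inv_shape = 1.0 / spec.dispersion
    for cond in CONDITIONS:
        gamma = rng.gamma(inv_shape, spec.dispersion, n)
        weights = abundance[cond] * lengths * gamma
        total = int(spec.library_sizes[cond])
        counts = rng.multinomial(total, weights / weights.sum())
        libraries[cond] = LibraryCounts(
            condition=cond,
            counts=pd.Series(counts, index=ids, name=cond),
            total_mapped_reads=total,
        )

    go_terms = _simulate_go(spec, rng, n, members)
    descriptions = pd.Series(
        [f"synthetic transcript ({truth['set_name'].iloc[i]})" for i in range(n)],
        index=ids,
        name="description",
    )
    catalog = TranscriptCatalog(
        lengths=pd.Series(lengths, index=ids, name="length_bp"),
        descriptions=descriptions,
        go_terms=go_terms,
    )
    return catalog, libraries, truth


def _simulate_go(spec, rng, n, members) -> dict:
    terms = [f"GO:{i:07d}" for i in range(1, spec.n_go_terms + 1)]
    if spec.planted_go_term not in terms:
        terms[-1] = spec.planted_go_term
    lo, hi = spec.go_freq_range
    freq = rng.uniform(lo, hi, len(terms))
    has_term = rng.random((n, len(terms))) < freq
    planted_col = terms.index(spec.planted_go_term)
    if spec.planted_go_set in members:
        block = members[spec.planted_go_set]
        has_term[block, planted_col] = rng.random(len(block)) < spec.planted_go_prob
    ids = [f"transcript{i:05d}" for i in range(1, n + 1)]
    out = {}
    for i, tid in enumerate(ids):
        carried = frozenset(t for j, t in enumerate(terms) if has_term[i, j])
        if carried:
            out[tid] = carried
    return out


def simulate_null_spots(
    spec: SimulationSpec,
    truth: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
):
    """Microarray spot table with a known pass-set.

    Spots backed by the low-abundance null pool are given quality metrics
    that pass every filter (valid, circular, uniform, snr < 1), with
    deliberate duplicate spot->transcript mappings and a few unmapped
    passing spots.  Decoy spots fail exactly one rule each (low
    circularity, high snr as a significant-signal spot, high within-spot
    CV, or invalid flag).  Returns ``(spots, spot_truth)`` where
    ``spot_truth`` holds each spot's id, pass/fail label and transcript.
    """
    if rng is None:
        rng = _rngs(spec)["spots"]
    pool = list(truth.index[truth["set_name"] == "null_pool"])
    if not pool:
        raise SimulationSpecError("truth table has no null_pool transcripts")
    spots, records = [], []
    n_pass = spec.n_null_spots

    def add(spot, should_pass):
        spots.append(spot)
        records.append(
            {
                "spot_id": spot.spot_id,
                "should_pass": should_pass,
                "transcript_id": spot.transcript_id,
            }
        )

    # passing spots: cycle over the pool so some transcripts get duplicates
    for k in range(n_pass):
        tid = pool[k % len(pool)] if k % 11 else None  # every 11th unmapped
        add(
            MicroarraySpot(
                spot_id=f"spot{k:04d}",
                circularity_pct=float(rng.uniform(82, 98)),
                intensity_cv=float(rng.uniform(0.01, 0.15)),
                valid_flag=True,
                snr=float(rng.uniform(0.05, 0.95)),
                transcript_id=tid,
            ),
            True,
        )
    # decoys, one failing rule each
    failure_modes = ("circularity", "snr", "cv", "flag")
    for k in range(n_pass, n_pass + 40):
        mode = failure_modes[k % 4]
        add(
            MicroarraySpot(
                spot_id=f"spot{k:04d}",
                circularity_pct=float(rng.uniform(40, 75))
                if mode == "circularity"
                else float(rng.uniform(82, 98)),
                intensity_cv=float(rng.uniform(0.4, 0.9))
                if mode == "cv"
                else float(rng.uniform(0.01, 0.15)),
                valid_flag=mode != "flag",
                snr=float(rng.uniform(3.5, 20.0))
                if mode == "snr"
                else float(rng.uniform(0.05, 0.95)),
                transcript_id=pool[k % len(pool)],
            ),
            False,
        )
    spot_truth = pd.DataFrame.from_records(records).set_index("spot_id")
    return spots, spot_truth


def simulate_qpcr(
    spec: SimulationSpec, rng: Optional[np.random.Generator] = None
):
    """Dilution-series standards and triplicate sample Cts.

    Standards span five decades (log10 amount -3..1) on the spec's line;
    sample Cts are the curve evaluated at each condition's true log10
    amount plus Gaussian noise.  The reference gene sits at amount 1 in
    every condition.  Returns ``(standards, samples, qpcr_truth)``.
    """
    if rng is None:
        rng = _rngs(spec)["qpcr"]
    genes = list(spec.qpcr_genes) + [
        QpcrGene(
            spec.reference_gene,
            {(s, d): 1.0 for s in ("dorsal", "ventral") for d in (4, 8)},
        )
    ]
    std_rows, sample_rows, truth_rows = [], [], []
    for gene in genes:
        for log10_amount in (-3.0, -2.0, -1.0, 0.0, 1.0):
            ct = spec.curve_slope * log10_amount + spec.curve_intercept
            if spec.standards_noise_sd > 0:
                ct += rng.normal(0.0, spec.standards_noise_sd)
            std_rows.append(
                {"gene": gene.name, "log10_amount": log10_amount, "ct": ct}
            )
        for (side, day), amount in sorted(gene.levels.items()):
            for rep in range(1, spec.n_replicates + 1):
                ct = spec.curve_slope * math.log10(amount) + spec.curve_intercept
                if spec.ct_noise_sd > 0:
                    ct += rng.normal(0.0, spec.ct_noise_sd)
                sample_rows.append(
                    {
                        "gene": gene.name,
                        "side": side,
                        "day": day,
                        "replicate": rep,
                        "ct": ct,
                    }
                )
            truth_rows.append(
                {"gene": gene.name, "side": side, "day": day, "true_amount": amount}
            )
    return (
        pd.DataFrame(std_rows),
        pd.DataFrame(sample_rows),
        pd.DataFrame(truth_rows),
    )


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Run all three generators from one seed, in a fixed substream order."""
    rngs = _rngs(spec)
    catalog, libraries, truth = simulate_counts(spec, rngs["counts"])
    spots, spot_truth = simulate_null_spots(spec, truth, rngs["spots"])
    standards, samples, qpcr_truth = simulate_qpcr(spec, rngs["qpcr"])
    return SimulatedDataset(
        catalog=catalog,
        libraries=libraries,
        truth=truth,
        spots=spots,
        spot_truth=spot_truth,
        standards=standards,
        samples=samples,
        qpcr_truth=qpcr_truth,
    )
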