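"""Detection cutoffs estimated from silent-but-valid microarray spots.

The transcriptome lacks a genome reference, so background read level cannot
be measured from intergenic regions.  Instead, the detection threshold is
borrowed from an independent microarray experiment on the same tissue:
spots with intact structure (circular, uniform, flagged valid) but no
signal (snr < 1; significant spots have snr > 3) mark transcripts that are
physically present on the array yet not detectably expressed.  The mean
RNA-seq RPKM of those transcripts, per library, is the RPKM value that
"looks like nothing" — anything above it is called expressed.

The quality filter, spot-to-transcript mapping and per-condition averaging
are separate operations so each is testable on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .errors import CutoffEstimationError
from .quantify import CONDITIONS, ExpressionTable


@dataclass(frozen=True)
class MicroarraySpot:
    """Precomputed quality metrics of one array spot.

    ``transcript_id`` is ``None`` when the array coordinate has no match in
    the transcriptome; such spots can pass the quality filter but contribute
    nothing to the null-transcript set.
    """

    spot_id: str
    circularity_pct: float
    intensity_cv: float
    valid_flag: bool
    snr: float
    transcript_id: Optional[str] = None

    def __post_init__(self):
        if not (0 <= self.circularity_pct <= 100):
            raise ValueError(f"spot {self.spot_id}: circularity outside [0, 100]")
        if self.snr < 0 or self.intensity_cv < 0:
            raise ValueError(f"spot {self.spot_id}: snr and cv must be >= 0")


@dataclass(frozen=True)
class CutoffSet:
    """One RPKM detection threshold per condition, plus its provenance."""

    cutoffs: Mapping[str, float]
    null_transcripts: frozenset

    def __post_init__(self):
        for cond, value in self.cutoffs.items():
            if value < 0 or not math.isfinite(value):
                raise CutoffEstimationError(f"cutoff for {cond} must be finite >= 0")

    def __getitem__(self, condition: str) -> float:
        return self.cutoffs[condition]


def select_null_spots(
    spots: Sequence[MicroarraySpot],
    circularity_min: float = 80.0,
    snr_max: float = 1.0,
    cv_max: float = 0.2,
) -> list[str]:
    """Spot ids with valid structure but no signal.

    Keeps spots that are flagged valid, with circularity strictly above
    ``circularity_min`` (%), within-spot intensity CV strictly below
    ``cv_max`` and snr strictly below ``snr_max``.  ``cv_max`` quantifies
    the otherwise loose "intensity variation very small" requirement; 0.2
    is the default and it is a free parameter.
    """
    if cv_max <= 0:
        raise ValueError("cv_max must be positive")
    for name, value in (("circularity_min", circularity_min), ("snr_max", snr_max)):
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite")
    return [
        s.spot_id
        for s in spots
        if s.valid_flag
        and s.circularity_pct > circularity_min
        and s.intensity_cv < cv_max
        and s.snr < snr_max
    ]


def map_spots_to_transcripts(
    selected: Iterable[str], spot_table: Sequence[MicroarraySpot]
) -> frozenset:
    """Non-redundant transcript set behind the selected spots.

    Duplicate spot->transcript mappings collapse; spots without a
    transcriptome match are dropped silently.
    """
    by_id = {s.spot_id: s for s in spot_table}
    selected = list(selected)
    unknown = [sid for sid in selected if sid not in by_id]
    if unknown:
        raise KeyError(f"spot id(s) not in spot table: {unknown[:3]}")
    return frozenset(
        by_id[sid].transcript_id
        for sid in selected
        if by_id[sid].transcript_id is not None
    )


def estimate_cutoffs(
    expression: ExpressionTable,
    null_transcripts: Iterable[str],
    method: str = "mean",
) -> CutoffSet:
    """Per-condition cutoff as the average null-transcript RPKM.

    ``method`` is ``"mean"`` (the default, matching the averaging the
    procedure prescribes) or ``"median"`` for robustness studies.

    Raises
    ------
    CutoffEstimationError
        If the null set is empty or contains transcripts missing from the
        expression table — no fallback threshold is invented.
    """
    null_ids = sorted(set(null_transcripts))
    if not null_ids:
        raise CutoffEstimationError("empty null-transcript set")
    missing = [t for t in null_ids if t not in expression.ids]
    if missing:
        raise CutoffEstimationError(
            f"null transcripts absent from expression table: {missing[:3]}"
        )
    if method not in ("mean", "median"):
        raise ValueError(f"unknown method {method!r}")
    sub = expression.rpkm.loc[null_ids, list(CONDITIONS)]
    agg = sub.mean() if method == "mean" else sub.median()
    return CutoffSet(
        cutoffs={cond: float(agg[cond]) for cond in CONDITIONS},
        null_transcripts=frozenset(null_ids),
    )
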