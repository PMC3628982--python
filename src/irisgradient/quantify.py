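"""RPKM quantification and expressed/not-expressed calls.

The pipeline starts from per-transcript unique-read counts (alignment is
upstream and out of scope).  Expression is summarised as reads per kilobase
of transcript per million mapped reads,

    RPKM(t) = 1e9 * C(t) / (N * L(t)),

where ``C`` is the unique-read count for transcript ``t``, ``L`` its length
in bp and ``N`` the library's total mapped reads.  A transcript is called
*expressed* in a library when its RPKM strictly exceeds that library's
detection cutoff (see :mod:`irisgradient.cutoffs`).

The four libraries of the dorsoventral design are labelled ``4dv``/``4dd``
(ventral/dorsal iris at 4 days post-lentectomy) and ``8dv``/``8dd`` (8 days).
Whether ``N`` counts all mapped reads or only the uniquely mapped subset is
left to the caller: the interface takes ``total_mapped_reads`` as given.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    CatalogError,
    CatalogMismatchError,
    InvalidLibraryError,
    SchemaError,
)

#: Library labels of the 2 sides x 2 timepoints design, in canonical order.
CONDITIONS = ("4dv", "4dd", "8dv", "8dd")

_GO_RE = re.compile(r"^GO:\d{7}$")


@dataclass(frozen=True)
class TranscriptCatalog:
    """Transcript ids with lengths, free-text annotation and GO labels.

    Parameters
    ----------
    lengths:
        Series of transcript lengths in bp, indexed by transcript id.
    descriptions:
        Free-text annotation per transcript (may be empty strings).
    go_terms:
        Mapping transcript id -> frozenset of ``GO:NNNNNNN`` identifiers.
    """

    lengths: pd.Series
    descriptions: pd.Series
    go_terms: Mapping[str, frozenset] = field(default_factory=dict)

    def __post_init__(self):
        idx = self.lengths.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise CatalogError(f"duplicate transcript id {dup!r}")
        if (self.lengths < 1).any() or not np.isfinite(self.lengths).all():
            raise CatalogError("transcript lengths must be integers >= 1")
        for tid, terms in self.go_terms.items():
            for term in terms:
                if not _GO_RE.match(term):
                    raise CatalogError(
                        f"malformed GO identifier {term!r} on {tid!r}"
                    )

    @classmethod
    def from_entries(cls, entries: Iterable[tuple]) -> "TranscriptCatalog":
        """Build from ``(transcript_id, length_bp, description, go_terms)``."""
        ids, lengths, descs, go = [], [], [], {}
        for tid, length, desc, terms in entries:
            ids.append(tid)
            lengths.append(int(length))
            descs.append(desc)
            if terms:
                go[tid] = frozenset(terms)
        idx = pd.Index(ids, name="transcript_id")
        return cls(
            lengths=pd.Series(lengths, index=idx, name="length_bp"),
            descriptions=pd.Series(descs, index=idx, name="description"),
            go_terms=go,
        )

    @property
    def ids(self) -> pd.Index:
        return self.lengths.index

    def __len__(self) -> int:
        return len(self.lengths)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.lengths.index

    def go_for(self, transcript_id: str) -> frozenset:
        return self.go_terms.get(transcript_id, frozenset())

    def with_go_terms(self, go_terms: Mapping[str, frozenset]) -> "TranscriptCatalog":
        """Return a copy carrying ``go_terms`` instead of the current labels."""
        return TranscriptCatalog(self.lengths, self.descriptions, dict(go_terms))


@dataclass(frozen=True)
class LibraryCounts:
    """Unique-read counts of one sequencing library.

    ``counts`` may omit transcripts (they are treated as zero); every id it
    does mention must exist in the catalog the counts are quantified against.
    """

    condition: str
    counts: pd.Series
    total_mapped_reads: int

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise SchemaError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if self.total_mapped_reads <= 0:
            raise InvalidLibraryError(
                f"library {self.condition}: total_mapped_reads must be positive"
            )
        if (self.counts < 0).any():
            raise InvalidLibraryError(
                f"library {self.condition}: negative read counts"
            )
        if self.counts.sum() > self.total_mapped_reads:
            raise InvalidLibraryError(
                f"library {self.condition}: counted reads exceed total_mapped_reads"
            )


def compute_rpkm(counts: LibraryCounts, catalog: TranscriptCatalog) -> pd.Series:
    """RPKM per transcript for one library, over the full catalog.

    Transcripts absent from ``counts`` get RPKM 0, so RPKM(t) == 0 exactly
    when no read mapped to t — the property the exclusivity rule relies on.

    Raises
    ------
    CatalogMismatchError
        If ``counts`` mentions a transcript the catalog does not contain.
    """
    unknown = counts.counts.index.difference(catalog.ids)
    if len(unknown):
        raise CatalogMismatchError(
            f"library {counts.condition}: {len(unknown)} transcript id(s) "
            f"not in catalog (first: {unknown[0]!r})"
        )
    c = counts.counts.reindex(catalog.ids, fill_value=0).astype(float)
    rpkm = 1e9 * c / (counts.total_mapped_reads * catalog.lengths.astype(float))
    rpkm.name = counts.condition
    return rpkm


def is_expressed(rpkm: float, cutoff: float) -> bool:
    """True when ``rpkm`` strictly exceeds the detection ``cutoff``.

    The comparison is strict ("more than the cutoff"): a transcript sitting
    exactly at the threshold is not called expressed.
    """
    if rpkm < 0 or cutoff < 0:
        raise ValueError("rpkm and cutoff must be non-negative")
    return rpkm > cutoff


@dataclass(frozen=True)
class ExpressionTable:
    """RPKM and raw counts for all transcripts across the four conditions."""

    rpkm: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self):
        for frame in (self.rpkm, self.counts):
            missing = [c for c in CONDITIONS if c not in frame.columns]
            if missing:
                raise SchemaError(f"expression table missing conditions {missing}")
        if not self.rpkm.index.equals(self.counts.index):
            raise SchemaError("rpkm and counts indexed by different transcripts")

    @classmethod
    def from_libraries(
        cls,
        catalog: TranscriptCatalog,
        libraries: Mapping[str, LibraryCounts],
    ) -> "ExpressionTable":
        """Quantify the four libraries against ``catalog``."""
        missing = [c for c in CONDITIONS if c not in libraries]
        if missing:
            raise SchemaError(f"missing libraries for conditions {missing}")
        rpkm = pd.DataFrame(
            {cond: compute_rpkm(libraries[cond], catalog) for cond in CONDITIONS}
        )
        counts = pd.DataFrame(
            {
                cond: libraries[cond]
                .counts.reindex(catalog.ids, fill_value=0)
                .astype(int)
                for cond in CONDITIONS
            }
        )
        return cls(rpkm=rpkm, counts=counts)

    @property
    def ids(self) -> pd.Index:
        return self.rpkm.index

    def expressed(self, cutoffs: Mapping[str, float]) -> pd.DataFrame:
        """Boolean expressed-call matrix (strict RPKM > cutoff per condition)."""
        return pd.DataFrame(
            {cond: self.rpkm[cond] > cutoffs[cond] for cond in CONDITIONS}
        )
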