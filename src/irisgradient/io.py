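"""Readers and writers for every pipeline format, plus the end-to-end run.

Formats are deliberately plain: tab-separated tables for counts, catalogs
and results, comma-separated tables for microarray spots and qPCR data,
OBO 1.2 for the ontology and FASTA for sequence-derived catalogs.  Output
floats are written with 3 decimals and undefined log ratios as ``NA``.

The package also ships two transcribed reference tables — the published
50-transcript dorsally-enriched and 50-transcript ventrally-enriched
fold-change tables — used by the regression tests and the worked examples
(spreadsheet artifacts in the originals are normalised to ``NA``).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import obonet
import pandas as pd
import yaml

from . import __version__
from .cutoffs import CutoffSet, MicroarraySpot, estimate_cutoffs, map_spots_to_transcripts, select_null_spots
from .enrichment import enrich, propagate_annotations
from .errors import CatalogError, ParseError, SchemaError
from .gradient import build_gradient_table, build_temporal_table
from .quantify import CONDITIONS, ExpressionTable, LibraryCounts, TranscriptCatalog
from .qpcr import (
    amounts_from_cts,
    fit_standard_curve,
    normalized_expression,
    two_way_anova,
)

_FLOAT_FMT = "%.3f"


# ---------------------------------------------------------------- catalogs


def read_catalog_tsv(path) -> TranscriptCatalog:
    """Catalog TSV: transcript_id, length_bp, description, go_terms.

    ``go_terms`` holds semicolon-separated GO identifiers and may be empty.
    """
    frame = _read_table(path, sep="\t", required={"transcript_id", "length_bp"})
    if frame["transcript_id"].duplicated().any():
        dup = frame.loc[frame["transcript_id"].duplicated(), "transcript_id"].iloc[0]
        raise CatalogError(f"duplicate transcript id {dup!r} in {path}")
    entries = []
    for _, row in frame.iterrows():
        terms = ()
        raw = row.get("go_terms", "")
        if isinstance(raw, str) and raw.strip():
            terms = tuple(t.strip() for t in raw.split(";") if t.strip())
        entries.append(
            (
                row["transcript_id"],
                int(row["length_bp"]),
                str(row.get("description", "") or ""),
                terms,
            )
        )
    return TranscriptCatalog.from_entries(entries)


def write_catalog_tsv(catalog: TranscriptCatalog, path) -> None:
    frame = pd.DataFrame(
        {
            "length_bp": catalog.lengths,
            "description": catalog.descriptions,
            "go_terms": [
                ";".join(sorted(catalog.go_for(t))) for t in catalog.ids
            ],
        },
        index=catalog.ids,
    )
    frame.to_csv(path, sep="\t")


def read_catalog_fasta(path, go_terms=None) -> TranscriptCatalog:
    """Catalog from a FASTA file; lengths are the sequence lengths."""
    from Bio import SeqIO

    entries = []
    seen = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise CatalogError(f"duplicate transcript id {record.id!r} in {path}")
        seen.add(record.id)
        terms = (go_terms or {}).get(record.id, ())
        entries.append((record.id, len(record.seq), record.description, terms))
    if not entries:
        raise ParseError("no FASTA records found", path=path)
    return TranscriptCatalog.from_entries(entries)


# ------------------------------------------------------------------ counts


def read_counts_tsv(counts_path, libraries_path) -> dict:
    """Counts TSV (transcript_id, count_4dv, ...) + library-size TSV.

    The companion table has columns ``condition`` and ``total_mapped_reads``
    with one row per library.  Returns ``{condition: LibraryCounts}``.
    """
    counts = _read_table(
        counts_path,
        sep="\t",
        required={"transcript_id"} | {f"count_{c}" for c in CONDITIONS},
    )
    if counts["transcript_id"].duplicated().any():
        raise ParseError("duplicate transcript ids in counts table", path=counts_path)
    sizes = _read_table(
        libraries_path, sep="\t", required={"condition", "total_mapped_reads"}
    ).set_index("condition")["total_mapped_reads"]
    missing = [c for c in CONDITIONS if c not in sizes.index]
    if missing:
        raise SchemaError(f"library table missing conditions {missing}")
    idx = pd.Index(counts["transcript_id"], name="transcript_id")
    out = {}
    for cond in CONDITIONS:
        col = counts[f"count_{cond}"]
        if not np.issubdtype(col.dtype, np.integer):
            raise ParseError(
                f"non-integer counts in column count_{cond}", path=counts_path
            )
        out[cond] = LibraryCounts(
            condition=cond,
            counts=pd.Series(col.to_numpy(), index=idx, name=cond),
            total_mapped_reads=int(sizes[cond]),
        )
    return out


def write_counts_tsv(libraries: dict, counts_path, libraries_path) -> None:
    ids = libraries[CONDITIONS[0]].counts.index
    frame = pd.DataFrame(
        {f"count_{c}": libraries[c].counts.reindex(ids, fill_value=0) for c in CONDITIONS},
        index=ids,
    )
    frame.to_csv(counts_path, sep="\t")
    pd.DataFrame(
        {
            "condition": list(CONDITIONS),
            "total_mapped_reads": [
                libraries[c].total_mapped_reads for c in CONDITIONS
            ],
        }
    ).to_csv(libraries_path, sep="\t", index=False)


# ------------------------------------------------------------------- spots


def read_spots_csv(path) -> list:
    frame = _read_table(
        path,
        sep=",",
        required={"spot_id", "circularity_pct", "intensity_cv", "valid_flag", "snr"},
    )
    spots = []
    for _, row in frame.iterrows():
        tid = row.get("transcript_id")
        if isinstance(tid, float) and math.isnan(tid):
            tid = None
        if tid == "":
            tid = None
        spots.append(
            MicroarraySpot(
                spot_id=str(row["spot_id"]),
                circularity_pct=float(row["circularity_pct"]),
                intensity_cv=float(row["intensity_cv"]),
                valid_flag=bool(int(row["valid_flag"])),
                snr=float(row["snr"]),
                transcript_id=tid,
            )
        )
    return spots


def write_spots_csv(spots, path) -> None:
    pd.DataFrame(
        [
            {
                "spot_id": s.spot_id,
                "circularity_pct": s.circularity_pct,
                "intensity_cv": s.intensity_cv,
                "valid_flag": int(s.valid_flag),
                "snr": s.snr,
                "transcript_id": s.transcript_id or "",
            }
            for s in spots
        ]
    ).to_csv(path, index=False, float_format="%.17g")  # lossless round trip


# ----------------------------------------------------------------- cutoffs


def write_cutoffs_tsv(cutoffs: CutoffSet, path) -> None:
    pd.DataFrame(
        {
            "condition": list(CONDITIONS),
            "cutoff_rpkm": [cutoffs[c] for c in CONDITIONS],
        }
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_cutoffs_tsv(path) -> CutoffSet:
    frame = _read_table(path, sep="\t", required={"condition", "cutoff_rpkm"})
    mapping = dict(zip(frame["condition"], frame["cutoff_rpkm"].astype(float)))
    missing = [c for c in CONDITIONS if c not in mapping]
    if missing:
        raise SchemaError(f"cutoff table missing conditions {missing}")
    return CutoffSet(cutoffs=mapping, null_transcripts=frozenset())


# ------------------------------------------------------------ result tables


def write_gradient_tsv(table: pd.DataFrame, path, catalog=None) -> None:
    """Fold-change table in the published column layout, NA for undefined."""
    out = table.copy()
    if catalog is not None:
        out.insert(0, "annotation", catalog.descriptions.reindex(out.index))
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT, na_rep="NA")


def write_enrichment_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


# -------------------------------------------------------------------- qPCR


def read_qpcr_samples_csv(path) -> pd.DataFrame:
    return _read_table(path, sep=",", required={"gene", "side", "day", "replicate", "ct"})


def read_qpcr_standards_csv(path) -> pd.DataFrame:
    return _read_table(path, sep=",", required={"gene", "log10_amount", "ct"})


# --------------------------------------------------------------- ontologies


def read_obo(path):
    """GO graph from an OBO 1.2 flat file (id, name, is_a, part_of)."""
    return obonet.read_obo(str(path))


# ---------------------------------------------------- packaged fixtures


def load_reference_gradient_table(which: str = "dorsal") -> pd.DataFrame:
    """One of the two shipped published fold-change reference tables.

    ``which`` is ``"dorsal"`` or ``"ventral"``.  Columns: annotation, the
    four RPKM values (v4, d4, v8, d8) and the three printed log2 fold
    changes (``log2fc4, log2fc8, log2fc``; NaN where the original printed
    an undefined-value placeholder).
    """
    if which not in ("dorsal", "ventral"):
        raise ValueError("which must be 'dorsal' or 'ventral'")
    name = f"reference_{which}_up.tsv"
    with resources.files("irisgradient.data").joinpath(name).open() as fh:
        frame = pd.read_csv(fh, sep="\t", na_values=["NA"])
    return frame.set_index("transcript_id")


# ------------------------------------------------------------- full runs


@dataclass
class PipelineConfig:
    """File locations and thresholds of one end-to-end run."""

    counts_path: str
    libraries_path: str
    catalog_path: str
    spots_path: str
    out_dir: str
    samples_path: Optional[str] = None
    standards_path: Optional[str] = None
    obo_path: Optional[str] = None
    reference_gene: str = "RPL27"
    dorsoventral_fold: float = 2.0
    temporal_fold: float = 2.0
    alpha: float = 0.05
    circularity_min: float = 80.0
    snr_max: float = 1.0
    cv_max: float = 0.2
    one_sided_fisher: bool = False
    propagate_go: bool = False
    require_both_sides: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.dorsoventral_fold <= 1 or self.temporal_fold <= 1:
            raise ValueError("fold thresholds must exceed 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def run_all(config: PipelineConfig) -> dict:
    """Quantify, estimate cutoffs, classify, enrich and (optionally) score
    qPCR, writing every result table plus a run manifest to ``out_dir``.

    Returns the output paths keyed by stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # annotate with the failing stage
            raise type(exc)(f"[stage {name}] {exc}") from exc

    catalog = _stage("catalog", lambda: read_catalog_tsv(config.catalog_path))
    if config.propagate_go:
        if not config.obo_path:
            raise SchemaError("[stage catalog] propagate_go requires obo_path")
        ontology = _stage("catalog", lambda: read_obo(config.obo_path))
        catalog = _stage("catalog", lambda: propagate_annotations(catalog, ontology))
    libraries = _stage(
        "quantify", lambda: read_counts_tsv(config.counts_path, config.libraries_path)
    )
    expression = _stage(
        "quantify", lambda: ExpressionTable.from_libraries(catalog, libraries)
    )

    def _cutoffs():
        spots = read_spots_csv(config.spots_path)
        selected = select_null_spots(
            spots, config.circularity_min, config.snr_max, config.cv_max
        )
        null_ids = map_spots_to_transcripts(selected, spots)
        return estimate_cutoffs(expression, null_ids)

    cutoffs = _stage("cutoff", _cutoffs)
    written["cutoffs"] = out_dir / "cutoffs.tsv"
    write_cutoffs_tsv(cutoffs, written["cutoffs"])

    gradient = _stage(
        "compare",
        lambda: build_gradient_table(
            expression,
            cutoffs,
            fold_threshold=config.dorsoventral_fold,
            require_both_sides=config.require_both_sides,
        ),
    )
    written["gradient"] = out_dir / "gradient_table.tsv"
    write_gradient_tsv(gradient, written["gradient"], catalog=catalog)

    temporal = _stage(
        "compare",
        lambda: build_temporal_table(expression, cutoffs, config.temporal_fold),
    )
    written["temporal"] = out_dir / "temporal_table.tsv"
    temporal.to_csv(written["temporal"], sep="\t", float_format=_FLOAT_FMT, na_rep="NA")

    all_ids = set(map(str, catalog.ids))
    dorsal_up = set(gradient.index[gradient["dv_class"].isin(["dorsal_up", "dorsal_exclusive"])])
    ventral_up = set(gradient.index[gradient["dv_class"].isin(["ventral_up", "ventral_exclusive"])])
    comparisons = {
        "enrichment_dorsal_vs_ventral": (dorsal_up, ventral_up, "group_vs_group"),
        "enrichment_ventral_vs_dorsal": (ventral_up, dorsal_up, "group_vs_group"),
    }
    for direction in ("day4_up", "day8_up"):
        group = set(temporal.index[temporal["day_class"] == direction])
        comparisons[f"enrichment_{direction}_vs_rest"] = (
            group,
            all_ids - group,
            "group_vs_rest",
        )
    for name, (test, ref, mode) in comparisons.items():
        frame = _stage(
            "enrich",
            lambda test=test, ref=ref, mode=mode: enrich(
                test,
                ref,
                catalog,
                alpha=config.alpha,
                mode=mode,
                one_sided=config.one_sided_fisher,
            )
            if test
            else None,
        )
        if frame is None:
            continue
        written[name] = out_dir / f"{name}.tsv"
        write_enrichment_tsv(frame, written[name])

    if config.samples_path and config.standards_path:

        def _qpcr():
            samples = read_qpcr_samples_csv(config.samples_path)
            standards = read_qpcr_standards_csv(config.standards_path)
            curves = {
                gene: fit_standard_curve(
                    list(zip(sub["log10_amount"], sub["ct"]))
                )
                for gene, sub in standards.groupby("gene")
            }
            amounts = amounts_from_cts(samples, curves)
            normalized = normalized_expression(amounts, config.reference_gene)
            rows = []
            for gene, sub in normalized.groupby("gene"):
                anova = two_way_anova(sub, value_col="relative_expression")
                rows.append(
                    {
                        "gene": gene,
                        "efficiency": curves[gene].efficiency,
                        "F_side": anova.loc["side", "F"],
                        "p_side": anova.loc["side", "p"],
                        "F_day": anova.loc["day", "F"],
                        "p_day": anova.loc["day", "p"],
                        "F_interaction": anova.loc["side:day", "F"],
                        "p_interaction": anova.loc["side:day", "p"],
                    }
                )
            report = pd.DataFrame(rows)
            norm_out = normalized[
                ["gene", "side", "day", "replicate", "ct", "amount", "relative_expression"]
            ]
            return report, norm_out

        report, norm_out = _stage("qpcr", _qpcr)
        written["qpcr_report"] = out_dir / "qpcr_report.tsv"
        report.to_csv(written["qpcr_report"], sep="\t", index=False, float_format="%.6g")
        written["qpcr_expression"] = out_dir / "qpcr_expression.tsv"
        norm_out.to_csv(
            written["qpcr_expression"], sep="\t", index=False, float_format="%.6g"
        )

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if not k.endswith("_path") and k != "out_dir"
        },
        "cutoffs": {c: cutoffs[c] for c in CONDITIONS},
        "n_transcripts": int(len(catalog)),
        "outputs": {k: str(v) for k, v in written.items()},
    }
    manifest_path = out_dir / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written["manifest"] = manifest_path
    return written


# ------------------------------------------------------------------ helpers


def _read_table(path, sep, required) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ParseError("empty input file", path=path) from None
    missing = sorted(required - set(frame.columns))
    if missing:
        raise ParseError(f"missing required column(s) {missing}", path=path, line=1)
    return frame
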