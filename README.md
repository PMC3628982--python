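# irisgradient

Analysis pipeline for dorsoventral expression gradients in the
regenerating newt iris.  After lens removal (lentectomy), only the dorsal
iris of the newt regenerates a lens; the ventral iris, although exposed to
the same injury, does not.  Comparing the transcriptomes of dorsal and
ventral iris at 4 and 8 days post-lentectomy (dpl) asks which genes give
the dorsal iris its regenerative identity.  This package implements that
comparison as a tested, deterministic pipeline for bulk RNA-seq
read-count data — plus the simulation machinery needed to validate every
stage against planted ground truth.

## What it computes

* **RPKM quantification** — per transcript and library,
  `RPKM = 1e9 · C / (N · L)` with unique-read count `C`, library depth `N`
  and transcript length `L` (bp).  Zero counts stay in the table as
  RPKM 0.
* **Detection cutoffs** — the expressed/not-expressed threshold per
  library is the mean RPKM of transcripts behind microarray spots that are
  structurally valid (circularity > 80 %, uniform intensity, valid flag)
  but signal-free (snr < 1): real probes measuring nothing.
* **Gradient classification** — per-day log2 ratios
  `log2Fc4 = log2(d4/v4)`, `log2Fc8 = log2(d8/v8)` and the combined
  ranking statistic `log2Fc = log2((d4+d8)/(v4+v8))`; transcripts are
  classed `dorsal_up` / `ventral_up` (expressed above cutoff on the up
  side both days, ≥ 2-fold both days), `dorsal_exclusive` /
  `ventral_exclusive` (zero reads on the opposite side both days), or
  `unclassified`.  A temporal mode classifies day-4-up / day-8-up
  transcripts (> 2-fold on *both* sides).
* **GO enrichment** — Fisher's exact test per GO term
  (group-vs-group or group-vs-rest), Benjamini–Hochberg FDR < 0.05,
  optional is_a/part_of ancestor propagation from an OBO file.
* **qPCR validation statistics** — standard-curve fits
  (`Ct = slope·log10(amount) + intercept`, efficiency
  `10^(−1/slope) − 1`), per-replicate back-transformation, normalization
  to a reference gene (RPL27), dorsoventral ratio with a delta-method SE,
  Levene-gated Student/Welch t-tests and balanced two-way side × day
  ANOVA.
* **Synthetic data** — negative-binomial counts over a log-normal
  transcript catalog with planted fold-change sets, side-exclusive sets, a
  planted GO term, null microarray spots and qPCR panels, all
  reproducible from one seed.

The package also ships, as packaged data, the two published 50-row
reference tables of the most dorsally- and ventrally-enriched transcripts
(RPKM quadruples plus printed fold-change columns), which the test suite
reproduces from scratch.

## Worked example

```python
from irisgradient import (
    SimulationSpec, simulate_dataset, ExpressionTable, estimate_cutoffs,
    select_null_spots, map_spots_to_transcripts, build_gradient_table, enrich,
)

data = simulate_dataset(SimulationSpec(seed=17))
expression = ExpressionTable.from_libraries(data.catalog, data.libraries)
cutoffs = estimate_cutoffs(
    expression, map_spots_to_transcripts(select_null_spots(data.spots), data.spots)
)
table = build_gradient_table(expression, cutoffs, fold_threshold=2)
print(table["dv_class"].value_counts().to_dict())
```

prints

```
{'unclassified': 4569, 'ventral_up': 235, 'dorsal_up': 186,
 'dorsal_exclusive': 5, 'ventral_exclusive': 5}
```

— of 5,000 synthetic transcripts, the 100 planted fold-8 dorsal-up
transcripts are recovered at sensitivity 0.96 inside the 186 `dorsal_up`
calls, and all 5 planted dorsal-exclusive transcripts are found.  Feeding
the dorsal-up set into `enrich` against the ventral-up set flags the
planted cell-cycle-like term `GO:0007049` at FDR ≈ 1e-21.  The
`examples/` directory walks through each capability
(`python examples/03_dorsoventral_gradient.py` etc.), and the same
stages are scriptable from the shell:

```bash
irisgradient simulate --seed 17 --out data/
irisgradient run-all --counts data/counts.tsv --libraries data/libraries.tsv \
    --catalog data/catalog.tsv --spots data/spots.csv --out results/
```

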