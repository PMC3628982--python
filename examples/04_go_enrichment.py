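"""GO term enrichment of the dorsally up-regulated transcript set.

Classifies a synthetic dataset, then asks which GO terms are
over-represented among dorsal-up transcripts relative to ventral-up ones
(Fisher's exact test, Benjamini-Hochberg FDR < 0.05).  The generator
plants a cell-cycle-like term in the dorsal set, mimicking the hallmark
signature of the regenerating dorsal iris.
"""

from irisgradient import (
    ExpressionTable,
    SimulationSpec,
    build_gradient_table,
    enrich,
    estimate_cutoffs,
    map_spots_to_transcripts,
    select_null_spots,
    simulate_dataset,
)

data = simulate_dataset(SimulationSpec(seed=17))
expression = ExpressionTable.from_libraries(data.catalog, data.libraries)
cutoffs = estimate_cutoffs(
    expression, map_spots_to_transcripts(select_null_spots(data.spots), data.spots)
)
table = build_gradient_table(expression, cutoffs)

dorsal = set(table.index[table["dv_class"].isin(["dorsal_up", "dorsal_exclusive"])])
ventral = set(table.index[table["dv_class"].isin(["ventral_up", "ventral_exclusive"])])
result = enrich(dorsal, ventral, data.catalog, alpha=0.05, mode="group_vs_group")

print(f"dorsal-up set: {len(dorsal)} transcripts; ventral-up: {len(ventral)}")
print(f"terms tested: {len(result)}, significant at FDR<0.05: "
      f"{int(result['significant'].sum())}")
print("\ntop terms (a/b = test with/without, c/d = reference):")
print(result.head(4)[["go_id", "a", "b", "c", "d", "p_value", "fdr", "enriched_in"]]
      .to_string(index=False))

# The planted term GO:0007049 should dominate with an FDR many orders of
# magnitude below 0.05; unplanted terms hover near uniform p-values.
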