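"""GO term enrichment by Fisher's exact test with BH false-discovery control.

Two comparison modes mirror the two selection workflows:

* ``group_vs_group`` — e.g. dorsally up-regulated transcripts against
  ventrally up-regulated ones;
* ``group_vs_rest`` — a selected group against the remaining transcriptome.

For each GO term annotating at least one transcript in either set, a 2x2
contingency table is built (term membership x set membership) and tested
with Fisher's exact test; p-values across all tested terms are adjusted
with the Benjamini–Hochberg step-up procedure and a term is significant
when its FDR falls below ``alpha`` (default 0.05).

The default test is two-sided by the minimum-likelihood convention (the sum
of the probabilities of all margin-fixed tables no more likely than the
observed one); a one-sided enrichment-only variant (upper hypergeometric
tail) is available since annotation tools have historically offered both.
Optional ancestor propagation closes each transcript's annotation set under
the ontology's is_a / part_of relations before testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Set

import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import OntologyError
from .quantify import TranscriptCatalog

_PROPAGATED_RELATIONS = ("is_a", "part_of")


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of a 2x2 term-by-set table.

    a: test-set transcripts carrying the term, b: test-set without,
    c: reference-set with, d: reference-set without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value of a 2x2 table.

    Degenerate tables (an empty row or column) carry no evidence and return
    p = 1.
    """
    t = table
    if (t.a + t.b == 0) or (t.c + t.d == 0) or (t.a + t.c == 0) or (t.b + t.d == 0):
        return 1.0
    p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")[1]
    return float(min(p, 1.0))


def fisher_exact_one_sided(table: ContingencyTable) -> float:
    """Upper-tail (enrichment in the test set) Fisher exact p-value."""
    t = table
    if (t.a + t.b == 0) or (t.c + t.d == 0) or (t.a + t.c == 0) or (t.b + t.d == 0):
        return 1.0
    p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="greater")[1]
    return float(min(p, 1.0))


def bh_fdr(p_values: Iterable[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values, in the input order.

    q(i) = min over ranks j >= rank(i) of p(j) * m / j, capped at 1.
    """
    p = list(p_values)
    if not p:
        return []
    if any((x < 0 or x > 1) for x in p):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def propagate_annotations(
    catalog: TranscriptCatalog, ontology: nx.MultiDiGraph
) -> TranscriptCatalog:
    """Close every transcript's GO set under is_a/part_of ancestors.

    ``ontology`` is the graph an OBO reader produces: one node per term,
    edges pointing child -> parent, keyed by relation type.  Only is_a and
    part_of edges are followed.  Terms absent from the ontology are kept
    as-is.  Idempotent.
    """
    closure_graph = nx.DiGraph(
        (u, v)
        for u, v, key in ontology.edges(keys=True)
        if key in _PROPAGATED_RELATIONS
    )
    if not nx.is_directed_acyclic_graph(closure_graph):
        raise OntologyError("cycle detected among is_a/part_of relations")

    ancestor_cache: dict[str, frozenset] = {}

    def ancestors(term: str) -> frozenset:
        if term not in ancestor_cache:
            if term in closure_graph:
                # edges point child -> parent, so ancestors are descendants
                # in graph orientation
                anc = frozenset(nx.descendants(closure_graph, term))
            else:
                anc = frozenset()
            ancestor_cache[term] = anc
        return ancestor_cache[term]

    closed = {}
    for tid, terms in catalog.go_terms.items():
        full = set(terms)
        for term in terms:
            full |= ancestors(term)
        closed[tid] = frozenset(full)
    return catalog.with_go_terms(closed)


def enrich(
    test_ids: Set[str],
    reference_ids: Set[str],
    catalog: TranscriptCatalog,
    alpha: float = 0.05,
    mode: str = "group_vs_group",
    one_sided: bool = False,
    ontology: Optional[nx.MultiDiGraph] = None,
) -> pd.DataFrame:
    """Per-term enrichment table for a test set against a reference set.

    In ``group_vs_rest`` mode the reference is forced to the complement of
    the test set within the catalog (a supplied ``reference_ids`` is
    validated against that).  Returns a DataFrame with columns ``go_id,
    term_name, a, b, c, d, p_value, fdr, enriched_in, significant`` sorted
    by FDR then term id.  Terms with no occurrence in either set are not
    tested and do not inflate the correction.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if mode not in ("group_vs_group", "group_vs_rest"):
        raise ValueError(f"unknown mode {mode!r}")
    test_ids = set(test_ids)
    if mode == "group_vs_rest":
        complement = set(map(str, catalog.ids)) - test_ids
        if reference_ids and set(reference_ids) != complement:
            raise ValueError(
                "group_vs_rest reference must be the catalog minus the test set"
            )
        reference_ids = complement
    reference_ids = set(reference_ids)
    overlap = test_ids & reference_ids
    if overlap:
        raise ValueError(f"test and reference sets overlap ({len(overlap)} ids)")
    if not test_ids:
        warnings.warn("empty test set: no terms to test", stacklevel=2)
        return _empty_enrichment_frame()

    go_of = catalog.go_terms
    terms = sorted(
        set().union(*(go_of.get(t, frozenset()) for t in test_ids | reference_ids))
        if (test_ids | reference_ids)
        else set()
    )
    names = _term_names(ontology)
    n_test, n_ref = len(test_ids), len(reference_ids)
    rows = []
    test_fn = fisher_exact_one_sided if one_sided else fisher_exact_two_sided
    for term in terms:
        a = sum(1 for t in test_ids if term in go_of.get(t, frozenset()))
        c = sum(1 for t in reference_ids if term in go_of.get(t, frozenset()))
        table = ContingencyTable(a, n_test - a, c, n_ref - c)
        p = test_fn(table)
        test_rate = a / n_test if n_test else 0.0
        ref_rate = c / n_ref if n_ref else 0.0
        rows.append(
            {
                "go_id": term,
                "term_name": names.get(term, ""),
                "a": a,
                "b": n_test - a,
                "c": c,
                "d": n_ref - c,
                "p_value": p,
                "enriched_in": "test" if test_rate >= ref_rate else "reference",
            }
        )
    frame = pd.DataFrame.from_records(rows)
    if frame.empty:
        return _empty_enrichment_frame()
    frame["fdr"] = bh_fdr(frame["p_value"])
    frame["significant"] = frame["fdr"] < alpha
    frame = frame.sort_values(["fdr", "go_id"]).reset_index(drop=True)
    return frame[
        [
            "go_id",
            "term_name",
            "a",
            "b",
            "c",
            "d",
            "p_value",
            "fdr",
            "enriched_in",
            "significant",
        ]
    ]


def _empty_enrichment_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "go_id",
            "term_name",
            "a",
            "b",
            "c",
            "d",
            "p_value",
            "fdr",
            "enriched_in",
            "significant",
        ]
    )


def _term_names(ontology: Optional[nx.MultiDiGraph]) -> dict:
    if ontology is None:
        return {}
    return {
        node: data.get("name", "") for node, data in ontology.nodes(data=True)
    }
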