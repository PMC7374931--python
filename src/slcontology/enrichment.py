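"""Substrate-term over-representation analysis of transporter gene sets.

Given a differential-expression table, the upregulated transporters
(log2 fold change > 0.5 at 5% FDR by default) are tested for enrichment
of substrate-ontology terms with a one-sided Fisher's exact test and
Benjamini-Hochberg correction.  Only chemical-entity terms carried by at
least five but fewer than 70% of annotated transporters are testable,
and reporting keeps the most specific enriched term of each branch
(an enriched term with no enriched descendant).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import SchemaError
from .ontology import OntologyGraph, term_to_slcs

DEFAULT_LFC_MIN = 0.5
DEFAULT_FDR_MAX = 0.05
DEFAULT_MIN_SLC = 5
DEFAULT_MAX_FRACTION = 0.7
SIGNIFICANCE_Q = 0.05


@dataclass(frozen=True)
class DEGene:
    """One row of a differential-expression result."""

    gene: str
    log2fc: float
    fdr: float

    def __post_init__(self):
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"{self.gene}: fdr {self.fdr} outside [0, 1]")


@dataclass
class EnrichmentResult:
    """Per-term 2x2 test outcome.

    ``a`` = upregulated transporters annotated with the term,
    ``b`` = upregulated without the term, ``c`` = non-upregulated with
    the term, ``d`` = the rest of the universe.
    """

    term_id: str
    term_label: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    q_value: float = 1.0
    significant: bool = False
    most_specific: bool = False


def hypergeom_tail_p(a, b, c, d):
    """One-sided over-representation p for a 2x2 table: the upper
    hypergeometric tail P[X >= a] with population a+b+c+d, a+c marked,
    and a+b drawn.  Identical to a one-sided Fisher's exact test.
    Accepts scalars or equal-shaped integer arrays."""
    a = np.asarray(a)
    return hypergeom.sf(a - 1, a + b + c + d, a + c, a + b)


def read_de_table(path, sep: str = "\t") -> list[DEGene]:
    """Load a DE table with columns gene, log2fc, fdr."""
    df = pd.read_csv(path, sep=sep)
    for col in ("gene", "log2fc", "fdr"):
        if col not in df.columns:
            raise SchemaError(f"DE table missing column {col!r}")
    return [
        DEGene(str(r.gene), float(r.log2fc), float(r.fdr))
        for r in df.itertuples(index=False)
    ]


def filter_upregulated(
    de_table: list[DEGene],
    slc_ids: set[str],
    lfc_min: float = DEFAULT_LFC_MIN,
    fdr_max: float = DEFAULT_FDR_MAX,
) -> set[str]:
    """Upregulated transporter genes: log2fc > lfc_min and fdr < fdr_max
    (both strict), intersected with *slc_ids*.

    Gene symbols are matched case-insensitively; the returned set uses
    the spelling from *slc_ids*.
    """
    slc_by_key = {s.strip().lower(): s for s in slc_ids}
    hits: set[str] = set()
    for row in de_table:
        if row.log2fc > lfc_min and row.fdr < fdr_max:
            key = row.gene.strip().lower()
            if key in slc_by_key:
                hits.add(slc_by_key[key])
    return hits


def select_testable_terms(
    graph: OntologyGraph,
    min_slc: int = DEFAULT_MIN_SLC,
    max_fraction: float = DEFAULT_MAX_FRACTION,
    universe: set[str] | None = None,
) -> set[str]:
    """Chemical-entity terms carried by >= *min_slc* and by strictly
    fewer than *max_fraction* of the annotated transporters.

    The annotated-transporter universe defaults to all transporters with
    at least one ontology term (i.e. all SLC nodes in the graph); role
    terms are never testable.
    """
    t2s = term_to_slcs(graph)
    if universe is None:
        n_annotated = len(graph.slc_nodes())
    else:
        n_annotated = len(universe)
        t2s = {t: s & universe for t, s in t2s.items()}
    limit = max_fraction * n_annotated
    return {
        t
        for t, slcs in t2s.items()
        if graph.namespace(t) == "chemical_entity"
        and len(slcs) >= min_slc
        and len(slcs) < limit
    }


def fisher_enrichment(
    hits: set[str],
    universe: set[str],
    term_slcs: dict[str, set[str]],
    graph: OntologyGraph | None = None,
    alpha: float = SIGNIFICANCE_Q,
) -> list[EnrichmentResult]:
    """One-sided (over-representation) Fisher's exact test per term.

    *hits* must be a subset of *universe*; each term's transporter set is
    intersected with the universe before counting.  Benjamini-Hochberg
    q-values are computed across all tested terms; ``significant`` means
    q < *alpha*.  Results are sorted by increasing p.
    """
    if not hits <= universe:
        raise ValueError(f"hits not a subset of universe: {sorted(hits - universe)}")
    results: list[EnrichmentResult] = []
    n = len(universe)
    for term_id in sorted(term_slcs):
        annot = term_slcs[term_id] & universe
        a = len(hits & annot)
        b = len(hits) - a
        c = len(annot) - a
        d = n - a - b - c
        p = hypergeom_tail_p(a, b, c, d)
        odds = (a * d) / (b * c) if b * c else float("inf") if a * d else float("nan")
        label = graph.label(term_id) if graph is not None and term_id in graph else term_id
        results.append(
            EnrichmentResult(term_id, label, a, b, c, d, float(odds), float(p))
        )
    if results:
        reject, qvals, _, _ = multipletests(
            [r.p_value for r in results], alpha=alpha, method="fdr_bh"
        )
        for r, q, rej in zip(results, qvals, reject):
            r.q_value = float(q)
            r.significant = bool(q < alpha)
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def most_specific_terms(
    results: list[EnrichmentResult], graph: OntologyGraph
) -> list[EnrichmentResult]:
    """Flag significant terms that have no significant descendant.

    A term is redundant if a more specific significant term lies below it
    (the general term is reachable from the specific one by directed
    paths); only the most specific terms of each enriched branch are
    flagged.  Non-significant results are left untouched.  The flagged
    set is an antichain of the ontology partial order.
    """
    sig = [r for r in results if r.significant]
    for r in sig:
        if r.term_id not in graph:
            raise KeyError(f"term {r.term_id!r} absent from ontology graph")
    for r in results:
        r.most_specific = False
    sig_ids = {r.term_id for r in sig}
    for r in sig:
        ancestors_of_others = set()
        for other in sig_ids - {r.term_id}:
            ancestors_of_others |= nx.descendants(graph.g, other)
        r.most_specific = r.term_id not in ancestors_of_others
    return results


def run_enrichment(
    de_table: list[DEGene],
    graph: OntologyGraph,
    lfc_min: float = DEFAULT_LFC_MIN,
    fdr_max: float = DEFAULT_FDR_MAX,
    min_slc: int = DEFAULT_MIN_SLC,
    max_fraction: float = DEFAULT_MAX_FRACTION,
    universe: set[str] | None = None,
) -> list[EnrichmentResult]:
    """Full per-condition pipeline: filter, select, test, simplify.

    The default universe is every transporter carrying at least one
    ontology term (cargo-bearing); pass an explicit *universe* to use a
    different set, e.g. all annotated transporters including orphans.
    """
    if universe is None:
        universe = {n[len("SLC:"):] for n in graph.slc_nodes()}
    hits = filter_upregulated(de_table, universe, lfc_min, fdr_max)
    testable = select_testable_terms(graph, min_slc, max_fraction, universe)
    t2s = term_to_slcs(graph)
    term_slcs = {t: t2s[t] for t in testable}
    results = fisher_enrichment(hits, universe, term_slcs, graph=graph)
    return most_specific_terms(results, graph)


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_label": r.term_label,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "significant": r.significant,
                "most_specific": r.most_specific,
            }
            for r in results
        ]
    )


def write_results_tsv(results: list[EnrichmentResult], path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)
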