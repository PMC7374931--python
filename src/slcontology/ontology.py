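"""Chemical-ontology surgery: parse, map, extract, merge, prune, attach.

The workflow turns a large general-purpose chemical ontology (ChEBI-style
OBO input) into a small transporter-specific substrate ontology:

1. parse the OBO file, keeping only five relationship types
   (``is_a``, ``has_role``, ``is_tautomer_of``, ``is_conjugate_acid_of``,
   ``is_conjugate_base_of``);
2. map curated substrate names to ontology terms (exact label/synonym
   match, with an offline manual mapping file as fallback);
3. extract the subgraph reachable from the substrate terms by directed
   paths, excluding the subatomic-particle sub-ontology;
4. merge tautomer and conjugate acid/base cycles into single terms,
   yielding a DAG;
5. prune non-substrate terms with exactly one incoming edge (one
   sub-term), bridging parents and child with ``derived`` edges;
6. attach one node per cargo-bearing transporter, linked to its substrate
   terms by ``transports`` edges.

Edge direction convention throughout: **child -> parent**, i.e. the more
specific term points at the more general one; ``transports`` edges point
from an SLC node to a chemical term.  "Incoming" edges of a term
therefore arrive from its sub-terms.
"""

from __future__ import annotations

import gzip
import json
import re
from dataclasses import dataclass, field

import networkx as nx
import obonet

from .annotation import AnnotationTable, distinct_cargoes
from .errors import IntegrityError, MappingError, ParseError

#: Relationship types retained from the source ontology.
ALLOWED_RELATIONS = (
    "is_a",
    "has_role",
    "is_tautomer_of",
    "is_conjugate_acid_of",
    "is_conjugate_base_of",
)

#: Relations whose cycles identify chemically equivalent terms.
EQUIVALENCE_RELATIONS = frozenset(
    {"is_tautomer_of", "is_conjugate_acid_of", "is_conjugate_base_of"}
)

SLC_NODE_PREFIX = "SLC:"

_SYNONYM_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"\s+(?P<scope>\w+)')


@dataclass(frozen=True)
class MappingEntry:
    """Links a free-text substrate name to an ontology term id."""

    substrate_name: str
    term_id: str
    method: str  # exact_label | translation | manual

    def __post_init__(self):
        if self.method not in {"exact_label", "translation", "manual"}:
            raise ValueError(f"unknown mapping method {self.method!r}")


class OntologyGraph:
    """Directed multigraph of typed ontology relationships.

    Thin wrapper over a :class:`networkx.MultiDiGraph` whose edge keys are
    the relation names (so parallel edges of the same relation between the
    same pair are impossible by construction).  Node attributes:

    ``label``
        preferred term name;
    ``member_ids``
        frozenset of original ids collapsed into this term (singleton
        unless terms were merged);
    ``namespace``
        ``chemical_entity``, ``role``, or ``slc``;
    ``is_substrate``
        True iff some member id is the image of a mapping entry.
    """

    def __init__(self, graph: nx.MultiDiGraph | None = None):
        self.g = graph if graph is not None else nx.MultiDiGraph()

    # -- basic accessors -------------------------------------------------
    def __contains__(self, term_id: str) -> bool:
        return term_id in self.g

    def __len__(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def label(self, term_id: str) -> str:
        return self.g.nodes[term_id].get("label", term_id)

    def members(self, term_id: str) -> frozenset[str]:
        return self.g.nodes[term_id].get("member_ids", frozenset({term_id}))

    def namespace(self, term_id: str) -> str:
        return self.g.nodes[term_id].get("namespace", "chemical_entity")

    def is_substrate(self, term_id: str) -> bool:
        return bool(self.g.nodes[term_id].get("is_substrate", False))

    def term_ids(self) -> list[str]:
        return sorted(self.g.nodes)

    def edges(self) -> list[tuple[str, str, str]]:
        """(source, target, relation) triples, source = more specific."""
        return sorted((u, v, k) for u, v, k in self.g.edges(keys=True))

    def add_term(
        self,
        term_id: str,
        label: str,
        member_ids=None,
        namespace: str = "chemical_entity",
        is_substrate: bool = False,
    ) -> None:
        self.g.add_node(
            term_id,
            label=label,
            member_ids=frozenset(member_ids) if member_ids else frozenset({term_id}),
            namespace=namespace,
            is_substrate=is_substrate,
        )

    def add_edge(self, source: str, target: str, relation: str) -> None:
        self.g.add_edge(source, target, key=relation)

    def member_index(self) -> dict[str, str]:
        """Map every original member id to its (possibly merged) term id."""
        index: dict[str, str] = {}
        for tid in self.g.nodes:
            for mid in self.members(tid):
                index[mid] = tid
        return index

    def copy(self) -> "OntologyGraph":
        return OntologyGraph(self.g.copy())

    # -- traversal -------------------------------------------------------
    def reachable_from(self, term_id: str, relations=None) -> set[str]:
        """All terms reachable from *term_id* by directed paths, excluding
        the start node (unless it lies on a cycle through itself)."""
        if relations is None:
            return set(nx.descendants(self.g, term_id))
        sub = self._relation_view(relations)
        return set(nx.descendants(sub, term_id))

    def _relation_view(self, relations) -> nx.MultiDiGraph:
        rel = set(relations)
        return nx.edge_subgraph(
            self.g, [(u, v, k) for u, v, k in self.g.edges(keys=True) if k in rel]
        )

    def terms_with_label(self, label: str) -> list[str]:
        needle = label.strip().lower()
        return sorted(
            tid for tid in self.g.nodes if self.label(tid).strip().lower() == needle
        )

    def slc_nodes(self) -> list[str]:
        return sorted(t for t in self.g.nodes if self.namespace(t) == "slc")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _exact_synonyms(node_data: dict) -> list[str]:
    """Pull EXACT synonyms out of raw OBO synonym strings."""
    out = []
    for raw in node_data.get("synonym", []):
        m = _SYNONYM_RE.match(raw)
        if m and m.group("scope").upper() == "EXACT":
            out.append(m.group("text").replace('\\"', '"'))
    return out


def parse_obo(path) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 flat file into an :class:`OntologyGraph`.

    Keeps every non-obsolete ``[Term]`` with its id and name; keeps only
    the five allowed relationship types and ignores every other relation
    (``has_part``, ...).  Gzip-compressed input is accepted.
    """
    try:
        if str(path).endswith(".gz"):
            with gzip.open(path, "rt") as fh:
                raw = obonet.read_obo(fh, ignore_obsolete=True)
        else:
            raw = obonet.read_obo(path, ignore_obsolete=True)
    except OSError:
        raise
    except Exception as exc:  # malformed stanza
        raise ParseError(f"cannot parse OBO file {path}: {exc}") from exc

    og = OntologyGraph()
    for tid, data in raw.nodes(data=True):
        og.add_term(tid, label=data.get("name", tid))
        og.g.nodes[tid]["exact_synonyms"] = tuple(_exact_synonyms(data))
    for u, v, rel in raw.edges(keys=True):
        if rel in ALLOWED_RELATIONS and u != v:
            og.add_edge(u, v, rel)
    return og


# ---------------------------------------------------------------------------
# Substrate mapping
# ---------------------------------------------------------------------------

@dataclass
class MappingResult:
    entries: list[MappingEntry]
    unresolved: list[str] = field(default_factory=list)
    ambiguous: dict[str, list[str]] = field(default_factory=dict)

    def term_ids(self) -> set[str]:
        return {e.term_id for e in self.entries}

    def by_name(self) -> dict[str, list[MappingEntry]]:
        out: dict[str, list[MappingEntry]] = {}
        for e in self.entries:
            out.setdefault(e.substrate_name.strip().lower(), []).append(e)
        return out


def map_substrates(
    table: AnnotationTable,
    graph: OntologyGraph,
    manual_map: list[MappingEntry] | None = None,
) -> MappingResult:
    """Resolve every distinct cargo name to ontology term id(s).

    Resolution order per name: (1) entries in *manual_map* (the offline
    stand-in for translation-service and hand-curated tiers); (2) exact
    case-insensitive match against term labels and EXACT synonyms.  A
    name matching several labels yields all matches and is flagged
    ambiguous for manual disambiguation.  Unresolved names are collected,
    never silently dropped.
    """
    manual_map = manual_map or []
    manual_by_name: dict[str, list[MappingEntry]] = {}
    for entry in manual_map:
        manual_by_name.setdefault(entry.substrate_name.strip().lower(), []).append(entry)

    label_index: dict[str, list[str]] = {}
    for tid in graph.g.nodes:
        if graph.namespace(tid) == "slc":
            continue
        keys = [graph.label(tid).strip().lower()]
        keys.extend(
            s.strip().lower() for s in graph.g.nodes[tid].get("exact_synonyms", ())
        )
        for key in keys:
            if key:
                label_index.setdefault(key, []).append(tid)

    result = MappingResult(entries=[])
    for name in sorted(distinct_cargoes(table), key=str.lower):
        key = name.strip().lower()
        if key in manual_by_name:
            for entry in manual_by_name[key]:
                if entry.term_id not in graph:
                    raise MappingError(
                        f"manual mapping for {name!r} names unknown term "
                        f"{entry.term_id!r}"
                    )
                result.entries.append(
                    MappingEntry(name, entry.term_id, entry.method)
                )
            continue
        hits = sorted(set(label_index.get(key, [])))
        if hits:
            if len(hits) > 1:
                result.ambiguous[name] = hits
            for tid in hits:
                result.entries.append(MappingEntry(name, tid, "exact_label"))
        else:
            result.unresolved.append(name)
    if not result.entries:
        raise MappingError("no substrate name could be mapped to any term")
    return result


def read_mapping(path, sep: str = "\t") -> list[MappingEntry]:
    """Read a mapping TSV with columns substrate_name, term_id, method."""
    import pandas as pd

    df = pd.read_csv(path, sep=sep, dtype=str)
    from .errors import SchemaError

    for col in ("substrate_name", "term_id", "method"):
        if col not in df.columns:
            raise SchemaError(f"mapping table missing column {col!r}")
    return [
        MappingEntry(r.substrate_name, r.term_id, r.method)
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Subgraph extraction
# ---------------------------------------------------------------------------

SUBATOMIC_LABEL = "subatomic particle"
ROLE_ROOT_LABEL = "role"


def _subatomic_terms(graph: OntologyGraph) -> set[str]:
    """Terms whose is_a ancestry reaches the 'subatomic particle' term."""
    isa = graph._relation_view({"is_a"})
    excluded: set[str] = set()
    for root in graph.terms_with_label(SUBATOMIC_LABEL):
        excluded.add(root)
        if root in isa:
            excluded |= nx.ancestors(isa, root)
    return excluded


def _assign_namespaces(graph: OntologyGraph) -> None:
    """Label-anchored namespace assignment: a term is in the role
    sub-ontology iff its is_a ancestry reaches a term labeled 'role';
    everything else is a chemical entity."""
    isa = graph._relation_view({"is_a"})
    role_terms: set[str] = set()
    for root in graph.terms_with_label(ROLE_ROOT_LABEL):
        role_terms.add(root)
        if root in isa:
            role_terms |= nx.ancestors(isa, root)
    for tid in graph.g.nodes:
        if graph.namespace(tid) == "slc":
            continue
        graph.g.nodes[tid]["namespace"] = (
            "role" if tid in role_terms else "chemical_entity"
        )


def extract_subgraph(graph: OntologyGraph, substrate_ids: set[str]) -> OntologyGraph:
    """Induce the subgraph of terms reachable from the substrate terms.

    Reachability follows directed edges of the five allowed relations.
    Terms in the subatomic-particle sub-ontology (identified by is_a
    ancestry to the term labeled 'subatomic particle') are excluded.
    Substrate nodes are flagged ``is_substrate``.
    """
    missing = sorted(s for s in substrate_ids if s not in graph)
    if missing:
        raise IntegrityError(f"substrate id(s) absent from ontology: {missing}")

    excluded = _subatomic_terms(graph)
    keep: set[str] = set()
    for sid in substrate_ids:
        if sid in excluded:
            continue
        keep.add(sid)
        keep |= nx.descendants(graph.g, sid)
    keep -= excluded

    sub = OntologyGraph(graph.g.subgraph(keep).copy())
    for tid in sub.g.nodes:
        sub.g.nodes[tid]["is_substrate"] = tid in substrate_ids
        sub.g.nodes[tid].setdefault("member_ids", frozenset({tid}))
    _assign_namespaces(sub)
    return sub


# ---------------------------------------------------------------------------
# Reduction step 1: merge equivalence cycles
# ---------------------------------------------------------------------------

def merge_equivalent_terms(graph: OntologyGraph) -> OntologyGraph:
    """Contract tautomer / conjugate acid-base cycles into single terms.

    Strongly connected components of the restriction to equivalence
    relations are collapsed; the merged term keeps the lexicographically
    smallest member id (and that member's label), records all member ids,
    and is a substrate node iff any member was.  All other edges are
    re-pointed at merged nodes with parallel duplicates removed and
    self-loops dropped.  The result must be acyclic.
    """
    equiv = graph._relation_view(EQUIVALENCE_RELATIONS)
    comp_of: dict[str, str] = {}
    components: list[set[str]] = []
    for comp in nx.strongly_connected_components(equiv):
        if len(comp) > 1:
            components.append(set(comp))
    for comp in components:
        rep = min(comp)
        for tid in comp:
            comp_of[tid] = rep

    merged = OntologyGraph()
    for tid in graph.g.nodes:
        rep = comp_of.get(tid, tid)
        if rep in merged:
            node = merged.g.nodes[rep]
            node["member_ids"] = node["member_ids"] | graph.members(tid)
            node["is_substrate"] = node["is_substrate"] or graph.is_substrate(tid)
        else:
            merged.add_term(
                rep,
                label=graph.label(rep),
                member_ids=graph.members(tid) | {rep},
                namespace=graph.namespace(rep),
                is_substrate=graph.is_substrate(tid),
            )
    for u, v, rel in graph.g.edges(keys=True):
        ru, rv = comp_of.get(u, u), comp_of.get(v, v)
        if ru == rv:
            continue  # intra-component (cycle) edge or self-loop
        merged.add_edge(ru, rv, rel)

    if not nx.is_directed_acyclic_graph(merged.g):
        cycle = nx.find_cycle(merged.g)
        raise IntegrityError(
            f"graph still cyclic after merging equivalence classes: {cycle}"
        )
    return merged


# ---------------------------------------------------------------------------
# Reduction step 2: prune single-child terms
# ---------------------------------------------------------------------------

def _distinct_children(g: nx.MultiDiGraph, node: str) -> set[str]:
    """Distinct more-specific terms pointing at *node* (parallel edges of
    different relations between the same pair count once)."""
    return set(g.predecessors(node))


def prune_single_child_terms(graph: OntologyGraph) -> OntologyGraph:
    """Remove non-substrate terms with exactly one sub-term.

    Such terms add a level of specificity without distinguishing between
    instances of their branch.  Removal bridges the single child to each
    parent with a ``derived`` edge, preserving reachability among the
    surviving terms exactly.  The rule is applied in topological order
    and iterated to fixpoint, since a removal can expose new
    single-child terms.  Parentless terms (roots) are kept even with a
    single sub-term: they are category endpoints, not pass-through
    levels, and the parent-child bridging rule does not apply to them.
    """
    g = graph.g.copy()
    changed = True
    while changed:
        changed = False
        for node in list(nx.topological_sort(g)):
            if g.nodes[node].get("is_substrate", False):
                continue
            if g.nodes[node].get("namespace") == "slc":
                continue
            if g.out_degree(node) == 0:
                continue
            children = _distinct_children(g, node)
            if len(children) != 1:
                continue
            (child,) = children
            parents = set(g.successors(node))
            g.remove_node(node)
            for parent in parents:
                if not g.has_edge(child, parent):
                    g.add_edge(child, parent, key="derived")
            changed = True
    return OntologyGraph(g)


# ---------------------------------------------------------------------------
# SLC attachment and closures
# ---------------------------------------------------------------------------

def attach_slc_terms(
    graph: OntologyGraph,
    table: AnnotationTable,
    mapping: MappingResult,
    keep_orphans: bool = False,
) -> OntologyGraph:
    """Add one ``slc``-namespace node per cargo-bearing transporter.

    Each node gets ``transports`` edges to the (merged) term containing
    each of its mapped cargo ids.  Orphan transporters get no node unless
    *keep_orphans* is set (then an isolated node is emitted).  A cargo id
    that was eliminated by the reduction and is inside no merged node is
    an integrity error: substrate nodes must never be pruned.
    """
    out = graph.copy()
    index = out.member_index()
    name_map = mapping.by_name()
    for rec in table:
        if rec.is_orphan and not keep_orphans:
            continue
        node_id = SLC_NODE_PREFIX + rec.slc_id
        out.add_term(node_id, label=rec.slc_id, namespace="slc")
        for cargo in rec.cargoes:
            entries = name_map.get(cargo.strip().lower(), [])
            for entry in entries:
                target = index.get(entry.term_id)
                if target is None:
                    raise IntegrityError(
                        f"cargo term {entry.term_id} ({cargo!r}, {rec.slc_id}) "
                        f"was eliminated by the reduction"
                    )
                out.add_edge(node_id, target, "transports")
    return out


def slc_term_closure(graph: OntologyGraph, slc_id: str) -> set[str]:
    """All ontology terms reachable from the transporter's node by
    directed paths, excluding the node itself."""
    node_id = slc_id if slc_id.startswith(SLC_NODE_PREFIX) else SLC_NODE_PREFIX + slc_id
    if node_id not in graph:
        raise KeyError(f"no SLC node {node_id!r} in graph")
    return set(nx.descendants(graph.g, node_id))


def all_slc_closures(graph: OntologyGraph) -> dict[str, set[str]]:
    """Term closure for every SLC node, keyed by bare transporter id."""
    return {
        node[len(SLC_NODE_PREFIX):]: set(nx.descendants(graph.g, node))
        for node in graph.slc_nodes()
    }


def term_to_slcs(graph: OntologyGraph) -> dict[str, set[str]]:
    """Invert the closures: for each term, which transporters carry it."""
    out: dict[str, set[str]] = {}
    for slc, terms in all_slc_closures(graph).items():
        for t in terms:
            out.setdefault(t, set()).add(slc)
    return out


# ---------------------------------------------------------------------------
# Summaries and serialization
# ---------------------------------------------------------------------------

def summarize_ontology(graph: OntologyGraph) -> dict:
    """Counts describing a (reduced) ontology graph.

    Relationship count excludes ``transports`` edges; per-namespace term
    counts exclude SLC nodes; both per-term-SLC-count and per-SLC-term-
    count distributions come with their medians.
    """
    import statistics

    slc_nodes = set(graph.slc_nodes())
    chem_terms = [t for t in graph.g.nodes if graph.namespace(t) == "chemical_entity"]
    role_terms = [t for t in graph.g.nodes if graph.namespace(t) == "role"]
    n_edges = sum(
        1 for _, _, k in graph.g.edges(keys=True) if k != "transports"
    )
    closures = all_slc_closures(graph) if slc_nodes else {}
    t2s = term_to_slcs(graph) if slc_nodes else {}
    slcs_per_term = {t: len(s) for t, s in t2s.items()}
    terms_per_slc = {s: len(ts) for s, ts in closures.items()}
    return {
        "n_terms": len(chem_terms) + len(role_terms),
        "n_relationships": n_edges,
        "n_chemical_entity_terms": len(chem_terms),
        "n_role_terms": len(role_terms),
        "n_slc_nodes": len(slc_nodes),
        "median_slcs_per_term": (
            statistics.median(slcs_per_term.values()) if slcs_per_term else 0
        ),
        "median_terms_per_slc": (
            statistics.median(terms_per_slc.values()) if terms_per_slc else 0
        ),
        "slcs_per_term": slcs_per_term,
        "terms_per_slc": terms_per_slc,
    }


def write_obo(graph: OntologyGraph, path) -> None:
    """Serialize a reduced ontology back to OBO.

    Merged terms list their absorbed ids as ``alt_id``; the two relations
    this workflow introduces (``transports``, ``derived``) are declared
    as ``[Typedef]`` stanzas.
    """
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: slc-substrate-ontology\n")
        for tid in graph.term_ids():
            fh.write(f"\n[Term]\nid: {tid}\nname: {graph.label(tid)}\n")
            ns = graph.namespace(tid)
            fh.write(f"namespace: {ns}\n")
            for alt in sorted(graph.members(tid) - {tid}):
                fh.write(f"alt_id: {alt}\n")
            for u, v, rel in sorted(graph.g.out_edges(tid, keys=True)):
                if rel == "is_a":
                    fh.write(f"is_a: {v} ! {graph.label(v)}\n")
                else:
                    fh.write(f"relationship: {rel} {v} ! {graph.label(v)}\n")
        for rel in ("transports", "derived"):
            fh.write(f"\n[Typedef]\nid: {rel}\nname: {rel}\n")


def write_edges_tsv(graph: OntologyGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\trelation\n")
        for u, v, rel in graph.edges():
            fh.write(f"{u}\t{v}\t{rel}\n")


def write_closures_tsv(graph: OntologyGraph, path) -> None:
    closures = all_slc_closures(graph)
    with open(path, "w") as fh:
        fh.write("slc_id\tterm_id\tterm_label\n")
        for slc in sorted(closures):
            for tid in sorted(closures[slc]):
                fh.write(f"{slc}\t{tid}\t{graph.label(tid)}\n")


def write_counts_json(counts: dict, path) -> None:
    slim = {k: v for k, v in counts.items() if not isinstance(v, dict)}
    with open(path, "w") as fh:
        json.dump(slim, fh, indent=2, sort_keys=True)
        fh.write("\n")
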