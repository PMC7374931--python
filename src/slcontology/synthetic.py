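"""Seeded synthetic fixtures with analytically known ground truth.

Every input the pipeline consumes can be generated here without any
download: toy OBO ontologies with planted conjugate/tautomer cycles and
single-child chains (so the expected post-merge and post-prune counts
are exact arithmetic), curated-annotation tables with known class
structure, differential-expression tables with planted transporter
upregulation, and protein sequences whose residue composition carries a
planted class signal.  Identical :class:`FixtureSpec` inputs produce
byte-identical outputs.

These fixtures are structural stand-ins: they make no attempt to mimic
real chemical vocabulary or true transporter biology.  Toy term ids use
the ``TOY:`` prefix so they can never be confused with real ontology ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import AnnotationTable, SLCRecord
from .errors import SLContologyError
from .features import ProteinTopology
from .ontology import OntologyGraph

_MECHANISMS = ("symporter", "antiporter", "uniporter", "unknown")


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and effect-size parameters for all generators.

    The ontology skeleton is ``n_classes`` class terms under one root,
    each with ``substrates_per_class`` substrate leaves; ``n_cycles``
    conjugate acid/base pairs and ``n_chains`` single-child chains of
    ``chain_len`` edges are planted on top.  ``de_effect`` is the log2
    fold change given to planted upregulated transporters and
    ``class_signal`` the transmembrane-leucine enrichment given to
    planted classifier positives.
    """

    seed: int = 0
    n_classes: int = 4
    substrates_per_class: int = 6
    n_cycles: int = 3
    n_chains: int = 2
    chain_len: int = 4
    n_slc: int = 50
    orphan_fraction: float = 0.3
    n_background_genes: int = 200
    de_effect: float = 2.0
    class_signal: float = 0.25
    include_subatomic: bool = False
    include_decoys: bool = True

    def __post_init__(self):
        if self.n_classes < 2 or self.substrates_per_class < 2:
            raise SLContologyError("need >= 2 classes with >= 2 substrates each")
        if self.n_classes * self.substrates_per_class < 4:
            raise SLContologyError("need >= 4 class substrates for role anchoring")
        if self.chain_len < 2 and self.n_chains > 0:
            raise SLContologyError("chains need length >= 2")
        if not 0.0 <= self.orphan_fraction <= 1.0:
            raise SLContologyError("orphan_fraction outside [0, 1]")

    @property
    def n_terms(self) -> int:
        """Total [Term] stanzas emitted (including decoys/subatomic)."""
        n = self._n_reachable()
        if self.include_subatomic:
            n += 2
        if self.include_decoys:
            n += 2
        return n

    def _n_reachable(self) -> int:
        return (
            self.n_classes * self.substrates_per_class
            + 2 * self.n_cycles
            + self.n_chains * self.chain_len  # substrate + (chain_len-1) interiors
            + self.n_classes
            + 1  # chemical root
            + 3  # role root + two role terms
        )


@dataclass
class ToyOntologyTruth:
    """Exact expected counts for the reduction pipeline on a toy OBO."""

    substrate_ids: set[str]
    class_terms: dict[int, str]
    class_substrate_labels: dict[int, list[str]]
    chain_substrate_labels: list[str]
    acid_labels_by_class: dict[int, list[str]]
    root_id: str
    role_root_id: str
    n_reachable_terms: int
    n_reachable_edges: int
    n_merge_removed_terms: int
    n_merge_removed_edges: int
    n_prune_removed_terms: int
    n_prune_removed_edges: int
    n_role_terms: int = 3

    @property
    def n_terms_post_merge(self) -> int:
        return self.n_reachable_terms - self.n_merge_removed_terms

    @property
    def n_edges_post_merge(self) -> int:
        return self.n_reachable_edges - self.n_merge_removed_edges

    @property
    def n_terms_final(self) -> int:
        return self.n_terms_post_merge - self.n_prune_removed_terms

    @property
    def n_edges_final(self) -> int:
        return self.n_edges_post_merge - self.n_prune_removed_edges

    def class_labels_for(self, index: int) -> list[str]:
        """All cargo labels whose closure includes class term *index*."""
        return self.class_substrate_labels[index] + self.acid_labels_by_class[index]


def make_toy_obo(spec: FixtureSpec) -> tuple[str, ToyOntologyTruth]:
    """Emit OBO text for a toy ontology plus its exact reduction truth.

    Layout (edge direction child -> parent):

    * one chemical root and one role root with two role terms;
    * ``n_classes`` class terms under the root, each with
      ``substrates_per_class`` substrate leaves (leaves alternate
      ``has_role`` edges to the two role terms);
    * ``n_cycles`` conjugate acid/base pairs (a 2-cycle each; the acid is
      a substrate, both members share one class parent), so merging
      removes exactly one term and three edges per pair;
    * ``n_chains`` chains substrate -> interior x (chain_len-1) -> root of
      single-child non-substrate interiors, so pruning removes exactly
      ``chain_len - 1`` terms and edges per chain;
    * optionally a subatomic-particle branch (with an 'electron'
      substrate) and two unreachable decoy terms.

    The generator is purely structural: the OBO bytes depend only on the
    spec, never on the seed.
    """
    counter = [0]

    def next_id() -> str:
        counter[0] += 1
        return f"TOY:{counter[0]:04d}"

    stanzas: list[str] = []

    def term(tid: str, name: str, is_a=(), rels=()) -> None:
        lines = [f"[Term]", f"id: {tid}", f"name: {name}"]
        lines += [f"is_a: {p}" for p in is_a]
        lines += [f"relationship: {rel} {t}" for rel, t in rels]
        stanzas.append("\n".join(lines))

    root = next_id()
    term(root, "toy chemical entity")
    role_root = next_id()
    term(role_root, "role")
    role_a = next_id()
    term(role_a, "toy cofactor role", is_a=[role_root])
    role_b = next_id()
    term(role_b, "toy nutrient role", is_a=[role_root])

    class_terms: dict[int, str] = {}
    for i in range(spec.n_classes):
        cid = next_id()
        class_terms[i] = cid
        term(cid, f"toy class {i}", is_a=[root])

    substrate_ids: set[str] = set()
    class_substrate_labels: dict[int, list[str]] = {i: [] for i in range(spec.n_classes)}
    k = 0
    for i in range(spec.n_classes):
        for j in range(spec.substrates_per_class):
            sid = next_id()
            label = f"toy compound {i}-{j}"
            role = role_a if k % 2 == 0 else role_b
            term(sid, label, is_a=[class_terms[i]], rels=[("has_role", role)])
            substrate_ids.add(sid)
            class_substrate_labels[i].append(label)
            k += 1

    acid_labels_by_class: dict[int, list[str]] = {i: [] for i in range(spec.n_classes)}
    for c in range(spec.n_cycles):
        cls = c % spec.n_classes
        acid = next_id()
        base = next_id()
        term(
            acid,
            f"toy acid {c}",
            is_a=[class_terms[cls]],
            rels=[("is_conjugate_acid_of", base)],
        )
        term(
            base,
            f"toy base {c}",
            is_a=[class_terms[cls]],
            rels=[("is_conjugate_base_of", acid)],
        )
        substrate_ids.add(acid)
        acid_labels_by_class[cls].append(f"toy acid {c}")

    chain_substrate_labels: list[str] = []
    for h in range(spec.n_chains):
        interiors = [next_id() for _ in range(spec.chain_len - 1)]
        for lvl, tid in enumerate(interiors):
            parent = interiors[lvl + 1] if lvl + 1 < len(interiors) else root
            term(tid, f"toy chain {h} level {lvl}", is_a=[parent])
        sid = next_id()
        label = f"toy chain compound {h}"
        term(sid, label, is_a=[interiors[0] if interiors else root])
        substrate_ids.add(sid)
        chain_substrate_labels.append(label)

    if spec.include_subatomic:
        sp = next_id()
        term(sp, "subatomic particle", is_a=[root])
        electron = next_id()
        term(electron, "electron", is_a=[sp])

    if spec.include_decoys:
        decoy_parent = next_id()
        term(decoy_parent, "toy decoy parent")
        decoy = next_id()
        term(decoy, "toy decoy compound", is_a=[decoy_parent])

    n_class_sub = spec.n_classes * spec.substrates_per_class
    truth = ToyOntologyTruth(
        substrate_ids=substrate_ids,
        class_terms=class_terms,
        class_substrate_labels=class_substrate_labels,
        chain_substrate_labels=chain_substrate_labels,
        acid_labels_by_class=acid_labels_by_class,
        root_id=root,
        role_root_id=role_root,
        n_reachable_terms=spec._n_reachable(),
        n_reachable_edges=(
            2 * n_class_sub  # substrate is_a + has_role
            + 2  # role terms is_a role root
            + spec.n_classes  # classes is_a root
            + 4 * spec.n_cycles  # two cycle edges + two is_a per pair
            + spec.n_chains * spec.chain_len
        ),
        n_merge_removed_terms=spec.n_cycles,
        n_merge_removed_edges=3 * spec.n_cycles,
        n_prune_removed_terms=spec.n_chains * (spec.chain_len - 1),
        n_prune_removed_edges=spec.n_chains * (spec.chain_len - 1),
    )
    header = "format-version: 1.2\nontology: toy\n\n"
    return header + "\n\n".join(stanzas) + "\n", truth


@dataclass
class AnnotationTruth:
    """Bookkeeping emitted with the synthetic annotation."""

    orphan_ids: list[str]
    class_of: dict[str, int]  # non-orphan slc_id -> ontology class index
    cargo_names: dict[str, list[str]]
    ion_class: int = 0
    distinct_cargo: set[str] = field(default_factory=set)

    def slcs_of_class(self, index: int) -> list[str]:
        return sorted(s for s, c in self.class_of.items() if c == index)

    def slcs_with_cargo_in(self, labels) -> list[str]:
        """Transporters carrying any cargo from *labels* — exactly the
        transporters whose ontology closure will contain the labels'
        class term."""
        wanted = {l.lower() for l in labels}
        return sorted(
            s
            for s, cargoes in self.cargo_names.items()
            if any(c.lower() in wanted for c in cargoes)
        )


_CLASS_VOCAB = (
    "amino acid",
    "ion",
    "carbohydrate",
    "lipid",
    "nucleoside/nucleotide",
    "peptide",
    "vitamin",
    "heavy metal",
    "other",
)


def make_annotation_fixture(
    spec: FixtureSpec, truth: ToyOntologyTruth
) -> tuple[AnnotationTable, AnnotationTruth]:
    """Synthetic curated annotation whose cargo names all resolve against
    the toy ontology by exact label match.

    ``round(orphan_fraction * n_slc)`` transporters are orphans.  Each
    remaining transporter is assigned one ontology class and draws 1-3
    substrates from that class's leaf labels; symporters and antiporters
    additionally get a coupled ion drawn from class 0 (the fixture's
    ion-like class).  Substrate-class labels are consistent with the
    assigned ontology class.  A final coverage pass guarantees that every
    toy substrate term (including chain substrates) is some transporter's
    cargo, so the extracted subgraph matches the toy ground truth
    exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n_orphan = round(spec.orphan_fraction * spec.n_slc)
    n_carrier = spec.n_slc - n_orphan
    if n_carrier < spec.n_classes:
        raise SLContologyError(
            "need at least one cargo-bearing transporter per ontology class"
        )
    ids = [f"SLCX{i + 1:03d}" for i in range(spec.n_slc)]
    orphan_ids = ids[:n_orphan]
    carrier_ids = ids[n_orphan:]

    # class membership: seeded shuffle + round-robin, so classes are
    # balanced (the curated classes the fixture emulates are all well
    # populated, and downstream planting requires every class to meet
    # the enrichment testability floor)
    class_of: dict[str, int] = {}
    order = [carrier_ids[int(i)] for i in rng.permutation(n_carrier)]
    for j, slc_id in enumerate(order):
        class_of[slc_id] = j % spec.n_classes
    substrates_of: dict[str, set[str]] = {}
    ions_of: dict[str, tuple[str, ...]] = {}
    mech_of: dict[str, str] = {}
    for slc_id in carrier_ids:
        cls = class_of[slc_id]
        pool = truth.class_labels_for(cls)
        n_cargo = int(rng.integers(1, min(3, len(pool)) + 1))
        substrates_of[slc_id] = set(
            rng.choice(pool, size=n_cargo, replace=False).tolist()
        )
        mechanism = _MECHANISMS[int(rng.integers(len(_MECHANISMS)))]
        mech_of[slc_id] = mechanism
        ions_of[slc_id] = ()
        if mechanism in ("symporter", "antiporter") and cls != ION_CLASS:
            ion_pool = truth.class_labels_for(ION_CLASS)
            ions_of[slc_id] = (str(rng.choice(ion_pool)),)

    # coverage pass: place every unused class label on a carrier of the
    # same class, and every chain substrate on some carrier
    for cls in range(spec.n_classes):
        members = sorted(s for s, c in class_of.items() if c == cls)
        used = set().union(*(substrates_of[s] for s in members))
        for label in truth.class_labels_for(cls):
            if label not in used:
                substrates_of[str(rng.choice(members))].add(label)
    for label in truth.chain_substrate_labels:
        substrates_of[str(rng.choice(carrier_ids))].add(label)

    records: list[SLCRecord] = []
    ann_truth = AnnotationTruth(orphan_ids=list(orphan_ids), class_of={}, cargo_names={})
    loc_vocab = ("plasma membrane", "mitochondria", "lysosome", "endoplasmic reticulum")
    for i, slc_id in enumerate(ids):
        family = f"SLCX{(i % 7) + 1}"
        if slc_id in set(orphan_ids):
            records.append(
                SLCRecord(
                    slc_id=slc_id,
                    family=family,
                    substrates=(),
                    coupled_ions=(),
                    mechanism="unknown",
                    substrate_class="orphan",
                    localizations=frozenset(),
                )
            )
            continue
        cls = class_of[slc_id]
        substrates = tuple(sorted(substrates_of[slc_id]))
        ions = ions_of[slc_id]
        localizations = frozenset(
            rng.choice(loc_vocab, size=int(rng.integers(0, 3)), replace=False).tolist()
        )
        records.append(
            SLCRecord(
                slc_id=slc_id,
                family=family,
                substrates=substrates,
                coupled_ions=ions,
                mechanism=mech_of[slc_id],
                substrate_class=_CLASS_VOCAB[cls % len(_CLASS_VOCAB)],
                localizations=localizations,
            )
        )
        ann_truth.class_of[slc_id] = cls
        ann_truth.cargo_names[slc_id] = list(substrates + ions)
        ann_truth.distinct_cargo.update(c.lower() for c in substrates + ions)
    table = AnnotationTable(records=records, provenance=f"synthetic fixture seed={spec.seed}")
    return table, ann_truth


#: Index of the toy class whose leaves double as coupled ions.
ION_CLASS = 0


def write_annotation_tsv(table: AnnotationTable, path, list_sep: str = ";") -> None:
    with open(path, "w") as fh:
        fh.write(
            "slc_id\tfamily\tsubstrates\tcoupled_ions\tmechanism\t"
            "substrate_class\tlocalizations\n"
        )
        for rec in table:
            fh.write(
                "\t".join(
                    [
                        rec.slc_id,
                        rec.family,
                        list_sep.join(rec.substrates),
                        list_sep.join(rec.coupled_ions),
                        rec.mechanism,
                        rec.substrate_class,
                        list_sep.join(sorted(rec.localizations)),
                    ]
                )
                + "\n"
            )


@dataclass
class DETruth:
    planted_slc_ids: list[str]
    target_class: int
    target_term_id: str


def make_de_fixture(
    spec: FixtureSpec,
    truth: ToyOntologyTruth,
    ann_truth: AnnotationTruth,
    target_class: int = 1,
    seed: int | None = None,
    min_slc: int = 5,
) -> tuple["pd.DataFrame", DETruth]:
    """Differential-expression table with planted transporter upregulation.

    Every transporter assigned to *target_class* gets log2fc equal to
    ``de_effect`` with a near-zero p-value; all other genes (remaining
    transporters plus ``n_background_genes`` background genes) get
    centered Gaussian log2fc and uniform p-values.  The fdr column is the
    Benjamini-Hochberg adjustment of the whole p-value vector, mirroring
    the provenance of a real DE result.  With ``de_effect == 0`` nothing
    is planted and the table is pure null.
    """
    import pandas as pd
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    planted = (
        ann_truth.slcs_with_cargo_in(truth.class_labels_for(target_class))
        if spec.de_effect > 0
        else []
    )
    if spec.de_effect > 0 and len(planted) < min_slc:
        raise SLContologyError(
            f"target class {target_class} has only {len(planted)} transporters; "
            f"planting requires >= {min_slc} for the term to be testable"
        )
    genes: list[str] = [r for r in sorted(ann_truth.class_of) ] + list(
        ann_truth.orphan_ids
    )
    genes += [f"GENE{i + 1:04d}" for i in range(spec.n_background_genes)]
    planted_set = set(planted)
    log2fc = np.empty(len(genes))
    pvals = np.empty(len(genes))
    for idx, g in enumerate(genes):
        if g in planted_set:
            log2fc[idx] = spec.de_effect
            pvals[idx] = 1e-8
        else:
            log2fc[idx] = rng.normal(0.0, 0.35)
            pvals[idx] = rng.uniform()
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    df = pd.DataFrame({"gene": genes, "log2fc": log2fc, "fdr": fdr})
    return df, DETruth(
        planted_slc_ids=planted,
        target_class=target_class,
        target_term_id=truth.class_terms[target_class],
    )


@dataclass
class SequenceTruth:
    positive_ids: list[str]
    signal_domain: str
    signal_residue: str
    class_signal: float


_BACKGROUND_AA = "ACDEFGHIKLMNPQRSTVWY"


def _draw_segment(rng, length: int, boost_residue: str | None, boost: float) -> str:
    probs = np.full(20, 1 / 20)
    if boost_residue and boost > 0:
        i = _BACKGROUND_AA.index(boost_residue)
        probs = probs * (1 - boost) / probs.sum()
        probs[i] += boost
        probs = probs / probs.sum()
    idx = rng.choice(20, size=length, p=probs)
    return "".join(_BACKGROUND_AA[i] for i in idx)


def make_sequence_fixture(
    spec: FixtureSpec,
    ids: list[str],
    positive_ids: set[str] | None = None,
    seed: int | None = None,
) -> tuple[list[ProteinTopology], SequenceTruth]:
    """Random multi-pass membrane protein sequences with topologies.

    Each protein gets an optional signal peptide followed by alternating
    non-cytoplasmic / transmembrane / cytoplasmic segments (8-12 membrane
    passes).  Proteins in *positive_ids* draw their transmembrane
    residues with the leucine fraction raised by ``class_signal``; with
    ``class_signal == 0`` positives and negatives are exchangeable.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    positive_ids = positive_ids or set()
    prots: list[ProteinTopology] = []
    for pid in ids:
        boost = spec.class_signal if pid in positive_ids else 0.0
        parts: list[str] = []
        domains: list[tuple[int, int, str]] = []
        pos = 1

        def emit(length: int, kind: str, boosted: bool):
            nonlocal pos
            seg = _draw_segment(rng, length, "L" if boosted else None, boost)
            parts.append(seg)
            domains.append((pos, pos + length - 1, kind))
            pos += length

        if rng.uniform() < 0.5:
            emit(int(rng.integers(15, 26)), "signal_peptide", False)
        n_tm = int(rng.integers(8, 13))
        outside = True
        emit(int(rng.integers(10, 41)), "non_cytoplasmic", False)
        for _ in range(n_tm):
            emit(21, "transmembrane", True)
            outside = not outside
            kind = "non_cytoplasmic" if outside else "cytoplasmic"
            emit(int(rng.integers(10, 41)), kind, False)
        prots.append(ProteinTopology(pid, "".join(parts), tuple(domains)))
    return prots, SequenceTruth(
        positive_ids=sorted(positive_ids),
        signal_domain="transmembrane",
        signal_residue="L",
        class_signal=spec.class_signal,
    )


def write_sequence_fixture(prots: list[ProteinTopology], fasta_path, topology_path) -> None:
    with open(fasta_path, "w") as fh:
        for p in prots:
            fh.write(f">{p.slc_id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")
    with open(topology_path, "w") as fh:
        fh.write("slc_id\tstart\tend\tkind\n")
        for p in prots:
            for start, end, kind in p.domains:
                fh.write(f"{p.slc_id}\t{start}\t{end}\t{kind}\n")


# ---------------------------------------------------------------------------
# Unstructured random cases for property tests
# ---------------------------------------------------------------------------

def random_reduction_case(seed: int, n_nodes: int = 30) -> tuple[OntologyGraph, set[str]]:
    """A random DAG ontology with seeded equivalence cycles, for
    invariant checks (acyclicity, reachability preservation, substrate
    survival).  Returns the graph and its substrate-node ids; no count
    ground truth is provided."""
    rng = np.random.default_rng(seed)
    g = OntologyGraph()
    ids = [f"TOY:{i:04d}" for i in range(1, n_nodes + 1)]
    for tid in ids:
        g.add_term(tid, label=f"node {tid}")
    # random DAG edges: each node points at 1-3 higher-numbered nodes
    for i, tid in enumerate(ids[:-1]):
        n_parents = int(rng.integers(1, 4))
        parents = rng.choice(np.arange(i + 1, n_nodes), size=min(n_parents, n_nodes - i - 1), replace=False)
        for p in parents:
            rel = "is_a" if rng.uniform() < 0.8 else "has_role"
            g.add_edge(tid, ids[int(p)], rel)
    # plant equivalence 2-cycles between order-adjacent pairs; any other
    # directed path between the members would survive contraction as a
    # genuine cycle, which real conjugate pairs do not produce
    n_cycles = int(rng.integers(0, max(1, n_nodes // 6)))
    for _ in range(n_cycles):
        i = int(rng.integers(0, n_nodes - 1))
        j = i + 1
        while g.g.has_edge(ids[i], ids[j]):
            g.g.remove_edge(ids[i], ids[j])
        g.add_edge(ids[i], ids[j], "is_conjugate_acid_of")
        g.add_edge(ids[j], ids[i], "is_conjugate_base_of")
    # substrates: a random subset of the lower half of the order
    n_sub = int(rng.integers(2, max(3, n_nodes // 3)))
    subs = {ids[int(i)] for i in rng.choice(n_nodes // 2, size=n_sub, replace=False)}
    for tid in subs:
        g.g.nodes[tid]["is_substrate"] = True
    return g, subs
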