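# Methods

This note records the modeling choices, conventions, defaults, and known
limitations of the package, in the order the pipeline runs.

## Annotation model

Each transporter carries: free-text substrate and coupled-ion lists, a
transport mechanism (`symporter`, `antiporter`, `uniporter`,
`unknown`), exactly one of eleven substrate classes (accessory protein,
amino acid, carbohydrate, ion, lipid, heavy metal,
nucleoside/nucleotide, orphan, peptide, vitamin, other), and a set of
subcellular localizations. A transporter is an orphan iff both cargo
lists are empty; orphan records must carry the `orphan` class. Empty
cells, `unknown` and `NA` (any case) are all read as "no annotation" to
tolerate dialects of curated supplementary tables.

Distinct-cargo counting is case-insensitive exact string matching after
whitespace trimming. No chemical normalization happens at this stage:
the curated table is the source of truth for names, and normalization is
the mapping table's job. Accessory proteins count as orphans (they bind
no cargo themselves).

## Substrate mapping

Name resolution is offline by design: (1) entries of a user-supplied
manual mapping file (covering what translation services or hand curation
would resolve) take precedence; (2) otherwise exact case-insensitive
match against term labels and EXACT synonyms of the loaded OBO. A name
matching several labels yields all matches and is flagged ambiguous for
manual disambiguation; unresolved names are reported, never silently
dropped. This trades recall (a live lookup service resolves more
spellings) for byte-for-byte reproducibility.

## Graph conventions and reduction

Edges point from the more specific to the more general term
(child → parent for `is_a`); `transports` edges point from a transporter
node to a chemical term. Only five source relations are kept: `is_a`,
`has_role`, `is_tautomer_of`, `is_conjugate_acid_of`,
`is_conjugate_base_of`. Parallel edges of the same relation between the
same pair cannot exist (edge keys are relation names).

**Extraction** keeps exactly the terms reachable from mapped substrate
terms by directed paths. The subatomic-particle branch is excluded by
label-anchored ancestor search (every term whose `is_a` ancestry reaches
the term labeled "subatomic particle"), not by hard-coded id, so the
rule also applies to toy fixtures. Namespace assignment (role vs
chemical entity) is likewise label-anchored on the term named "role".

**Merge** contracts strongly connected components of the restriction to
tautomer/conjugate relations. The merged term takes the
lexicographically smallest member id (deterministic, diff-stable) and
that member's label, keeps all member ids, and is a substrate node iff
any member was. Intra-component edges vanish; re-pointed duplicates
collapse. The result must be acyclic — a residual cycle raises an
integrity error rather than being silently broken.

**Prune** removes non-substrate terms with exactly one sub-term
("incoming" edges arrive from more specific terms under the direction
convention; distinct child terms are counted, so parallel `is_a` +
`has_role` paths from the same child count once). Each removal bridges
the single child to every parent with a `derived` edge, which preserves
pairwise reachability among the survivors exactly (property-tested
against a transitive-closure oracle). Two boundary choices were
genuinely open:

- *iteration*: the rule is applied in topological order and iterated to
  fixpoint, because removals can expose new single-child terms and a
  fixpoint is the only order-independent reading;
- *roots*: a parentless term with one sub-term is kept. The bridging
  rule presupposes a parent, and deleting a category endpoint loses
  information instead of collapsing a pass-through level.

Both choices can shift the exact number of terms removed on a full-scale
ontology by a small amount relative to a single-pass or root-pruning
reading.

Substrate nodes are never removed by either step; transporter nodes are
attached after reduction, one per cargo-bearing transporter (orphans get
no node unless requested). A transporter's term closure is everything
reachable from its node, which equals the union of its cargo terms and
their closures (BFS-oracle-tested).

## Enrichment

Upregulation filtering uses strict inequalities: log₂FC > 0.5 and
FDR < 0.05 by default. Gene symbols match transporter ids by exact
case-insensitive equality; alias maps, if wanted, are an input.

The enrichment universe is the cargo-bearing transporters (those with at
least one ontology term). Orphans carry no terms, so including them
would only inflate the "rest" cell of every table uniformly; a flag
restores the all-transporters universe. Testable terms are
chemical-entity terms carried by ≥ 5 and strictly < 70% of the universe;
role terms are never tested.

The one-sided p-value is the hypergeometric upper tail
P[X ≥ a] — identical to one-sided Fisher — computed via `scipy`'s
survival function (verified against exact rational-arithmetic summation
over all tables with universe ≤ 60 to < 1e-12). BH correction is applied
per condition across the tested terms; significance means q < 0.05.
Branch simplification flags a significant term as most specific iff no
other significant term lies below it; the flagged set is therefore an
antichain of the ontology order.

## Classifier

Features are computed per topological domain kind, pooling residues of
all segments of that kind: 20 amino-acid frequencies over canonical
residues (`X` is tolerated but excluded from the frequency denominator),
segment count, total residue count, average segment length, plus the
count of N-glycosylation sequons (overlapping `N[^P][ST]`, never
spanning segment boundaries) within non-cytoplasmic segments — 93
features. The published feature scheme this approximates includes a
larger motif catalog from prior work; here the motif set is reduced to
the glycosylation sequon plus user-supplied regular expressions. This is
a deliberate approximation: per-protein probabilities from the original
study are not reproducible by construction, only the machinery and its
behavior on planted signal.

Training is per term: positives are transporters whose closure contains
the term, negatives all remaining cargo-bearing transporters, with at
least 10 per class (terms below the floor are skipped with an explicit
report). The grid covers `mtry` ∈ {20, 50, 100, 150, 200} (clipped to
the feature count), `ntree` ∈ {300, 700, 1100, 1500}, and unweighted vs
class-weighted fits — even steps across the stated ranges. Out-of-bag
probabilities drive both grid selection (F1 at the 0.5 cut by default;
at the optimized cut via a flag, since which was used originally is
unstated) and threshold selection; no separate validation split exists.
Grid ties break to smaller `ntree`, then smaller `mtry`. A sample left
out of no bootstrap (possible only at tiny `ntree`) scores 0.5.

The decision threshold maximizes recall subject to precision ≥ 0.75 over
the distinct observed score values (ties → higher precision, then higher
threshold). If no cut reaches the floor, the precision-maximizing cut is
used and flagged. Gamma normalization s ↦ s^(ln 0.5 / ln t) relocates
the threshold to 0.5, fixes 0 and 1, and preserves ranking; thresholds
of exactly 0 or 1 are nudged by 1e-9 before taking logs. Every source of
randomness takes an explicit seed; a fixed seed and grid give an
identical serialized model spec.

## Synthetic study conditions

The fixture generators define the conditions all desk-scale results are
measured under; they are structural stand-ins and mimic neither real
chemical vocabulary nor true transporter biology.

- *Toy ontology*: 4 classes × 6 substrate leaves under one root, a
  3-term role branch, 3 conjugate acid/base pairs (each merge removes
  exactly 1 term and 3 edges), 2 single-child chains of 4 edges (each
  prune removes exactly 3 terms and 3 edges), plus unreachable decoys.
  The OBO bytes depend only on the shape parameters, so expected counts
  are closed-form arithmetic.
- *Annotation*: 50 transporters, 30% orphans. Classes are assigned by
  seeded shuffle + round-robin so every class is populated well above
  the enrichment testability floor (mirroring the heavily populated
  curated classes); cargo draws, mechanisms, ions, and localizations are
  random. A coverage pass guarantees every toy substrate term is used,
  so extraction ground truth is exact.
- *Differential expression*: planted transporters (all carriers of the
  target class, ≥ 5 required) get log₂FC = 2.0 and p = 1e-8; background
  genes (200) get N(0, 0.35) log₂FC and uniform p. The fdr column is BH
  applied by the generator itself, matching the provenance of real DE
  output. With effect 0 nothing is planted.
- *Sequences*: 8–12 membrane passes of length 21, loops of 10–40
  residues, optional signal peptide; positives draw transmembrane
  residues with the leucine fraction raised by 0.25. That effect size
  gives near-perfect separation — the recovery checks test the
  machinery, not a realistic signal-to-noise regime.

Desk-scale problem sizes — 100-seed reduction sweeps, 50–100 enrichment
pipeline runs, classifier training at n = 120 with a 2-cell grid and 300
trees across 5–10 seeds — were chosen so the whole suite and the
acceptance script each finish in minutes on one CPU while keeping the
Monte-Carlo margins of the pass criteria comfortable.

## Known limitations

- Passing planted-signal tests shows the pipeline recovers what the
  generators plant; real data have correlated expression, aliasing gene
  symbols, imbalanced substrate classes, and far weaker compositional
  signals than the fixtures.
- Exact label matching under-resolves real curated names; the manual
  mapping file must carry the remainder.
- The full-scale construction counts depend on the pruning-iteration and
  root-handling readings above; step-by-step stage counts are reported
  so any deviation is attributable.
- No OWL input, no chemical-structure reasoning, no topology prediction
  (topology is an input), no differential-expression computation.
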