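"""End-to-end wiring of the ontology-construction workflow.

``build_reduced_ontology`` chains mapping, extraction, cycle merging,
single-child pruning, and SLC attachment, recording the term/edge counts
after every stage so that reductions can be audited step by step.
"""

from __future__ import annotations

import hashlib
import json
import platform
import time
from dataclasses import dataclass, field

from .annotation import AnnotationTable
from .ontology import (
    MappingEntry,
    MappingResult,
    OntologyGraph,
    attach_slc_terms,
    extract_subgraph,
    map_substrates,
    merge_equivalent_terms,
    prune_single_child_terms,
    summarize_ontology,
)


@dataclass
class BuildResult:
    graph: OntologyGraph
    mapping: MappingResult
    stage_counts: dict[str, dict[str, int]]
    summary: dict

    @property
    def n_merge_removed_terms(self) -> int:
        return (
            self.stage_counts["extracted"]["terms"]
            - self.stage_counts["merged"]["terms"]
        )

    @property
    def n_merge_removed_edges(self) -> int:
        return (
            self.stage_counts["extracted"]["edges"]
            - self.stage_counts["merged"]["edges"]
        )

    @property
    def n_prune_removed_terms(self) -> int:
        return (
            self.stage_counts["merged"]["terms"]
            - self.stage_counts["pruned"]["terms"]
        )


def build_reduced_ontology(
    raw: OntologyGraph,
    table: AnnotationTable,
    manual_map: list[MappingEntry] | None = None,
    do_merge: bool = True,
    do_prune: bool = True,
    keep_orphans: bool = False,
) -> BuildResult:
    """Run the full reduction workflow on a parsed ontology.

    Stages: map substrate names to terms, extract the reachable subgraph
    (minus the subatomic-particle branch), merge equivalence cycles,
    prune single-child non-substrate terms, attach transporter nodes.
    The merge and prune stages can be bypassed for diagnostics.
    """
    mapping = map_substrates(table, raw, manual_map)
    graph = extract_subgraph(raw, mapping.term_ids())
    counts = {"extracted": {"terms": len(graph), "edges": graph.n_edges}}
    if do_merge:
        graph = merge_equivalent_terms(graph)
    counts["merged"] = {"terms": len(graph), "edges": graph.n_edges}
    if do_prune:
        graph = prune_single_child_terms(graph)
    counts["pruned"] = {"terms": len(graph), "edges": graph.n_edges}
    graph = attach_slc_terms(graph, table, mapping, keep_orphans=keep_orphans)
    counts["final"] = {"terms": len(graph), "edges": graph.n_edges}
    return BuildResult(
        graph=graph,
        mapping=mapping,
        stage_counts=counts,
        summary=summarize_ontology(graph),
    )


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI run's outputs."""

    command: str
    config: dict
    inputs: dict[str, str] = field(default_factory=dict)
    seed: int | None = None
    version: str = ""
    started: str = ""
    finished: str = ""

    def add_input(self, name: str, path) -> None:
        self.inputs[name] = _digest(path)

    def write(self, path) -> None:
        from . import __version__

        self.version = self.version or __version__
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        payload = {
            "command": self.command,
            "config": self.config,
            "input_sha256": self.inputs,
            "seed": self.seed,
            "tool_version": self.version,
            "python": platform.python_version(),
            "started": self.started,
            "finished": self.finished,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def new_manifest(command: str, config: dict, seed: int | None = None) -> RunManifest:
    return RunManifest(
        command=command,
        config=config,
        seed=seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
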