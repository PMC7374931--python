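"""Sequence-derived numeric features over topological protein domains.

Multi-pass transporters are described by per-domain composition
statistics: for each of the four topological domain kinds (cytoplasmic,
non-cytoplasmic, transmembrane, signal peptide) the residues of all
segments of that kind are pooled and summarized as the 20 amino-acid
frequencies, the segment count, the total residue count, and the average
segment length.  N-glycosylation sequons (N-x-S/T, x != P) are counted
within non-cytoplasmic segments only, since glycosylation happens on the
lumenal/extracellular side.  Additional user-supplied motif patterns can
extend the feature set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError, SequenceError, TopologyError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DOMAIN_KINDS = ("cytoplasmic", "non_cytoplasmic", "transmembrane", "signal_peptide")

#: Overlap-tolerant N-glycosylation sequon: N, not-P, then S or T.
SEQUON_RE = re.compile(r"(?=N[^P][ST])")


@dataclass(frozen=True)
class ProteinTopology:
    """A protein sequence with 1-based inclusive topological domains."""

    slc_id: str
    sequence: str
    domains: tuple[tuple[int, int, str], ...]

    def __post_init__(self):
        n = len(self.sequence)
        bad = set(self.sequence.upper()) - set(AMINO_ACIDS) - {"X"}
        if bad:
            raise SequenceError(
                f"{self.slc_id}: residues outside alphabet: {sorted(bad)}"
            )
        spans = []
        for start, end, kind in self.domains:
            if kind not in DOMAIN_KINDS:
                raise TopologyError(f"{self.slc_id}: unknown domain kind {kind!r}")
            if not (1 <= start <= end <= n):
                raise TopologyError(
                    f"{self.slc_id}: span ({start}, {end}) outside sequence of "
                    f"length {n}"
                )
            spans.append((start, end))
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise TopologyError(
                    f"{self.slc_id}: overlapping domains ({s1},{e1}) and ({s2},{e2})"
                )

    def segments(self, kind: str) -> list[str]:
        """Subsequences of all segments of the given kind, in order."""
        return [
            self.sequence[start - 1 : end].upper()
            for start, end, k in self.domains
            if k == kind
        ]


@dataclass(frozen=True)
class FeatureVector:
    slc_id: str
    names: tuple[str, ...]
    values: tuple[float, ...]

    def __post_init__(self):
        if len(self.names) != len(self.values):
            raise ValueError("feature names and values differ in length")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def feature_names(extra_motifs: dict[str, str] | None = None) -> tuple[str, ...]:
    """The fixed, documented feature order: per domain kind the 20
    amino-acid frequencies then n_segments / n_residues / avg_length,
    then the non-cytoplasmic sequon count, then any extra motif counts
    (per domain, sorted by motif name)."""
    names: list[str] = []
    for kind in DOMAIN_KINDS:
        names.extend(f"{kind}.freq_{aa}" for aa in AMINO_ACIDS)
        names.extend(
            (f"{kind}.n_segments", f"{kind}.n_residues", f"{kind}.avg_length")
        )
    names.append("non_cytoplasmic.nglyc_sequons")
    if extra_motifs:
        for motif in sorted(extra_motifs):
            names.extend(f"{kind}.motif_{motif}" for kind in DOMAIN_KINDS)
    return tuple(names)


def count_sequons(segment: str) -> int:
    """Overlapping N-x-S/T (x != P) matches in one segment; sequons never
    span segment boundaries."""
    return len(SEQUON_RE.findall(segment.upper()))


def extract_features(
    prot: ProteinTopology, extra_motifs: dict[str, str] | None = None
) -> FeatureVector:
    """Compute the per-domain feature vector for one protein.

    Amino-acid frequencies are fractions of the canonical residues pooled
    across segments of the kind (they sum to 1 when any canonical residue
    exists, and are all zero for an absent domain).  *extra_motifs* maps
    motif names to regular expressions counted per domain kind.
    """
    values: list[float] = []
    for kind in DOMAIN_KINDS:
        segs = prot.segments(kind)
        pooled = "".join(segs)
        canonical = [c for c in pooled if c in AMINO_ACIDS]
        n_canon = len(canonical)
        if n_canon:
            counts = {aa: 0 for aa in AMINO_ACIDS}
            for c in canonical:
                counts[c] += 1
            values.extend(counts[aa] / n_canon for aa in AMINO_ACIDS)
        else:
            values.extend(0.0 for _ in AMINO_ACIDS)
        values.append(float(len(segs)))
        values.append(float(len(pooled)))
        values.append(float(np.mean([len(s) for s in segs])) if segs else 0.0)
    values.append(float(sum(count_sequons(s) for s in prot.segments("non_cytoplasmic"))))
    if extra_motifs:
        for motif in sorted(extra_motifs):
            pat = re.compile(f"(?={extra_motifs[motif]})")
            for kind in DOMAIN_KINDS:
                values.append(
                    float(sum(len(pat.findall(s)) for s in prot.segments(kind)))
                )
    return FeatureVector(
        slc_id=prot.slc_id,
        names=feature_names(extra_motifs),
        values=tuple(values),
    )


def feature_matrix(
    prots: list[ProteinTopology], extra_motifs: dict[str, str] | None = None
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Stack feature vectors into a DataFrame indexed by protein id."""
    vecs = [extract_features(p, extra_motifs) for p in prots]
    names = feature_names(extra_motifs)
    df = pd.DataFrame(
        [v.values for v in vecs], index=[v.slc_id for v in vecs], columns=names
    )
    return df, names


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Minimal-dependency FASTA reader: id = first word of the header."""
    seqs: dict[str, list[str]] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                seqs[current] = []
            elif current is not None:
                seqs[current].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def read_topologies(fasta_path, topology_path, sep: str = "\t") -> list[ProteinTopology]:
    """Assemble :class:`ProteinTopology` records from a FASTA file and a
    domain table (columns slc_id, start, end, kind)."""
    seqs = read_fasta(fasta_path)
    df = pd.read_csv(topology_path, sep=sep)
    for col in ("slc_id", "start", "end", "kind"):
        if col not in df.columns:
            raise SchemaError(f"topology table missing column {col!r}")
    out = []
    for slc_id, grp in df.groupby("slc_id", sort=True):
        if slc_id not in seqs:
            raise SchemaError(f"no sequence for {slc_id!r} in FASTA")
        domains = tuple(
            (int(r.start), int(r.end), str(r.kind)) for r in grp.itertuples(index=False)
        )
        out.append(ProteinTopology(str(slc_id), seqs[slc_id], domains))
    return out
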