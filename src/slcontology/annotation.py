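"""Curated SLC annotation: data model, I/O, and summary statistics.

The human solute carrier (SLC) superfamily comprises 446 transporters in
70 families.  The curated annotation assigns to each transporter its
experimentally confirmed substrates, coupled ions, transport mechanism
(symporter / antiporter / uniporter), a single substrate class, and
subcellular localizations.  A transporter with neither substrates nor
coupled ions is an *orphan*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .errors import IntegrityError, SchemaError, VocabularyError

#: The closed vocabulary of substrate classes; exactly one per transporter.
SUBSTRATE_CLASSES = frozenset(
    {
        "accessory protein",
        "amino acid",
        "carbohydrate",
        "ion",
        "lipid",
        "heavy metal",
        "nucleoside/nucleotide",
        "orphan",
        "peptide",
        "vitamin",
        "other",
    }
)

MECHANISMS = frozenset({"symporter", "antiporter", "uniporter", "unknown"})

#: Cell values treated as "no annotation" regardless of case.
_UNKNOWN_TOKENS = {"", "unknown", "na"}

REQUIRED_COLUMNS = (
    "slc_id",
    "family",
    "substrates",
    "coupled_ions",
    "mechanism",
    "substrate_class",
    "localizations",
)


@dataclass(frozen=True)
class SLCRecord:
    """One transporter's curated annotation."""

    slc_id: str
    family: str
    substrates: tuple[str, ...]
    coupled_ions: tuple[str, ...]
    mechanism: str
    substrate_class: str
    localizations: frozenset[str] = field(default_factory=frozenset)

    @property
    def is_orphan(self) -> bool:
        """True iff no substrate and no coupled ion is annotated."""
        return not self.substrates and not self.coupled_ions

    @property
    def cargoes(self) -> tuple[str, ...]:
        """Substrates and coupled ions merged, order preserved."""
        return self.substrates + self.coupled_ions

    def validate(self) -> None:
        if self.substrate_class not in SUBSTRATE_CLASSES:
            raise VocabularyError(
                f"{self.slc_id}: substrate_class {self.substrate_class!r} "
                f"not in the 11-class vocabulary"
            )
        if self.mechanism not in MECHANISMS:
            raise VocabularyError(
                f"{self.slc_id}: mechanism {self.mechanism!r} invalid"
            )


@dataclass
class AnnotationTable:
    """A validated collection of :class:`SLCRecord`."""

    records: list[SLCRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise IntegrityError("annotation table is empty")
        seen: set[str] = set()
        for rec in self.records:
            if rec.slc_id in seen:
                raise IntegrityError(f"duplicate slc_id {rec.slc_id!r}")
            seen.add(rec.slc_id)
            rec.validate()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, slc_id: str) -> SLCRecord:
        for rec in self.records:
            if rec.slc_id == slc_id:
                return rec
        raise KeyError(slc_id)

    @property
    def slc_ids(self) -> set[str]:
        return {r.slc_id for r in self.records}

    @property
    def cargo_bearing(self) -> list[SLCRecord]:
        return [r for r in self.records if not r.is_orphan]

    @property
    def orphans(self) -> list[SLCRecord]:
        return [r for r in self.records if r.is_orphan]


def _split_list_cell(cell, list_sep: str) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return ()
    text = str(cell).strip()
    if text.lower() in _UNKNOWN_TOKENS:
        return ()
    parts = [p.strip() for p in text.split(list_sep)]
    return tuple(p for p in parts if p)


def _scalar_cell(cell, default: str = "unknown") -> str:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return default
    text = str(cell).strip()
    if text.lower() in _UNKNOWN_TOKENS:
        return default
    return text


def read_annotation(path, sep: str = "\t", list_sep: str = ";") -> AnnotationTable:
    """Load a curated annotation table from delimited text.

    One row per SLC; list-valued columns (substrates, coupled_ions,
    localizations) use *list_sep* as a secondary delimiter.  Empty cells,
    ``unknown`` and ``NA`` (any case) all read as "no annotation".

    Raises
    ------
    SchemaError
        if a required column is missing.
    IntegrityError
        on duplicate ``slc_id``.
    VocabularyError
        if ``substrate_class`` is outside the 11-class vocabulary, listing
        the offending rows.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"annotation table missing column(s): {', '.join(missing)}")

    bad_class: list[str] = []
    records: list[SLCRecord] = []
    for _, row in df.iterrows():
        cls = _scalar_cell(row["substrate_class"], default="orphan").lower()
        if cls not in SUBSTRATE_CLASSES:
            bad_class.append(f"{row['slc_id']} ({row['substrate_class']!r})")
            continue
        records.append(
            SLCRecord(
                slc_id=str(row["slc_id"]).strip(),
                family=_scalar_cell(row["family"], default=""),
                substrates=_split_list_cell(row["substrates"], list_sep),
                coupled_ions=_split_list_cell(row["coupled_ions"], list_sep),
                mechanism=_scalar_cell(row["mechanism"]).lower(),
                substrate_class=cls,
                localizations=frozenset(
                    _split_list_cell(row["localizations"], list_sep)
                ),
            )
        )
    if bad_class:
        raise VocabularyError(
            "substrate_class outside vocabulary in rows: " + "; ".join(bad_class)
        )
    return AnnotationTable(records=records, provenance=str(path))


def distinct_cargoes(table: AnnotationTable) -> set[str]:
    """Distinct transported molecules across substrates and coupled ions.

    Deduplication is case-insensitive exact string match after trimming;
    no chemical normalization is attempted here (that is the mapping
    table's job).  The representative kept is the first-seen spelling.
    """
    seen: dict[str, str] = {}
    for rec in table:
        for name in rec.cargoes:
            key = name.strip().lower()
            if key and key not in seen:
                seen[key] = name.strip()
    return set(seen.values())


def summarize_annotation(table: AnnotationTable) -> dict:
    """Summary statistics of the curated annotation.

    Counts orphans, cargo-bearing transporters, distinct cargo names, and
    the per-class / per-mechanism / per-localization / per-ion
    distributions, plus the fraction of transporters with no annotation
    in each category.
    """
    n = len(table)
    orphans = table.orphans
    per_class: dict[str, int] = {}
    per_mechanism: dict[str, int] = {}
    per_localization: dict[str, int] = {}
    per_ion: dict[str, int] = {}
    n_unknown_loc = 0
    n_unknown_mech = 0
    n_unknown_ion = 0
    for rec in table:
        per_class[rec.substrate_class] = per_class.get(rec.substrate_class, 0) + 1
        per_mechanism[rec.mechanism] = per_mechanism.get(rec.mechanism, 0) + 1
        if rec.mechanism == "unknown":
            n_unknown_mech += 1
        if rec.localizations:
            for loc in rec.localizations:
                per_localization[loc] = per_localization.get(loc, 0) + 1
        else:
            n_unknown_loc += 1
        if rec.coupled_ions:
            for ion in rec.coupled_ions:
                key = ion.strip().lower()
                per_ion[key] = per_ion.get(key, 0) + 1
        else:
            n_unknown_ion += 1
    return {
        "n_records": n,
        "n_orphan": len(orphans),
        "n_with_cargo": n - len(orphans),
        "n_distinct_cargo": len(distinct_cargoes(table)),
        "per_class": dict(sorted(per_class.items())),
        "per_mechanism": dict(sorted(per_mechanism.items())),
        "per_localization": dict(sorted(per_localization.items())),
        "per_ion": dict(sorted(per_ion.items())),
        "fraction_unknown": {
            "substrate": round(len(orphans) / n, 4),
            "mechanism": round(n_unknown_mech / n, 4),
            "localization": round(n_unknown_loc / n, 4),
            "coupled_ion": round(n_unknown_ion / n, 4),
        },
    }


def write_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def format_summary(summary: dict) -> str:
    """Human-readable rendering of :func:`summarize_annotation` output."""
    lines = [
        f"SLC records:            {summary['n_records']}",
        f"orphans (no cargo):     {summary['n_orphan']}",
        f"cargo-bearing:          {summary['n_with_cargo']}",
        f"distinct cargo names:   {summary['n_distinct_cargo']}",
        "per substrate class:",
    ]
    for k, v in summary["per_class"].items():
        lines.append(f"  {k:24s} {v}")
    lines.append("per mechanism:")
    for k, v in summary["per_mechanism"].items():
        lines.append(f"  {k:24s} {v}")
    return "\n".join(lines)
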