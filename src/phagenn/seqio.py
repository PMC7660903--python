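"""Protein sequence I/O and class labeling.

Reads and writes FASTA through Biopython, represents labeled protein
records, and assigns class labels either from free-text description
terms or from an explicit two-column label table (the canonical path,
since real corpora are curated by hand).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: B/Z/J are two-way ambiguity codes resolved to the more common member;
#: U (selenocysteine) maps to C. X stays in the sequence and is handled
#: downstream (excluded from k-mer windows, counted in length).
AMBIGUITY_MAP = {"B": "D", "Z": "E", "U": "C", "J": "L"}

#: The ten structural classes plus the background class, in the fixed
#: order used for network outputs and argmax tie-breaking.
DEFAULT_CLASS_NAMES = (
    "Major capsid",
    "Minor capsid",
    "Baseplate",
    "Major tail",
    "Minor tail",
    "Portal",
    "Tail fiber",
    "Tail sheath",
    "Collar",
    "Head-Tail joining",
    "others",
)

SANITIZE_POLICIES = ("strict", "drop-ambiguous", "map-ambiguous")


class FastaParseError(ValueError):
    """Raised when a FASTA entry cannot be parsed or sanitized."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with identifier, free-text description and
    an optional class label."""

    id: str
    sequence: str
    description: str = ""
    label: str | None = None

    def with_label(self, label: str | None) -> "ProteinRecord":
        return replace(self, label=label)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ClassList:
    """Ordered list of class names; order defines network output units
    and deterministic tie-breaking."""

    names: tuple[str, ...] = DEFAULT_CLASS_NAMES

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("class names must be unique")
        if len(self.names) < 2:
            raise ValueError("need at least two classes")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def index(self, name: str) -> int:
        return self.names.index(name)

    def without(self, *excluded: str) -> "ClassList":
        """Drop classes (e.g. the minor-capsid exclusion experiment)."""
        missing = [c for c in excluded if c not in self.names]
        if missing:
            raise ValueError(f"not in class list: {missing}")
        return ClassList(tuple(n for n in self.names if n not in excluded))


def sanitize_sequence(seq: str, policy: str, *, entry_id: str = "?") -> str | None:
    """Upper-case and apply the ambiguity policy.

    Returns None when the record should be skipped (drop-ambiguous).
    """
    if policy not in SANITIZE_POLICIES:
        raise ValueError(f"unknown sanitize policy {policy!r}")
    seq = seq.upper().replace("*", "").replace("-", "")
    bad = sorted(set(seq) - set(CANONICAL_AA))
    if not bad:
        if not seq:
            raise FastaParseError(f"entry {entry_id!r} has an empty sequence")
        return seq
    if policy == "strict":
        raise FastaParseError(
            f"entry {entry_id!r} contains non-canonical letters {bad}"
        )
    if policy == "drop-ambiguous":
        logger.warning("dropping entry %s with non-canonical letters %s", entry_id, bad)
        return None
    mapped = []
    for ch in seq:
        if ch in CANONICAL_AA:
            mapped.append(ch)
        elif ch in AMBIGUITY_MAP:
            mapped.append(AMBIGUITY_MAP[ch])
        elif ch == "X":
            mapped.append("X")
        else:
            raise FastaParseError(
                f"entry {entry_id!r} contains unmappable letter {ch!r}"
            )
    out = "".join(mapped)
    if not out:
        raise FastaParseError(f"entry {entry_id!r} has an empty sequence")
    return out


def read_fasta(path: str | Path, sanitize_policy: str = "map-ambiguous") -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    ``sanitize_policy`` is one of ``strict`` (non-canonical letters
    raise), ``drop-ambiguous`` (offending records skipped with a
    warning), or ``map-ambiguous`` (B→D, Z→E, U→C, J→L; X retained and
    excluded from k-mer windows downstream).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.id:
            raise FastaParseError(f"unnamed FASTA entry in {path}")
        if entry.id in seen:
            raise FastaParseError(f"duplicate id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = sanitize_sequence(str(entry.seq), sanitize_policy, entry_id=entry.id)
        if seq is None:
            continue
        records.append(ProteinRecord(id=entry.id, sequence=seq, description=entry.description))
    if not records:
        logger.warning("no records read from %s", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA (wrapped at 60 columns)."""
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


def label_from_terms(
    records: Sequence[ProteinRecord],
    term_table: Mapping[str, Sequence[str]],
    classes: ClassList | None = None,
) -> list[ProteinRecord]:
    """Assign class labels by case-insensitive substring match of
    description terms.

    A record matching terms of exactly one class receives that label;
    records matching zero or two-plus classes come back unlabeled, with
    the ambiguous count logged (ambiguity is reported, never fatal).
    """
    if not term_table:
        raise ValueError("term_table must be non-empty")
    if classes is not None:
        unknown = [c for c in term_table if c not in classes]
        if unknown:
            raise ValueError(f"term_table classes not in class list: {unknown}")
    lowered = {
        cls: [t.lower() for t in terms] for cls, terms in term_table.items()
    }
    out: list[ProteinRecord] = []
    n_ambiguous = 0
    n_unmatched = 0
    for rec in records:
        desc = (rec.description or rec.id).lower()
        hits = [cls for cls, terms in lowered.items() if any(t in desc for t in terms)]
        if len(hits) == 1:
            out.append(rec.with_label(hits[0]))
        else:
            if len(hits) > 1:
                n_ambiguous += 1
            else:
                n_unmatched += 1
            out.append(rec.with_label(None))
    logger.info(
        "label_from_terms: %d labeled, %d unmatched, %d ambiguous",
        len(records) - n_unmatched - n_ambiguous, n_unmatched, n_ambiguous,
    )
    return out


#: Small illustrative description-term table. Real corpora should use an
#: explicit curated label table instead.
DEFAULT_TERM_TABLE: dict[str, tuple[str, ...]] = {
    "Major capsid": ("major capsid",),
    "Minor capsid": ("minor capsid",),
    "Baseplate": ("baseplate",),
    "Major tail": ("major tail",),
    "Minor tail": ("minor tail",),
    "Portal": ("portal",),
    "Tail fiber": ("tail fiber", "tail fibre"),
    "Tail sheath": ("tail sheath", "sheath protein"),
    "Collar": ("collar",),
    "Head-Tail joining": ("head-tail", "head tail connector"),
}


def read_label_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV label table: ``id<TAB>class``."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>class'")
            rec_id, cls = parts
            if rec_id in labels:
                raise ValueError(f"{path}:{lineno}: duplicate id {rec_id!r}")
            labels[rec_id] = cls
    return labels


def write_label_table(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec_id, cls in labels.items():
            fh.write(f"{rec_id}\t{cls}\n")


def apply_label_table(
    records: Sequence[ProteinRecord],
    labels: Mapping[str, str],
    classes: ClassList,
) -> list[ProteinRecord]:
    """Label records from an explicit id→class table; unknown classes raise."""
    out = []
    for rec in records:
        cls = labels.get(rec.id)
        if cls is not None and cls not in classes:
            raise ValueError(f"record {rec.id!r}: unknown class {cls!r}")
        out.append(rec.with_label(cls))
    return out
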