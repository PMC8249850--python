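"""Data model and I/O for reference databases, taxonomy maps, reads and assignments.

The taxonomy dialect is the Greengenes one: seven canonical ranks
(kingdom..species) with ``k__``/``p__``/.../``s__`` prefixes, joined by
semicolons.  Lineages may be truncated: an empty label (e.g. ``s__``)
terminates the lineage, which is how Greengenes marks unresolved ranks.
"""
from __future__ import annotations

import csv
import re
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

RANK_NAMES = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
N_RANKS = len(RANK_NAMES)

#: IUPAC nucleotide codes (upper case); anything else in a reference FASTA is an error.
IUPAC_NUCLEOTIDES = frozenset("ACGTURYSWKMBDHVN")

UNASSIGNED_LABEL = "Unassigned"


class FormatError(ValueError):
    """A file or string does not conform to the expected dialect."""


@dataclass(frozen=True, order=True)
class Lineage:
    """An ordered, possibly truncated taxonomy path from kingdom toward species.

    ``labels`` holds bare taxon names (without rank prefixes); position i
    corresponds to ``RANK_NAMES[i]``.  Depth 0 means Unassigned.
    """

    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.labels) > N_RANKS:
            raise FormatError(f"lineage deeper than {N_RANKS} ranks: {self.labels!r}")
        if any(not lab for lab in self.labels):
            raise FormatError("empty label inside a Lineage; truncate instead")

    @property
    def depth(self) -> int:
        return len(self.labels)

    @property
    def is_empty(self) -> bool:
        return not self.labels

    def truncate(self, depth: int) -> "Lineage":
        """Ancestor at ``depth`` (identity if already at or above it)."""
        if depth < 0:
            raise ValueError("depth must be >= 0")
        return Lineage(self.labels[:depth]) if depth < len(self.labels) else self

    def matches_at(self, other: "Lineage", depth: int) -> bool:
        """True when both lineages carry identical labels down to ``depth``."""
        return (
            self.depth >= depth
            and other.depth >= depth
            and self.labels[:depth] == other.labels[:depth]
        )

    def common_prefix_depth(self, other: "Lineage") -> int:
        d = 0
        for a, b in zip(self.labels, other.labels):
            if a != b:
                break
            d += 1
        return d

    def __str__(self) -> str:
        return "; ".join(p + lab for p, lab in zip(RANK_PREFIXES, self.labels))


def parse_lineage(text: str) -> Lineage:
    """Parse a semicolon-delimited Greengenes lineage string.

    An empty label (``"s__"``) truncates the lineage; any non-empty label
    after an empty one, an out-of-order prefix, or an unknown prefix raises
    :class:`FormatError`.
    """
    text = text.strip()
    if not text or text == UNASSIGNED_LABEL:
        return Lineage()
    labels: list[str] = []
    truncated = False
    tokens = [tok.strip() for tok in text.split(";")]
    if len(tokens) > N_RANKS:
        raise FormatError(f"more than {N_RANKS} ranks in {text!r}")
    for i, tok in enumerate(tokens):
        expected = RANK_PREFIXES[i]
        if not tok.startswith(expected):
            raise FormatError(
                f"token {tok!r} at position {i} does not carry rank prefix {expected!r}"
            )
        label = tok[len(expected):].strip()
        if not label:
            truncated = True
            continue
        if truncated:
            raise FormatError(f"non-empty rank {tok!r} follows an empty rank in {text!r}")
        labels.append(label)
    return Lineage(tuple(labels))


def format_lineage(lineage: Lineage) -> str:
    """Inverse of :func:`parse_lineage` for non-empty lineages."""
    return str(lineage)


@dataclass(frozen=True)
class RefRecord:
    sequence: str
    lineage: Lineage


@dataclass
class ReferenceDB:
    """Id-keyed reference sequences paired with their lineages."""

    records: dict[str, RefRecord]

    def __post_init__(self) -> None:
        for rid, rec in self.records.items():
            if not rec.sequence:
                raise FormatError(f"reference record {rid!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return list(self.records)

    def species_set(self) -> list[Lineage]:
        """Distinct class lineages, sorted.  Truncated lineages are their own class."""
        return sorted({rec.lineage for rec in self.records.values()})

    def sequences_for(self, lineage: Lineage) -> list[str]:
        return [r.sequence for r in self.records.values() if r.lineage == lineage]

    def subset(self, ids: Iterable[str]) -> "ReferenceDB":
        keep = set(ids)
        return ReferenceDB({i: r for i, r in self.records.items() if i in keep})

    @classmethod
    def from_files(cls, fasta_path: str | Path, taxonomy_path: str | Path) -> "ReferenceDB":
        seqs = read_reference_fasta(fasta_path)
        taxa = read_taxonomy_map(taxonomy_path)
        missing = set(seqs) ^ set(taxa)
        if missing:
            raise FormatError(
                f"sequence ids and taxonomy ids disagree; symmetric difference: {sorted(missing)[:5]}"
            )
        return cls({i: RefRecord(seqs[i], taxa[i]) for i in seqs})


@dataclass
class ReadSet:
    """Ordered reads with optional truth lineages (for evaluation)."""

    reads: list[tuple[str, str]]
    truth: dict[str, Lineage] | None = None

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.reads]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate read ids in ReadSet")
        if self.truth is not None:
            absent = [i for i in ids if i not in self.truth]
            if absent:
                raise FormatError(f"truth missing for reads {absent[:5]}")

    def __len__(self) -> int:
        return len(self.reads)

    def ids(self) -> list[str]:
        return [i for i, _ in self.reads]

    def sequences(self) -> list[str]:
        return [s for _, s in self.reads]


@dataclass(frozen=True)
class Assignment:
    """One read's classification: a possibly truncated lineage plus the
    aggregated probability that won the confidence test (0 for Unassigned)."""

    read_id: str
    lineage: Lineage
    confidence: float


@dataclass
class TrimResult:
    reads: ReadSet
    n_dropped: int


_seq_re = re.compile(r"^[A-Z]+$")


def _validate_sequence(rid: str, seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - IUPAC_NUCLEOTIDES
    if bad:
        raise FormatError(
            f"record {rid!r} contains non-IUPAC characters: {sorted(bad)}"
        )
    return seq


def read_reference_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> upper-cased sequence mapping.

    The id is the header token up to the first whitespace.  Duplicate ids,
    empty files, and non-IUPAC characters raise :class:`FormatError`.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        out[rec.id] = _validate_sequence(rec.id, str(rec.seq))
    if not out:
        raise FormatError(f"no FASTA records in {path}")
    return out


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


_ID_LIKE = re.compile(r"^[\w.\-]+$")


def read_taxonomy_map(path: str | Path) -> dict[str, Lineage]:
    """Read a 2-column Greengenes-style taxonomy TSV (id TAB lineage).

    A header row of the "Feature ID / Taxon" kind is detected (first field
    contains whitespace or the second field does not parse as a lineage) and
    skipped.
    """
    out: dict[str, Lineage] = {}
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(row)}"
                )
            rid, lin_text = row[0].strip(), row[1]
            if lineno == 1 and not _ID_LIKE.match(rid):
                continue  # header row ("Feature ID\tTaxon")
            if rid in out:
                raise FormatError(f"{path}:{lineno}: duplicate id {rid!r}")
            try:
                out[rid] = parse_lineage(lin_text)
            except FormatError as err:
                raise FormatError(f"{path}:{lineno}: {err}") from err
    if not out:
        raise FormatError(f"no taxonomy rows in {path}")
    return out


def write_taxonomy_map(taxa: Mapping[str, Lineage], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, lin in taxa.items():
            fh.write(f"{rid}\t{lin}\n")


def read_reads_fasta(path: str | Path, truth_path: str | Path | None = None) -> ReadSet:
    seqs = read_reference_fasta(path)
    truth = read_taxonomy_map(truth_path) if truth_path is not None else None
    return ReadSet(list(seqs.items()), truth)


def trim_reads(reads: ReadSet, length: int) -> TrimResult:
    """Truncate every read to its first ``length`` bases; shorter reads are dropped.

    Dropping (rather than padding) keeps the fixed-length geometry the
    sentence encoder relies on.
    """
    if length <= 0:
        raise ValueError("trim length must be positive")
    kept: list[tuple[str, str]] = []
    dropped = 0
    for rid, seq in reads.reads:
        if len(seq) < length:
            dropped += 1
            continue
        kept.append((rid, seq[:length]))
    truth = None
    if reads.truth is not None:
        keep_ids = {i for i, _ in kept}
        truth = {i: l for i, l in reads.truth.items() if i in keep_ids}
    return TrimResult(ReadSet(kept, truth), dropped)


def write_assignments(
    assignments: Sequence[Assignment], path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    """Write assignments as a 3-column TSV (read id, lineage, confidence).

    Unassigned reads serialize as the literal ``Unassigned`` with confidence 0
    so the file round-trips unambiguously through :func:`parse_lineage`.
    """
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("read_id\tlineage\tconfidence\n")
        for a in assignments:
            lin = UNASSIGNED_LABEL if a.lineage.is_empty else str(a.lineage)
            fh.write(f"{a.read_id}\t{lin}\t{a.confidence:.6g}\n")


def read_assignments(path: str | Path) -> list[Assignment]:
    out: list[Assignment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if raw.startswith("#") or not raw.strip():
                continue
            row = raw.rstrip("\n").split("\t")
            if row[0] == "read_id":
                continue
            if len(row) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            out.append(Assignment(row[0], parse_lineage(row[1]), float(row[2])))
    return out
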