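"""Peptide and protein set I/O: FASTA, delimited tables, alphabet policies.

Peptide sets carry optional class labels (``OP`` / ``non-OP`` / ``unknown``)
and free-text provenance. Sequences are canonicalized (uppercased, whitespace
stripped) against a configurable amino-acid alphabet; nonstandard one-letter
codes such as B, J, O, U, X, Z can be rejected, mapped to X, or passed through.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Nonstandard / ambiguity one-letter codes seen in curated peptide tables.
DEFAULT_EXTENDED = frozenset("BJOUXZ")

LABEL_OP = "OP"
LABEL_NON_OP = "non-OP"
LABEL_UNKNOWN = "unknown"


class PeptideIOError(Exception):
    """Base error for peptide set reading/writing."""


class FastaParseError(PeptideIOError):
    """Malformed FASTA input."""


class AlphabetError(PeptideIOError):
    """Sequence contains a symbol outside the configured alphabet."""


class SchemaError(PeptideIOError):
    """Delimited table lacks a required mapped column."""


@dataclass(frozen=True)
class AlphabetPolicy:
    """How to canonicalize and validate amino-acid sequences.

    Parameters
    ----------
    mode : {"strict", "map_to_X", "pass_through"}
        ``strict`` rejects any symbol outside the 20 canonical residues;
        ``map_to_X`` deterministically replaces configured extended symbols
        with X; ``pass_through`` keeps extended symbols as-is. Symbols outside
        canonical ∪ extended are always rejected.
    extended : frozenset of str
        Extra one-letter codes tolerated by the non-strict modes.
    """

    mode: str = "map_to_X"
    extended: frozenset = DEFAULT_EXTENDED

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "map_to_X", "pass_through"):
            raise ValueError(f"unknown alphabet mode {self.mode!r}")

    def canonicalize(self, sequence: str, context: str = "") -> str:
        """Uppercase, strip whitespace, and apply the alphabet mode.

        Idempotent: applying the policy twice equals applying it once.
        """
        seq = "".join(sequence.split()).upper()
        out = []
        for pos, ch in enumerate(seq):
            if ch in CANONICAL_RESIDUES:
                out.append(ch)
            elif self.mode != "strict" and ch in self.extended:
                out.append("X" if self.mode == "map_to_X" else ch)
            else:
                where = f" in {context}" if context else ""
                raise AlphabetError(
                    f"symbol {ch!r} at position {pos}{where} is outside the "
                    f"{'canonical' if self.mode == 'strict' else 'allowed'} alphabet"
                )
        return "".join(out)


STRICT_POLICY = AlphabetPolicy(mode="strict")
DEFAULT_POLICY = AlphabetPolicy()


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence with identity, optional label, and provenance."""

    id: str
    sequence: str
    label: str = LABEL_UNKNOWN
    source: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"peptide {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PeptideSet:
    """An ordered, id-unique collection of peptides.

    ``role`` optionally records how the set is used in the workflow
    (positive/negative training pool, test set, raw pool).
    """

    name: str
    members: list[Peptide] = field(default_factory=list)
    role: Optional[str] = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.members:
            if p.id in seen:
                raise ValueError(f"duplicate peptide id {p.id!r} in set {self.name!r}")
            seen.add(p.id)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.members)

    def __getitem__(self, key):
        if isinstance(key, str):
            for p in self.members:
                if p.id == key:
                    return p
            raise KeyError(key)
        return self.members[key]

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.members]

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.members]

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.members]

    def add(self, peptide: Peptide) -> None:
        if peptide.id in set(self.ids):
            raise ValueError(f"duplicate peptide id {peptide.id!r} in set {self.name!r}")
        self.members.append(peptide)

    def subset(self, ids: Iterable[str], name: Optional[str] = None) -> "PeptideSet":
        wanted = list(ids)
        by_id = {p.id: p for p in self.members}
        return PeptideSet(name or self.name, [by_id[i] for i in wanted], role=self.role)

    def with_labels(self, label: str) -> "PeptideSet":
        return PeptideSet(self.name, [replace(p, label=label) for p in self.members], role=self.role)

    def duplicate_sequences(self) -> dict[str, list[str]]:
        """Map each sequence occurring more than once to the ids carrying it."""
        index: dict[str, list[str]] = {}
        for p in self.members:
            index.setdefault(p.sequence, []).append(p.id)
        return {s: ids for s, ids in index.items() if len(ids) > 1}


def read_fasta(path, policy: AlphabetPolicy = DEFAULT_POLICY, name: Optional[str] = None) -> PeptideSet:
    """Read a FASTA file into a :class:`PeptideSet`.

    The header token before the first whitespace becomes the peptide id;
    sequences are canonicalized under ``policy``; record order is preserved.

    Raises
    ------
    FastaParseError
        If the file is empty or sequence data precedes the first header
        (the offending line number is named).
    AlphabetError
        In strict mode, if a sequence contains a non-canonical symbol.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before first '>' header"
                )
            break
        else:
            raise FastaParseError(f"{path}: empty FASTA file")

    members = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = policy.canonicalize(str(record.seq), context=f"record {record.id!r}")
        members.append(Peptide(id=record.id, sequence=seq))
    if not members:
        raise FastaParseError(f"{path}: no FASTA records found")
    return PeptideSet(name or path.stem, members)


def write_fasta(peptides: PeptideSet, path) -> None:
    """Write a peptide set to FASTA. Refuses to write an empty set.

    Round-trip property: ``read_fasta(write_fasta(S))`` reproduces ids and
    sequences exactly (under a pass-through policy).
    """
    if len(peptides) == 0:
        raise PeptideIOError(f"refusing to write empty FASTA for set {peptides.name!r}")
    records = [SeqRecord(Seq(p.sequence), id=p.id, description="") for p in peptides]
    SeqIO.write(records, str(path), "fasta")


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return "\t" if "\t" in sample else ","


def load_peptide_table(
    path,
    schema: Optional[Mapping[str, str]] = None,
    policy: AlphabetPolicy = DEFAULT_POLICY,
    name: Optional[str] = None,
) -> PeptideSet:
    """Load peptides from a delimited text table (CSV or TSV, auto-detected).

    ``schema`` maps logical fields to column names; recognized fields are
    ``sequence`` (required), ``id``, ``label``, ``reference`` and ``year``
    (the latter two are joined into the provenance string). Rows with an
    empty sequence are rejected with a logged count; duplicate sequences are
    retained but flagged in the log.
    """
    path = Path(path)
    schema = dict(schema or {})
    seq_col = schema.get("sequence", "sequence")

    try:
        text = path.read_text(encoding="utf-8")
    except UnicodeDecodeError as exc:
        raise PeptideIOError(f"{path}: not decodable as UTF-8: {exc}") from exc

    delimiter = _sniff_delimiter(text.splitlines()[0] if text.splitlines() else ",")
    reader = csv.DictReader(text.splitlines(), delimiter=delimiter)
    if reader.fieldnames is None or seq_col not in reader.fieldnames:
        raise SchemaError(f"{path}: missing mapped sequence column {seq_col!r}")
    for logical in ("id", "label", "reference", "year"):
        col = schema.get(logical)
        if col is not None and col not in reader.fieldnames:
            raise SchemaError(f"{path}: missing mapped column {col!r} for field {logical!r}")

    members: list[Peptide] = []
    rejected = 0
    for i, row in enumerate(reader):
        raw_seq = (row.get(seq_col) or "").strip()
        if not raw_seq:
            rejected += 1
            continue
        pid = row.get(schema.get("id", ""), "") or f"row{i + 1}"
        label = row.get(schema.get("label", ""), "") or LABEL_UNKNOWN
        prov_bits = [row.get(schema[k], "") for k in ("reference", "year") if k in schema]
        source = "; ".join(b for b in prov_bits if b) or None
        seq = policy.canonicalize(raw_seq, context=f"row {i + 1}")
        members.append(Peptide(id=pid, sequence=seq, label=label, source=source))

    if rejected:
        logger.warning("%s: rejected %d row(s) with empty sequence", path, rejected)
    peptide_set = PeptideSet(name or path.stem, members)
    dups = peptide_set.duplicate_sequences()
    if dups:
        logger.warning("%s: %d duplicated sequence(s): %s", path, len(dups),
                       ", ".join(sorted(dups)))
    return peptide_set


def check_cross_set_duplicates(a: PeptideSet, b: PeptideSet) -> set[str]:
    """Report sequences occurring in both sets (warning-level concern, not an error)."""
    shared = set(a.sequences) & set(b.sequences)
    if shared:
        logger.warning("sets %r and %r share %d sequence(s)", a.name, b.name, len(shared))
    return shared
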