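"""Reference and read I/O for shRNA/miRNA small-RNA analysis.

Handles the motif reference dialect (FASTA-like: header ``>name motif``,
one mature sequence line per record), plain FASTA scaffolds, 4-line FASTQ
reads, guide-passenger pairing tables, and TSV report output.

All sequences are normalized to the DNA alphabet (U -> T, uppercase) on
input; all coordinates are 0-based, half-open.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "FormatError",
    "ValidationError",
    "ReadRecord",
    "MotifEntry",
    "ScaffoldRecord",
    "PairSpec",
    "normalize_seq",
    "parse_motif_file",
    "write_motif_file",
    "read_fastq",
    "write_fastq",
    "load_scaffolds",
    "load_pairs",
    "infer_pairs",
    "write_tsv",
]

DNA_ALPHABET = frozenset("ACGTN")

#: Conventional anchor-motif length; other lengths >= MIN_MOTIF_LEN warn.
DEFAULT_MOTIF_LEN = 13
MIN_MOTIF_LEN = 10


class FormatError(ValueError):
    """A stream does not conform to its expected file format."""


class ValidationError(ValueError):
    """Parsed content violates a semantic invariant."""


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA to DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


@dataclass
class ReadRecord:
    """One sequenced small-RNA read.

    ``count`` carries multiplicity after duplicate collapsing; it is 1 for
    reads straight off the sequencer.
    """

    id: str
    seq: str
    qual: str | None = None
    umi: str | None = None
    count: int = 1

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValidationError(f"read {self.id!r}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValidationError(
                f"read {self.id!r}: non-nucleotide characters {sorted(bad)}"
            )
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FormatError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )


@dataclass
class MotifEntry:
    """One reference small RNA: a unique anchor motif inside its mature sequence.

    ``arm`` ("5p"/"3p"/"unknown") and ``construct`` are optional metadata
    used for guide-passenger pairing.
    """

    name: str
    motif: str
    mature: str
    arm: str = "unknown"
    construct: str | None = None

    def __post_init__(self) -> None:
        self.motif = normalize_seq(self.motif)
        self.mature = normalize_seq(self.mature)
        if self.motif not in self.mature:
            raise ValidationError(
                f"entry {self.name!r}: motif {self.motif!r} is not a substring "
                f"of the mature sequence"
            )
        if len(self.motif) < MIN_MOTIF_LEN:
            raise ValidationError(
                f"entry {self.name!r}: motif length {len(self.motif)} < "
                f"minimum {MIN_MOTIF_LEN}"
            )
        if len(self.motif) != DEFAULT_MOTIF_LEN:
            warnings.warn(
                f"entry {self.name!r}: motif length {len(self.motif)} differs "
                f"from the conventional {DEFAULT_MOTIF_LEN}",
                stacklevel=2,
            )

    @property
    def motif_start(self) -> int:
        """0-based start of the motif within the mature sequence."""
        return self.mature.index(self.motif)


@dataclass
class ScaffoldRecord:
    """A hairpin/scaffold sequence with anchor positions of mature sequences.

    ``anchors`` maps entry name -> 0-based start of that entry's mature
    sequence within ``seq``; used to classify templated 3' tails.
    """

    name: str
    seq: str
    anchors: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class PairSpec:
    """A guide-passenger pair belonging to one shRNA construct."""

    construct: str
    guide: str
    passenger: str


def parse_motif_file(stream: IO[str]) -> list[MotifEntry]:
    """Parse the motif reference dialect into a list of :class:`MotifEntry`.

    Each record is a header line ``>name<space>motif`` followed by exactly one
    mature-sequence line (wrapped sequences are not accepted). Motif
    uniqueness across the file is enforced.
    """
    entries: list[MotifEntry] = []
    header: tuple[str, str] | None = None
    header_lineno = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                raise FormatError(
                    f"line {header_lineno}: header {header[0]!r} has no "
                    f"sequence line"
                )
            tokens = line[1:].split()
            if len(tokens) < 2:
                raise FormatError(
                    f"line {lineno}: header must be '>name motif', "
                    f"got {line!r}"
                )
            header = (tokens[0], tokens[1])
            header_lineno = lineno
        else:
            if header is None:
                raise FormatError(
                    f"line {lineno}: sequence line without a preceding header"
                )
            name, motif = header
            entries.append(MotifEntry(name=name, motif=motif, mature=line))
            header = None
    if header is not None:
        raise FormatError(
            f"line {header_lineno}: header {header[0]!r} has no sequence line"
        )

    seen: dict[str, str] = {}
    for entry in entries:
        if entry.motif in seen:
            raise ValidationError(
                f"motif {entry.motif!r} is shared by entries "
                f"{seen[entry.motif]!r} and {entry.name!r}; motifs must be "
                f"unique within a reference set"
            )
        seen[entry.motif] = entry.name
    names = [e.name for e in entries]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate entry names: {dupes}")
    return entries


def write_motif_file(entries: Iterable[MotifEntry], stream: IO[str]) -> None:
    """Write entries back to the motif dialect (inverse of parsing)."""
    for entry in entries:
        stream.write(f">{entry.name} {entry.motif}\n{entry.mature}\n")


def read_fastq(stream: IO[str]) -> Iterator[ReadRecord]:
    """Yield :class:`ReadRecord` from 4-line FASTQ, normalizing U -> T."""
    index = 0
    try:
        for title, seq, qual in FastqGeneralIterator(stream):
            index += 1
            yield ReadRecord(
                id=title.split()[0],
                seq=normalize_seq(seq),
                qual=qual,
            )
    except ValueError as exc:
        raise FormatError(f"FASTQ record {index + 1}: {exc}") from exc


def write_fastq(records: Iterable[ReadRecord], stream: IO[str]) -> None:
    """Write records as 4-line FASTQ (constant quality when absent)."""
    for rec in records:
        qual = rec.qual if rec.qual is not None else "I" * len(rec.seq)
        stream.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


def load_scaffolds(
    stream: IO[str], entries: Iterable[MotifEntry]
) -> list[ScaffoldRecord]:
    """Load FASTA scaffolds and anchor each entry's mature sequence.

    Anchoring is exact substring search. An entry found nowhere stays
    unanchored (its tails can then never be classified templated); an entry
    found twice within one scaffold is ambiguous and raises.
    """
    entries = list(entries)
    scaffolds: list[ScaffoldRecord] = []
    for title, seq in SimpleFastaParser(stream):
        name = title.split()[0]
        seq = normalize_seq(seq)
        anchors: dict[str, int] = {}
        for entry in entries:
            start = seq.find(entry.mature)
            if start == -1:
                continue
            if seq.find(entry.mature, start + 1) != -1:
                raise ValidationError(
                    f"mature sequence of entry {entry.name!r} occurs more than "
                    f"once in scaffold {name!r}; anchoring is ambiguous"
                )
            anchors[entry.name] = start
        scaffolds.append(ScaffoldRecord(name=name, seq=seq, anchors=anchors))
    return scaffolds


def load_pairs(stream: IO[str]) -> list[PairSpec]:
    """Parse a pairing table: tab/whitespace-separated ``guide passenger``
    columns, optional third column naming the construct.

    Lines starting with ``#`` and a header line beginning with ``guide`` are
    skipped.
    """
    pairs: list[PairSpec] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if lineno == 1 and tokens[0].lower() == "guide":
            continue
        if len(tokens) < 2:
            raise FormatError(
                f"pairing table line {lineno}: expected 'guide passenger "
                f"[construct]', got {line!r}"
            )
        guide, passenger = tokens[0], tokens[1]
        construct = tokens[2] if len(tokens) > 2 else _common_stem(guide, passenger)
        pairs.append(PairSpec(construct=construct, guide=guide, passenger=passenger))
    return pairs


def _common_stem(guide: str, passenger: str) -> str:
    stem_g = _strip_role_suffix(guide)
    stem_p = _strip_role_suffix(passenger)
    if stem_g is not None and stem_g == stem_p:
        return stem_g.replace("|", "") or f"{guide}/{passenger}"
    return f"{guide}/{passenger}"


def _strip_role_suffix(name: str) -> str | None:
    """Split a name like ``shRNA-guide1`` into its construct stem ``shRNA1``.

    Returns None when no guide/passenger role token is present.
    """
    for role in ("guide", "passenger"):
        idx = name.lower().find(role)
        if idx != -1:
            return name[:idx].rstrip("-_.") + "|" + name[idx + len(role):]
    return None


def infer_pairs(entries: Iterable[MotifEntry]) -> list[PairSpec]:
    """Infer guide-passenger pairs from ``-guide``/``-passenger`` name tokens
    sharing a construct stem (e.g. ``shRNA-guide1`` with ``shRNA-passenger1``).

    Entries whose names carry neither token are ignored (endogenous miRNAs).
    """
    guides: dict[str, str] = {}
    passengers: dict[str, str] = {}
    for entry in entries:
        stem = _strip_role_suffix(entry.name)
        if stem is None:
            continue
        if "guide" in entry.name.lower():
            guides[stem] = entry.name
        else:
            passengers[stem] = entry.name
    pairs = []
    for stem in sorted(guides):
        if stem in passengers:
            construct = stem.replace("|", "") or "construct"
            pairs.append(
                PairSpec(
                    construct=construct,
                    guide=guides[stem],
                    passenger=passengers[stem],
                )
            )
    return pairs


def write_tsv(df, path_or_stream) -> None:
    """Write a DataFrame as UTF-8 TSV with a header row and no index."""
    df.to_csv(path_or_stream, sep="\t", index=False)


def log(message: str) -> None:
    """Leveled-enough logging: reports go to stdout/files, messages to stderr."""
    print(message, file=sys.stderr)
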