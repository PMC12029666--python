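"""Motif-anchored assignment of trimmed reads and isoform decomposition.

Each reference entry carries a short anchor motif (conventionally a 13-mer)
drawn from the middle of its mature sequence. A read containing that motif
is split at the motif start into a 5' segment and a 3' segment, each
compared against the corresponding reference segment by Levenshtein
distance. The decomposition yields the read's isoform anatomy:

* ``offset5`` — reference-prefix length minus read-prefix length; positive
  means the read starts inside the reference (5' trimming), negative means
  it starts upstream of it (5' extension).
* ``trim3`` / ``tail`` — the 3' walk extends an exact templated match from
  the motif end; reference bases left unmatched are trimming, read bases
  beyond the templated match are the tail.
* ``tail_templated`` — a tail that continues the hairpin scaffold downstream
  of the templated match is a miscleavage product (templated isoform);
  anything else is non-templated (e.g. post-transcriptional A/U tailing).
* ``seed`` — nucleotides 2-8 of the read (1-based), the target-recognition
  window.

Reads within the edit gates (defaults: 2 on the 5' segment, 5 on the 3'
segment) are assigned; a read matching several entries goes to the one with
the smallest total edit distance, with ties discarded as ambiguous.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib
import pandas as pd

from .refio import MotifEntry, ReadRecord, ScaffoldRecord, ValidationError

__all__ = [
    "AssignmentParams",
    "IsoformRecord",
    "AssignmentResult",
    "levenshtein",
    "decompose_read",
    "assign_reads",
    "sequence_report",
]

DEFAULT_MAX_EDIT5 = 2
DEFAULT_MAX_EDIT3 = 5

#: Seed window, 0-based half-open over the read (nucleotides 2-8, 1-based).
SEED_SLICE = slice(1, 8)


@dataclass(frozen=True)
class AssignmentParams:
    """Edit-distance gates and report-granularity thresholds.

    ``min_reads``/``min_ratio`` only control which isoforms are listed
    individually in sequence-level reports; they never affect assignment or
    metric computation.
    """

    max_edit5: int = DEFAULT_MAX_EDIT5
    max_edit3: int = DEFAULT_MAX_EDIT3
    min_reads: int = 1
    min_ratio: float = 0.0

    def __post_init__(self) -> None:
        if self.max_edit5 < 0 or self.max_edit3 < 0:
            raise ValidationError("edit-distance gates must be >= 0")
        if self.min_reads < 1:
            raise ValidationError(f"min_reads {self.min_reads} < 1")
        if not 0.0 <= self.min_ratio <= 1.0:
            raise ValidationError(f"min_ratio {self.min_ratio} not in [0, 1]")


@dataclass
class IsoformRecord:
    """One distinct read sequence assigned to an entry, with its anatomy."""

    entry: str
    seq: str
    count: int
    offset5: int
    edit5: int
    trim3: int
    tail: str
    tail_templated: bool
    edit3: int
    seed: str


@dataclass
class AssignmentResult:
    """Per-entry isoform lists plus the read-disposition tally.

    ``n_assigned + n_unassigned + n_ambiguous`` equals the input read count
    (reads counted with their multiplicity).
    """

    isoforms: dict[str, list[IsoformRecord]] = field(default_factory=dict)
    n_assigned: int = 0
    n_unassigned: int = 0
    n_ambiguous: int = 0

    @property
    def n_total(self) -> int:
        return self.n_assigned + self.n_unassigned + self.n_ambiguous


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def decompose_read(
    seq: str,
    entry: MotifEntry,
    scaffold: ScaffoldRecord | None,
    params: AssignmentParams,
) -> IsoformRecord | None:
    """Split ``seq`` at the first motif occurrence and compute its anatomy.

    Returns None when the motif is absent or an edit gate is exceeded.
    The count field is left at 0 for the caller to fill.
    """
    if entry.motif not in entry.mature:
        raise ValidationError(
            f"entry {entry.name!r} is corrupt: motif not in mature sequence"
        )
    idx = seq.find(entry.motif)
    if idx == -1:
        return None
    ref_idx = entry.motif_start

    read_prefix = seq[:idx]
    ref_prefix = entry.mature[:ref_idx]
    offset5 = len(ref_prefix) - len(read_prefix)
    edit5 = levenshtein(read_prefix, ref_prefix)
    if edit5 > params.max_edit5:
        return None

    motif_end = idx + len(entry.motif)
    read_suffix = seq[motif_end:]
    ref_suffix = entry.mature[ref_idx + len(entry.motif):]
    edit3 = levenshtein(read_suffix, ref_suffix)
    if edit3 > params.max_edit3:
        return None

    # exact templated walk: first mismatch ends the templated region
    matched = 0
    limit = min(len(read_suffix), len(ref_suffix))
    while matched < limit and read_suffix[matched] == ref_suffix[matched]:
        matched += 1
    trim3 = len(ref_suffix) - matched
    tail = read_suffix[matched:]

    tail_templated = False
    if tail and scaffold is not None and entry.name in scaffold.anchors:
        anchor = scaffold.anchors[entry.name]
        pos = anchor + ref_idx + len(entry.motif) + matched
        tail_templated = scaffold.seq[pos: pos + len(tail)] == tail

    return IsoformRecord(
        entry=entry.name,
        seq=seq,
        count=0,
        offset5=offset5,
        edit5=edit5,
        trim3=trim3,
        tail=tail,
        tail_templated=tail_templated,
        edit3=edit3,
        seed=seq[SEED_SLICE],
    )


def assign_reads(
    reads: list[ReadRecord],
    entries: list[MotifEntry],
    scaffolds: list[ScaffoldRecord] | None = None,
    params: AssignmentParams | None = None,
) -> AssignmentResult:
    """Assign reads to motif entries; collapse identical sequences first so
    the result is independent of read order.

    A distinct sequence accepted by several entries is assigned to the one
    with minimal edit5+edit3; exact ties are counted as ambiguous.
    """
    if not entries:
        raise ValidationError("assignment requires at least one motif entry")
    params = params or AssignmentParams()
    scaffolds = scaffolds or []

    scaffold_of: dict[str, ScaffoldRecord] = {}
    for scaffold in scaffolds:
        for entry_name in scaffold.anchors:
            scaffold_of[entry_name] = scaffold

    seq_counts: Counter[str] = Counter()
    for read in reads:
        seq_counts[read.seq] += read.count

    result = AssignmentResult(isoforms={entry.name: [] for entry in entries})
    for seq in sorted(seq_counts):
        count = seq_counts[seq]
        candidates: list[IsoformRecord] = []
        for entry in entries:
            rec = decompose_read(seq, entry, scaffold_of.get(entry.name), params)
            if rec is not None:
                candidates.append(rec)
        if not candidates:
            result.n_unassigned += count
            continue
        if len(candidates) > 1:
            candidates.sort(key=lambda r: (r.edit5 + r.edit3, r.entry))
            best, runner = candidates[0], candidates[1]
            if best.edit5 + best.edit3 == runner.edit5 + runner.edit3:
                result.n_ambiguous += count
                continue
        chosen = candidates[0]
        chosen.count = count
        result.isoforms[chosen.entry].append(chosen)
        result.n_assigned += count

    for records in result.isoforms.values():
        records.sort(key=lambda r: (-r.count, r.seq))
    return result


def sequence_report(
    result: AssignmentResult, params: AssignmentParams | None = None
) -> pd.DataFrame:
    """Sequence-level report: one row per reported isoform.

    Isoforms below ``min_reads`` or ``min_ratio`` collapse into one
    ``(other)`` row per entry; collapsing changes display granularity only.
    """
    params = params or AssignmentParams()
    rows = []
    for entry_name in result.isoforms:
        records = result.isoforms[entry_name]
        total = sum(r.count for r in records)
        other = 0
        for rec in records:
            ratio = rec.count / total if total else 0.0
            if rec.count < params.min_reads or ratio < params.min_ratio:
                other += rec.count
                continue
            rows.append(
                {
                    "entry": rec.entry,
                    "sequence": rec.seq,
                    "count": rec.count,
                    "offset5": rec.offset5,
                    "edit5": rec.edit5,
                    "trim3": rec.trim3,
                    "tail": rec.tail,
                    "tail_templated": rec.tail_templated,
                    "edit3": rec.edit3,
                    "seed": rec.seed,
                }
            )
        if other:
            rows.append(
                {
                    "entry": entry_name,
                    "sequence": "(other)",
                    "count": other,
                    "offset5": pd.NA,
                    "edit5": pd.NA,
                    "trim3": pd.NA,
                    "tail": "",
                    "tail_templated": pd.NA,
                    "edit3": pd.NA,
                    "seed": "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "entry",
            "sequence",
            "count",
            "offset5",
            "edit5",
            "trim3",
            "tail",
            "tail_templated",
            "edit3",
            "seed",
        ],
    )
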