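"""3' adapter location and removal with an error-rate model, UMI extraction,
length filtering, UMI deduplication, and QC reporting.

The adapter design modelled here is a ligated 3' adapter of the form
``prefix + N{umi_len} + suffix`` (the RA3 design: an 8-nt fixed prefix, a
15-nt degenerate unique molecular identifier, and a 22-nt fixed suffix).
The insert is everything 5' of the located adapter; the UMI is read out of
the degenerate window.

Matching model: the adapter is aligned without gaps at every start position
of the read (Hamming distance over the overlapping window); degenerate N
positions match any base at zero cost. A window truncated by the read's 3'
end is accepted down to ``min_overlap`` matched bases. A window of length L
tolerates ``floor(L * error_rate)`` mismatches — at the default rate of 0.1,
one error per 10 matched nucleotides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

from .refio import ReadRecord, ValidationError

__all__ = [
    "AdapterSpec",
    "AdapterMatch",
    "TrimReport",
    "allowed_errors",
    "locate_adapter",
    "process_reads",
]

# RA3 adapter anatomy
RA3_PREFIX = "CTGTTAAC"
RA3_UMI_LEN = 15
RA3_SUFFIX = "TGGAATTCTCGGGTGCCAAGGC"

DEFAULT_ERROR_RATE = 0.1
DEFAULT_MIN_OVERLAP = 3
DEFAULT_MIN_LEN = 15


@dataclass(frozen=True)
class AdapterSpec:
    """Anatomy of the ligated 3' adapter and the matching tolerances."""

    prefix: str = RA3_PREFIX
    umi_len: int = RA3_UMI_LEN
    suffix: str = RA3_SUFFIX
    error_rate: float = DEFAULT_ERROR_RATE
    min_overlap: int = DEFAULT_MIN_OVERLAP

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 1:
            raise ValidationError(f"error_rate {self.error_rate} not in [0, 1)")
        if self.min_overlap < 1:
            raise ValidationError(f"min_overlap {self.min_overlap} < 1")
        if self.umi_len < 0:
            raise ValidationError(f"umi_len {self.umi_len} < 0")

    @property
    def full(self) -> str:
        """The complete adapter string with the UMI as N bases."""
        return self.prefix + "N" * self.umi_len + self.suffix


class AdapterMatch(NamedTuple):
    start: int      # insert = seq[:start]
    errors: int
    matched_len: int


def allowed_errors(matched_len: int, error_rate: float) -> int:
    """Maximum mismatches tolerated in a matched window of ``matched_len``
    bases: floor(matched_len * error_rate).

    The epsilon shields the floor from binary-float artifacts
    (e.g. 0.1 * 30 = 2.9999...96) without changing any exact value.
    """
    if matched_len < 1:
        raise ValidationError(f"matched_len {matched_len} < 1")
    return math.floor(matched_len * error_rate + 1e-9)


def locate_adapter(seq: str, spec: AdapterSpec) -> AdapterMatch | None:
    """Find the leftmost acceptable adapter occurrence in ``seq``.

    Returns None when no start position qualifies; absence of the adapter is
    a read disposition, not an error.
    """
    adapter = spec.full
    n, m = len(seq), len(adapter)
    for start in range(0, n - spec.min_overlap + 1):
        matched_len = min(m, n - start)
        budget = allowed_errors(matched_len, spec.error_rate)
        errors = 0
        for i in range(matched_len):
            a = adapter[i]
            if a != "N" and seq[start + i] != a:
                errors += 1
                if errors > budget:
                    break
        else:
            return AdapterMatch(start=start, errors=errors, matched_len=matched_len)
    return None


@dataclass
class TrimReport:
    """QC tally of one trimming run.

    Disposition counts are nested: ``n_after_dedup <= n_pass_length <=
    n_with_adapter <= n_input``. ``length_hist`` covers reads passing the
    length filter; ``base_before_adapter`` covers every read in which an
    adapter was located (empty inserts are tallied under N).
    """

    n_input: int = 0
    n_with_adapter: int = 0
    n_pass_length: int = 0
    n_after_dedup: int = 0
    length_hist: dict[int, int] = field(default_factory=dict)
    base_before_adapter: dict[str, int] = field(
        default_factory=lambda: {b: 0 for b in "ACGTN"}
    )

    @property
    def pct_with_adapter(self) -> float:
        return 100.0 * self.n_with_adapter / self.n_input if self.n_input else 0.0

    @property
    def pct_pass_length(self) -> float:
        return 100.0 * self.n_pass_length / self.n_input if self.n_input else 0.0

    def summary_text(self) -> str:
        lines = [
            f"reads in                         {self.n_input}",
            f"reads with adapter               {self.n_with_adapter} "
            f"({self.pct_with_adapter:.1f}%)",
            f"reads passing length filter      {self.n_pass_length} "
            f"({self.pct_pass_length:.1f}%)",
            f"reads after UMI deduplication    {self.n_after_dedup}",
            "",
            "base preceding adapter:",
        ]
        total = sum(self.base_before_adapter.values()) or 1
        for base in "ACGTN":
            count = self.base_before_adapter.get(base, 0)
            lines.append(f"  {base}  {count}  ({100.0 * count / total:.1f}%)")
        lines.append("")
        lines.append("insert length histogram (after filters):")
        for length in sorted(self.length_hist):
            lines.append(f"  {length}  {self.length_hist[length]}")
        return "\n".join(lines) + "\n"

    def to_rows(self) -> list[dict]:
        rows = [
            {"metric": "n_input", "key": "", "value": self.n_input},
            {"metric": "n_with_adapter", "key": "", "value": self.n_with_adapter},
            {"metric": "n_pass_length", "key": "", "value": self.n_pass_length},
            {"metric": "n_after_dedup", "key": "", "value": self.n_after_dedup},
        ]
        for base in "ACGTN":
            rows.append(
                {
                    "metric": "base_before_adapter",
                    "key": base,
                    "value": self.base_before_adapter.get(base, 0),
                }
            )
        for length in sorted(self.length_hist):
            rows.append(
                {
                    "metric": "length_hist",
                    "key": length,
                    "value": self.length_hist[length],
                }
            )
        return rows


def process_reads(
    reads: Iterable[ReadRecord] | Iterator[ReadRecord],
    spec: AdapterSpec,
    min_len: int = DEFAULT_MIN_LEN,
    discard_untrimmed: bool = True,
    dedup: bool = True,
) -> tuple[list[ReadRecord], TrimReport]:
    """Trim the 3' adapter off each read, extract UMIs, filter, deduplicate.

    Returns the retained reads (insert as ``seq``, UMI attached when the
    degenerate window was fully read) and the QC report. With ``dedup``,
    reads sharing (insert, UMI) collapse to one representative whose
    ``count`` is the multiplicity; reads with a truncated UMI window keep
    ``umi=None`` and are never collapsed.
    """
    if min_len < 1:
        raise ValidationError(f"min_len {min_len} < 1")

    report = TrimReport()
    kept: list[ReadRecord] = []
    kept_untrimmed: list[ReadRecord] = []  # outside the nested adapter tallies
    for read in reads:
        report.n_input += 1
        match = locate_adapter(read.seq, spec)
        if match is None:
            if not discard_untrimmed and len(read.seq) >= min_len:
                kept_untrimmed.append(read)
            continue
        report.n_with_adapter += 1
        insert = read.seq[: match.start]
        last_base = insert[-1] if insert else "N"
        if last_base not in report.base_before_adapter:
            last_base = "N"
        report.base_before_adapter[last_base] += 1

        if len(insert) < min_len:
            continue
        report.n_pass_length += 1
        report.length_hist[len(insert)] = report.length_hist.get(len(insert), 0) + 1

        umi_start = match.start + len(spec.prefix)
        umi_end = umi_start + spec.umi_len
        umi = read.seq[umi_start:umi_end] if umi_end <= len(read.seq) else None
        kept.append(
            ReadRecord(
                id=read.id,
                seq=insert,
                qual=read.qual[: match.start] if read.qual is not None else None,
                umi=umi,
                count=read.count,
            )
        )

    if dedup:
        kept = _dedup_by_umi(kept)
    report.n_after_dedup = len(kept)
    return kept + kept_untrimmed, report


def _dedup_by_umi(reads: list[ReadRecord]) -> list[ReadRecord]:
    """Collapse reads sharing (insert sequence, UMI); first-seen representative."""
    out: list[ReadRecord] = []
    index: dict[tuple[str, str], int] = {}
    for read in reads:
        if read.umi is None:
            out.append(read)
            continue
        key = (read.seq, read.umi)
        if key in index:
            rep = out[index[key]]
            out[index[key]] = ReadRecord(
                id=rep.id,
                seq=rep.seq,
                qual=rep.qual,
                umi=rep.umi,
                count=rep.count + read.count,
            )
        else:
            index[key] = len(out)
            out.append(read)
    return out
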