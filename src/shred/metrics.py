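"""Biogenesis metrics for shRNA/miRNA libraries.

Per entry: CPM abundance (reads per million reads assigned to any entry),
Fidelity_5P (count-weighted mean |5' offset| in nucleotides — 0 for
perfectly homogeneous 5' ends, rising toward 1-2 nt for imprecisely
processed scaffolds), trimming/tailing percentages, and isoform counts.

Per guide-passenger pair:

* strand selection index = CPM_guide / (CPM_guide + CPM_passenger);
  efficient designs reach 0.9 or higher.
* N effective seed = 1 / sum(p_i^2) over the observed seed-sequence
  proportions p_i (the inverse Simpson effective number); efficient designs
  stay within [1, 1.1].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .assign import AssignmentResult, IsoformRecord
from .refio import PairSpec, ValidationError

__all__ = [
    "EntryMetrics",
    "PairMetrics",
    "compute_entry_metrics",
    "strand_selection_index",
    "effective_seed_number",
    "compute_pair_metrics",
    "entry_metrics_frame",
    "pair_metrics_frame",
]

STRAND_INDEX_BOUND = 0.9
N_SEED_BOUND = 1.1


@dataclass
class EntryMetrics:
    """Per-reference summary. Percentage fields are read-weighted (fraction
    of reads showing the event); mean lengths are companions. Fields are NaN
    for entries with no assigned reads."""

    entry: str
    reads: int
    cpm: float
    fidelity5p: float
    pct_trimmed: float
    pct_tailed: float
    pct_tailed_nontemplated: float
    mean_trim_len: float
    mean_tail_len: float
    n_isoforms: int


@dataclass
class PairMetrics:
    """Guide-passenger pair summary with efficiency classification."""

    construct: str
    guide: str
    passenger: str
    strand_index: float
    n_seed: float
    efficient_strand: bool
    efficient_seed: bool


def compute_entry_metrics(result: AssignmentResult) -> list[EntryMetrics]:
    """Summarise every entry of an assignment result; entries with zero
    assigned reads get cpm 0 and NaN for the undefined fields."""
    if result.n_assigned == 0:
        warnings.warn("no reads assigned to any entry; metrics are undefined",
                      stacklevel=2)
    out: list[EntryMetrics] = []
    for entry_name, records in result.isoforms.items():
        reads = sum(r.count for r in records)
        cpm = 1e6 * reads / result.n_assigned if result.n_assigned else 0.0
        if reads == 0:
            out.append(
                EntryMetrics(
                    entry=entry_name, reads=0, cpm=cpm,
                    fidelity5p=math.nan, pct_trimmed=math.nan,
                    pct_tailed=math.nan, pct_tailed_nontemplated=math.nan,
                    mean_trim_len=math.nan, mean_tail_len=math.nan,
                    n_isoforms=0,
                )
            )
            continue
        fidelity5p = sum(r.count * abs(r.offset5) for r in records) / reads
        n_trimmed = sum(r.count for r in records if r.trim3 >= 1)
        n_tailed = sum(r.count for r in records if r.tail)
        n_tailed_nt = sum(
            r.count for r in records if r.tail and not r.tail_templated
        )
        out.append(
            EntryMetrics(
                entry=entry_name,
                reads=reads,
                cpm=cpm,
                fidelity5p=fidelity5p,
                pct_trimmed=100.0 * n_trimmed / reads,
                pct_tailed=100.0 * n_tailed / reads,
                pct_tailed_nontemplated=100.0 * n_tailed_nt / reads,
                mean_trim_len=sum(r.count * r.trim3 for r in records) / reads,
                mean_tail_len=sum(r.count * len(r.tail) for r in records) / reads,
                n_isoforms=len(records),
            )
        )
    return out


def strand_selection_index(cpm_guide: float, cpm_passenger: float) -> float:
    """CPM_guide / (CPM_guide + CPM_passenger); NaN when both are zero."""
    if cpm_guide < 0 or cpm_passenger < 0:
        raise ValidationError("CPM values must be non-negative")
    total = cpm_guide + cpm_passenger
    if total == 0:
        warnings.warn("strand selection index undefined: both CPMs are zero",
                      stacklevel=2)
        return math.nan
    return cpm_guide / total


def effective_seed_number(guide_isoforms: list[IsoformRecord]) -> float:
    """Inverse Simpson effective number of seed sequences (read positions
    2-8) over the guide's reads; NaN for empty input."""
    seed_counts: dict[str, int] = {}
    for rec in guide_isoforms:
        seed_counts[rec.seed] = seed_counts.get(rec.seed, 0) + rec.count
    total = sum(seed_counts.values())
    if total == 0:
        warnings.warn("N effective seed undefined: no reads", stacklevel=2)
        return math.nan
    simpson = sum((count / total) ** 2 for count in seed_counts.values())
    return 1.0 / simpson


def compute_pair_metrics(
    entry_metrics: list[EntryMetrics],
    isoforms: dict[str, list[IsoformRecord]],
    pairs: list[PairSpec],
) -> list[PairMetrics]:
    """Evaluate strand selection and seed-number metrics for each pair and
    classify against the efficiency bounds (index >= 0.9; N seed in [1, 1.1])."""
    by_name = {m.entry: m for m in entry_metrics}
    out: list[PairMetrics] = []
    for pair in pairs:
        for role, name in (("guide", pair.guide), ("passenger", pair.passenger)):
            if name not in by_name:
                raise ValidationError(
                    f"pair {pair.construct!r}: {role} entry {name!r} is not "
                    f"in the reference set"
                )
        index = strand_selection_index(by_name[pair.guide].cpm,
                                       by_name[pair.passenger].cpm)
        n_seed = effective_seed_number(isoforms.get(pair.guide, []))
        out.append(
            PairMetrics(
                construct=pair.construct,
                guide=pair.guide,
                passenger=pair.passenger,
                strand_index=index,
                n_seed=n_seed,
                efficient_strand=bool(index >= STRAND_INDEX_BOUND),
                efficient_seed=bool(1.0 <= n_seed <= N_SEED_BOUND),
            )
        )
    return out


def entry_metrics_frame(metrics: list[EntryMetrics]) -> pd.DataFrame:
    """Summary-report DataFrame, one row per entry."""
    return pd.DataFrame(
        [
            {
                "entry": m.entry,
                "reads": m.reads,
                "cpm": m.cpm,
                "fidelity5p": m.fidelity5p,
                "pct_trimmed": m.pct_trimmed,
                "pct_tailed": m.pct_tailed,
                "pct_tailed_nontemplated": m.pct_tailed_nontemplated,
                "mean_trim_len": m.mean_trim_len,
                "mean_tail_len": m.mean_tail_len,
                "n_isoforms": m.n_isoforms,
            }
            for m in metrics
        ],
        columns=[
            "entry", "reads", "cpm", "fidelity5p", "pct_trimmed",
            "pct_tailed", "pct_tailed_nontemplated", "mean_trim_len",
            "mean_tail_len", "n_isoforms",
        ],
    )


def pair_metrics_frame(metrics: list[PairMetrics]) -> pd.DataFrame:
    """Pair-report DataFrame, one row per guide-passenger pair."""
    return pd.DataFrame(
        [
            {
                "construct": m.construct,
                "guide": m.guide,
                "passenger": m.passenger,
                "strand_index": m.strand_index,
                "n_seed": m.n_seed,
                "efficient_strand": m.efficient_strand,
                "efficient_seed": m.efficient_seed,
            }
            for m in metrics
        ],
        columns=[
            "construct", "guide", "passenger", "strand_index", "n_seed",
            "efficient_strand", "efficient_seed",
        ],
    )
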