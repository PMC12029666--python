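"""Ground-truth simulator for shRNA hairpin processing.

Reads are drawn from a hairpin laid out as
``flank5 + arm5p(passenger) + loop + arm3p(guide) + flank3``. Each read
picks an arm (guide with probability ``p_guide``), shifts the canonical arm
boundaries by sampled 5'/3' cleavage offsets, optionally appends a
non-templated tail (A/U-biased base, geometric length), applies per-base
substitution errors, and is optionally suffixed with a ligated 3' adapter
carrying a random UMI. The per-read truth table records the generating
parameters, so the trimming, assignment, and metrics stages can be tested
against known ground truth.

Offset conventions match the decomposition stage: positive 5' offset =
start shifted into the arm (5' trimming), negative = start upstream in the
scaffold (templated 5' extension). Positive 3' offset = 3' trimming,
negative = templated 3' extension past the canonical arm end. 2-nt-overhang
and transcription-start heterogeneity are emulated through these offset
distributions rather than a mechanistic cleavage model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .refio import (
    DNA_ALPHABET,
    MotifEntry,
    ReadRecord,
    ScaffoldRecord,
    ValidationError,
)
from .trim import AdapterSpec

__all__ = [
    "GenerationError",
    "HairpinSpec",
    "ProcessingModel",
    "simulate_library",
    "motif_entries",
    "scaffold_record",
    "scenario_presets",
]

BASES = "ACGT"
GUIDE_ARM = "3p"
PASSENGER_ARM = "5p"


class GenerationError(ValueError):
    """A sampled read cannot be realised on the hairpin."""


@dataclass(frozen=True)
class HairpinSpec:
    """Anatomy of one hairpin construct.

    The guide strand sits on the 3p arm and the passenger on the 5p arm, the
    usual stem orientation of miRNA-scaffold shRNAs.
    """

    name: str
    flank5: str
    arm5p: str
    loop: str
    arm3p: str
    flank3: str

    def __post_init__(self) -> None:
        for label, seg in (
            ("flank5", self.flank5), ("arm5p", self.arm5p), ("loop", self.loop),
            ("arm3p", self.arm3p), ("flank3", self.flank3),
        ):
            if set(seg) - (DNA_ALPHABET - {"N"}):
                raise ValidationError(
                    f"hairpin {self.name!r}: segment {label} contains "
                    f"non-ACGT characters"
                )
        for label, arm in (("arm5p", self.arm5p), ("arm3p", self.arm3p)):
            if len(arm) < 15:
                raise ValidationError(
                    f"hairpin {self.name!r}: {label} shorter than 15 nt would "
                    f"not survive the length filter"
                )

    @property
    def sequence(self) -> str:
        return self.flank5 + self.arm5p + self.loop + self.arm3p + self.flank3

    def arm_bounds(self, arm: str) -> tuple[int, int]:
        """Canonical [start, end) of an arm within the full hairpin string."""
        if arm == PASSENGER_ARM:
            start = len(self.flank5)
            return start, start + len(self.arm5p)
        if arm == GUIDE_ARM:
            start = len(self.flank5) + len(self.arm5p) + len(self.loop)
            return start, start + len(self.arm3p)
        raise ValidationError(f"unknown arm {arm!r}")


def _validate_categorical(name: str, dist: Mapping[int, float]) -> None:
    if not dist:
        raise ValidationError(f"{name}: empty distribution")
    if any(p < 0 for p in dist.values()):
        raise ValidationError(f"{name}: negative probability")
    if abs(sum(dist.values()) - 1.0) > 1e-9:
        raise ValidationError(f"{name}: probabilities must sum to 1")


@dataclass(frozen=True)
class ProcessingModel:
    """Stochastic model of hairpin processing and sequencing.

    ``offset5_dist``/``offset3_dist`` are categorical offset distributions
    keyed by arm ("5p"/"3p"). Tails have a geometric length (support >= 1,
    success probability ``tail_len_param``) and bases drawn from
    ``tail_base_weights`` — A/U-biased, since adenylation and uridylation
    dominate non-templated tailing in cells.
    """

    offset5_dist: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {GUIDE_ARM: {0: 1.0}, PASSENGER_ARM: {0: 1.0}}
    )
    offset3_dist: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {GUIDE_ARM: {0: 1.0}, PASSENGER_ARM: {0: 1.0}}
    )
    p_guide: float = 0.5
    tail_prob: float = 0.0
    tail_base_weights: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.7, "T": 0.3}
    )
    tail_len_param: float = 0.5
    seq_error: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for prob, label in (
            (self.p_guide, "p_guide"),
            (self.tail_prob, "tail_prob"),
            (self.seq_error, "seq_error"),
        ):
            if not 0.0 <= prob <= 1.0:
                raise ValidationError(f"{label} {prob} not in [0, 1]")
        if not 0.0 < self.tail_len_param <= 1.0:
            raise ValidationError(
                f"tail_len_param {self.tail_len_param} not in (0, 1]"
            )
        # an arm omitted from an offset map defaults to canonical ends
        for attr in ("offset5_dist", "offset3_dist"):
            dist = dict(getattr(self, attr))
            for arm in (GUIDE_ARM, PASSENGER_ARM):
                dist.setdefault(arm, {0: 1.0})
                _validate_categorical(f"{attr}[{arm}]", dist[arm])
            object.__setattr__(self, attr, dist)
        if not self.tail_base_weights:
            raise ValidationError("tail_base_weights is empty")


def _sample_categorical(rng: np.random.Generator, dist: Mapping[int, float]) -> int:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=probs / probs.sum()))


def simulate_library(
    spec: HairpinSpec,
    model: ProcessingModel,
    n: int,
    adapter: AdapterSpec | None = None,
    read_len: int | None = None,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Draw ``n`` independent reads; return FASTQ-ready records plus the
    per-read truth table (read_id, arm, offset5, offset3, tail, umi,
    n_errors).

    Identical ``model.rng_seed`` yields byte-identical output. With
    ``adapter``, each read is suffixed by prefix + random UMI + suffix and
    truncated to ``read_len`` when given.
    """
    if n < 1:
        raise ValidationError(f"read count {n} < 1")
    rng = np.random.default_rng(model.rng_seed)
    hairpin = spec.sequence
    tail_bases = sorted(model.tail_base_weights)
    tail_probs = np.array(
        [model.tail_base_weights[b] for b in tail_bases], dtype=float
    )
    tail_probs = tail_probs / tail_probs.sum()

    reads: list[ReadRecord] = []
    truth_rows: list[dict] = []
    for i in range(n):
        arm = GUIDE_ARM if rng.random() < model.p_guide else PASSENGER_ARM
        start0, end0 = spec.arm_bounds(arm)
        off5 = _sample_categorical(rng, model.offset5_dist[arm])
        off3 = _sample_categorical(rng, model.offset3_dist[arm])
        start, end = start0 + off5, end0 - off3
        if start < 0 or end > len(hairpin) or end <= start:
            raise GenerationError(
                f"read {i}: offsets ({off5}, {off3}) leave the hairpin"
            )
        core = hairpin[start:end]

        tail = ""
        if model.tail_prob and rng.random() < model.tail_prob:
            length = int(rng.geometric(model.tail_len_param))
            tail = "".join(
                tail_bases[int(k)]
                for k in rng.choice(len(tail_bases), size=length, p=tail_probs)
            )
        insert = core + tail

        seq = list(insert)
        n_errors = 0
        if model.seq_error:
            for j in range(len(seq)):
                if rng.random() < model.seq_error:
                    alternatives = [b for b in BASES if b != seq[j]]
                    seq[j] = alternatives[int(rng.integers(3))]
                    n_errors += 1
        seq_str = "".join(seq)

        umi = None
        if adapter is not None:
            umi = "".join(
                BASES[int(k)] for k in rng.integers(0, 4, size=adapter.umi_len)
            )
            seq_str = seq_str + adapter.prefix + umi + adapter.suffix
            if read_len is not None:
                seq_str = seq_str[:read_len]

        read_id = f"{spec.name}_r{i:06d}"
        reads.append(ReadRecord(id=read_id, seq=seq_str, qual="I" * len(seq_str)))
        truth_rows.append(
            {
                "read_id": read_id,
                "arm": arm,
                "offset5": off5,
                "offset3": off3,
                "tail": tail,
                "umi": umi if umi is not None else "",
                "n_errors": n_errors,
            }
        )
    return reads, pd.DataFrame(truth_rows)


def motif_entries(spec: HairpinSpec, motif_len: int = 13) -> list[MotifEntry]:
    """Reference entries for the hairpin's two arms, with the anchor motif
    taken from the centre of each mature sequence."""
    entries = []
    for arm, mature, role in (
        (GUIDE_ARM, spec.arm3p, "guide"),
        (PASSENGER_ARM, spec.arm5p, "passenger"),
    ):
        start = (len(mature) - motif_len) // 2
        entries.append(
            MotifEntry(
                name=f"{spec.name}-{role}",
                motif=mature[start: start + motif_len],
                mature=mature,
                arm=arm,
                construct=spec.name,
            )
        )
    if entries[0].motif == entries[1].motif:
        raise ValidationError(
            f"hairpin {spec.name!r}: the two arms share their central "
            f"{motif_len}-mer; motifs would not be unique"
        )
    return entries


def scaffold_record(
    spec: HairpinSpec, entries: list[MotifEntry] | None = None
) -> ScaffoldRecord:
    """Scaffold record over the full hairpin with both arms anchored."""
    entries = entries if entries is not None else motif_entries(spec)
    anchors = {}
    for entry in entries:
        start = spec.sequence.find(entry.mature)
        if start != -1:
            anchors[entry.name] = start
    return ScaffoldRecord(name=spec.name, seq=spec.sequence, anchors=anchors)


# The preset hairpin's arms are a guide/passenger mature pair whose central
# 13-mers are unique; flanks and loop are fixed scaffold context.
_PRESET_HAIRPIN = HairpinSpec(
    name="shRNA1",
    flank5="GGCTGCTTGAGA",
    arm5p="TGAGGTAGTAGGTTGTATAGAA",
    loop="GTTTTGGCCACTGACTGAC",
    arm3p="TCAGGATACAGATACATAACTT",
    flank3="GTCACTGCCTACTGCC",
)


def scenario_presets() -> dict[str, tuple[HairpinSpec, ProcessingModel]]:
    """Named hairpin + processing-model bundles covering the qualitative
    construct archetypes seen in practice:

    * ``precise`` — efficient design: strong guide loading, homogeneous ends.
    * ``imprecise_5p`` — heterogeneous 5' cleavage on the guide arm (seed
      shifting, fidelity loss).
    * ``passenger_heavy`` — substantial passenger-strand incorporation.
    * ``tailed`` — frequent non-templated A/U tailing.
    * ``arm_switched`` — the passenger arm dominates (strand index < 0.5).
    """
    h = _PRESET_HAIRPIN
    uniform0 = {GUIDE_ARM: {0: 1.0}, PASSENGER_ARM: {0: 1.0}}
    jitter3 = {
        GUIDE_ARM: {-1: 0.1, 0: 0.8, 1: 0.1},
        PASSENGER_ARM: {-1: 0.1, 0: 0.8, 1: 0.1},
    }
    return {
        "precise": (
            h,
            ProcessingModel(
                offset5_dist=uniform0, offset3_dist=uniform0,
                p_guide=0.95, tail_prob=0.02, seq_error=0.001, rng_seed=7,
            ),
        ),
        "imprecise_5p": (
            h,
            ProcessingModel(
                offset5_dist={
                    GUIDE_ARM: {-1: 0.15, 0: 0.5, 1: 0.25, 2: 0.1},
                    PASSENGER_ARM: {0: 0.8, 1: 0.2},
                },
                offset3_dist=jitter3,
                p_guide=0.9, tail_prob=0.05, seq_error=0.001, rng_seed=7,
            ),
        ),
        "passenger_heavy": (
            h,
            ProcessingModel(
                offset5_dist=uniform0, offset3_dist=jitter3,
                p_guide=0.6, tail_prob=0.05, seq_error=0.001, rng_seed=7,
            ),
        ),
        "tailed": (
            h,
            ProcessingModel(
                offset5_dist=uniform0, offset3_dist=jitter3,
                p_guide=0.9, tail_prob=0.35, tail_len_param=0.4,
                seq_error=0.001, rng_seed=7,
            ),
        ),
        "arm_switched": (
            h,
            ProcessingModel(
                offset5_dist=uniform0, offset3_dist=jitter3,
                p_guide=0.3, tail_prob=0.05, seq_error=0.001, rng_seed=7,
            ),
        ),
    }
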