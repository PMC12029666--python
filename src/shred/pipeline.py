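"""End-to-end pipeline: trim -> assign -> metrics, with report files.

A run produces five reports under one output prefix plus a manifest:

* ``<prefix>.trim_report.tsv``   — trimming QC tallies
* ``<prefix>.trim_summary.txt``  — the same QC in human-readable form
* ``<prefix>.sequence.tsv``      — sequence-level isoform report
* ``<prefix>.summary.tsv``       — per-entry summary metrics
* ``<prefix>.pairs.tsv``         — guide-passenger strand/seed metrics
* ``<prefix>.dominant.tsv``      — top-N most abundant sequences per entry
* ``<prefix>.manifest.txt``      — version, config echo, input checksums

The config file is flat ``key = value`` text; any CLI flag overrides its
config key. Identical inputs and config give byte-identical reports.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd

from . import __version__
from .assign import AssignmentParams, assign_reads, sequence_report
from .metrics import (
    compute_entry_metrics,
    compute_pair_metrics,
    entry_metrics_frame,
    pair_metrics_frame,
)
from .refio import (
    ValidationError,
    infer_pairs,
    load_pairs,
    load_scaffolds,
    log,
    parse_motif_file,
    read_fastq,
    write_fastq,
    write_tsv,
)
from .trim import AdapterSpec, process_reads

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; see module docstring for outputs."""

    fastq: str
    motifs: str
    out_prefix: str
    scaffolds: str | None = None
    pairs: str | None = None
    # trimming
    skip_trim: bool = False
    adapter_prefix: str = AdapterSpec.prefix
    umi_len: int = AdapterSpec.umi_len
    adapter_suffix: str = AdapterSpec.suffix
    error_rate: float = AdapterSpec.error_rate
    min_overlap: int = AdapterSpec.min_overlap
    min_len: int = 15
    discard_untrimmed: bool = True
    dedup: bool = True
    # assignment
    edit5: int = 2
    edit3: int = 5
    min_reads: int = 1
    min_ratio: float = 0.0
    # reporting
    top_n: int = 5

    def validate(self) -> None:
        for label, path in (("fastq", self.fastq), ("motifs", self.motifs),
                            ("scaffolds", self.scaffolds), ("pairs", self.pairs)):
            if path is not None and not Path(path).exists():
                raise ValidationError(f"{label} path {path!r} does not exist")
        if self.min_len < 1:
            raise ValidationError(f"min_len {self.min_len} < 1")
        if self.top_n < 1:
            raise ValidationError(f"top_n {self.top_n} < 1")
        # delegate range checks to the parameter objects
        self.adapter_spec()
        self.assignment_params()

    def adapter_spec(self) -> AdapterSpec:
        return AdapterSpec(
            prefix=self.adapter_prefix,
            umi_len=self.umi_len,
            suffix=self.adapter_suffix,
            error_rate=self.error_rate,
            min_overlap=self.min_overlap,
        )

    def assignment_params(self) -> AssignmentParams:
        return AssignmentParams(
            max_edit5=self.edit5,
            max_edit3=self.edit3,
            min_reads=self.min_reads,
            min_ratio=self.min_ratio,
        )


_BOOL_KEYS = {"skip_trim", "discard_untrimmed", "dedup"}


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Read a flat ``key = value`` config file; keyword overrides win."""
    values: dict[str, object] = {}
    types = {f.name: f.type for f in fields(PipelineConfig)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValidationError(
                f"config line {lineno}: expected 'key = value', got {line!r}"
            )
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in types:
            raise ValidationError(f"config line {lineno}: unknown key {key!r}")
        values[key] = _coerce(key, value)
    values.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return PipelineConfig(**values)
    except TypeError as exc:
        raise ValidationError(f"incomplete config: {exc}") from exc


def _coerce(key: str, value: str):
    if key in _BOOL_KEYS:
        if value.lower() in {"true", "yes", "1"}:
            return True
        if value.lower() in {"false", "no", "0"}:
            return False
        raise ValidationError(f"config key {key}: not a boolean: {value!r}")
    for cast in (int, float):
        hints = {
            int: {"umi_len", "min_overlap", "min_len", "edit5", "edit3",
                  "min_reads", "top_n"},
            float: {"error_rate", "min_ratio"},
        }
        if key in hints[cast]:
            return cast(value)
    return value


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def dominant_reads(seq_frame: pd.DataFrame, top_n: int) -> pd.DataFrame:
    """Top-N most abundant reported sequences per entry, by count then
    sequence (deterministic)."""
    real = seq_frame[seq_frame["sequence"] != "(other)"]
    if real.empty:
        return real.assign(rank=pd.Series(dtype=int))
    ranked = real.sort_values(
        ["entry", "count", "sequence"], ascending=[True, False, True]
    )
    ranked = ranked.groupby("entry", sort=True).head(top_n).copy()
    ranked["rank"] = ranked.groupby("entry").cumcount() + 1
    return ranked


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute trim -> assign -> metrics and write all report files.

    Returns a mapping from artifact name to path. Raises ValidationError on
    bad configuration or inputs; stage errors propagate with context.
    """
    config.validate()
    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    with open(config.motifs) as fh:
        entries = parse_motif_file(fh)
    log(f"[refio] {len(entries)} motif entries loaded")

    scaffolds = []
    if config.scaffolds:
        with open(config.scaffolds) as fh:
            scaffolds = load_scaffolds(fh, entries)
        anchored = sum(len(s.anchors) for s in scaffolds)
        log(f"[refio] {len(scaffolds)} scaffolds loaded, {anchored} anchors")

    if config.pairs:
        with open(config.pairs) as fh:
            pairs = load_pairs(fh)
    else:
        pairs = infer_pairs(entries)
    log(f"[refio] {len(pairs)} guide-passenger pairs")

    with open(config.fastq) as fh:
        reads = list(read_fastq(fh))
    log(f"[trim] {len(reads)} reads in")

    if config.skip_trim:
        trimmed = [r for r in reads if len(r.seq) >= config.min_len]
        log(f"[trim] skipped (pre-trimmed input); {len(trimmed)} reads "
            f">= {config.min_len} nt")
    else:
        trimmed, trim_report = process_reads(
            iter(reads),
            config.adapter_spec(),
            min_len=config.min_len,
            discard_untrimmed=config.discard_untrimmed,
            dedup=config.dedup,
        )
        report_path = Path(str(prefix) + ".trim_report.tsv")
        write_tsv(pd.DataFrame(trim_report.to_rows()), report_path)
        artifacts["trim_report"] = report_path
        summary_path = Path(str(prefix) + ".trim_summary.txt")
        summary_path.write_text(trim_report.summary_text())
        artifacts["trim_summary"] = summary_path
        trimmed_path = Path(str(prefix) + ".trimmed.fastq")
        with open(trimmed_path, "w") as fh:
            write_fastq(trimmed, fh)
        artifacts["trimmed_fastq"] = trimmed_path
        log(f"[trim] {trim_report.n_with_adapter} with adapter, "
            f"{trim_report.n_pass_length} pass length, "
            f"{trim_report.n_after_dedup} after dedup")

    params = config.assignment_params()
    result = assign_reads(trimmed, entries, scaffolds, params)
    log(f"[assign] {result.n_assigned} assigned, {result.n_unassigned} "
        f"unassigned, {result.n_ambiguous} ambiguous")

    seq_frame = sequence_report(result, params)
    seq_path = Path(str(prefix) + ".sequence.tsv")
    write_tsv(seq_frame, seq_path)
    artifacts["sequence"] = seq_path

    entry_metrics = compute_entry_metrics(result)
    summary_frame = entry_metrics_frame(entry_metrics)
    summary_path = Path(str(prefix) + ".summary.tsv")
    write_tsv(summary_frame, summary_path)
    artifacts["summary"] = summary_path

    pair_frame = pair_metrics_frame(
        compute_pair_metrics(entry_metrics, result.isoforms, pairs)
    )
    pairs_path = Path(str(prefix) + ".pairs.tsv")
    write_tsv(pair_frame, pairs_path)
    artifacts["pairs"] = pairs_path

    dom_path = Path(str(prefix) + ".dominant.tsv")
    write_tsv(dominant_reads(seq_frame, config.top_n), dom_path)
    artifacts["dominant"] = dom_path

    manifest_path = Path(str(prefix) + ".manifest.txt")
    manifest_lines = [f"shred_version = {__version__}"]
    for f in fields(config):
        manifest_lines.append(f"{f.name} = {getattr(config, f.name)}")
    for label, path in (("fastq", config.fastq), ("motifs", config.motifs),
                        ("scaffolds", config.scaffolds), ("pairs", config.pairs)):
        if path is not None:
            manifest_lines.append(f"sha256_{label} = {_sha256(path)}")
    manifest_path.write_text("\n".join(manifest_lines) + "\n")
    artifacts["manifest"] = manifest_path
    return artifacts
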