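# Methods

## Scope and data model

`shred` analyses bulk small-RNA-seq libraries from cells expressing shRNA
constructs. Reads begin at the insert's 5′ end and run into a ligated 3′
adapter; there is no 5′ adapter and no paired-end logic. All sequences are
normalized to the DNA alphabet (U→T, uppercase) on input, and all
coordinates are 0-based, half-open.

The reference is a motif file in a FASTA-like dialect: each record is a
header `>name motif` followed by exactly one mature-sequence line.
Wrapped (multi-line) sequences are not accepted — the dialect is defined as
one line per record, and the parser rejects anything else rather than guess.
The anchor motif must occur in the mature sequence and be unique across the
file. The conventional motif length is 13; lengths of 10–12 or ≥14 parse
with a warning (the convention is not a law), below 10 is an error because
anchor specificity collapses. Guide–passenger pairing comes from an
explicit two-column table when given, else from name tokens
`guide`/`passenger` sharing a construct stem (e.g. `shRNA-guide1` /
`shRNA-passenger1`).

## Adapter trimming

The adapter is modelled as `prefix + N{umi_len} + suffix` (defaults: the
RA3 design `CTGTTAAC` + N15 + `TGGAATTCTCGGGTGCCAAGGC`). Matching is
gapless: at each read position the overlapping window of the adapter is
compared by Hamming distance; `N` positions match any base at zero cost.
Substitutions dominate Illumina error and a gapless model keeps the
matching exactly checkable against a brute-force scorer, which the test
suite does on randomized reads.

A window of length L tolerates ⌊L·r⌋ mismatches (error rate r, default
0.1). L counts the whole window including degenerate positions, so the
documented rule — one error per 10 matched nucleotides — holds regardless
of where the window sits. Partial windows arise only at the read's 3′
terminus (adapter truncated by read length) and are accepted down to
`min_overlap` (default 3) matched bases. The leftmost qualifying start wins,
which maximizes determinism and mirrors 3′-adapter semantics.

The insert is everything 5′ of the match; inserts shorter than `min_len`
(default 15 nt — shorter species are rarely genuine Argonaute cargo) are
dropped. The UMI is read from the degenerate window; reads that end before
the window completes keep `umi = None` and are exempt from deduplication,
because duplicates cannot be distinguished without a full UMI.
Deduplication collapses identical (insert, UMI) pairs to the first-seen
record with a multiplicity count. The QC report tallies dispositions
(input ≥ with-adapter ≥ pass-length ≥ after-dedup), the insert-length
histogram, and the base preceding the adapter — an A/T excess there is the
signature of tailed small RNAs.

## Isoform decomposition

A read is tested against every entry whose motif it contains. The first
motif occurrence anchors the split: motifs are designed unique and central,
so a repeat within one short read indicates a degenerate design, and
first-occurrence is deterministic. Relative to the anchored split:

* `offset5` = len(reference prefix) − len(read prefix); positive = 5′
  trimming, negative = 5′ extension. The offset is a length difference, not
  an alignment traceback — 5′ heterogeneity is end-position variability,
  and substitutions in the prefix affect only `edit5`.
* `edit5` / `edit3` are Levenshtein distances between the read and
  reference segments (computed with edlib; an independent dynamic-program
  oracle checks it in the tests). Defaults gates are 2 (5′) and 5 (3′),
  reflecting that 3′ modification is far more prevalent than 5′. The gates
  apply inclusive of length differences, since Levenshtein counts
  insertions and deletions.
* The 3′ anatomy comes from an exact templated walk from the motif end:
  matching continues while read and reference agree base-for-base; the
  unmatched reference remainder is `trim3`, the read remainder is the
  `tail`. The first mismatch ends the templated region — a single
  unambiguous operator separating scaffold miscleavage from
  post-transcriptional addition.
* A non-empty tail is **templated** iff the entry is anchored in a scaffold
  and the tail equals, base-exactly, the scaffold continuation immediately
  after the templated match. Entries without a scaffold anchor can never be
  templated-tailed; their classification is partial by construction.
* `seed` is the read's nucleotides 2–8 (1-based; 7 nt) — the window that
  determines miRNA-like target recognition. The minimum-length filter
  guarantees every assigned read has one.

Reads are collapsed to distinct sequences before decomposition, making the
result independent of input order. A sequence accepted by several entries
goes to the entry with minimal `edit5 + edit3`; exact ties are counted as
ambiguous and discarded rather than split arbitrarily. (How multi-entry
reads should be arbitrated is not standardized; minimal-total-edit is this
package's choice.) `min_reads`/`min_ratio` only collapse low-abundance
isoforms into an `(other)` row in the sequence-level report; metrics never
depend on display thresholds.

## Metrics

* **CPM**: reads per million reads assigned to any motif entry (shRNA arms
  plus whatever endogenous miRNAs the motif file covers). Unassigned reads
  are excluded from the denominator, so Σ CPM = 10⁶ whenever anything is
  assigned.
* **Fidelity_5P**: the count-weighted mean of |offset5| in nucleotides.
  The underlying notion — a weighted average of 5′ heterogeneity that is 0
  for perfectly precise processing and reaches 1–2 for sloppy scaffolds —
  admits isoform- or read-weighting; this package weights by read and keeps
  that convention across every report.
* **pct_trimmed / pct_tailed / pct_tailed_nontemplated**: read-weighted
  percentages of reads exhibiting the event; mean trim/tail lengths are
  companion columns.
* **Strand selection index** = CPM_guide / (CPM_guide + CPM_passenger);
  undefined (reported missing, with a warning) when both are zero.
  Efficient designs score ≥ 0.9; values below 0.5 indicate arm switching.
* **N effective seed** = 1 / Σ p²ᵢ over seed-sequence read proportions —
  the inverse Simpson effective number, bounded by 1 and the number of
  observed seeds, equal to the latter only under a uniform distribution.
  Efficient designs stay within [1, 1.1]. Reads shorter than 8 nt would
  lack a seed, but the 15-nt length filter makes the case unreachable.

## Simulator

The simulator is the package's ground-truth generator, not a fixture: it
draws reads from a hairpin `flank5 + arm5p + loop + arm3p + flank3` (guide
on the 3p arm). Per read: the arm is Bernoulli(p_guide); the canonical arm
boundaries shift by 5′/3′ offsets drawn from per-arm categorical
distributions (positive = trimming; negative = templated extension into
the scaffold, which is how templated isoforms arise); with probability
`tail_prob` a non-templated tail is appended, geometric in length
(support ≥ 1) with A/T-weighted bases, since adenylation/uridylation
dominate cellular tailing; substitution errors apply per base at
`seq_error`; optionally the RA3 adapter with a uniformly random UMI is
ligated. Quality strings are constant maximum quality — quality-aware
behaviour is out of scope. Identical `rng_seed` gives byte-identical
output.

Deliberate simplifications: no thermodynamic duplex or secondary-structure
model, no mechanistic DROSHA/DICER cleavage (the 2-nt overhang biology and
Pol III transcription-start heterogeneity are folded into the offset
distributions), UMIs are uniform (no PCR-duplicate structure unless reads
collide by chance), and errors are uniform substitutions without a quality
model. Passing tests therefore demonstrate correctness of the decomposition
and metrics under this generative model, not robustness to real-library
artifacts such as ligation bias or quality-correlated errors.

Five presets bundle a shared hairpin (its arms are the documented worked
guide/passenger matures, whose central 13-mers are exactly the worked
anchor motifs) with archetypal models: `precise` (p_guide 0.95, offsets 0,
2% tails, 0.1% error), `imprecise_5p` (guide 5′ offsets −1…+2, 50% mass off
zero), `passenger_heavy` (p_guide 0.6), `tailed` (35% tails), and
`arm_switched` (p_guide 0.3).

## Numerical and design choices

* `allowed_errors` adds 1e-9 before flooring to guard against binary-float
  artifacts (0.1·30 = 2.999…96); no realistic (length, rate) pair changes
  value.
* Categorical distributions must sum to 1 within 1e-9; sampling sorts
  category keys so output is reproducible across dict orderings.
* Assignment iterates distinct sequences in lexicographic order and sorts
  isoforms by (−count, sequence); dominant-read ranking breaks count ties
  by sequence. All reports are therefore byte-stable.
* Zero-read entries report CPM 0 and missing (NaN) fidelity/percentage
  fields; an entirely empty assignment emits a warning, never a crash.
* The pipeline config is flat `key = value` text; CLI flags override config
  keys. Exit codes: 0 success, 1 validation error, 2 runtime error.

## Problem sizes

The test suite and acceptance script use simulations of 1,000–10,000 reads
and randomized-oracle suites of 1,000 cases; at these sizes every metric's
binomial standard error is small (≤ 0.005 for the strand index at
n = 10,000) while the whole suite runs in seconds.

## Known limitations

* Motif search in reads is exact; a sequencing error inside the anchor
  motif makes the read unassignable (visible as the unassigned fraction in
  the worked example).
* Hamming-only adapter matching cannot recover adapters with indels.
* Fidelity_5P as defined here is one interpretation of "weighted-average 5′
  heterogeneity" (read-weighted mean |offset|); other tools may weight by
  isoform.
* No genome alignment or multi-mapping resolution beyond the
  minimal-total-edit rule; no differential expression or normalization
  beyond CPM.
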