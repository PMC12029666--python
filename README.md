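# shred — shRNA read decomposition

`shred` is a small-RNA-seq toolkit for quality control of short hairpin RNA
(shRNA) constructs used in gene and cell therapy. An shRNA hairpin is
processed by DROSHA/DICER1 into a guide–passenger duplex; only the guide
strand should load into Argonaute. Imprecise cleavage, passenger-strand
loading, and 3′ trimming/tailing all degrade potency and create off-target
(miRNA-like) activity. `shred` quantifies these failure modes from
sequencing reads:

* **Adapter trimming** with an error-rate model: a matched adapter window of
  L nucleotides tolerates ⌊L·r⌋ mismatches (default rate r = 0.1, i.e. one
  error per 10 matched bases), UMI extraction from the degenerate N15
  segment of the ligated 3′ adapter (`CTGTTAAC` + N15 +
  `TGGAATTCTCGGGTGCCAAGGC`), a 15-nt minimum insert length, and
  (insert, UMI) duplicate collapsing.
* **Motif-anchored isoform assignment**: each reference carries a unique
  13-mer anchor motif from the middle of its mature sequence; a read
  containing the motif is split there and its 5′/3′ segments are compared to
  the reference segments by Levenshtein distance (default gates: 2 on the 5′
  segment, 5 on the 3′). The decomposition yields the 5′ offset, 3′
  trimming, the tail, and whether the tail continues the hairpin scaffold
  (**templated**, a miscleavage product) or not (**non-templated**, e.g.
  A/U tailing).
* **Biogenesis metrics** per entry and per guide–passenger pair:
  * CPM — reads per million reads assigned to any reference entry;
  * Fidelity_5P — count-weighted mean |5′ offset| in nucleotides (0 =
    perfectly homogeneous 5′ ends);
  * strand selection index = CPM_guide / (CPM_guide + CPM_passenger),
    with ≥ 0.9 marking efficient designs;
  * N effective seed = 1 / Σᵢ p²ᵢ over the observed seed-sequence
    (read nucleotides 2–8) proportions pᵢ — the inverse Simpson effective
    number — with values in [1, 1.1] marking efficient designs.
* **A ground-truth hairpin simulator** with configurable cleavage-offset
  distributions, strand bias, A/U tailing, sequencing error, and adapter
  ligation, so the whole pipeline is testable against known truth.

## Worked example

Simulate an efficient construct (10,000 adapter-ligated reads) and run the
full pipeline:

```
shred simulate --preset precise --n 10000 --with-adapter --out sim
shred run --fastq sim.fastq --motifs sim.motifs.fa --scaffolds sim.scaffolds.fa --out pipe
```

The run log reports `10000 with adapter, 10000 pass length` and
`9866 assigned, 134 unassigned, 0 ambiguous` (the unassigned reads carry
simulated sequencing errors inside the anchor motif). `pipe.pairs.tsv`
contains the pair-level verdict:

```
construct  guide         passenger         strand_index  n_seed   efficient_strand  efficient_seed
shRNA1     shRNA1-guide  shRNA1-passenger  0.95013       1.00643  True              True
```

The strand selection index ≈ 0.95 matches the preset's guide-loading
probability of 0.95 and clears the 0.9 efficiency bound; N effective seed ≈
1.006 (≤ 1.1) says essentially every guide read carries the same seed, so
off-target seed shifting is negligible. The per-entry summary
(`pipe.summary.tsv`) shows `fidelity5p = 0.0` for both arms — the preset
cleaves precisely — and the sequence-level report (`pipe.sequence.tsv`)
lists each distinct read with its 5′ offset, trimming, tail, and
templated/non-templated classification, e.g. the canonical guide
(9121 reads) followed by rare single-base A/T tails.

Other presets (`imprecise_5p`, `passenger_heavy`, `tailed`, `arm_switched`)
emulate the characteristic failure archetypes. The same stages are
available as a library API (`shred.process_reads`, `shred.assign_reads`,
`shred.compute_pair_metrics`, `shred.simulate_library`, ...).

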