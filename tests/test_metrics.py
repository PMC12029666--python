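"""CPM, Fidelity_5P, trimming/tailing percentages, strand index, N seed."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shred import (
    ReadRecord,
    assign_reads,
    compute_entry_metrics,
    compute_pair_metrics,
    effective_seed_number,
    strand_selection_index,
)
from shred.assign import AssignmentResult, IsoformRecord
from shred.metrics import EntryMetrics
from shred.refio import PairSpec, ValidationError
from shred.simulate import motif_entries, scenario_presets, simulate_library
from tests.conftest import GUIDE_MATURE


def make_isoform(entry="e", seq="A" * 22, count=1, offset5=0, trim3=0,
                 tail="", tail_templated=False, seed=None):
    return IsoformRecord(
        entry=entry, seq=seq, count=count, offset5=offset5, edit5=abs(offset5),
        trim3=trim3, tail=tail, tail_templated=tail_templated,
        edit3=trim3 + len(tail), seed=seed if seed is not None else seq[1:8],
    )


def result_from(isoforms_by_entry):
    total = sum(r.count for recs in isoforms_by_entry.values() for r in recs)
    return AssignmentResult(isoforms=isoforms_by_entry, n_assigned=total)


class TestEntryMetrics:
    def test_homogeneous_library_hits_the_floor(self, entries):
        """All reads identical to the mature: Fidelity_5P is exactly 0, no
        trimming or tailing, one isoform, CPM = 1e6."""
        reads = [ReadRecord(id=f"r{i}", seq=GUIDE_MATURE) for i in range(500)]
        result = assign_reads(reads, entries)
        by_name = {m.entry: m for m in compute_entry_metrics(result)}
        m = by_name["shRNA-guide1"]
        assert m.fidelity5p == 0.0
        assert m.pct_trimmed == 0.0 and m.pct_tailed == 0.0
        assert m.n_isoforms == 1
        assert m.cpm == pytest.approx(1_000_000.0)

    def test_cpm_proportionality(self):
        result = result_from({
            "a": [make_isoform("a", count=750_000)],
            "b": [make_isoform("b", seq="C" * 22, count=250_000)],
        })
        by_name = {m.entry: m for m in compute_entry_metrics(result)}
        assert by_name["a"].cpm == pytest.approx(750_000.0)
        assert by_name["b"].cpm == pytest.approx(250_000.0)

    def test_fidelity_weighted_mean(self):
        result = result_from({
            "a": [make_isoform("a", count=50, offset5=0),
                  make_isoform("a", seq="G" * 21, count=50, offset5=1)],
        })
        (m,) = compute_entry_metrics(result)
        assert m.fidelity5p == pytest.approx(0.5)

    @given(
        st.lists(
            st.tuples(st.integers(1, 500), st.integers(-3, 3)),
            min_size=1, max_size=20,
        )
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_fidelity_matches_brute_force(self, spec_list):
        records = [
            make_isoform("a", seq=f"SEQ{i:04d}" + "A" * 15, count=count,
                         offset5=off, seed=f"SD{i:05d}")
            for i, (count, off) in enumerate(spec_list)
        ]
        result = result_from({"a": records})
        (m,) = compute_entry_metrics(result)
        brute = sum(r.count * abs(r.offset5) for r in records) / sum(
            r.count for r in records
        )
        assert m.fidelity5p == pytest.approx(brute)

    def test_zero_assigned_warns_not_crashes(self):
        result = AssignmentResult(isoforms={"a": []})
        with pytest.warns(UserWarning, match="no reads assigned"):
            metrics = compute_entry_metrics(result)
        assert metrics[0].reads == 0 and math.isnan(metrics[0].fidelity5p)

    def test_tail_percentages_ordering(self):
        result = result_from({
            "a": [
                make_isoform("a", count=60),
                make_isoform("a", seq="C" * 22, count=20, tail="GT",
                             tail_templated=True),
                make_isoform("a", seq="G" * 22, count=20, tail="AA"),
            ],
        })
        (m,) = compute_entry_metrics(result)
        assert m.pct_tailed == pytest.approx(40.0)
        assert m.pct_tailed_nontemplated == pytest.approx(20.0)
        assert m.pct_tailed_nontemplated <= m.pct_tailed


class TestStrandIndex:
    @pytest.mark.parametrize(
        "guide, passenger, expected",
        [(500, 500, 0.5), (1000, 0, 1.0), (950, 50, 0.95)],
    )
    def test_known_values(self, guide, passenger, expected):
        assert strand_selection_index(guide, passenger) == pytest.approx(expected)

    def test_both_zero_is_missing(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert math.isnan(strand_selection_index(0.0, 0.0))

    @given(st.floats(1e-6, 1e6), st.floats(1e-6, 1e6))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_complement_identity(self, a, b):
        assert strand_selection_index(a, b) + strand_selection_index(b, a) == (
            pytest.approx(1.0)
        )


class TestEffectiveSeedNumber:
    def test_single_seed_is_one(self):
        recs = [make_isoform(count=100, seed="AACGTTA")]
        assert effective_seed_number(recs) == pytest.approx(1.0)

    def test_two_equal_seeds_is_two(self):
        recs = [make_isoform(count=50, seed="AACGTTA"),
                make_isoform(count=50, seed="ACGTTAC")]
        assert effective_seed_number(recs) == pytest.approx(2.0)

    def test_ninety_eight_two_split(self):
        recs = [make_isoform(count=98, seed="AACGTTA"),
                make_isoform(count=2, seed="ACGTTAC")]
        assert effective_seed_number(recs) == pytest.approx(1 / 0.9608)

    def test_ninety_ten_split_inefficient(self):
        recs = [make_isoform(count=90, seed="AACGTTA"),
                make_isoform(count=10, seed="ACGTTAC")]
        assert effective_seed_number(recs) == pytest.approx(1 / 0.82)

    def test_empty_is_missing(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert math.isnan(effective_seed_number([]))

    @given(st.lists(st.integers(1, 1000), min_size=1, max_size=15))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_inverse_simpson_bounds_and_brute_force(self, counts):
        """1 <= N_eff <= k, with equality at k iff the distribution is
        uniform; value agrees with a direct evaluation of the formula."""
        seeds = [f"S{i:06d}" for i in range(len(counts))]
        recs = [make_isoform(count=c, seed=s) for c, s in zip(counts, seeds)]
        n_eff = effective_seed_number(recs)
        total = sum(counts)
        brute = 1.0 / sum((c / total) ** 2 for c in counts)
        assert n_eff == pytest.approx(brute)
        assert 1.0 - 1e-9 <= n_eff <= len(counts) + 1e-9
        if len(set(counts)) == 1:
            assert n_eff == pytest.approx(len(counts))


class TestPairMetrics:
    def _entry_metrics(self, cpm_guide, cpm_passenger):
        return [
            EntryMetrics(entry="g", reads=1, cpm=cpm_guide, fidelity5p=0,
                         pct_trimmed=0, pct_tailed=0, pct_tailed_nontemplated=0,
                         mean_trim_len=0, mean_tail_len=0, n_isoforms=1),
            EntryMetrics(entry="p", reads=1, cpm=cpm_passenger, fidelity5p=0,
                         pct_trimmed=0, pct_tailed=0, pct_tailed_nontemplated=0,
                         mean_trim_len=0, mean_tail_len=0, n_isoforms=1),
        ]

    def test_efficient_design_at_the_bounds(self):
        """Index exactly 0.9 with a single seed classifies as efficient on
        both axes."""
        metrics = self._entry_metrics(900_000, 100_000)
        isoforms = {"g": [make_isoform("g", count=10, seed="AACGTTA")], "p": []}
        (pm,) = compute_pair_metrics(
            metrics, isoforms, [PairSpec("sh1", "g", "p")]
        )
        assert pm.strand_index == pytest.approx(0.9)
        assert pm.efficient_strand is True
        assert pm.n_seed == pytest.approx(1.0)
        assert pm.efficient_seed is True

    def test_arm_switched_design_flagged(self):
        metrics = self._entry_metrics(100_000, 900_000)
        isoforms = {"g": [make_isoform("g", count=10)], "p": []}
        (pm,) = compute_pair_metrics(
            metrics, isoforms, [PairSpec("sh5", "g", "p")]
        )
        assert pm.strand_index == pytest.approx(0.1)
        assert pm.efficient_strand is False

    def test_seed_split_over_bound_flagged(self):
        metrics = self._entry_metrics(900_000, 100_000)
        isoforms = {
            "g": [make_isoform("g", count=90, seed="AACGTTA"),
                  make_isoform("g", count=10, seed="ACGTTAC")],
            "p": [],
        }
        (pm,) = compute_pair_metrics(
            metrics, isoforms, [PairSpec("sh1", "g", "p")]
        )
        assert pm.n_seed == pytest.approx(1.2195, abs=1e-3)
        assert pm.efficient_seed is False

    def test_unknown_entry_is_configuration_error(self):
        with pytest.raises(ValidationError, match="ghost"):
            compute_pair_metrics(self._entry_metrics(1, 1), {},
                                 [PairSpec("shX", "ghost", "p")])


class TestParameterRecovery:
    @pytest.mark.parametrize("q", [0.5, 0.7, 0.9, 0.95])
    def test_strand_index_recovers_guide_probability(self, q):
        """On noise-free simulated libraries the strand index estimates the
        guide-loading probability within 3 binomial standard errors."""
        spec, _ = scenario_presets()["precise"]
        from shred.simulate import ProcessingModel

        model = ProcessingModel(p_guide=q, rng_seed=int(q * 1000))
        n = 10_000
        reads, _ = simulate_library(spec, model, n)
        entries = motif_entries(spec)
        result = assign_reads(reads, entries)
        by_name = {m.entry: m for m in compute_entry_metrics(result)}
        index = strand_selection_index(
            by_name["shRNA1-guide"].cpm, by_name["shRNA1-passenger"].cpm
        )
        se = math.sqrt(q * (1 - q) / n)
        assert abs(index - q) <= 3 * se
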