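"""Switch/flip decomposition, benchmark comparison, quality groups."""

import itertools

import numpy as np
import pytest

import beadphase as bp
from beadphase.evaluation import EvalReport, VariantPhase


def brute_force_switch_flip(truth, called):
    """Minimum switches+flips by enumerating every switch subset and
    both global orientations; independent of the DP implementation."""
    n = len(truth)
    d = [t ^ c for t, c in zip(truth, called)]
    best = None
    for g in (0, 1):
        for switches in itertools.product((0, 1), repeat=max(n - 1, 0)):
            parity = g
            cost = 0
            for i in range(n):
                if i > 0 and switches[i - 1]:
                    parity ^= 1
                    cost += 1
                if d[i] != parity:
                    cost += 1  # flip
            best = cost if best is None else min(best, cost)
    return best if best is not None else 0


class TestSwitchFlipDecompose:
    def test_identical_vectors(self):
        assert bp.switch_flip_decompose([0, 1, 0, 1], [0, 1, 0, 1]) == (0, 0)

    def test_global_swap_is_free(self):
        assert bp.switch_flip_decompose([0, 1, 0], [1, 0, 1]) == (0, 0)

    def test_single_interior_flip(self):
        truth = [0, 0, 0, 0, 0]
        called = [0, 0, 1, 0, 0]
        assert bp.switch_flip_decompose(truth, called) == (0, 1)

    def test_suffix_inversion_is_one_switch(self):
        truth = [0] * 6
        called = [0, 0, 1, 1, 1, 1]
        assert bp.switch_flip_decompose(truth, called) == (1, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(bp.ParameterError):
            bp.switch_flip_decompose([0, 1], [0])
        with pytest.raises(bp.ParameterError):
            bp.switch_flip_decompose([0, 2], [0, 1])

    @pytest.mark.parametrize("n", range(1, 9))
    def test_matches_enumeration_on_all_instances(self, n):
        """Total operations equal the exhaustive minimum for every
        disagreement pattern of up to 8 sites."""
        truth = [0] * n
        for bits in itertools.product((0, 1), repeat=n):
            sw, fl = bp.switch_flip_decompose(truth, list(bits))
            assert sw + fl == brute_force_switch_flip(truth, list(bits))


def phase_set(entries):
    """{pos: (hap1, hap2, phased, ps)} -> PhaseSet on contig 'c'."""
    return {("c", pos): VariantPhase("c", pos, (h1, h2), phased, ps)
            for pos, (h1, h2, phased, ps) in entries.items()}


class TestComparePhasing:
    def _benchmark(self, n=5):
        return phase_set({i * 100: ("A", "C", True, 1) for i in range(n)})

    def test_perfect_agreement(self):
        bench = self._benchmark()
        rep = bp.compare_phasing(bench, dict(bench))
        assert (rep.annotated, rep.recalled, rep.phased) == (5, 5, 5)
        assert rep.correctly_phased == 5
        assert rep.flip_errors == rep.switch_errors == 0
        assert rep.single_block
        assert rep.accuracy_of_annotated == pytest.approx(100.0)

    def test_globally_swapped_inference_is_perfect(self):
        bench = self._benchmark()
        swapped = phase_set({i * 100: ("C", "A", True, 1) for i in range(5)})
        rep = bp.compare_phasing(bench, swapped)
        assert rep.correctly_phased == 5 and rep.flip_errors == 0

    def test_one_flip_counts_one_incorrect_site(self):
        bench = self._benchmark()
        inferred = dict(bench)
        inferred[("c", 200)] = VariantPhase("c", 200, ("C", "A"), True, 1)
        rep = bp.compare_phasing(bench, inferred)
        assert rep.flip_errors == 1 and rep.switch_errors == 0
        assert rep.correctly_phased == 4

    def test_switch_marks_downstream_incorrect(self):
        bench = self._benchmark()
        inferred = dict(bench)
        for pos in (300, 400):
            inferred[("c", pos)] = VariantPhase("c", pos, ("C", "A"), True, 1)
        rep = bp.compare_phasing(bench, inferred)
        assert rep.switch_errors == 1 and rep.flip_errors == 0
        assert rep.correctly_phased == 3

    def test_unphased_sites_not_correct(self):
        bench = self._benchmark()
        inferred = dict(bench)
        inferred[("c", 0)] = VariantPhase("c", 0, ("A", "C"), False, None)
        inferred[("c", 100)] = VariantPhase("c", 100, ("A", "C"), False, None)
        rep = bp.compare_phasing(bench, inferred)
        assert rep.phased == 3 and rep.unphased == 2
        assert rep.correctly_phased == 3
        # the seven-of-nine regime: accuracy over recalled
        assert rep.accuracy_of_recalled == pytest.approx(60.0)

    def test_missed_sites_counted(self):
        bench = self._benchmark()
        inferred = {sp: v for sp, v in bench.items() if sp != ("c", 400)}
        rep = bp.compare_phasing(bench, inferred)
        assert rep.missed == 1 and rep.recalled == 4

    def test_disjoint_site_sets_reported_not_raised(self):
        bench = self._benchmark()
        inferred = phase_set({999: ("A", "C", True, 1)})
        rep = bp.compare_phasing(bench, inferred)
        assert rep.recalled == 0 and rep.notes

    def test_two_blocks_counted(self):
        bench = self._benchmark(6)
        inferred = dict(bench)
        for pos in (300, 400, 500):
            inferred[("c", pos)] = VariantPhase("c", pos, ("A", "C"), True, 2)
        rep = bp.compare_phasing(bench, inferred)
        assert rep.n_blocks == 2
        assert rep.correctly_phased == 6  # relative phase fine in each block

    def test_de_novo_confirmed_by_replicates(self):
        bench = self._benchmark()
        extra = VariantPhase("c", 450, ("G", "T"), True, 1)
        inferred = dict(bench)
        inferred[("c", 450)] = extra
        rep_same = dict(inferred)
        rep_disagree = dict(inferred)
        rep_disagree[("c", 450)] = VariantPhase("c", 450, ("T", "G"), True, 1)
        rep = bp.compare_phasing(bench, inferred, replicate_set=[rep_same])
        assert rep.de_novo_phased == 1 and rep.de_novo_confirmed == 1
        rep2 = bp.compare_phasing(bench, inferred,
                                  replicate_set=[rep_disagree])
        assert rep2.de_novo_confirmed == 0
        rep3 = bp.compare_phasing(bench, inferred)
        assert rep3.de_novo_confirmed is None  # unconfirmed without replicates

    def test_invariant_to_global_swap_of_benchmark(self):
        bench = self._benchmark()
        swapped_bench = phase_set({i * 100: ("C", "A", True, 1)
                                   for i in range(5)})
        inferred = dict(bench)
        inferred[("c", 200)] = VariantPhase("c", 200, ("C", "A"), True, 1)
        a = bp.compare_phasing(bench, inferred)
        b = bp.compare_phasing(swapped_bench, inferred)
        assert (a.correctly_phased, a.flip_errors, a.switch_errors) == \
            (b.correctly_phased, b.flip_errors, b.switch_errors)


class TestEvalReportInvariants:
    def test_count_identities_enforced(self):
        with pytest.raises(bp.ParameterError):
            EvalReport(annotated=5, recalled=6)
        with pytest.raises(bp.ParameterError):
            EvalReport(annotated=5, recalled=4, phased=5)

    def test_aggregate_sums_counts(self):
        a = EvalReport(annotated=10, recalled=10, phased=9,
                       correctly_phased=9, n_blocks=1)
        b = EvalReport(annotated=6, recalled=5, phased=5, correctly_phased=4,
                       flip_errors=1, n_blocks=1)
        agg = EvalReport.aggregate([a, b])
        assert agg.annotated == 16 and agg.correctly_phased == 13
        assert agg.accuracy_of_annotated == pytest.approx(100 * 13 / 16)


class TestQualityGroups:
    def _report(self, **kw):
        base = dict(annotated=10, recalled=10, phased=10, correctly_phased=10,
                    n_blocks=1)
        base.update(kw)
        return EvalReport(**base)

    def test_error_free_single_block_is_group1(self):
        assert bp.classify_quality_group(self._report()).group == 1

    def test_single_flip_is_group2(self):
        rep = self._report(correctly_phased=9, flip_errors=1)
        assert bp.classify_quality_group(rep).group == 2

    def test_missed_genotyping_is_group3(self):
        rep = self._report(recalled=9, phased=9, correctly_phased=9)
        assert bp.classify_quality_group(rep).group == 3

    def test_discontinuous_blocks_is_group3(self):
        rep = self._report(n_blocks=2)
        assert bp.classify_quality_group(rep).group == 3

    def test_two_errors_is_group3(self):
        rep = self._report(correctly_phased=8, flip_errors=2)
        assert bp.classify_quality_group(rep).group == 3

    def test_mostly_unphased_is_group4(self):
        rep = self._report(phased=4, correctly_phased=4)
        assert bp.classify_quality_group(rep).group == 4

    def test_nothing_recalled_is_group4(self):
        rep = EvalReport(annotated=5, recalled=0, phased=0)
        assert bp.classify_quality_group(rep).group == 4


class TestSubsampleReads:
    def _reads(self, n):
        from beadphase.simulate import ReadPair, ReadTruth
        truth = ReadTruth(0, 0, 0, "", False)
        return [ReadPair(f"r{i}", "A", "A", "B" * 18, truth)
                for i in range(n)]

    def test_identity_at_fraction_one(self):
        reads = self._reads(10)
        assert bp.subsample_reads(reads, 1.0) == reads

    def test_binomial_retention(self):
        reads = self._reads(10_000)
        kept = bp.subsample_reads(reads, 0.5, seed=1)
        assert abs(len(kept) - 5000) <= 3 * np.sqrt(10_000 * 0.25)

    def test_fraction_domain(self):
        with pytest.raises(bp.ParameterError):
            bp.subsample_reads(self._reads(5), 0.0)
        with pytest.raises(bp.ParameterError):
            bp.subsample_reads(self._reads(5), 1.5)

    def test_ladder_halves_expected_depth(self):
        ladder = (0.5, 0.25, 0.125, 0.0625, 0.03125, 0.0156, 0.0078)
        ratios = [b / a for a, b in zip(ladder, ladder[1:])]
        assert all(abs(r - 0.5) < 0.01 for r in ratios)


class TestCoverageTitration:
    def test_ladder_must_descend(self):
        with pytest.raises(bp.ParameterError):
            bp.coverage_titration([], [0.1, 0.5], lambda r: (None, 0.0), [0])

    def test_failure_recorded_as_group4(self):
        def analyze(reads):
            raise RuntimeError("stage failure")
        table = bp.coverage_titration(
            TestSubsampleReads()._reads(10), [1.0, 0.5], analyze, [0])
        assert (table.quality_group == 4).all()
        assert table.note.str.contains("failure").all()
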