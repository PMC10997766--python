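"""Fragment matrix construction and MEC phasing."""

import itertools

import numpy as np
import pytest

import beadphase as bp
from beadphase.align import AlignedRead, GenotypeCall
from beadphase.phasing import FragmentMatrix, PhasingParams


def matrix_from_rows(rows, positions=None, ref="chr"):
    """FragmentMatrix from {barcode: {site_index: allele}} dicts."""
    n = 1 + max(i for row in rows.values() for i in row)
    if positions is None:
        positions = [i * 1000 for i in range(n)]
    sites = [(ref, p) for p in positions]
    alleles = [("A", "C")] * n
    return FragmentMatrix(sites=sites, alleles=alleles, rows=dict(rows))


def brute_force_mec(matrix):
    """Exhaustive minimum MEC over all assignments of all sites."""
    n = matrix.n_sites
    best = None
    for bits in itertools.product((0, 1), repeat=max(n - 1, 0)):
        x = {0: 0, **{i + 1: b for i, b in enumerate(bits)}}
        best = min(best, bp.mec_score(matrix, x)) if best is not None \
            else bp.mec_score(matrix, x)
    return best if best is not None else 0


class TestMecScore:
    def test_consistent_matrix_scores_zero(self):
        m = matrix_from_rows({"b1": {0: 0, 1: 0}, "b2": {0: 1, 1: 1}})
        assert bp.mec_score(m, {0: 0, 1: 0}) == 0

    def test_fully_opposite_row_attributed_to_other_haplotype(self):
        m = matrix_from_rows({"b1": {0: 1, 1: 1}})
        assert bp.mec_score(m, {0: 0, 1: 0}) == 0

    def test_mixed_row_costs_one(self):
        m = matrix_from_rows({"b1": {0: 0, 1: 1}})
        assert bp.mec_score(m, {0: 0, 1: 0}) == 1

    def test_restricted_to_phased_sites(self):
        m = matrix_from_rows({"b1": {0: 0, 1: 1, 2: 0}})
        assert bp.mec_score(m, {0: 0, 2: 0}) == 0


class TestBuildFragmentMatrix:
    def _call(self, pos, ref="chr"):
        return GenotypeCall(ref, pos, "A", "het", ("A", "C"), (5, 5), 10)

    def _read(self, read_id, barcode, start, seq, is_dup=False):
        return AlignedRead(read_id=read_id, mate=1, ref_id="chr", start=start,
                           cigar=f"{len(seq)}M", strand="+", barcode=barcode,
                           mapped=True, is_dup=is_dup, seq=seq)

    def test_direct_construction(self):
        calls = [self._call(2), self._call(6)]
        reads = [self._read("r1", "BX1", 0, "AAAAAAAA")]
        m = bp.build_fragment_matrix(reads, calls)
        assert m.rows == {"BX1": {0: 0, 1: 0}}

    def test_majority_vote_per_site(self):
        calls = [self._call(1)]
        reads = [self._read("r1", "BX1", 0, "AAA"),
                 self._read("r2", "BX1", 0, "AAA"),
                 self._read("r3", "BX1", 0, "ACA")]
        m = bp.build_fragment_matrix(reads, calls)
        assert m.rows["BX1"] == {0: 0}

    def test_tie_drops_site(self):
        calls = [self._call(1)]
        reads = [self._read("r1", "BX1", 0, "AAA"),
                 self._read("r2", "BX1", 0, "ACA")]
        m = bp.build_fragment_matrix(reads, calls)
        assert "BX1" not in m.rows

    def test_non_allele_bases_ignored(self):
        calls = [self._call(1)]
        reads = [self._read("r1", "BX1", 0, "AGA")]  # G is neither allele
        m = bp.build_fragment_matrix(reads, calls)
        assert "BX1" not in m.rows

    def test_duplicates_excluded_and_single_site_rows_kept(self):
        calls = [self._call(1)]
        reads = [self._read("r1", "BX1", 0, "ACA"),
                 self._read("r2", "BX1", 0, "ACA", is_dup=True)]
        m = bp.build_fragment_matrix(reads, calls)
        assert m.rows == {"BX1": {0: 1}}

    def test_no_het_sites_gives_empty_matrix(self):
        m = bp.build_fragment_matrix([], [])
        assert m.n_sites == 0 and m.n_rows == 0


def consistent_rows(truth, n_rows, sites_per_row=2, start=0):
    """Rows drawn from one of the two haplotypes of ``truth``."""
    rows = {}
    n = len(truth)
    for k in range(n_rows):
        i = (start + k) % max(n - sites_per_row + 1, 1)
        hap = k % 2
        rows[f"b{start}_{k}"] = {
            j: truth[j] ^ hap for j in range(i, min(i + sites_per_row, n))}
    return rows


class TestPhaseBlocks:
    def test_noiseless_three_sites_single_block_zero_mec(self):
        truth = [0, 1, 0]
        rows = {}
        for k in range(10):
            hap = k % 2
            rows[f"a{k}"] = {0: truth[0] ^ hap, 1: truth[1] ^ hap}
            rows[f"b{k}"] = {1: truth[1] ^ hap, 2: truth[2] ^ hap}
        m = matrix_from_rows(rows)
        res = bp.phase_blocks(m)
        assert len(res.blocks) == 1 and sorted(res.blocks[0]) == [0, 1, 2]
        rel = [res.assignment[i] ^ res.assignment[0] for i in range(3)]
        assert rel == [t ^ truth[0] for t in truth]
        assert bp.mec_score(m, res.assignment) == 0

    def test_one_contradictory_row_gives_same_phasing_mec_one(self):
        truth = [0, 1, 0]
        rows = {}
        for k in range(10):
            hap = k % 2
            rows[f"a{k}"] = {0: truth[0] ^ hap, 1: truth[1] ^ hap}
            rows[f"b{k}"] = {1: truth[1] ^ hap, 2: truth[2] ^ hap}
        rows["bad"] = {0: truth[0], 1: truth[1] ^ 1}
        m = matrix_from_rows(rows)
        res = bp.phase_blocks(m)
        rel = [res.assignment[i] ^ res.assignment[0] for i in range(3)]
        assert rel == [t ^ truth[0] for t in truth]
        assert bp.mec_score(m, res.assignment) == 1
        assert brute_force_mec(m) == 1

    def test_distant_clusters_form_two_blocks(self):
        positions = [0, 1000, 60_000, 61_000]  # gap > 40 kb link distance
        rows = {}
        rows.update(consistent_rows([0, 0], 6, start=0))
        far = {f"c{k}": {2: k % 2, 3: k % 2} for k in range(6)}
        rows.update(far)
        m = matrix_from_rows(rows, positions=positions)
        res = bp.phase_blocks(m)
        assert len(res.blocks) == 2
        assert sorted(map(sorted, res.blocks)) == [[0, 1], [2, 3]]

    def test_only_single_site_rows_gives_no_phasing(self):
        m = matrix_from_rows({"b1": {0: 0}, "b2": {1: 1}, "b3": {2: 0}})
        res = bp.phase_blocks(m)
        assert res.assignment == {} and res.blocks == []

    def test_single_supporting_barcode_cannot_phase_a_pair(self):
        m = matrix_from_rows({"b1": {0: 0, 1: 0}})
        res = bp.phase_blocks(m)
        assert res.assignment == {}
        # two consistent rows suffice
        m2 = matrix_from_rows({"b1": {0: 0, 1: 0}, "b2": {0: 1, 1: 1}})
        res2 = bp.phase_blocks(m2)
        assert set(res2.assignment) == {0, 1}

    def test_canonical_orientation_first_site_allele0(self):
        rows = consistent_rows([1, 0, 1], 12, sites_per_row=3)
        m = matrix_from_rows(rows)
        res = bp.phase_blocks(m)
        assert res.assignment[0] == 0

    def test_empty_matrix(self):
        res = bp.phase_blocks(FragmentMatrix([], [], {}))
        assert res.blocks == [] and res.assignment == {}

    def test_matches_exhaustive_mec_on_random_small_matrices(self, rng):
        """The optimizer's assignment reaches the exhaustive MEC optimum
        for every returned block of <= 10 sites."""
        for trial in range(30):
            n = int(rng.integers(3, 9))
            truth = [int(b) for b in rng.integers(0, 2, n)]
            rows = {}
            for k in range(22):
                i = int(rng.integers(0, n - 1))
                width = int(rng.integers(2, min(4, n - i) + 1))
                hap = int(rng.integers(0, 2))
                row = {}
                for j in range(i, i + width):
                    allele = truth[j] ^ hap
                    if rng.random() < 0.08:  # observation error
                        allele ^= 1
                    row[j] = allele
                rows[f"b{k}"] = row
            m = matrix_from_rows(rows)
            res = bp.phase_blocks(m)
            for block in res.blocks:
                sub_rows = {
                    bc: {i: a for i, a in row.items() if i in set(block)}
                    for bc, row in m.rows.items()}
                sub_rows = {bc: r for bc, r in sub_rows.items() if r}
                sub = FragmentMatrix(sites=m.sites, alleles=m.alleles,
                                     rows=sub_rows)
                block_assignment = {i: res.assignment[i] for i in block}
                achieved = bp.mec_score(sub, block_assignment)
                # exhaustive optimum over the block's sites
                best = None
                rest = block[1:]
                for bits in itertools.product((0, 1), repeat=len(rest)):
                    cand = {block[0]: 0,
                            **{s: b for s, b in zip(rest, bits)}}
                    score = bp.mec_score(sub, cand)
                    best = score if best is None else min(best, score)
                assert achieved == best

    def test_invariant_under_global_haplotype_relabeling(self):
        rows = consistent_rows([0, 1, 1, 0], 16, sites_per_row=2)
        m = matrix_from_rows(rows)
        flipped = matrix_from_rows(
            {bc: {i: a ^ 1 for i, a in row.items()} for bc, row in rows.items()})
        res_a = bp.phase_blocks(m)
        res_b = bp.phase_blocks(flipped)
        assert res_a.blocks == res_b.blocks
        rel_a = {i: res_a.assignment[i] ^ res_a.assignment[0]
                 for i in res_a.assignment}
        rel_b = {i: res_b.assignment[i] ^ res_b.assignment[0]
                 for i in res_b.assignment}
        assert rel_a == rel_b


class TestEmitPhasedVariants:
    def _setup(self):
        calls = [GenotypeCall("chr", p, "A", "het", ("A", "C"), (5, 5), 10)
                 for p in (100, 200, 300)]
        rows = consistent_rows([0, 1, 0], 12, sites_per_row=3)
        m = matrix_from_rows(rows, positions=[100, 200, 300])
        res = bp.phase_blocks(m)
        return calls, res

    def test_single_block_shares_ps(self):
        calls, res = self._setup()
        records = bp.emit_phased_variants(calls, res)
        ps = {r.ps for r in records if r.phased}
        assert len(ps) == 1 and ps == {101}  # 1-based leftmost position

    def test_phased_genotypes_encode_relative_phase(self):
        calls, res = self._setup()
        records = {r.pos: r for r in bp.emit_phased_variants(calls, res)}
        assert records[100].gt != records[200].gt  # truth 0,1 -> opposite
        assert records[100].gt == records[300].gt

    def test_unphased_het_written_unphased(self):
        calls = [GenotypeCall("chr", 10, "A", "het", ("A", "C"), (5, 5), 10)]
        res = bp.PhaseResult(sites=[("chr", 10)], alleles=[("A", "C")],
                             assignment={}, blocks=[])
        records = bp.emit_phased_variants(calls, res)
        assert not records[0].phased and records[0].ps is None

    def test_phased_site_without_call_raises(self):
        res = bp.PhaseResult(sites=[("chr", 10), ("chr", 20)],
                             alleles=[("A", "C")] * 2,
                             assignment={0: 0, 1: 1}, blocks=[[0, 1]])
        calls = [GenotypeCall("chr", 10, "A", "het", ("A", "C"), (5, 5), 10)]
        with pytest.raises(bp.ConsistencyError):
            bp.emit_phased_variants(calls, res)


class TestPhasingParams:
    def test_distance_must_be_positive(self):
        with pytest.raises(bp.ParameterError):
            PhasingParams(max_link_distance=0)

    def test_default_prune_requires_two_rows(self):
        p = PhasingParams()
        assert p.log_odds_per_row < p.prune_threshold <= 2 * p.log_odds_per_row
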