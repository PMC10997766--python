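"""Barcode-linked haplotype phasing by minimum error correction (MEC).

Reads sharing a bead barcode derive (collisions aside) from one long
molecule, hence from one parental haplotype.  Collapsing each barcode's
allele observations at heterozygous sites gives a *fragment matrix*;
phasing chooses the bipartition of site alleles that minimises the
number of observations that must be flipped for every barcode row to
fit one haplotype (the MEC objective).

The optimizer builds a site graph whose edge weights are log-odds that
two sites are co-phased under a symmetric per-observation error rate,
keeps edges above a pruning threshold (so that a single supporting
barcode can never phase a pair), seeds each connected component with a
greedy maximum spanning tree, and then refines: exhaustively for blocks
of <= 10 sites (guaranteeing MEC optimality) and by iterated
single-site flips otherwise.  Sites whose flip leaves the MEC unchanged
are reported unphased.  Output is invariant under global relabeling of
the two haplotypes; blocks are canonically oriented by assigning the
first site's first allele to haplotype 1.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .align import AlignedRead, GenotypeCall, cigar_to_ref_coords
from .errors import ConsistencyError, ParameterError

DEFAULT_LINK_DISTANCE = 40_000
DEFAULT_PRUNE_THRESHOLD = 6.0
DEFAULT_ERROR_RATE = 0.02


@dataclass(frozen=True)
class PhasingParams:
    """Tunables of the phasing stage.

    ``max_link_distance`` (bp) bounds the span over which two sites may
    be linked directly (default 40 kb, matching typical molecule
    lengths).  ``prune_threshold`` is the log-odds needed to emit a
    link; with the default symmetric ``error_rate`` of 0.02 one
    consistent barcode contributes ~3.2, so the default of 6.0 requires
    at least two independent consistent rows per link.
    """

    max_link_distance: int = DEFAULT_LINK_DISTANCE
    prune_threshold: float = DEFAULT_PRUNE_THRESHOLD
    min_reads_per_site_per_barcode: int = 1
    error_rate: float = DEFAULT_ERROR_RATE

    def __post_init__(self) -> None:
        if self.max_link_distance <= 0:
            raise ParameterError("max_link_distance must be > 0")
        if not 0.0 < self.error_rate < 0.5:
            raise ParameterError("error_rate must be in (0, 0.5)")

    @property
    def log_odds_per_row(self) -> float:
        e = self.error_rate
        return math.log(((1 - e) ** 2 + e ** 2) / (2 * e * (1 - e)))


@dataclass
class FragmentMatrix:
    """Per-barcode allele observations at heterozygous sites.

    ``sites`` lists (reference id, 0-based position) in sorted order;
    ``alleles[i]`` is the genotype call's (first, second) allele at site
    i, and row values are 0/1 indices into that pair.
    """

    sites: list[tuple[str, int]]
    alleles: list[tuple[str, str]]
    rows: dict[str, dict[int, int]] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_rows(self) -> int:
        return len(self.rows)


@dataclass
class PhaseResult:
    """Haplotype assignment per het site plus phase-block structure.

    ``assignment[i]`` is the allele index carried by haplotype 1 at site
    i (only phased sites appear); ``blocks`` are disjoint sorted site
    index lists, each identified by its leftmost phased position.
    """

    sites: list[tuple[str, int]]
    alleles: list[tuple[str, str]]
    assignment: dict[int, int]
    blocks: list[list[int]]

    @property
    def phased_sites(self) -> list[int]:
        return sorted(self.assignment)

    @property
    def unphased_sites(self) -> list[int]:
        return [i for i in range(len(self.sites)) if i not in self.assignment]

    def block_id(self, block_index: int) -> tuple[str, int]:
        """(reference, leftmost phased position) naming a block."""
        sites = self.blocks[block_index]
        return self.sites[min(sites)]

    def block_of(self) -> dict[int, int]:
        return {s: bi for bi, block in enumerate(self.blocks) for s in block}


def build_fragment_matrix(
    aligned_reads: list[AlignedRead],
    genotype_calls: list[GenotypeCall],
    params: PhasingParams = PhasingParams(),
) -> FragmentMatrix:
    """Collapse per-barcode read bases at het sites into allele rows.

    Each barcode's allele at a covered site is the majority over its
    read bases there (bases matching neither call allele are ignored;
    exact ties drop the site for that barcode).  Reads must be
    deduplicated and barcode-corrected upstream.
    """
    het = [c for c in genotype_calls if c.is_het]
    sites = sorted((c.ref_id, c.pos) for c in het)
    site_index = {sp: i for i, sp in enumerate(sites)}
    alleles_by_site = {(c.ref_id, c.pos): (c.alleles[0], c.alleles[1]) for c in het}
    alleles = [alleles_by_site[sp] for sp in sites]
    if not sites:
        return FragmentMatrix(sites=[], alleles=[], rows={})

    votes: dict[str, dict[int, Counter]] = defaultdict(lambda: defaultdict(Counter))
    site_pos_by_ref: dict[str, dict[int, int]] = defaultdict(dict)
    for (ref, pos), i in site_index.items():
        site_pos_by_ref[ref][pos] = i
    for read in aligned_reads:
        if not read.mapped or read.is_dup:
            continue
        lookup = site_pos_by_ref.get(read.ref_id)
        if not lookup:
            continue
        for q, r in cigar_to_ref_coords(read):
            i = lookup.get(r)
            if i is None:
                continue
            base = read.seq[q]
            a0, a1 = alleles[i]
            if base == a0:
                votes[read.barcode][i][0] += 1
            elif base == a1:
                votes[read.barcode][i][1] += 1

    rows: dict[str, dict[int, int]] = {}
    min_reads = params.min_reads_per_site_per_barcode
    for barcode, per_site in votes.items():
        row: dict[int, int] = {}
        for i, counter in per_site.items():
            if sum(counter.values()) < min_reads:
                continue
            if counter[0] > counter[1]:
                row[i] = 0
            elif counter[1] > counter[0]:
                row[i] = 1
            # exact tie: conflicting evidence, drop the site
        if row:
            rows[barcode] = row
    return FragmentMatrix(sites=sites, alleles=alleles, rows=rows)


def mec_score(matrix: FragmentMatrix, haplotype_assignment: dict[int, int]) -> int:
    """Minimum-error-correction objective of an assignment.

    Sum over barcode rows of min(mismatches vs haplotype 1, mismatches
    vs haplotype 2), restricted to the phased sites of the assignment.
    """
    total = 0
    for row in matrix.rows.values():
        mism = covered = 0
        for i, a in row.items():
            h = haplotype_assignment.get(i)
            if h is None:
                continue
            covered += 1
            if a != h:
                mism += 1
        if covered:
            total += min(mism, covered - mism)
    return total


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _block_mec(rows: list[dict[int, int]], x: dict[int, int]) -> int:
    total = 0
    for row in rows:
        mism = covered = 0
        for i, a in row.items():
            if i in x:
                covered += 1
                if a != x[i]:
                    mism += 1
        if covered:
            total += min(mism, covered - mism)
    return total


def phase_blocks(matrix: FragmentMatrix,
                 params: PhasingParams = PhasingParams(),
                 seed: int = 0) -> PhaseResult:
    """Phase a fragment matrix into haplotype blocks (see module docs).

    ``seed`` is accepted for interface stability; every step is
    deterministic (tie-breaks by weight then site position)."""
    n = matrix.n_sites
    if n == 0:
        return PhaseResult(sites=[], alleles=[], assignment={}, blocks=[])

    # Pairwise agreement counts between co-observed sites within range.
    pair_stats: dict[tuple[int, int], list[int]] = defaultdict(lambda: [0, 0])
    for row in matrix.rows.values():
        covered = sorted(row)
        for ai in range(len(covered)):
            i = covered[ai]
            ref_i, pos_i = matrix.sites[i]
            for bi in range(ai + 1, len(covered)):
                j = covered[bi]
                ref_j, pos_j = matrix.sites[j]
                if ref_i != ref_j or pos_j - pos_i > params.max_link_distance:
                    continue
                rel = row[i] ^ row[j]
                pair_stats[(i, j)][rel] += 1

    c = params.log_odds_per_row
    edges = []  # (magnitude, i, j, relation)
    for (i, j), (n_same, n_diff) in pair_stats.items():
        w = (n_same - n_diff) * c
        if abs(w) >= params.prune_threshold:
            edges.append((abs(w), i, j, 0 if w > 0 else 1))

    uf = _UnionFind(range(n))
    for _, i, j, _rel in edges:
        uf.union(i, j)
    components: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        components[uf.find(i)].append(i)

    assignment: dict[int, int] = {}
    blocks: list[list[int]] = []
    for comp in sorted(components.values(), key=min):
        comp = sorted(comp)
        if len(comp) < 2:
            continue
        comp_set = set(comp)
        comp_edges = sorted((e for e in edges if e[1] in comp_set),
                            key=lambda e: (-e[0], e[1], e[2]))
        rows = []
        for row in matrix.rows.values():
            sub = {i: a for i, a in row.items() if i in comp_set}
            if sub:
                rows.append(sub)
        x = _initial_assignment(comp, comp_edges)
        x = _refine(comp, rows, x)
        # Ambiguity: a site whose flip leaves the MEC unchanged carries
        # no net phasing evidence at the optimum -- report it unphased.
        base = _block_mec(rows, x)
        kept = []
        for s in comp:
            flipped = dict(x)
            flipped[s] ^= 1
            if _block_mec(rows, flipped) - base >= 1:
                kept.append(s)
        if len(kept) < 2:
            continue
        block_x = {s: x[s] for s in kept}
        # Canonical orientation: first site's first allele on haplotype 1.
        if block_x[min(kept)] == 1:
            block_x = {s: v ^ 1 for s, v in block_x.items()}
        assignment.update(block_x)
        blocks.append(sorted(kept))

    return PhaseResult(sites=matrix.sites, alleles=matrix.alleles,
                       assignment=assignment, blocks=blocks)


def _initial_assignment(comp: list[int], comp_edges: list) -> dict[int, int]:
    """Greedy max-spanning-tree relative phases over a component."""
    uf = _UnionFind(comp)
    adj: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for _mag, i, j, rel in comp_edges:
        if uf.union(i, j):
            adj[i].append((j, rel))
            adj[j].append((i, rel))
    x = {comp[0]: 0}
    stack = [comp[0]]
    while stack:
        i = stack.pop()
        for j, rel in adj[i]:
            if j not in x:
                x[j] = x[i] ^ rel
                stack.append(j)
    for s in comp:  # sites isolated inside the component (shouldn't occur)
        x.setdefault(s, 0)
    return x


def _refine(comp: list[int], rows: list[dict[int, int]],
            x: dict[int, int]) -> dict[int, int]:
    if len(comp) <= 10:
        # Exhaustive over 2^(n-1) assignments (site 0 fixed): MEC-optimal.
        best, best_x = None, None
        rest = comp[1:]
        for mask in range(1 << len(rest)):
            cand = {comp[0]: 0}
            for b, s in enumerate(rest):
                cand[s] = (mask >> b) & 1
            score = _block_mec(rows, cand)
            if best is None or score < best:
                best, best_x = score, cand
        return best_x
    # Iterated single-site flips while the MEC decreases.
    rows_of: dict[int, list[int]] = defaultdict(list)
    for ri, row in enumerate(rows):
        for i in row:
            rows_of[i].append(ri)
    current = _block_mec(rows, x)
    for _ in range(100):
        improved = False
        for s in comp:
            x[s] ^= 1
            trial = _block_mec(rows, x)
            if trial < current:
                current = trial
                improved = True
            else:
                x[s] ^= 1
        if not improved:
            break
    return x


def emit_phased_variants(calls: list[GenotypeCall],
                         phase_result: PhaseResult) -> list:
    """Phased VCF records (GT with "|" and a PS phase-set tag).

    Phased het sites carry ordered alleles (haplotype 1 first) and a PS
    equal to their block's leftmost phased position (1-based); unphased
    het sites are written with an unphased genotype.
    """
    from .io import PhasedRecord

    call_at = {(c.ref_id, c.pos): c for c in calls if c.is_het}
    site_of = {sp: i for i, sp in enumerate(phase_result.sites)}
    for i in phase_result.assignment:
        if phase_result.sites[i] not in call_at:
            raise ConsistencyError(
                f"phased site {phase_result.sites[i]} has no genotype call")
    block_of = phase_result.block_of()
    block_ps = {bi: phase_result.block_id(bi)[1] + 1
                for bi in range(len(phase_result.blocks))}
    records = []
    for (ref, pos), call in sorted(call_at.items()):
        a0, a1 = call.alleles
        vcf_alleles = [call.ref_base] + [a for a in (a0, a1) if a != call.ref_base]
        idx = {a: vcf_alleles.index(a) for a in (a0, a1)}
        i = site_of.get((ref, pos))
        h = phase_result.assignment.get(i) if i is not None else None
        if h is None:
            records.append(PhasedRecord(ref, pos, vcf_alleles[0],
                                        ",".join(vcf_alleles[1:]),
                                        gt=(idx[a0], idx[a1]), phased=False,
                                        ps=None))
        else:
            hap1, hap2 = (a0, a1) if h == 0 else (a1, a0)
            records.append(PhasedRecord(ref, pos, vcf_alleles[0],
                                        ",".join(vcf_alleles[1:]),
                                        gt=(idx[hap1], idx[hap2]), phased=True,
                                        ps=block_ps[block_of[i]]))
    return records
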