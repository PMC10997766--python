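"""Library-level statistics: collisions, linked-read efficiency,
on-target recovery, coverage, and allele burden.

A *collision* is two or more distinct DNA fragments captured on the
same barcoded bead.  The collision estimator works from mapped reads
only: a barcode is associated with every fragment receiving at least
``min_reads`` of its reads (read midpoints decide the fragment), and is
collision-free iff it associates with exactly one fragment.  Two
molecules of the *same* fragment on one bead are therefore invisible to
the estimator, as in the real assay.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .align import AlignedRead, SiteCounts
from .errors import ParameterError

DEFAULT_MIN_READS_PER_FRAGMENT = 2
DEFAULT_IMBALANCE_THRESHOLD = 0.2

Interval = tuple[str, str, int, int]  # (name, ref_id, start, end) half-open


class _FragmentLookup:
    """Midpoint -> fragment lookup over non-overlapping intervals."""

    def __init__(self, intervals: list[Interval]):
        self.by_ref: dict[str, tuple[list[int], list[int], list[str]]] = {}
        grouped: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
        for name, ref, start, end in intervals:
            grouped[ref].append((start, end, name))
        for ref, ivs in grouped.items():
            ivs.sort()
            for (s1, e1, n1), (s2, e2, n2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ParameterError(
                        f"overlapping fragment intervals {n1} and {n2} on {ref}")
            self.by_ref[ref] = ([s for s, _, _ in ivs],
                                [e for _, e, _ in ivs],
                                [n for _, _, n in ivs])

    def fragment_at(self, ref: str, pos: int) -> str | None:
        entry = self.by_ref.get(ref)
        if entry is None:
            return None
        starts, ends, names = entry
        i = bisect_right(starts, pos) - 1
        if i >= 0 and pos < ends[i]:
            return names[i]
        return None


def _midpoint(read: AlignedRead) -> int:
    return read.start + read.ref_len() // 2


@dataclass
class CollisionReport:
    """Collision-free fractions (%) per fragment and overall."""

    barcode_fragments: dict[str, frozenset[str]]
    per_fragment_pct: dict[str, float]
    overall_pct: float
    min_reads: int
    input_label: str = ""

    @property
    def collision_free_barcodes(self) -> set[str]:
        return {b for b, f in self.barcode_fragments.items() if len(f) == 1}


def collision_report(aligned_reads: list[AlignedRead],
                     fragment_intervals: list[Interval],
                     min_reads: int = DEFAULT_MIN_READS_PER_FRAGMENT,
                     input_label: str = "") -> CollisionReport:
    """Estimate collision-free barcoding fractions from mapped reads.

    Reads must be deduplicated, mapped and barcode-corrected.  A
    barcode is assigned to every fragment where >= ``min_reads`` of its
    reads place their alignment midpoint; barcodes assigned no fragment
    are not counted.
    """
    lookup = _FragmentLookup(fragment_intervals)
    hits: dict[str, defaultdict] = defaultdict(lambda: defaultdict(int))
    for read in aligned_reads:
        if not read.mapped or read.is_dup:
            continue
        frag = lookup.fragment_at(read.ref_id, _midpoint(read))
        if frag is not None:
            hits[read.barcode][frag] += 1
    barcode_fragments = {
        bc: frozenset(f for f, n in frags.items() if n >= min_reads)
        for bc, frags in hits.items()
    }
    barcode_fragments = {bc: fs for bc, fs in barcode_fragments.items() if fs}
    counted = list(barcode_fragments.values())
    overall = (100.0 * sum(1 for fs in counted if len(fs) == 1) / len(counted)
               if counted else float("nan"))
    per_fragment: dict[str, float] = {}
    for name, _, _, _ in fragment_intervals:
        touching = [fs for fs in counted if name in fs]
        per_fragment[name] = (
            100.0 * sum(1 for fs in touching if len(fs) == 1) / len(touching)
            if touching else float("nan"))
    return CollisionReport(barcode_fragments=barcode_fragments,
                           per_fragment_pct=per_fragment, overall_pct=overall,
                           min_reads=min_reads, input_label=input_label)


@dataclass
class EfficiencyReport:
    linked_reads: int
    total_reads: int
    efficiency_pct: float
    restricted_to_collision_free: bool = True


def linked_read_efficiency(aligned_reads: list[AlignedRead],
                           report: CollisionReport) -> EfficiencyReport:
    """Linked reads over total reads (%) among collision-free barcodes.

    A read is *linked* iff its barcode has >= 2 non-duplicate reads
    from distinct templates (read ids) mapping to the same fragment --
    the two mates of one pair do not link anything by themselves.
    Analysis is restricted to barcodes that are not multi-fragment in
    ``report``.
    """
    multi = {b for b, fs in report.barcode_fragments.items() if len(fs) > 1}
    templates: dict[str, set[str]] = defaultdict(set)
    reads = [r for r in aligned_reads
             if r.mapped and not r.is_dup and r.barcode not in multi]
    if not reads:
        raise ParameterError("no reads available for efficiency calculation")
    for r in reads:
        templates[r.barcode].add(r.read_id)
    # With at most one associated fragment per retained barcode, >= 2
    # templates on the barcode means >= 2 on that fragment.
    linked = sum(1 for r in reads
                 if len(templates[r.barcode]) >= 2
                 and r.barcode in report.barcode_fragments)
    total = len(reads)
    return EfficiencyReport(linked_reads=linked, total_reads=total,
                            efficiency_pct=100.0 * linked / total)


@dataclass
class RecoveryReport:
    on_target_pct: float
    coverage_per_target: dict[str, float]
    mean_coverage: float


def target_recovery(aligned_reads: list[AlignedRead],
                    target_bed: list[tuple[str, int, int]],
                    reference_lengths: dict[str, int] | None = None
                    ) -> RecoveryReport:
    """On-target read percentage and mean coverage per target interval.

    A mapped, non-duplicate read is on-target iff its alignment
    midpoint lies in a target interval; coverage is aligned bases
    falling in the interval divided by interval length.
    """
    if not target_bed:
        raise ParameterError("target BED is empty")
    intervals = [(f"{ref}:{start}-{end}", ref, start, end)
                 for ref, start, end in target_bed]
    lookup = _FragmentLookup(intervals)
    on = total = 0
    bases: dict[str, float] = {name: 0.0 for name, _, _, _ in intervals}
    for read in aligned_reads:
        if not read.mapped or read.is_dup:
            continue
        total += 1
        name = lookup.fragment_at(read.ref_id, _midpoint(read))
        if name is not None:
            on += 1
        for iv_name, ref, start, end in intervals:
            if read.ref_id == ref:
                ov = min(read.ref_end(), end) - max(read.start, start)
                if ov > 0:
                    bases[iv_name] += ov
    if total == 0:
        raise ParameterError("no mapped reads")
    coverage = {name: bases[name] / (end - start)
                for name, _, start, end in intervals}
    return RecoveryReport(
        on_target_pct=100.0 * on / total,
        coverage_per_target=coverage,
        mean_coverage=float(np.mean(list(coverage.values()))),
    )


@dataclass
class BurdenReport:
    """Allele burden: per-site fractions of the two annotated alleles.

    Per-site fractions are over reads carrying either annotated allele
    (other bases tallied separately); ``mean_fractions`` averages the
    per-site (hap1, hap2) fractions.  ``imbalanced`` flags a mean minor
    fraction under the threshold, the signature of haplotype dropout.
    """

    per_site: dict[tuple[str, int], tuple[float, float]]
    mean_fractions: tuple[float, float]
    other_base_fraction: float
    imbalanced: bool
    zero_depth_sites: list[tuple[str, int]] = field(default_factory=list)


def allele_burden(site_counts: SiteCounts,
                  het_sites: list[tuple[int, str, str]],
                  imbalance_threshold: float = DEFAULT_IMBALANCE_THRESHOLD
                  ) -> BurdenReport:
    """Fractions of reads carrying each annotated allele at het sites.

    ``het_sites`` holds (position, allele_hap1, allele_hap2) on the
    pileup's reference; zero-depth sites are excluded and reported.
    """
    per_site: dict[tuple[str, int], tuple[float, float]] = {}
    zero_depth: list[tuple[str, int]] = []
    other_total = 0
    allele_total = 0
    for pos, a1, a2 in het_sites:
        counts = site_counts.at(pos)
        c1, c2 = counts[a1], counts[a2]
        depth = sum(counts.values())
        if c1 + c2 == 0:
            zero_depth.append((site_counts.ref_id, pos))
            continue
        other_total += depth - c1 - c2
        allele_total += depth
        per_site[(site_counts.ref_id, pos)] = (c1 / (c1 + c2), c2 / (c1 + c2))
    if per_site:
        f1 = float(np.mean([v[0] for v in per_site.values()]))
        f2 = float(np.mean([v[1] for v in per_site.values()]))
    else:
        f1 = f2 = float("nan")
    minor = min(f1, f2)
    return BurdenReport(
        per_site=per_site,
        mean_fractions=(f1, f2),
        other_base_fraction=(other_total / allele_total if allele_total else 0.0),
        imbalanced=bool(minor < imbalance_threshold) if per_site else False,
        zero_depth_sites=zero_depth,
    )
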