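"""Scoring inferred phasing against a benchmark, and the
coverage-titration experiment.

Phasing disagreement is decomposed into *switch* errors (all sites
downstream of a point inverted) and *flip* errors (a single site
inverted), minimising switches + flips over the two global block
orientations -- phase is relative, so a globally swapped block is not
an error.  The decomposition is computed by an exact two-state dynamic
program over the per-site disagreement vector and agrees with
exhaustive enumeration.

Results are bucketed into the four phasing-quality groups used for
depth titration: 1 = error-free single block; 2 = single block with
exactly one flip or switch; 3 = genotyping errors, discontinuous
blocks, or multiple flip/switch errors; 4 = mostly unphased sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .simulate import ReadPair

DEFAULT_UNPHASED_THRESHOLD = 0.5
DEFAULT_FRACTION_LADDER = (0.5, 0.25, 0.125, 0.0625, 0.03125, 0.0156, 0.0078)


@dataclass(frozen=True)
class VariantPhase:
    """One het site of a phased call set.

    ``alleles`` is (haplotype-1 base, haplotype-2 base) when phased;
    order is arbitrary when unphased.
    """

    ref_id: str
    pos: int
    alleles: tuple[str, str]
    phased: bool
    ps: int | None = None


PhaseSet = Mapping[tuple[str, int], VariantPhase]


def _decompose(d: Sequence[int]) -> tuple[int, int, int, list[int]]:
    """Exact DP over a 0/1 disagreement vector.

    Returns (switches, flips, orientation, parity path).  A switch
    toggles the parity between consecutive sites (cost 1); a flip pays
    1 where the vector disagrees with the parity.  Ties prefer fewer
    switches, then orientation 0.
    """
    n = len(d)
    if n == 0:
        return 0, 0, 0, []
    INF = float("inf")
    cost = [[INF, INF] for _ in range(n)]
    prev = [[0, 0] for _ in range(n)]
    for p in (0, 1):
        cost[0][p] = 1 if d[0] != p else 0
    for i in range(1, n):
        for p in (0, 1):
            flip = 1 if d[i] != p else 0
            stay = cost[i - 1][p]
            switch = cost[i - 1][1 - p] + 1
            if stay <= switch:
                cost[i][p] = stay + flip
                prev[i][p] = p
            else:
                cost[i][p] = switch + flip
                prev[i][p] = 1 - p
    end = 0 if cost[n - 1][0] <= cost[n - 1][1] else 1
    path = [0] * n
    path[n - 1] = end
    for i in range(n - 1, 0, -1):
        path[i - 1] = prev[i][path[i]]
    switches = sum(1 for i in range(1, n) if path[i] != path[i - 1])
    flips = sum(1 for i in range(n) if d[i] != path[i])
    return switches, flips, path[0], path


def switch_flip_decompose(truth_phase_vector: Sequence[int],
                          called_phase_vector: Sequence[int]
                          ) -> tuple[int, int]:
    """Minimal (switch count, flip count) turning the called phase
    vector into the truth, over the two global orientations."""
    if len(truth_phase_vector) != len(called_phase_vector):
        raise ParameterError("phase vectors differ in length")
    for v in (*truth_phase_vector, *called_phase_vector):
        if v not in (0, 1):
            raise ParameterError("phase vectors must be 0/1")
    d = [t ^ c for t, c in zip(truth_phase_vector, called_phase_vector)]
    switches, flips, _, _ = _decompose(d)
    return switches, flips


@dataclass
class EvalReport:
    """Per-target phasing accounting against a benchmark."""

    annotated: int = 0
    recalled: int = 0
    phased: int = 0
    correctly_phased: int = 0
    flip_errors: int = 0
    switch_errors: int = 0
    de_novo_phased: int = 0
    de_novo_confirmed: int | None = None
    n_blocks: int = 0
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.recalled > self.annotated:
            raise ParameterError("recalled > annotated")
        if self.phased > self.recalled:
            raise ParameterError("phased > recalled")

    @property
    def missed(self) -> int:
        return self.annotated - self.recalled

    @property
    def unphased(self) -> int:
        return self.recalled - self.phased

    @property
    def single_block(self) -> bool:
        return self.n_blocks == 1

    @property
    def accuracy_of_annotated(self) -> float:
        return 100.0 * self.correctly_phased / self.annotated if self.annotated else float("nan")

    @property
    def accuracy_of_recalled(self) -> float:
        return 100.0 * self.correctly_phased / self.recalled if self.recalled else float("nan")

    @classmethod
    def aggregate(cls, reports: Sequence["EvalReport"]) -> "EvalReport":
        """Pool per-target counts, as done when quoting a single
        accuracy over several targets or replicates."""
        agg = cls()
        for r in reports:
            agg.annotated += r.annotated
            agg.recalled += r.recalled
            agg.phased += r.phased
            agg.correctly_phased += r.correctly_phased
            agg.flip_errors += r.flip_errors
            agg.switch_errors += r.switch_errors
            agg.de_novo_phased += r.de_novo_phased
            agg.n_blocks += r.n_blocks
        return agg


def _block_orientation(block_sites: list[tuple[str, int]],
                       inferred: PhaseSet, benchmark: PhaseSet
                       ) -> tuple[int, list[tuple[str, int]], list[int]] | None:
    """Disagreement vector of a block vs the benchmark.

    Returns (orientation, comparable site list, disagreement vector);
    None when no site is comparable."""
    comparable: list[tuple[str, int]] = []
    d: list[int] = []
    for sp in sorted(block_sites, key=lambda x: (x[0], x[1])):
        bench = benchmark.get(sp)
        inf = inferred[sp]
        if bench is None or not bench.phased:
            continue
        if set(bench.alleles) != set(inf.alleles):
            continue  # allele mismatch handled by the caller
        comparable.append(sp)
        d.append(0 if inf.alleles[0] == bench.alleles[0] else 1)
    if not comparable:
        return None
    _, _, orientation, _ = _decompose(d)
    return orientation, comparable, d


def compare_phasing(benchmark: PhaseSet, inferred: PhaseSet,
                    replicate_set: Sequence[PhaseSet] | None = None
                    ) -> EvalReport:
    """Score an inferred phased call set against a benchmark.

    Both inputs map (reference, 0-based position) to
    :class:`VariantPhase`; het sites only.  ``replicate_set`` enables
    confirmation of de novo phased sites (phased by the method, absent
    or unphased in the benchmark): a site is confirmed when >= 2
    replicates phase it identically relative to shared benchmark-phased
    sites; without replicates de novo sites are reported unconfirmed.
    """
    annotated = {sp for sp, v in benchmark.items() if v.alleles[0] != v.alleles[1]}
    recalled = {sp for sp in annotated
                if sp in inferred and inferred[sp].alleles[0] != inferred[sp].alleles[1]}
    phased = {sp for sp in recalled if inferred[sp].phased}

    blocks: dict[int | None, list[tuple[str, int]]] = {}
    for sp, v in inferred.items():
        if v.phased:
            blocks.setdefault(v.ps, []).append(sp)

    correct = flips = switches = 0
    for block_sites in blocks.values():
        cmp_sites = [sp for sp in block_sites if sp in phased]
        res = _block_orientation(cmp_sites, inferred, benchmark)
        if res is None:
            continue
        orientation, comparable, d = res
        if len(comparable) == 1:
            correct += 1  # no relative phase to contradict
            continue
        sw, fl, g, path = _decompose(d)
        switches += sw
        flips += fl
        correct += sum(1 for v in d if v == g)

    de_novo = [sp for sp, v in inferred.items()
               if v.phased and (sp not in benchmark or not benchmark[sp].phased)]
    confirmed: int | None = None
    if replicate_set:
        confirmed = 0
        for sp in de_novo:
            calls = []
            for rep in (inferred, *replicate_set):
                o = _oriented_de_novo_allele(sp, rep, benchmark)
                if o is not None:
                    calls.append(o)
            if len(calls) >= 2 and len(set(calls)) == 1:
                confirmed += 1

    block_count = sum(
        1 for block_sites in blocks.values()
        if sum(1 for sp in block_sites if sp in phased) >= 1
    )
    report = EvalReport(
        annotated=len(annotated), recalled=len(recalled), phased=len(phased),
        correctly_phased=correct, flip_errors=flips, switch_errors=switches,
        de_novo_phased=len(de_novo), de_novo_confirmed=confirmed,
        n_blocks=block_count,
    )
    if not annotated & set(inferred):
        report.notes.append("disjoint site sets: recall 0")
    return report


def _oriented_de_novo_allele(sp: tuple[str, int], phase_set: PhaseSet,
                             benchmark: PhaseSet) -> str | None:
    """Haplotype-1 allele of a de novo site after orienting its block
    to the benchmark via shared phased sites."""
    v = phase_set.get(sp)
    if v is None or not v.phased:
        return None
    block_sites = [s for s, w in phase_set.items()
                   if w.phased and w.ps == v.ps and s != sp]
    res = _block_orientation(block_sites, phase_set, benchmark)
    if res is None:
        return None
    orientation, _, _ = res
    return v.alleles[orientation]


@dataclass(frozen=True)
class QualityGroup:
    """Phasing-quality bucket 1-4 plus the booleans that determined it."""

    group: int
    mostly_unphased: bool
    any_missed: bool
    multiple_blocks: bool
    n_flip_switch: int


def classify_quality_group(report: EvalReport,
                           mostly_unphased_threshold: float = DEFAULT_UNPHASED_THRESHOLD
                           ) -> QualityGroup:
    """Bucket an evaluation into quality groups 1-4 (see module docs)."""
    unphased_frac = (report.unphased / report.recalled
                     if report.recalled else 1.0)
    mostly_unphased = unphased_frac > mostly_unphased_threshold
    any_missed = report.missed > 0
    multiple_blocks = report.n_blocks != 1
    n_err = report.flip_errors + report.switch_errors
    if mostly_unphased:
        group = 4
    elif any_missed or multiple_blocks or n_err > 1:
        group = 3
    elif n_err == 1:
        group = 2
    else:
        group = 1
    return QualityGroup(group, mostly_unphased, any_missed, multiple_blocks, n_err)


def subsample_reads(read_set: list[ReadPair], fraction: float,
                    seed: int = 0) -> list[ReadPair]:
    """Retain each read pair independently with probability ``fraction``."""
    if not 0.0 < fraction <= 1.0:
        raise ParameterError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return list(read_set)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(read_set)) < fraction
    return [r for r, k in zip(read_set, keep) if k]


def coverage_titration(read_set: list[ReadPair],
                       fraction_ladder: Sequence[float],
                       analyze: Callable[[list[ReadPair]], tuple[EvalReport, float]],
                       seeds: Sequence[int],
                       mostly_unphased_threshold: float = DEFAULT_UNPHASED_THRESHOLD
                       ) -> pd.DataFrame:
    """Re-run the analysis at each subsampling fraction and seed.

    ``analyze`` maps a read set through the full downstream pipeline
    (dedup re-applied) and returns (EvalReport, post-dedup coverage).
    A pipeline failure at a cell is recorded as group 4 with a note.
    Returns a tidy table with one row per (fraction, seed).
    """
    fractions = list(fraction_ladder)
    if fractions != sorted(fractions, reverse=True):
        raise ParameterError("fraction ladder must be sorted descending")
    rows = []
    for fraction in fractions:
        for seed in seeds:
            sub = subsample_reads(read_set, fraction, seed)
            note = ""
            try:
                report, coverage = analyze(sub)
                group = classify_quality_group(report, mostly_unphased_threshold)
                rows.append(dict(
                    fraction=fraction, seed=seed, coverage_x=coverage,
                    quality_group=group.group, annotated=report.annotated,
                    recalled=report.recalled, phased=report.phased,
                    flip_errors=report.flip_errors,
                    switch_errors=report.switch_errors,
                    n_blocks=report.n_blocks, note=note,
                ))
            except Exception as exc:  # recorded, not raised: the cell failed
                rows.append(dict(
                    fraction=fraction, seed=seed, coverage_x=float("nan"),
                    quality_group=4, annotated=0, recalled=0, phased=0,
                    flip_errors=0, switch_errors=0, n_blocks=0,
                    note=f"pipeline failure: {exc}",
                ))
    return pd.DataFrame(rows)
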