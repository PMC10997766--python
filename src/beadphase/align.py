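"""Lite read mapping, CIGAR coordinate projection, per-position
nucleotide counting, and diploid SNV genotyping.

The mapper places each read at the reference position collecting the
most exact k-mer seed votes and emits a substitution-only alignment
(CIGAR over S/M).  It is intended for the small references of targeted
experiments; real-data users can import externally produced alignments
through the SAM reader in :mod:`beadphase.io` instead.

Genotyping is a depth/allele-fraction rule: a site is heterozygous iff
its two most frequent bases both reach the allele-fraction cutoff
(default 0.1) at sufficient depth, mirroring diploid small-variant
calling on amplicon data.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .errors import FormatError, ParameterError
from .simulate import ReadPair, revcomp

DEFAULT_SEED_K = 21
DEFAULT_AF_CUTOFF = 0.1
DEFAULT_MIN_DEPTH = 10

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_CIGAR_RE = re.compile(r"(\d+)([MIDS])")


@dataclass(slots=True)
class AlignedRead:
    """One aligned read end.

    ``seq`` is stored in reference orientation (reverse-complemented for
    '-' strand alignments) so that query index i of the CIGAR walk
    indexes ``seq`` directly.
    """

    read_id: str
    mate: int                 # 1 or 2
    ref_id: str | None
    start: int                # 0-based; -1 if unmapped
    cigar: str                # over {M, I, D, S}; "*" if unmapped
    strand: str               # "+", "-", or "." if unmapped
    barcode: str
    mapped: bool
    is_dup: bool
    seq: str

    def ref_len(self) -> int:
        """Reference bases consumed by the alignment."""
        if not self.mapped:
            return 0
        return sum(n for n, op in parse_cigar(self.cigar) if op in "MD")

    def ref_end(self) -> int:
        return self.start + self.ref_len()


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = _CIGAR_RE.findall(cigar)
    if not ops or "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise FormatError(f"malformed CIGAR: {cigar!r}")
    return [(int(n), op) for n, op in ops]


class ReferenceIndex:
    """Exact k-mer index over a set of reference contigs."""

    def __init__(self, references: dict[str, str], k: int = DEFAULT_SEED_K):
        if k < 8:
            raise ParameterError("seed length k must be >= 8")
        self.k = k
        self.references = references
        self.index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in references.items():
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos:pos + k]
                self.index.setdefault(kmer, []).append((name, pos))

    def vote(self, seq: str) -> tuple[str, int, int] | None:
        """Best (ref, start, votes) by exact seed voting; None on a tie
        or no hits.  Seeds are sampled at ~7 offsets across the read."""
        k = self.k
        n = len(seq) - k
        if n < 0:
            return None
        step = max(1, n // 6) if n else 1
        offsets = list(range(0, n + 1, step))
        votes: Counter = Counter()
        for off in offsets:
            for ref, pos in self.index.get(seq[off:off + k], ()):
                votes[(ref, pos - off)] += 1
        if not votes:
            return None
        ranked = votes.most_common(2)
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            return None
        (ref, start), best = ranked[0]
        return ref, start, best


def _align_end(index: ReferenceIndex, read_id: str, mate: int, seq: str,
               barcode: str) -> AlignedRead:
    fwd = index.vote(seq)
    rc_seq = revcomp(seq)
    rev = index.vote(rc_seq)
    if fwd is not None and (rev is None or fwd[2] > rev[2]):
        ref, start, _ = fwd
        strand, oriented = "+", seq
    elif rev is not None and (fwd is None or rev[2] > fwd[2]):
        ref, start, _ = rev
        strand, oriented = "-", rc_seq
    else:  # no hits either way, or a strand tie
        return AlignedRead(read_id, mate, None, -1, "*", ".", barcode,
                           False, False, seq)
    ref_len = len(index.references[ref])
    lead = max(0, -start)
    trail = max(0, start + len(oriented) - ref_len)
    matched = len(oriented) - lead - trail
    if matched < index.k:
        return AlignedRead(read_id, mate, None, -1, "*", ".", barcode,
                           False, False, seq)
    cigar = ""
    if lead:
        cigar += f"{lead}S"
    cigar += f"{matched}M"
    if trail:
        cigar += f"{trail}S"
    return AlignedRead(read_id, mate, ref, start + lead, cigar, strand,
                       barcode, True, False, oriented)


def map_reads(read_pairs: list[ReadPair], references: dict[str, str],
              k: int = DEFAULT_SEED_K,
              barcode_table=None) -> list[AlignedRead]:
    """Map both ends of every pair by k-mer seed voting.

    Reads with no seed hits, or with tied best positions, are flagged
    unmapped.  If a :class:`~beadphase.preprocess.BarcodeTable` is
    given, its corrections are applied to the carried barcode.
    """
    index = references if isinstance(references, ReferenceIndex) \
        else ReferenceIndex(references, k)
    out: list[AlignedRead] = []
    for pair in read_pairs:
        bc = pair.observed_barcode
        if barcode_table is not None:
            bc = barcode_table.corrected(bc)
        out.append(_align_end(index, pair.read_id, 1, pair.r1_seq, bc))
        out.append(_align_end(index, pair.read_id, 2, pair.r2_seq, bc))
    return out


def cigar_to_ref_coords(read: AlignedRead) -> list[tuple[int, int]]:
    """(query index, reference position) for every aligned base.

    M advances both coordinates, I and S advance the query only, D
    advances the reference only.  The result is a bijection between
    aligned query bases and covered reference positions.
    """
    pairs: list[tuple[int, int]] = []
    q = r = 0
    for n, op in parse_cigar(read.cigar):
        if op == "M":
            pairs.extend((q + i, read.start + r + i) for i in range(n))
            q += n
            r += n
        elif op in ("I", "S"):
            q += n
        elif op == "D":
            r += n
    return pairs


@dataclass
class SiteCounts:
    """Per-position A/C/G/T counts over a reference region."""

    ref_id: str
    start: int
    counts: np.ndarray  # shape (region length, 4), columns A/C/G/T

    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def at(self, pos: int) -> dict[str, int]:
        row = self.counts[pos - self.start]
        return {b: int(row[i]) for b, i in _BASE_INDEX.items()}


def pileup_counts(aligned_reads: list[AlignedRead],
                  region: tuple[str, int, int]) -> SiteCounts:
    """Per-position nucleotide counts over ``region`` (0-based half-open),
    excluding duplicate-flagged and unmapped reads."""
    ref_id, start, end = region
    counts = np.zeros((max(0, end - start), 4), dtype=np.int64)
    for read in aligned_reads:
        if not read.mapped or read.is_dup or read.ref_id != ref_id:
            continue
        if read.ref_end() <= start or read.start >= end:
            continue
        for q, r in cigar_to_ref_coords(read):
            if start <= r < end:
                idx = _BASE_INDEX.get(read.seq[q])
                if idx is not None:
                    counts[r - start, idx] += 1
    return SiteCounts(ref_id=ref_id, start=start, counts=counts)


@dataclass(frozen=True)
class GenotypeCall:
    ref_id: str
    pos: int                      # 0-based
    ref_base: str
    genotype: str                 # {"hom_ref", "het", "hom_alt"}
    alleles: tuple[str, ...]      # het: (first, second); hom: (base,)
    allele_depths: tuple[int, ...]
    depth: int

    @property
    def is_het(self) -> bool:
        return self.genotype == "het"


def call_genotypes(site_counts: SiteCounts, ref_seq: str,
                   af_cutoff: float = DEFAULT_AF_CUTOFF,
                   min_depth: int = DEFAULT_MIN_DEPTH) -> list[GenotypeCall]:
    """Diploid SNV calls from pileup counts.

    A site is heterozygous iff its two most frequent bases both have
    allele fraction >= ``af_cutoff`` and depth >= ``min_depth``;
    otherwise it is homozygous for the majority base.  Only sites
    differing from the reference or heterozygous are emitted; zero-depth
    sites are skipped.  For het sites the reference base, when it is one
    of the two alleles, is listed first.
    """
    if not 0.0 < af_cutoff <= 0.5:
        raise ParameterError("af_cutoff must be in (0, 0.5]")
    if min_depth < 1:
        raise ParameterError("min_depth must be >= 1")
    calls: list[GenotypeCall] = []
    depths = site_counts.depth()
    for i in range(site_counts.counts.shape[0]):
        depth = int(depths[i])
        if depth == 0:
            continue
        pos = site_counts.start + i
        row = site_counts.counts[i]
        order = np.argsort(row, kind="stable")[::-1]
        top, second = int(order[0]), int(order[1])
        ref_base = ref_seq[pos]
        if (depth >= min_depth
                and row[second] / depth >= af_cutoff
                and row[top] / depth >= af_cutoff):
            a, b = BASES[top], BASES[second]
            if b == ref_base:
                a, b = b, a
            calls.append(GenotypeCall(
                site_counts.ref_id, pos, ref_base, "het", (a, b),
                (int(row[_BASE_INDEX[a]]), int(row[_BASE_INDEX[b]])), depth))
        else:
            maj = BASES[top]
            if maj != ref_base:
                calls.append(GenotypeCall(
                    site_counts.ref_id, pos, ref_base, "hom_alt", (maj,),
                    (int(row[top]),), depth))
    return calls
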