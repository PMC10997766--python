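"""Read preprocessing: adapter trimming, bead-barcode error correction,
and within-barcode duplicate marking.

Barcode correction follows the single-substitution rule used for bead
barcodes: a barcode observed on exactly one read that lies at Hamming
distance 1 from exactly one multi-read (count >= 2) barcode is assumed
to carry a sequencing error and is reassigned to that neighbour.
Duplicate marking is restricted to reads sharing a (corrected) barcode:
identical coordinates under different barcodes are independent
molecules, not PCR duplicates.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import FormatError, ParameterError

# 3' adapter sequences trimmed from the two mates (adapter-dimer aware:
# three candidates for R1, one for R2).
R1_ADAPTERS: tuple[str, ...] = (
    "TGAAGCGGCGCACGAAAAACGCGAAAGCGTTTCAC",
    "ATCACGGACTGCCCATAGAGAGGCTCTGG",
    "TGGTCATGTGGAGACGCTGGG",
)
R2_ADAPTERS: tuple[str, ...] = ("TGGGCCGGTGCAGTTAATGTAGGGAAAGAGTGT",)

DEFAULT_MIN_OVERLAP = 5


def trim_adapters(read_seq: str, adapter_set: Sequence[str],
                  min_overlap: int = DEFAULT_MIN_OVERLAP) -> str:
    """Remove a 3' adapter from ``read_seq``.

    A full internal adapter occurrence truncates the read from the match
    start; otherwise the longest read suffix equal to an adapter prefix
    of length >= ``min_overlap`` is removed.  Matching is exact.
    """
    if min_overlap < 1:
        raise ParameterError("min_overlap must be >= 1")
    if not adapter_set:
        return read_seq
    cut = len(read_seq)
    for adapter in adapter_set:
        hit = read_seq.find(adapter)
        if hit != -1:
            cut = min(cut, hit)
    if cut < len(read_seq):
        return read_seq[:cut]
    best = 0
    for adapter in adapter_set:
        max_k = min(len(adapter) - 1, len(read_seq))
        for k in range(max_k, max(min_overlap, best + 1) - 1, -1):
            if read_seq.endswith(adapter[:k]):
                best = max(best, k)
                break
    return read_seq[:len(read_seq) - best] if best else read_seq


@dataclass
class BarcodeTable:
    """Observed barcode read counts plus the correction map."""

    counts: dict[str, int]
    corrections: dict[str, str] = field(default_factory=dict)

    def corrected(self, barcode: str) -> str:
        return self.corrections.get(barcode, barcode)

    @property
    def n_corrected(self) -> int:
        return sum(1 for k, v in self.corrections.items() if k != v)


def _neighbors(barcode: str) -> Iterable[str]:
    for i, b in enumerate(barcode):
        for repl in "ACGT":
            if repl != b:
                yield barcode[:i] + repl + barcode[i + 1:]


def correct_barcodes(barcode_counts: Mapping[str, int]) -> BarcodeTable:
    """Map single-read barcodes onto a unique multi-read neighbour.

    Every barcode with count 1 that has exactly one count >= 2 barcode
    at Hamming distance 1 is corrected to it; ambiguous singletons (two
    or more candidate neighbours) and all multi-read barcodes are left
    unchanged.
    """
    lengths = {len(b) for b in barcode_counts}
    if len(lengths) > 1:
        raise FormatError(f"barcodes of unequal length: {sorted(lengths)}")
    for bc, count in barcode_counts.items():
        if count < 1:
            raise ParameterError(f"barcode {bc} has count {count} < 1")
    multi = {b for b, c in barcode_counts.items() if c >= 2}
    corrections: dict[str, str] = {}
    for bc, count in barcode_counts.items():
        if count != 1:
            continue
        candidates = [n for n in _neighbors(bc) if n in multi]
        if len(candidates) == 1:
            corrections[bc] = candidates[0]
    return BarcodeTable(counts=dict(barcode_counts), corrections=corrections)


def mark_duplicates(aligned_reads: list) -> list:
    """Flag within-barcode PCR duplicates on a set of aligned read ends.

    Read pairs sharing (barcode, reference, R1 start, R2 start,
    orientation) beyond the first -- in a stable sort by read id -- are
    flagged.  Identical coordinates under different barcodes are never
    flagged.  Unaligned reads pass through unflagged.  Returns the same
    reads with ``is_dup`` set; idempotent.
    """
    pairs: dict[str, list] = defaultdict(list)
    for read in aligned_reads:
        read.is_dup = False
        pairs[read.read_id].append(read)
    seen: set[tuple] = set()
    for read_id in sorted(pairs):
        ends = pairs[read_id]
        if not all(r.mapped for r in ends):
            continue
        ends_sorted = sorted(ends, key=lambda r: r.mate)
        key = (
            ends_sorted[0].barcode,
            tuple(r.ref_id for r in ends_sorted),
            tuple(r.start for r in ends_sorted),
            tuple(r.strand for r in ends_sorted),
        )
        if key in seen:
            for r in ends:
                r.is_dup = True
        else:
            seen.add(key)
    return aligned_reads
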