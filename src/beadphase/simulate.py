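"""Synthetic targeted linked-read experiments with known truth.

This module emulates the wet-lab side of a microbead co-barcoding assay:

* diploid target loci with heterozygous SNVs placed by a renewal process
  (mean spacing ~1-2 kb, as in human genomes);
* a sample composition given in picograms of target, off-target
  (background) and "filling" DNA, converted to molecule counts;
* Poisson loading of molecules onto barcoded microbeads -- two molecules
  landing on the same bead is a *collision*;
* 2 x 145 bp paired-end reads carrying an 18-base bead barcode, with
  substitution noise, barcode sequencing errors and PCR duplicates.

Every stochastic step is driven by an explicit seed, so a full
experiment is bit-reproducible.  All generated objects keep enough truth
information (source molecule, true barcode, duplicate flags, bead
assignments) for downstream estimators to be validated exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

logger = logging.getLogger(__name__)

# Lengths (bp) of the fourteen non-overlapping fragments produced by
# BstP I digestion of the 48.5 kb lambda phage genome, used as filling
# DNA.  A digest is equimolar: each genome copy yields one molecule of
# every fragment.
BSTPI_FRAGMENT_LENGTHS: tuple[int, ...] = (
    117, 224, 702, 1264, 1371, 1929, 2323, 3675,
    4324, 4822, 5687, 6369, 7242, 8453,
)
LAMBDA_GENOME_BP = sum(BSTPI_FRAGMENT_LENGTHS)  # 48,502 bp

# Spacings (bp) between the seven clinically relevant heterozygous sites
# of the 13 kb cardiac sodium-channel (SCN5A-SCN10A) amplicon, 5' to 3'.
SCN10A_SITE_SPACINGS: tuple[int, ...] = (288, 4299, 23, 69, 5560, 2505)

AVOGADRO = 6.022e23
GRAMS_PER_MOL_PER_BP = 650.0  # average molecular weight of one bp of dsDNA

BARCODE_LENGTH = 18
DEFAULT_READ_LENGTH = 145

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, n)])


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class DiploidLocus:
    """A reference segment plus truth haplotypes at heterozygous sites.

    ``het_sites`` holds ``(position, allele_hap1, allele_hap2)`` with
    0-based positions strictly increasing; exactly one of the two
    alleles equals the reference base, the haplotype carrying it is
    random per site.
    """

    locus_id: str
    ref_seq: str
    het_sites: list[tuple[int, str, str]]
    _hap_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def length_bp(self) -> int:
        return len(self.ref_seq)

    def haplotype_seq(self, hap: int) -> str:
        """Full sequence of haplotype 1 or 2 (ref with alleles substituted)."""
        if hap not in (1, 2):
            raise ParameterError(f"haplotype must be 1 or 2, got {hap}")
        if hap not in self._hap_cache:
            seq = list(self.ref_seq)
            for pos, a1, a2 in self.het_sites:
                seq[pos] = a1 if hap == 1 else a2
            self._hap_cache[hap] = "".join(seq)
        return self._hap_cache[hap]


@dataclass(frozen=True)
class SampleComposition:
    """Masses (pg) and haplotype skews defining what goes into the tube.

    ``target_mass_pg`` applies per locus (pooled targets use equal
    masses).  ``hap_bias`` is the fraction of target molecules drawn
    from haplotype 1; ``dropout_fraction`` removes that fraction of
    ``dropout_hap`` molecules after the split, modelling amplification
    dropout or inversion mosaicism.
    """

    target_mass_pg: float = 20.0
    purity_class: str = "pure"  # {"impure", "pure"}
    background_mass_pg: float = 0.0
    filling_mass_pg: float = 0.0
    filling_lengths: tuple[int, ...] = BSTPI_FRAGMENT_LENGTHS
    hap_bias: float = 0.5
    dropout_fraction: float = 0.0
    dropout_hap: int = 2
    background_genome_bp: int = 200_000
    background_fragment_bp: tuple[int, int] = (20_000, 50_000)

    def __post_init__(self) -> None:
        for name in ("target_mass_pg", "background_mass_pg", "filling_mass_pg"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0.0 <= self.hap_bias <= 1.0:
            raise ParameterError("hap_bias must be in [0, 1]")
        if not 0.0 <= self.dropout_fraction <= 1.0:
            raise ParameterError("dropout_fraction must be in [0, 1]")
        if self.purity_class not in ("impure", "pure"):
            raise ParameterError("purity_class must be 'impure' or 'pure'")
        if self.dropout_hap not in (1, 2):
            raise ParameterError("dropout_hap must be 1 or 2")


@dataclass(frozen=True, slots=True)
class Molecule:
    """One long DNA molecule in the barcoding reaction.

    The sequence is not materialised (pools can hold millions of
    molecules); it is extracted lazily from the owning
    :class:`FragmentPool` via :meth:`FragmentPool.molecule_sequence`.
    """

    molecule_id: int
    source: str       # {"target_hap1", "target_hap2", "background", "filling"}
    source_id: str    # locus id, "background", or filling-fragment contig
    start: int        # 0-based half-open interval on the source sequence
    end: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class FragmentPool:
    """All molecules of one experiment plus the sequences behind them."""

    molecules: list[Molecule]
    loci: dict[str, DiploidLocus]
    background_seq: str | None = None
    filling_seqs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_id = {m.molecule_id: m for m in self.molecules}

    def molecule(self, molecule_id: int) -> Molecule:
        return self._by_id[molecule_id]

    def references(self) -> dict[str, str]:
        """Reference contigs for mapping: locus refs, background, filling."""
        refs = {lid: loc.ref_seq for lid, loc in self.loci.items()}
        if self.background_seq is not None:
            refs["background"] = self.background_seq
        refs.update(self.filling_seqs)
        return refs

    def molecule_sequence(self, mol: Molecule) -> str:
        if mol.source == "target_hap1":
            src = self.loci[mol.source_id].haplotype_seq(1)
        elif mol.source == "target_hap2":
            src = self.loci[mol.source_id].haplotype_seq(2)
        elif mol.source == "background":
            src = self.background_seq
        elif mol.source == "filling":
            src = self.filling_seqs[mol.source_id]
        else:
            raise ParameterError(f"unknown molecule source {mol.source!r}")
        return src[mol.start:mol.end]


@dataclass
class BeadAssignment:
    """One occupied microbead: its barcode and the molecules it captured."""

    barcode: str
    molecule_ids: list[int]
    retained: bool = True


@dataclass
class BeadSet:
    """All occupied beads of a loading experiment.

    ``lam`` is the realised mean load |pool| / n_beads; beads with zero
    molecules are not stored but are implied by ``n_beads``.
    """

    n_beads: int
    lam: float
    beads: list[BeadAssignment]

    def occupancy_counts(self) -> np.ndarray:
        """Histogram of molecules-per-bead including empty beads."""
        occ = np.array([len(b.molecule_ids) for b in self.beads], dtype=int)
        counts = np.bincount(occ) if occ.size else np.zeros(1, dtype=int)
        counts = counts.copy()
        if counts.size == 0:
            counts = np.zeros(1, dtype=int)
        counts[0] = self.n_beads - len(self.beads)
        return counts


@dataclass(frozen=True, slots=True)
class ReadTruth:
    molecule_id: int
    r1_offset: int       # 0-based offset of R1 on the molecule
    r2_offset: int       # 0-based offset of the R2 segment on the molecule
    true_barcode: str
    is_pcr_duplicate: bool


@dataclass(slots=True)
class ReadPair:
    """A barcoded paired-end read with full truth provenance."""

    read_id: str
    r1_seq: str
    r2_seq: str
    observed_barcode: str
    truth: ReadTruth

    @property
    def qual(self) -> str:
        # Base qualities are constant by design: no analysis here uses them.
        return "I" * len(self.r1_seq)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def make_diploid_locus(
    length_bp: int,
    mean_het_spacing_bp: float,
    seed: int,
    locus_id: str = "locus",
) -> DiploidLocus:
    """Random diploid locus with geometrically spaced heterozygous SNVs.

    Inter-site distances are geometric with the given mean, i.e. het
    sites form a renewal (Bernoulli) process along the sequence, which
    matches the ~1 site per 1-2 kb density of human genomes when called
    with spacings in that range.
    """
    if length_bp < 100:
        raise ParameterError("length_bp must be >= 100")
    if mean_het_spacing_bp <= 0:
        raise ParameterError("mean_het_spacing_bp must be > 0")
    rng = np.random.default_rng(seed)
    ref_seq = _random_seq(rng, length_bp)
    het_sites: list[tuple[int, str, str]] = []
    pos = int(rng.geometric(1.0 / mean_het_spacing_bp)) - 1
    while pos < length_bp:
        ref_base = ref_seq[pos]
        alt = _BASES[(_BASES.index(ref_base) + int(rng.integers(1, 4))) % 4]
        if rng.random() < 0.5:
            het_sites.append((pos, ref_base, alt))
        else:
            het_sites.append((pos, alt, ref_base))
        pos += int(rng.geometric(1.0 / mean_het_spacing_bp))
    return DiploidLocus(locus_id=locus_id, ref_seq=ref_seq, het_sites=het_sites)


def make_locus_with_sites(
    length_bp: int,
    het_positions: list[int],
    seed: int,
    locus_id: str = "locus",
) -> DiploidLocus:
    """Diploid locus with heterozygous sites at explicit positions,
    e.g. the seven-site 13 kb amplicon layout built from
    ``SCN10A_SITE_SPACINGS``."""
    if length_bp < 100:
        raise ParameterError("length_bp must be >= 100")
    positions = sorted(set(int(p) for p in het_positions))
    if positions != sorted(het_positions):
        raise ParameterError("het positions must be unique")
    if positions and (positions[0] < 0 or positions[-1] >= length_bp):
        raise ParameterError("het positions outside the locus")
    rng = np.random.default_rng(seed)
    ref_seq = _random_seq(rng, length_bp)
    het_sites: list[tuple[int, str, str]] = []
    for pos in positions:
        ref_base = ref_seq[pos]
        alt = _BASES[(_BASES.index(ref_base) + int(rng.integers(1, 4))) % 4]
        if rng.random() < 0.5:
            het_sites.append((pos, ref_base, alt))
        else:
            het_sites.append((pos, alt, ref_base))
    return DiploidLocus(locus_id=locus_id, ref_seq=ref_seq, het_sites=het_sites)


def mass_to_molecules(mass_pg: float, length_bp: int) -> int:
    """Number of dsDNA molecules in ``mass_pg`` picograms of ``length_bp`` DNA.

    Uses 650 g/mol per base pair:
    N = round(mass_pg * 1e-12 * N_A / (length_bp * 650)).
    """
    if mass_pg < 0:
        raise ParameterError("mass_pg must be >= 0")
    if length_bp <= 0:
        raise ParameterError("length_bp must be > 0")
    return int(round(mass_pg * 1e-12 * AVOGADRO / (length_bp * GRAMS_PER_MOL_PER_BP)))


def build_fragment_pool(
    loci: list[DiploidLocus],
    composition: SampleComposition,
    seed: int,
    count_scale: float = 1.0,
) -> FragmentPool:
    """Assemble the molecule pool for one barcoding reaction.

    Target molecules are full-length copies of each locus, split between
    haplotypes by ``hap_bias`` and thinned on ``dropout_hap`` by
    ``dropout_fraction``.  Background molecules are random fragments of
    a separate random genome.  Filling molecules follow the digest's
    equimolar rule: each genome copy contributes one molecule of every
    fragment length.

    ``count_scale`` scales all molecule counts; picogram inputs imply
    ~1e6 molecules, so desk-scale runs use a small scale factor while
    keeping the mass arithmetic exact.
    """
    ids = {loc.locus_id for loc in loci}
    if len(ids) != len(loci):
        raise ParameterError("loci must have unique ids")
    if not loci and composition.target_mass_pg > 0:
        raise ParameterError("nonzero target mass with no loci")
    rng = np.random.default_rng(seed)
    molecules: list[Molecule] = []
    next_id = 0

    for loc in loci:
        n = int(round(count_scale * mass_to_molecules(composition.target_mass_pg,
                                                      loc.length_bp)))
        n1 = int(rng.binomial(n, composition.hap_bias))
        n2 = n - n1
        if composition.dropout_fraction > 0:
            keep = 1.0 - composition.dropout_fraction
            if composition.dropout_hap == 1:
                n1 = int(rng.binomial(n1, keep))
            else:
                n2 = int(rng.binomial(n2, keep))
        for hap, count in ((1, n1), (2, n2)):
            for _ in range(count):
                molecules.append(Molecule(next_id, f"target_hap{hap}",
                                          loc.locus_id, 0, loc.length_bp))
                next_id += 1

    background_seq = None
    if composition.background_mass_pg > 0:
        background_seq = _random_seq(rng, composition.background_genome_bp)
        lo, hi = composition.background_fragment_bp
        lo = min(lo, composition.background_genome_bp)
        hi = min(hi, composition.background_genome_bp)
        mean_len = (lo + hi) / 2
        n = int(round(count_scale * mass_to_molecules(composition.background_mass_pg,
                                                      int(mean_len))))
        for _ in range(n):
            frag_len = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, composition.background_genome_bp - frag_len + 1))
            molecules.append(Molecule(next_id, "background", "background",
                                      start, start + frag_len))
            next_id += 1

    filling_seqs: dict[str, str] = {}
    if composition.filling_mass_pg > 0:
        total_bp = sum(composition.filling_lengths)
        copies = int(round(count_scale * mass_to_molecules(composition.filling_mass_pg,
                                                           total_bp)))
        for frag_len in composition.filling_lengths:
            name = f"filling_{frag_len}bp"
            filling_seqs[name] = _random_seq(rng, frag_len)
            for _ in range(copies):
                molecules.append(Molecule(next_id, "filling", name, 0, frag_len))
                next_id += 1

    return FragmentPool(molecules=molecules,
                        loci={loc.locus_id: loc for loc in loci},
                        background_seq=background_seq,
                        filling_seqs=filling_seqs)


def _random_barcodes(rng: np.random.Generator, n: int) -> list[str]:
    """Distinct random 18-mers (collision probability ~n^2/4^18 is negligible,
    but uniqueness is enforced anyway)."""
    bases = np.array(list(_BASES))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = bases[rng.integers(0, 4, ((n - len(out)), BARCODE_LENGTH))]
        for row in block:
            bc = "".join(row)
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def assign_beads(
    pool: FragmentPool | list[Molecule],
    n_beads: int,
    bead_subsample_fraction: float = 1.0,
    seed: int = 0,
) -> BeadSet:
    """Load molecules onto beads uniformly at random (Poisson loading).

    With |pool| molecules and ``n_beads`` beads the per-bead load is
    Poisson with lambda = |pool| / n_beads.  Only a Bernoulli
    ``bead_subsample_fraction`` of beads is retained for read
    generation, mirroring the indexing of a fraction of the bead
    solution.
    """
    if n_beads < 1:
        raise ParameterError("n_beads must be >= 1")
    if not 0.0 < bead_subsample_fraction <= 1.0:
        raise ParameterError("bead_subsample_fraction must be in (0, 1]")
    molecules = pool.molecules if isinstance(pool, FragmentPool) else pool
    rng = np.random.default_rng(seed)
    bead_of = rng.integers(0, n_beads, len(molecules))
    groups: dict[int, list[int]] = {}
    for mol, b in zip(molecules, bead_of):
        groups.setdefault(int(b), []).append(mol.molecule_id)
    occupied = sorted(groups)
    barcodes = _random_barcodes(rng, len(occupied))
    keep = rng.random(len(occupied)) < bead_subsample_fraction
    beads = [
        BeadAssignment(barcode=bc, molecule_ids=groups[b], retained=bool(k))
        for b, bc, k in zip(occupied, barcodes, keep)
    ]
    lam = len(molecules) / n_beads
    return BeadSet(n_beads=n_beads, lam=lam, beads=beads)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if hits.size == 0:
        return seq
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = base_codes[base_codes != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def generate_reads(
    assignment: BeadSet,
    pool: FragmentPool,
    reads_per_kb: float,
    read_len: int = DEFAULT_READ_LENGTH,
    sub_error_rate: float = 0.0,
    barcode_error_rate: float = 0.0,
    pcr_dup_rate: float = 0.0,
    seed: int = 0,
    max_insert: int = 500,
) -> list[ReadPair]:
    """Emit barcoded paired-end reads from molecules on retained beads.

    Each molecule yields Poisson(reads_per_kb * L/1000) pairs placed
    uniformly, with insert sizes uniform in [2*read_len, max_insert].
    Substitutions are i.i.d. per base; with probability
    ``barcode_error_rate`` one random base of the emitted barcode is
    substituted.  PCR duplicates are exact re-emissions of an existing
    pair (same coordinates, sequences and observed barcode) flagged in
    the truth record.
    """
    for name, rate in (("sub_error_rate", sub_error_rate),
                       ("barcode_error_rate", barcode_error_rate),
                       ("pcr_dup_rate", pcr_dup_rate)):
        if not 0.0 <= rate < 1.0:
            raise ParameterError(f"{name} must be in [0, 1)")
    if read_len < 20:
        raise ParameterError("read_len must be >= 20")
    rng = np.random.default_rng(seed)
    reads: list[ReadPair] = []
    n_skipped = 0
    serial = 0
    for bead in assignment.beads:
        if not bead.retained:
            continue
        for mid in bead.molecule_ids:
            mol = pool.molecule(mid)
            L = mol.length_bp
            if L < 2 * read_len:
                n_skipped += 1
                continue
            seq = pool.molecule_sequence(mol)
            n_pairs = int(rng.poisson(reads_per_kb * L / 1000.0))
            for _ in range(n_pairs):
                insert = int(rng.integers(2 * read_len, min(max_insert, L) + 1))
                start = int(rng.integers(0, L - insert + 1))
                r1 = seq[start:start + read_len]
                r2 = revcomp(seq[start + insert - read_len:start + insert])
                r1 = _mutate(rng, r1, sub_error_rate)
                r2 = _mutate(rng, r2, sub_error_rate)
                obs_bc = bead.barcode
                if barcode_error_rate > 0 and rng.random() < barcode_error_rate:
                    i = int(rng.integers(0, BARCODE_LENGTH))
                    repl = _BASES[(_BASES.index(obs_bc[i]) + int(rng.integers(1, 4))) % 4]
                    obs_bc = obs_bc[:i] + repl + obs_bc[i + 1:]
                truth = ReadTruth(mid, start, start + insert - read_len,
                                  bead.barcode, False)
                pair = ReadPair(f"read{serial:08d}", r1, r2, obs_bc, truth)
                serial += 1
                reads.append(pair)
                if pcr_dup_rate > 0 and rng.random() < pcr_dup_rate:
                    dup_truth = ReadTruth(mid, start, start + insert - read_len,
                                          bead.barcode, True)
                    reads.append(ReadPair(f"read{serial:08d}", r1, r2,
                                          obs_bc, dup_truth))
                    serial += 1
    if n_skipped:
        logger.warning("skipped %d molecules shorter than 2*read_len=%d",
                       n_skipped, 2 * read_len)
    return reads


def write_truth_set(
    loci: list[DiploidLocus],
    pool: FragmentPool,
    assignment: BeadSet,
    reads: list[ReadPair],
    out_dir,
) -> dict[str, str]:
    """Write the experiment to disk: reference FASTA, target BED, truth
    phased VCF, bead-to-molecule table, and the FASTQ trio (R1/R2/I1).
    Returns a name -> path mapping."""
    from pathlib import Path

    from . import io as bio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    refs = pool.references()
    paths = {
        "reference": str(out / "reference.fasta"),
        "targets": str(out / "targets.bed"),
        "truth_vcf": str(out / "truth.vcf"),
        "beads": str(out / "beads.tsv"),
        "r1": str(out / "reads_R1.fastq.gz"),
        "r2": str(out / "reads_R2.fastq.gz"),
        "i1": str(out / "reads_I1.fastq.gz"),
    }
    bio.write_fasta(paths["reference"], refs)
    bio.write_bed(paths["targets"],
                  [(loc.locus_id, 0, loc.length_bp) for loc in loci])
    records = []
    for loc in loci:
        if not loc.het_sites:
            continue
        ps = loc.het_sites[0][0] + 1
        for pos, a1, a2 in loc.het_sites:
            ref_base = loc.ref_seq[pos]
            alt = a2 if a1 == ref_base else a1
            gt = (0, 1) if a1 == ref_base else (1, 0)
            records.append(bio.PhasedRecord(loc.locus_id, pos, ref_base, alt,
                                            gt=gt, phased=True, ps=ps))
    contig_lengths = {name: len(seq) for name, seq in refs.items()}
    bio.write_phased_vcf(paths["truth_vcf"], records, contig_lengths)
    with open(paths["beads"], "w") as fh:
        fh.write("# beadphase bead-truth v1\n")
        fh.write("barcode\tretained\tmolecule_ids\n")
        for bead in assignment.beads:
            fh.write(f"{bead.barcode}\t{int(bead.retained)}\t"
                     + ",".join(map(str, bead.molecule_ids)) + "\n")
    bio.write_fastq_trio(paths["r1"], paths["r2"], paths["i1"], reads)
    return paths
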