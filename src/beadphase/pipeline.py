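"""End-to-end glue: simulate an experiment, run the processing chain
(trim -> barcode-correct -> map -> dedup -> genotype -> phase), and
evaluate against truth.

Every stage logs its in/out counts so a run's accounting (reads,
barcodes, sites, blocks) can be reconstructed from the logs alone.
Stage randomness derives from the single config seed via stable
per-stage offsets.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, align, evaluation, io, metrics, phasing, preprocess
from . import simulate as sim
from .config import PipelineConfig

logger = logging.getLogger(__name__)


def derive_seed(seed: int, label: str) -> int:
    """Stable per-stage sub-seed below 2**31."""
    return (seed ^ zlib.crc32(label.encode())) % (2 ** 31)


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------

@dataclass
class SimulatedExperiment:
    loci: list[sim.DiploidLocus]
    pool: sim.FragmentPool
    beads: sim.BeadSet
    reads: list[sim.ReadPair]

    def references(self) -> dict[str, str]:
        return self.pool.references()

    def targets(self) -> list[tuple[str, int, int]]:
        return [(loc.locus_id, 0, loc.length_bp) for loc in self.loci]

    def truth_phase_set(self) -> dict:
        """Benchmark-style phase set from the truth haplotypes."""
        out = {}
        for loc in self.loci:
            if not loc.het_sites:
                continue
            ps = loc.het_sites[0][0] + 1
            for pos, a1, a2 in loc.het_sites:
                out[(loc.locus_id, pos)] = evaluation.VariantPhase(
                    loc.locus_id, pos, (a1, a2), True, ps)
        return out


def simulate_experiment(config: PipelineConfig,
                        loci: list[sim.DiploidLocus] | None = None
                        ) -> SimulatedExperiment:
    """Generate loci, molecule pool, bead loading and reads per config.

    Pass ``loci`` to use pre-built loci (e.g. with explicit het-site
    positions) instead of drawing them from the config's locus specs."""
    p = config.simulation
    if loci is None:
        loci = [
            sim.make_diploid_locus(spec.length_bp, spec.mean_het_spacing_bp,
                                   derive_seed(config.seed, f"locus:{spec.locus_id}"),
                                   locus_id=spec.locus_id)
            for spec in p.loci
        ]
    pool = sim.build_fragment_pool(loci, p.composition,
                                   derive_seed(config.seed, "pool"),
                                   count_scale=p.count_scale)
    beads = sim.assign_beads(pool, p.n_beads, p.bead_subsample_fraction,
                             derive_seed(config.seed, "beads"))
    reads = sim.generate_reads(beads, pool, p.reads_per_kb, p.read_len,
                               p.sub_error_rate, p.barcode_error_rate,
                               p.pcr_dup_rate,
                               derive_seed(config.seed, "reads"))
    logger.info("simulated %d loci, %d molecules, %d occupied beads "
                "(lambda=%.3f), %d read pairs",
                len(loci), len(pool.molecules), len(beads.beads),
                beads.lam, len(reads))
    return SimulatedExperiment(loci, pool, beads, reads)


def run_simulation(config: PipelineConfig, out_dir) -> dict[str, str]:
    """Simulate and write the full truth set plus a manifest."""
    exp = simulate_experiment(config)
    paths = sim.write_truth_set(exp.loci, exp.pool, exp.beads, exp.reads,
                                out_dir)
    manifest = {
        "package": "beadphase",
        "version": __version__,
        "seed": config.seed,
        "n_molecules": len(exp.pool.molecules),
        "n_occupied_beads": len(exp.beads.beads),
        "n_read_pairs": len(exp.reads),
        "outputs": paths,
    }
    manifest_path = str(Path(out_dir) / "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = manifest_path
    return paths


# ---------------------------------------------------------------------------
# Processing chain
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    aligned_reads: list[align.AlignedRead]
    barcode_table: preprocess.BarcodeTable
    calls: list[align.GenotypeCall]
    matrix: phasing.FragmentMatrix
    phase_result: phasing.PhaseResult
    phased_records: list[io.PhasedRecord]
    recovery: metrics.RecoveryReport
    counters: dict[str, float] = field(default_factory=dict)

    def het_calls(self) -> list[align.GenotypeCall]:
        return [c for c in self.calls if c.is_het]

    def phase_set(self) -> dict:
        return phase_set_from_records(self.phased_records)


def phase_set_from_records(records: list[io.PhasedRecord]) -> dict:
    out = {}
    for rec in records:
        alleles = [rec.ref_allele] + rec.alt_alleles.split(",")
        pair = (alleles[rec.gt[0]], alleles[rec.gt[1]])
        out[(rec.ref_id, rec.pos)] = evaluation.VariantPhase(
            rec.ref_id, rec.pos, pair, rec.phased, rec.ps)
    return out


def process_reads(read_pairs: list[sim.ReadPair],
                  references: dict[str, str] | align.ReferenceIndex,
                  targets: list[tuple[str, int, int]],
                  config: PipelineConfig) -> PipelineResult:
    """Run the full processing chain on read pairs, in memory."""
    proc = config.processing

    trimmed = []
    for pair in read_pairs:
        r1 = preprocess.trim_adapters(pair.r1_seq, preprocess.R1_ADAPTERS,
                                      proc.min_overlap)
        r2 = preprocess.trim_adapters(pair.r2_seq, preprocess.R2_ADAPTERS,
                                      proc.min_overlap)
        if r1 is pair.r1_seq and r2 is pair.r2_seq:
            trimmed.append(pair)
        else:
            trimmed.append(sim.ReadPair(pair.read_id, r1, r2,
                                        pair.observed_barcode, pair.truth))
    logger.info("trim: %d read pairs in/out", len(trimmed))

    counts: dict[str, int] = {}
    for pair in trimmed:
        counts[pair.observed_barcode] = counts.get(pair.observed_barcode, 0) + 2
    table = preprocess.correct_barcodes(counts)
    logger.info("barcode correction: %d observed barcodes, %d corrected",
                len(counts), table.n_corrected)

    aligned = align.map_reads(trimmed, references, proc.seed_k,
                              barcode_table=table)
    n_mapped = sum(1 for r in aligned if r.mapped)
    logger.info("map: %d/%d read ends mapped", n_mapped, len(aligned))

    preprocess.mark_duplicates(aligned)
    n_dup = sum(1 for r in aligned if r.is_dup)
    logger.info("dedup: %d read ends flagged as within-barcode duplicates",
                n_dup)

    ref_seqs = (references.references
                if isinstance(references, align.ReferenceIndex) else references)
    calls: list[align.GenotypeCall] = []
    for ref, start, end in targets:
        pile = align.pileup_counts(aligned, (ref, start, end))
        calls.extend(align.call_genotypes(pile, ref_seqs[ref],
                                          proc.af_cutoff, proc.min_depth))
    n_het = sum(1 for c in calls if c.is_het)
    logger.info("genotype: %d calls, %d het", len(calls), n_het)

    matrix = phasing.build_fragment_matrix(aligned, calls, proc.phasing)
    result = phasing.phase_blocks(matrix, proc.phasing)
    records = phasing.emit_phased_variants(calls, result)
    logger.info("phase: %d/%d het sites phased in %d blocks",
                len(result.assignment), matrix.n_sites, len(result.blocks))

    recovery = metrics.target_recovery(aligned, targets)
    counters = {
        "read_pairs": len(read_pairs),
        "mapped_ends": n_mapped,
        "duplicate_ends": n_dup,
        "het_sites": n_het,
        "phased_sites": len(result.assignment),
        "phase_blocks": len(result.blocks),
        "on_target_pct": recovery.on_target_pct,
        "mean_coverage": recovery.mean_coverage,
    }
    return PipelineResult(aligned, table, calls, matrix, result, records,
                          recovery, counters)


def run_pipeline(r1_path, r2_path, i1_path, reference_fasta, targets_bed,
                 config: PipelineConfig, out_dir) -> PipelineResult:
    """File-based entry point: FASTQ trio in, phased VCF and reports out."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    references = io.read_fasta(reference_fasta)
    targets = io.read_bed(targets_bed)
    pairs = io.read_fastq_trio(r1_path, r2_path, i1_path)
    result = process_reads(pairs, references, targets, config)
    contig_lengths = {name: len(seq) for name, seq in references.items()}
    io.write_phased_vcf(out / "phased.vcf", result.phased_records,
                        contig_lengths)
    io.write_sam_tsv(out / "aligned.tsv", result.aligned_reads)
    io.write_summary(out / "summary.tsv", result.counters)
    logger.info("pipeline done: on-target %.2f%%, mean coverage %.1fx, "
                "%d blocks", result.recovery.on_target_pct,
                result.recovery.mean_coverage, len(result.phase_result.blocks))
    return result


# ---------------------------------------------------------------------------
# Evaluation glue
# ---------------------------------------------------------------------------

def evaluate_against_truth(result: PipelineResult,
                           exp: SimulatedExperiment) -> evaluation.EvalReport:
    return evaluation.compare_phasing(exp.truth_phase_set(),
                                      result.phase_set())


def make_titration_analyzer(references, targets, config: PipelineConfig,
                            benchmark: dict):
    """Build the per-cell analysis for :func:`evaluation.coverage_titration`:
    full pipeline re-run, then scoring against the benchmark."""
    index = references if isinstance(references, align.ReferenceIndex) \
        else align.ReferenceIndex(references, config.processing.seed_k)

    def analyze(read_subset):
        result = process_reads(read_subset, index, targets, config)
        report = evaluation.compare_phasing(benchmark, result.phase_set())
        return report, result.recovery.mean_coverage

    return analyze
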