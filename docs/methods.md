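# Methods

## What the simulator models

The generator emulates a single-tube microbead co-barcoding (linked-
read) library built from a small number of enriched targets, with the
whole causal chain kept explicit so every downstream estimator can be
validated against truth.

**Loci.** A diploid locus is a random A/C/G/T sequence with
heterozygous SNVs placed by a renewal process: inter-site distances are
geometric with a configurable mean (default 1.5 kb, the human-typical
1–2 kb density). At each site one allele equals the reference base and
the haplotype carrying it is chosen at random, so truth genotypes are
an unbiased mix of `0|1` and `1|0`. Loci can also be built with
explicit site positions; the packaged seven-site layout for a 13 kb
amplicon uses the spacings 288, 4299, 23, 69, 5560, 2505 bp.

**Sample composition.** Inputs are masses in picograms, converted to
molecule counts with 650 g/mol per base pair:
`N = round(mass_pg · 1e−12 · 6.022e23 / (length · 650))`. Target
molecules are full-length copies of each locus (amplicons and excised
fragments are delivered intact), split between haplotypes by
`hap_bias` (default 0.5) and optionally thinned on one haplotype by
`dropout_fraction`, which models amplification dropout or inversion
mosaicism. Background (off-target) molecules are 20–50 kb fragments of
a separate random genome (default 200 kb), which is included in the
mapping reference so background reads map *off-target* rather than
failing to map. Filling DNA follows the restriction-digest rule: the
digest is equimolar, each genome copy contributing one molecule of
every fragment; the packaged table is the fourteen BstP I lambda
fragments (117…8453 bp, totalling 48 502 bp). Amplicon pools, by
contrast, use equal *masses* per target, so smaller targets contribute
proportionally more molecules.

Picogram inputs imply ~10⁶ molecules. A `count_scale` factor (default
1.0) scales all counts uniformly so that desk-scale runs — a few
hundred molecules, chosen as the package's working problem size — keep
the mass arithmetic and all ratios exact. The bead load λ is therefore
controlled directly through pool size and `n_beads`; the real assay's
effective λ is not derivable from bead counts alone and is exposed as
a parameter.

**Bead loading.** Molecules land on beads uniformly at random, the
minimal exchangeable model, giving Poisson(λ) occupancy (verified by
chi-square in the tests). Barcodes are distinct random 18-mers. A
Bernoulli `bead_subsample_fraction` models indexing only part of the
bead solution; only retained beads emit reads.

**Reads.** Each molecule yields Poisson(reads_per_kb · L/1000) pairs
of 2×145 bp reads placed uniformly with insert sizes uniform in
[290, 500] bp. Substitution errors are i.i.d. per base; with
probability `barcode_error_rate` one base of the emitted barcode is
substituted (single substitutions only — the reach of the correction
rule). PCR duplicates are exact re-emissions of an existing pair with
the same coordinates and observed barcode, so within-barcode dedup can
be validated exactly. Base qualities are constant ("I"): no analysis
in this package uses them. Molecules shorter than two read lengths
emit nothing (logged); this reproduces the loss of the 117 bp digest
fragment in short-fragment pools.

**What is not modelled.** Quality-score structure, indels (variants
and errors), transposase insertion bias, adapter read-through
chimeras, PCR chimeras between haplotypes, and any calibration from
input mass to the real assay's collision rate. Passing tests therefore
demonstrate correctness of the estimators and the phasing machinery
under the stated generative model, not the numeric collision or
efficiency levels of any physical assay.

## Processing chain

1. **Adapter trimming** — exact-match removal of 3' adapters (three R1
   sequences, one R2 sequence) with minimum overlap 5 nt; a full
   internal occurrence truncates from the match start. No mismatch
   tolerance: only the minimum-overlap behaviour is specified for this
   protocol, and exactness keeps the operation auditable.
2. **Barcode correction** — a barcode seen on exactly one read with
   exactly one multi-read (count ≥ 2) barcode at Hamming distance 1 is
   reassigned to it. Ambiguous singletons (≥ 2 candidate neighbours)
   stay uncorrected: the conservative choice, avoiding false merges.
   "Multi-read" is read minimally as count ≥ 2.
3. **Mapping** — a substitution-only k-mer seed mapper (k = 21, ~7
   seeds per read, both strands): the position with most exact seed
   votes wins; ties and zero hits are unmapped. This suffices because
   the simulator emits no indels; real data can enter through the SAM
   importer with externally produced alignments instead.
4. **Duplicate marking** — within each corrected barcode, read pairs
   sharing (reference, R1 start, R2 start, orientation) beyond the
   first are flagged; the first in a stable sort by read id is kept
   for determinism. Equal coordinates under different barcodes are
   independent molecules and are never flagged.
5. **Genotyping** — per-position A/C/G/T counts from aligned,
   non-duplicate bases (CIGAR-projected); a site is heterozygous iff
   its two top bases both reach allele fraction ≥ 0.1 at depth ≥
   `min_depth` (default 10 — the smallest depth at which a 0.1 cutoff
   is meaningful). Otherwise the site is homozygous for the majority
   base. This is a declared rule, not an emulation of any specific
   caller's internals. Haplotype dropout surfaces here naturally: a
   90% dropout pushes the minor fraction below the cutoff and het
   sites are miscalled homozygous.
6. **Phasing** — see README for the MEC formulation. Numerical
   choices: symmetric per-observation error rate 0.02 (the simulator's
   per-base error rates are well below this; the value mostly sets the
   log-odds scale, c ≈ 3.2 per consistent row); prune threshold 6.0,
   chosen in (c, 2c] so one supporting barcode can never phase a pair
   while two concordant barcodes can; link distance 40 kb (typical
   molecule length); spanning-tree ties broken by (weight, site
   position); blocks of ≤ 10 sites solved exhaustively over 2^(n−1)
   assignments, larger blocks by iterated single-site flips; a site
   whose flip changes the block MEC by < 1 is reported unphased;
   blocks are canonically oriented by giving the first site's first
   allele to haplotype 1, and a block needs ≥ 2 phased sites.
   Collisions are not detected at phasing time — a maternal+paternal
   collision simply contributes conflicting rows, as in the real
   assay, where the mitigation is experimental (input mass), not
   algorithmic.

## Metrics and evaluation

**Collisions.** A barcode associates with every fragment receiving
≥ 2 of its non-duplicate reads (midpoint rule — one read is weak
evidence, and midpoints avoid edge double-counting; neither counting
rule is externally specified, so both are declared here). Collision-
free = exactly one association. Two molecules of the *same* fragment
on one bead are invisible to this estimator, by construction; the
truth comparison in the tests adopts the same convention.

**Linked-read efficiency.** Restricted to non-multi-fragment barcodes;
a read is linked iff its barcode carries ≥ 2 non-duplicate *templates*
(read ids) on the fragment — the two mates of a single pair do not
link anything by themselves.

**Allele burden.** Per het site, fractions of the two annotated
alleles among reads carrying either; other bases are tallied
separately. A mean minor fraction < 0.2 (midway between the balanced
≈ 0.5 and dropout ≈ 0.08 regimes) flags putative dropout.

**Switch/flip decomposition.** An exact two-state DP over the per-site
disagreement vector: a switch toggles the orientation parity between
consecutive sites (cost 1), a flip pays 1 where the vector disagrees
with the parity; the global orientation is free. Ties prefer fewer
switches. The DP equals exhaustive enumeration (tested for all
patterns up to 8 sites). For the "correctly phased" tally a flip
counts one incorrect site and a switch marks the downstream sites
incorrect, matching per-site accounting of published accuracy figures.
Both accuracy denominators — annotated sites and recalled sites — are
reported, since both conventions appear in practice.

**De novo sites.** A site phased by the method but absent/unphased in
the benchmark is *confirmed* when ≥ 2 replicates phase it identically
relative to shared benchmark-phased sites (erroneous phasing is
non-reproducible); without replicates it is reported unconfirmed.

**Quality groups.** Group 4: > 50% of recalled sites unphased ("mostly
unphased" needs a number; 50% is the declared one). Group 3: any
missed-genotype site, ≠ 1 block, or > 1 flip+switch. Group 2: exactly
one flip or switch with a single block and full recall. Group 1:
error-free single block. The titration reruns the full pipeline
(dedup re-applied) at each fraction of the ladder
{0.5, 0.25, 0.125, 0.0625, 0.03125, 0.0156, 0.0078}.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen as the
package's standard working sizes: ~400–550 molecules per amplicon
experiment (count_scale ≈ 3e−4 on 20 pg), 180–400× target coverage,
500–900 counted barcodes per collision estimate, 20 seeds for the
phasing-correctness property, 8–10 subsampling seeds for titration.
Statistical assertions use 3σ binomial/Poisson bands at these sizes.

## Known limitations

* The mapper is substitution-only and unsuitable for indel-bearing or
  repetitive references; import external alignments for real data.
* The MEC refinement is exhaustive only for blocks ≤ 10 sites; larger
  blocks get a local optimum (greedy tree + single-site flips).
* The collision estimator's same-fragment blindness biases it upward
  at high loads of low-diversity pools; this matches the measurement
  convention, not the physical truth.
* Masses map to molecule counts deterministically (no pipetting or
  capture-efficiency variance), so yield variability between
  replicates is not represented.
* De novo confirmation requires replicates generated under the same
  reference; cross-library barcode structure is not modelled.
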