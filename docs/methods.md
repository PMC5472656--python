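# Methods

This note documents the models, parameter choices and numerical conventions
behind `slatyper`, and what the synthetic-data tests do and do not establish
about real sequencing runs.

## In-silico PCR and resolvability

Primer matching is exact outside IUPAC-degenerate positions (Y = C/T,
R = A/G, ...). Zero mismatch tolerance is deliberate: the universal primers
are designed in conserved stretches, and exact matching reproduces both the
method's normal behaviour and its documented failure mode (an animal whose
template has diverged under a primer produces a mis-sized or absent product
and is reported typing-failed, not silently mistyped). When a primer site
occurs more than once, the 5′-most match wins on each side — deterministic,
and consistent with the dominance of the outermost priming site in PCR.

An amplicon records the primer-binding regions, but all sequence comparison
(clustering, typing, resolvability) operates on the *insert* with primers
stripped: bases under a primer are dictated by the primer, not the template,
so they carry no allelic information. Resolvability classifies each amplified
allele as `unique` (no other allele shares its insert) or `group`
(equivalence class of identical inserts, labelled by the sorted member names
joined with `/`); fractions are percentages of amplified alleles, and
unamplified alleles are reported separately. Coordinates throughout are
1-based inclusive.

Published figures for the real reference library (68% of known alleles
uniquely resolved by the 320-nt amplicon, 88% by the 510-nt one) depend on a
specific library snapshot and are not recomputed here; the package instead
verifies the defining property — lengthening the amplicon can only split,
never merge, insert equivalence classes, so the unique fraction is monotone
in amplicon extent.

## Read pipeline

Stage order: demultiplex → quality trim → join → dereplicate → size filter →
chimera flagging → cap at the 20 largest non-chimeric clusters → length /
artifact filter.

* **Demultiplexing** requires mate 1 to begin with a sample's exact 6-nt
  barcode followed by the forward primer and mate 2 the same barcode followed
  by the reverse primer. Barcode matching is exact; with barcode sets at
  pairwise Hamming distance ≥ 2 this gives zero cross-talk, and random
  (spike-in) sequence essentially never passes the additional 18–19-nt primer
  check. Rejects are tallied by reason (`no_barcode`, `barcode_conflict`,
  `no_primer`) — they are data for the run's loss accounting, not errors.
* **Trimming** removes the maximal prefix and suffix of bases under Q17
  (98% call accuracy); interior low-quality bases are retained, since the
  merge consensus can still out-vote them.
* **Joining** scores every ungapped overlap of the reverse-complemented mate
  2 against mate 1 (computed exactly for all offsets via per-base
  cross-correlation). An overlap is admissible at ≥ 35 nt and ≥ 80%
  identity; the best identity wins, ties broken by longer overlap, then
  smaller shift, then smaller signed offset. The consensus takes the
  higher-quality base at mismatches (mate 1 on quality ties). Merged length
  is always len₁ + len₂ − overlap.
* **Dereplication** groups reads at 100% identity — one substitution, one
  cluster. Clusters are ranked by size (ties: lexicographic sequence).
  Clusters under 10 reads are discarded.
* **Chimera flagging** tests each cluster against all ordered pairs of
  same-length clusters at least twice its size. Because dereplication is at
  100% identity, a true PCR chimera is a *noise-free* single-crossover
  mosaic of its parents, so the model is accepted only at exact (100%)
  model identity, with neither parent alone identical to the candidate and
  at least 3 parent-diagnostic positions on each side of the crossover.
  This is a deliberate simplification of UCHIME's scoring (no abundance
  skew or vote fractions); it is exact in the regime the pipeline creates.
* **Artifact filter.** Clusters within ±15 nt of the expected insert length
  pass. Longer clusters with a stop codon in all three sense reading frames
  are alternative-splicing artifacts and are removed; any other off-length
  cluster is flagged `off_size` and excluded from typing but reported. A
  sample whose retained signal is dominated (≥ 50% of reads) by off-size
  clusters is reported typing-failed — the mis-sized-product failure mode.

"Dominant" clusters, used in reports and recovery tests, hold ≥ 5% of a
sample's retained reads; the threshold is a reporting convention, not a
filter.

## Typing

Identification is exact-insert lookup first (one name → `specific`, several
→ `group`), then best global alignment against all library inserts with unit
costs and free end gaps (amplicons share primer-anchored ends). Identity is
matches / alignment length, counting internal but not terminal gap columns;
hits at ≥ 95% identity but below 100% are `novel_candidate` with the closest
match and an x/y similarity, below 95% `unclassified`. Note that the optimal
alignment may absorb a terminal mismatch into a free end gap or bridge a
dense mismatch cluster with a gap pair, so reported identity can slightly
exceed the ungapped (Hamming) identity; for the isolated interior
substitutions that dominate real near-miss alleles the two coincide.

Identical novel sequences are pooled across samples into a registry with
stable ids (NS#1, NS#2, ... ordered by total read support, ties by
sequence). A novel observed in a single animal is labelled low-confidence:
recurrence across individuals — independent PCRs — is the argument against a
polymerase artifact.

Read fractions are computed within samples over retained clusters only, and
no cross-sample normalisation is attempted (library pooling makes absolute
depths incomparable). Group calls count as one carried allele; a locus with
one call is homozygous, with more than two calls duplicated.

## Haplotype inference

A haplotype is an allele set over the three loci (possibly empty at one —
a null locus — or with two alleles at one — a duplication). Inference is the
deterministic fixpoint of the defining rule: (1) every fully homozygous
animal (at most one distinct allele at *every* locus) seeds the pool;
(2) an unresolved animal is first tested for an exact decomposition into two
pool haplotypes, and otherwise any pool haplotype that is a sub-multiset of
its alleles proposes the residual as the complementary haplotype, accepted
when no locus exceeds `max_dup_per_locus` (default 2); (3) repeat to
fixpoint. Iteration order (animals by id, pool by discovery) makes the result
reproducible, and relabelling animals consistently does not change the pool.
An allele set that decomposes exactly into *three* pool haplotypes is
reported as a multi-haplotype anomaly rather than force-resolved; animals
with a contained haplotype but an inadmissible residual stay `partial`, the
rest `unresolved`. Known published haplotypes can be supplied as priors and
are consulted before new ids (`Hp-A.0`, `Hp-B.0`, ... in discovery order)
are assigned.

Prevalence is the carrier percentage (animals carrying the haplotype in any
slot, over animals with at least one call); chromosome frequency
(slots / 2N) is reported as a secondary column since carrier counts are what
expression data directly support. For a homozygous diplotype the called
alleles appear once each — expression data cannot show dosage — so
reconstruction checks compare support, not doubled multisets.

## Novel-allele characterisation

Exon 2–3 assembly joins two flanking amplicons onto the core sequence by
maximal exact suffix–prefix overlap (≥ 30 nt; containment collapses);
any disagreement in a claimed overlap is an error naming the junction and
first mismatching position — assembly never averages over conflicts.
Assembled length is data-driven; the conventional full-length exon spans
(exon 2 ending at nt 302, exon 3 at nt 578) only set completeness flags.

Jukes–Cantor distances d = −¾·ln(1 − 4p/3) exclude non-ACGT columns;
p ≥ 3/4 saturates to a cap of 5.0 substitutions/site with a flag. Neighbor
joining uses the standard Q criterion with two pinned conventions: ties are
broken by the lexicographically smallest representative-leaf pair, and a
negative branch length is clamped to zero with the deficit moved to its
sibling, preserving path lengths. Bootstrap supports are classic
Felsenstein column resampling attached to the point-estimate tree's
bipartitions (no consensus tree). Locus placement reads the smallest clade
enclosing the novel leaf whose other leaves are ≥ 90% one locus, reporting
that clade's support; without such a clade the nearest neighbour's locus is
used and flagged low-confidence. Spans under 100 nt are refused outright —
placement from short partial sequences is unreliable, which is also why the
purity threshold is below 100%: even good trees occasionally misplace single
reference alleles.

## Simulator

The generator emulates the data-generating process the pipeline assumes:
per-locus ancestral inserts diverged far more between loci (40 substitutions
from a common base) than within (6 substitutions from the locus ancestor),
embedded in templates carrying the real primer sites verbatim; haplotypes
with one allele per locus; both mates barcoded with the same sample barcode.
Defaults are the study conditions used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| `depth_per_allele` | 2000 | read pairs per allele before locus weighting |
| `locus_weights` | 1.0 / 1.5 / 0.3 | SLA-1 / SLA-2 / SLA-3 relative transcription |
| `error_rate` | 0.001 | mean per-base substitution probability |
| `q_start`, `q_end`, `q_jitter` | 37, 22, 3 | per-cycle Phred profile (linear decline, Gaussian jitter, clamped to [2, 40]) |
| `chimera_rate` | 0.02 | single-crossover two-parent mosaics, crossover uniform over insert positions 40..L−40 |
| `spikein_fraction` | 0.30 | barcode-free random pairs, emulating the PhiX fraction added for sequence diversity |
| `splice_variant_rate` | 0.01 | overlong templates (+120 nt) with stops in all frames |
| `read_length` | 250 | per mate, truncating the template |

Substitution errors are drawn per base from the realised quality, rescaled
so the profile's mean equals `error_rate` — quality and error rate stay
consistent without requiring a calibrated instrument model. Chimera and
splice rates are testability choices (their real-run counterparts were
reported as counts, not rates). All randomness flows from one seeded
generator; the ground-truth table reconciles exactly with the emitted read
count.

What the simulator does *not* model: indel sequencing errors, PCR-cycle
amplification bias, real PhiX genome content, primer-template mismatch
kinetics, or cross-sample index hopping. Passing recovery tests therefore
demonstrate the pipeline's logic and accounting, not robustness to
platform-specific artifacts beyond the modelled ones.

## Problem sizes and determinism

The shipped test suite runs the full study-conditions simulation (six
samples, 2,000 pairs per allele, ~80,000 read pairs) once and reuses it
across the acceptance checks; oracle-equivalence suites use libraries of up
to 50 alleles, trees of up to 6 taxa against exhaustive topology search
(105 topologies), and 100-seed haplotype-recovery replicates of 20 animals.
`scripts/acceptance.py` simulates one homozygous animal (~8,000 pairs)
end to end. Every stochastic component takes an explicit seed; identical
seeds give byte-identical FASTA/FASTQ and identical reports.
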