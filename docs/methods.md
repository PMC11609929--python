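# Methods

## Model and assumptions

The pipeline genotypes single cells for KRAS hotspot substitutions from a
targeted amplicon re-sequencing of a 10x Genomics 3′ v3 library. Its model
of the data is deliberately minimal:

* The amplicon covers codons 12–61 of the KRAS coding sequence plus enough
  flank to place full-length probes; coordinates are 0-based, half-open,
  with codon *c* mapping to amplicon position
  `cds_offset + 3·(c − first_target_codon)`.
* Variants are substitutions only (SNVs, or multi-nucleotide substitutions
  within one codon). Insertions and deletions are rejected at load time;
  matching is strictly ungapped, which is appropriate because the targeted
  KRAS hotspots (G12/G13/Q61) are substitutions.
* Reads sharing a (cell barcode, UMI) pair are PCR copies of one original
  cDNA molecule, so allele evidence is consolidated per UMI before any
  per-cell decision.
* Base qualities are ignored; the only error handling is the bounded
  Hamming mismatch budget and the UMI coverage/conflict filters.

## Probe (fishhook) design

Each variant yields one mutant and one paired wildtype 38-mer occupying the
same amplicon window. Placement **centers the probe on the variant's
differing base(s)** (for a single changed base at amplicon position *p*,
window start = `p − ⌊(38−1)/2⌋`, clamped so the window keeps full length at
the amplicon edges). Centering maximizes symmetric flanking context so that
clean seed k-mers exist on both sides of the discriminating base. The probe
window placement is a design choice of this package; only the probe length
itself (38) is fixed by the assay.

Explicit wildtype probes are generated so wildtype transcripts are
countable — the per-cell wildtype assignment requires them. Variants
sharing a codon (e.g. G12D/G12V) produce sequence-identical wildtype
probes; their allele identity is collapsed to a single `WILDTYPE` label so
such reads remain unambiguous.

`validate_probe_set` reports probe pairs within the mismatch budget of each
other at the end-to-end alignment, *excluding* same-locus pairs (equal
window start), which are intentional allele alternatives resolved by the
discriminant-exact rule. The default KRAS panel is hazard-free under this
check.

## Matching rules and numerical choices

* **Mismatch accounting.** "At most two mismatches after a perfect seed"
  is implemented as: the seed is exact by construction, and the acceptance
  bound (default 2) applies to Hamming mismatches counted over the *entire*
  38-mer placement. This is the simplest reading consistent with a seeded
  ungapped search and is directly checkable against a brute-force scorer.
* **Full containment.** A probe placement must lie entirely within the
  read; partial overlaps are not scored. 91-nt reads comfortably contain
  38-nt probes, and this avoids edge-length bias.
* **Discriminant-exact rule (on by default).** A placement must agree with
  the probe verbatim at every discriminating offset. Without it, a
  wildtype read with two sequencing errors could be miscalled mutant;
  allele-specific capture only makes sense with the informative base
  error-free.
* **Strand handling.** The read's reverse complement is searched rather
  than complementing probes; the orientation is recorded.
* **Ties and ambiguity.** All seed hits are expanded and deduplicated by
  (orientation, probe, placement) — no first-hit shortcut — so results are
  order-independent. Among accepted placements the fewest-mismatch one
  wins; exact ties are broken (forward before reverse, smaller read offset,
  lexicographic probe id) only when all tied candidates share one allele
  identity; otherwise the read is counted ambiguous and discarded.
* **Seed completeness.** With ≤ 2 mismatches over 38 nt, the mismatch
  positions split the probe into at most 3 segments totalling ≥ 36 nt, so
  at least one segment has length ≥ 6 and carries a clean seed: the seeded
  search provably loses no placement within the budget. The test suite
  asserts this empirically by exact comparison against an exhaustive
  all-offsets/both-strands scorer on 10,000 randomized noisy reads.
* Reads shorter than the probe, or containing characters outside A/C/G/T/N,
  yield no match and are counted. `N` never seed-matches and always counts
  as a mismatch in extension.

## UMI and cell calling

Filter precedence is fixed: **coverage before conflict** (a depth-3 mixed
UMI reports low coverage), making counters deterministic. Two distinct
mutant variants in one UMI are conflict-filtered, the natural extension of
the stated wildtype/mutant conflict rule. Only fishhook-matched,
unambiguous reads count toward UMI depth. No UMI-sequence error collapsing
(e.g. Hamming-1 merging) is performed.

A cell with ≥ 2 mutant UMIs *and* ≥ 2 wildtype UMIs is labeled mutant —
heterozygous tumor cells express both alleles — and both counts are
retained in `cell_genotypes.tsv`. A tie between two distinct variants
leaves the cell unassigned. When duplicate PCR runs are sequenced, their
FASTQs are expected to be merged *before* UMI grouping.

Barcode handling: the 28-bp R1 is split 16 + 12 (the 10x v3 convention);
with a whitelist, barcodes are either matched exactly (default) or rescued
at Hamming distance 1 when the rescue is unique; with no whitelist, raw
barcodes pass through with a logged warning.

## The simulator: what it does and does not emulate

`simulate_run` emulates per-cell genotype truth, UMIs per cell and reads
per UMI (fixed counts, or negative-binomial with given mean/dispersion,
truncated at 1), uniform per-base substitution error on R2, and ambient
reads with fresh random non-whitelist barcodes. All reads of one UMI share
one amplicon window (PCR copies of one molecule), drawn uniformly among
placements that fully contain the cell allele's probe window, mirroring
the matcher's full-containment rule. Default conditions (3 UMIs/cell, 6
reads/UMI) sit just above the filter thresholds (2 UMIs, 5 reads), so the
filters are genuinely exercised.

It does **not** emulate: indels or quality-score structure (constant
placeholder qualities), PCR-cycle–explicit duplication or polymerase
errors shared across reads of a UMI, chimeric molecules beyond random
barcodes, barcode/UMI sequencing errors, heterozygous wildtype expression
in mutant cells (mutant cells emit mutant molecules only, so noise-free
recovery is exact by construction), or transcriptome-wide background.
Passing tests therefore demonstrate the correctness of the algorithmic
pipeline under substitution noise and contamination — not calibrated
performance on real libraries, where allele dropout, expression
heterogeneity and PCR artifacts will lower the assignable fraction.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen to exercise every code path
quickly: the matcher-vs-brute-force comparison uses 10,000 reads of 91 nt
at 1% error; recovery experiments use 100 cells (50 wildtype + 50 G12D, 3
UMIs/cell, 6 reads/UMI) for the noise-free case and a 3-seed grid over
error ∈ {0, 1%, 3%} × reads/UMI ∈ {5, 10} for degradation; determinism is
asserted by hashing every output file across repeated identical runs.

## Known limitations

* Substitution-only variants; no gapped matching, fusions, or copy number.
* The default reference embeds KRAS codons 1–75; assays on longer
  amplicons must supply their own FASTA (`cds_offset=` in the header) and
  variant table.
* With probes shorter than ~3× the seed length, or mismatch budgets above
  2, the pigeonhole completeness guarantee weakens; the brute-force
  reference matcher (`scfishhook.bruteforce`) exists to validate any such
  reconfiguration.
* UMI collisions (two molecules drawing one UMI in the same cell) are not
  modeled or corrected; at 12-nt UMIs and assay-scale depths they are
  negligible.
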