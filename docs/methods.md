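# Methods

This note records the models, rules, numerical choices and limitations
behind `pavpan`, at the level of detail a maintainer or reviewer needs to
judge what a passing test suite does and does not demonstrate.

## Pipeline model

The pipeline treats a cohort study as five stages over shared data types:

1. **Contig classification** (`contig_classify`). Per-sample assembly
   contigs longer than `min_contig_len` (500 bp) are aligned to the
   reference. A contig whose length-weighted identity is ≥ `ref_identity`
   (0.95) over ≥ `ref_query_coverage` (0.95) of its length is reference
   sequence; a contig with no alignment at all is fully unaligned;
   anything else is partially unaligned. From partial contigs, each
   maximal unaligned query segment ≥ `min_contig_len` is extracted as a
   candidate non-reference sequence. Both comparisons are deliberately
   literal readings of the rules they encode: the reference rule is
   inclusive (≥), the presence rule below is strict (>).

   Flank placement of an extracted segment is a rule the source
   literature leaves undefined, so it is defined here: *two-end placed*
   when both flanking aligned blocks hit the same chromosome and strand
   and the reference gap between them is under 10× the segment length
   (the factor rejects chimeric joins); *one-end placed* when exactly one
   flank aligns (a discordant pair degrades to one-end on the left
   flank). Redundancy removal is greedy longest-first absorption at the
   same 95/95 pair as the reference rule, chosen for internal
   consistency; it is idempotent by construction.

2. **PAV calling** (`pav`). Coverage is evaluated on the representative
   transcript only — the transcript with the largest total CDS length,
   ties to the lowest index — not on the CDS union across transcripts.
   A base is covered when at least `depth_presence_min` (default 1) reads
   overlap it; presence requires CDS coverage strictly above
   `presence_cds_coverage` (0.80), so exactly 80% is an absence. Genes on
   chrY are evaluated over male samples only; in an all-female cohort
   they are labelled `UNEVALUABLE` rather than silently core, a label
   introduced here because the source cohorts always contained males.

3. **Cohort comparison** (`pop_compare`). Fisher's exact two-sided
   p-value follows the probability-ordering convention (sum of
   hypergeometric probabilities of all same-margin tables no more
   probable than the observed one). It is computed in exact integer
   arithmetic over a single shared denominator, so the float result is
   the correctly rounded value of the exact rational — no tolerance
   gymnastics. BH correction delegates to statsmodels
   (`fdr_bh`); the FDR family is exactly the set of genes tested in one
   comparison, never pooled across comparisons. Odds ratios are absence
   odds (case vs control); a zero cell triggers the Haldane–Anscombe
   +0.5 correction on all four cells. HAG/LAG ranking uses case absence
   frequency (descending) to pick the top N (20), then splits at the
   median CDS coverage over absence-called samples against
   `hag_cds_coverage` (0.50); frequency ranking and the median summary
   are choices made here and isolated behind parameters. When sex itself
   is the phenotype, chrY genes are removed before the FDR family is
   formed, since their absence in females is confounded by design.

4. **Placement** (`placement`). The gene-to-contig match requires global
   identity — matching columns as a fraction of the full coding length —
   above `gene_contig_min_identity` (0.80); a local-chain interpretation
   over the CDS is used because novel genes sit in genomic cassettes with
   introns. Anchor flanks shorter than `anchor_flank_len` (3000 bp)
   disqualify that side rather than shrinking, keeping the
   `anchor_min_aln_len` (1500 bp) acceptance rule meaningful. The locus
   is the gap between inner anchor boundaries (anchor spans excluded);
   abutting or overlapping anchors collapse to a zero-length insertion
   point, accepted. Loci from multiple contigs aggregate by
   single-linkage overlap clustering; most distinct supporting contigs
   wins, ties to the leftmost locus.

5. **SV merging** (`sv_merge`). The merge decodes the parameter string of
   the SURVIVOR-style protocol as: max breakpoint distance 1000 bp, min
   support 2 callers, type agreement on, strand agreement on, no distance
   scaling, min size 30 bp — re-implemented (single-linkage over pairs
   whose start *and* end breakpoints each agree within the distance, one
   call per caller per cluster, median consensus breakpoints) rather than
   shelling out. Calls never merge across samples. Tandem-repeat content
   of insertion sequences is measured by an explicit simplification of
   full repeat masking: perfect tandem tracts of period ≤ 6 and length
   ≥ 20 bp; a mask computed by a dedicated masker can be supplied
   instead. Deletion-derived PAVs subtract merged DEL intervals from an
   all-covered track and reuse the CDS-coverage presence rule verbatim;
   the homozygous-only variant trusts the genotypes the callers report.

## The internal aligner

`alignment` provides a minimal exact-seed aligner: k-mer seeds (k = 15,
both strands, N-containing k-mers skipped), chained per exact diagonal
(blocks are ungapped, so a chain lives on one diagonal; seeds more than
500 bp apart on the query never chain), merged into one block and
extended with an X-drop rule (match +1, mismatch −3, drop 12). Identity
is the exact column-match fraction over the final block. Overlapping
chains are all reported; a best non-overlapping subset (maximal total
aligned length, ties to higher identity, by weighted interval scheduling)
is selected only inside `summarize_query`, because classification rules
operate on coverage, not on a unique alignment.

This aligner handles substitution-only sequence, which is what the
generator emits; it makes no claim to reproduce MUMmer or minimap2
output, and it does not model indels, spliced alignment or affine gaps.
Real-data users should supply PAF from an external aligner through
`read_paf`, which maps PAF columns 1–12 onto the same `AlignmentBlock`
type. All internal coordinates are 0-based half-open; 1-based formats
(GFF3, depth TSV, the SV TSV dialect) convert only at their readers and
writers.

The read-mapping rate counts a read as mapped when one block covers
≥ 90% of it — loose enough that ≤ 2% substitution noise never unmaps a
read; the contract is the comparison of rates between targets, not the
absolute value.

## The synthetic-data generator

`synthetic_data` emulates, at desk scale, a two-cohort WGS PAV study:

- Reference: 3 chromosomes of 100 kb (the last is chrY), uniform random
  A/C/G/T, 120 genes of 600–2000 bp with 1–3 CDS exons (occasionally a
  second, shorter transcript), 10% of genes on chrY. Six novel genes live
  in random cassettes (gene ± 200 bp pad) with one fixed insertion locus
  each, reserved intergenically and kept ≥ 3.6 kb from chromosome ends so
  long-read contigs can carry full anchor flanks.
- Cohorts: by default 25 samples each ("case"/"control"). Genes
  G0001–G0005 are planted absent at frequency 0.6 in cases vs 0.05 in
  controls (the differential set the power analyses target); G0006–G0015
  at 0.2 in both; novel genes are carried with probability 0.5
  everywhere. Sexes are drawn at 0.5; females carry no chrY. A deletion
  excises the gene span ± 50 bp, giving unambiguous truth for both the
  PAV and the SV stage; each carried cassette is one insertion event.
- Reads and depth: read length 150 bp at mean depth 30, placed uniformly
  over the individual's *actual* sequence, so deleted regions get zero
  depth by construction and at depth 30 a present CDS base is uncovered
  with probability e^−30. The depth track is the exact pileup lifted back
  to reference/cassette coordinates.
- Contigs: Poisson fragmentation at 1 break / 10 kb with optional
  substitution errors (0 by default); with zero error the contigs of a
  chromosome concatenate back to it exactly.
- SV callsets: three callers, each missing a true event with probability
  0.1, jittering breakpoints with rounded N(0, 50²) noise, and adding
  Poisson false positives at 0.05 per true event.

Determinism: one global seed; per-sample streams are seeded by
(seed, CRC32(sample id)), so adding samples never perturbs existing ones.
`simulate_presence_matrix` is a deliberate shortcut for statistical
calibration only: it draws presence matrices directly from Bernoulli
absence frequencies, skipping genomes entirely.

What the generator does *not* model — and therefore what passing tests do
not show about real data: diploidy and heterozygous deletions, indel and
base-quality error, repeat families and segmental duplications (the
planted cassettes are unique random sequence, so redundancy removal and
best-hit mapping face no hard paralogy), contamination, assembly
collapse, or somatic-vs-germline differences. Truth recovery at 100% is
the expected behaviour of a correct implementation under these idealized
conditions, not a claim about real cohorts.

## Problem sizes in the checked runs

The test suite and `scripts/acceptance.py` use study sizes chosen to make
every stage's statistics stable while keeping full runs desk-sized: the
depth-based PAV and SV stages run on the standard 2 × 25-sample study
(6300 sample×gene pairs, several hundred true SVs); non-reference
discovery, mapping rates and placement run on 8–12 samples (alignment of
every contig of every sample is the dominant cost); the null and power
calibrations use 200 replicates of direct Bernoulli matrices at n = 50
per cohort; the Fisher oracle sweep covers all 246,016 tables with both
margins ≤ 30.

## Known limitations

- The exact-diagonal chaining means a single indel inside a true block
  would split it; acceptable for the substitution-only generator,
  wrong for raw long reads — use external PAF there.
- `remove_redundancy` re-indexes the kept set as it grows (quadratic in
  the number of kept sequences); fine for dozens of candidates, not for
  millions.
- The SV TSV dialect appends a genotype column beyond the minimal
  CHROM/POS/ID/TYPE/END/SVLEN/STRANDS/SAMPLE columns, because
  homozygous-deletion PAV needs genotypes; readers accept files without
  it.
- `build-pan` run purely from FASTA (via the CLI) cannot distinguish
  fully vs partially unaligned totals, since placements live in the
  classification catalog, not the FASTA.
- Gene prediction on non-reference sequence is out of scope: novel gene
  models come from the generator's truth or an external GFF3.
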