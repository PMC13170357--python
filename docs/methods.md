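# Methods

`rbscreen` implements the computational side of a randomly barcoded
T-DNA mutagenesis screen in a filamentous fungus: mapping where each
barcoded cassette inserted (TnSeq of cassette–genome junctions), counting
each mutant's abundance in pooled cultures grown at two temperatures
(BarSeq of barcode amplicons), and testing per gene whether mutant
abundance depends on temperature. A synthetic-data generator with known
ground truth makes every stage testable end to end.

## Junction mapping

A junction read is laid out as `barcode + right-arm junction + genomic
flank`: the random barcode sits inside the cassette immediately upstream
of the right border, so a read that spans the junction carries both the
mutant's identity and the genomic sequence adjacent to the insertion.

Processing rules, in order:

1. **Junction detection.** A Hamming-distance window scan locates the
   right-arm junction sequence in each read, tolerating up to 2
   mismatches. Among qualifying windows the one with the fewest
   mismatches wins, ties going to the lowest offset. The 20 nt before
   the junction are the barcode; the remainder of the read is the flank.
2. **Flank alignment.** Flanks of at least 20 nt are aligned with the
   built-in local aligner (below). Hits are retained at ≥ 95% identity
   and E-value ≤ 0.1.
3. **Uniqueness.** A flank maps uniquely only when its best hit exceeds
   the runner-up by at least 10 bitscore units (a single passing hit is
   trivially unique).
4. **Barcode collapsing.** Barcodes at Hamming distance 1 from a
   strictly better-supported barcode are absorbed into it (counts
   summed), iterated to a fixed point; among equally supported absorbers
   the lexicographically smaller wins. Collapsing is idempotent and
   conserves read counts.
5. **Position resolution.** Within one barcode's evidence on one
   chromosome and strand, positions closer than 10 bp merge into the
   most abundantly supported locus (ties: smaller coordinate).
6. **Classification.** `single`: one resolved locus with unique support;
   `multi-locus`: every aligned read failed the uniqueness test;
   `concatameric` (insert-derived): the flank evidence aligns to the
   T-DNA/vector itself better than to the genome — more insert-derived
   reads than uniquely genome-mapped ones; `ambiguous`: uniquely mapped
   reads support conflicting loci (different chromosome or strand, or
   loci ≥ 10 bp apart that each pass uniqueness). Only `single` records
   with at least one uniquely mapped read enter fitness analysis. The
   boundary between `concatameric` and `ambiguous` is a documented
   interpretation: insert-vs-genome evidence is tested first, then locus
   conflicts.
7. **Annotation and density.** The insertion coordinate is the first
   genomic base adjacent to the right arm; strand records the direction
   the flank reads into the genome (on the minus strand the flank is the
   reverse complement of the reference interval ending at the
   coordinate). Coordinates are 1-based inclusive throughout (GFF3
   convention) — one convention end to end avoids off-by-one drift
   between annotation and mapping. A coordinate inside exactly one gene
   interval takes that gene; inside none, `intergenic`; inside two or
   more overlapping features it is flagged multi-feature and excluded
   from gene-level statistics. Genome-wide insertion density is
   summarized in 50-kb bins `[k·50000+1, (k+1)·50000]` per chromosome.

Multiple sequencing batches are concatenated before collapsing, with
per-batch provenance kept in the pool file.

Near-position resolution is applied within one barcode's evidence; a
`merge_shared_positions` flag exists for the stricter variant that also
merges distinct barcodes sharing a locus, but it is off by default
because distinct barcodes at one locus are legitimate sibling mutants.

## The local aligner

Flanks are short (≈ 50 nt) and retained hits must clear 95% identity, so
the aligner is an exact k-mer seed (k = 12) plus ungapped X-drop
extension, scored match +1 / mismatch −2. Scores are converted to
bitscores and E-values by the Karlin–Altschul formulation

    bits = (λ·S − ln K) / ln 2,     E = m·n·2^(−bits)

with λ = 1.28, K = 0.46 for this scoring scheme, m the query length and
n the total genome length. Gapped alignment is omitted by default
(an indel in a 50-nt flank almost always drops it below the identity
threshold anyway); the contract an alternative backend must honour is
the hit filter (identity, E-value) and the 10-bit uniqueness gap, not
the alignment algorithm. Duplicate seeds on one diagonal are extended
once; overlapping hits at the same subject interval keep the best score.

## BarSeq counting and normalization

Barcodes are extracted from amplicon reads by anchoring the two constant
priming sites flanking the barcode, each tolerating 1 mismatch; the
barcode is the fixed-length window between them, and reads where either
anchor fails are tallied as unparseable. Observed barcodes are assigned
to pool barcodes by exact match; Hamming-1 rescue toward the pool exists
behind a flag but is off by default because it can misassign reads
between genuine neighbouring barcodes. Unassigned barcodes are reported
but never enter statistics — they are mutants absent from the mapped
pool. Counts are normalized by total-count scaling to counts per million
(CPM); the target constant is arbitrary and CPM is the conventional,
scale-invariant choice. Replicate concordance is reported as pairwise
Pearson r and OLS R² between same-temperature samples; constant columns
yield NaN, not 0.

## Gene-level fitness statistics

For each gene passing the filters:

- **Filters.** Multi-feature barcodes are dropped; a gene is dropped
  when every one of its (barcode, sample) *raw* counts is below 5; genes
  with more than 15 uniquely mapped barcodes are excluded from testing
  (insertion hotspots would otherwise dominate the variance structure)
  and reported in a flags table.
- **Effect size.** The baseline is the mean normalized abundance across
  all the gene's mutants over all 37 °C replicates — one joint baseline
  per gene, not per barcode. Each (mutant, 50 °C replicate) abundance is
  divided by it; log₂ of these ratios gives one value per mutant per hot
  replicate, and their arithmetic mean is the gene's effect,
  log₂(50 °C/37 °C). Zero hot abundances leave the log undefined; they
  are dropped and tallied by default, or replaced by
  log₂((value + pseudocount)/baseline) when a pseudocount is configured.
  Dropping is the default because the statistic is defined on observed
  per-mutant abundances; the pseudocount variant biases small counts.
- **Test.** A one-sample Wilcoxon signed-rank test of the ratios against
  median 0 (default framework), or alternatively a Mann–Whitney U test
  comparing the raw abundance distributions between temperatures. Exact
  null distributions are used up to n = 25 non-zero ratios
  (signed-rank) / combined n = 20 (Mann–Whitney) so every desk-scale
  case is exact; both exact branches tolerate ties (rank convolution,
  respectively enumeration of group assignments over mid-ranks), which
  is why they are computed in-package rather than delegated. Larger
  samples use tie-corrected normal approximations with continuity
  correction. Genes with fewer than 3 non-zero ratios are reported
  untestable rather than tested.
- **Multiplicity and hit call.** Benjamini–Hochberg step-up adjustment
  across tested genes; a gene is temperature-responsive when
  |mean log₂FC| ≥ 1 and FDR < 0.05, with direction `favors-50` for a
  positive mean. Dispersion is reported as sample SD (n−1) and
  CV% = 100·SD/|mean| (undefined at mean 0). The volcano table lists
  (gene, mean log₂FC, −log₁₀ FDR, hit flag) sorted by FDR then effect
  magnitude.

Two-sided exact p-values are `min(1, 2·min(P(T ≤ t), P(T ≥ t)))`.

## Synthetic data: what it emulates and what it does not

- **Genome.** i.i.d. bases at configurable GC content; non-overlapping
  genes placed by distributing inter-gene slack multinomially. No
  repeats, introns or codon structure — sufficient for exercising
  coordinate arithmetic, not for modeling repeat-induced multi-mapping
  (the `multi-locus` path is tested with explicitly duplicated loci
  instead).
- **Insertions.** Uniform over the genome with equal strand probability,
  optionally with a hotspot window whose density is multiplied by an
  enrichment factor (emulating the transcriptional hotspots real T-DNA
  pools show). Barcodes are distinct random 20-mers (the conventional
  length for randomly barcoded T-DNA cassettes; the length is
  configurable since real cassettes vary).
- **Reads.** One junction-bearing read per fragment with i.i.d.
  substitution errors (rate < 0.25); no indels, chimeras, PCR
  duplicates or paired-end structure. 10 reads per insertion by
  default: a 20-nt barcode is misread in ≈ 18% of reads at a 1% error
  rate, so a mutant's barcode is reliably established only when several
  reads cover it — at 3 reads ≈ 0.6% of mutants would have every read
  misread and be pooled under a wrong barcode, an artifact of shallow
  coverage rather than of the mapping rules, whereas real junction
  libraries cover each insertion tens to hundreds of times. Flanks
  truncated by a chromosome end are emitted (real libraries contain
  them) and flagged in the simulation log so recovery can be scored on
  full-length evidence. Read names are opaque serials; no truth is
  recoverable from the FASTQ.
- **Counts.** Baseline mutant abundances are hierarchical lognormals: a
  gene-level factor (σ = 1) shared by all mutants of a gene times a
  mutant-level factor (σ = 0.25). The hierarchy reflects that disrupting
  the same gene perturbs pool representation similarly, while
  transformation and bottleneck variation differentiates sibling
  mutants; it also matters statistically, because the gene-mean baseline
  makes the mean log₂ ratio downward-biased by ≈ σ_w²/(2 ln 2) in the
  within-gene spread σ_w (≈ 0.72 bits at σ_w = 1, ≈ 0.05 at 0.25).
  At the hot temperature each barcode's weight is scaled by 2^(planted
  gene effect); proportions are renormalized and counts drawn
  multinomially at fixed depth (10⁶ by default), with per-(barcode,
  sample) lognormal replicate noise of σ = 0.05 — calibrated so
  simulated replicate concordance matches the r > 0.994 observed between
  biological replicates in real screens of this design. Renormalization
  means measured effects are compositional: with 5% of genes planted at
  +2, every measured effect shifts by −log₂(1.15) ≈ −0.2 bits. A
  negative-binomial per-barcode sampling option models extra
  overdispersion; its columns sum to depth only in expectation.

Passing tests on these data therefore demonstrate the correctness of the
decision rules and the calibration of the statistics under a clean error
model; they do not certify behaviour on repeat-rich genomes, indel-heavy
chemistry, or strong batch effects.

## Evaluation scenarios

`rbscreen.benchmarks` fixes two standard scenarios, used by both the
test suite and `scripts/acceptance.py`:

- **Mapping fidelity**: 500 insertions in a 1-Mb genome over 7
  chromosomes, 10 junction reads each, mapped back with default
  thresholds; recovery is the fraction of non-truncated truth insertions
  whose (chromosome, position, strand) is reproduced exactly under the
  truth barcode. Run error-free and at a 1% substitution rate.
- **Statistical calibration**: 200 genes × 5 barcodes × 3 replicates per
  temperature at depth 10⁶, averaged over 20 seeded screens; the null
  design (no planted effects) measures the false-call rate of the
  |log₂FC| ≥ 1 ∧ FDR < 0.05 rule, and the planted design (10 genes at
  +2) measures effect recovery and hit recall.

These problem sizes keep a full run of suite plus script in the
low tens of seconds while leaving every rule exercised at realistic
scale.

## Known limitations

- The aligner is ungapped by design; enabling gapped alignment is left
  as a backend extension point.
- Exact Mann–Whitney enumeration grows combinatorially; above combined
  n = 20 the tie-corrected approximation takes over (desk-scale cases
  stay exact).
- The ratio statistic treats a mutant's ratios in different hot
  replicates as exchangeable observations; mutant-level correlation
  across replicates (present in both real and simulated data) makes the
  signed-rank test anticonservative in principle, which is why hit
  calling also requires the effect-size threshold — the null calibration
  scenario measures the joint rule, not the test alone.
- Compositional (total-count) normalization shifts all measured effects
  when a large fraction of the pool responds; no centering correction is
  applied, matching the screen's own analysis.
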