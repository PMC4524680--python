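# Methods

## CArG permutation table and scanner

The CArG box is modeled positionally: positions 1–2 must be `C`,
positions 3–8 each `A` or `T`, positions 9–10 `G`. The consensus set
is therefore the 64 = 2⁶ sequences `CC(A/T)6GG`. The single-mismatch
("CArG-like") table admits every 10-mer at Hamming distance exactly 1
from some consensus sequence: 1,152 additional sequences, 1,216 in
total. Because each position's allowed alphabet is independent, the
distance from any 10-mer to the consensus *set* is simply the number
of positions whose base falls outside its slot; the test suite uses
this closed form to enumerate all 4¹⁰ 10-mers independently of the
table construction. Deviations beyond one mismatch are deliberately
undefined — two mismatches in 10 bp no longer describe a credible SRF
site, and the scanner refuses to build such a table.

The scanner tests every 10-bp window on the forward strand for table
membership. Three conventions make the counts well defined and are
fixed in code:

* **Forward strand only.** The consensus set is closed under reverse
  complement (the `W` core is self-complementary as a set; `CC…GG`
  maps to `CC…GG`), and single-mismatch status is preserved by
  reverse complement, so both tables are RC-closed and a
  forward-strand scan sees every CArG locus exactly once. Loading a
  user table that violates RC closure triggers a warning (the scan
  becomes strand-dependent) or an error in strict mode.
* **Overlapping matches are all reported.** Any exclusion rule would
  make counts ambiguous.
* **Windows containing `N` are skipped.** Soft-masked (lowercase)
  bases are uppercased and scanned by default; a flag preserves
  masking and skips masked windows instead, since the provenance of
  published genome-wide counts with respect to masking is usually
  unstated.

Output is sorted by (chromosome lexicographic, start ascending) and
serialises to BED5 (name = matched 10-mer; score = 0 for consensus,
else the 1-based mismatch position) with a UCSC custom-track header.

Distances to a transcription start site are signed and strand-aware:
the box's 5′ edge relative to the TSS, negative upstream, so promoter
boxes read like the familiar −45…−1,117 bp offsets.

A genome-scale note: scanning unmasked mouse mm9 with this table is
expected to yield on the order of 3.1 million boxes. That number
depends on the reference build and masking convention and needs the
actual genome FASTA, so it is not part of the desk-scale test
surface; the scanner's correctness is instead certified by exhaustive
oracle equivalence and exact planted recovery (below).

## Conservation

Conservation is positional, not sequence-based: a source box is
conserved when its projection through an alignment-block map overlaps
at least `min_overlap` bp (default 1) of a CArG box found
independently in the target genome. This is the weakest defensible
reading of "conserved between the two CArGomes", and the overlap
requirement is an explicit parameter rather than a hidden constant.
The map is a simplified chain: ordered gapless blocks
(source interval, equal-length target interval, target strand).
Projections are all-or-nothing — an interval straddling two blocks is
unmapped, mirroring liftover's minMatch spirit — and minus-strand
blocks reverse coordinates within the block.

## Peak association

* Signal filter: strictly greater than the threshold (default 1.5
  signal value), exactly as a "peak height > 1.5" rule reads.
* CArG-in-peak: the 10-bp box must be fully contained in the peak
  interval (default), making `carg_count` unambiguous; any-overlap is
  available as a flag.
* CpG association: any overlap ≥ 1 bp with an island.
* Gene location: decided by the peak midpoint, so every peak gets
  exactly one class. The promoter is the `promoter_bp` window
  (default 5,000 bp — generous enough to contain functional promoter
  CArGs, which cluster within ~1 kb of the TSS) immediately upstream
  of each transcript's TSS, strand-adjusted. Precedence is promoter >
  exon 1 > intron 1 > other exon > other intron, evaluated across all
  transcripts of each gene; among genes achieving the best class the
  smallest |midpoint − TSS| wins, ties broken by lexicographic gene
  id. A midpoint in no gene context is intergenic, and intergenic ⇔
  no associated gene is an invariant of the annotation type.
* Proteomics overlap: gene symbols are matched case-insensitively
  after stripping numeric isoform suffixes (`.2`, `-201`); genes
  absent from the proteomics table count as "not detected", so the
  three status counts always sum to the input gene count.

## Expression

* **Reliability cutoff.** Labels come from the FPKM confidence
  interval: reliable ⇔ lower bound > 0. For a candidate threshold
  *t*, FP(*t*) is the fraction of unreliable transcripts with FPKM ≥
  *t* and FN(*t*) the fraction of reliable transcripts with FPKM <
  *t*. The cutoff is the argmin of |FP − FN| over 1,000 log₁₀-spaced
  thresholds spanning the positive FPKM range (smallest threshold on
  ties); an exhaustive search over every distinct FPKM value is
  available for small inputs and serves as the oracle in tests. The
  crossing is undefined when either class is empty, which is an
  error. "Equal false positive and false negative ratios" admits no
  other formalisation without the original plotted curves; argmin of
  the gap is the minimal faithful one. On the original Cufflinks
  output this procedure reportedly lands at 0.025 FPKM; that input is
  not available here, so the value is context, not a test target.
* **Censoring** sets FPKM < cutoff to exactly 0 (strictly less than,
  so FPKM equal to the cutoff survives); it is idempotent and never
  increases a value.
* **Aggregation** sums isoform FPKM per gene (and per sample), the
  usual meaning of combined expression over transcriptional variants.
* **Correlation** between samples is Pearson on log₁₀(FPKM + 1) over
  the union of gene ids, absent genes contributing 0 before the
  transform. The transform is configurable and recorded; published
  correlation coefficients (0.96 between SMC samples) do not state
  their transform or gene universe, so correlation is property-tested
  rather than targeted.
* **Specificity** = SMC / (ICC + PDGFRα⁺ + pseudocount), FPKM units,
  dimensionless. The pseudocount (default 0.01 FPKM, denominator
  only) keeps genes silent in both comparator cell types finite; at
  pseudocount 0 the score is scale-invariant and a zero denominator
  is an error pointing at the pseudocount.
* **SRF-target nomination**: peak-associated genes strictly above
  `min_fpkm` (default 100), descending FPKM, gene-id tiebreak.
* **ORF translation** scans the three forward frames only (assembled
  transcripts are already oriented), takes the longest ATG-initiated
  ORF ending at an in-frame stop or the sequence end, leftmost start
  on ties, excludes the stop, and renders N-containing codons as `X`.

## Histone signatures

Each gene's per-mark signal value is (min + max)/2 of the
piecewise-constant ChIP signal over the window [TSS − w, TSS + w)
with w = 2,000 bp by default (the window is symmetric, hence
strand-invariant; uncovered positions read 0; windows are clipped at
chromosome ends with a warning). Signal values become low/high levels
against per-mark thresholds; the level triple maps to a class:

| H3K4me3 | H3K27ac | H3K27me3 | class |
|---|---|---|---|
| low | low | high | restricted_active |
| high | high | low | ubiquitous_active |
| low | low | low | silenced |
| any other combination | | | ambiguous |

Only the first two rows have a biological reading anchored in marker
genes (a calponin-like SMC-restricted promoter vs a ubiquitin-B-like
housekeeping promoter). All-low as "silenced" is a stated convention;
the four remaining combinations are deliberately ambiguous rather
than guessed. The map is total over the 8 combinations and the tests
enumerate all of them.

Default thresholds are cohort-derived: per mark, the midpoint of the
25th and 75th percentiles, with a value exactly at the threshold
falling to high (values at/below the low quantile are always low,
at/above the high quantile always high). This rule presumes a cohort
whose low/high mass is roughly balanced per mark; for skewed cohorts
absolute thresholds should be supplied, and the CLI accepts them as
JSON.

## Synthetic data

The generators emulate every pipeline input with known ground truth;
a manifest records planted boxes, designed conserved subsets,
per-peak truth, designed specific/ubiquitous genes, designed
reliable/unreliable transcripts and designed chromatin classes, plus
all parameters and the seed. All randomness flows from one explicit
`numpy` Generator per call; identical (parameters, seed) reproduce
identical bytes.

* **Genome.** I.i.d. background at the requested GC fraction (default
  0.42, mouse-like), then *scrubbed*: any window matching the
  permutation table outside the planted set is redrawn (protected
  planted bases untouched) until none remain. Scrubbing is what makes
  exact-recovery assertions possible — expected accidental matches are
  ~1.2 per kb before scrubbing and exactly zero after. Planted boxes
  are non-overlapping (≥ 20 bp apart); a designed fraction carries
  exactly one mismatch (a base drawn outside its consensus slot, so
  the distance is exactly 1, never 0).
* **Regulatory layout.** One territory (12 kb) per peak; the peak
  (300 bp), its optional planted box (centred in the peak), its
  optional CpG island and its optional three-exon gene all live in
  that territory, so every designed association — CArG containment,
  CpG overlap, location class (designed fractions 40/15/15/10/10%
  genic, 10% intergenic), signal above/below 1.5 (drawn from
  U(1.6,10) vs U(0.1,1.4)) — is unambiguous by construction and
  cannot collide across territories (promoter windows never span a
  boundary). Genes alternate strands to exercise strand-aware code. A
  designed subset of CArG-containing peaks has a 200-bp block around
  its box copied into a second genome through the alignment map
  (alternating target strands, reverse-complemented on −), with
  spacers scrubbed; the designed conserved subset is therefore
  exactly recoverable. The layout generator builds its own substrate
  (it calls the genome generator with explicit planted positions)
  rather than accepting one, because the designed relationships
  require control over box placement.
* **Expression.** Four samples (jejunal and colonic SMC, ICC,
  PDGFRα⁺). Designed SMC-specific genes have FPKM around 200 in SMC
  samples and near-zero (< 0.02) backgrounds in the comparators;
  other genes share a log-normal base level (median 10 FPKM, σ = 1.5
  on the log) with per-sample noise exp N(0, noise_sd), noise_sd =
  0.25 by default. Gene FPKM is split over 1 + Poisson(2) isoforms
  (mean 3 per gene) by a Dirichlet(5) draw. A designed unreliable
  population (500 spurious transcripts per sample, log-normal around
  0.005 FPKM, capped below 0.02, zero lower confidence bound) sits
  strictly below the reliable floor of 0.1 FPKM, so a cutoff with
  FP = FN = 0 exists in the gap by design — the separable regime the
  cutoff procedure is specified to handle.
* **Histone tracks.** Per gene and mark, three bedGraph sub-blocks
  over the TSS window with values drawn from well-separated bands —
  low U(0.5, 2), high U(8, 12) — around a designed threshold of 5,
  according to the gene's designed class. Windows must not overlap
  between genes (enforced).

What passing on these data shows — and does not. Exact recovery
certifies the combinatorics and the coordinate arithmetic: the
scanner finds precisely the planted motif set, projections and
containment rules behave as stated, the cutoff finds the designed
separation, ranking recovers designed specificity, the signature map
is total and correct. Real data differ in ways the generators do not
emulate: backgrounds contain genuine CArG-like motifs at high density
(no scrubbing in nature), peaks overlap several genes and straddle
classes, FPKM reliability classes overlap rather than separate,
chromatin signal is not piecewise-constant within bands, and gene
models are vastly messier. Performance on the synthetic suite
therefore validates implementation correctness, not biological
discovery power.

## Numerical and procedural choices

* Coordinates are 0-based half-open everywhere; GTF (1-based
  inclusive) is converted on read by decrementing starts.
* The cutoff grid is log-spaced with 1,000 points; argmin takes the
  first (smallest) threshold on exact ties.
* Quantile thresholds use NumPy's linear-interpolation quantiles; the
  stored threshold is nudged one ulp above the quantile midpoint so
  the "ties → low" rule holds exactly.
* The peak-location tiebreak (class precedence, then TSS distance,
  then gene id) is deterministic and matched by an independent
  brute-force classifier in tests.
* Scrubbing retries up to 200 rounds and fails loudly if a match
  cannot be removed without touching protected bases (possible only
  if planted features are packed closer than a window length, which
  placement prevents).
* Problem sizes in the acceptance script — 1 Mb genome / 500 boxes,
  100 peaks, 2,000 genes, 80-gene histone cohort, 200 transcripts —
  are the package's chosen desk-scale study conditions; every
  quantity it reports is recomputed from scratch at run time from the
  given seed.

## Known limitations

* Conservation ignores sequence identity of the aligned boxes; a
  projected locus overlapping any target box counts.
* Split-block (partial) projections are dropped rather than stitched.
* The published genome-scale counts (mouse CArGome size, conserved
  count, the 1,540-peak association table, the 0.025 FPKM cutoff, the
  86-gene / 34-protein intersection) require the original genome,
  ChIP and supplementary tables, which are not distributed here; the
  corresponding test fails explicitly rather than silently skipping.
* Multi-mismatch or spacer-variant CArG-like elements, PWM scoring,
  peak calling, FPKM estimation and GO enrichment are out of scope.
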