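# Methods

This note documents the models, conventions and parameter choices behind
`riboext`, in the spirit of the methods documentation of mature
scientific packages: what is computed, under which assumptions, and what
the validation on synthetic data does and does not establish.

## Coordinates and formats

All internal coordinates are 0-based half-open, with converters at every
format boundary: GFF3 is read and written 1-based closed, SAM positions
1-based. A `TranscriptModel` stores exons as genomic intervals plus the
genomic coordinates of the first base of the start codon and of the stop
codon, both in transcript orientation; all region arithmetic (masks,
extensions, frames) is done in transcript coordinates and mapped back to
genomic positions, which makes plus- and minus-strand handling uniform.
Reported extension coordinates join exon blocks with `^` and carry the
strand in parentheses. The GFF3 reader handles the restricted
gene/mRNA/exon/CDS dialect this package writes (CDS inclusive of the
stop codon); it is not a general-purpose GFF3 parser.

## Density mapping

Footprints shorter than 25 nt are discarded; only uniquely-mapped reads
are counted. The P-site estimate trims 12 nt from each end of an
alignment and spreads one read uniformly over the remaining
*n* = *l* − 24 positions. This rule is symmetric, so it is identical on
both strands; for spliced alignments the trim operates on aligned bases,
not genomic distance. mRNA fragments contribute 1/*l* per aligned
position. Weights are accumulated in floating point; the track asserts
conservation (total weight = counted reads) to 1e-6 × reads.

RPKM over a position set *S* is `counts(S) / (|S|/1000) / (library/1e6)`.
Two named peak-mask presets remove start/stop-codon peak positions:

- `te` (expression comparisons): 9 nt before the start codon, 15 nt
  after it, 15 nt before and after the stop codon.
- `readthrough` (rate estimation): the start codon plus the 12 nt after
  it, the 15 nt before each stop codon, and the 9 nt after the CDS stop.

The two presets are kept as distinct named conventions rather than
reconciled, since they serve different estimators. In the `readthrough`
preset the start codon itself is masked along with the 12 nt following
it: the initiation peak sits on the start codon, and leaving it in would
bias CDS density upward by several percent at typical peak heights.

The 128-count threshold is applied wherever an analysis depends on a
reliable per-gene count (TE comparisons require ≥ 128 mRNA counts;
readthrough quantification and differential tests require ≥ 128 CDS
footprints). Coverage evenness is summarised as the area under the
Lorenz curve of per-position weights (uniform coverage → 0.5), computed
by trapezoid from (0,0) to (1,1).

## Candidate extensions and scoring

Candidates are enumerated by walking in frame from each annotated stop
codon to the next in-frame stop within the annotated 3′UTR; one
candidate per unique (stop, next-stop) genomic pair, with isoforms
grouped. Exclusions: length < 5 codons, or any overlap with annotated
CDS/5′UTR positions (including longer isoforms of the same gene, which
also covers splice forms that omit the stop) or with structural-RNA
biotypes (miRNA, rRNA, sn/snoRNA, tRNA). A methionine in the first three
extension codons bars a positive score (possible downstream cistron)
unless the gene is whitelisted; any extension containing a methionine
must additionally show density upstream of the first one.

ρ is the ratio of peak-masked extension RPKM to peak-masked CDS RPKM,
minimised over isoforms sharing the extension. Extensions too short to
retain unmasked positions (≤ 24 nt between the masks) are flagged
rate-unmeasurable. The distal 3′UTR is the 40-codon window past the
extension's stop, extended in uninterrupted genomic coordinates to
114 nt when the transcript ends sooner.

Scoring operationalises a judgement that was partly manual in practice:

- *positive*: filters (a)–(f) all pass **and** covered positions are
  evenly spread (no gap > 50% of the extension length); or, when
  coverage is sparse, rate ≥ 0.001 plus a peak of ≥ 2 reads at the
  extension's stop codon (the sparse path does not require the 0.2-RPKM
  density floor, which sparse but real readthrough can miss).
- *ambiguous*: unquantifiable (no testable CDS, rate-unmeasurable,
  zero CDS density) or barred by the methionine rules.
- *negative*: no extension density, no density drop after the
  extension's stop, or coverage patterns failing the extent/evenness
  criteria without a sparse-peak rescue.

Double readthrough is scanned to depth 2: after a positive call the
extension's stop is treated as the annotated stop and the extension as
the baseline region.

Differential readthrough uses per-gene 2×2 tables of rounded peak-masked
CDS/extension counts, two-sided Fisher's exact test (probability-mass
convention), BH FDR at 5%, and log₁₀(ρ₂/ρ₁) fold changes. Eligibility:
isoforms sharing one CDS, ≥ 128 CDS footprints in each sample, positive
score in at least one.

## Mismatch and editing analysis

For each of the three nucleotides of each annotated stop codon,
matching/mismatching read bases are tabulated in three datasets: mRNA
fragments, all footprints, and the subset of footprints whose pruned
P-site window lies entirely 3′ of the position (ribosomes that have
decoded it). Mismatches at a read's first aligned position (read
orientation) are ignored as reverse-transcriptase artifacts.
Substitutions are reported in mRNA sense (A→G on a minus-strand gene is
genomic T→C).

Elevated-mismatch detection is a one-sided (greater) exact binomial test
per position against the per-offset global mismatch rate, BH-corrected
at 5% ("far exceeded" implies the one-sided alternative). Significant
calls are classified: a single dominant substitution class (≥ 80% of
mismatches) at 35–65% of covering reads is a heterozygous, at ≥ 90% a
homozygous polymorphism (bands are config-exposed; the idealised
expectations are 50%/100%), subclassified stop→stop or stop→sense by
mutating the codon; among the rest, only reference adenines with
dominant A→G are editing candidates, everything else sequencing error.
The editing null test assumes conservatively that 90% of A-site-passed
footprints would carry G if editing drove readthrough
(`editing_null_fraction`, default 0.9) and computes a one-sided lower
binomial p with Bonferroni correction; rejection is positive evidence
against editing.

## Translation signatures

Metagene profiles normalise each region-of-interest coverage vector to
its mean CDS coverage excluding a 3-codon buffer at each CDS end, then
take the per-offset median (default window ±50 nt; ROIs need ≥ 10 reads
in the coding subregion). The median makes the profile invariant to
per-ROI scaling. Release scores are the ratio of reads in the 5-codon
window downstream of a codon to the 5-codon window upstream, with no
pseudocount (undefined when the upstream window is empty). Footprint
frames use the fixed 5′+12 offset relative to the annotated CDS frame;
phasing tables count 28-mers (the best-phased population) and test their
frame counts against expected proportions from mRNA fragments in the
same region (the cloning-bias control; a uniform null is available as an
option), χ² with dof 2.

## Z-curve classifier and SNP synonymy

The 189-variable Z-curve maps phase-specific k-mer frequencies
(k = 1..3) to (x, y, z) = (purine−pyrimidine, amino−keto, weak−strong)
axes: 9 mononucleotide + 36 dinucleotide + 144 trinucleotide components.
The phase of a k-mer is the codon position of its first base; k > 1
frequencies are conditioned on the (k−1)-mer prefix at that phase
(joint-frequency mode is a switch — the published formulation's
parameterisation is not fully pinned down, and both satisfy the
dimension and bound contracts). Zero-occurrence contexts contribute
(0, 0, 0). Windows must be > 81 nt-class (≥ 81 enforced) because shorter
windows make the classifier error-prone. The classifier is Fisher's
linear discriminant (scikit-learn's `LinearDiscriminantAnalysis` behind
a thin model type serialised as 189 weights + intercept), trained with
stratified k-fold cross-validation; extension scoring draws one seeded
random 81-nt window per region, optionally avoiding the last bases of
the UTR (polyadenylation-signal avoidance), and groups are compared by
Mann-Whitney U (exact enumeration up to 20 combined observations,
normal approximation with midrank tie correction beyond).

SNP synonymy translates the host codon with and without the variant
allele (standard genetic code, stop treated as its own residue) and
compares per-region (synonymous, nonsynonymous) counts by one-sided
Fisher tests. The ER-retention scan is a literal C-terminal
`[KH]DEL` match.

## The synthetic-data generator

`generate_transcriptome` lays single-exon genes (5′UTR, ATG…stop CDS
with length a multiple of 3, 3′UTR) on both strands of one toy
chromosome with intergenic spacers; readthrough genes carry an in-frame
next stop ≥ 5 codons into the 3′UTR with no ATG in the extension's first
three codons, and double-readthrough genes a second in-frame stop beyond
that. `simulate_reads` draws footprint P-sites from a per-codon weight
vector: uniform elongation density, an initiation peak (×5 over the
first three codons) and, when `include_termination_peaks` (emetine-like
sample handling), a termination peak (×3 over the three codons ending at
the stop — a terminating ribosome's P-site never lies past its stop
codon); a fraction ρ of ribosomes continues through the stop at the
configured per-gene rate (ρ² beyond a second stop). Contaminants add
frameshifted (phased, +1/+2) or structure-protected (unphased, narrow)
3′UTR density; uORF density is available but off by default. Footprint
lengths follow a 25–35 nt distribution peaked at 29–31; in `phased`
(RNase-I-like) mode the 5′ end sits exactly 12 nt upstream of the
P-site and frames are drawn 90/5/5, in `blurred` (MNase-like) mode a
±2 nt jitter and a uniform offset within the pruned window add
positional uncertainty. Sequencing errors are injected per base
(default 0.001), and polymorphism/editing sites (specified in mRNA
sense) substitute alleles in covering reads at their configured
fractions. Reads are emitted as arrays for fast in-memory analysis and
as minimal SAM with MD/NM tags (plus a plain tab table), so the
ingestion path for simulated and real data is identical and exercises
pysam.

Peak heights and 3′UTR background levels are free parameters — the
source observations are qualitative — and are flagged as such in the
config; the defaults above were chosen once as field-plausible values.
The generator does **not** emulate sequence-dependent nuclease bias,
realistic base-caller error profiles, rRNA contamination, alternative
splicing, or overdispersed biological replication. Passing tests
therefore establish correctness of the estimators under the stated
generative model, not robustness to every artifact of real libraries.

## Validation design and problem sizes

- Parameter recovery: single-gene simulations at 10⁵ footprints, rates
  {0.005, 0.01, 0.05, 0.2} × 20 seeds; the estimate must fall within 3
  delta-method binomial standard errors of truth in ≥ 95% of runs,
  sensitivity ≥ 0.9 at rates ≥ 0.01, and zero positive calls at rate 0.
- Oracle equivalence: degeneracy masking vs a literal align-every-29-mer
  brute force on ~1.3 kb genomes with planted direct and
  reverse-complement repeats; Z-curve features vs a string-slicing
  counter (component-wise < 1e-12); Fisher/binomial/BH/χ²/rank-sum vs
  scipy, statsmodels and hand enumeration.
- Signatures: termination peaks appear/disappear with the sample-type
  flag; release scores at true stops vs internal codons (Mann-Whitney
  p < 0.01) using 25/26-mer footprints, which resolve the P-site exactly
  — with longer footprints the spread-window estimate necessarily bleeds
  a few nt downstream of the stop and release scores plateau around
  0.1–0.3 even at perfect termination, a resolution limit of the
  trim-and-spread rule, not a defect of the score;
  phased extensions show frame-0 dominance vs mRNA controls.
- Artifact exclusion: injected homozygous stop→sense polymorphisms and
  30% A→G editing sites detected and correctly classified in 20/20
  seeds at ≥ 20× coverage; pooled null simulations keep the significant
  fraction ≤ 5%; the 90% editing null rejects clean stops and retains
  heavily edited ones.

## Known limitations

- Isoform handling assumes the reported isoform's exon structure for
  all coordinate arithmetic; no isoform-level expression deconvolution.
- The evenness criterion (max gap ≤ 50% of extension length) is a
  reproducible proxy for a visual judgement; borderline sparse cases can
  legitimately score differently than a human curator would call them.
- The degeneracy mask flags exact 29-mer multi-hits only (both strands
  by default, forward-only as a switch); near-identical repeats with
  mismatches are not modelled.
- Fractional coverage weights are rounded to integers for contingency
  tables, a negligible distortion at the ≥ 128-count eligibility floor.
- The GFF3/SAM/VCF-like interfaces target the dialects this package
  writes; arbitrary annotation files from other pipelines may need
  normalisation first.
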