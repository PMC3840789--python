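# riboext

Genome-wide detection of **stop-codon readthrough** from ribosome
profiling data.

When a ribosome reads through a stop codon, translation continues in
frame to the next stop, appending a *C-terminal extension* to the
protein. Ribosome profiling makes these events visible as
ribosome-protected footprint density between an annotated stop codon and
the next in-frame stop. Distinguishing genuine readthrough from
artifacts — multimapping reads, frameshifted translation, protected RNA
structures, genomic polymorphisms that abolish the stop, and A-to-I
editing — requires a pipeline of density mapping, filtering, and
statistical tests. `riboext` implements that pipeline end to end,
together with a synthetic-data generator that emulates the statistical
structure of ribosome-profiling data, so every stage can be validated
against known ground truth without any external download.

## What it computes

**P-site density.** Each footprint alignment of length *l* ≥ 25 nt is
trimmed by 12 nt at both ends and the remaining *n* = *l* − 24 central
positions each receive 1/*n* read (a 25-mer maps to one position; a
26-mer to two positions at 0.5 reads each). mRNA fragments are spread
1/*l* over their full alignment. Density is reported in RPKM and
translation efficiency as TE = footprint RPKM (CDS) / mRNA RPKM (locus).

**Readthrough rate.** For each candidate extension (annotated stop →
next in-frame stop, ≥ 5 codons, no overlap with CDS/5′UTR/structural
RNA),

ρ = RPKM(extension) / RPKM(CDS)

over peak-masked coordinates (the start codon plus 12 nt after it, 15 nt
before each stop codon, and 9 nt after the CDS stop are excluded; the
isoform minimising ρ is reported). Candidates are filtered on extension
density (≥ 0.2 RPKM), rate (≥ 0.001), coverage (≥ 10% of positions,
first/last reads within the outer quartiles) and a ≥ 75% density drop
into the first 114 nt of the distal 3′UTR, then scored
readthrough / ambiguous / negative.

**Artifact exclusion.** Per-nucleotide mismatch tests over stop codons
(one-sided exact binomial vs the per-offset global rate, BH FDR at 5%)
find and classify polymorphisms and editing candidates; a conservative
90%-editing null on footprints whose P-site has passed the position
yields positive evidence against editing (Bonferroni-corrected).

**Translation signatures.** Metagene profiles (median of CDS-normalised
coverage), ribosome release scores (downstream/upstream 5-codon window
ratio at a stop; near zero at efficient termination), footprint length
distributions, and triplet phasing of 28-mers tested against matched
mRNA fragments (χ², dof = 2).

**Coding character.** A 189-variable phase-specific Z-curve feature
vector feeds a Fisher linear discriminant (coding vs distal-3′UTR 81-nt
windows, k-fold cross-validated); extension scores are compared by
Mann-Whitney U. SNP synonymy proportions per region are compared by
one-sided Fisher tests, and peptides are scanned for the C-terminal
`[KH]DEL` ER-retention consensus.

**Differential readthrough.** Per-gene 2×2 tables of peak-masked CDS and
extension counts in two samples are tested with Fisher's exact test
under BH FDR control; fold changes are reported as log₁₀(ρ₂/ρ₁).

## Worked example

Simulate three genes (one with a true readthrough rate of 0.05 and a
30-codon extension) at 100,000 footprints, then detect:

```python
from riboext import run_simulated_sample
from riboext.simulate import SimulationConfig

cfg = SimulationConfig(
    seed=42, n_genes=3, cds_len=(300, 360), utr3_len=(250, 300),
    readthrough_rate_map={"g000": 0.05}, extension_codons_map={"g000": 30},
    total_footprints=100_000, total_mrna_fragments=50_000,
)
res = run_simulated_sample(cfg)
for r in res["records"]:
    print(r.candidate.gene_id, r.candidate.length_codons, r.rho,
          r.drop_fraction, r.filters, r.score)
```

prints (reformatted):

```
gene   len(codons)       rho    drop  filters  score
g000            30    0.0490    0.98  abcdef  readthrough
g001             7        NA     nan  cd      ambiguous
g002            32    0.0000    1.00  acdf    negative
```

The true readthrough gene is recovered with ρ = 0.049 (truth 0.05, within
binomial sampling error at this depth), passing all six filters with a
98% density drop after the extension's stop. A 7-codon chance candidate
is too short to quantify once peak masks are applied (`NA`, ambiguous),
and a 32-codon chance candidate with no footprint support in the
extension scores negative.

The same pipeline is scriptable from the shell:

```bash
riboext simulate --outdir sim --seed 7        # FASTA + GFF3 + SAM + truth
riboext detect --genome sim/genome.fa --annotation sim/annotation.gff3 \
    --footprints sim/footprints.sam
riboext diff ... ; riboext mismatch-scan ...
```

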