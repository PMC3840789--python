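"""Synthetic ribosome-profiling data with known ground truth.

Generates a toy genome and annotation (single-exon genes with 5'UTR, CDS
and 3'UTR on either strand) and simulates footprint and mRNA-fragment
alignments with the statistical structure the analysis assumes:
CDS-biased footprint density with initiation and termination peaks,
footprint lengths on 25-35 nt, optional codon phasing (RNase-I-like) or
jittered positions (MNase-like), per-transcript stop-codon readthrough at
configurable rates, 3'UTR contaminants (frameshifted translation and
structure-protected intervals), sequencing errors, genomic polymorphisms
and A-to-I editing sites.

Every read carries exactly one provenance label, and identical
config+seed yields byte-identical outputs.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, field

import numpy as np

from .annotation import TranscriptModel, revcomp

__all__ = [
    "SimulationConfig",
    "Contaminant",
    "SimulatedReads",
    "GroundTruth",
    "generate_transcriptome",
    "simulate_reads",
    "write_fasta",
    "read_fasta",
    "write_sam",
    "write_read_table",
]

STOPS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS
)
SENSE_NO_MET = tuple(c for c in SENSE_CODONS if c != "ATG")

# provenance label codes
LBL_CDS, LBL_UORF, LBL_EXTENSION, LBL_CONTAMINANT, LBL_MRNA = 0, 1, 2, 3, 4
LABEL_NAMES = {
    LBL_CDS: "CDS",
    LBL_UORF: "uORF",
    LBL_EXTENSION: "extension",
    LBL_CONTAMINANT: "contaminant",
    LBL_MRNA: "mrna",
}


def _default_length_dist() -> dict[int, float]:
    """Footprint lengths on 25-35 nt, peaked near 29-31 (monosome mode)."""
    raw = {25: 2, 26: 4, 27: 7, 28: 12, 29: 18, 30: 20, 31: 16, 32: 10,
           33: 6, 34: 3, 35: 2}
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


@dataclass
class Contaminant:
    """A non-readthrough source of 3'UTR footprint density.

    ``kind`` is "frameshift" (phased density in the +1 or +2 frame relative
    to the CDS) or "structure" (a narrow protected interval with unphased
    density).  ``offset`` is in nt downstream of the CDS stop codon's 3'
    edge, ``length`` in nt, ``density`` relative to one CDS codon's weight.
    """

    kind: str
    offset: int
    length: int
    density: float
    frame: int = 1  # for frameshift: +1 or +2


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 10
    utr5_len: tuple[int, int] = (60, 120)
    cds_len: tuple[int, int] = (300, 600)
    utr3_len: tuple[int, int] = (200, 400)
    readthrough_rate_map: dict[str, float] = field(default_factory=dict)
    extension_codons_map: dict[str, int] = field(default_factory=dict)
    double_readthrough_genes: frozenset = field(default_factory=frozenset)
    peak_multipliers: tuple[float, float] = (5.0, 3.0)
    include_termination_peaks: bool = True
    footprint_length_dist: dict[int, float] = field(default_factory=_default_length_dist)
    phasing_mode: str = "blurred"  # "phased" (RNase-I-like) or "blurred" (MNase-like)
    frame_weights: tuple[float, float, float] = (0.90, 0.05, 0.05)
    blur_jitter: int = 2
    per_base_error: float = 0.001
    polymorphism_sites: dict[int, tuple[str, str, float]] = field(default_factory=dict)
    editing_sites: dict[int, tuple[str, str, float]] = field(default_factory=dict)
    contaminant_spec: dict[str, list[Contaminant]] = field(default_factory=dict)
    uorf_spec: dict[str, tuple[int, int, float]] = field(default_factory=dict)
    gene_abundance: dict[str, float] = field(default_factory=dict)
    mrna_length_range: tuple[int, int] = (40, 60)
    total_footprints: int = 200_000
    total_mrna_fragments: int = 100_000
    minus_strand_fraction: float = 0.5
    intergenic_len: int = 200
    edge_pad: int = 300
    chrom: str = "chr1"

    def gene_ids(self) -> list[str]:
        return [f"g{i:03d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        for lo, hi in (self.utr5_len, self.cds_len, self.utr3_len):
            if lo <= 0 or hi < lo:
                raise ValueError("length ranges must be positive and ordered")
        probs = np.array(list(self.footprint_length_dist.values()))
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("footprint_length_dist must sum to 1")
        if any(l < 25 or l > 35 for l in self.footprint_length_dist):
            raise ValueError("footprint lengths must lie in 25-35 nt")
        if abs(sum(self.frame_weights) - 1.0) > 1e-9:
            raise ValueError("frame_weights must sum to 1")
        for g, r in self.readthrough_rate_map.items():
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"readthrough rate for {g} outside [0,1]")
            ext = self.extension_codons_map.get(g, 30)
            if 3 * (ext + 1) + 3 > self.utr3_len[0]:
                raise ValueError(
                    f"3'UTR range too short to host the next in-frame stop for {g}"
                )
        if not (0.0 <= self.per_base_error <= 1.0):
            raise ValueError("per_base_error outside [0,1]")
        if any(m < 1 for m in self.peak_multipliers):
            raise ValueError("peak multipliers must be >= 1")
        if self.phasing_mode not in ("phased", "blurred"):
            raise ValueError("phasing_mode must be 'phased' or 'blurred'")


@dataclass
class SimulatedReads:
    """Gapless simulated alignments as parallel arrays (one chromosome)."""

    chrom: str
    start: np.ndarray          # genomic leftmost position
    length: np.ndarray
    minus: np.ndarray          # bool: aligned to the minus strand
    label: np.ndarray          # provenance code
    gene_index: np.ndarray
    read_class: str            # "footprint" or "mrna"
    # sparse per-read substitutions: read idx -> [(genomic pos, read base)]
    variants: dict[int, list[tuple[int, str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return int(self.start.size)


@dataclass
class GroundTruth:
    readthrough_rate: dict[str, float]
    contaminant_intervals: dict[str, list[tuple[int, int, str]]]
    polymorphic_positions: dict[int, tuple[str, str, float]]
    edited_positions: dict[int, tuple[str, str, float]]
    extension_bounds: dict[str, tuple[int, int]]  # tx coords of extension (excl. stops)


# ---------------------------------------------------------------------------
# transcriptome generation
# ---------------------------------------------------------------------------

def _rand_seq(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _rand_codons(rng, n: int, pool) -> str:
    return "".join(rng.choice(pool, size=n)) if n else ""


def generate_transcriptome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[TranscriptModel]]:
    """Generate a toy genome (FASTA-ready dict) and its annotation.

    Each gene gets one single-exon transcript with 5'UTR, an ATG..stop CDS
    whose length is a multiple of 3, and a 3'UTR.  Genes named in
    ``readthrough_rate_map`` (or ``double_readthrough_genes``) carry an
    in-frame next stop codon >= 5 codons into the 3'UTR, with no ATG in
    the extension's first three codons; double-readthrough genes carry a
    second in-frame extension beyond that stop.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pieces = [_rand_seq(rng, config.edge_pad)]
    cursor = config.edge_pad
    transcripts = []
    for gi, gid in enumerate(config.gene_ids()):
        u5 = int(rng.integers(config.utr5_len[0], config.utr5_len[1] + 1))
        cds_nt = int(rng.integers(config.cds_len[0], config.cds_len[1] + 1)) // 3 * 3
        u3 = int(rng.integers(config.utr3_len[0], config.utr3_len[1] + 1))
        cds = "ATG" + _rand_codons(rng, cds_nt // 3 - 2, SENSE_CODONS) + str(
            rng.choice(STOPS)
        )
        has_rt = gid in config.readthrough_rate_map or gid in config.double_readthrough_genes
        if has_rt:
            ext_codons = int(config.extension_codons_map.get(gid, rng.integers(10, 31)))
            if ext_codons < 5:
                raise ValueError("extensions must be at least 5 codons")
            ext = (
                _rand_codons(rng, min(3, ext_codons), SENSE_NO_MET)
                + _rand_codons(rng, max(0, ext_codons - 3), SENSE_CODONS)
                + str(rng.choice(STOPS))
            )
            if gid in config.double_readthrough_genes:
                ext2_codons = int(rng.integers(8, 16))
                ext += (
                    _rand_codons(rng, min(3, ext2_codons), SENSE_NO_MET)
                    + _rand_codons(rng, max(0, ext2_codons - 3), SENSE_CODONS)
                    + str(rng.choice(STOPS))
                )
            if len(ext) > u3:
                u3 = len(ext) + 60
            utr3 = ext + _rand_seq(rng, u3 - len(ext))
        else:
            utr3 = _rand_seq(rng, u3)
        sense = _rand_seq(rng, u5) + cds + utr3
        minus = bool(rng.random() < config.minus_strand_fraction)
        gstart, gend = cursor, cursor + len(sense)
        pieces.append(revcomp(sense) if minus else sense)
        cursor = gend
        spacer = _rand_seq(rng, config.intergenic_len)
        pieces.append(spacer)
        cursor += config.intergenic_len
        if minus:
            cds_start = gend - 1 - u5
            cds_stop = gend - 1 - (u5 + cds_nt - 3)
        else:
            cds_start = gstart + u5
            cds_stop = gstart + u5 + cds_nt - 3
        transcripts.append(
            TranscriptModel(
                gene_id=gid,
                transcript_id=f"{gid}.t1",
                chrom=config.chrom,
                strand="-" if minus else "+",
                exons=[(gstart, gend)],
                cds_start=cds_start,
                cds_stop=cds_stop,
            )
        )
    pieces.append(_rand_seq(rng, config.edge_pad))
    genome = {config.chrom: "".join(pieces)}
    for t in transcripts:
        t.validate_cds(genome)
    return genome, transcripts


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _find_extension(seq: str, stop_tx: int) -> tuple[int, int] | None:
    """Tx-coordinate interval of the in-frame extension after ``stop_tx``."""
    i = stop_tx + 3
    while i + 3 <= len(seq):
        if seq[i : i + 3] in STOPS:
            return stop_tx + 3, i  # exclusive of both stop codons
        i += 3
    return None


def _psite_weight_vector(
    config: SimulationConfig, t: TranscriptModel, seq: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-codon P-site sampling weights, codon tx starts and labels."""
    init_m, term_m = config.peak_multipliers
    peaks = config.include_termination_peaks
    s, p = t.cds_tx_start, t.stop_tx
    starts, weights, labels = [], [], []

    def add(codon_start, w, lbl):
        if 0 <= codon_start and codon_start + 3 <= len(seq) and w > 0:
            starts.append(codon_start)
            weights.append(w)
            labels.append(lbl)

    def stop_peak(stop_codon_start, base, lbl):
        """Termination density: a 3-codon peak ending at the stop (a
        ribosome's P-site never lies past the stop it terminates on),
        or plain stop-codon dwell when peaks are off."""
        if peaks:
            for cs in (stop_codon_start - 6, stop_codon_start - 3, stop_codon_start):
                add(cs, base * term_m, lbl)
        else:
            add(stop_codon_start, base, lbl)

    n_codons = (p - s) // 3  # elongation codons, excl. stop
    for c in range(n_codons):
        if peaks and c >= n_codons - 2:
            continue  # replaced by the termination peak below
        add(s + 3 * c, init_m if c < 3 else 1.0, LBL_CDS)
    stop_peak(p, 1.0, LBL_CDS)
    rate = config.readthrough_rate_map.get(t.gene_id, 0.0)
    ext = _find_extension(seq, p) if rate > 0 else None
    if ext is not None:
        a, b = ext
        skip = 2 if peaks else 0  # last codons replaced by the stop peak
        for c in range((b - a) // 3 - skip):
            add(a + 3 * c, rate, LBL_EXTENSION)
        stop_peak(b, rate, LBL_EXTENSION)
        if t.gene_id in config.double_readthrough_genes:
            ext2 = _find_extension(seq, b)
            if ext2 is not None:
                a2, b2 = ext2
                r2 = rate * rate
                for c in range((b2 - a2) // 3 - skip):
                    add(a2 + 3 * c, r2, LBL_EXTENSION)
                stop_peak(b2, r2, LBL_EXTENSION)
    for cont in config.contaminant_spec.get(t.gene_id, []):
        base = p + 3 + cont.offset
        if cont.kind == "frameshift":
            for k in range(cont.length // 3):
                pos = base + cont.frame + 3 * k
                if pos + 3 <= len(seq):
                    add(pos, cont.density, LBL_CONTAMINANT)
        elif cont.kind == "structure":
            for pos in range(base, min(base + cont.length, len(seq) - 2)):
                add(pos, cont.density / 3.0, LBL_CONTAMINANT)
        else:
            raise ValueError(f"unknown contaminant kind {cont.kind!r}")
    if t.gene_id in config.uorf_spec:
        off, length, dens = config.uorf_spec[t.gene_id]
        for k in range(length // 3):
            add(off + 3 * k, dens, LBL_UORF)
    return (
        np.asarray(starts, dtype=np.int64),
        np.asarray(weights, dtype=float),
        np.asarray(labels, dtype=np.int8),
    )


def _tx_to_genomic_left(t: TranscriptModel, tx_start: np.ndarray, length: np.ndarray):
    """Leftmost genomic coordinate of a gapless read at tx 5' index tx_start."""
    g0, g1 = t.exons[0][0], t.exons[0][1]
    if t.strand == "-":
        return g1 - tx_start - length
    return g0 + tx_start


def simulate_reads(
    config: SimulationConfig,
    genome: dict[str, str],
    transcripts: list[TranscriptModel],
) -> tuple[SimulatedReads, SimulatedReads, GroundTruth]:
    """Simulate footprint and mRNA alignments plus ground truth.

    Footprint P-sites are drawn per codon from a weight vector with
    initiation/termination peaks and readthrough continuation; the read is
    then placed so that its pruned central window (the P-site estimate)
    covers the drawn position.  mRNA fragments are uniform along each
    transcript.  Mismatches are injected per ``per_base_error`` plus the
    polymorphism/editing site specs (given in mRNA sense orientation).
    """
    config.validate()
    if config.total_footprints <= 0 or config.total_mrna_fragments <= 0:
        raise ValueError("requested read counts must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    chrom = config.chrom
    seqs = {t.gene_id: t.sequence(genome) for t in transcripts}

    # global categorical over (gene, codon)
    all_starts, all_w, all_lbl, all_gene = [], [], [], []
    truth_ext: dict[str, tuple[int, int]] = {}
    for gi, t in enumerate(transcripts):
        st, w, lb = _psite_weight_vector(config, t, seqs[t.gene_id])
        ab = config.gene_abundance.get(t.gene_id, 1.0)
        all_starts.append(st)
        all_w.append(w * ab)
        all_lbl.append(lb)
        all_gene.append(np.full(st.size, gi, dtype=np.int32))
        ext = _find_extension(seqs[t.gene_id], t.stop_tx)
        if ext is not None and config.readthrough_rate_map.get(t.gene_id, 0.0) > 0:
            truth_ext[t.gene_id] = ext
    cat_start = np.concatenate(all_starts)
    cat_w = np.concatenate(all_w)
    cat_lbl = np.concatenate(all_lbl)
    cat_gene = np.concatenate(all_gene)
    p = cat_w / cat_w.sum()

    n_fp = config.total_footprints
    draw = rng.choice(cat_start.size, size=n_fp, p=p)
    psite = cat_start[draw].copy()
    labels = cat_lbl[draw]
    gene_idx = cat_gene[draw]
    # frame offset / jitter within the codon
    frame = rng.choice(3, size=n_fp, p=np.asarray(config.frame_weights))
    psite += frame
    if config.phasing_mode == "blurred":
        psite += rng.integers(-config.blur_jitter, config.blur_jitter + 1, size=n_fp)
    lens = np.array(sorted(config.footprint_length_dist), dtype=np.int64)
    lprob = np.array([config.footprint_length_dist[int(l)] for l in lens])
    fp_len = lens[rng.choice(lens.size, size=n_fp, p=lprob)]
    n_inner = fp_len - 2 * 12
    if config.phasing_mode == "phased":
        # RNase-I-like: fixed 5' geometry, the P-site sits at 5'+12
        offset = np.zeros(n_fp, dtype=np.int64)
    else:
        # MNase-like positional uncertainty within the pruned window
        offset = (rng.random(n_fp) * n_inner).astype(np.int64)
    tx5 = psite - 12 - offset

    fp_start = np.empty(n_fp, dtype=np.int64)
    fp_minus = np.zeros(n_fp, dtype=bool)
    for gi, t in enumerate(transcripts):
        sel = gene_idx == gi
        fp_start[sel] = _tx_to_genomic_left(t, tx5[sel], fp_len[sel])
        fp_minus[sel] = t.strand == "-"
    np.clip(fp_start, 0, len(genome[chrom]) - fp_len, out=fp_start)

    fp = SimulatedReads(chrom, fp_start, fp_len, fp_minus, labels.copy(),
                        gene_idx.copy(), "footprint")

    # mRNA fragments: uniform along transcripts, weight ~ abundance * length
    n_mr = config.total_mrna_fragments
    tx_lens = np.array([len(seqs[t.gene_id]) for t in transcripts])
    gw = np.array(
        [config.gene_abundance.get(t.gene_id, 1.0) for t in transcripts]
    ) * tx_lens
    mg = rng.choice(len(transcripts), size=n_mr, p=gw / gw.sum())
    mr_len = rng.integers(
        config.mrna_length_range[0], config.mrna_length_range[1] + 1, size=n_mr
    )
    mr_tx5 = (rng.random(n_mr) * np.maximum(1, tx_lens[mg] - mr_len)).astype(np.int64)
    mr_start = np.empty(n_mr, dtype=np.int64)
    mr_minus = np.zeros(n_mr, dtype=bool)
    for gi, t in enumerate(transcripts):
        sel = mg == gi
        mr_start[sel] = _tx_to_genomic_left(t, mr_tx5[sel], mr_len[sel])
        mr_minus[sel] = t.strand == "-"
    mrna = SimulatedReads(chrom, mr_start, mr_len,
                          mr_minus, np.full(n_mr, LBL_MRNA, dtype=np.int8),
                          mg.astype(np.int32), "mrna")

    _inject_variants(config, rng, genome, transcripts, fp, mrna)

    truth = GroundTruth(
        readthrough_rate=dict(config.readthrough_rate_map),
        contaminant_intervals={
            g: [(c.offset, c.offset + c.length, c.kind) for c in cl]
            for g, cl in config.contaminant_spec.items()
        },
        polymorphic_positions=dict(config.polymorphism_sites),
        edited_positions=dict(config.editing_sites),
        extension_bounds=truth_ext,
    )
    return fp, mrna, truth


def _inject_variants(config, rng, genome, transcripts, *read_sets):
    """Apply sequencing errors, polymorphisms and editing to read bases."""
    chrom_seq = genome[config.chrom]
    # site specs are in mRNA sense; convert to genomic forward orientation
    site_specs = []
    for spec, is_edit in ((config.polymorphism_sites, False), (config.editing_sites, True)):
        for gpos, (ref, alt, frac) in spec.items():
            strand = "+"
            for t in transcripts:
                if t.exons[0][0] <= gpos < t.exons[0][1]:
                    strand = t.strand
                    break
            g_ref, g_alt = (ref, alt) if strand == "+" else (revcomp(ref), revcomp(alt))
            if chrom_seq[gpos].upper() != g_ref:
                raise ValueError(
                    f"site {gpos}: genomic base {chrom_seq[gpos]} != declared ref"
                )
            site_specs.append((gpos, g_alt, frac))
    bases = np.array(list("ACGT"))
    for reads in read_sets:
        n = len(reads)
        if config.per_base_error > 0:
            n_err = rng.binomial(reads.length, config.per_base_error)
            for i in np.nonzero(n_err)[0]:
                for _ in range(int(n_err[i])):
                    off = int(rng.integers(reads.length[i]))
                    gpos = int(reads.start[i]) + off
                    ref = chrom_seq[gpos].upper()
                    alt = str(rng.choice(bases[bases != ref]))
                    reads.variants.setdefault(int(i), []).append((gpos, alt))
        for gpos, g_alt, frac in site_specs:
            cover = (reads.start <= gpos) & (gpos < reads.start + reads.length)
            hit = np.nonzero(cover)[0]
            take = hit[rng.random(hit.size) < frac]
            for i in take:
                reads.variants.setdefault(int(i), []).append((gpos, g_alt))


# ---------------------------------------------------------------------------
# output formats
# ---------------------------------------------------------------------------

def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            fh.write(textwrap.fill(genome[chrom], width) + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _read_seq_and_md(reads: SimulatedReads, i: int, chrom_seq: str):
    s, l = int(reads.start[i]), int(reads.length[i])
    seq = list(chrom_seq[s : s + l].upper())
    subs = {}
    for gpos, alt in reads.variants.get(i, []):
        if seq[gpos - s] != alt:
            subs[gpos - s] = chrom_seq[gpos].upper()
            seq[gpos - s] = alt
    # MD tag: runs of matches separated by reference bases at mismatches
    md, run = [], 0
    for j in range(l):
        if j in subs:
            md.append(str(run))
            md.append(subs[j])
            run = 0
        else:
            run += 1
    md.append(str(run))
    return "".join(seq), "".join(md), len(subs)


def write_sam(
    reads: SimulatedReads, genome: dict[str, str], path, prefix: str = "r"
) -> None:
    """Write simulated alignments as minimal SAM with MD/NM tags."""
    chrom_seq = genome[reads.chrom]
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom in sorted(genome):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{len(genome[chrom])}\n")
        for i in range(len(reads)):
            # SEQ is stored in reference-forward orientation; FLAG 16
            # records that the read originally came from the minus strand
            seq, md, nm = _read_seq_and_md(reads, i, chrom_seq)
            flag = 16 if reads.minus[i] else 0
            out_seq = seq
            fh.write(
                f"{prefix}{i:08d}\t{flag}\t{reads.chrom}\t{int(reads.start[i]) + 1}\t"
                f"255\t{int(reads.length[i])}M\t*\t0\t0\t{out_seq}\t*\t"
                f"MD:Z:{md}\tNM:i:{nm}\n"
            )


def write_read_table(reads: SimulatedReads, path) -> None:
    """Plain tab table of simulated reads for debugging / ground truth."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tlabel\tgene_index\n")
        for i in range(len(reads)):
            fh.write(
                f"{reads.chrom}\t{int(reads.start[i])}\t"
                f"{int(reads.start[i] + reads.length[i])}\t"
                f"{'-' if reads.minus[i] else '+'}\t"
                f"{LABEL_NAMES[int(reads.label[i])]}\t{int(reads.gene_index[i])}\n"
            )
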