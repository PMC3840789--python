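"""Strand-aware fractional coverage from alignments, and expression metrics.

Footprint alignments are mapped to their estimated P-sites: 12 nt are
pruned from each end of the alignment and the remaining n = l - 24 central
positions each receive 1/n read.  A 25-mer therefore maps to one unique
position; a 26-mer is spread over two positions at 0.5 reads each.
Randomly fragmented mRNA alignments are counted along their whole length
at 1/l per position.  Each counted read contributes exactly one read of
total weight, so track totals conserve read counts.

Expression is reported in RPKM (reads per kilobase of feature per million
aligned reads) and translation efficiency (TE) as the ratio of footprint
RPKM in the CDS to mRNA-fragment RPKM over the locus, with peak-mask
windows around start and stop codons excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import R_CDS, Locus, TranscriptModel

__all__ = [
    "AlignedRead",
    "CoverageTrack",
    "assign_psite_weights",
    "assign_mrna_weights",
    "rpkm",
    "translation_efficiency",
    "lorenz_evenness",
    "peak_mask_positions",
    "reads_from_sam",
    "track_from_sam",
]

MIN_FOOTPRINT_LEN = 25
PSITE_TRIM = 12

# Peak-mask presets, in nt, all relative to codon boundaries in transcript
# coordinates.  "te" is the expression/TE mask (9 nt before the start codon,
# 15 nt after it, 15 nt before and after the stop codon); "readthrough" is
# the readthrough-rate mask (start codon + 12 nt after it, 15 nt before
# each stop codon, 9 nt after the CDS stop codon).
MASK_PRESETS = ("te", "readthrough")


@dataclass
class AlignedRead:
    """One uniquely-mapped read alignment with per-base match information.

    ``positions`` are the aligned reference positions in genomic ascending
    order (splice gaps simply absent); ``read_bases``/``ref_match`` are
    parallel arrays.  ``length`` is the aligned length.
    """

    qname: str
    chrom: str
    strand: str
    positions: np.ndarray
    read_bases: np.ndarray | None = None
    ref_match: np.ndarray | None = None
    unique: bool = True

    @property
    def length(self) -> int:
        return int(self.positions.size)

    def tx_order(self) -> np.ndarray:
        """Aligned positions in the read's 5'->3' orientation."""
        return self.positions[::-1] if self.strand == "-" else self.positions


class CoverageTrack:
    """Per-position fractional read weights for one read class.

    Holds one dense float array per (chromosome, strand).  ``n_reads``
    counts the reads accumulated, so conservation (total weight == reads)
    can be asserted.
    """

    def __init__(self, chrom_lengths: dict[str, int], read_class: str = "footprint"):
        self.read_class = read_class
        self.chrom_lengths = dict(chrom_lengths)
        self.arrays: dict[tuple[str, str], np.ndarray] = {}
        self.n_reads = 0
        self.n_rejected = 0

    def _arr(self, chrom: str, strand: str) -> np.ndarray:
        key = (chrom, strand)
        if key not in self.arrays:
            self.arrays[key] = np.zeros(self.chrom_lengths[chrom])
        return self.arrays[key]

    def add_read(self, read: AlignedRead) -> bool:
        """Accumulate one read; returns False if rejected (QC tally)."""
        if not read.unique:
            self.n_rejected += 1
            return False
        if self.read_class == "footprint":
            if read.length < MIN_FOOTPRINT_LEN:
                self.n_rejected += 1
                return False
            pos, w = assign_psite_weights(read)
        else:
            pos, w = assign_mrna_weights(read)
        np.add.at(self._arr(read.chrom, read.strand), pos, w)
        self.n_reads += 1
        return True

    def add_simple_reads(self, chrom: str, strand: str, starts, lengths) -> None:
        """Vectorised accumulation of gapless alignments (simulator path)."""
        starts = np.asarray(starts, dtype=np.int64)
        lengths = np.asarray(lengths, dtype=np.int64)
        arr = self._arr(chrom, strand)
        if self.read_class == "footprint":
            ok = lengths >= MIN_FOOTPRINT_LEN
            self.n_rejected += int((~ok).sum())
            starts, lengths = starts[ok], lengths[ok]
            for n in np.unique(lengths - 2 * PSITE_TRIM):
                sel = lengths - 2 * PSITE_TRIM == n
                s = starts[sel] + PSITE_TRIM
                for j in range(int(n)):
                    np.add.at(arr, s + j, 1.0 / n)
        else:
            for l in np.unique(lengths):
                sel = lengths == l
                s = starts[sel]
                for j in range(int(l)):
                    np.add.at(arr, s + j, 1.0 / l)
        self.n_reads += int(starts.size)

    def total_weight(self) -> float:
        return float(sum(a.sum() for a in self.arrays.values()))

    def weights_at(self, chrom: str, strand: str, positions: np.ndarray) -> np.ndarray:
        key = (chrom, strand)
        if key not in self.arrays:
            return np.zeros(np.asarray(positions).size)
        return self.arrays[key][np.asarray(positions, dtype=np.int64)]


def assign_psite_weights(read: AlignedRead) -> tuple[np.ndarray, float]:
    """P-site assignment: prune 12 nt from each alignment end, spread 1/n.

    Returns (genomic positions, per-position weight).  Rejects reads
    shorter than 25 nt.
    """
    l = read.length
    if l < MIN_FOOTPRINT_LEN:
        raise ValueError(f"footprint of length {l} < {MIN_FOOTPRINT_LEN} nt")
    n = l - 2 * PSITE_TRIM
    pos = read.positions[PSITE_TRIM : PSITE_TRIM + n]
    return pos, 1.0 / n


def assign_mrna_weights(read: AlignedRead) -> tuple[np.ndarray, float]:
    """mRNA-fragment rule: every aligned position receives 1/l."""
    return read.positions, 1.0 / read.length


def rpkm(
    track: CoverageTrack,
    chrom: str,
    strand: str,
    positions: np.ndarray,
    library_size: float,
) -> float:
    """RPKM over a position set: counts / (kb of feature) / (M aligned reads)."""
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size == 0:
        raise ValueError("RPKM undefined on an empty position set")
    counts = float(track.weights_at(chrom, strand, positions).sum())
    return counts / (positions.size / 1000.0) / (library_size / 1e6)


def lorenz_evenness(weights) -> float:
    """Area under the Lorenz curve of per-position weights.

    Weights are sorted ascending; the curve runs from (0, 0) to (1, 1) in
    cumulative position-share vs cumulative weight-share, integrated by
    trapezoids.  Uniform coverage gives exactly 0.5; concentration of all
    weight on few of many positions drives the area toward 0.
    """
    w = np.sort(np.asarray(weights, dtype=float))
    if w.size == 0:
        raise ValueError("need at least one position")
    total = w.sum()
    if total == 0:
        return 0.5  # empty track is uniform by convention
    y = np.concatenate([[0.0], np.cumsum(w) / total])
    x = np.linspace(0.0, 1.0, w.size + 1)
    return float(np.trapezoid(y, x))


def peak_mask_positions(t: TranscriptModel, preset: str = "te") -> set[int]:
    """Genomic positions excluded by the named start/stop peak mask."""
    tx = t.tx_positions()
    s, p = t.cds_tx_start, t.stop_tx
    idx: list[int] = []

    def add(a, b):
        idx.extend(range(max(0, a), min(len(tx), b)))

    if preset == "te":
        add(s - 9, s)        # 9 nt preceding the start codon
        add(s + 3, s + 18)   # 15 nt following it
        add(p - 15, p)       # 15 nt preceding the stop codon
        add(p + 3, p + 18)   # 15 nt following it
    elif preset == "readthrough":
        add(s, s + 15)       # start codon + 12 nt following it
        add(p - 15, p)       # 15 nt preceding the CDS stop codon
        add(p + 3, p + 12)   # 9 nt following it (start of any extension)
    else:
        raise ValueError(f"unknown mask preset {preset!r}")
    return {int(tx[i]) for i in idx}


@dataclass
class ExpressionRecord:
    locus_id: str
    footprint_counts: float
    mrna_counts: float
    footprint_rpkm: float
    mrna_rpkm: float
    translation_efficiency: float | None
    lorenz: float
    testable: bool


def translation_efficiency(
    locus: Locus,
    fp_track: CoverageTrack,
    mrna_track: CoverageTrack,
    fp_library_size: float,
    mrna_library_size: float,
    min_mrna_counts: float = 128.0,
    mask_preset: str = "te",
) -> ExpressionRecord:
    """Locus-level TE: CDS footprint RPKM over whole-locus mRNA RPKM.

    Ambiguously labelled, degenerate and peak-mask positions are excluded.
    Loci below the mRNA count threshold are flagged untestable (TE None).
    """
    masked = set()
    for t in locus.transcripts:
        masked |= peak_mask_positions(t, mask_preset)
    keep = ~locus.degenerate
    if masked:
        keep &= ~np.isin(locus.positions, np.fromiter(masked, dtype=np.int64))
    pos_all = locus.positions[keep]
    pos_cds = locus.positions[keep & (locus.labels == R_CDS)]
    ch, st = locus.chrom, locus.strand
    mrna_counts = float(mrna_track.weights_at(ch, st, pos_all).sum())
    fp_counts = float(fp_track.weights_at(ch, st, pos_cds).sum()) if pos_cds.size else 0.0
    mrna_r = rpkm(mrna_track, ch, st, pos_all, mrna_library_size) if pos_all.size else 0.0
    fp_r = rpkm(fp_track, ch, st, pos_cds, fp_library_size) if pos_cds.size else 0.0
    testable = mrna_counts >= min_mrna_counts
    te = (fp_r / mrna_r) if (testable and mrna_r > 0) else None
    lz = lorenz_evenness(fp_track.weights_at(ch, st, pos_cds)) if pos_cds.size else 0.5
    return ExpressionRecord(
        locus_id=locus.locus_id,
        footprint_counts=fp_counts,
        mrna_counts=mrna_counts,
        footprint_rpkm=fp_r,
        mrna_rpkm=mrna_r,
        translation_efficiency=te,
        lorenz=lz,
        testable=testable,
    )


# ---------------------------------------------------------------------------
# SAM ingestion (pysam)
# ---------------------------------------------------------------------------

def reads_from_sam(path):
    """Yield AlignedRead objects from a SAM/BAM file (requires MD tags)."""
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            pairs = aln.get_aligned_pairs(matches_only=True, with_seq=True)
            pos = np.array([p[1] for p in pairs], dtype=np.int64)
            refb = np.array([p[2].upper() for p in pairs])
            seq = aln.query_sequence
            readb = np.array([seq[p[0]] for p in pairs])
            yield AlignedRead(
                qname=aln.query_name,
                chrom=aln.reference_name,
                strand="-" if aln.is_reverse else "+",
                positions=pos,
                read_bases=readb,
                ref_match=refb == readb,
                unique=(aln.mapping_quality > 0),
            )


def track_from_sam(
    path, chrom_lengths: dict[str, int], read_class: str = "footprint"
) -> CoverageTrack:
    """Build a coverage track directly from a SAM/BAM file."""
    track = CoverageTrack(chrom_lengths, read_class)
    for read in reads_from_sam(path):
        track.add_read(read)
    return track
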