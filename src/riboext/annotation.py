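"""Transcript models, locus merging, region labelling and degeneracy masking.

Builds the countable coordinate space for all downstream counting: genes
whose transcripts share exons are collapsed into merged loci, positions are
labelled 5'UTR/CDS/3'UTR only where every isoform agrees, and genomic
positions whose centred 29-mer is non-unique in the genome (on either
strand) are masked as degenerate, since reads from them cannot map
uniquely.

Internal coordinates are 0-based half-open throughout; GFF3 (1-based
closed) is converted at the format boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TranscriptModel",
    "Locus",
    "mask_degenerate_positions",
    "merge_loci",
    "label_regions",
    "fraction_degenerate",
    "read_gff3",
    "write_gff3",
    "write_degenerate_bed",
]

# Region label codes used in per-position label arrays.
R_5UTR, R_CDS, R_3UTR, R_AMBIG = 0, 1, 2, 3
REGION_NAMES = {R_5UTR: "5UTR", R_CDS: "CDS", R_3UTR: "3UTR", R_AMBIG: "ambiguous"}

EXCLUDED_BIOTYPES = frozenset(
    {"miRNA", "pre_miRNA", "rRNA", "snRNA", "snoRNA", "tRNA"}
)

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript, strand-aware.

    ``cds_start`` is the genomic coordinate of the first base of the start
    codon in transcript orientation; ``cds_stop`` is the genomic coordinate
    of the first (transcript-orientation) base of the stop codon.  Exons
    are genomic 0-based half-open intervals sorted by genomic start.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_stop: int
    biotype: str = "protein_coding"

    def __post_init__(self):
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if b > c:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        self._tx_pos = None
        self._tx_index = None

    # -- coordinate helpers ------------------------------------------------
    def tx_positions(self) -> np.ndarray:
        """Genomic positions in 5'->3' transcript order."""
        if self._tx_pos is None:
            pos = np.concatenate([np.arange(a, b) for a, b in self.exons])
            if self.strand == "-":
                pos = pos[::-1]
            self._tx_pos = pos
        return self._tx_pos

    def __len__(self) -> int:
        return sum(b - a for a, b in self.exons)

    def to_tx(self, genomic_pos: int) -> int:
        """Transcript index of a genomic position (KeyError if intronic)."""
        if self._tx_index is None:
            self._tx_index = {int(g): i for i, g in enumerate(self.tx_positions())}
        return self._tx_index[int(genomic_pos)]

    @property
    def cds_tx_start(self) -> int:
        return self.to_tx(self.cds_start)

    @property
    def stop_tx(self) -> int:
        """Transcript index of the first base of the stop codon."""
        return self.to_tx(self.cds_stop)

    def sequence(self, genome: dict[str, str]) -> str:
        """Spliced mRNA sequence in transcript orientation."""
        seq = "".join(genome[self.chrom][a:b] for a, b in self.exons)
        return revcomp(seq) if self.strand == "-" else seq.upper()

    def validate_cds(self, genome: dict[str, str] | None = None) -> None:
        """Check CDS frame and, when a genome is supplied, start/stop codons."""
        cds_len = self.stop_tx - self.cds_tx_start + 3  # incl. stop codon
        if cds_len <= 0 or cds_len % 3:
            raise ValueError(
                f"{self.transcript_id}: CDS length {cds_len} not a positive multiple of 3"
            )
        if genome is not None:
            seq = self.sequence(genome)
            s = self.cds_tx_start
            if seq[s : s + 3] != "ATG":
                raise ValueError(f"{self.transcript_id}: CDS does not begin ATG")
            if seq[self.stop_tx : self.stop_tx + 3] not in ("TAA", "TAG", "TGA"):
                raise ValueError(f"{self.transcript_id}: CDS does not end in a stop")

    def region_of_tx(self, i: int) -> int:
        """Region label of transcript index i (stop codon counts as CDS)."""
        if i < self.cds_tx_start:
            return R_5UTR
        if i < self.stop_tx + 3:
            return R_CDS
        return R_3UTR


@dataclass
class Locus:
    """A merged gene locus with per-position region labels and masks."""

    locus_id: str
    gene_ids: list[str]
    chrom: str
    strand: str
    transcripts: list[TranscriptModel]
    positions: np.ndarray            # sorted genomic positions kept for counting
    labels: np.ndarray               # region codes parallel to positions
    degenerate: np.ndarray = field(default=None)  # bool mask parallel to positions
    biotype: str = "protein_coding"
    countable: bool = True

    def region_positions(self, region: int) -> np.ndarray:
        return self.positions[self.labels == region]

    def countable_positions(self) -> np.ndarray:
        if self.degenerate is None:
            return self.positions
        return self.positions[~self.degenerate]


# ---------------------------------------------------------------------------
# degeneracy masking
# ---------------------------------------------------------------------------

def mask_degenerate_positions(
    genome: dict[str, str], k: int = 29, both_strands: bool = True
) -> dict[str, np.ndarray]:
    """Flag genomic positions whose centred k-mer is non-unique.

    A position is degenerate iff the k-mer centred on it (position +/- k//2)
    occurs anywhere else in the genome, by default on either strand.
    Positions closer than k//2 to a sequence end cannot form the centred
    window and are flagged as degenerate (unmappable).

    Returns a per-chromosome boolean array.
    """
    half = k // 2
    counts: dict[str, int] = {}
    for seq in genome.values():
        s = seq.upper()
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            key = min(kmer, revcomp(kmer)) if both_strands else kmer
            counts[key] = counts.get(key, 0) + 1
    out = {}
    for chrom, seq in genome.items():
        s = seq.upper()
        n = len(s)
        mask = np.ones(n, dtype=bool)
        for center in range(half, n - half):
            kmer = s[center - half : center + half + 1]
            key = min(kmer, revcomp(kmer)) if both_strands else kmer
            mask[center] = counts[key] > 1
        out[chrom] = mask
    return out


# ---------------------------------------------------------------------------
# locus merging and labelling
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def merge_loci(
    transcripts: list[TranscriptModel],
    degenerate: dict[str, np.ndarray] | None = None,
    min_nondegenerate_fraction: float = 0.95,
    min_exonic_length: int = 60,
    excluded_biotypes: frozenset[str] = EXCLUDED_BIOTYPES,
) -> list[Locus]:
    """Collapse genes whose transcripts share an exon into merged loci.

    Genes are merged by transitive closure of sharing an identical exon on
    the same strand.  Genomic positions that remain attributed to more than
    one merged locus afterwards (e.g. overlapping genes) are excluded from
    every locus.  A locus is countable iff, after exclusions, at least
    ``min_nondegenerate_fraction`` of its positions are non-degenerate, the
    non-degenerate positions number at least ``min_exonic_length``, and its
    biotype is not in the excluded set.
    """
    for t in transcripts:
        t.validate_cds()
    genes: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        genes.setdefault(t.gene_id, []).append(t)
    uf = _UnionFind(genes)
    exon_owner: dict[tuple, str] = {}
    for t in transcripts:
        for ex in t.exons:
            key = (t.chrom, t.strand, ex)
            if key in exon_owner:
                uf.union(exon_owner[key], t.gene_id)
            else:
                exon_owner[key] = t.gene_id
    groups: dict[str, list[str]] = {}
    for g in genes:
        groups.setdefault(uf.find(g), []).append(g)

    # collect exonic positions per locus, then strike cross-locus overlaps
    loci_raw = []
    claim: dict[tuple[str, int], int] = {}
    for li, (root, members) in enumerate(sorted(groups.items())):
        txs = [t for g in sorted(members) for t in genes[g]]
        chrom = txs[0].chrom
        strand = txs[0].strand
        pos = np.unique(np.concatenate([t.tx_positions() for t in txs]))
        for p in pos:
            key = (chrom, int(p))
            claim[key] = -1 if key in claim else li
        loci_raw.append((sorted(members), chrom, strand, txs, pos))

    loci = []
    for li, (members, chrom, strand, txs, pos) in enumerate(loci_raw):
        keep = np.array([claim[(chrom, int(p))] == li for p in pos])
        pos = pos[keep]
        labels = label_regions(txs, pos)
        if degenerate is not None:
            dg = degenerate[chrom][pos]
        else:
            dg = np.zeros(pos.size, dtype=bool)
        biotype = txs[0].biotype
        n_ok = int((~dg).sum())
        countable = (
            biotype not in excluded_biotypes
            and pos.size > 0
            and n_ok / pos.size >= min_nondegenerate_fraction
            and n_ok >= min_exonic_length
        )
        loci.append(
            Locus(
                locus_id=f"LOC{li:05d}",
                gene_ids=members,
                chrom=chrom,
                strand=strand,
                transcripts=txs,
                positions=pos,
                labels=labels,
                degenerate=dg,
                biotype=biotype,
                countable=countable,
            )
        )
    return loci


def label_regions(
    transcripts: list[TranscriptModel], positions: np.ndarray
) -> np.ndarray:
    """Label each position 5UTR/CDS/3UTR where all isoforms agree, else ambiguous."""
    labels = np.full(positions.size, -1, dtype=np.int8)
    for t in transcripts:
        tx_set = {int(g): t.region_of_tx(i) for i, g in enumerate(t.tx_positions())}
        for j, p in enumerate(positions):
            r = tx_set.get(int(p))
            if r is None:
                continue
            if labels[j] == -1:
                labels[j] = r
            elif labels[j] != r:
                labels[j] = R_AMBIG
    if np.any(labels == -1):
        raise ValueError("position not covered by any member transcript")
    return labels


def fraction_degenerate(locus: Locus) -> float:
    """Fraction of a locus's exonic positions flagged degenerate."""
    if locus.positions.size == 0:
        return 0.0
    return float(locus.degenerate.sum() / locus.positions.size)


# ---------------------------------------------------------------------------
# GFF3 / BED I/O
# ---------------------------------------------------------------------------

def write_gff3(transcripts: list[TranscriptModel], path) -> None:
    """Write transcripts as GFF3 (gene/mRNA/exon/CDS; CDS includes the stop)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        by_gene: dict[str, list[TranscriptModel]] = {}
        for t in transcripts:
            by_gene.setdefault(t.gene_id, []).append(t)
        for gid in sorted(by_gene):
            txs = by_gene[gid]
            g0 = min(t.exons[0][0] for t in txs)
            g1 = max(t.exons[-1][1] for t in txs)
            t0 = txs[0]
            fh.write(
                f"{t0.chrom}\triboext\tgene\t{g0 + 1}\t{g1}\t.\t{t0.strand}\t.\t"
                f"ID={gid};biotype={t0.biotype}\n"
            )
            for t in txs:
                fh.write(
                    f"{t.chrom}\triboext\tmRNA\t{t.exons[0][0] + 1}\t{t.exons[-1][1]}\t.\t"
                    f"{t.strand}\t.\tID={t.transcript_id};Parent={gid}\n"
                )
                for a, b in t.exons:
                    fh.write(
                        f"{t.chrom}\triboext\texon\t{a + 1}\t{b}\t.\t{t.strand}\t.\t"
                        f"Parent={t.transcript_id}\n"
                    )
                # CDS genomic span including the stop codon
                tx = t.tx_positions()
                cds_idx = tx[t.cds_tx_start : t.stop_tx + 3]
                lo, hi = int(cds_idx.min()), int(cds_idx.max()) + 1
                # emit per-exon CDS blocks
                for a, b in t.exons:
                    s, e = max(a, lo), min(b, hi)
                    if s < e:
                        fh.write(
                            f"{t.chrom}\triboext\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t0\t"
                            f"Parent={t.transcript_id}\n"
                        )


def read_gff3(path) -> list[TranscriptModel]:
    """Read transcripts from a GFF3 written in the dialect above.

    Understands gene/mRNA/exon/CDS rows with ID/Parent/biotype attributes;
    GFF3 1-based closed coordinates are converted to 0-based half-open.
    """
    genes_bio: dict[str, str] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}  # tid -> (chrom, strand, gene)
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = (
                line.rstrip("\n").split("\t")
            )
            a = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            start, end = int(start) - 1, int(end)
            if ftype == "gene":
                genes_bio[a["ID"]] = a.get("biotype", "protein_coding")
            elif ftype == "mRNA":
                tx_meta[a["ID"]] = (chrom, strand, a["Parent"])
            elif ftype == "exon":
                exons.setdefault(a["Parent"], []).append((start, end))
            elif ftype == "CDS":
                cds.setdefault(a["Parent"], []).append((start, end))
    out = []
    for tid, (chrom, strand, gid) in tx_meta.items():
        ex = sorted(exons[tid])
        cd = sorted(cds[tid])
        if strand == "+":
            cds_start = cd[0][0]
            # first base of stop codon = 3 bases before CDS end, in tx coords
            stop_first = cd[-1][1] - 3  # single-exon stop assumed within last block
        else:
            cds_start = cd[-1][1] - 1
            stop_first = cd[0][0] + 2
        t = TranscriptModel(
            gene_id=gid,
            transcript_id=tid,
            chrom=chrom,
            strand=strand,
            exons=ex,
            cds_start=cds_start,
            cds_stop=stop_first,
            biotype=genes_bio.get(gid, "protein_coding"),
        )
        # correct stop coordinate across splice junctions via tx coords
        tx = t.tx_positions()
        cds_len = sum(e - s for s, e in cd)
        t.cds_stop = int(tx[t.cds_tx_start + cds_len - 3])
        t._tx_index = None
        out.append(t)
    return out


def write_degenerate_bed(mask: dict[str, np.ndarray], path) -> None:
    """Write the degenerate mask as merged BED intervals."""
    with open(path, "w") as fh:
        for chrom in sorted(mask):
            m = mask[chrom]
            diffs = np.flatnonzero(np.diff(np.concatenate([[0], m.view(np.int8), [0]])))
            for s, e in zip(diffs[::2], diffs[1::2]):
                fh.write(f"{chrom}\t{s}\t{e}\n")
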