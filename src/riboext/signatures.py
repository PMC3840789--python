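"""Diagnostics separating true translation from contaminant density.

Metagene profiles (median of CDS-normalised coverage around start/stop
anchors), ribosome release scores (reads in the five-codon window
downstream of a stop over the five-codon window upstream; near zero at
efficient termination), footprint length distributions, and triplet
phasing of 28-mer footprints tested against the frame composition of
matched mRNA fragments (chi-squared, dof = 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import TranscriptModel
from .density import CoverageTrack
from .simulate import SimulatedReads
from .stats import chi_squared_gof

__all__ = [
    "MetageneProfile",
    "ReleaseScore",
    "PhasingTable",
    "metagene_profile",
    "release_score",
    "length_distribution",
    "tv_distance",
    "phasing_test",
    "read_tx_positions",
]

CODON_BUFFER_NT = 9       # 3-codon buffer excluded from the normaliser
PSITE_FRAME_OFFSET = 12   # fixed 5'+12 offset used for frame calls


@dataclass
class MetageneProfile:
    anchor: str
    offsets: np.ndarray
    median: np.ndarray
    n_roi: int


def _tx_coverage(t: TranscriptModel, track: CoverageTrack) -> np.ndarray:
    return track.weights_at(t.chrom, t.strand, t.tx_positions())


def metagene_profile(
    rois: list[tuple[TranscriptModel, int]],
    track: CoverageTrack,
    anchor: str = "stop",
    window: tuple[int, int] = (-50, 50),
    min_reads: float = 10.0,
) -> MetageneProfile:
    """Median of normalised coverage across ROIs, anchored at a landmark.

    Each ROI is (transcript, anchor transcript-index); use cds_tx_start
    for a start anchor, stop_tx for a stop anchor, or an extension's stop
    index.  Each coverage vector is normalised to the mean footprint
    coverage of the ROI's coding region excluding a 3-codon buffer at each
    CDS end; ROIs with fewer than ``min_reads`` reads in the coding
    subregion are dropped.  At least two ROIs must survive.
    """
    lo, hi = window
    offsets = np.arange(lo, hi + 1)
    vectors = []
    for t, a in rois:
        cov = _tx_coverage(t, track)
        if a + lo < 0 or a + hi >= cov.size:
            continue
        s, p = t.cds_tx_start, t.stop_tx
        body = cov[s + CODON_BUFFER_NT : p - CODON_BUFFER_NT]
        if body.size == 0 or cov[s:p].sum() < min_reads:
            continue
        mean = body.mean()
        if mean <= 0:
            continue
        vectors.append(cov[a + lo : a + hi + 1] / mean)
    if len(vectors) < 2:
        raise ValueError("metagene profile needs at least 2 qualifying ROIs")
    med = np.median(np.vstack(vectors), axis=0)
    return MetageneProfile(anchor=anchor, offsets=offsets, median=med,
                           n_roi=len(vectors))


@dataclass
class ReleaseScore:
    upstream_counts: float
    downstream_counts: float
    score: float | None  # None when the upstream window is empty

    @property
    def defined(self) -> bool:
        return self.score is not None


def release_score(
    t: TranscriptModel, codon_tx: int, track: CoverageTrack
) -> ReleaseScore:
    """Ratio of reads in the 5-codon window downstream of a codon to the
    5-codon window upstream.  No pseudocount: zero upstream leaves the
    score undefined."""
    cov = _tx_coverage(t, track)
    if codon_tx - 15 < 0 or codon_tx + 18 > cov.size:
        raise ValueError("release-score windows fall outside the transcript")
    up = float(cov[codon_tx - 15 : codon_tx].sum())
    down = float(cov[codon_tx + 3 : codon_tx + 18].sum())
    return ReleaseScore(up, down, down / up if up > 0 else None)


def length_distribution(lengths, lo: int = 25, hi: int = 35) -> np.ndarray:
    """Normalised histogram of read lengths over [lo, hi]."""
    lengths = np.asarray(lengths)
    if lengths.size == 0:
        raise ValueError("need at least one read")
    counts = np.array([(lengths == l).sum() for l in range(lo, hi + 1)], dtype=float)
    return counts / counts.sum()


def tv_distance(p, q) -> float:
    """Total variation distance between two discrete distributions."""
    return float(0.5 * np.abs(np.asarray(p) - np.asarray(q)).sum())


def read_tx_positions(
    reads: SimulatedReads, transcripts: list[TranscriptModel]
) -> np.ndarray:
    """Transcript coordinate of each read's 5' end (gapless reads)."""
    tx5 = np.full(len(reads), -1, dtype=np.int64)
    for gi, t in enumerate(transcripts):
        sel = reads.gene_index == gi
        g0, g1 = t.exons[0][0], t.exons[0][1]
        if t.strand == "-":
            tx5[sel] = g1 - (reads.start[sel] + reads.length[sel])
        else:
            tx5[sel] = reads.start[sel] - g0
    return tx5


@dataclass
class PhasingTable:
    region: str
    footprint_frames: np.ndarray  # counts for frames 0, 1, 2
    mrna_frames: np.ndarray
    chi2: float = float("nan")
    dof: int = 2
    p: float = float("nan")


def phasing_test(
    fp_reads: SimulatedReads,
    mrna_reads: SimulatedReads,
    transcripts: list[TranscriptModel],
    regions: dict[str, tuple[int, int]],
    region_name: str = "CDS",
    footprint_length: int = 28,
    uniform_null: bool = False,
) -> PhasingTable:
    """Frame counts of 28-mer footprints in a region, tested against the
    frame composition of mRNA fragments in the same region.

    ``regions`` maps gene_id to a transcript-coordinate half-open interval
    (e.g. the CDS, an extension, or a 40-codon distal window).  Frames are
    relative to the annotated CDS frame via the fixed 5'+12 P-site offset.
    The chi-squared statistic (dof = 2) compares footprint frame counts to
    expected proportions from the mRNA fragments (the cloning-bias
    control), or to a uniform null when ``uniform_null``.
    """
    gene_of = {t.gene_id: (gi, t) for gi, t in enumerate(transcripts)}

    def frames(reads, length_filter):
        tx5 = read_tx_positions(reads, transcripts)
        counts = np.zeros(3)
        psite = tx5 + PSITE_FRAME_OFFSET
        for gid, (lo, hi) in regions.items():
            gi, t = gene_of[gid]
            sel = (reads.gene_index == gi) & (psite >= lo) & (psite < hi)
            if length_filter is not None:
                sel &= reads.length == length_filter
            fr = (psite[sel] - t.cds_tx_start) % 3
            for k in range(3):
                counts[k] += int((fr == k).sum())
        return counts

    fp = frames(fp_reads, footprint_length)
    mr = frames(mrna_reads, None)
    if uniform_null:
        props = np.ones(3) / 3
    else:
        if np.any(mr == 0):
            raise ValueError("expected (mRNA) frame count of zero")
        props = mr / mr.sum()
    stat, dof, p = chi_squared_gof(fp, props)
    return PhasingTable(region_name, fp, mr, stat, dof, p)
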