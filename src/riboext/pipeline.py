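"""End-to-end glue: simulated or ingested reads -> tracks -> readthrough calls."""

from __future__ import annotations

import numpy as np

from .annotation import TranscriptModel
from .density import AlignedRead, CoverageTrack
from .readthrough import (
    ReadthroughRecord,
    apply_filters,
    enumerate_candidates,
    readthrough_rate,
    score_candidate,
)
from .simulate import SimulatedReads, SimulationConfig

__all__ = [
    "track_from_simulated",
    "to_aligned_reads",
    "detect_readthrough",
    "run_simulated_sample",
]


def track_from_simulated(
    reads: SimulatedReads, genome: dict[str, str], read_class: str | None = None
) -> CoverageTrack:
    """Vectorised coverage accumulation from simulated alignments."""
    track = CoverageTrack(
        {c: len(s) for c, s in genome.items()}, read_class or reads.read_class
    )
    for minus in (False, True):
        sel = reads.minus == minus
        if sel.any():
            track.add_simple_reads(
                reads.chrom, "-" if minus else "+", reads.start[sel], reads.length[sel]
            )
    return track


def to_aligned_reads(reads: SimulatedReads, genome: dict[str, str]):
    """Yield AlignedRead objects (with per-base match info) from simulated reads."""
    chrom_seq = genome[reads.chrom]
    for i in range(len(reads)):
        s, l = int(reads.start[i]), int(reads.length[i])
        pos = np.arange(s, s + l, dtype=np.int64)
        refb = np.array(list(chrom_seq[s : s + l].upper()))
        readb = refb.copy()
        for gpos, alt in reads.variants.get(i, []):
            readb[gpos - s] = alt
        yield AlignedRead(
            qname=f"sim{i:08d}",
            chrom=reads.chrom,
            strand="-" if reads.minus[i] else "+",
            positions=pos,
            read_bases=readb,
            ref_match=refb == readb,
        )


def detect_readthrough(
    transcripts: list[TranscriptModel],
    genome: dict[str, str],
    fp_track: CoverageTrack,
    library_size: float | None = None,
    min_cds_counts: float = 128.0,
    met_whitelist: frozenset = frozenset(),
) -> list[ReadthroughRecord]:
    """Enumerate, quantify, filter and score all candidate extensions."""
    if library_size is None:
        library_size = fp_track.n_reads
    genome_len = max(len(s) for s in genome.values())
    records = []
    for cand in enumerate_candidates(transcripts, genome, met_whitelist):
        if cand.excluded:
            continue
        rec = readthrough_rate(
            cand, fp_track, library_size, min_cds_counts, genome_len
        )
        apply_filters(rec, fp_track, library_size)
        score_candidate(rec, fp_track)
        records.append(rec)
    return records


def run_simulated_sample(config: SimulationConfig):
    """Simulate one sample and run detection; returns a results bundle."""
    from .simulate import generate_transcriptome, simulate_reads

    genome, transcripts = generate_transcriptome(config)
    fp_reads, mrna_reads, truth = simulate_reads(config, genome, transcripts)
    fp_track = track_from_simulated(fp_reads, genome)
    mrna_track = track_from_simulated(mrna_reads, genome)
    records = detect_readthrough(transcripts, genome, fp_track)
    return {
        "genome": genome,
        "transcripts": transcripts,
        "footprints": fp_reads,
        "mrna": mrna_reads,
        "truth": truth,
        "fp_track": fp_track,
        "mrna_track": mrna_track,
        "records": records,
    }
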