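import pytest

from riboext.annotation import TranscriptModel
from riboext.density import CoverageTrack
from riboext.pipeline import run_simulated_sample
from riboext.simulate import SimulationConfig


def make_transcript(
    utr5=30,
    cds_codons=40,
    utr3=60,
    strand="+",
    offset=0,
    chrom_len=None,
    gene_id="gA",
):
    """Single-exon transcript skeleton; coordinates only, no sequence."""
    tx_len = utr5 + 3 * cds_codons + utr3
    g0, g1 = offset, offset + tx_len
    if strand == "+":
        cds_start = g0 + utr5
        cds_stop = g0 + utr5 + 3 * cds_codons - 3
    else:
        cds_start = g1 - 1 - utr5
        cds_stop = g1 - 1 - (utr5 + 3 * cds_codons - 3)
    return TranscriptModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.t1",
        chrom="chr1",
        strand=strand,
        exons=[(g0, g1)],
        cds_start=cds_start,
        cds_stop=cds_stop,
    )


def uniform_track(t, cds_weight=1.0, ext_weight=0.0, ext_nt=0, chrom_len=2000):
    """Track with uniform per-nt weight over the CDS and optionally the
    first ext_nt of the 3'UTR (an extension)."""
    track = CoverageTrack({"chr1": chrom_len})
    tx = t.tx_positions()
    arr = track._arr("chr1", t.strand)
    for i in range(t.cds_tx_start, t.stop_tx + 3):
        arr[tx[i]] = cds_weight
    for i in range(t.stop_tx + 3, min(t.stop_tx + 3 + ext_nt, len(tx))):
        arr[tx[i]] = ext_weight
    track.n_reads = int(round(track.total_weight()))
    return track


@pytest.fixture(scope="session")
def base_sim():
    """A small mixed sample: readthrough genes on both strands plus nulls."""
    cfg = SimulationConfig(
        seed=11,
        n_genes=4,
        cds_len=(300, 450),
        utr3_len=(250, 300),
        readthrough_rate_map={"g000": 0.05, "g002": 0.1},
        extension_codons_map={"g000": 25, "g002": 30},
        total_footprints=80_000,
        total_mrna_fragments=40_000,
    )
    return run_simulated_sample(cfg)
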