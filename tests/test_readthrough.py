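"""Candidate enumeration, readthrough rates, filters, scoring, differential."""

import pytest

from riboext.annotation import TranscriptModel
from riboext.density import CoverageTrack
from riboext.pipeline import run_simulated_sample, track_from_simulated
from riboext.readthrough import (
    apply_filters,
    differential_readthrough,
    double_readthrough_scan,
    enumerate_candidates,
    format_extension_coords,
    log10_fold_change,
    readthrough_rate,
    score_candidate,
)
from riboext.simulate import SimulationConfig, generate_transcriptome, simulate_reads

PAD = 60


def toy_gene(utr3_codons, cds_codons=50, utr5=30, gene_id="gA"):
    """Deterministic single-gene genome with a hand-built 3'UTR."""
    cds = "ATG" + "GCT" * (cds_codons - 2) + "TAA"
    utr3 = "".join(utr3_codons)
    sense = "C" * utr5 + cds + utr3
    genome = {"chr1": "C" * PAD + sense + "C" * PAD}
    t = TranscriptModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.t1",
        chrom="chr1",
        strand="+",
        exons=[(PAD, PAD + len(sense))],
        cds_start=PAD + utr5,
        cds_stop=PAD + utr5 + 3 * cds_codons - 3,
    )
    return genome, t


def fill_track(t, cds_w=0.0, ext_w=0.0, ext_nt=None, distal_w=0.0, chrom_len=None):
    """Uniform per-nt weights over CDS, extension and distal window.

    With library_size=1e9 downstream, RPKM equals the per-position weight.
    """
    chrom_len = chrom_len or (t.exons[0][1] + 400)
    track = CoverageTrack({"chr1": chrom_len})
    arr = track._arr("chr1", t.strand)
    tx = t.tx_positions()
    for i in range(t.cds_tx_start, t.stop_tx + 3):
        arr[tx[i]] = cds_w
    if ext_nt:
        for i in range(t.stop_tx + 3, t.stop_tx + 3 + ext_nt):
            arr[tx[i]] = ext_w
        for i in range(t.stop_tx + 6 + ext_nt, t.stop_tx + 6 + ext_nt + 120):
            if i < len(tx):
                arr[tx[i]] = distal_w
    track.n_reads = max(1, int(round(track.total_weight())))
    return track


LIB = 1e9  # library size making RPKM == mean per-position weight


class TestEnumerateCandidates:
    def test_extension_ends_at_first_inframe_stop(self):
        # 8 sense codons, then TAA, then more UTR
        genome, t = toy_gene(["GGC"] * 8 + ["TAA"] + ["CCA"] * 20)
        (cand,) = enumerate_candidates([t], genome)
        assert not cand.excluded
        assert cand.length_codons == 8
        tx = t.tx_positions()
        assert cand.ext_genomic()[0] == tx[t.stop_tx + 3]

    def test_out_of_frame_stop_ignored(self):
        # a TAA shifted by 1 nt must not terminate the walk
        utr3 = ["GGC", "CTA", "AGC", "GGC", "GGC", "GGC", "TGA", "CCC"]
        genome, t = toy_gene(utr3)
        (cand,) = enumerate_candidates([t], genome)
        assert cand.length_codons == 6

    def test_short_extension_excluded(self):
        genome, t = toy_gene(["GGC"] * 4 + ["TAA"] + ["CCA"] * 10)
        (cand,) = enumerate_candidates([t], genome)
        assert cand.excluded and "5 codons" in cand.exclusion_reason

    def test_met_in_first_three_codons_flagged(self):
        genome, t = toy_gene(["GGC", "ATG"] + ["GGC"] * 8 + ["TAA", "CCC"])
        (cand,) = enumerate_candidates([t], genome)
        assert cand.met_in_first3 and cand.first_met_codon == 1
        # whitelisting lifts the flag (the experimentally-validated exception)
        (cand_wl,) = enumerate_candidates([t], genome, met_whitelist=frozenset(["gA"]))
        assert not cand_wl.met_in_first3

    def test_no_next_stop_yields_no_candidate(self):
        genome, t = toy_gene(["GGC"] * 10)
        assert enumerate_candidates([t], genome) == []

    def test_isoforms_sharing_extension_grouped(self):
        genome, t1 = toy_gene(["GGC"] * 8 + ["TAA", "CCC"], cds_codons=50)
        # second isoform: same stop, shorter CDS (annotated start 10 codons in)
        t2 = TranscriptModel(
            "gA", "gA.t2", "chr1", "+", t1.exons,
            cds_start=t1.cds_start + 30, cds_stop=t1.cds_stop,
        )
        cands = enumerate_candidates([t1, t2], genome)
        assert len(cands) == 1
        assert sorted(c.split(".")[1] for c in cands[0].transcript_ids) == ["t1", "t2"]


class TestReadthroughRate:
    def test_rho_is_density_ratio(self):
        genome, t = toy_gene(["GGC"] * 30 + ["TAA"] + ["CCA"] * 40)
        (cand,) = enumerate_candidates([t], genome)
        track = fill_track(t, cds_w=50.0, ext_w=0.5, ext_nt=90)
        rec = readthrough_rate(cand, track, LIB, min_cds_counts=0)
        assert rec.rho == pytest.approx(0.01)
        assert rec.cds_rpkm == pytest.approx(50.0)
        assert rec.ext_rpkm == pytest.approx(0.5)

    def test_isoform_minimising_rho_reported(self):
        genome, t1 = toy_gene(["GGC"] * 30 + ["TAA", "CCC"], cds_codons=60)
        t2 = TranscriptModel(
            "gA", "gA.t2", "chr1", "+", t1.exons,
            cds_start=t1.cds_start + 60, cds_stop=t1.cds_stop,
        )
        (cand,) = enumerate_candidates([t1, t2], genome)
        # weight only over t2's (shorter) CDS: t1's density is diluted,
        # so t1 yields the higher rho and t2 must be chosen
        track = fill_track(t2, cds_w=100.0, ext_w=1.0, ext_nt=90)
        rec = readthrough_rate(cand, track, LIB, min_cds_counts=0)
        chosen = cand.isoforms[rec.isoform_index][0]
        assert chosen.transcript_id == "gA.t2"
        assert rec.rho == pytest.approx(0.01)

    def test_extension_shorter_than_mask_unmeasurable(self):
        genome, t = toy_gene(["GGC"] * 6 + ["TAA", "CCC"])
        (cand,) = enumerate_candidates([t], genome)
        track = fill_track(t, cds_w=10.0)
        rec = readthrough_rate(cand, track, LIB, min_cds_counts=0)
        assert rec.rate_unmeasurable

    def test_low_cds_counts_untestable(self):
        genome, t = toy_gene(["GGC"] * 30 + ["TAA", "CCC"])
        (cand,) = enumerate_candidates([t], genome)
        track = fill_track(t, cds_w=0.1, ext_w=0.01, ext_nt=90)
        rec = readthrough_rate(cand, track, LIB, min_cds_counts=128)
        assert not rec.testable


class TestFilters:
    def _record(self, cds_w, ext_w, distal_w):
        genome, t = toy_gene(["GGC"] * 40 + ["TAA"] + ["CCA"] * 45)
        (cand,) = enumerate_candidates([t], genome)
        track = fill_track(t, cds_w=cds_w, ext_w=ext_w, ext_nt=120, distal_w=distal_w)
        rec = readthrough_rate(cand, track, LIB, min_cds_counts=0)
        apply_filters(rec, track, LIB)
        return rec

    def test_low_extension_density_fails_a(self):
        rec = self._record(cds_w=50.0, ext_w=0.1, distal_w=0.0)
        assert not rec.filters["a"] and rec.filters["b"]

    def test_low_rate_fails_b(self):
        rec = self._record(cds_w=1000.0, ext_w=0.5, distal_w=0.0)
        assert rec.filters["a"] and not rec.filters["b"]
        assert rec.rho == pytest.approx(0.0005)

    def test_insufficient_drop_fails_f(self):
        rec = self._record(cds_w=50.0, ext_w=1.0, distal_w=0.3)
        assert rec.drop_fraction == pytest.approx(0.7)
        assert not rec.filters["f"]
        rec2 = self._record(cds_w=50.0, ext_w=1.0, distal_w=0.2)
        assert rec2.filters["f"]

    def test_uniform_coverage_passes_all(self):
        rec = self._record(cds_w=50.0, ext_w=1.0, distal_w=0.0)
        assert all(rec.filters.values())


class TestScoring:
    def test_dense_even_coverage_scores_readthrough(self):
        genome, t = toy_gene(["GGC"] * 40 + ["TAA"] + ["CCA"] * 45)
        (cand,) = enumerate_candidates([t], genome)
        track = fill_track(t, cds_w=50.0, ext_w=1.0, ext_nt=120)
        rec = readthrough_rate(cand, track, LIB, min_cds_counts=0)
        apply_filters(rec, track, LIB)
        assert score_candidate(rec, track) == "readthrough"

    def test_coverage_confined_to_start_scores_negative(self):
        genome, t = toy_gene(["GGC"] * 40 + ["TAA"] + ["CCA"] * 45)
        (cand,) = enumerate_candidates([t], genome)
        track = fill_track(t, cds_w=50.0)
        arr = track.arrays[("chr1", "+")]
        tx = t.tx_positions()
        for i in range(t.stop_tx + 3, t.stop_tx + 3 + 12):  # first 10% only
            arr[tx[i]] = 5.0
        rec = readthrough_rate(cand, track, LIB, min_cds_counts=0)
        apply_filters(rec, track, LIB)
        assert score_candidate(rec, track) == "negative"

    def test_sparse_coverage_rescued_by_stop_peak(self):
        genome, t = toy_gene(["GGC"] * 40 + ["TAA"] + ["CCA"] * 45)
        (cand,) = enumerate_candidates([t], genome)
        track = fill_track(t, cds_w=50.0)
        arr = track.arrays[("chr1", "+")]
        tx = t.tx_positions()
        a, b = cand.isoforms[0][1]
        for i in (a + 20, a + 50, a + 80):  # a few scattered positions
            arr[tx[i]] = 2.0
        arr[tx[b]] = 2.5  # >= 2 reads at the extension's stop codon
        rec = readthrough_rate(cand, track, LIB, min_cds_counts=0)
        apply_filters(rec, track, LIB)
        assert score_candidate(rec, track) == "readthrough"
        assert any("sparse" in r for r in rec.reasons)

    def test_met_in_first_codons_never_positive(self):
        genome, t = toy_gene(["GGC", "ATG"] + ["GGC"] * 38 + ["TAA"] + ["CCA"] * 45)
        (cand,) = enumerate_candidates([t], genome)
        track = fill_track(t, cds_w=50.0, ext_w=1.0, ext_nt=120)
        rec = readthrough_rate(cand, track, LIB, min_cds_counts=0)
        apply_filters(rec, track, LIB)
        assert score_candidate(rec, track) == "ambiguous"


class TestSimulationRecovery:
    def test_rate_recovered_within_20pct(self):
        cfg = SimulationConfig(
            seed=17, n_genes=1, cds_len=(300, 300), utr3_len=(250, 250),
            readthrough_rate_map={"g000": 0.05}, extension_codons_map={"g000": 30},
            total_footprints=200_000, total_mrna_fragments=1000,
        )
        res = run_simulated_sample(cfg)
        (rec,) = res["records"]
        assert rec.score == "readthrough"
        assert rec.rho == pytest.approx(0.05, rel=0.2)

    def test_double_readthrough_second_tier(self):
        cfg = SimulationConfig(
            seed=23, n_genes=1, cds_len=(300, 300), utr3_len=(300, 320),
            readthrough_rate_map={"g000": 0.2},
            extension_codons_map={"g000": 25},
            double_readthrough_genes=frozenset(["g000"]),
            total_footprints=300_000, total_mrna_fragments=1000,
        )
        res = run_simulated_sample(cfg)
        (rec,) = [r for r in res["records"] if r.score == "readthrough"]
        tier2 = double_readthrough_scan(
            rec, res["genome"], res["fp_track"], res["fp_track"].n_reads
        )
        assert tier2 is not None
        # ribosomes traverse the second stop at the same per-stop rate
        assert tier2.rho == pytest.approx(0.2, rel=0.3)


class TestDifferential:
    def test_identical_samples_not_significant(self, base_sim):
        records = [r for r in base_sim["records"] if r.score == "readthrough"]
        assert records, "fixture must contain positive calls"
        results, _ = differential_readthrough(records, records)
        for r in results:
            assert r.p == pytest.approx(1.0)
            assert r.log10_fold == 0.0
            assert not r.significant

    def test_rate_change_detected_with_direction(self):
        base = dict(
            n_genes=2, cds_len=(360, 420), utr3_len=(250, 280),
            extension_codons_map={"g000": 30},
            total_footprints=150_000, total_mrna_fragments=1000,
        )
        cfg1 = SimulationConfig(seed=31, readthrough_rate_map={"g000": 0.02}, **base)
        cfg2 = SimulationConfig(seed=31, readthrough_rate_map={"g000": 0.2}, **base)
        genome, txs = generate_transcriptome(cfg1)
        from riboext.pipeline import detect_readthrough

        recs = []
        for cfg in (cfg1, cfg2):
            fp, _, _ = simulate_reads(cfg, genome, txs)
            track = track_from_simulated(fp, genome)
            recs.append(detect_readthrough(txs, genome, track))
        results, _ = differential_readthrough(recs[0], recs[1])
        hit = {r.gene_id: r for r in results}["g000"]
        assert hit.significant and hit.direction == "up"
        assert hit.log10_fold == pytest.approx(1.0, abs=0.15)

    def test_log10_fold_change_arithmetic(self):
        assert log10_fold_change(8.82e-3, 1.21e-2) == pytest.approx(0.14, abs=0.005)
        with pytest.raises(ValueError):
            log10_fold_change(0.0, 0.1)


class TestCoordinateFormatting:
    def test_junction_notation(self):
        genome, t = toy_gene(["GGC"] * 8 + ["TAA", "CCC"])
        (cand,) = enumerate_candidates([t], genome)
        s = format_extension_coords(cand)
        a, b = cand.isoforms[0][1]
        tx = t.tx_positions()
        assert s == f"chr1:{int(tx[a])}-{int(tx[b - 1]) + 1}(+)"
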