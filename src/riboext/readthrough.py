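"""Detection and quantification of stop-codon readthrough.

A candidate C-terminal extension is the in-frame interval from an
annotated stop codon to the next in-frame stop codon (exclusive of both),
at least five codons long and free of overlap with annotated CDS, 5'UTRs
or structural-RNA loci.  The readthrough rate rho is the ratio of
footprint density (RPKM) in the extension to that in its CDS, computed
over peak-masked coordinates: the start codon plus 12 nt after it, the 15
nt preceding each stop codon and the 9 nt following the CDS stop codon
are excluded.  Candidates are filtered (a)-(f) on density, coverage and
the drop into the distal 3'UTR, scored readthrough/ambiguous/negative,
and tested for differential regulation between two samples with Fisher's
exact test under Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .annotation import R_5UTR, R_CDS, EXCLUDED_BIOTYPES, TranscriptModel
from .density import CoverageTrack, peak_mask_positions, rpkm
from .simulate import STOPS
from .stats import bh_fdr, fisher_exact

__all__ = [
    "ExtensionCandidate",
    "ReadthroughRecord",
    "DifferentialResult",
    "enumerate_candidates",
    "readthrough_rate",
    "apply_filters",
    "score_candidate",
    "differential_readthrough",
    "double_readthrough_scan",
    "log10_fold_change",
    "format_extension_coords",
]

DISTAL_CODONS = 40
DISTAL_MIN_NT = 114


@dataclass
class ExtensionCandidate:
    """One (stop codon, next in-frame stop) pair with its coordinates."""

    gene_id: str
    chrom: str
    strand: str
    isoforms: list[tuple[TranscriptModel, tuple[int, int]]]  # (tx, ext tx interval)
    length_codons: int
    met_in_first3: bool = False
    first_met_codon: int | None = None
    excluded: bool = False
    exclusion_reason: str = ""

    @property
    def transcript_ids(self) -> list[str]:
        return [t.transcript_id for t, _ in self.isoforms]

    def ext_genomic(self, iso: int = 0) -> np.ndarray:
        """Genomic positions of the extension (exclusive of both stops)."""
        t, (a, b) = self.isoforms[iso]
        return np.sort(t.tx_positions()[a:b])

    def stop_genomic(self, iso: int = 0) -> int:
        t, (a, _b) = self.isoforms[iso]
        return int(t.tx_positions()[a - 3])

    def distal_genomic(self, iso: int = 0, genome_len: int | None = None) -> np.ndarray:
        """Distal 3'UTR window: 40 codons past the extension's stop codon.

        Extended in uninterrupted genomic coordinates to >= 114 nt when the
        transcript ends sooner.
        """
        t, (_a, b) = self.isoforms[iso]
        tx = t.tx_positions()
        want = DISTAL_CODONS * 3
        inside = tx[b + 3 : b + 3 + want]
        pos = list(int(x) for x in inside)
        if len(pos) < DISTAL_MIN_NT:
            step = -1 if t.strand == "-" else 1
            last = pos[-1] if pos else int(tx[-1])
            while len(pos) < DISTAL_MIN_NT:
                last += step
                if last < 0 or (genome_len is not None and last >= genome_len):
                    break
                pos.append(last)
        return np.sort(np.asarray(pos, dtype=np.int64))


def _walk_to_next_stop(seq: str, stop_tx: int) -> tuple[int, int] | None:
    i = stop_tx + 3
    while i + 3 <= len(seq):
        if seq[i : i + 3] in STOPS:
            return stop_tx + 3, i
        i += 3
    return None


def enumerate_candidates(
    transcripts: list[TranscriptModel],
    genome: dict[str, str],
    met_whitelist: frozenset[str] = frozenset(),
    min_codons: int = 5,
) -> list[ExtensionCandidate]:
    """Enumerate candidate extensions from annotated stops.

    One candidate is emitted per unique (stop codon, next in-frame stop)
    genomic pair; isoforms sharing that pair are grouped.  Candidates
    shorter than five codons, lacking an annotated 3'UTR, or overlapping
    annotated CDS/5'UTR or excluded-biotype loci are marked excluded with
    a reason (and transcripts without a 3'UTR are skipped).
    """
    # genomic positions that disqualify an extension
    forbidden: set[int] = set()
    for t in transcripts:
        tx = t.tx_positions()
        if t.biotype in EXCLUDED_BIOTYPES:
            forbidden.update(int(x) for x in tx)
        else:
            for i, g in enumerate(tx):
                if t.region_of_tx(i) in (R_CDS, R_5UTR):
                    forbidden.add(int(g))

    grouped: dict[tuple, ExtensionCandidate] = {}
    for t in transcripts:
        if t.biotype in EXCLUDED_BIOTYPES:
            continue
        seq = t.sequence(genome)
        if t.stop_tx + 3 >= len(seq):
            continue  # no annotated 3'UTR
        ext = _walk_to_next_stop(seq, t.stop_tx)
        if ext is None:
            continue
        a, b = ext
        tx = t.tx_positions()
        key = (t.chrom, t.strand, int(tx[a - 3]), int(tx[b]))
        if key in grouped:
            grouped[key].isoforms.append((t, (a, b)))
            continue
        n_codons = (b - a) // 3
        ext_codons = [seq[a + 3 * c : a + 3 * c + 3] for c in range(n_codons)]
        met_first3 = "ATG" in ext_codons[:3] and t.gene_id not in met_whitelist
        first_met = ext_codons.index("ATG") if "ATG" in ext_codons else None
        cand = ExtensionCandidate(
            gene_id=t.gene_id,
            chrom=t.chrom,
            strand=t.strand,
            isoforms=[(t, (a, b))],
            length_codons=n_codons,
            met_in_first3=met_first3,
            first_met_codon=first_met,
        )
        if n_codons < min_codons:
            cand.excluded, cand.exclusion_reason = True, "shorter than 5 codons"
        elif {int(x) for x in tx[a:b]} & forbidden:
            # an overlap with any CDS/5'UTR (including a longer isoform of
            # the same gene, i.e. splice forms omitting this stop) or a
            # structural-RNA locus disqualifies the candidate
            cand.excluded = True
            cand.exclusion_reason = "overlaps annotated CDS/5'UTR/ncRNA"
        grouped[key] = cand
    return list(grouped.values())


@dataclass
class ReadthroughRecord:
    candidate: ExtensionCandidate
    isoform_index: int
    cds_rpkm: float
    ext_rpkm: float
    rho: float | None
    cds_counts: float
    ext_counts: float
    distal_rpkm: float = float("nan")
    drop_fraction: float = float("nan")
    testable: bool = True
    rate_unmeasurable: bool = False
    filters: dict[str, bool] = field(default_factory=dict)
    score: str = "unscored"
    reasons: list[str] = field(default_factory=list)


def _masked_region_positions(t: TranscriptModel, ext: tuple[int, int]):
    """(masked CDS, masked extension, full extension) genomic positions."""
    tx = t.tx_positions()
    mask = peak_mask_positions(t, "readthrough")
    a, b = ext
    cds_idx = np.arange(t.cds_tx_start, t.stop_tx)
    cds_pos = np.array(
        [int(tx[i]) for i in cds_idx if int(tx[i]) not in mask], dtype=np.int64
    )
    ext_mask_b = b - 15
    ext_idx = np.arange(a + 9, max(a + 9, ext_mask_b))
    ext_pos = np.asarray([int(tx[i]) for i in ext_idx], dtype=np.int64)
    full_ext = np.asarray([int(tx[i]) for i in range(a, b)], dtype=np.int64)
    return cds_pos, ext_pos, full_ext


def readthrough_rate(
    candidate: ExtensionCandidate,
    fp_track: CoverageTrack,
    library_size: float,
    min_cds_counts: float = 128.0,
    genome_len: int | None = None,
) -> ReadthroughRecord:
    """Compute rho = masked extension RPKM / masked CDS RPKM.

    Among isoforms sharing the extension, the one minimising rho is
    reported.  Extensions too short to retain unmasked positions are
    flagged rate-unmeasurable; CDSs below the footprint count threshold
    are flagged untestable.
    """
    ch, st = candidate.chrom, candidate.strand
    best = None
    for iso, (t, ext) in enumerate(candidate.isoforms):
        cds_pos, ext_pos, full_ext = _masked_region_positions(t, ext)
        cds_counts = float(fp_track.weights_at(ch, st, cds_pos).sum())
        cds_r = rpkm(fp_track, ch, st, cds_pos, library_size) if cds_pos.size else 0.0
        if ext_pos.size == 0:
            rec = ReadthroughRecord(candidate, iso, cds_r, 0.0, None,
                                    cds_counts, 0.0, rate_unmeasurable=True)
        else:
            ext_counts = float(fp_track.weights_at(ch, st, ext_pos).sum())
            ext_r = rpkm(fp_track, ch, st, ext_pos, library_size)
            rho = ext_r / cds_r if cds_r > 0 else None
            rec = ReadthroughRecord(candidate, iso, cds_r, ext_r, rho,
                                    cds_counts, ext_counts)
            if rho is None:
                rec.reasons.append("zero CDS density")
        if cds_counts < min_cds_counts:
            rec.testable = False
            rec.reasons.append(f"CDS footprint count {cds_counts:.0f} < {min_cds_counts:.0f}")
        if best is None or (
            rec.rho is not None
            and (best.rho is None or rec.rho < best.rho)
        ):
            best = rec
    # distal 3'UTR density for the drop statistic
    t, _ = candidate.isoforms[best.isoform_index]
    distal = candidate.distal_genomic(best.isoform_index, genome_len)[:DISTAL_MIN_NT]
    if distal.size:
        best.distal_rpkm = rpkm(fp_track, ch, st, distal, library_size)
        if best.ext_rpkm > 0:
            best.drop_fraction = 1.0 - best.distal_rpkm / best.ext_rpkm
    return best


def apply_filters(
    record: ReadthroughRecord,
    fp_track: CoverageTrack,
    library_size: float,
    min_ext_rpkm: float = 0.2,
    min_rho: float = 0.001,
    min_covered_fraction: float = 0.10,
    min_drop: float = 0.75,
) -> dict[str, bool]:
    """Evaluate filters (a)-(f) on a quantified candidate.

    (a) extension density >= 0.2 RPKM; (b) rho >= 0.001; (c) >= 10% of
    extension positions covered; (d) first covered position within the
    first quartile; (e) last within the last quartile; (f) >= 75% density
    drop into the first 114 nt of distal 3'UTR.
    """
    cand = record.candidate
    ch, st = cand.chrom, cand.strand
    full_ext = cand.ext_genomic(record.isoform_index)
    w = fp_track.weights_at(ch, st, full_ext)
    covered = np.nonzero(w > 0)[0]
    n = full_ext.size
    f = {}
    f["a"] = record.ext_rpkm >= min_ext_rpkm
    f["b"] = record.rho is not None and record.rho >= min_rho
    f["c"] = covered.size / n >= min_covered_fraction
    # quartiles in transcript orientation
    rel = covered / n if st == "+" else (n - 1 - covered[::-1]) / n
    f["d"] = covered.size > 0 and rel.min() <= 0.25
    f["e"] = covered.size > 0 and rel.max() >= 0.75
    f["f"] = (
        not math.isnan(record.drop_fraction) and record.drop_fraction >= min_drop
    )
    record.filters = f
    return f


def score_candidate(
    record: ReadthroughRecord,
    fp_track: CoverageTrack,
    max_gap_fraction: float = 0.5,
    sparse_peak_reads: float = 2.0,
) -> str:
    """Score a filtered candidate as readthrough / ambiguous / negative.

    Positive calls require all filters (a)-(f) plus even spacing of
    covered positions (no gap exceeding half the extension length).  When
    coverage is sparse, filters (c)-(e) are relaxed if a peak of at least
    two reads sits at the extension's stop codon.  Candidates with a
    methionine in their first three codons (unless whitelisted) are never
    scored positive, and any candidate containing a methionine must show
    density upstream of the first one.
    """
    cand = record.candidate
    f = record.filters or {}
    reasons = record.reasons

    if record.rate_unmeasurable or not record.testable:
        record.score = "ambiguous"
        reasons.append("not quantifiable")
        return record.score

    full_ext = cand.ext_genomic(record.isoform_index)
    w = fp_track.weights_at(cand.chrom, cand.strand, full_ext)
    covered = np.nonzero(w > 0)[0]
    if covered.size == 0:
        record.score = "negative"
        reasons.append("no extension density")
        return record.score
    if not f.get("f", False):
        record.score = "negative"
        reasons.append("density does not drop after the extension stop")
        return record.score
    if cand.met_in_first3:
        record.score = "ambiguous"
        reasons.append("methionine in first three codons (possible downstream cistron)")
        return record.score
    if cand.first_met_codon is not None:
        # require density upstream of the first Met codon, in tx orientation
        n = full_ext.size
        rel = covered / n if cand.strand == "+" else (n - 1 - covered[::-1]) / n
        if rel.min() * cand.length_codons >= cand.first_met_codon:
            record.score = "ambiguous"
            reasons.append("no density upstream of first extension methionine")
            return record.score

    edges = np.concatenate([[-1], covered, [full_ext.size]])
    max_gap = int(np.diff(edges).max()) - 1
    even = max_gap <= max_gap_fraction * full_ext.size
    dense_ok = all(f.get(k, False) for k in "abcdef") and even
    if dense_ok:
        record.score = "readthrough"
        return record.score
    # sparse relaxation: stop-codon peak of at least two reads
    t, (_a, b) = cand.isoforms[record.isoform_index]
    tx = t.tx_positions()
    peak_idx = [i for i in range(b - 3, b + 6) if 0 <= i < len(tx)]
    peak_pos = np.asarray([int(tx[i]) for i in peak_idx], dtype=np.int64)
    peak_w = float(fp_track.weights_at(cand.chrom, cand.strand, peak_pos).sum())
    if f.get("b", False) and peak_w >= sparse_peak_reads:
        record.score = "readthrough"
        reasons.append("sparse coverage accepted on stop-codon peak")
        return record.score
    record.score = "negative"
    failed = [k for k in "abcdef" if not f.get(k, False)]
    if not even:
        failed.append("evenness")
    reasons.append("failed: " + ",".join(failed))
    return record.score


def log10_fold_change(rho1: float, rho2: float) -> float:
    """log10 fold change of the readthrough rate, sample 2 over sample 1."""
    if rho1 <= 0 or rho2 <= 0:
        raise ValueError("fold change undefined for non-positive rates")
    return math.log10(rho2 / rho1)


def double_readthrough_scan(
    record: ReadthroughRecord,
    genome: dict[str, str],
    fp_track: CoverageTrack,
    library_size: float,
) -> ReadthroughRecord | None:
    """After a positive call, re-run candidate logic one tier further.

    The extension's stop codon is treated as the annotated stop and the
    extension itself as the CDS; depth is limited to this second tier.
    Returns None when no further in-frame stop exists.
    """
    if record.score != "readthrough":
        return None
    cand = record.candidate
    t, (a, b) = cand.isoforms[record.isoform_index]
    seq = t.sequence(genome)
    ext2 = _walk_to_next_stop(seq, b)
    if ext2 is None:
        return None
    a2, b2 = ext2
    if (b2 - a2) // 3 < 5:
        return None
    tier2 = ExtensionCandidate(
        gene_id=cand.gene_id,
        chrom=cand.chrom,
        strand=cand.strand,
        isoforms=[(t, (a2, b2))],
        length_codons=(b2 - a2) // 3,
    )
    tx = t.tx_positions()
    ch, st = cand.chrom, cand.strand
    # first-tier extension (masked like a CDS: 15 nt before its stop) as baseline
    base_idx = np.arange(a + 9, max(a + 9, b - 15))
    base_pos = np.asarray([int(tx[i]) for i in base_idx], dtype=np.int64)
    ext2_idx = np.arange(a2 + 9, max(a2 + 9, b2 - 15))
    if ext2_idx.size == 0 or base_pos.size == 0:
        return None
    ext2_pos = np.asarray([int(tx[i]) for i in ext2_idx], dtype=np.int64)
    base_r = rpkm(fp_track, ch, st, base_pos, library_size)
    ext2_r = rpkm(fp_track, ch, st, ext2_pos, library_size)
    rec2 = ReadthroughRecord(
        tier2, 0, base_r, ext2_r,
        ext2_r / base_r if base_r > 0 else None,
        float(fp_track.weights_at(ch, st, base_pos).sum()),
        float(fp_track.weights_at(ch, st, ext2_pos).sum()),
    )
    rec2.reasons.append("second-tier (double readthrough) candidate")
    return rec2


@dataclass
class DifferentialResult:
    gene_id: str
    table: tuple[tuple[int, int], tuple[int, int]]  # (CDS, ext) x (s1, s2)
    rho1: float
    rho2: float
    p: float
    q: float = float("nan")
    log10_fold: float = float("nan")
    direction: str = "="
    significant: bool = False


def differential_readthrough(
    records1: list[ReadthroughRecord],
    records2: list[ReadthroughRecord],
    alpha: float = 0.05,
    min_cds_counts: float = 128.0,
) -> tuple[list[DifferentialResult], list[tuple[str, str]]]:
    """Fisher-exact test for per-gene changes in readthrough between samples.

    Eligible genes have all isoforms sharing one CDS, >= 128 CDS footprints
    in each sample, and a positive readthrough score in at least one.  The
    2x2 table holds peak-masked CDS and extension counts per sample; p is
    two-sided, FDR is controlled at ``alpha`` by Benjamini-Hochberg, and
    the fold change is log10(rho2/rho1).
    """
    by_gene2 = {r.candidate.gene_id: r for r in records2}
    results, excluded = [], []
    for r1 in records1:
        gid = r1.candidate.gene_id
        r2 = by_gene2.get(gid)
        if r2 is None:
            excluded.append((gid, "absent from second sample"))
            continue
        cds_sets = {
            tuple(map(int, (t.cds_start, t.cds_stop))) for t, _ in r1.candidate.isoforms
        }
        if len(cds_sets) > 1:
            excluded.append((gid, "isoforms with differing CDS"))
            continue
        if r1.cds_counts < min_cds_counts or r2.cds_counts < min_cds_counts:
            excluded.append((gid, "CDS below 128 footprints in a sample"))
            continue
        if "readthrough" not in (r1.score, r2.score):
            excluded.append((gid, "not scored positive in either sample"))
            continue
        if r1.rho is None or r2.rho is None or r1.rho <= 0 or r2.rho <= 0:
            excluded.append((gid, "undefined readthrough rate"))
            continue
        table = (
            (int(round(r1.cds_counts)), int(round(r2.cds_counts))),
            (int(round(r1.ext_counts)), int(round(r2.ext_counts))),
        )
        p = fisher_exact(table, "two-sided")
        lf = log10_fold_change(r1.rho, r2.rho)
        results.append(
            DifferentialResult(
                gene_id=gid, table=table, rho1=r1.rho, rho2=r2.rho, p=p,
                log10_fold=lf,
                direction="up" if lf > 0 else ("down" if lf < 0 else "="),
            )
        )
    if results:
        adj = bh_fdr([r.p for r in results], alpha)
        for r, q, rej in zip(results, adj.qvalues, adj.rejected):
            r.q, r.significant = float(q), bool(rej)
    return results, excluded


def format_extension_coords(candidate: ExtensionCandidate, iso: int = 0) -> str:
    """Extension coordinates with '^' splice-junction notation.

    0-indexed half-open genomic blocks joined by '^', strand in
    parentheses, e.g. ``chr1:100-150^200-230(+)``.
    """
    pos = candidate.ext_genomic(iso)
    blocks = []
    s = e = int(pos[0])
    for p in pos[1:]:
        if int(p) == e + 1:
            e = int(p)
        else:
            blocks.append((s, e + 1))
            s = e = int(p)
    blocks.append((s, e + 1))
    body = "^".join(f"{a}-{b}" for a, b in blocks)
    return f"{candidate.chrom}:{body}({candidate.strand})"
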