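"""Per-position mismatch statistics over stop codons.

Excludes genomic-polymorphism and RNA-editing explanations for apparent
readthrough: for each of the three nucleotides of each annotated stop
codon, matching and mismatching read bases are tabulated (ignoring the
first aligned position of each read, where reverse transcriptase adds
non-templated nucleotides), positions whose mismatch rate exceeds the
per-offset global average are found by one-sided exact binomial tests
under Benjamini-Hochberg FDR control, significant positions are
classified (stop-to-stop or stop-to-sense polymorphism, A-to-I editing
candidate, or sequencing error), and a conservative 90%-editing null is
tested on the A-site-passed footprint subset with Bonferroni correction.

Substitutions are reported in mRNA sense orientation throughout: an A->G
call on a minus-strand gene corresponds to genomic T->C.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .annotation import TranscriptModel, revcomp
from .density import PSITE_TRIM
from .stats import binomial_tail, bh_fdr

__all__ = [
    "StopSite",
    "PositionCounts",
    "MismatchCall",
    "stop_codon_sites",
    "tabulate_mismatches",
    "elevated_mismatch_test",
    "classify_calls",
    "editing_null_test",
]

STOP_CODONS = ("TAA", "TAG", "TGA")
DATASETS = ("mrna", "footprints_all", "footprints_Apassed")


@dataclass(frozen=True)
class StopSite:
    """One nucleotide of an annotated stop codon, in mRNA sense."""

    gene_id: str
    offset: int          # 1, 2 or 3 within the stop codon
    genomic_pos: int
    strand: str
    ref: str             # mRNA-sense reference base
    codon: str           # the annotated stop codon


@dataclass
class PositionCounts:
    site: StopSite
    m: int = 0                                  # matching reads
    x: int = 0                                  # mismatching reads
    subs: Counter = field(default_factory=Counter)  # mRNA-sense alt base -> count

    @property
    def n(self) -> int:
        return self.m + self.x


def stop_codon_sites(
    transcripts: list[TranscriptModel], genome: dict[str, str]
) -> list[StopSite]:
    """All (stop codon, offset) nucleotide sites of coding transcripts."""
    sites = []
    seen = set()
    for t in transcripts:
        seq = t.sequence(genome)
        codon = seq[t.stop_tx : t.stop_tx + 3]
        tx = t.tx_positions()
        for k in range(3):
            gpos = int(tx[t.stop_tx + k])
            key = (t.chrom, gpos)
            if key in seen:
                continue
            seen.add(key)
            sites.append(
                StopSite(t.gene_id, k + 1, gpos, t.strand, seq[t.stop_tx + k], codon)
            )
    return sites


def tabulate_mismatches(
    reads, sites: list[StopSite], dataset: str = "footprints_all"
) -> dict[tuple[str, int], PositionCounts]:
    """Count matching/mismatching read bases at stop-codon nucleotides.

    ``reads`` iterates AlignedRead-like objects carrying per-base match
    flags (e.g. from :func:`riboext.density.reads_from_sam`).  Mismatches
    at the first aligned position of a read (in read orientation) count
    toward neither m nor x.  For dataset "footprints_Apassed" only
    footprints whose pruned P-site window lies entirely 3' (in transcript
    orientation) of the queried position are counted — ribosomes that
    have already decoded it.
    """
    if dataset not in DATASETS:
        raise ValueError(f"unknown dataset {dataset!r}")
    table = {(s.gene_id, s.offset): PositionCounts(s) for s in sites}
    by_pos = {s.genomic_pos: table[(s.gene_id, s.offset)] for s in sites}
    n_rejected = 0
    for read in reads:
        if read.ref_match is None:
            n_rejected += 1
            continue
        pos = read.positions
        lo, hi = int(pos[0]), int(pos[-1])
        first_idx = pos.size - 1 if read.strand == "-" else 0
        for gpos, pc in by_pos.items():
            if gpos < lo or gpos > hi:
                continue
            idx = int(np.searchsorted(pos, gpos))
            if idx >= pos.size or pos[idx] != gpos:
                continue  # spliced over
            if idx == first_idx:
                continue  # non-templated addition artifact
            if dataset == "footprints_Apassed":
                l = pos.size
                if l < 2 * PSITE_TRIM + 1:
                    continue
                window = pos[PSITE_TRIM : l - PSITE_TRIM]
                if read.strand == "-":
                    passed = window[-1] < gpos
                else:
                    passed = window[0] > gpos
                if not passed:
                    continue
            if read.ref_match[idx]:
                pc.m += 1
            else:
                alt = str(read.read_bases[idx])
                if pc.site.strand == "-":
                    alt = revcomp(alt)
                pc.x += 1
                pc.subs[alt] += 1
    return table


@dataclass
class MismatchCall:
    site: StopSite
    counts: PositionCounts
    p: float
    q: float = float("nan")
    significant: bool = False
    tested: bool = True
    classification: str = ""


def elevated_mismatch_test(
    table: dict[tuple[str, int], PositionCounts], alpha: float = 0.05
) -> list[MismatchCall]:
    """Find positions whose mismatch rate exceeds the per-offset average.

    A global average mismatch frequency is computed separately for stop
    codon offsets 1, 2 and 3; each covered position is tested one-sided
    (greater) against its offset's average with an exact binomial test,
    and the FDR over tested positions is controlled at ``alpha``.
    Positions with zero coverage are flagged untested.
    """
    global_rate = {}
    for off in (1, 2, 3):
        xs = sum(pc.x for pc in table.values() if pc.site.offset == off)
        ns = sum(pc.n for pc in table.values() if pc.site.offset == off)
        global_rate[off] = xs / ns if ns else 0.0
    calls = []
    for pc in table.values():
        if pc.n == 0:
            calls.append(MismatchCall(pc.site, pc, 1.0, tested=False))
            continue
        p = binomial_tail(pc.x, pc.n, global_rate[pc.site.offset], "greater")
        calls.append(MismatchCall(pc.site, pc, p))
    tested = [c for c in calls if c.tested]
    if tested:
        adj = bh_fdr([c.p for c in tested], alpha)
        for c, q, rej in zip(tested, adj.qvalues, adj.rejected):
            c.q, c.significant = float(q), bool(rej)
    return calls


def classify_calls(
    calls: list[MismatchCall],
    het_band: tuple[float, float] = (0.35, 0.65),
    hom_min: float = 0.9,
    dominant_fraction: float = 0.8,
) -> list[MismatchCall]:
    """Classify significant calls by their substitution spectrum.

    A single dominant substitution class at ~50% (within ``het_band``) or
    ~100% (>= ``hom_min``) of covering reads indicates a genomic
    polymorphism, subclassified stop-to-stop or stop-to-sense by mutating
    the codon.  Among the rest, only reference adenines with a dominant
    A->G substitution are editing candidates; everything else is
    sequencing error.
    """
    for c in calls:
        if not c.significant:
            continue
        pc = c.counts
        alt, alt_n = pc.subs.most_common(1)[0]
        f_reads = alt_n / pc.n
        is_single_class = alt_n / pc.x >= dominant_fraction
        if is_single_class and (
            het_band[0] <= f_reads <= het_band[1] or f_reads >= hom_min
        ):
            codon = pc.site.codon
            k = pc.site.offset - 1
            mutated = codon[:k] + alt + codon[k + 1 :]
            if mutated in STOP_CODONS:
                c.classification = "stop->stop polymorphism"
            else:
                c.classification = "stop->sense polymorphism"
        elif pc.site.ref == "A" and alt == "G":
            c.classification = "editing-candidate"
        else:
            c.classification = "sequencing error"
    return calls


@dataclass
class EditingNullResult:
    site: StopSite
    n: int
    a_to_g: int
    p: float
    p_bonferroni: float = float("nan")
    rejects_editing: bool = False


def editing_null_test(
    apassed_table: dict[tuple[str, int], PositionCounts],
    null_fraction: float = 0.9,
    alpha: float = 0.05,
) -> list[EditingNullResult]:
    """Test the A-to-I editing null on A-site-passed footprints.

    Under the null that editing drives readthrough, (conservatively) 90%
    of footprints that have decoded a reference adenine should carry G
    there.  A one-sided (lower) binomial p per adenine position, with
    Bonferroni correction over tested positions; a significant result is
    positive evidence against editing at that position.
    """
    results = []
    adenines = [pc for pc in apassed_table.values() if pc.site.ref == "A" and pc.n > 0]
    for pc in adenines:
        k = pc.subs.get("G", 0)
        p = binomial_tail(k, pc.n, null_fraction, "less")
        results.append(EditingNullResult(pc.site, pc.n, k, p))
    m = len(results)
    for r in results:
        r.p_bonferroni = min(1.0, r.p * m)
        r.rejects_editing = r.p_bonferroni < alpha
    return results
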