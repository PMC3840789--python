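"""Z-curve features, coding/noncoding classifier, SNP synonymy, ER motif."""

import itertools

import numpy as np
import pytest

from riboext.evolution import (
    ClassifierModel,
    compare_scores,
    er_retention_scan,
    score_windows,
    snp_is_synonymous,
    snp_synonymy,
    synonymy_enrichment,
    train_classifier,
    zcurve_features,
    SnpRecord,
)


def _xyz(freqs):
    a, c, g, t = freqs
    return [(a + g) - (c + t), (a + c) - (g + t), (a + t) - (g + c)]


def brute_force_zcurve(seq, joint=False):
    """Literal phase-specific k-mer counting oracle (string slicing only)."""
    out = []
    for p in range(3):
        sub = seq[p::3]
        out += _xyz([sub.count(b) / len(sub) for b in "ACGT"])
    for k in (2, 3):
        for p in range(3):
            starts = list(range(p, len(seq) - k + 1, 3))
            for prefix in itertools.product("ACGT", repeat=k - 1):
                pre = "".join(prefix)
                hits = [seq[i + k - 1] for i in starts if seq[i : i + k - 1] == pre]
                if not hits:
                    out += [0.0, 0.0, 0.0]
                    continue
                denom = len(starts) if joint else len(hits)
                out += _xyz([hits.count(b) / denom for b in "ACGT"])
    return np.array(out)


def random_window(rng, n=81):
    return "".join(rng.choice(list("ACGT"), size=n))


def coding_like_window(rng, n_codons=27):
    pool = ["GCT", "GAA", "AAG", "CTG", "GAT", "TTC", "GGT", "CCA"]
    return "".join(rng.choice(pool, size=n_codons))


class TestZCurveFeatures:
    def test_dimension_is_189(self):
        rng = np.random.default_rng(0)
        assert zcurve_features(random_window(rng)).size == 189

    def test_poly_a_structure(self):
        vec = zcurve_features("A" * 81)
        assert np.sum(vec == 1.0) == 27   # all-A contexts at every phase
        assert np.sum(vec == 0.0) == 162

    def test_inframe_triplication_invariance(self):
        # phase-specific frequencies are invariant to in-frame repetition,
        # up to the k-mers created at the two repeat junctions
        rng = np.random.default_rng(1)
        w = random_window(rng, 240)
        # mononucleotide components (no junction effect) are exact
        assert np.allclose(zcurve_features(w)[:9], zcurve_features(w * 3)[:9])
        # joint-frequency k-mer components shift by at most the two junction
        # k-mers over ~3x80 window starts
        dj = np.abs(zcurve_features(w, joint=True) - zcurve_features(w * 3, joint=True))
        assert dj.max() < 0.05
        # conditional components of rare prefixes are the most
        # junction-sensitive; bound them loosely
        dc = np.abs(zcurve_features(w) - zcurve_features(w * 3))
        assert np.median(dc) < 0.02 and dc.max() < 0.3

    @pytest.mark.parametrize("joint", [False, True])
    def test_matches_brute_force_oracle(self, joint):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(81, 301))
            w = random_window(rng, n)
            ours = zcurve_features(w, joint=joint)
            assert np.max(np.abs(ours - brute_force_zcurve(w, joint))) < 1e-12

    def test_components_bounded(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            vec = zcurve_features(random_window(rng, 120))
            assert np.all(vec >= -1.0) and np.all(vec <= 1.0)

    def test_short_or_ambiguous_windows_rejected(self):
        with pytest.raises(ValueError):
            zcurve_features("ACGT" * 20)  # 80 nt
        with pytest.raises(ValueError):
            zcurve_features("N" * 81)


class TestClassifier:
    def test_separable_classes_low_cv_error(self):
        rng = np.random.default_rng(4)
        pos = [coding_like_window(rng) for _ in range(250)]
        neg = [random_window(rng) for _ in range(250)]
        model, err = train_classifier(pos, neg, k_folds=4)
        assert err < 0.05
        assert model.weights.size == 189

    def test_identical_distributions_chance_level(self):
        rng = np.random.default_rng(5)
        pos = [random_window(rng) for _ in range(500)]
        neg = [random_window(rng) for _ in range(500)]
        _, err = train_classifier(pos, neg, k_folds=4)
        assert abs(err - 0.5) < 0.05

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(6)
        a = [coding_like_window(rng) for _ in range(80)]
        b = [random_window(rng) for _ in range(80)]
        _, e1 = train_classifier(a, b, seed=3)
        _, e2 = train_classifier(b, a, seed=3)
        assert abs(e1 - e2) < 0.05

    def test_degenerate_class_rejected(self):
        with pytest.raises(ValueError):
            train_classifier(["A" * 81] * 10, ["ACG" * 27] * 10)

    def test_model_text_roundtrip(self, tmp_path):
        rng = np.random.default_rng(7)
        model, _ = train_classifier(
            [coding_like_window(rng) for _ in range(40)],
            [random_window(rng) for _ in range(40)],
        )
        path = tmp_path / "model.tsv"
        model.save(path)
        back = ClassifierModel.load(path)
        w = random_window(rng)
        assert back.score(zcurve_features(w)) == pytest.approx(
            model.score(zcurve_features(w))
        )


@pytest.fixture(scope="module")
def model():
    rng = np.random.default_rng(8)
    m, _ = train_classifier(
        [coding_like_window(rng) for _ in range(150)],
        [random_window(rng) for _ in range(150)],
    )
    return m


class TestScoring:

    def test_short_regions_excluded(self, model):
        scores = score_windows(model, ["ACGT" * 10, "A" * 200], seed=0)
        assert scores.size == 1

    def test_intermediate_mixture_scores_between_classes(self, model):
        rng = np.random.default_rng(9)
        coding = score_windows(model, [coding_like_window(rng, 60) for _ in range(80)])
        noncod = score_windows(model, [random_window(rng, 180) for _ in range(80)])
        # half coding-like, half random sequence spliced in frame
        mixed = score_windows(
            model,
            [coding_like_window(rng, 27) + random_window(rng, 81) for _ in range(80)],
        )
        assert np.median(noncod) < np.median(mixed) < np.median(coding)
        _u, p = compare_scores(mixed, noncod)
        assert p < 0.01

    def test_fully_separated_rank_sum(self, model):
        u, p = compare_scores(np.arange(10), np.arange(100, 110))
        assert u == 0.0
        assert p == pytest.approx(2 / 184756, rel=1e-6)  # 2/C(20,10)


# explicit standard genetic code, typed out as an independent oracle
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class TestSnpSynonymy:
    def test_worked_examples(self):
        assert snp_is_synonymous("CTA", 2, "G")       # CTA -> CTG, both Leu
        assert not snp_is_synonymous("TGG", 2, "A")   # Trp -> stop

    def test_brute_force_all_codons_all_mutations(self):
        for codon in GENETIC_CODE:
            for off in range(3):
                for alt in "ACGT":
                    if alt == codon[off]:
                        continue
                    mutated = codon[:off] + alt + codon[off + 1 :]
                    expected = GENETIC_CODE[mutated] == GENETIC_CODE[codon]
                    assert snp_is_synonymous(codon, off, alt) == expected

    def test_region_counts_and_null_enrichment(self):
        snps = [SnpRecord("CDS", "CTA", 2, "A", "G"),
                SnpRecord("CDS", "TGG", 2, "G", "A"),
                SnpRecord("distal", "TGG", 2, "G", "A")]
        counts = snp_synonymy(snps)
        assert counts["CDS"] == (1, 1) and counts["distal"] == (0, 1)
        # identical compositions cannot be enriched
        p = synonymy_enrichment((10, 90), (10, 90))
        assert p > 0.5


class TestErRetention:
    @pytest.mark.parametrize(
        "pep,hit",
        [("MAAKDEL", True), ("MAAHDEL", True), ("MAAQDEL", False),
         ("KDELA", False), ("KDEL", True)],
    )
    def test_consensus(self, pep, hit):
        assert er_retention_scan(pep) is hit
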