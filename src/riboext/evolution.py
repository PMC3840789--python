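"""Protein-coding character of extensions: Z-curve features, a linear
discriminant classifier, SNP synonymy tests and the ER-retention motif.

The 189-variable phase-specific Z-curve maps nucleotide k-mer frequencies
(k = 1..3, each conditioned on its (k-1)-mer prefix at a given codon
phase) onto (x, y, z) purine/amino/weak-strong axes:

    x = (A + G) - (C + T),  y = (A + C) - (G + T),  z = (A + T) - (G + C)

giving 9 mononucleotide + 36 dinucleotide + 144 trinucleotide components,
each in [-1, 1].  A Fisher linear discriminant trained on 81-nt windows
from coding regions vs distal 3'UTRs separates coding from non-coding
character; extensions are scored on one seeded random 81-nt window each
and compared between groups with the Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .stats import fisher_exact, rank_sum

__all__ = [
    "zcurve_features",
    "ClassifierModel",
    "train_classifier",
    "score_windows",
    "compare_scores",
    "SnpRecord",
    "snp_is_synonymous",
    "snp_synonymy",
    "synonymy_enrichment",
    "er_retention_scan",
]

MIN_WINDOW = 81
BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}


def _xyz(freqs: np.ndarray) -> tuple[float, float, float]:
    a, c, g, t = freqs
    return (a + g) - (c + t), (a + c) - (g + t), (a + t) - (g + c)


def zcurve_features(window: str, joint: bool = False) -> np.ndarray:
    """The 189-component phase-specific Z-curve of a nucleotide window.

    The phase of a k-mer is the codon position (0, 1, 2 relative to the
    window start) of its first base.  By default k-mer frequencies are
    conditioned on their (k-1)-mer prefix at that phase; ``joint=True``
    uses joint (unconditioned) frequencies instead.  Contexts that never
    occur contribute (0, 0, 0).  Windows shorter than 81 nt, or containing
    ambiguity codes, are rejected.
    """
    seq = window.upper()
    if len(seq) < MIN_WINDOW:
        raise ValueError(f"window shorter than {MIN_WINDOW} nt")
    if any(b not in _BASE_IDX for b in seq):
        raise ValueError("window contains non-ACGT characters")
    n = len(seq)
    arr = np.array([_BASE_IDX[b] for b in seq], dtype=np.int64)
    out = []
    # mononucleotide, per phase
    for p in range(3):
        sub = arr[p::3]
        counts = np.bincount(sub, minlength=4).astype(float)
        total = counts.sum()
        out.extend(_xyz(counts / total) if total else (0.0, 0.0, 0.0))
    # k = 2, 3 with (k-1)-mer prefix context
    for k in (2, 3):
        for p in range(3):
            starts = np.arange(p, n - k + 1, 3)
            kmers = {}
            for s in starts:
                kmers.setdefault(tuple(arr[s : s + k - 1]), np.zeros(4))[
                    arr[s + k - 1]
                ] += 1
            for prefix in product(range(4), repeat=k - 1):
                counts = kmers.get(prefix)
                if counts is None or counts.sum() == 0:
                    out.extend((0.0, 0.0, 0.0))
                    continue
                if joint:
                    freqs = counts / len(starts)
                else:
                    freqs = counts / counts.sum()
                out.extend(_xyz(freqs))
    vec = np.asarray(out)
    assert vec.size == 189
    return vec


@dataclass
class ClassifierModel:
    """Linear discriminant over Z-curve features: score = w.f + b."""

    weights: np.ndarray
    intercept: float
    classes: tuple[str, str] = ("noncoding", "coding")

    def score(self, features: np.ndarray) -> float:
        return float(features @ self.weights + self.intercept)

    def predict(self, features: np.ndarray) -> str:
        return self.classes[1] if self.score(features) > 0 else self.classes[0]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# intercept\t{float(self.intercept)!r}\n")
            for w in self.weights:
                fh.write(f"{float(w)!r}\n")

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            first = fh.readline().split("\t")[1]
            weights = np.array([float(line) for line in fh])
        return cls(weights, float(first))


def train_classifier(
    positive_windows: list[str],
    negative_windows: list[str],
    k_folds: int = 4,
    seed: int = 0,
    joint: bool = False,
) -> tuple[ClassifierModel, float]:
    """Fit a Fisher linear discriminant on Z-curve features with k-fold CV.

    Returns the model trained on all data plus the mean cross-validated
    misclassification error.  Positive windows are labelled coding.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.model_selection import StratifiedKFold

    if len(positive_windows) < 2 or len(negative_windows) < 2:
        raise ValueError("need at least 2 windows per class")
    X = np.vstack(
        [zcurve_features(w, joint) for w in positive_windows]
        + [zcurve_features(w, joint) for w in negative_windows]
    )
    y = np.concatenate(
        [np.ones(len(positive_windows)), np.zeros(len(negative_windows))]
    )
    for cls in (0, 1):
        if np.allclose(X[y == cls].var(axis=0), 0.0):
            raise ValueError("degenerate class: zero within-class variance")
    errs = []
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        lda = LinearDiscriminantAnalysis()
        lda.fit(X[tr], y[tr])
        errs.append(1.0 - lda.score(X[te], y[te]))
    lda = LinearDiscriminantAnalysis()
    lda.fit(X, y)
    model = ClassifierModel(lda.coef_[0].copy(), float(lda.intercept_[0]))
    return model, float(np.mean(errs))


def score_windows(
    model: ClassifierModel,
    sequences: list[str],
    seed: int = 0,
    window: int = MIN_WINDOW,
    avoid_last: int = 0,
    joint: bool = False,
) -> np.ndarray:
    """Discriminant score of one seeded random window per sequence.

    Sequences shorter than the window (after trimming ``avoid_last``
    terminal bases, e.g. to dodge polyadenylation signals) are excluded.
    """
    rng = np.random.default_rng(seed)
    scores = []
    for seq in sequences:
        usable = seq[: len(seq) - avoid_last] if avoid_last else seq
        if len(usable) < window:
            continue
        start = int(rng.integers(0, len(usable) - window + 1))
        scores.append(model.score(zcurve_features(usable[start : start + window], joint)))
    return np.asarray(scores)


def compare_scores(scores_a, scores_b, sidedness: str = "two-sided"):
    """Mann-Whitney U comparison of two groups of discriminant scores."""
    return rank_sum(scores_a, scores_b, sidedness)


# ---------------------------------------------------------------------------
# SNP synonymy
# ---------------------------------------------------------------------------

_CODON_TABLE: dict[str, str] = {}


def _translate(codon: str) -> str:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE[codon]


@dataclass
class SnpRecord:
    """A SNP located in a translated frame, alleles in mRNA sense."""

    region: str          # CDS / predicted extension / novel extension / distal 3UTR
    codon: str
    offset: int          # 0-2 within the codon
    ref: str
    alt: str

    @property
    def synonymous(self) -> bool:
        return snp_is_synonymous(self.codon, self.offset, self.alt)


def snp_is_synonymous(codon: str, offset: int, alt: str) -> bool:
    """Whether substituting ``alt`` at ``offset`` preserves the amino acid
    (stop counting as its own residue)."""
    codon = codon.upper()
    mutated = codon[:offset] + alt.upper() + codon[offset + 1 :]
    return _translate(mutated) == _translate(codon)


def snp_synonymy(snps: list[SnpRecord]) -> dict[str, tuple[int, int]]:
    """Per-region (synonymous, nonsynonymous) SNP counts."""
    out: dict[str, list[int]] = {}
    for s in snps:
        c = out.setdefault(s.region, [0, 0])
        c[0 if s.synonymous else 1] += 1
    return {k: (v[0], v[1]) for k, v in out.items()}


def synonymy_enrichment(
    counts_a: tuple[int, int], counts_b: tuple[int, int]
) -> float:
    """One-sided Fisher p that region A is enriched for synonymous SNPs
    relative to region B."""
    return fisher_exact([list(counts_a), list(counts_b)], "greater")


def er_retention_scan(peptide: str) -> bool:
    """C-terminal ER retention signal: consensus [KH]DEL at the terminus."""
    tail = peptide.upper()[-4:]
    return tail in ("KDEL", "HDEL")
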