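"""Genomic categorization of conserved elements and target-gene analysis.

The genome is partitioned into four categories -- UTR, intron, promoter
(1,000 bp upstream of a transcription start site, strand-aware) and
intergenic -- intersecting over all annotated transcripts, with fixed
precedence UTR > intron > promoter > intergenic.  Elements are assigned to
every category they overlap (an element spanning a boundary counts once
per category), compared against genome-wide fractions by chi-square,
linked to their likely target gene (containing gene, else nearest), and
tested for functional-term fold enrichment with a hypergeometric tail and
Bonferroni correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval
from .io_formats import GtfFeature

log = logging.getLogger(__name__)

CATEGORIES = ("intergenic", "promoter", "intron", "UTR")
_CAT_CODE = {name: i for i, name in enumerate(CATEGORIES)}


@dataclass
class CategoryPartition:
    """Per-base category labels over each sequence (a true partition:
    disjoint and covering)."""

    labels: dict[str, np.ndarray]  # uint8 codes into CATEGORIES
    promoter_length: int
    annotation_id: str = ""

    def category_at(self, chrom: str, pos: int) -> str:
        return CATEGORIES[self.labels[chrom][pos]]

    def genome_fractions(self) -> dict[str, float]:
        total = sum(a.size for a in self.labels.values())
        counts = np.zeros(len(CATEGORIES), dtype=np.int64)
        for arr in self.labels.values():
            counts += np.bincount(arr, minlength=len(CATEGORIES))
        return {name: counts[i] / total for i, name in enumerate(CATEGORIES)}

    def categories_overlapping(self, iv: GenomicInterval) -> set[str]:
        arr = self.labels[iv.chrom]
        codes = np.unique(arr[iv.start : min(iv.end, arr.size)])
        return {CATEGORIES[c] for c in codes}


def build_partition(
    features: Sequence[GtfFeature],
    genome_lengths: Mapping[str, int],
    promoter_length: int = 1000,
    annotation_id: str = "",
) -> CategoryPartition:
    """Partition the genome from a GTF-lite annotation.

    A site is UTR if it is UTR in any transcript; else intron if it lies
    between exons of any transcript; else promoter if within
    ``promoter_length`` bp upstream (strand-aware) of any transcription
    start site; else intergenic.  Transcripts without exons are skipped.
    """
    labels = {
        chrom: np.zeros(length, dtype=np.uint8)
        for chrom, length in genome_lengths.items()
    }
    utr = {c: np.zeros(l, dtype=bool) for c, l in genome_lengths.items()}
    intron = {c: np.zeros(l, dtype=bool) for c, l in genome_lengths.items()}
    promoter = {c: np.zeros(l, dtype=bool) for c, l in genome_lengths.items()}

    by_transcript: dict[str, list[GtfFeature]] = {}
    transcripts: dict[str, GtfFeature] = {}
    for f in features:
        if f.chrom not in labels:
            continue
        if f.feature == "transcript" and f.transcript_id:
            transcripts[f.transcript_id] = f
        elif f.feature in ("exon", "UTR") and f.transcript_id:
            by_transcript.setdefault(f.transcript_id, []).append(f)

    for tid, tf in transcripts.items():
        feats = by_transcript.get(tid, [])
        exons = sorted(
            ((f.start, f.end) for f in feats if f.feature == "exon")
        )
        if not exons:
            log.warning("transcript %s has no exons; skipped", tid)
            continue
        L = labels[tf.chrom].size
        for f in feats:
            if f.feature == "UTR":
                utr[tf.chrom][max(0, f.start) : min(L, f.end)] = True
        span_start, span_end = exons[0][0], exons[-1][1]
        body = np.zeros(span_end - span_start, dtype=bool)
        for s, e in exons:
            body[s - span_start : e - span_start] = True
        intron[tf.chrom][span_start:span_end] |= ~body
        tss = tf.start if tf.strand == "+" else tf.end - 1
        if tf.strand == "+":
            p0, p1 = tss - promoter_length, tss
        else:
            p0, p1 = tss + 1, tss + 1 + promoter_length
        promoter[tf.chrom][max(0, p0) : min(L, p1)] = True

    for chrom, arr in labels.items():
        arr[promoter[chrom]] = _CAT_CODE["promoter"]
        arr[intron[chrom]] = _CAT_CODE["intron"]
        arr[utr[chrom]] = _CAT_CODE["UTR"]
    return CategoryPartition(labels, promoter_length, annotation_id)


# ---------------------------------------------------------------------------
# Classification and genome-fraction test


@dataclass(frozen=True)
class CategoryReport:
    counts: dict[str, int]  # assignments per category (an element may
    # count in several)
    fractions_pct: dict[str, float]  # over total assignments, in percent
    genome_fractions_pct: dict[str, float]
    chisq: float
    p_value: float
    n_elements: int


def fractions_from_counts(counts: Mapping[str, int]) -> dict[str, float]:
    """Category fractions (percent) over total assignments."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no assignments")
    return {k: 100.0 * v / total for k, v in counts.items()}


def classify_and_test(
    hcns_intervals: Sequence[GenomicInterval],
    partition: CategoryPartition,
    genome_fractions: Optional[Mapping[str, float]] = None,
) -> CategoryReport:
    """Assign each element to every category it overlaps by >= 1 bp and
    chi-square the assignment counts against genome-wide expectations
    (taken from the partition itself when not supplied)."""
    counts = {name: 0 for name in CATEGORIES}
    for iv in hcns_intervals:
        for cat in partition.categories_overlapping(iv):
            counts[cat] += 1
    fractions = fractions_from_counts(counts)
    gfrac = dict(genome_fractions) if genome_fractions else partition.genome_fractions()
    total = sum(counts.values())
    observed = np.array([counts[c] for c in CATEGORIES], dtype=float)
    expected = np.array([gfrac[c] for c in CATEGORIES], dtype=float)
    expected = expected / expected.sum() * total
    keep = expected > 0
    res = stats.chisquare(observed[keep], expected[keep])
    return CategoryReport(
        counts,
        fractions,
        {c: 100.0 * gfrac[c] / sum(gfrac.values()) for c in CATEGORIES},
        float(res.statistic),
        float(res.pvalue),
        len(hcns_intervals),
    )


# ---------------------------------------------------------------------------
# Target genes


def likely_target_gene(
    hcns: GenomicInterval, genes: Sequence[GenomicInterval]
) -> tuple[Optional[GenomicInterval], Optional[int]]:
    """The gene containing the element (any overlap, distance 0), else the
    nearest gene by edge-to-edge distance; ties break to the smaller gene
    start.  Returns (None, None) on a gene-free input."""
    if not genes:
        return None, None
    same_chrom = [g for g in genes if g.chrom == hcns.chrom]
    if not same_chrom:
        return None, None
    containing = sorted((g for g in same_chrom if g.overlaps(hcns)),
                        key=lambda g: g.start)
    if containing:
        return containing[0], 0
    best = min(same_chrom, key=lambda g: (hcns.distance(g), g.start))
    return best, hcns.distance(best)


@dataclass(frozen=True)
class ProximityResult:
    fraction_within: float
    distances: tuple[Optional[int], ...]
    n_no_gene: int
    null_fractions: tuple[float, ...] = ()
    empirical_p: Optional[float] = None


def proximity_fraction(
    hcns_set: Sequence[GenomicInterval],
    genes: Sequence[GenomicInterval],
    radius: float = 1e6,
    null_generator=None,
    n_reps: int = 0,
    seed=None,
) -> ProximityResult:
    """Fraction of elements whose likely-target distance is <= ``radius``.

    With ``null_generator`` (a callable rng -> interval list) and
    ``n_reps``, an empirical null distribution of the fraction over
    matched random interval sets gives an empirical p for enrichment.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")

    def frac(intervals):
        dists = [likely_target_gene(iv, genes)[1] for iv in intervals]
        within = sum(1 for d in dists if d is not None and d <= radius)
        return within / len(intervals) if intervals else 0.0, dists

    observed, distances = frac(hcns_set)
    n_no_gene = sum(1 for d in distances if d is None)
    nulls: list[float] = []
    p = None
    if null_generator is not None and n_reps > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_reps):
            nulls.append(frac(null_generator(rng))[0])
        p = (1 + sum(1 for f in nulls if f >= observed)) / (n_reps + 1)
    return ProximityResult(
        observed, tuple(distances), n_no_gene, tuple(nulls), p
    )


# ---------------------------------------------------------------------------
# Term enrichment


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    target_count: int
    background_count: int
    fold: float
    p_raw: float
    p_bonferroni: float


def fold_enrichment(
    target_genes: Sequence[str],
    background_genes: Sequence[str],
    term_map: Mapping[str, Sequence[str]],
) -> list[EnrichmentRow]:
    """Per-term fold enrichment of target genes over background.

    fold = (k/n) / (K/N); raw p is the hypergeometric upper tail
    P(X >= k); the correction is Bonferroni over the tested terms.  Terms
    with no background gene are dropped (logged).  Rows sort by fold,
    descending.
    """
    target = set(target_genes)
    background = set(background_genes)
    if not target <= background:
        raise ValueError("target genes must be a subset of the background")
    if not term_map:
        raise ValueError("empty term map")
    gene_terms = {g: set(ts) for g, ts in term_map.items()}
    terms = sorted({t for g in background for t in gene_terms.get(g, ())})
    n, N = len(target), len(background)
    tested = []
    for term in terms:
        K = sum(1 for g in background if term in gene_terms.get(g, ()))
        if K == 0:
            log.info("term %s absent from background; dropped", term)
            continue
        k = sum(1 for g in target if term in gene_terms.get(g, ()))
        fold = (k / n) / (K / N) if n else 0.0
        p_raw = float(stats.hypergeom.sf(k - 1, N, K, n))
        tested.append((term, k, K, fold, p_raw))
    m = len(tested)
    rows = [
        EnrichmentRow(term, k, K, fold, p_raw, min(1.0, p_raw * m))
        for term, k, K, fold, p_raw in tested
    ]
    rows.sort(key=lambda r: (-r.fold, r.term))
    return rows
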