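"""Genome partition, category classification, target genes, enrichment."""

import math

import numpy as np
import pytest
from scipy import stats

from hcnskit.genomic_context import (
    CATEGORIES,
    build_partition,
    classify_and_test,
    fold_enrichment,
    fractions_from_counts,
    likely_target_gene,
    proximity_fraction,
)
from hcnskit.intervals import GenomicInterval
from hcnskit.io_formats import GtfFeature


def _gene(chrom, start, end, strand, gid, utrs=()):
    tid = f"{gid}.t1"
    feats = [
        GtfFeature(chrom, "gene", start, end, strand, gid),
        GtfFeature(chrom, "transcript", start, end, strand, gid, tid),
        GtfFeature(chrom, "exon", start, start + 200, strand, gid, tid),
        GtfFeature(chrom, "exon", end - 200, end, strand, gid, tid),
    ]
    for s, e in utrs:
        feats.append(GtfFeature(chrom, "UTR", s, e, strand, gid, tid))
    return feats


# ---------------------------------------------------------------------------
# partition


def test_promoter_definition_plus_strand():
    feats = _gene("c", 5000, 8000, "+", "g")
    part = build_partition(feats, {"c": 10_000})
    assert all(part.category_at("c", p) == "promoter" for p in range(4000, 5000))
    assert part.category_at("c", 3999) == "intergenic"
    assert part.category_at("c", 5000) != "promoter"


def test_promoter_definition_minus_strand():
    feats = _gene("c", 2000, 5000, "-", "g")
    part = build_partition(feats, {"c": 10_000})
    # TSS at 4999; promoter covers the 1,000 bp upstream on the minus strand
    assert all(part.category_at("c", p) == "promoter" for p in range(5000, 6000))


def test_utr_precedence_over_intron():
    # site is UTR in transcript A and intronic in transcript B
    feats = _gene("c", 1000, 3000, "+", "a", utrs=[(1000, 1100)])
    feats += _gene("c", 500, 3500, "+", "b")  # intron spans [700, 3300)
    part = build_partition(feats, {"c": 5000})
    assert part.category_at("c", 1050) == "UTR"


def test_partition_matches_per_base_brute_force():
    """Every base of a toy genome gets the category the precedence rules
    dictate, checked against an independent per-base evaluation."""
    feats = _gene("c", 1000, 2400, "+", "g1", utrs=[(1000, 1150)])
    feats += _gene("c", 3000, 4600, "-", "g2", utrs=[(4450, 4600)])
    L = 6000
    part = build_partition(feats, {"c": L})

    utr_sites = set()
    intron_sites = set()
    promoter_sites = set()
    by_tid = {}
    for f in feats:
        if f.feature in ("exon", "UTR") and f.transcript_id:
            by_tid.setdefault(f.transcript_id, []).append(f)
    for f in feats:
        if f.feature != "transcript":
            continue
        exons = sorted(
            (x.start, x.end) for x in by_tid[f.transcript_id] if x.feature == "exon"
        )
        for x in by_tid[f.transcript_id]:
            if x.feature == "UTR":
                utr_sites.update(range(x.start, x.end))
        for p in range(exons[0][0], exons[-1][1]):
            if not any(s <= p < e for s, e in exons):
                intron_sites.add(p)
        tss = f.start if f.strand == "+" else f.end - 1
        rng = (
            range(max(0, tss - 1000), tss)
            if f.strand == "+"
            else range(tss + 1, min(L, tss + 1001))
        )
        promoter_sites.update(rng)

    for p in range(L):
        if p in utr_sites:
            expected = "UTR"
        elif p in intron_sites:
            expected = "intron"
        elif p in promoter_sites:
            expected = "promoter"
        else:
            expected = "intergenic"
        assert part.category_at("c", p) == expected, p

    fracs = part.genome_fractions()
    assert sum(fracs.values()) == pytest.approx(1.0)


def test_transcript_without_exons_skipped():
    feats = [
        GtfFeature("c", "gene", 0, 100, "+", "g"),
        GtfFeature("c", "transcript", 0, 100, "+", "g", "g.t1"),
    ]
    part = build_partition(feats, {"c": 200})
    assert part.category_at("c", 50) == "intergenic"


# ---------------------------------------------------------------------------
# classification


def test_fractions_from_printed_counts():
    counts = {"intergenic": 1102, "intron": 703, "promoter": 21, "UTR": 26}
    fr = fractions_from_counts(counts)
    assert round(fr["intergenic"], 1) == 59.5
    assert round(fr["intron"], 1) == 38.0
    assert round(fr["promoter"], 1) == 1.1
    assert round(fr["UTR"], 1) == 1.4


def test_all_intergenic_classification():
    part = build_partition([], {"c": 1000})
    report = classify_and_test(
        [GenomicInterval("c", 0, 100), GenomicInterval("c", 200, 300)], part
    )
    assert report.fractions_pct["intergenic"] == pytest.approx(100.0)
    assert sum(report.fractions_pct.values()) == pytest.approx(100.0, abs=0.1)


def test_boundary_spanning_element_counts_in_both_categories():
    feats = _gene("c", 1000, 2400, "+", "g")
    part = build_partition(feats, {"c": 4000})
    report = classify_and_test([GenomicInterval("c", 900, 1100)], part)
    # spans the promoter/transcript boundary: counted once per category
    assert sum(report.counts.values()) >= 2


def test_classification_matches_overlap_scan():
    feats = _gene("c", 1000, 2400, "+", "g1", utrs=[(1000, 1150)])
    part = build_partition(feats, {"c": 4000})
    rng = np.random.default_rng(0)
    ivs = [
        GenomicInterval("c", int(s), int(s) + 120)
        for s in rng.integers(0, 3800, 40)
    ]
    report = classify_and_test(ivs, part)
    expected = {name: 0 for name in CATEGORIES}
    for iv in ivs:
        cats = {part.category_at("c", p) for p in range(iv.start, iv.end)}
        for c in cats:
            expected[c] += 1
    assert report.counts == expected


# ---------------------------------------------------------------------------
# target genes


GENES = [
    GenomicInterval("c", 1000, 3000, "+", "gA"),
    GenomicInterval("c", 5000, 7000, "+", "gB"),
]


def test_containing_gene_wins():
    g, d = likely_target_gene(GenomicInterval("c", 1500, 1700), GENES)
    assert g.label == "gA" and d == 0


def test_equidistant_tie_breaks_to_smaller_start():
    # midpoint gap: distance 500 to both genes
    g, d = likely_target_gene(GenomicInterval("c", 3500, 4500), GENES)
    assert g.label == "gA" and d == 500


def test_nearest_gene_matches_brute_force():
    rng = np.random.default_rng(1)
    genes = [
        GenomicInterval("c", int(s), int(s) + int(l), "+", f"g{i}")
        for i, (s, l) in enumerate(
            zip(rng.integers(0, 50_000, 30), rng.integers(500, 3000, 30))
        )
    ]
    for s in rng.integers(0, 50_000, 50):
        iv = GenomicInterval("c", int(s), int(s) + 100)
        g, d = likely_target_gene(iv, genes)
        brute = min(genes, key=lambda x: (iv.distance(x), x.start))
        assert d == iv.distance(brute)
        assert g.start == brute.start


def test_proximity_fraction_and_flags():
    ivs = [GenomicInterval("c", 1500, 1600), GenomicInterval("c", 5500, 5600)]
    res = proximity_fraction(ivs, GENES)
    assert res.fraction_within == 1.0
    res = proximity_fraction(ivs, [])
    assert res.fraction_within == 0.0
    assert res.n_no_gene == 2


def test_proximity_empirical_null_bounds():
    rng_genes = GENES

    def null_gen(rng):
        s = int(rng.integers(0, 9_000))
        return [GenomicInterval("c", s, s + 100)]

    res = proximity_fraction(
        [GenomicInterval("c", 1500, 1600)], rng_genes, radius=100,
        null_generator=null_gen, n_reps=200, seed=2,
    )
    assert 1 / 201 <= res.empirical_p <= 1.0


# ---------------------------------------------------------------------------
# enrichment


def test_fold_enrichment_arithmetic():
    # k/n = 20/200 against K/N = 50/1000 -> fold 2.0
    background = [f"g{i}" for i in range(1000)]
    target = background[:200]
    term_map = {g: ["T"] for g in background[:20] + background[200:230]}
    (row,) = fold_enrichment(target, background, term_map)
    assert row.target_count == 20 and row.background_count == 50
    assert row.fold == pytest.approx(2.0)


def test_target_equals_background_gives_unit_folds():
    background = [f"g{i}" for i in range(100)]
    terms = {g: ["A"] if i % 2 else ["B"] for i, g in enumerate(background)}
    rows = fold_enrichment(background, background, terms)
    assert all(r.fold == pytest.approx(1.0) for r in rows)
    assert all(r.p_bonferroni == 1.0 for r in rows)


def test_hypergeometric_tail_matches_enumeration():
    # brute-force upper tail for N <= 50
    N, K, n = 40, 12, 15
    background = [f"g{i}" for i in range(N)]
    terms = {g: ["T"] for g in background[:K]}
    target = background[: n - 5] + background[K : K + 5]
    rows = fold_enrichment(target, background, terms)
    k = rows[0].target_count
    tail = sum(
        math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
        for x in range(k, min(K, n) + 1)
    )
    assert rows[0].p_raw == pytest.approx(tail, rel=1e-9)


def test_enrichment_p_monotone_in_k():
    ps = [
        float(stats.hypergeom.sf(k - 1, 1000, 50, 200)) for k in range(1, 30)
    ]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_target_must_be_subset():
    with pytest.raises(ValueError):
        fold_enrichment(["x"], ["a", "b"], {"a": ["T"]})
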