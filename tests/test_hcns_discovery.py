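"""Discovery machinery: local homology search, overlap resolution, the
filter cascade, and the end-to-end planted-element guarantees."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hcnskit.hcns_discovery import (
    HCNSCandidate,
    chance_probability,
    conservation_filter,
    find_local_homologies,
    outgroup_exclusion,
    repeat_coding_filter,
    resolve_overlaps,
    revcomp,
)
from hcnskit.intervals import GenomicInterval
from hcnskit.io_formats import HomologyHit


def _random_seq(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _hit(q0, q1, identity=1.0, chrom="ref", s0=None, sname="sp", evalue=1e-10):
    s0 = q0 if s0 is None else s0
    return HomologyHit(
        GenomicInterval(chrom, q0, q1, "+"),
        GenomicInterval(sname, s0, s0 + (q1 - q0), "+"),
        identity,
        q1 - q0,
        evalue,
    )


# ---------------------------------------------------------------------------
# find_local_homologies


def test_self_homology_perfect_hit():
    seq = _random_seq(200, seed=1)
    hits = find_local_homologies({"q": seq}, {"s": seq})
    assert hits
    best = max(hits, key=lambda h: h.length)
    assert best.identity == 1.0
    assert best.length >= 200


def test_reverse_complement_hit_on_minus_strand():
    rng = np.random.default_rng(2)
    element = _random_seq(150, seed=3)
    query = _random_seq(400, seed=4) + element + _random_seq(400, seed=5)
    subject = _random_seq(300, seed=6) + revcomp(element) + _random_seq(300, seed=7)
    hits = find_local_homologies({"q": query}, {"s": subject})
    minus = [h for h in hits if h.subject.strand == "-"]
    assert minus
    best = max(minus, key=lambda h: h.length)
    assert best.length >= 150
    assert best.query.start <= 400 and best.query.end >= 550
    assert best.subject.start <= 300 and best.subject.end >= 450


def test_empty_sequences_rejected():
    with pytest.raises(ValueError):
        find_local_homologies({"q": ""}, {"s": "ACGT"})
    with pytest.raises(ValueError):
        find_local_homologies({}, {"s": "ACGT"})


def test_evalue_filter_removes_weak_hits():
    # a short shared word is not significant at genome-scale search space
    q = _random_seq(100, seed=8) + "ACGTACGTACGTACG" + _random_seq(100, seed=9)
    s = _random_seq(100, seed=10) + "ACGTACGTACGTACG" + _random_seq(100, seed=11)
    hits = find_local_homologies({"q": q}, {"s": s}, evalue_max=1e-5)
    assert all(h.evalue <= 1e-5 for h in hits)
    assert not any(h.length < 25 for h in hits)


def test_search_superset_of_smith_waterman_oracle():
    """On a diverged pair with planted perfect elements, every element
    region attains the optimal ungapped local-alignment score found by an
    independent dynamic-programming oracle."""
    import biotite.sequence as bseq
    import biotite.sequence.align as balign

    from hcnskit.synthetic_world import evolve_sequence

    rng = np.random.default_rng(12)
    element = _random_seq(300, seed=13)
    parts = []
    for k in range(3):
        parts.append(_random_seq(1200, seed=20 + k))
        parts.append(element if k == 1 else _random_seq(300, seed=30 + k))
    query = "".join(parts)
    subject, _ = evolve_sequence(query, 1.0, 0.04, seed=14)  # 4% divergence
    # re-plant the element exactly (perfectly conserved region)
    subject = subject[:2700] + element + subject[3000:]  # element sits at query [2700, 3000)
    hits = find_local_homologies({"q": query}, {"s": subject})

    alph = bseq.NucleotideSequence.alphabet_unamb
    matrix = balign.SubstitutionMatrix(
        alph, alph, np.where(np.eye(4, dtype=bool), 1, -3).astype(np.int32)
    )
    # DP oracle on the element neighborhood
    aln = balign.align_optimal(
        bseq.NucleotideSequence(query[2600:3100]),
        bseq.NucleotideSequence(subject[2600:3100]),
        matrix,
        gap_penalty=-1000,  # effectively ungapped
        local=True,
        max_number=1,
    )[0]
    element_hits = [
        h for h in hits if h.query.start <= 2700 and h.query.end >= 3000
    ]
    assert element_hits  # the planted element is covered by a single hit
    assert max(h.score for h in element_hits) >= aln.score
    assert aln.score >= 300  # the perfect element alone clears the cutoff


# ---------------------------------------------------------------------------
# resolve_overlaps


def test_longest_of_overlapping_pair_retained():
    a, b = _hit(0, 150), _hit(100, 220)
    assert resolve_overlaps([a, b]) == [a]


def test_disjoint_hits_all_kept():
    a, b = _hit(0, 100), _hit(200, 300)
    assert resolve_overlaps([b, a]) == [a, b]


def test_overlap_chain_keeps_middle_only():
    # A(100) - B(120) - C(110), A and C disjoint: the longest (B) survives
    a, b, c = _hit(0, 100), _hit(50, 170), _hit(160, 270)
    assert resolve_overlaps([a, b, c]) == [b]


def test_slop_tolerates_junction_overlap():
    a, b = _hit(0, 300), _hit(295, 400)
    assert resolve_overlaps([a, b]) == [a]  # strict rule
    assert resolve_overlaps([a, b], slop=10) == [a, b]


@given(
    st.lists(
        st.tuples(st.integers(0, 60), st.integers(1, 30), st.integers(0, 3)),
        min_size=1,
        max_size=12,
    )
)
def test_resolve_matches_brute_force_greedy(spec):
    hits = [
        _hit(s, s + ln, identity=1.0 - 0.01 * j) for s, ln, j in spec
    ]
    # independent greedy reference: repeatedly take the best-ranked hit and
    # discard everything overlapping it
    pool = sorted(
        hits, key=lambda h: (-h.length, -h.identity, h.query.chrom, h.query.start)
    )
    expected = []
    while pool:
        top = pool.pop(0)
        expected.append(top)
        pool = [h for h in pool if not h.query.overlaps(top.query)]
    expected.sort(key=lambda h: (h.query.chrom, h.query.start))
    assert resolve_overlaps(hits) == expected


# ---------------------------------------------------------------------------
# conservation_filter (hit-level semantics)


def test_perfect_region_in_all_species_accepted():
    hits = {sp: [_hit(0, 120, 1.0, sname=sp)] for sp in ("a", "b", "c")}
    (cand,) = conservation_filter(hits)
    assert cand.accepted
    assert (cand.interval.start, cand.interval.end) == (0, 120)
    assert set(cand.species_support) == {"a", "b", "c"}


def test_short_region_rejected_with_length_flag():
    hits = {sp: [_hit(0, 99, 1.0, sname=sp)] for sp in ("a", "b", "c")}
    (cand,) = conservation_filter(hits)
    assert not cand.accepted
    assert cand.flags == {"length"}


def test_subthreshold_identity_rejected_with_identity_flag():
    hits = {
        "a": [_hit(0, 120, 1.0, sname="a")],
        "b": [_hit(0, 120, 1.0, sname="b")],
        "c": [_hit(0, 120, 0.99, sname="c")],
    }
    (cand,) = conservation_filter(hits)
    assert not cand.accepted
    assert cand.flags == {"identity"}


# ---------------------------------------------------------------------------
# outgroup_exclusion


def _candidate(start=0, end=150):
    return HCNSCandidate(GenomicInterval("ref", start, end, "+"))


@pytest.mark.parametrize(
    "identity,expect_excluded",
    [(0.95, True), (0.80, False), (0.88, False)],  # threshold 0.12: 1-0.88 = 0.12 boundary retains
)
def test_outgroup_threshold_rule(identity, expect_excluded):
    cand = _candidate()
    hits = {"og": [_hit(0, 150, identity, sname="og")]}
    outgroup_exclusion([cand], hits, 0.12)
    assert (not cand.accepted) == expect_excluded
    assert cand.outgroup_identity["og"] == pytest.approx(identity)


def test_no_outgroup_hit_retains_candidate():
    cand = _candidate()
    outgroup_exclusion([cand], {"og": []}, 0.12)
    assert cand.accepted
    assert cand.outgroup_identity["og"] is None


def test_short_fragment_does_not_veto():
    # a 30 bp perfect fragment of a 150 bp candidate is 20% element-level
    # conservation, far below any neutral threshold
    cand = _candidate()
    frag = HomologyHit(
        GenomicInterval(cand.id, 10, 40, "+"),
        GenomicInterval("og", 0, 30, "+"),
        1.0, 30, 1e-9,
    )
    outgroup_exclusion([cand], {"og": [frag]}, 0.12)
    assert cand.accepted


# ---------------------------------------------------------------------------
# repeat_coding_filter


def test_repeat_overlap_rules():
    inside = _candidate(100, 250)
    edge = _candidate(300, 400)
    bookended = _candidate(500, 600)
    repeats = [GenomicInterval("ref", 50, 300), GenomicInterval("ref", 399, 500)]
    repeat_coding_filter([inside, edge, bookended], repeats, [])
    assert inside.flags == {"repeat"}
    assert edge.flags == {"repeat"}  # 1 bp overlap removes
    assert bookended.accepted  # half-open adjacency is not overlap


def test_coding_filter_checks_ortholog_intervals():
    cand = _candidate(0, 150)
    cand.species_support["b"] = (GenomicInterval("b", 700, 850, "+"), 1.0)
    repeat_coding_filter([cand], [], [GenomicInterval("b", 840, 900)])
    assert cand.flags == {"coding"}


# ---------------------------------------------------------------------------
# chance_probability


def test_chance_frequency_single_comparison():
    hits = [_hit(0, 150, 1.0)] * 2 + [_hit(0, 150, 0.9)] * 8
    est = chance_probability(hits, 100, 1.0, n_comparisons=1)
    assert est.per_comparison_frequency == pytest.approx(0.2)
    assert est.joint_probability == pytest.approx(0.2)


def test_chance_independence_product():
    hits = [_hit(0, 150, 1.0)] + [_hit(0, 150, 0.9)] * 999
    est = chance_probability(hits, 100, 1.0, n_comparisons=3)
    assert est.per_comparison_frequency == pytest.approx(1e-3)
    assert est.joint_probability == pytest.approx(1e-9)
    assert est.expected_count == pytest.approx(1e-6)
    with pytest.raises(ValueError):
        chance_probability([], 100, 1.0, 1)


def test_chance_frequency_predicts_heldout_counts():
    """The qualifying-hit frequency estimated on half of a neutral hit
    population predicts the count in the held-out half within the Poisson
    95% envelope (direct count on simulation)."""
    from hcnskit.synthetic_world import evolve_sequence

    q = _random_seq(120_000, seed=22)
    s, _ = evolve_sequence(
        q, 1e-9, 4e7, seed=23, indel_rate_per_site_per_myr=1e-4
    )
    hits = resolve_overlaps(find_local_homologies({"q": q}, {"s": s}), slop=15)
    assert len(hits) > 100
    half = len(hits) // 2
    est = chance_probability(hits[:half], 150, 0.97, n_comparisons=1)
    observed = sum(
        1 for h in hits[half:] if h.length >= 150 and h.identity >= 0.97
    )
    expected = est.per_comparison_frequency * (len(hits) - half)
    lo, hi = __import__("scipy.stats", fromlist=["poisson"]).poisson.interval(
        0.95, max(expected, 1e-9)
    )
    assert lo - 2 <= observed <= hi + 2


# ---------------------------------------------------------------------------
# End-to-end guarantees on the planted world


def test_planted_recall_and_decoy_rejection(discovery_world, discovery_result):
    from hcnskit.pipeline import evaluate_discovery

    ev = evaluate_discovery(discovery_world, discovery_result)
    assert ev.recall_accelerated == 1.0
    assert ev.stage_recall_frozen == 1.0
    assert ev.decoys_accepted == 0


def test_accepted_candidates_pairwise_disjoint(discovery_result):
    acc = sorted(discovery_result.accepted, key=lambda c: c.interval.start)
    for a, b in zip(acc, acc[1:]):
        assert not a.interval.overlaps(b.interval)


def test_filter_cascade_order_independent(discovery_world):
    """Applying outgroup and mask filters in either order yields the same
    accepted set (filters add flags independently)."""
    import copy

    from hcnskit.pipeline import run_discovery

    masks = [GenomicInterval(discovery_world.reference, 0, 1500)]
    base = run_discovery(discovery_world)
    cands_a = copy.deepcopy(base.candidates)
    cands_b = copy.deepcopy(base.candidates)
    for c in cands_a + cands_b:
        c.flags = {f for f in c.flags if not f.startswith(("outgroup", "repeat", "coding"))}
    og_hits = {
        sp: [] for sp in discovery_world.outgroups
    }  # no outgroup evidence in this re-run; mask order is what varies
    outgroup_exclusion(cands_a, og_hits, base.threshold.value)
    repeat_coding_filter(cands_a, masks, [])
    repeat_coding_filter(cands_b, masks, [])
    outgroup_exclusion(cands_b, og_hits, base.threshold.value)
    assert [c.interval for c in cands_a if c.accepted] == [
        c.interval for c in cands_b if c.accepted
    ]
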