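"""Synthetic world generator: substitution model, indels, planted-element
guarantees, polymorphism spectra."""

import numpy as np
import pytest
from scipy import stats

from hcnskit.synthetic_world import (
    Branch,
    PlantedElement,
    Regime,
    SpeciesTree,
    build_world,
    evolve_sequence,
    hominid_tree,
    map_interval,
    plant_elements,
    sample_derived_counts,
    simulate_ds_sample,
    simulate_variants,
)


def _random_seq(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# ---------------------------------------------------------------------------
# evolve_sequence


def test_zero_rate_is_identity():
    seq = _random_seq(500)
    child, cmap = evolve_sequence(seq, 0.0, 1e7, seed=1)
    assert child == seq
    assert np.array_equal(cmap, np.arange(500))


def test_jukes_cantor_expected_divergence():
    # d = 0.01 substitutions/site; expected p = (3/4)(1 - exp(-4d/3))
    seq = _random_seq(100_000, seed=2)
    child, _ = evolve_sequence(seq, 1e-9, 1e7, seed=3)
    p_obs = np.mean(
        np.frombuffer(seq.encode(), np.uint8) != np.frombuffer(child.encode(), np.uint8)
    )
    p_exp = 0.75 * (1 - np.exp(-4 * 0.01 / 3))
    se = np.sqrt(p_exp * (1 - p_exp) / 100_000)
    assert abs(p_obs - p_exp) < 3 * se


def test_same_seed_reproduces():
    seq = _random_seq(2000)
    a = evolve_sequence(seq, 1e-9, 1e7, seed=7, indel_rate_per_site_per_myr=1e-3)
    b = evolve_sequence(seq, 1e-9, 1e7, seed=7, indel_rate_per_site_per_myr=1e-3)
    assert a[0] == b[0]
    assert np.array_equal(a[1], b[1])


def test_non_acgt_rejected_with_position():
    with pytest.raises(ValueError, match="position 2"):
        evolve_sequence("ACNT", 0, 0, seed=0)


def test_coordinate_map_consistency_with_indels():
    seq = _random_seq(5000, seed=4)
    child, cmap = evolve_sequence(
        seq, 0.0, 1e7, seed=5, indel_rate_per_site_per_myr=5e-3
    )
    kept = cmap[cmap >= 0]
    # strictly increasing, within child bounds
    assert np.all(np.diff(kept) > 0)
    assert kept.max() < len(child)
    # zero substitution rate: surviving bases are carried over unchanged
    for parent_pos in np.nonzero(cmap >= 0)[0][::97]:
        assert child[cmap[parent_pos]] == seq[parent_pos]


def test_indels_suppressed_inside_protected_interval():
    seq = _random_seq(4000, seed=6)
    child, cmap = evolve_sequence(
        seq, 0.0, 5e7, seed=8, indel_rate_per_site_per_myr=5e-3,
        no_indel_intervals=[(1000, 1400)],
    )
    span = map_interval(cmap, 1000, 1400)
    assert span is not None
    assert span[1] - span[0] == 400
    assert child[span[0] : span[1]] == seq[1000:1400]


# ---------------------------------------------------------------------------
# Species tree


def test_hominid_tree_structure():
    tree = hominid_tree()
    assert set(tree.leaves) == {
        "human", "chimpanzee", "gorilla", "orangutan", "gibbon", "macaque"
    }
    assert tree.root == "root"
    # human-gibbon separation is twice the gibbon split age
    assert tree.path_years("human", "gibbon") == pytest.approx(2 * 18.8e6)
    assert tree.branch_to("hominidae_mrca").duration_myr == pytest.approx(3.1)


def test_tree_validation_rejects_malformed():
    with pytest.raises(ValueError, match="root"):
        SpeciesTree((Branch("a", "b", 1, 0), Branch("c", "d", 1, 0)))
    with pytest.raises(ValueError, match="children"):
        SpeciesTree(
            (
                Branch("r", "a", 1, 0),
                Branch("r", "b", 1, 0),
                Branch("r", "c", 1, 0),
            )
        )


# ---------------------------------------------------------------------------
# build_world


def test_frozen_elements_identical_across_ingroup():
    rng = np.random.default_rng(0)
    elements = plant_elements(
        60_000, {Regime.CONSERVED: 10}, 150, rng, stem_multiplier=1.0
    )
    world = build_world(hominid_tree(), elements, 60_000, seed=0)
    for i in range(10):
        copies = set()
        for sp in world.ingroup:
            iv = world.element_interval(sp, i)
            assert iv is not None
            copies.add(world.sequences[sp][iv.start : iv.end])
        assert len(copies) == 1  # pairwise identical


def test_overlapping_elements_rejected():
    els = [
        PlantedElement(100, 250, Regime.CONSERVED),
        PlantedElement(200, 350, Regime.CONSERVED),
    ]
    with pytest.raises(ValueError, match="overlap"):
        build_world(hominid_tree(), els, 10_000, seed=0)


def test_world_files_byte_identical_under_seed(tmp_path):
    els = [PlantedElement(3000, 3150, Regime.STEM_ACCELERATED, 5.0)]
    for d in ("w1", "w2"):
        world = build_world(hominid_tree(), els, 20_000, seed=42)
        world.write(tmp_path / d)
    for name in ["human.fa", "gibbon.fa", "human.truth.bed", "manifest.txt"]:
        assert (tmp_path / "w1" / name).read_bytes() == (
            tmp_path / "w2" / name
        ).read_bytes()


def test_stem_accelerated_elements_diverge_beyond_frozen_ones():
    """Multiplier-5 stem: accelerated elements carry visibly more
    human-gibbon divergence than frozen-stem elements, and the recovered
    stem rate sits within 2 SE of the configured 5.5e-9/site/year."""
    rng = np.random.default_rng(3)
    n, L = 40, 300
    elements = plant_elements(
        150_000,
        {Regime.STEM_ACCELERATED: n, Regime.CONSERVED: n},
        L,
        rng,
        stem_multiplier=5.0,
    )
    world = build_world(hominid_tree(), elements, 150_000, seed=3)
    ref = world.reference
    h, g = world.sequences[ref], world.sequences["gibbon"]
    div = {Regime.STEM_ACCELERATED: [], Regime.CONSERVED: []}
    for i, el in enumerate(world.elements):
        ih = world.element_interval(ref, i)
        ig = world.element_interval("gibbon", i)
        if ih is None or ig is None or ih.length != ig.length:
            continue
        a, b = h[ih.start : ih.end], g[ig.start : ig.end]
        div[el.regime].append(np.mean([x != y for x, y in zip(a, b)]))
    assert np.mean(div[Regime.STEM_ACCELERATED]) > np.mean(div[Regime.CONSERVED])

    from hcnskit.pipeline import rate_recovery_study

    rec = rate_recovery_study(seed=3, n_elements=100, element_length=300)
    se = rec.rates["alpha_rate"].std() / np.sqrt(len(rec.rates))
    assert abs(rec.alpha_mean - 5.5e-9) < 2 * se


def test_neutral_decoys_match_background_divergence():
    """Decoy ingroup divergence is indistinguishable from background
    (two-sample KS on human-chimpanzee per-window mismatch counts)."""
    rng = np.random.default_rng(5)
    n, L = 100, 150
    elements = plant_elements(
        200_000, {Regime.NEUTRAL_DECOY: n}, L, rng, min_gap=300
    )
    world = build_world(hominid_tree(), elements, 200_000, seed=5)
    h, c = world.sequences["human"], world.sequences["chimpanzee"]

    def mismatches(root_start, root_end):
        sh = map_interval(world.root_maps["human"], root_start, root_end)
        sc = map_interval(world.root_maps["chimpanzee"], root_start, root_end)
        if sh is None or sc is None:
            return None
        a, b = h[sh[0] : sh[1]], c[sc[0] : sc[1]]
        if len(a) != len(b) or len(a) != root_end - root_start:
            return None
        return sum(x != y for x, y in zip(a, b))

    decoy, background = [], []
    for el in world.elements:
        m = mismatches(el.start, el.end)
        if m is not None:
            decoy.append(m)
        m_bg = mismatches(el.start - 50 - L, el.start - 50)
        if m_bg is not None:
            background.append(m_bg)
    p = stats.ks_2samp(decoy, background).pvalue
    assert p > 0.01


# ---------------------------------------------------------------------------
# simulate_variants


def test_neutral_singleton_fraction_matches_harmonic_sum():
    # P(count = 1) = 1 / sum_{i=1..9} 1/i for n = 10 chromosomes
    rng = np.random.default_rng(11)
    counts = sample_derived_counts(10_000, 10, "neutral", rng)
    expected = 1.0 / np.sum(1.0 / np.arange(1, 10))
    se = np.sqrt(expected * (1 - expected) / 10_000)
    assert abs(np.mean(counts == 1) - expected) < 3 * se


def test_purifying_factor_halves_constrained_density():
    seq = _random_seq(40_000, seed=12)
    variants = simulate_variants(
        seq, 50, 0.02, regime="purifying",
        constrained_intervals=[(10_000, 20_000)], seed=13, purifying_factor=0.5,
    )
    inside = sum(1 for v in variants if 10_000 <= v.pos < 20_000)
    outside = len(variants) - inside
    lam_in, lam_out = 0.01 * 10_000, 0.02 * 30_000
    assert abs(inside - lam_in) < 3 * np.sqrt(lam_in)
    assert abs(outside - lam_out) < 3 * np.sqrt(lam_out)


def test_variant_edge_cases():
    seq = _random_seq(1000)
    assert simulate_variants(seq, 10, 0.0, seed=0) == []
    with pytest.raises(ValueError):
        simulate_variants(seq, 10, -0.1, seed=0)
    with pytest.raises(ValueError):
        sample_derived_counts(10, 1, "neutral", np.random.default_rng(0))


def test_no_fixed_frequencies_emitted():
    seq = _random_seq(20_000, seed=14)
    variants = simulate_variants(seq, 5, 0.05, seed=15, indel_fraction=0.2)
    assert variants
    assert all(v.frequency < 1.0 for v in variants)
    assert {v.vclass for v in variants} <= {"SNP", "insertion", "deletion"}


def test_ds_sample_mode_sits_at_neutral_divergence():
    vals = simulate_ds_sample(5000, 0.10, np.random.default_rng(16))
    from hcnskit.neutral_threshold import histogram_mode

    assert abs(histogram_mode(vals, 0.01) - 0.10) <= 0.01
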