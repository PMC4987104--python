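"""End-to-end drivers: discovery on a synthetic world, and the parameter
recovery / power studies that validate each stage against configured truth.

These functions tie the modules together exactly the way the command-line
interface and the reproduction script run them, so tests, CLI and scripted
analyses share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .branch_rates import PhyloCalibration, ThreeTaxonAlignment, estimate_element_rates
from .hcns_discovery import (
    ChanceEstimate,
    HCNSCandidate,
    chance_probability,
    conservation_filter,
    find_local_homologies,
    outgroup_exclusion,
    repeat_coding_filter,
    resolve_overlaps,
)
from .intervals import GenomicInterval
from .neutral_threshold import DivergenceSample, ThresholdRecord, neutral_threshold
from .selection_signals import daf_spectrum_tests, matched_random_intervals, variant_density
from .synthetic_world import (
    Regime,
    World,
    build_world,
    hominid_tree,
    plant_elements,
    sample_derived_counts,
    simulate_ds_sample,
    simulate_variants,
)


# ---------------------------------------------------------------------------
# Discovery on a world


@dataclass
class DiscoveryResult:
    candidates: list[HCNSCandidate]
    threshold: ThresholdRecord
    chance: ChanceEstimate
    n_ingroup_hits: int

    @property
    def accepted(self) -> list[HCNSCandidate]:
        return [c for c in self.candidates if c.accepted]


def default_discovery_world(
    seed: int = 0,
    genome_length: int = 100_000,
    n_accelerated: int = 10,
    n_conserved: int = 5,
    n_decoys: int = 5,
    element_length: int = 150,
    stem_multiplier: float = 60.0,
) -> World:
    """The standard discovery test world: a 100 kb genome over the
    4-ingroup + 2-outgroup calibrated tree with 20 planted elements.

    Accelerated elements use a strong stem multiplier (stem divergence
    ~0.2/site), emulating the majority of real clade-specific elements
    whose ancestral sequences diverged far beyond the neutral envelope of
    the outgroups (most could not even be mapped there).
    """
    rng = np.random.default_rng(seed)
    tree = hominid_tree()
    elements = plant_elements(
        genome_length,
        {
            Regime.CONSERVED: n_conserved,
            Regime.STEM_ACCELERATED: n_accelerated,
            Regime.NEUTRAL_DECOY: n_decoys,
        },
        element_length,
        rng,
        stem_multiplier=stem_multiplier,
    )
    return build_world(tree, elements, genome_length, seed=seed)


def discover(
    sequences: dict[str, str],
    reference: str,
    ingroup: Sequence[str],
    outgroups: Sequence[str],
    min_length: int = 100,
    min_identity: float = 1.0,
    evalue_max: float = 1e-5,
    bin_width: float = 0.005,
    repeat_intervals: Sequence[GenomicInterval] = (),
    coding_intervals: Sequence[GenomicInterval] = (),
    min_threshold_hit_length: int = 200,
    overlap_slop: int = 15,
    ds_values: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> DiscoveryResult:
    """The full filter cascade on a set of genome sequences.

    Reference vs each ingroup genome: local homology search and overlap
    resolution; perfect-conservation filter; neutral threshold from the
    reference-vs-nearest-outgroup background hit divergences
    (cross-checked against a synonymous-rate sample -- supplied via
    ``ds_values``, or synthesized around the observed background
    divergence when absent); element-targeted outgroup searches and
    exclusion; repeat/coding mask filter.
    """
    ref_seq = sequences[reference]
    others = [sp for sp in ingroup if sp != reference]

    hits_by_species = {}
    all_hits = []
    for sp in others:
        hits = find_local_homologies(
            {reference: ref_seq}, {sp: sequences[sp]}, evalue_max=evalue_max
        )
        hits = resolve_overlaps(hits, slop=overlap_slop)
        hits_by_species[sp] = hits
        all_hits.extend(hits)

    candidates = conservation_filter(
        hits_by_species,
        min_length=min_length,
        min_identity=min_identity,
        reference_sequence=ref_seq,
        species_sequences={sp: sequences[sp] for sp in others},
    )

    # neutral threshold from reference vs nearest-outgroup background
    og1 = outgroups[0]
    og_bg_hits = resolve_overlaps(
        find_local_homologies(
            {reference: ref_seq}, {og1: sequences[og1]}, evalue_max=evalue_max
        ),
        slop=overlap_slop,
    )
    identities = [
        h.identity for h in og_bg_hits if h.length >= min_threshold_hit_length
    ]
    noncoding = DivergenceSample(
        tuple(identities), "noncoding-identity", (reference, og1)
    )
    if ds_values is None:
        pooled = sum(h.length * (1 - h.identity) for h in og_bg_hits) / max(
            1, sum(h.length for h in og_bg_hits)
        )
        ds_values = simulate_ds_sample(
            2000, pooled, np.random.default_rng(seed + 101)
        ).tolist()
    ds_sample = DivergenceSample(tuple(ds_values), "synonymous-ds", (reference, og1))
    threshold = neutral_threshold(noncoding, ds_sample, bin_width=bin_width)

    # element-targeted outgroup searches (only conservation-passing
    # candidates can still be accepted; rejected ones skip the search)
    queries = {
        c.id: ref_seq[c.interval.start : c.interval.end]
        for c in candidates
        if not ({"length", "identity"} & c.flags)
    }
    outgroup_hits = {}
    for sp in outgroups:
        outgroup_hits[sp] = (
            find_local_homologies(
                queries, {sp: sequences[sp]}, evalue_max=evalue_max
            )
            if queries
            else []
        )
    outgroup_exclusion(candidates, outgroup_hits, threshold.value)
    repeat_coding_filter(candidates, repeat_intervals, coding_intervals)

    chance = chance_probability(
        all_hits, min_length, min_identity, n_comparisons=len(others)
    )
    return DiscoveryResult(candidates, threshold, chance, len(all_hits))


def run_discovery(
    world: World,
    min_length: int = 100,
    min_identity: float = 1.0,
    evalue_max: float = 1e-5,
    bin_width: float = 0.005,
    repeat_intervals: Sequence[GenomicInterval] = (),
    coding_intervals: Sequence[GenomicInterval] = (),
    min_threshold_hit_length: int = 200,
    overlap_slop: int = 15,
) -> DiscoveryResult:
    """The full filter cascade on a synthetic world; the synonymous-rate
    comparator sample is synthesized at the world's true background
    divergence."""
    og1 = world.outgroups[0]
    d_true = _expected_p_distance(world, world.reference, og1)
    ds_values = simulate_ds_sample(
        2000, d_true, np.random.default_rng(world.seed + 101)
    ).tolist()
    return discover(
        world.sequences,
        world.reference,
        world.ingroup,
        world.outgroups,
        min_length=min_length,
        min_identity=min_identity,
        evalue_max=evalue_max,
        bin_width=bin_width,
        repeat_intervals=repeat_intervals,
        coding_intervals=coding_intervals,
        min_threshold_hit_length=min_threshold_hit_length,
        overlap_slop=overlap_slop,
        ds_values=ds_values,
        seed=world.seed,
    )


def _expected_p_distance(world: World, sp_a: str, sp_b: str) -> float:
    """Expected background p-distance between two leaves (truth from the
    generating tree, used only to parameterize synthetic comparators)."""
    d = 0.0
    parent = {b.child: b.parent for b in world.tree.branches}

    def chain(leaf):
        out = [leaf]
        while out[-1] in parent:
            out.append(parent[out[-1]])
        return out

    ca, cb = chain(sp_a), chain(sp_b)
    common = next(n for n in ca if n in set(cb))
    for c in (ca, cb):
        for node in c:
            if node == common:
                break
            br = world.tree.branch_to(node)
            d += br.rate * br.duration_myr * 1e6
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


@dataclass(frozen=True)
class DiscoveryEvaluation:
    recall_accelerated: float
    stage_recall_frozen: float  # conservation stage, all ingroup-frozen plants
    decoys_accepted: int
    conserved_vetoed: int  # anciently conserved plants removed by outgroup filter
    n_accepted: int


def evaluate_discovery(world: World, result: DiscoveryResult) -> DiscoveryEvaluation:
    """Score a discovery run against the world's planted truth.

    An element counts as recovered when an accepted candidate contains its
    full reference-species truth interval; a decoy counts as accepted
    under the same containment rule.
    """
    ref = world.reference

    def containing(idx: int, pool: list[HCNSCandidate]) -> bool:
        truth = world.element_interval(ref, idx)
        if truth is None:
            return False
        return any(c.interval.contains(truth) for c in pool)

    accepted = result.accepted
    no_cons_flags = [
        c for c in result.candidates if not ({"length", "identity"} & c.flags)
    ]
    accel = world.elements_of(Regime.STEM_ACCELERATED)
    frozen = world.elements_of(Regime.STEM_ACCELERATED, Regime.CONSERVED)
    conserved = world.elements_of(Regime.CONSERVED)
    decoys = world.elements_of(Regime.NEUTRAL_DECOY)

    recall = (
        sum(containing(i, accepted) for i in accel) / len(accel) if accel else 1.0
    )
    stage = (
        sum(containing(i, no_cons_flags) for i in frozen) / len(frozen)
        if frozen else 1.0
    )
    vetoed = sum(
        1
        for i in conserved
        if containing(i, [c for c in result.candidates
                          if any(f.startswith("outgroup:") for f in c.flags)])
    )
    n_decoys = sum(containing(i, accepted) for i in decoys)
    return DiscoveryEvaluation(recall, stage, n_decoys, vetoed, len(accepted))


# ---------------------------------------------------------------------------
# Branch-rate parameter recovery


@dataclass(frozen=True)
class RateRecovery:
    rates: pd.DataFrame
    alpha_mean: float
    beta_mean: float
    gamma_mean: float
    truth: dict[str, float]


def rate_recovery_study(
    seed: int = 0,
    n_elements: int = 200,
    element_length: int = 300,
    alpha_rate: float = 5.5e-9,
    beta_rate: float = 2.0e-9,
    gamma_rate: float = 1.9e-9,
    neutral_rate: float = 1.1e-9,
    t_og2_myr: float = 29.0,
    distance: str = "jc",
) -> RateRecovery:
    """Simulate stem-accelerated elements at known branch rates and
    re-estimate the rates from the three-taxon decomposition.

    The ingroup stem runs at ``alpha_rate`` inside elements (multiplier
    over the neutral rate), the first-outgroup branch at ``beta_rate`` and
    the second-outgroup side at ``gamma_rate``.  Element copies are
    extracted via the true coordinate maps; with indels suppressed inside
    elements the copies align positionally.
    """
    rng = np.random.default_rng(seed)
    tree = hominid_tree(
        neutral_rate=neutral_rate,
        t_og2_myr=t_og2_myr,
        branch_rates={
            "gibbon": beta_rate,
            "macaque": gamma_rate,
            "hylobatidae_split": gamma_rate,
        },
    )
    genome_length = n_elements * (element_length + 400) + 8000
    elements = plant_elements(
        genome_length,
        {Regime.STEM_ACCELERATED: n_elements},
        element_length,
        rng,
        min_gap=400,
        edge_margin=2000,
        stem_multiplier=alpha_rate / neutral_rate,
    )
    world = build_world(tree, elements, genome_length, seed=seed)

    ref = world.reference
    alignments = []
    for i in range(len(world.elements)):
        spans = [world.element_interval(sp, i) for sp in (ref, "gibbon", "macaque")]
        if any(s is None for s in spans):
            continue
        rows = [world.sequences[sp][s.start : s.end] for sp, s in
                zip((ref, "gibbon", "macaque"), spans)]
        if len({len(r) for r in rows}) != 1:
            continue
        alignments.append(ThreeTaxonAlignment(f"element_{i}", *rows))

    calibration = PhyloCalibration(t_og2=t_og2_myr * 1e6)
    rates = estimate_element_rates(alignments, calibration, distance=distance)
    return RateRecovery(
        rates,
        float(rates["alpha_rate"].mean()),
        float(rates["beta_rate"].mean()),
        float(rates["gamma_rate"].mean()),
        {"alpha": alpha_rate, "beta": beta_rate, "gamma": gamma_rate},
    )


# ---------------------------------------------------------------------------
# Neutral threshold recovery


@dataclass(frozen=True)
class ThresholdRecovery:
    record: ThresholdRecord
    true_p_distance: float
    n_windows: int
    bin_width: float


def threshold_recovery_study(
    seed: int = 0,
    n_windows: int = 10_000,
    window: int = 1000,
    rate: float = 1.1e-9,
    path_years: float = 2 * 18.8e6,
    bin_width: float = 0.005,
) -> ThresholdRecovery:
    """Evolve windows over a neutral two-species path and recover the
    configured divergence as the histogram mode of per-window identity."""
    from .synthetic_world import decode_sequence, evolve_sequence

    rng = np.random.default_rng(seed)
    L = n_windows * window
    parent = decode_sequence(rng.integers(0, 4, size=L).astype(np.int8))
    child, _ = evolve_sequence(parent, rate, path_years, seed=rng)
    pa = np.frombuffer(parent.encode(), np.uint8)
    ca = np.frombuffer(child.encode(), np.uint8)
    mism = (pa != ca).reshape(n_windows, window)
    identities = 1.0 - mism.mean(axis=1)
    noncoding = DivergenceSample(tuple(identities.tolist()), "noncoding-identity")
    d_subst = rate * path_years
    true_p = 0.75 * (1.0 - np.exp(-4.0 * d_subst / 3.0))
    ds = DivergenceSample(
        tuple(simulate_ds_sample(2000, true_p, rng).tolist()), "synonymous-ds"
    )
    record = neutral_threshold(noncoding, ds, bin_width=bin_width)
    return ThresholdRecovery(record, float(true_p), n_windows, bin_width)


# ---------------------------------------------------------------------------
# DAF test calibration (type-I error and power)


@dataclass(frozen=True)
class DAFCalibration:
    type1_error: float
    power: float
    n_reps_type1: int
    n_reps_power: int
    n_per_sample: int
    alpha: float


def daf_calibration_study(
    seed: int = 0,
    n_reps_type1: int = 200,
    n_reps_power: int = 100,
    n_per_sample: int = 500,
    n_chromosomes: int = 100,
    alpha: float = 0.05,
    purifying_shape: float = 2.0,
) -> DAFCalibration:
    """Operating characteristics of the rare-excess Fisher test.

    Type-I error: both samples neutral.  Power: test sample drawn from the
    rare-reweighted purifying spectrum against a neutral background.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps_type1):
        t = sample_derived_counts(n_per_sample, n_chromosomes, "neutral", rng) / n_chromosomes
        b = sample_derived_counts(n_per_sample, n_chromosomes, "neutral", rng) / n_chromosomes
        if daf_spectrum_tests(t, b).fisher_p < alpha:
            rejections += 1
    hits = 0
    for _ in range(n_reps_power):
        t = sample_derived_counts(
            n_per_sample, n_chromosomes, "purifying", rng, purifying_shape
        ) / n_chromosomes
        b = sample_derived_counts(n_per_sample, n_chromosomes, "neutral", rng) / n_chromosomes
        if daf_spectrum_tests(t, b).fisher_p < alpha:
            hits += 1
    return DAFCalibration(
        rejections / n_reps_type1, hits / n_reps_power,
        n_reps_type1, n_reps_power, n_per_sample, alpha,
    )


# ---------------------------------------------------------------------------
# Polymorphism density contrast


@dataclass(frozen=True)
class DensityStudy:
    hcns_density: float
    random_density: float
    t_statistic: float
    p_value: float
    n_elements: int


def density_study(
    seed: int = 0,
    n_elements: int = 200,
    element_length: int = 114,
    genome_length: int = 200_000,
    theta: float = 2.9e-2,
    purifying_factor: float = 2.4 / 2.9,
    n_chromosomes: int = 100,
) -> DensityStudy:
    """Polymorphism density inside constrained elements vs matched random
    intervals.

    Defaults reflect human-population polymorphism levels: background SNP
    density 2.9e-2 per site, constrained elements at 2.4e-2 (factor ~0.83).
    """
    rng = np.random.default_rng(seed)
    seq_codes = rng.integers(0, 4, size=genome_length).astype(np.int8)
    from .synthetic_world import decode_sequence

    sequence = decode_sequence(seq_codes)
    extent = GenomicInterval("ref", 0, genome_length)
    elements = matched_random_intervals(
        n_elements, [element_length] * n_elements, extent, seed=rng
    )
    variants = simulate_variants(
        sequence,
        n_chromosomes,
        theta,
        regime="purifying",
        constrained_intervals=elements,
        seed=rng,
        purifying_factor=purifying_factor,
    )
    randoms = matched_random_intervals(
        n_elements, [element_length] * n_elements, extent, excluded=elements, seed=rng
    )
    from .selection_signals import density_difference_test

    d_h, counts_h = variant_density(elements, variants)
    d_r, counts_r = variant_density(randoms, variants)
    t, p = density_difference_test(counts_h, counts_r)
    return DensityStudy(d_h, d_r, t, p, n_elements)
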