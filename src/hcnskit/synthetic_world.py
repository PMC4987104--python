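"""Synthetic multi-species world generator.

Evolves a root genome down a calibrated primate-like species tree
(4 ingroup hominids + gibbon + macaque outgroups) under a Jukes-Cantor
substitution model with geometric-length indels, planting noncoding
elements with one of three histories:

* ``CONSERVED`` -- frozen on the ingroup stem and every ingroup branch: an
  anciently conserved element whose outgroup ortholog is itself conserved
  (so the outgroup-exclusion filter must veto it);
* ``STEM_ACCELERATED`` -- evolved at ``stem_multiplier`` times the branch
  rate on the ingroup stem, then frozen in the ingroup crown: the history
  of a clade-specific highly conserved element (accelerated origin, then
  purifying selection);
* ``NEUTRAL_DECOY`` -- plain background, recorded in the manifest only so
  that discovery specificity can be scored.

Also simulates polymorphism tables with neutral or purifying site-frequency
structure, synonymous-rate samples, toy gene annotations, and per-base
signal tracks.  A fixed seed reproduces every output byte-identically.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .intervals import GenomicInterval
from .io_formats import (
    GtfFeature,
    VariantRecord,
    write_bed,
    write_config,
    write_fasta,
)

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

INGROUP = ("human", "chimpanzee", "gorilla", "orangutan")
OUTGROUPS = ("gibbon", "macaque")
STEM_CHILD = "hominidae_mrca"  # child node of the ingroup stem branch


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as 0..3 codes; reject anything else with a
    position report."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    bad = np.nonzero(codes < 0)[0]
    if bad.size:
        raise ValueError(
            f"non-ACGT character {seq[bad[0]]!r} at position {int(bad[0])}"
        )
    return codes.astype(np.int8)


def decode_sequence(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Species tree


@dataclass(frozen=True)
class Branch:
    parent: str
    child: str
    duration_myr: float
    rate: float  # substitutions / site / year
    indel_rate: float = 0.0  # events / site / Myr
    mean_indel_length: float = 3.0

    def __post_init__(self) -> None:
        if self.duration_myr <= 0:
            raise ValueError(f"branch {self.parent}->{self.child}: duration must be > 0")
        if self.rate < 0 or self.indel_rate < 0:
            raise ValueError("rates must be >= 0")


@dataclass(frozen=True)
class SpeciesTree:
    """A rooted binary tree given as a branch list (parent, child, duration,
    per-branch rates)."""

    branches: tuple[Branch, ...]

    def __post_init__(self) -> None:
        children: dict[str, list[str]] = {}
        child_set = set()
        for b in self.branches:
            if b.child in child_set:
                raise ValueError(f"node {b.child} has two parents")
            child_set.add(b.child)
            children.setdefault(b.parent, []).append(b.child)
        roots = set(children) - child_set
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {sorted(roots)}")
        for node, kids in children.items():
            if len(kids) != 2:
                raise ValueError(f"internal node {node} has {len(kids)} children (need 2)")
        leaves = [b.child for b in self.branches if b.child not in children]
        if len(set(leaves)) != len(leaves):
            raise ValueError("leaf names must be unique")

    @property
    def root(self) -> str:
        child_set = {b.child for b in self.branches}
        return next(b.parent for b in self.branches if b.parent not in child_set)

    @property
    def leaves(self) -> tuple[str, ...]:
        parents = {b.parent for b in self.branches}
        return tuple(b.child for b in self.branches if b.child not in parents)

    def branch_to(self, child: str) -> Branch:
        for b in self.branches:
            if b.child == child:
                return b
        raise KeyError(child)

    def descendants(self, node: str) -> set[str]:
        """All nodes strictly below ``node``."""
        kids = {}
        for b in self.branches:
            kids.setdefault(b.parent, []).append(b.child)
        out: set[str] = set()
        stack = list(kids.get(node, []))
        while stack:
            n = stack.pop()
            out.add(n)
            stack.extend(kids.get(n, []))
        return out

    def path_years(self, leaf_a: str, leaf_b: str) -> float:
        """Total time (years) separating two leaves along the tree."""
        def ancestors(leaf):
            chain = [leaf]
            parent = {b.child: b.parent for b in self.branches}
            while chain[-1] in parent:
                chain.append(parent[chain[-1]])
            return chain

        ca, cb = ancestors(leaf_a), ancestors(leaf_b)
        common = next(n for n in ca if n in set(cb))
        years = 0.0
        for chain in (ca, cb):
            for node in chain:
                if node == common:
                    break
                years += self.branch_to(node).duration_myr * 1e6
        return years


def hominid_tree(
    neutral_rate: float = 1.1e-9,
    indel_rate: float = 1.0e-4,
    mean_indel_length: float = 3.0,
    t_og2_myr: float = 29.0,
    branch_rates: Optional[dict[str, float]] = None,
) -> SpeciesTree:
    """The default 4-ingroup + 2-outgroup calibrated tree.

    Split ages: human/chimpanzee 6.9 Ma, +gorilla 8.8 Ma, +orangutan
    15.7 Ma, gibbon 18.8 Ma (so the ingroup stem spans 3.1 Myr), macaque
    at ``t_og2_myr``.  ``branch_rates`` overrides the neutral rate on
    selected branches, keyed by child node name.
    """
    if t_og2_myr <= 18.8:
        raise ValueError("outgroup2 split must predate the gibbon split")
    overrides = branch_rates or {}

    def mk(parent, child, dur):
        return Branch(parent, child, dur, overrides.get(child, neutral_rate),
                      indel_rate, mean_indel_length)

    return SpeciesTree(
        (
            mk("root", "macaque", t_og2_myr),
            mk("root", "hylobatidae_split", t_og2_myr - 18.8),
            mk("hylobatidae_split", "gibbon", 18.8),
            mk("hylobatidae_split", STEM_CHILD, 3.1),
            mk(STEM_CHILD, "orangutan", 15.7),
            mk(STEM_CHILD, "homininae_split", 15.7 - 8.8),
            mk("homininae_split", "gorilla", 8.8),
            mk("homininae_split", "hominini_split", 8.8 - 6.9),
            mk("hominini_split", "human", 6.9),
            mk("hominini_split", "chimpanzee", 6.9),
        )
    )


# ---------------------------------------------------------------------------
# Planted elements


class Regime(enum.Enum):
    CONSERVED = "conserved"
    STEM_ACCELERATED = "stem_accelerated"
    NEUTRAL_DECOY = "neutral_decoy"


@dataclass(frozen=True)
class PlantedElement:
    """An element planted on the root sequence. Coordinates are root-based,
    half-open. ``stem_multiplier`` applies only to STEM_ACCELERATED."""

    start: int
    end: int
    regime: Regime
    stem_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("element length must be >= 1")
        if self.stem_multiplier < 0:
            raise ValueError("stem multiplier must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


def plant_elements(
    genome_length: int,
    n_per_regime: dict[Regime, int],
    element_length: int,
    rng,
    min_gap: int = 500,
    edge_margin: int = 2000,
    stem_multiplier: float = 60.0,
) -> list[PlantedElement]:
    """Place disjoint elements uniformly with a minimum gap, round-robin
    over regimes, deterministic under the given rng."""
    rng = _as_rng(rng)
    total = sum(n_per_regime.values())
    regimes: list[Regime] = []
    for regime in (Regime.CONSERVED, Regime.STEM_ACCELERATED, Regime.NEUTRAL_DECOY):
        regimes.extend([regime] * n_per_regime.get(regime, 0))
    span = genome_length - 2 * edge_margin
    need = total * (element_length + min_gap)
    if span < need:
        raise ValueError("genome too small for the requested elements")
    # sample ordered gap layout: uniform starts then sort with spacing
    slack = span - need
    cuts = np.sort(rng.integers(0, slack + 1, size=total))
    elements = []
    pos = edge_margin
    order = rng.permutation(total)
    for k in range(total):
        start = int(edge_margin + cuts[k] + k * (element_length + min_gap) + min_gap // 2)
        regime = regimes[order[k]]
        mult = stem_multiplier if regime is Regime.STEM_ACCELERATED else 1.0
        elements.append(PlantedElement(start, start + element_length, regime, mult))
    return elements


# ---------------------------------------------------------------------------
# Sequence evolution


def evolve_sequence(
    parent: str,
    rate: float,
    duration_years: float,
    *,
    seed=None,
    indel_rate_per_site_per_myr: float = 0.0,
    mean_indel_length: float = 3.0,
    site_multiplier: Optional[np.ndarray] = None,
    no_indel_intervals: Sequence[tuple[int, int]] = (),
) -> tuple[str, np.ndarray]:
    """Evolve ``parent`` for ``duration_years`` at ``rate`` subs/site/year.

    Substitutions follow Jukes-Cantor: a site changes with probability
    (3/4)(1 - exp(-(4/3) d)) where d = rate x duration (x per-site
    multiplier), the multiple-hit closed form.  Indels arrive as a Poisson
    process with geometric lengths and are suppressed inside
    ``no_indel_intervals``.

    Returns the child sequence and a parent->child coordinate map: an
    integer array where entry i is the child position of parent base i, or
    -1 if that base was deleted.
    """
    if rate < 0 or duration_years < 0:
        raise ValueError("rate and duration must be >= 0")
    rng = _as_rng(seed)
    codes = encode_sequence(parent)
    L = codes.size

    d = np.full(L, rate * duration_years)
    if site_multiplier is not None:
        if len(site_multiplier) != L:
            raise ValueError("site_multiplier length mismatch")
        d = d * np.asarray(site_multiplier, dtype=float)
    p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    changed = rng.random(L) < p_change
    new_codes = codes.copy()
    if changed.any():
        shift = rng.integers(1, 4, size=int(changed.sum()))
        new_codes[changed] = (codes[changed] + shift) % 4

    protected = np.zeros(L, dtype=bool)
    for s, e in no_indel_intervals:
        protected[max(0, s) : min(L, e)] = True

    keep = np.ones(L, dtype=bool)
    insertions: dict[int, np.ndarray] = {}
    duration_myr = duration_years / 1e6
    n_events = (
        rng.poisson(indel_rate_per_site_per_myr * L * duration_myr)
        if indel_rate_per_site_per_myr > 0
        else 0
    )
    for _ in range(n_events):
        pos = int(rng.integers(0, L))
        is_insertion = rng.random() < 0.5
        length = int(rng.geometric(1.0 / mean_indel_length))
        if is_insertion:
            # insertion lands between pos-1 and pos; it disrupts nothing
            # unless both flanking bases sit inside a protected element
            if 0 < pos < L and protected[pos] and protected[pos - 1]:
                continue
            seq = rng.integers(0, 4, size=length).astype(np.int8)
            insertions[pos] = np.concatenate([insertions.get(pos, np.empty(0, np.int8)), seq])
        else:
            end = min(L, pos + length)
            if protected[pos:end].any():
                continue
            keep[pos:end] = False

    # child coordinates: kept bases shifted by deletions + insertions
    kept_before = np.cumsum(keep) - keep  # kept bases strictly before i
    add = np.zeros(L + 1, dtype=np.int64)
    for pos, seq in insertions.items():
        add[pos] += len(seq)
    ins_upto = np.cumsum(add)[:L]  # inserted bases at or before position i
    parent_to_child = np.where(keep, kept_before + ins_upto, -1).astype(np.int64)

    pieces = []
    prev = 0
    for pos in sorted(insertions):
        seg = new_codes[prev:pos]
        pieces.append(seg[keep[prev:pos]])
        pieces.append(insertions[pos])
        prev = pos
    seg = new_codes[prev:]
    pieces.append(seg[keep[prev:]])
    child_codes = np.concatenate(pieces) if pieces else new_codes[keep]
    return decode_sequence(child_codes), parent_to_child


def compose_maps(first: np.ndarray, second: np.ndarray) -> np.ndarray:
    """Compose coordinate maps: result maps A->C given A->B and B->C."""
    out = np.full_like(first, -1)
    kept = first >= 0
    out[kept] = second[first[kept]]
    return out


def map_interval(cmap: np.ndarray, start: int, end: int) -> Optional[tuple[int, int]]:
    """Image of [start, end) under a coordinate map, or None if every base
    was deleted.  The image spans min..max of surviving positions."""
    seg = cmap[start:end]
    seg = seg[seg >= 0]
    if seg.size == 0:
        return None
    return int(seg.min()), int(seg.max()) + 1


# ---------------------------------------------------------------------------
# World construction


@dataclass
class WorldManifest:
    """Ground truth for one synthetic world, serializable as flat key=value
    text."""

    seed: int
    genome_length: int
    fasta: dict[str, str] = field(default_factory=dict)
    truth_bed: dict[str, str] = field(default_factory=dict)
    variants: Optional[str] = None
    branch_rates: dict[str, float] = field(default_factory=dict)

    def to_file(self, path) -> None:
        cfg: dict[str, str] = {
            "seed": str(self.seed),
            "genome_length": str(self.genome_length),
        }
        for sp, p in self.fasta.items():
            cfg[f"fasta.{sp}"] = str(p)
        for sp, p in self.truth_bed.items():
            cfg[f"truth_bed.{sp}"] = str(p)
        if self.variants:
            cfg["variants"] = str(self.variants)
        for child, r in self.branch_rates.items():
            cfg[f"rate.{child}"] = repr(r)
        write_config(path, cfg)


@dataclass
class World:
    """In-memory synthetic world: leaf sequences, root->leaf coordinate
    maps, planted-element truth, and the generating parameters."""

    tree: SpeciesTree
    elements: list[PlantedElement]
    seed: int
    genome_length: int
    sequences: dict[str, str]
    root_maps: dict[str, np.ndarray]

    @property
    def ingroup(self) -> list[str]:
        return [sp for sp in INGROUP if sp in self.sequences]

    @property
    def outgroups(self) -> list[str]:
        """Outgroup species, nearest first."""
        named = [sp for sp in OUTGROUPS if sp in self.sequences]
        rest = [
            sp for sp in self.sequences
            if sp not in INGROUP and sp not in OUTGROUPS
        ]
        return named + rest

    @property
    def reference(self) -> str:
        return "human" if "human" in self.sequences else self.ingroup[0]

    def element_interval(self, species: str, index: int) -> Optional[GenomicInterval]:
        """Truth coordinates of planted element ``index`` in ``species``
        (None when every base of it was deleted on the path)."""
        el = self.elements[index]
        span = map_interval(self.root_maps[species], el.start, el.end)
        if span is None:
            return None
        return GenomicInterval(species, span[0], span[1], "+", f"element_{index}")

    def elements_of(self, *regimes: Regime) -> list[int]:
        return [i for i, el in enumerate(self.elements) if el.regime in regimes]

    def write(self, out_dir) -> WorldManifest:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = WorldManifest(
            seed=self.seed,
            genome_length=self.genome_length,
            branch_rates={b.child: b.rate for b in self.tree.branches},
        )
        for sp in self.sequences:
            fa = out / f"{sp}.fa"
            write_fasta(fa, [(sp, self.sequences[sp])])
            manifest.fasta[sp] = fa.name  # paths relative to the manifest
            bed = out / f"{sp}.truth.bed"
            truth = []
            for i, el in enumerate(self.elements):
                iv = self.element_interval(sp, i)
                if iv is not None:
                    truth.append(
                        GenomicInterval(sp, iv.start, iv.end, "+",
                                        f"element_{i}:{el.regime.value}")
                    )
            write_bed(bed, truth)
            manifest.truth_bed[sp] = bed.name
        manifest.to_file(out / "manifest.txt")
        return manifest


def build_world(
    tree: SpeciesTree,
    elements: Sequence[PlantedElement],
    genome_length: int = 100_000,
    seed: int = 0,
) -> World:
    """Evolve a random root genome down ``tree`` with the planted-element
    regimes applied; returns the world with full ground truth.

    Overlapping elements are rejected.  Perfectly-conserved and
    stem-accelerated elements are identical across every ingroup species by
    construction (frozen crown, indels suppressed inside elements).
    """
    elements = sorted(elements, key=lambda e: e.start)
    for a, b in zip(elements, elements[1:]):
        if b.start < a.end:
            raise ValueError(f"overlapping planted elements at {b.start}")
    if elements and elements[-1].end > genome_length:
        raise ValueError("elements must fit inside genome_length")

    rng = np.random.default_rng(seed)
    root = tree.root
    root_codes = rng.integers(0, 4, size=genome_length).astype(np.int8)
    sequences: dict[str, str] = {root: decode_sequence(root_codes)}
    maps: dict[str, np.ndarray] = {root: np.arange(genome_length, dtype=np.int64)}

    ingroup_nodes = tree.descendants(STEM_CHILD) if STEM_CHILD in {
        b.child for b in tree.branches
    } else set()

    for branch in tree.branches:  # branch list is in preorder
        parent_seq = sequences[branch.parent]
        parent_map = maps[branch.parent]
        L = len(parent_seq)
        mult = np.ones(L)
        protect: list[tuple[int, int]] = []
        is_stem = branch.child == STEM_CHILD
        below_stem = branch.child in ingroup_nodes
        for el in elements:
            if el.regime is Regime.NEUTRAL_DECOY:
                continue
            span = map_interval(parent_map, el.start, el.end)
            if span is None:
                continue
            s, e = span
            protect.append((s, e))
            if below_stem:
                mult[s:e] = 0.0
            elif is_stem:
                mult[s:e] = (
                    0.0 if el.regime is Regime.CONSERVED else el.stem_multiplier
                )
        child_seq, cmap = evolve_sequence(
            parent_seq,
            branch.rate,
            branch.duration_myr * 1e6,
            seed=rng,
            indel_rate_per_site_per_myr=branch.indel_rate,
            mean_indel_length=branch.mean_indel_length,
            site_multiplier=mult,
            no_indel_intervals=protect,
        )
        sequences[branch.child] = child_seq
        maps[branch.child] = compose_maps(parent_map, cmap)

    leaf_seqs = {sp: sequences[sp] for sp in tree.leaves}
    leaf_maps = {sp: maps[sp] for sp in tree.leaves}
    return World(tree, list(elements), seed, genome_length, leaf_seqs, leaf_maps)


# ---------------------------------------------------------------------------
# Polymorphism simulation


def sample_derived_counts(
    n_draws: int, n_chromosomes: int, regime: str, rng, purifying_shape: float = 2.0
) -> np.ndarray:
    """Draw derived-allele counts i in [1, n-1]: neutral weights 1/i;
    purifying weights i**(-shape) (rare-skewed)."""
    if n_chromosomes < 2:
        raise ValueError("need at least 2 chromosomes")
    i = np.arange(1, n_chromosomes)
    if regime == "neutral":
        w = 1.0 / i
    elif regime == "purifying":
        w = i ** (-float(purifying_shape))
    else:
        raise ValueError(f"unknown regime {regime!r}")
    w = w / w.sum()
    return _as_rng(rng).choice(i, size=n_draws, p=w)


def simulate_variants(
    sequence: str,
    n_chromosomes: int,
    theta: float,
    regime: str = "neutral",
    constrained_intervals: Sequence = (),
    seed=None,
    purifying_factor: float = 0.5,
    purifying_shape: float = 2.0,
    indel_fraction: float = 0.0,
    chrom: str = "ref",
) -> list[VariantRecord]:
    """Simulate segregating variants on ``sequence``.

    ``theta`` is the expected number of variants per site.  Under the
    purifying regime, density inside ``constrained_intervals`` is scaled by
    ``purifying_factor`` (< 1) and the derived-count spectrum there is
    reweighted toward rare classes; outside, variation is neutral.  Fixed
    differences (frequency 1.0) are never emitted.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if n_chromosomes < 2:
        raise ValueError("need at least 2 chromosomes")
    if regime not in ("neutral", "purifying"):
        raise ValueError(f"unknown regime {regime!r}")
    if regime == "purifying" and not (0 < purifying_factor < 1):
        raise ValueError("purifying factor must lie in (0, 1)")
    rng = _as_rng(seed)
    L = len(sequence)
    if theta == 0 or L == 0:
        return []

    inside = np.zeros(L, dtype=bool)
    for iv in constrained_intervals:
        s, e = (iv.start, iv.end) if hasattr(iv, "start") else iv
        inside[max(0, s) : min(L, e)] = True
    idx_in = np.nonzero(inside)[0]
    idx_out = np.nonzero(~inside)[0]

    factor = purifying_factor if regime == "purifying" else 1.0
    variants: list[VariantRecord] = []
    for idx, dens, spec in (
        (idx_out, theta, "neutral"),
        (idx_in, theta * factor, regime),
    ):
        if idx.size == 0:
            continue
        n = min(int(rng.poisson(dens * idx.size)), idx.size)
        if n == 0:
            continue
        positions = rng.choice(idx, size=n, replace=False)
        counts = sample_derived_counts(n, n_chromosomes, spec, rng, purifying_shape)
        kinds = rng.random(n)
        for pos, count, kind in zip(positions, counts, kinds):
            pos = int(pos)
            ref = sequence[pos]
            freq = float(count) / n_chromosomes
            if kind >= indel_fraction:  # SNP
                alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
                variants.append(VariantRecord(chrom, pos, ref, alt, freq, "SNP"))
            else:
                length = int(rng.geometric(1.0 / 3.0))
                if rng.random() < 0.5 or pos + 1 + length > L:  # insertion
                    ins = decode_sequence(rng.integers(0, 4, size=length).astype(np.int8))
                    variants.append(
                        VariantRecord(chrom, pos, ref, ref + ins, freq, "insertion")
                    )
                else:
                    variants.append(
                        VariantRecord(
                            chrom, pos, sequence[pos : pos + 1 + length], ref, freq,
                            "deletion",
                        )
                    )
    variants.sort(key=lambda v: v.pos)
    return variants


def simulate_ds_sample(
    n_genes: int,
    neutral_divergence: float,
    rng,
    synonymous_sites: int = 300,
    constrained_fraction: float = 0.3,
    constrained_factor: float = 0.7,
) -> np.ndarray:
    """Per-gene synonymous divergence values: most genes neutral, a
    fraction under weak constraint -- yielding a distribution whose mode
    sits at the neutral divergence with a skew toward the conserved end."""
    rng = _as_rng(rng)
    d = np.full(n_genes, neutral_divergence)
    weak = rng.random(n_genes) < constrained_fraction
    d[weak] *= constrained_factor
    return rng.binomial(synonymous_sites, np.clip(d, 0, 1)) / synonymous_sites


# ---------------------------------------------------------------------------
# Toy annotation and signal tracks


def make_toy_annotation(
    genome_length: int,
    n_genes: int,
    rng,
    chrom: str = "human",
    utr_length: int = 150,
) -> list[GtfFeature]:
    """A deterministic toy gene annotation: evenly spaced genes with one
    transcript, three exons, and terminal UTRs on alternating strands."""
    rng = _as_rng(rng)
    feats: list[GtfFeature] = []
    pitch = genome_length // (n_genes + 1)
    for g in range(n_genes):
        span = int(rng.integers(2000, min(5000, pitch - 500)))
        start = (g + 1) * pitch - span // 2
        end = start + span
        strand = "+" if g % 2 == 0 else "-"
        gid, tid = f"gene{g}", f"gene{g}.t1"
        feats.append(GtfFeature(chrom, "gene", start, end, strand, gid))
        feats.append(GtfFeature(chrom, "transcript", start, end, strand, gid, tid))
        exon_len = span // 5
        exons = [
            (start, start + exon_len),
            (start + 2 * exon_len, start + 3 * exon_len),
            (end - exon_len, end),
        ]
        for es, ee in exons:
            feats.append(GtfFeature(chrom, "exon", es, ee, strand, gid, tid))
        u = min(utr_length, exon_len)
        feats.append(GtfFeature(chrom, "UTR", start, start + u, strand, gid, tid))
        feats.append(GtfFeature(chrom, "UTR", end - u, end, strand, gid, tid))
    return feats


def make_signal_track(
    length: int,
    dip_intervals: Sequence,
    rng,
    baseline: float = 0.5,
    dip_depth: float = 0.2,
    noise_sd: float = 0.05,
) -> np.ndarray:
    """A per-base signal with Gaussian noise and a depressed level inside
    ``dip_intervals`` (emulating nucleosome-occupancy dips at elements)."""
    rng = _as_rng(rng)
    track = baseline + rng.normal(0.0, noise_sd, size=length)
    for iv in dip_intervals:
        s, e = (iv.start, iv.end) if hasattr(iv, "start") else iv
        track[max(0, s) : min(length, e)] -= dip_depth
    return track
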