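"""Polymorphism-based tests of purifying selection on conserved elements.

Purifying selection leaves two population-genetic signatures: a depressed
polymorphism density inside constrained elements relative to matched random
intervals, and a derived-allele-frequency (DAF) spectrum shifted toward
rare classes (deleterious variants are held at low frequency).  This module
provides the matched-interval generator, density comparison, outgroup-based
polarization, DAF spectrum tests (one-sided Fisher rare-excess and
chi-square spectrum shift), center-anchored flanking conservation profiles,
and Tajima's D.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, IntervalIndex
from .io_formats import VariantRecord

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Matched random intervals


def matched_random_intervals(
    n: int,
    lengths: Sequence[int],
    genome_extent: GenomicInterval,
    excluded: Iterable[GenomicInterval] = (),
    seed=None,
    max_tries: int = 1000,
) -> list[GenomicInterval]:
    """Place ``n`` intervals with exactly the given lengths uniformly over
    the allowed positions of ``genome_extent``, avoiding ``excluded`` and
    each other.  Raises after ``max_tries`` failed placements per interval.
    """
    if len(lengths) != n:
        raise ValueError("need exactly one length per interval")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    occupied = IntervalIndex(excluded)
    placed: list[GenomicInterval] = []
    for k, length in enumerate(lengths):
        hi = genome_extent.end - length
        if hi < genome_extent.start:
            raise ValueError(f"interval of length {length} cannot fit the extent")
        for _ in range(max_tries):
            start = int(rng.integers(genome_extent.start, hi + 1))
            iv = GenomicInterval(genome_extent.chrom, start, start + length, ".",
                                 f"random_{k}")
            if not occupied.any_overlap(iv):
                occupied.add(iv)
                placed.append(iv)
                break
        else:
            raise RuntimeError(
                f"could not place interval {k} (length {length}) after "
                f"{max_tries} tries"
            )
    return placed


# ---------------------------------------------------------------------------
# Polymorphism density


def variant_density(
    intervals: Sequence[GenomicInterval], variants: Sequence[VariantRecord]
) -> tuple[float, np.ndarray]:
    """Per-site polymorphism density over non-overlapping intervals.

    SNPs and insertions count at their (anchor) position; deletions count
    in every interval their deleted span overlaps.  Returns the pooled
    density and the per-interval counts.
    """
    if not intervals:
        raise ValueError("empty interval set")
    ivs = sorted(intervals, key=lambda i: (i.chrom, i.start))
    for a, b in zip(ivs, ivs[1:]):
        if a.overlaps(b):
            raise ValueError("intervals must be non-overlapping")
    counts = np.zeros(len(ivs), dtype=np.int64)
    index = IntervalIndex(
        GenomicInterval(iv.chrom, iv.start, iv.end, ".", str(i))
        for i, iv in enumerate(ivs)
    )
    for v in variants:
        span_end = v.pos + (len(v.ref) if v.vclass == "deletion" else 1)
        probe = GenomicInterval(v.chrom, v.pos, max(span_end, v.pos + 1))
        for hit in index.overlapping(probe):
            counts[int(hit.label)] += 1
    total_len = sum(iv.length for iv in ivs)
    return float(counts.sum()) / total_len, counts


def density_difference_test(
    counts_test: np.ndarray, counts_background: np.ndarray
) -> tuple[float, float]:
    """One-sided Welch t-test that per-interval counts are LOWER in the
    test set than in the background; returns (t, p)."""
    res = stats.ttest_ind(
        counts_test, counts_background, equal_var=False, alternative="less"
    )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Polarization


@dataclass(frozen=True)
class PolarizedVariant:
    variant: VariantRecord
    derived_allele: str
    daf: float


def polarize(
    variant: VariantRecord, outgroup_base: str
) -> tuple[Optional[PolarizedVariant], Optional[str]]:
    """Polarize a SNP with an outgroup base: the allele matching the
    outgroup is ancestral.

    Returns ``(polarized, None)`` on success or ``(None, reason)`` when the
    variant is excluded (non-SNP, unknown frequency, or outgroup matching
    neither allele).
    """
    if variant.vclass != "SNP":
        return None, "not-a-SNP"
    if variant.frequency is None:
        return None, "unknown-frequency"
    base = outgroup_base.upper()
    if base == variant.ref:
        return PolarizedVariant(variant, variant.alt, variant.frequency), None
    if base == variant.alt:
        return PolarizedVariant(variant, variant.ref, 1.0 - variant.frequency), None
    return None, "outgroup-matches-neither"


def polarize_all(
    variants: Sequence[VariantRecord], outgroup_sequence: str,
    position_map: Optional[np.ndarray] = None,
) -> tuple[list[PolarizedVariant], dict[str, int]]:
    """Polarize SNPs against an outgroup sequence; ``position_map`` maps
    reference positions into the outgroup sequence (identity when None).
    Returns the polarized variants and exclusion tallies by reason."""
    polarized = []
    excluded: dict[str, int] = {}
    for v in variants:
        pos = v.pos if position_map is None else int(position_map[v.pos])
        if pos < 0 or pos >= len(outgroup_sequence):
            excluded["unmapped"] = excluded.get("unmapped", 0) + 1
            continue
        pv, reason = polarize(v, outgroup_sequence[pos])
        if pv is not None:
            polarized.append(pv)
        else:
            excluded[reason] = excluded.get(reason, 0) + 1
    return polarized, excluded


# ---------------------------------------------------------------------------
# DAF spectrum


@dataclass(frozen=True)
class DAFBin:
    lo: float
    hi: float
    count: int
    proportion: float
    sigma: float  # binomial standard error sqrt(p(1-p)/N)


@dataclass(frozen=True)
class DAFTestResult:
    bins_test: tuple[DAFBin, ...]
    bins_background: tuple[DAFBin, ...]
    fisher_p: float  # one-sided rare-excess
    chisq_p: float  # spectrum shift over all bins
    rare_cutoff: float
    merged_bins: int  # bins merged upward to satisfy expected counts


def _bin_daf(dafs: np.ndarray, edges: np.ndarray) -> list[DAFBin]:
    n = dafs.size
    bins = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        count = int(np.sum((dafs >= lo) & (dafs < hi)))
        p = count / n
        bins.append(DAFBin(float(lo), float(hi), count, p, math.sqrt(p * (1 - p) / n)))
    return bins


def daf_spectrum_tests(
    dafs_test: Sequence[float],
    dafs_background: Sequence[float],
    bin_width: float = 0.1,
    rare_cutoff: float = 0.1,
) -> DAFTestResult:
    """Compare two derived-allele-frequency spectra.

    Rare-excess: one-sided Fisher exact test on the 2x2 table of rare
    (DAF < ``rare_cutoff``) vs non-rare counts in test vs background.
    Spectrum shift: chi-square of the test bin counts against background
    proportions; bins with expected count < 1 are merged upward (logged).
    Per-bin sigma is the binomial standard error sqrt(p(1-p)/N).
    """
    t = np.asarray(dafs_test, dtype=float)
    b = np.asarray(dafs_background, dtype=float)
    if t.size == 0 or b.size == 0:
        raise ValueError("both DAF sets must be nonempty")
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    bins_t = _bin_daf(t, edges)
    bins_b = _bin_daf(b, edges)

    rare_t = int(np.sum(t < rare_cutoff))
    rare_b = int(np.sum(b < rare_cutoff))
    _, fisher_p = stats.fisher_exact(
        [[rare_t, t.size - rare_t], [rare_b, b.size - rare_b]], alternative="greater"
    )

    obs = np.array([bn.count for bn in bins_t], dtype=float)
    exp = np.array([bn.proportion for bn in bins_b]) * t.size
    merged = 0
    # merge upward (toward higher frequency) until every expected cell >= 1
    i = len(exp) - 1
    while i > 0:
        if exp[i] < 1.0:
            exp[i - 1] += exp[i]
            obs[i - 1] += obs[i]
            exp = np.delete(exp, i)
            obs = np.delete(obs, i)
            merged += 1
            log.info("chi-square: merged DAF bin %d upward (expected < 1)", i)
        i -= 1
    if exp[0] < 1.0 and len(exp) > 1:
        exp[1] += exp[0]
        obs[1] += obs[0]
        exp, obs = exp[1:], obs[1:]
        merged += 1
    # guard against zero-probability cells; renormalize to observed total
    keep = exp > 0
    obs, exp = obs[keep], exp[keep]
    exp = exp * obs.sum() / exp.sum()
    chisq_p = float(stats.chisquare(obs, exp).pvalue) if len(obs) > 1 else 1.0

    return DAFTestResult(
        tuple(bins_t), tuple(bins_b), float(fisher_p), chisq_p, rare_cutoff, merged
    )


# ---------------------------------------------------------------------------
# Flanking conservation profile


@dataclass(frozen=True)
class FlankAlignment:
    """Aligned rows spanning one element plus its flanks; element
    boundaries are in alignment coordinates."""

    rows: tuple[str, ...]
    element_start: int
    element_end: int

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("rows must be equal length")
        if not (0 <= self.element_start < self.element_end <= len(self.rows[0])):
            raise ValueError("element boundaries outside the alignment")


@dataclass(frozen=True)
class ConservationProfile:
    offsets: tuple[float, ...]  # bp relative to element center, increasing
    mean_identity: tuple[float, ...]
    sem: tuple[float, ...]
    n_alignments: int


def _window_identity(rows: Sequence[str], start: int, end: int) -> Optional[float]:
    start = max(0, start)
    end = min(len(rows[0]), end)
    if end - start <= 0:
        return None
    arrs = [np.frombuffer(r[start:end].encode(), np.uint8) for r in rows]
    same = np.ones(end - start, dtype=bool)
    for other in arrs[1:]:
        same &= arrs[0] == other
    return float(same.mean())


def flanking_conservation_profile(
    alignments: Sequence[FlankAlignment],
    window: int = 50,
    step: int = 20,
    inset: int = 30,
    center_width: int = 100,
    n_windows: Optional[int] = None,
) -> ConservationProfile:
    """Center-anchored conservation profile of elements and their flanks.

    The offset-0 value is the mean identity of the ``center_width`` bp at
    each element's center.  Lateral windows of ``window`` bp advance
    outward in ``step`` bp increments, the first window beginning ``inset``
    bp inside each element edge; windows extending past an alignment are
    truncated (logged).  Per-window mean and SEM are taken over alignments;
    offsets are reported against the mean element half-length.
    """
    if not alignments:
        raise ValueError("no alignments")
    if n_windows is None:
        max_flank = max(
            max(a.element_start, len(a.rows[0]) - a.element_end) for a in alignments
        )
        n_windows = max(1, (max_flank + inset - window) // step + 1)

    half = float(np.mean([(a.element_end - a.element_start) / 2 for a in alignments]))
    offsets: list[float] = []
    means: list[float] = []
    sems: list[float] = []

    def collect(values: list[float], offset: float) -> None:
        if not values:
            return
        arr = np.asarray(values)
        offsets.append(offset)
        means.append(float(arr.mean()))
        sems.append(float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0)

    for k in range(n_windows, 0, -1):  # left flank, outermost first
        vals = []
        for a in alignments:
            ws = a.element_start + inset - window - (k - 1) * step
            v = _window_identity(a.rows, ws, ws + window)
            if v is None:
                log.info("left window %d truncated away for one alignment", k)
            else:
                vals.append(v)
        collect(vals, -(half - inset + window / 2 + (k - 1) * step))

    vals = []
    for a in alignments:
        mid = (a.element_start + a.element_end) // 2
        v = _window_identity(a.rows, mid - center_width // 2, mid + center_width // 2)
        if v is not None:
            vals.append(v)
    collect(vals, 0.0)

    for k in range(1, n_windows + 1):  # right flank
        vals = []
        for a in alignments:
            ws = a.element_end - inset + (k - 1) * step
            v = _window_identity(a.rows, ws, ws + window)
            if v is not None:
                vals.append(v)
        collect(vals, half - inset + window / 2 + (k - 1) * step)

    return ConservationProfile(
        tuple(offsets), tuple(means), tuple(sems), len(alignments)
    )


# ---------------------------------------------------------------------------
# Tajima's D


def tajimas_d(segregating_sites: int, pi: float, n: int) -> float:
    """Tajima's D from the segregating-site count S, the mean pairwise
    diversity pi, and the number of sampled chromosomes n.

    D = (pi - S/a1) / sqrt(e1 S + e2 S (S - 1)) with the standard
    coefficients; undefined for S = 0.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if segregating_sites <= 0:
        raise ValueError("Tajima's D undefined for S = 0")
    s = segregating_sites
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def diversity_stats(haplotypes: np.ndarray) -> tuple[int, float]:
    """(S, pi) from an (n_chromosomes x n_sites) 0/1 haplotype matrix:
    segregating-site count and mean pairwise difference."""
    h = np.asarray(haplotypes)
    n = h.shape[0]
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    counts = h.sum(axis=0)
    seg = (counts > 0) & (counts < n)
    s = int(seg.sum())
    # per-site pairwise differences: i * (n - i) pairs differ
    pi = float(np.sum(counts * (n - counts)) / (n * (n - 1) / 2))
    return s, pi
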