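"""Center-anchored aggregation of per-base signal tracks around elements.

Used for nucleosome-occupancy-style analyses: average a signal (occupancy
probability, MNase-seq coverage, ...) over a fixed window centered on each
element, compare per-element scores against matched random intervals, and
test overlap enrichment/depletion against mark intervals (e.g. H3K9me
heterochromatin) with an empirical null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval

log = logging.getLogger(__name__)


class SignalTrack:
    """Per-base scores over named sequences; undefined positions are NaN."""

    def __init__(self, values: Mapping[str, np.ndarray]) -> None:
        self.values = {c: np.asarray(v, dtype=float) for c, v in values.items()}
        for chrom, arr in self.values.items():
            if np.isinf(arr).any():
                raise ValueError(f"non-finite scores on {chrom}")

    @classmethod
    def from_bedgraph(
        cls,
        entries: Mapping[str, Sequence[tuple[int, int, float]]],
        lengths: Optional[Mapping[str, int]] = None,
    ) -> "SignalTrack":
        values = {}
        for chrom, items in entries.items():
            L = lengths[chrom] if lengths else max(e for _, e, _ in items)
            arr = np.full(L, np.nan)
            for s, e, v in items:
                arr[s:e] = v
            values[chrom] = arr
        return cls(values)

    def slice(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Values over [start, end), NaN-padded outside the track extent."""
        arr = self.values[chrom]
        out = np.full(end - start, np.nan)
        s, e = max(0, start), min(arr.size, end)
        if s < e:
            out[s - start : e - start] = arr[s:e]
        return out


def interval_center(iv: GenomicInterval) -> int:
    """Center convention: start + floor(length / 2)."""
    return iv.start + iv.length // 2


@dataclass(frozen=True)
class CenterProfile:
    offsets: tuple[int, ...]  # -halfwidth .. +halfwidth
    mean: tuple[float, ...]
    sem: tuple[float, ...]
    n: tuple[int, ...]  # intervals contributing per offset


def center_profile(
    intervals: Sequence[GenomicInterval],
    track: SignalTrack,
    halfwidth: int = 4000,
) -> CenterProfile:
    """Mean track value at each offset in [-halfwidth, +halfwidth] from
    interval centers; minus-strand intervals are flipped; missing positions
    are excluded per offset; intervals whose center lies outside the track
    extent are skipped (logged)."""
    if halfwidth <= 0:
        raise ValueError("halfwidth must be > 0")
    width = 2 * halfwidth + 1
    slices = []
    for iv in intervals:
        arr = track.values.get(iv.chrom)
        c = interval_center(iv)
        if arr is None or not (0 <= c < arr.size):
            log.warning("interval %s center outside track extent; skipped", iv)
            continue
        sl = track.slice(iv.chrom, c - halfwidth, c + halfwidth + 1)
        if iv.strand == "-":
            sl = sl[::-1]
        slices.append(sl)
    if not slices:
        raise ValueError("no interval center inside the track extent")
    mat = np.vstack(slices)
    n = np.sum(~np.isnan(mat), axis=0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    return CenterProfile(
        tuple(range(-halfwidth, halfwidth + 1)),
        tuple(mean.tolist()),
        tuple(sem.tolist()),
        tuple(int(x) for x in n),
    )


def element_mean_scores(
    intervals: Sequence[GenomicInterval], track: SignalTrack
) -> np.ndarray:
    """Mean in-span track score per interval (NaN-aware)."""
    out = []
    for iv in intervals:
        sl = track.slice(iv.chrom, iv.start, iv.end)
        with np.errstate(invalid="ignore"):
            out.append(np.nanmean(sl))
    return np.asarray(out)


def profile_difference_test(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, float]:
    """Welch two-sample t-test, one-sided for scores_a LOWER than
    scores_b; operates on per-element mean scores."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 scores per group")
    res = stats.ttest_ind(a, b, equal_var=False, alternative="less")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class OverlapEnrichment:
    observed_fraction: float
    null_mean: float
    null_sd: float
    empirical_p: float  # depletion: P(null <= observed)
    n_reps: int


def overlap_enrichment(
    intervals: Sequence[GenomicInterval],
    marks: Sequence[GenomicInterval],
    random_generator,
    n_reps: int = 1000,
    seed=None,
) -> OverlapEnrichment:
    """Fraction of intervals overlapping any mark by >= 1 bp, against a
    null of matched random interval sets.

    ``random_generator`` is a callable ``rng -> interval list``.  The
    empirical depletion p-value is (1 + #{null <= observed}) / (n_reps+1),
    so it always lies in [1/(n_reps+1), 1].
    """
    if n_reps < 100:
        raise ValueError("need n_reps >= 100")
    from .intervals import IntervalIndex

    index = IntervalIndex(marks)

    def frac(ivs):
        if not ivs:
            return 0.0
        return sum(1 for iv in ivs if index.any_overlap(iv)) / len(ivs)

    observed = frac(intervals)
    rng = np.random.default_rng(seed)
    nulls = np.array([frac(random_generator(rng)) for _ in range(n_reps)])
    p = (1 + int(np.sum(nulls <= observed))) / (n_reps + 1)
    return OverlapEnrichment(
        observed, float(nulls.mean()), float(nulls.std(ddof=1)), p, n_reps
    )
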