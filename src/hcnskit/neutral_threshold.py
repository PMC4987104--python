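"""Neutral-evolution divergence threshold estimation.

The divergence level typical of unconstrained sequence is estimated as the
mode of a genome-wide divergence distribution -- pairwise noncoding
identity on one hand, synonymous-site rates (d_s) of orthologous coding
genes on the other.  Because some synonymous sites are under weak
constraint, the d_s distribution is expected to sit at or slightly below
the noncoding mode; the estimator records whether that consistency holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class DivergenceSample:
    """A sample of dimensionless divergences (or identity fractions).

    ``kind`` is ``"noncoding-identity"`` (values are identity fractions,
    converted to divergence as 1 - identity before binning) or
    ``"synonymous-ds"`` (values already on the divergence scale).
    """

    values: tuple[float, ...]
    kind: str
    source_pair: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        if self.kind not in ("noncoding-identity", "synonymous-ds"):
            raise ValueError(f"unknown sample kind {self.kind!r}")
        arr = np.asarray(self.values, dtype=float)
        if arr.size and arr.min() < 0:
            raise ValueError("divergence values must be >= 0")
        if self.kind == "noncoding-identity" and arr.size and arr.max() > 1:
            raise ValueError("identity fractions must be <= 1")

    def divergences(self) -> np.ndarray:
        arr = np.asarray(self.values, dtype=float)
        if self.kind == "noncoding-identity":
            return 1.0 - arr
        return arr


@dataclass(frozen=True)
class ThresholdRecord:
    value: float
    kind_used: str
    bin_width: float
    noncoding_mode: float
    ds_mode: float
    consistent: bool


def trim_upper_outliers(values: Sequence[float], fraction: float) -> list[float]:
    """Drop the ceil(fraction * n) largest values; among tied values the
    later-indexed ones are removed first; surviving order is preserved."""
    values = list(values)
    if not values:
        raise ValueError("empty input")
    if not (0 <= fraction < 1):
        raise ValueError("fraction must lie in [0, 1)")
    k = math.ceil(fraction * len(values))
    if k == 0:
        return values
    order = sorted(range(len(values)), key=lambda i: (values[i], i))
    drop = set(order[-k:])
    return [v for i, v in enumerate(values) if i not in drop]


def histogram_mode(values: Sequence[float], bin_width: float) -> float:
    """Midpoint of the maximal-count histogram bin, bins anchored at 0.

    Ties between maximal bins resolve to the lower midpoint.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one value")
    idx = np.floor(arr / bin_width).astype(np.int64)
    counts = np.bincount(idx)
    best = int(np.argmax(counts))  # argmax returns the first (lowest) maximum
    return (best + 0.5) * bin_width


def neutral_threshold(
    noncoding_sample: DivergenceSample,
    ds_sample: DivergenceSample,
    bin_width: float = 0.005,
    trim_fraction: float = 0.01,
) -> ThresholdRecord:
    """Neutral threshold = mode of the noncoding divergence distribution.

    Both samples are trimmed of their upper ``trim_fraction`` outliers and
    binned at ``bin_width``.  The consistency flag is set when the
    d_s-derived mode is at or below the noncoding mode (the expected weak
    skew of coding synonymous sites toward the conserved end), and cleared
    otherwise.
    """
    nc = trim_upper_outliers(list(noncoding_sample.divergences()), trim_fraction)
    ds = trim_upper_outliers(list(ds_sample.divergences()), trim_fraction)
    nc_mode = histogram_mode(nc, bin_width)
    ds_mode = histogram_mode(ds, bin_width)
    return ThresholdRecord(
        value=nc_mode,
        kind_used="noncoding-identity",
        bin_width=bin_width,
        noncoding_mode=nc_mode,
        ds_mode=ds_mode,
        consistent=ds_mode <= nc_mode,
    )
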