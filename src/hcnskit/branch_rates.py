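"""Branch-specific substitution-rate estimation from three-taxon alignments.

Each conserved element with orthologs in two successive outgroups yields a
three-taxon alignment (reference ingroup, outgroup 1, outgroup 2).  After
gap-column stripping, the three pairwise distances decompose exactly into
the three star-tree branch lengths.  Dividing each length by the time it
spans gives a per-site, per-year rate:

* alpha -- the ingroup stem branch (the clade's common ancestor after the
  first outgroup split).  The reference terminal branch length is
  attributed entirely to the stem, because substitutions after the stem
  are excluded by the perfect-conservation construction of the elements.
* beta  -- the outgroup-1 terminal branch.
* gamma -- the outgroup-2 side of the star (terminal branch plus the
  internal segment), spanning ``2 * t_og2 - t_og1`` years.

A subtraction estimator recovers the stem rate from elements mappable only
to outgroup 1, where alpha and beta cannot be separated directly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GAP = "-"


@dataclass(frozen=True, kw_only=True)
class PhyloCalibration:
    """Divergence-time calibration (years) and the neutral rate.

    Defaults: stem 3.1 Myr, outgroup-1 split 18.8 Ma; the outgroup-2 split
    age has no asserted default and must be supplied.
    """

    t_og2: float
    t_stem: float = 3.1e6
    t_og1: float = 1.88e7
    neutral_rate: float = 1.1e-9

    def __post_init__(self) -> None:
        if not (self.t_og2 > self.t_og1 > self.t_stem > 0):
            raise ValueError("need t_og2 > t_og1 > t_stem > 0")

    @property
    def gamma_duration(self) -> float:
        """Years spanned by the outgroup-2 side of the three-taxon star."""
        return 2 * self.t_og2 - self.t_og1


@dataclass(frozen=True)
class ThreeTaxonAlignment:
    """Equal-length aligned sequences for one element: reference ingroup,
    outgroup 1, outgroup 2.  Gap character is ``-``."""

    element_id: str
    ref: str
    og1: str
    og2: str

    def __post_init__(self) -> None:
        if not (len(self.ref) == len(self.og1) == len(self.og2)):
            raise ValueError(f"{self.element_id}: aligned rows must be equal length")


@dataclass(frozen=True)
class BranchLengths:
    b_ref: float
    b_og1: float
    b_og2_side: float
    clamped: bool = False


@dataclass(frozen=True)
class BranchRateEstimate:
    branch: str  # alpha | beta | gamma | alpha+beta
    length: float  # substitutions / site
    duration_years: float
    clamped: bool = False

    @property
    def rate(self) -> float:
        return self.length / self.duration_years


def strip_gap_columns(alignment: ThreeTaxonAlignment) -> ThreeTaxonAlignment:
    """Remove every column containing at least one gap, preserving order.

    An alignment with no gap-free columns is unusable and raises."""
    rows = [alignment.ref, alignment.og1, alignment.og2]
    arrs = [np.frombuffer(r.encode(), np.uint8) for r in rows]
    gap = np.uint8(ord(GAP))
    keep = (arrs[0] != gap) & (arrs[1] != gap) & (arrs[2] != gap)
    if not keep.any():
        raise ValueError(f"{alignment.element_id}: no gap-free columns remain")
    stripped = [a[keep].tobytes().decode() for a in arrs]
    return ThreeTaxonAlignment(alignment.element_id, *stripped)


def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of mismatching sites between gap-free aligned sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned (equal length)")
    if not seq_a:
        raise ValueError("empty sequences")
    if GAP in seq_a or GAP in seq_b:
        raise ValueError("gap columns must be stripped first")
    a = np.frombuffer(seq_a.encode(), np.uint8)
    b = np.frombuffer(seq_b.encode(), np.uint8)
    return float(np.mean(a != b))


def jc_distance(seq_a: str, seq_b: str) -> float:
    """Jukes-Cantor multiple-hit-corrected distance,
    d = -(3/4) ln(1 - (4/3) p); undefined for p >= 0.75."""
    p = p_distance(seq_a, seq_b)
    if p >= 0.75:
        raise ValueError(f"p-distance {p:.3f} >= 0.75: JC distance undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def three_taxon_branch_lengths(
    d_ref_og1: float, d_ref_og2: float, d_og1_og2: float
) -> BranchLengths:
    """Exact star decomposition of three pairwise distances.

    Negative solutions (possible with noisy distances) clamp to 0 with the
    ``clamped`` flag set; without clamping the decomposition inverts the
    pairwise distances exactly.
    """
    if min(d_ref_og1, d_ref_og2, d_og1_og2) < 0:
        raise ValueError("distances must be >= 0")
    b_ref = (d_ref_og1 + d_ref_og2 - d_og1_og2) / 2.0
    b_og1 = (d_ref_og1 + d_og1_og2 - d_ref_og2) / 2.0
    b_og2 = (d_ref_og2 + d_og1_og2 - d_ref_og1) / 2.0
    clamped = min(b_ref, b_og1, b_og2) < 0
    return BranchLengths(
        max(b_ref, 0.0), max(b_og1, 0.0), max(b_og2, 0.0), clamped
    )


def branch_rate(branch_length: float, duration_years: float) -> float:
    """Substitutions per site per year."""
    if duration_years <= 0:
        raise ValueError("duration must be > 0")
    return branch_length / duration_years


def subtract_branch_rate(
    r_combined: float, r_beta: float, t_alpha: float, t_beta: float
) -> tuple[float, bool]:
    """Stem rate recovered from a combined two-branch rate.

    ``r_combined`` averages the stem (alpha, duration ``t_alpha``) and the
    outgroup branch (beta, duration ``t_beta``) by time; removing beta's
    time-weighted contribution leaves the stem rate.  Negative results
    clamp to 0 and are flagged.
    """
    if min(r_combined, r_beta, t_alpha, t_beta) <= 0:
        raise ValueError("all inputs must be > 0")
    r_alpha = (r_combined * (t_alpha + t_beta) - r_beta * t_beta) / t_alpha
    if r_alpha < 0:
        return 0.0, True
    return r_alpha, False


@dataclass(frozen=True)
class RateDistributionSummary:
    count_above: int
    fraction_above: float
    bin_edges: tuple[float, ...]
    bin_counts: tuple[int, ...]
    n: int


def rate_distribution_summary(
    branch_lengths: Sequence[float],
    length_threshold: float = 0.02,
    bin_width: float = 0.005,
) -> RateDistributionSummary:
    """Count elements with branch length strictly above the threshold and
    histogram the distribution (bins anchored at 0)."""
    if length_threshold < 0:
        raise ValueError("threshold must be >= 0")
    arr = np.asarray(branch_lengths, dtype=float)
    above = int(np.sum(arr > length_threshold))
    n_bins = max(1, int(np.floor(arr.max() / bin_width)) + 1) if arr.size else 1
    counts, edges = np.histogram(arr, bins=n_bins, range=(0.0, n_bins * bin_width))
    return RateDistributionSummary(
        above,
        above / arr.size if arr.size else 0.0,
        tuple(edges.tolist()),
        tuple(int(c) for c in counts),
        int(arr.size),
    )


# ---------------------------------------------------------------------------
# Per-element estimation


def estimate_element_rates(
    alignments: Sequence[ThreeTaxonAlignment],
    calibration: PhyloCalibration,
    distance: str = "p",
    min_columns: int = 50,
) -> pd.DataFrame:
    """Per-element branch lengths and rates for a set of three-taxon
    alignments.

    Gap columns are stripped; elements retaining fewer than
    ``min_columns`` columns are dropped (and logged).  ``distance`` is
    ``"p"`` (default; divergences here are far below saturation) or
    ``"jc"``.  Returns one row per usable element with columns
    ``alpha_length``/``beta_length``/``gamma_length``, the matching
    ``*_rate`` columns, ``n_columns`` and ``clamped``.
    """
    if distance not in ("p", "jc"):
        raise ValueError("distance must be 'p' or 'jc'")
    dist = p_distance if distance == "p" else jc_distance
    rows = []
    for aln in alignments:
        stripped = strip_gap_columns(aln)
        n_cols = len(stripped.ref)
        if n_cols < min_columns:
            log.info("%s: only %d gap-free columns, dropped", aln.element_id, n_cols)
            continue
        lengths = three_taxon_branch_lengths(
            dist(stripped.ref, stripped.og1),
            dist(stripped.ref, stripped.og2),
            dist(stripped.og1, stripped.og2),
        )
        rows.append(
            {
                "element_id": aln.element_id,
                "n_columns": n_cols,
                "alpha_length": lengths.b_ref,
                "beta_length": lengths.b_og1,
                "gamma_length": lengths.b_og2_side,
                "alpha_rate": branch_rate(lengths.b_ref, calibration.t_stem),
                "beta_rate": branch_rate(lengths.b_og1, calibration.t_og1),
                "gamma_rate": branch_rate(
                    lengths.b_og2_side, calibration.gamma_duration
                ),
                "clamped": lengths.clamped,
            }
        )
    return pd.DataFrame(rows)


def read_three_taxon_fasta(path) -> list[ThreeTaxonAlignment]:
    """Read concatenated per-element alignments from multi-record aligned
    FASTA: consecutive triples of records (reference, outgroup 1,
    outgroup 2), the element id taken from the first record's name up to
    the last ``|`` or ``_`` separator."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 3 != 0:
        raise ValueError(f"{path}: record count {len(records)} is not a multiple of 3")
    out = []
    for i in range(0, len(records), 3):
        name = records[i].id
        for sep in ("|", "_"):
            if sep in name:
                name = name.rsplit(sep, 1)[0]
                break
        out.append(
            ThreeTaxonAlignment(
                name,
                str(records[i].seq).upper(),
                str(records[i + 1].seq).upper(),
                str(records[i + 2].seq).upper(),
            )
        )
    return out
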