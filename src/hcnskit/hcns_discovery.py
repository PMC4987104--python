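"""Clade-specific HCNS discovery: local homology search and filter cascade.

The cascade mirrors genome-scale practice at desk scale:

1. pairwise local homology hits between a designated reference genome and
   every other ingroup genome (word-seeded ungapped extension with
   Karlin-Altschul E-values -- a stand-in for BLASTN);
2. overlap resolution (among query-overlapping hits only the longest
   survives);
3. perfect-conservation filter: a reference region is a candidate iff every
   ingroup species supports it at >= ``min_identity`` over >=
   ``min_length`` bp (defaults 100% and 100 bp);
4. outgroup exclusion: candidates whose outgroup ortholog is conserved
   above the neutral-evolution threshold are vetoed (they are anciently,
   not clade-specifically, conserved);
5. repeat/coding mask filter (any-overlap, on the reference and on every
   ingroup ortholog);
6. chance-occurrence probability of qualifying hits under independence
   across species comparisons.

Filters mark candidates with flags rather than deleting them, so the
accepted set is independent of filter order and a full audit table can be
emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .intervals import GenomicInterval, IntervalIndex
from .io_formats import HomologyHit
from .synthetic_world import encode_sequence

# Karlin-Altschul parameters for ungapped +1/-3 nucleotide scoring
KA_K = 0.711
KA_LAMBDA = 1.374

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Local homology search


def _extend_one_way(
    qc: np.ndarray, sc: np.ndarray, match: int, mismatch: int, x_drop: int,
    block: int = 2048,
) -> tuple[int, int, int]:
    """Ungapped X-drop extension along aligned arrays, scanned in blocks.

    Returns (best_extent, best_score, explored_extent): the prefix length
    maximizing the cumulative score, that score, and how far the scan ran
    before the X-drop rule terminated it.
    """
    n = min(qc.size, sc.size)
    best_ext = 0
    best_score = 0
    carry = 0  # cumulative score entering the block
    runmax = 0
    pos = 0
    while pos < n:
        hi = min(n, pos + block)
        step = np.where(qc[pos:hi] == sc[pos:hi], match, mismatch)
        cum = carry + np.cumsum(step)
        rm = np.maximum(np.maximum.accumulate(cum), runmax)
        dropped = rm - cum > x_drop
        stop_rel = int(np.argmax(dropped)) if dropped.any() else hi - pos
        if stop_rel > 0:
            seg = cum[:stop_rel]
            i = int(np.argmax(seg))
            if seg[i] > best_score:
                best_score = int(seg[i])
                best_ext = pos + i + 1
        if dropped.any():
            return best_ext, best_score, pos + stop_rel
        carry = int(cum[-1])
        runmax = int(rm[-1])
        pos = hi
    return best_ext, best_score, n


def _word_index(seq: str, word_size: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - word_size + 1):
        index.setdefault(seq[i : i + word_size], []).append(i)
    return index


def _search_pair(
    qseq: str,
    qcodes: np.ndarray,
    scodes: np.ndarray,
    index: dict[str, list[int]],
    word_size: int,
    x_drop: int,
    match: int,
    mismatch: int,
) -> list[tuple[int, int, int, int, int]]:
    """Seeded ungapped hits of one strand orientation.

    Returns (q0, q1, s0, s1, score) in the coordinates of the (possibly
    reverse-complemented) subject string.
    """
    reached: dict[int, int] = {}  # diagonal -> query end already explored
    hits: set[tuple[int, int, int, int, int]] = set()
    for qpos in range(len(qseq) - word_size + 1):
        positions = index.get(qseq[qpos : qpos + word_size])
        if not positions:
            continue
        for spos in positions:
            diag = qpos - spos
            if qpos < reached.get(diag, 0):
                continue
            r_ext, r_score, r_explored = _extend_one_way(
                qcodes[qpos + word_size :], scodes[spos + word_size :],
                match, mismatch, x_drop,
            )
            l_ext, l_score, _ = _extend_one_way(
                qcodes[:qpos][::-1], scodes[:spos][::-1],
                match, mismatch, x_drop,
            )
            score = word_size * match + r_score + l_score
            q0, q1 = qpos - l_ext, qpos + word_size + r_ext
            s0, s1 = spos - l_ext, spos + word_size + r_ext
            reached[diag] = qpos + word_size + r_explored
            hits.add((q0, q1, s0, s1, score))
    return sorted(hits)


def find_local_homologies(
    queries,
    subjects,
    word_size: int = 11,
    evalue_max: float = 1e-5,
    *,
    db_size: float = 3e9,
    search_space: Optional[float] = None,
    x_drop: int = 20,
    match: int = 1,
    mismatch: int = -3,
    both_strands: bool = True,
) -> list[HomologyHit]:
    """Word-seeded ungapped local homology search between sequence sets.

    ``queries`` and ``subjects`` are mappings or iterables of
    ``(name, sequence)``.  E-values follow the ungapped Karlin-Altschul
    formula ``E = K * space * exp(-lambda * S)`` with K=0.711 and
    lambda=1.374 for +1/-3 scoring; the effective search space defaults to
    query length x ``db_size`` (an emulated genome-scale database), or is
    fixed via ``search_space``.
    """
    queries = list(queries.items() if isinstance(queries, Mapping) else queries)
    subjects = list(subjects.items() if isinstance(subjects, Mapping) else subjects)
    if not queries or not subjects:
        raise ValueError("empty query or subject set")
    for name, seq in queries + subjects:
        if not seq:
            raise ValueError(f"empty sequence {name!r}")

    qcodes = {name: encode_sequence(seq) for name, seq in queries}
    out: list[HomologyHit] = []
    for sname, sseq in subjects:
        strands = ("+", "-") if both_strands else ("+",)
        for strand in strands:
            s_oriented = sseq if strand == "+" else revcomp(sseq)
            scodes = encode_sequence(s_oriented)
            index = _word_index(s_oriented, word_size)
            for qname, qseq in queries:
                space = (
                    search_space if search_space is not None
                    else len(qseq) * db_size
                )
                for q0, q1, s0, s1, score in _search_pair(
                    qseq, qcodes[qname], scodes, index, word_size, x_drop,
                    match, mismatch,
                ):
                    evalue = KA_K * space * np.exp(-KA_LAMBDA * score)
                    if evalue > evalue_max:
                        continue
                    length = q1 - q0
                    matches = int(
                        np.sum(qcodes[qname][q0:q1] == scodes[s0:s1])
                    )
                    if strand == "+":
                        subject = GenomicInterval(sname, s0, s1, "+")
                    else:
                        n = len(sseq)
                        subject = GenomicInterval(sname, n - s1, n - s0, "-")
                    out.append(
                        HomologyHit(
                            GenomicInterval(qname, q0, q1, "+"),
                            subject,
                            matches / length,
                            length,
                            float(evalue),
                            float(score),
                        )
                    )
    return out


def hit_match_profile(hit: HomologyHit, qseq: str, sseq: str) -> np.ndarray:
    """Per-query-position match/mismatch profile of an ungapped hit."""
    q = qseq[hit.query.start : hit.query.end]
    if hit.subject.strand == "-":
        s = revcomp(sseq[hit.subject.start : hit.subject.end])
    else:
        s = sseq[hit.subject.start : hit.subject.end]
    if len(q) != len(s):
        raise ValueError("match profile requires an ungapped (equal-span) hit")
    return np.frombuffer(q.encode(), np.uint8) == np.frombuffer(s.encode(), np.uint8)


def subject_subinterval(hit: HomologyHit, qstart: int, qend: int) -> GenomicInterval:
    """Subject coordinates of a query subspan of an ungapped hit."""
    off0, off1 = qstart - hit.query.start, qend - hit.query.start
    if hit.subject.strand == "-":
        return GenomicInterval(
            hit.subject.chrom, hit.subject.end - off1, hit.subject.end - off0, "-"
        )
    return GenomicInterval(
        hit.subject.chrom, hit.subject.start + off0, hit.subject.start + off1, "+"
    )


# ---------------------------------------------------------------------------
# Overlap resolution


def resolve_overlaps(
    hits: Sequence[HomologyHit], slop: int = 0
) -> list[HomologyHit]:
    """Greedy longest-first non-redundancy on query coordinates: among any
    query-overlapping hits only the longest survives; ties break to higher
    identity, then to the smaller query start.

    ``slop`` bp of terminal overlap are tolerated before two hits are
    considered overlapping: consecutive ungapped segments of one homology
    chain broken at an indel routinely share a few chance-matching bases
    across the junction, and such segments are complementary pieces of one
    alignment, not redundant alternatives.
    """
    ranked = sorted(
        hits, key=lambda h: (-h.length, -h.identity, h.query.chrom, h.query.start)
    )
    kept: list[HomologyHit] = []
    index = IntervalIndex()
    for h in ranked:
        q = h.query
        if q.length > 2 * slop:
            probe = GenomicInterval(q.chrom, q.start + slop, q.end - slop,
                                    q.strand, q.label)
        else:
            probe = q
        if not index.any_overlap(probe):
            kept.append(h)
            index.add(probe)
    kept.sort(key=lambda h: (h.query.chrom, h.query.start))
    return kept


# ---------------------------------------------------------------------------
# Candidates and filters


@dataclass
class HCNSCandidate:
    """A candidate clade-specific conserved element on the reference.

    ``flags`` collects every reason for rejection ("length", "identity",
    "outgroup:<species>", "repeat", "coding"); a candidate is accepted iff
    it carries no flags.
    """

    interval: GenomicInterval
    species_support: dict[str, tuple[GenomicInterval, float]] = field(default_factory=dict)
    outgroup_identity: dict[str, Optional[float]] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)

    @property
    def accepted(self) -> bool:
        return not self.flags

    @property
    def id(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}"


def _perfect_runs(profile: np.ndarray, q_offset: int) -> list[tuple[int, int]]:
    """Maximal all-match runs of a hit profile, in query coordinates."""
    runs = []
    padded = np.concatenate([[False], profile, [False]])
    delta = np.diff(padded.astype(np.int8))
    starts = np.nonzero(delta == 1)[0]
    ends = np.nonzero(delta == -1)[0]
    for s, e in zip(starts, ends):
        runs.append((q_offset + int(s), q_offset + int(e)))
    return runs


def _intersect_coverage(a: list[tuple[int, int]], b: list[tuple[int, int]]):
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def conservation_filter(
    hits_by_species: Mapping[str, Sequence[HomologyHit]],
    min_length: int = 100,
    min_identity: float = 1.0,
    reference_sequence: Optional[str] = None,
    species_sequences: Optional[Mapping[str, str]] = None,
) -> list[HCNSCandidate]:
    """Find reference regions conserved in every ingroup species.

    A region becomes an accepted candidate iff each species covers it with
    homology at identity >= ``min_identity`` over length >= ``min_length``.
    When ``min_identity`` is 1.0 and the sequences are supplied, each hit is
    refined into its maximal exact-match runs first: local alignments
    maximize score, so a perfect element embedded in nearly identical
    flanking sequence would otherwise be absorbed into a longer imperfect
    hit and never qualify.  Sub-threshold regions are returned flagged
    ("length" or "identity") for the audit table.
    """
    if not (0 < min_identity <= 1.0) or min_length < 1:
        raise ValueError("min_identity in (0,1] and min_length >= 1 required")
    refine = (
        min_identity >= 1.0
        and reference_sequence is not None
        and species_sequences is not None
    )
    qualifying: dict[str, list[tuple[tuple[int, int], HomologyHit]]] = {}
    any_cov: dict[str, list[tuple[int, int]]] = {}
    ref_chrom = None
    for sp, hits in hits_by_species.items():
        spans: list[tuple[tuple[int, int], HomologyHit]] = []
        cover: list[tuple[int, int]] = []
        for h in hits:
            ref_chrom = ref_chrom or h.query.chrom
            cover.append((h.query.start, h.query.end))
            if refine:
                profile = hit_match_profile(
                    h, reference_sequence, species_sequences[sp]
                )
                for s, e in _perfect_runs(profile, h.query.start):
                    if e - s >= min_length:
                        spans.append(((s, e), h))
            elif h.identity >= min_identity:
                spans.append(((h.query.start, h.query.end), h))
        spans.sort(key=lambda t: t[0])
        qualifying[sp] = spans
        cover.sort()
        merged = []
        for s, e in cover:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        any_cov[sp] = merged

    if not qualifying:
        return []
    species = list(qualifying)

    def merged_spans(spans):
        merged = []
        for (s, e), _ in sorted(spans, key=lambda t: t[0]):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    good = merged_spans(qualifying[species[0]])
    cov = any_cov[species[0]]
    for sp in species[1:]:
        good = _intersect_coverage(good, merged_spans(qualifying[sp]))
        cov = _intersect_coverage(cov, any_cov[sp])

    candidates: list[HCNSCandidate] = []

    def support_for(span: tuple[int, int]) -> dict[str, tuple[GenomicInterval, float]]:
        support = {}
        for sp in species:
            best = None
            for (s, e), h in qualifying[sp]:
                if s <= span[0] and span[1] <= e:
                    best = (subject_subinterval(h, *span), 1.0 if refine else h.identity)
                    break
            if best is None:  # fall back to any covering hit
                for h in hits_by_species[sp]:
                    if h.query.start <= span[0] and span[1] <= h.query.end:
                        best = (subject_subinterval(h, *span), h.identity)
                        break
            if best is not None:
                support[sp] = best
        return support

    accepted_cov = []
    for s, e in good:
        cand = HCNSCandidate(GenomicInterval(ref_chrom, s, e, "+"))
        cand.species_support = support_for((s, e))
        if e - s < min_length:
            cand.flags.add("length")
        else:
            accepted_cov.append((s, e))
        candidates.append(cand)

    # regions homologous everywhere but sub-threshold in >= 1 species
    residual = cov
    for s, e in accepted_cov:
        residual = [
            r for r in (
                (rs, min(re_, s)) if rs < s else (max(rs, e), re_)
                for rs, re_ in residual
                if not (s <= rs and re_ <= e)
            )
            if r[0] < r[1]
        ]
    for s, e in residual:
        if e - s >= min_length:
            cand = HCNSCandidate(GenomicInterval(ref_chrom, s, e, "+"))
            cand.flags.add("identity")
            candidates.append(cand)
    candidates.sort(key=lambda c: c.interval.start)
    return candidates


def outgroup_exclusion(
    candidates: Sequence[HCNSCandidate],
    outgroup_hits: Mapping[str, Sequence[HomologyHit]],
    neutral_divergence_threshold: float,
) -> list[HCNSCandidate]:
    """Veto candidates whose outgroup homolog is conserved above the
    neutral threshold.

    A candidate is flagged ``outgroup:<species>`` iff its outgroup
    conservation is strictly above the neutral threshold, i.e. divergence
    (1 - identity) below it; boundary equality retains the candidate, and
    a candidate with no outgroup hit at all is retained.  Hits address a
    candidate either by query-interval overlap on the reference or by
    carrying the candidate id as their query name (element-targeted
    search).  Conservation is evaluated element-wise: a hit's matches are
    spread over the full candidate length, so candidate positions the hit
    does not align count as divergent -- a short near-perfect fragment
    inside an otherwise diverged ortholog is not a conserved homolog.
    """
    for cand in candidates:
        clen = cand.interval.length
        for sp, hits in outgroup_hits.items():
            best: Optional[float] = None
            for h in hits:
                if h.query.chrom == cand.id:
                    overlap = min(h.length, clen)
                elif h.query.overlaps(cand.interval):
                    inter = h.query.intersection(cand.interval)
                    overlap = inter.length if inter else 0
                else:
                    continue
                effective = min(1.0, h.identity * overlap / clen)
                if best is None or effective > best:
                    best = effective
            cand.outgroup_identity[sp] = best
            if best is not None and (1.0 - best) < neutral_divergence_threshold:
                cand.flags.add(f"outgroup:{sp}")
    return list(candidates)


def repeat_coding_filter(
    candidates: Sequence[HCNSCandidate],
    repeat_intervals: Iterable[GenomicInterval] = (),
    coding_intervals: Iterable[GenomicInterval] = (),
) -> list[HCNSCandidate]:
    """Flag candidates overlapping repeat or coding masks by >= 1 bp, on
    the reference interval or on any ingroup ortholog interval.  Mask
    intervals carry the species as their sequence name; bookended
    (adjacent) intervals do not overlap."""
    repeats = IntervalIndex(repeat_intervals)
    coding = IntervalIndex(coding_intervals)
    for cand in candidates:
        spans = [cand.interval] + [iv for iv, _ in cand.species_support.values()]
        for span in spans:
            if repeats.any_overlap(span):
                cand.flags.add("repeat")
            if coding.any_overlap(span):
                cand.flags.add("coding")
    return list(candidates)


@dataclass(frozen=True)
class ChanceEstimate:
    per_comparison_frequency: float
    joint_probability: float
    expected_count: float
    qualifying_hits: int
    total_hits: int


def chance_probability(
    hits: Sequence[HomologyHit],
    min_length: int = 100,
    min_identity: float = 1.0,
    n_comparisons: int = 3,
) -> ChanceEstimate:
    """Chance frequency of hits satisfying the conservation thresholds.

    ``f`` = qualifying / total within the hit population; the joint
    probability assumes independence across the ``n_comparisons`` species
    comparisons; the expected count scales the joint probability back to
    the population size.
    """
    if not hits:
        raise ValueError("empty hit population")
    qualifying = sum(
        1 for h in hits if h.length >= min_length and h.identity >= min_identity
    )
    f = qualifying / len(hits)
    joint = f ** n_comparisons
    return ChanceEstimate(f, joint, joint * len(hits), qualifying, len(hits))
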