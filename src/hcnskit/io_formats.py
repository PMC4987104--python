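"""Readers and writers for every on-disk format the pipeline touches.

All readers convert to the internal convention (0-based, half-open, strand
explicit, identities as fractions); writers convert back.  Formats handled:

* FASTA (via Bio.SeqIO; 60-column wrap; lowercase = soft mask)
* BED6 and a 7-column paired-BED ortholog coordinate map
* 12-column tabular homology hits (BLAST ``outfmt 6`` dialect)
* minimal VCF v4.2 (CHROM/POS/ID/REF/ALT/QUAL/FILTER/INFO with ``AF=``)
* bedGraph per-base signal
* GTF-lite gene annotation (1-based inclusive, ``gene_id``/``transcript_id``)
* flat ``key=value`` configuration files
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval

log = logging.getLogger(__name__)

IUPAC = set("ACGTURYSWKMBDHVN")


@dataclass(frozen=True)
class HomologyHit:
    """A pairwise local-homology hit (one aligned query/subject span)."""

    query: GenomicInterval
    subject: GenomicInterval
    identity: float  # fraction in [0, 1]
    length: int  # alignment length, bp
    evalue: float
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("alignment length must be >= 1")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity {self.identity} outside [0, 1]")
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")


@dataclass(frozen=True)
class VariantRecord:
    """A polymorphism: position is 0-based; ``frequency`` is the alternate
    allele frequency (``None`` when the source file lacked ``AF=``).
    Records with frequency 1.0 (fixed differences) are rejected."""

    chrom: str
    pos: int
    ref: str
    alt: str
    frequency: Optional[float]
    vclass: str  # "SNP" | "insertion" | "deletion"

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if self.frequency is not None and not (0.0 <= self.frequency < 1.0):
            raise ValueError(
                f"allele frequency {self.frequency} outside [0, 1); fixed "
                "differences (frequency 1.0) are excluded"
            )
        if self.vclass not in ("SNP", "insertion", "deletion"):
            raise ValueError(f"unknown variant class {self.vclass!r}")


def classify_alleles(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNP"
    return "insertion" if len(alt) > len(ref) else "deletion"


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> tuple[list[tuple[str, str]], dict[str, list[GenomicInterval]]]:
    """Read FASTA; return ordered ``(name, SEQUENCE)`` records plus, per
    record, the soft-mask intervals (runs of lowercase in the input).

    Sequences are upper-cased.  Duplicate names or non-IUPAC characters
    raise ``ValueError`` naming the offending record.
    """
    records: list[tuple[str, str]] = []
    masks: dict[str, list[GenomicInterval]] = {}
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in seen:
            raise ValueError(f"duplicate FASTA record name {name!r} in {path}")
        seen.add(name)
        raw = str(rec.seq)
        upper = raw.upper()
        bad = set(upper) - IUPAC
        if bad:
            raise ValueError(
                f"non-IUPAC characters {sorted(bad)} in record {name!r} of {path}"
            )
        mask: list[GenomicInterval] = []
        run_start = None
        for i, c in enumerate(raw):
            if c.islower():
                if run_start is None:
                    run_start = i
            elif run_start is not None:
                mask.append(GenomicInterval(name, run_start, i))
                run_start = None
        if run_start is not None:
            mask.append(GenomicInterval(name, run_start, len(raw)))
        records.append((name, upper))
        masks[name] = mask
    return records, masks


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    """Write records as 60-column-wrapped FASTA."""
    seqrecs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# BED


def read_bed(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            strand = parts[5] if len(parts) > 5 else "."
            out.append(GenomicInterval(chrom, start, end, strand, name))
    return out


def write_bed(path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t0\t{iv.strand}\n"
            )


def read_pair_bed(path) -> list[tuple[GenomicInterval, GenomicInterval, str]]:
    """Paired-BED ortholog coordinate map: source interval, target interval,
    strand (optional 7th column, default ``+``)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: paired-BED needs >= 6 columns")
            src = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            dst = GenomicInterval(parts[3], int(parts[4]), int(parts[5]))
            strand = parts[6] if len(parts) > 6 else "+"
            out.append((src, dst, strand))
    return out


def write_pair_bed(path, pairs) -> None:
    with open(path, "w") as fh:
        for src, dst, strand in pairs:
            fh.write(
                f"{src.chrom}\t{src.start}\t{src.end}\t"
                f"{dst.chrom}\t{dst.start}\t{dst.end}\t{strand}\n"
            )


# ---------------------------------------------------------------------------
# Tabular homology hits (outfmt-6 dialect)
#
# Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
# send evalue bitscore.  Coordinates are 1-based inclusive; a subject start
# greater than the subject end encodes a minus-strand hit.


def read_hits_tab(path) -> list[HomologyHit]:
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(parts)}"
                )
            qid, sid = parts[0], parts[1]
            pident = float(parts[2])
            length = int(parts[3])
            qstart, qend = int(parts[6]), int(parts[7])
            sstart, send = int(parts[8]), int(parts[9])
            evalue = float(parts[10])
            bitscore = float(parts[11])
            query = GenomicInterval(qid, qstart - 1, qend, "+")
            if sstart <= send:
                subject = GenomicInterval(sid, sstart - 1, send, "+")
            else:
                subject = GenomicInterval(sid, send - 1, sstart, "-")
            hits.append(
                HomologyHit(query, subject, pident / 100.0, length, evalue, bitscore)
            )
    return hits


def write_hits_tab(path, hits: Iterable[HomologyHit]) -> None:
    with open(path, "w") as fh:
        for h in hits:
            if h.subject.strand == "-":
                sstart, send = h.subject.end, h.subject.start + 1
            else:
                sstart, send = h.subject.start + 1, h.subject.end
            mismatch = round(h.length * (1 - h.identity))
            fh.write(
                "\t".join(
                    [
                        h.query.chrom,
                        h.subject.chrom,
                        f"{h.identity * 100:.2f}",
                        str(h.length),
                        str(mismatch),
                        "0",
                        str(h.query.start + 1),
                        str(h.query.end),
                        str(sstart),
                        str(send),
                        f"{h.evalue:.3g}",
                        f"{h.score if h.score is not None else 0:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Minimal VCF


def read_vcf_minimal(path) -> list[VariantRecord]:
    """Read a minimal VCF v4.2: CHROM POS ID REF ALT QUAL FILTER INFO.

    Positions convert 1-based -> 0-based.  ``AF=`` is taken from INFO;
    records without it are kept with frequency ``None`` (unknown).
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ValueError(f"{path}:{lineno}: VCF data line needs 8 columns")
            chrom, pos, _, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            info = parts[7]
            freq: Optional[float] = None
            for item in info.split(";"):
                if item.startswith("AF="):
                    freq = float(item[3:])
                    break
            else:
                log.warning("%s:%d: missing AF, frequency marked unknown", path, lineno)
            out.append(
                VariantRecord(chrom, pos - 1, ref, alt, freq, classify_alleles(ref, alt))
            )
    return out


def write_vcf_minimal(path, variants: Iterable[VariantRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            info = f"AF={v.frequency:.6g}" if v.frequency is not None else "."
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path) -> dict[str, list[tuple[int, int, float]]]:
    """Read bedGraph into per-sequence sorted ``(start, end, value)`` lists.

    Intervals are 0-based half-open; overlapping intervals on one sequence
    are an error (a per-base track must be single-valued).
    """
    raw: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: bedGraph needs 4 columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if not math.isfinite(value):
                raise ValueError(f"{path}:{lineno}: non-finite value")
            raw.setdefault(chrom, []).append((start, end, value))
    for chrom, entries in raw.items():
        entries.sort()
        for (s1, e1, _), (s2, _, _) in zip(entries, entries[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{path}: overlapping bedGraph intervals on {chrom} at {s2}"
                )
    return raw


def write_bedgraph(path, tracks: dict[str, list[tuple[int, int, float]]]) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(tracks):
            for start, end, value in sorted(tracks[chrom]):
                fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


# ---------------------------------------------------------------------------
# GTF-lite


@dataclass(frozen=True)
class GtfFeature:
    """One GTF-lite feature, converted to 0-based half-open coordinates."""

    chrom: str
    feature: str  # gene | transcript | exon | UTR | CDS
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_id: Optional[str] = None

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand,
                               self.transcript_id or self.gene_id)


def _parse_gtf_attrs(text: str) -> dict[str, str]:
    attrs = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf_lite(path) -> list[GtfFeature]:
    """Read GTF-lite (1-based inclusive) into 0-based half-open features."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: GTF needs 9 columns")
            chrom, _, feature, start, end, _, strand, _, attr_text = parts
            attrs = _parse_gtf_attrs(attr_text)
            if "gene_id" not in attrs:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            out.append(
                GtfFeature(
                    chrom,
                    feature,
                    int(start) - 1,
                    int(end),
                    strand,
                    attrs["gene_id"],
                    attrs.get("transcript_id"),
                )
            )
    return out


def write_gtf_lite(path, features: Iterable[GtfFeature]) -> None:
    with open(path, "w") as fh:
        for f in features:
            attrs = f'gene_id "{f.gene_id}";'
            if f.transcript_id:
                attrs += f' transcript_id "{f.transcript_id}";'
            fh.write(
                f"{f.chrom}\thcnskit\t{f.feature}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Flat key=value configuration


def read_config(path) -> dict[str, str]:
    cfg = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, _, value = line.partition("=")
            cfg[key.strip()] = value.strip()
    return cfg


def write_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        for key in cfg:
            fh.write(f"{key}={cfg[key]}\n")


def resolve(path) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    return p
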