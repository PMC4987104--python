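"""Clade-specific (orphan) gene identification over ortholog-presence and
homology-evidence tables.

Three stages: (1) intersect ingroup ortholog tables to get the clade-shared
gene set; (2) subtract genes with an ortholog in any outgroup table;
(3) reject remaining candidates with strong residual homology outside the
clade -- any hit with coverage strictly above ``min_coverage`` AND identity
strictly above ``min_identity`` (defaults 0.70 and 0.50; both thresholds
strict).  The pipeline is monotone: adding tables or evidence can only
shrink the final set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class HomologyEvidence:
    gene_id: str
    hit_species: str
    coverage: float  # query coverage fraction
    identity: float

    def __post_init__(self) -> None:
        if not (0 <= self.coverage <= 1 and 0 <= self.identity <= 1):
            raise ValueError("coverage and identity must lie in [0, 1]")


def clade_shared(
    focal_genes: Iterable[str], ingroup_tables: Sequence[Iterable[str]]
) -> set[str]:
    """Genes of the focal species present in EVERY ingroup ortholog table
    (one table per non-focal ingroup species)."""
    shared = set(focal_genes)
    for table in ingroup_tables:
        shared &= set(table)
    return shared


def outgroup_subtract(
    shared: Iterable[str], outgroup_tables: Sequence[Iterable[str]]
) -> set[str]:
    """Remove genes present in ANY outgroup table."""
    if not outgroup_tables:
        raise ValueError("need at least one outgroup table")
    out = set(shared)
    for table in outgroup_tables:
        out -= set(table)
    return out


def homology_reject(
    candidates: Iterable[str],
    evidence: Sequence[HomologyEvidence],
    clade_species: Iterable[str],
    min_coverage: float = 0.70,
    min_identity: float = 0.50,
) -> tuple[set[str], pd.DataFrame]:
    """Discard candidates with non-clade homology above BOTH thresholds
    (strict inequalities: coverage exactly at the threshold keeps the
    gene).  Returns the surviving set and an audit table listing every
    triggering piece of evidence."""
    clade = set(clade_species)
    candidates = set(candidates)
    kept = set(candidates)
    audit_rows = []
    for ev in evidence:
        if ev.gene_id not in candidates or ev.hit_species in clade:
            continue
        if ev.coverage > min_coverage and ev.identity > min_identity:
            kept.discard(ev.gene_id)
            audit_rows.append(
                {
                    "gene_id": ev.gene_id,
                    "hit_species": ev.hit_species,
                    "coverage": ev.coverage,
                    "identity": ev.identity,
                }
            )
    audit = pd.DataFrame(
        audit_rows, columns=["gene_id", "hit_species", "coverage", "identity"]
    )
    return kept, audit


def read_presence_table(path) -> dict[str, set[str]]:
    """Wide TSV: first column gene ids, remaining columns species with 0/1
    presence.  Returns species -> set of present genes."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    gene_col = df.columns[0]
    out: dict[str, set[str]] = {}
    for sp in df.columns[1:]:
        out[sp] = set(df.loc[df[sp].astype(int) == 1, gene_col])
    return out


def read_evidence_table(path) -> list[HomologyEvidence]:
    """TSV with columns gene_id, hit_species, coverage, identity."""
    df = pd.read_csv(path, sep="\t")
    return [
        HomologyEvidence(r.gene_id, r.hit_species, float(r.coverage), float(r.identity))
        for r in df.itertuples()
    ]
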