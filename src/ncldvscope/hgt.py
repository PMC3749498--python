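"""Reciprocal-best-hit screen for virus-to-cell horizontal gene transfer.

A viral peptide and a cellular protein form an HGT candidate when (1) the
cellular protein is the viral peptide's best cellular homolog (E <= 1e-5)
and (2) the cellular protein's best hit in the combined cellular+viral
database - after masking every subject sharing the query's first three
lineage labels - is a viral peptide.  The taxonomic mask removes the
query's own relatives so that a transferred gene can surface its viral
donor instead of the vertical neighbours.

Candidates are a screen, not a verdict: confirming a transfer requires
phylogenetic analysis, which is outside this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import Lineage, ReferenceDB
from .search import Hsp, SearchParams, search_protein


@dataclass(frozen=True)
class HgtCandidate:
    viral_peptide_id: str
    cellular_protein_id: str
    e1: float  # viral -> best cellular homolog
    e2: float  # reciprocal search best E
    cellular_lineage: Lineage
    excluded_group: tuple[str, ...]  # the masked lineage prefix


def best_cellular_hit(
    viral_peptide_id: str,
    viral_peptide_seq: str,
    cellular_db: ReferenceDB,
    max_evalue: float = 1e-5,
    params: Optional[SearchParams] = None,
) -> Optional[Hsp]:
    """Best cellular homolog of a viral peptide, or None below threshold.

    Best is by ascending E-value, then descending bit score (ties broken
    lexically by subject id inside the search itself).
    """
    base = params or SearchParams()
    sp = SearchParams(
        max_evalue=max_evalue,
        matrix=base.matrix,
        gap_open=base.gap_open,
        gap_extend=base.gap_extend,
        db_size_letters=base.db_size_letters,
    )
    hits = search_protein(viral_peptide_seq, cellular_db, sp, query_id=viral_peptide_id)
    return hits[0] if hits else None


def reciprocal_check(
    cellular_protein_id: str,
    combined_db: ReferenceDB,
    exclusion_levels: int = 3,
    max_evalue: float = 1e-5,
    params: Optional[SearchParams] = None,
) -> tuple[bool, Optional[Hsp]]:
    """Does the cellular protein's best *surviving* hit point at a virus?

    The cellular protein is searched against the combined (cellular +
    viral) database; hits sharing the query's first ``exclusion_levels``
    lineage labels are discarded (a query shallower than that masks on its
    full depth), as is the query itself.  Returns (passed, best surviving
    hit): the check passes when the best surviving hit is a viral protein,
    with ties between equal-E viral and cellular hits resolved by bit
    score and rejected on a residual tie (conservative).
    """
    query = combined_db[cellular_protein_id]
    mask = query.lineage.ranks[:exclusion_levels]
    base = params or SearchParams()
    sp = SearchParams(
        max_evalue=max_evalue,
        matrix=base.matrix,
        gap_open=base.gap_open,
        gap_extend=base.gap_extend,
        db_size_letters=base.db_size_letters,
    )
    hits = search_protein(query.seq, combined_db, sp, query_id=cellular_protein_id)
    surviving = [
        h
        for h in hits
        if h.subject_id != cellular_protein_id
        and combined_db[h.subject_id].lineage.ranks[: len(mask)] != mask
    ]
    if not surviving:
        return False, None
    best_key = min((h.e_value, -h.bit_score) for h in surviving)
    top = [h for h in surviving if (h.e_value, -h.bit_score) == best_key]
    viral_top = [h for h in top if combined_db[h.subject_id].source_group == "viral"]
    cellular_top = [h for h in top if combined_db[h.subject_id].source_group != "viral"]
    if viral_top and not cellular_top:
        return True, viral_top[0]
    # residual tie between a viral and a cellular best hit: reject
    return False, top[0]


def screen_hgt(
    viral_proteome: ReferenceDB,
    cellular_db: ReferenceDB,
    max_evalue: float = 1e-5,
    exclusion_levels: int = 3,
    params: Optional[SearchParams] = None,
) -> list[HgtCandidate]:
    """Run the full reciprocal screen over every viral peptide.

    The combined database is the union of the cellular set and the viral
    proteome; candidates are deduplicated by (viral, cellular) pair and
    returned in deterministic (sorted) order.
    """
    combined = ReferenceDB(list(cellular_db) + list(viral_proteome))
    seen: dict[tuple[str, str], HgtCandidate] = {}
    for viral in viral_proteome:
        h1 = best_cellular_hit(
            viral.protein_id, viral.seq, cellular_db, max_evalue, params
        )
        if h1 is None:
            continue
        cellular_id = h1.subject_id
        passed, h2 = reciprocal_check(
            cellular_id, combined, exclusion_levels, max_evalue, params
        )
        if not passed or h2 is None:
            continue
        if combined[h2.subject_id].source_group != "viral":
            continue
        key = (viral.protein_id, cellular_id)
        if key not in seen:
            seen[key] = HgtCandidate(
                viral_peptide_id=viral.protein_id,
                cellular_protein_id=cellular_id,
                e1=h1.e_value,
                e2=h2.e_value,
                cellular_lineage=cellular_db[cellular_id].lineage,
                excluded_group=cellular_db[cellular_id].lineage.ranks[:exclusion_levels],
            )
    return [seen[k] for k in sorted(seen)]
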