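"""Dual-BLAST last-common-ancestor (2bLCA) taxonomic annotation.

Each read is annotated by (1) a translated search (B1) against the
reference proteins; (2) re-querying the *subject fragment* of the best B1
HSP against the same database (B2) with an adaptive per-protein cutoff:
every B2 hit at least as significant as the B1 best E-value is recorded as
a close homolog of the read (the set H); (3) the LCA of the lineages of H
becomes the read's annotation.  Reads whose H spans more than one domain
of life are flagged ambiguous; reads not longer than 100 bp are not
annotated; reads with no B1 hit at E <= 1e-5 are 'no hits'.

The same protocol applies to predicted protein queries (marker-gene
homologs), with a protein-protein B1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import DOMAINS, NCLDV_FAMILIES, Lineage, NucRead, ReferenceDB, lca
from .qc import six_frame_orfs
from .search import (
    Hsp,
    SearchParams,
    protein_scores,
    search_protein,
    search_translated,
    traceback_hsp,
)

log = logging.getLogger(__name__)

STATUS_ASSIGNED = "assigned"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_NO_HIT = "no_hit"
STATUS_TOO_SHORT = "too_short"


@dataclass(frozen=True)
class TaxonAssignment:
    """The 2bLCA outcome for one query."""

    read_id: str
    status: str
    lineage: Optional[Lineage] = None
    b1_best_evalue: Optional[float] = None
    support_ids: frozenset[str] = frozenset()

    @property
    def support_size(self) -> int:
        return len(self.support_ids)

    def __post_init__(self) -> None:
        if self.status == STATUS_ASSIGNED and (
            self.lineage is None or not self.support_ids
        ):
            raise ValueError("assigned status requires a lineage and support")
        if self.status == STATUS_NO_HIT and self.support_ids:
            raise ValueError("no_hit status cannot carry support")


def _finish_from_b1(
    query_id: str,
    best_subject: str,
    fragment: str,
    e_star: float,
    db: ReferenceDB,
    params: SearchParams,
) -> TaxonAssignment:
    """Steps (3)-(5) shared by read and protein queries: re-query the best
    B1 subject fragment (B2), collect the homolog set H at the adaptive
    cutoff E <= E*, and reduce H's lineages to their LCA."""
    ids, _, evalues = protein_scores(fragment, db, params)
    support = {sid for sid, e in zip(ids, evalues) if e <= e_star}
    # The fragment's self-hit aligns at least as well as the B1 alignment,
    # so the B1 best subject is always in H.
    support.add(best_subject)
    lineages = [db.lineage_of(pid) for pid in support]
    domains = {l.domain for l in lineages}
    consensus = lca(lineages)
    status = STATUS_AMBIGUOUS if len(domains & set(DOMAINS)) > 1 else STATUS_ASSIGNED
    return TaxonAssignment(
        read_id=query_id,
        status=status,
        lineage=consensus,
        b1_best_evalue=e_star,
        support_ids=frozenset(support),
    )


def assign_2blca(
    read: NucRead,
    db: ReferenceDB,
    b1_max_evalue: float = 1e-5,
    min_read_len: int = 100,
    min_len_aa: int = 20,
    params: Optional[SearchParams] = None,
) -> TaxonAssignment:
    """Annotate a nucleotide read (translated B1).

    Only reads strictly longer than ``min_read_len`` are annotated.
    """
    if len(read) <= min_read_len:
        return TaxonAssignment(read.read_id, STATUS_TOO_SHORT)
    base = params or SearchParams()
    b1_params = SearchParams(
        max_evalue=b1_max_evalue,
        matrix=base.matrix,
        gap_open=base.gap_open,
        gap_extend=base.gap_extend,
        db_size_letters=base.db_size_letters,
    )
    best_e = float("inf")
    best_subject = None
    best_pep = None
    for pep in six_frame_orfs(read, min_len_aa=min_len_aa):
        ids, _, evalues = protein_scores(pep.seq, db, b1_params)
        if len(ids) == 0:
            continue
        k = int(np.argmin(evalues))  # first minimum = lexically smallest id
        if evalues[k] < best_e:
            best_e = float(evalues[k])
            best_subject = ids[k]
            best_pep = pep
    if best_subject is None or best_e > b1_max_evalue:
        return TaxonAssignment(read.read_id, STATUS_NO_HIT)
    hsp = traceback_hsp(best_pep.seq, best_subject, db, b1_params, read.read_id)
    return _finish_from_b1(
        read.read_id, best_subject, hsp.subject_aligned_subseq, best_e, db, b1_params
    )


def assign_2blca_protein(
    query_seq: str,
    db: ReferenceDB,
    query_id: str = "query",
    b1_max_evalue: float = 1e-5,
    params: Optional[SearchParams] = None,
) -> TaxonAssignment:
    """Annotate a predicted protein (protein-protein B1), as done for
    marker-gene homologs."""
    base = params or SearchParams()
    b1_params = SearchParams(
        max_evalue=b1_max_evalue,
        matrix=base.matrix,
        gap_open=base.gap_open,
        gap_extend=base.gap_extend,
        db_size_letters=base.db_size_letters,
    )
    ids, _, evalues = protein_scores(query_seq, db, b1_params)
    if len(ids) == 0:
        return TaxonAssignment(query_id, STATUS_NO_HIT)
    k = int(np.argmin(evalues))
    if evalues[k] > b1_max_evalue:
        return TaxonAssignment(query_id, STATUS_NO_HIT)
    hsp = traceback_hsp(query_seq, ids[k], db, b1_params, query_id)
    return _finish_from_b1(
        query_id, ids[k], hsp.subject_aligned_subseq, float(evalues[k]), db, b1_params
    )


BIN_NCLDV = "NCLDV"
BIN_AMBIGUOUS = "ambiguous"
BIN_NO_HIT = "no_hit"
BIN_OTHER_VIRUS = "other_virus"
CELLULAR_BINS = ("Bacteria", "Archaea", "Eukaryota")


def classify_bin(
    assignment: TaxonAssignment,
    ncldv_families: tuple[str, ...] = NCLDV_FAMILIES,
) -> str:
    """Place a 2bLCA assignment into the NCLDV / Bacteria / Archaea /
    Eukaryota bins.

    A lineage counts as NCLDV when its domain is ``Viruses`` and any label
    of the configured family list appears in the path.  Viruses outside
    those families fall into no bin (returned as ``other_virus`` and
    logged); ambiguous and no-hit statuses pass through unchanged.
    """
    if assignment.status == STATUS_AMBIGUOUS:
        return BIN_AMBIGUOUS
    if assignment.status in (STATUS_NO_HIT, STATUS_TOO_SHORT):
        return BIN_NO_HIT
    lineage = assignment.lineage
    if lineage is None or lineage.depth == 0:
        return BIN_AMBIGUOUS
    domain = lineage.domain
    if domain == "Viruses":
        if any(label in ncldv_families for label in lineage.ranks):
            return BIN_NCLDV
        log.debug("non-NCLDV virus excluded from bins: %s", lineage)
        return BIN_OTHER_VIRUS
    if domain in CELLULAR_BINS:
        return domain
    return BIN_AMBIGUOUS
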