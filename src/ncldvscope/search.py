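"""Protein homology search: the local-alignment contract used by the 2bLCA
annotator, the marker scan and the HGT screen.

The built-in engine computes Smith-Waterman local alignments (BLOSUM62,
affine gaps) against every subject and converts raw scores to bit scores
and E-values with the ungapped Karlin-Altschul parameters for the chosen
matrix: E = K*m*n*exp(-lambda*S) with m the query length and n the database
length in letters.  Absolute parity with any particular external engine is
not attempted - E-values gate fixed thresholds and define the adaptive
2bLCA cutoff, so internal consistency is what matters; a tabular adapter
(:func:`load_tabular_hits`) exists for users who need engine parity at
scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from ._align import sw_score_batch, sw_traceback
from .model import NucRead, ReferenceDB
from .qc import Peptide, six_frame_orfs

# Ungapped Karlin-Altschul parameters per scoring matrix.
_KA_PARAMS = {"BLOSUM62": (0.3176, 0.134)}

_MATRICES: dict[str, np.ndarray] = {}
_ALPHABETS: dict[str, str] = {}


def _matrix(name: str) -> tuple[np.ndarray, str]:
    if name not in _MATRICES:
        sm = substitution_matrices.load(name)
        alphabet = str(sm.alphabet)
        _MATRICES[name] = np.asarray(sm, dtype=np.float64)
        _ALPHABETS[name] = alphabet
    return _MATRICES[name], _ALPHABETS[name]


def encode_protein(seq: str, alphabet: str) -> np.ndarray:
    idx = np.full(128, -1, dtype=np.int64)
    for i, ch in enumerate(alphabet):
        idx[ord(ch)] = i
    arr = idx[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = sorted({seq[i] for i in np.nonzero(arr < 0)[0]})
        raise ValueError(f"illegal residue(s) {bad} for matrix alphabet")
    return arr


@dataclass(frozen=True)
class SearchParams:
    """Search thresholds and scoring model."""

    max_evalue: float = 1e-5
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    db_size_letters: Optional[int] = None  # default: actual db letters

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be > 0")
        if self.matrix not in _KA_PARAMS:
            raise ValueError(f"no Karlin-Altschul parameters for {self.matrix}")


def _encoded_db(db: ReferenceDB, matrix: str):
    """Integer-encode all db subjects once per (db, matrix); cached on the db."""
    key = f"_enc_{matrix}"
    cached = getattr(db, key, None)
    if cached is None:
        _, alphabet = _matrix(matrix)
        subs = [encode_protein(db[i].seq, alphabet) for i in db.ids]
        lengths = np.array([len(s) for s in subs], dtype=np.int64)
        starts = (
            np.concatenate(([0], np.cumsum(lengths)[:-1])).astype(np.int64)
            if subs
            else np.empty(0, dtype=np.int64)
        )
        flat = np.concatenate(subs) if subs else np.empty(0, dtype=np.int64)
        cached = (subs, flat, starts, lengths)
        setattr(db, key, cached)
    return cached


def protein_scores(
    query: str, db: ReferenceDB, params: Optional[SearchParams] = None
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Raw Smith-Waterman scores and E-values of a query against every db
    subject, without tracebacks (the fast path behind the 2bLCA steps).

    Returns (subject ids in lexical order, raw scores, E-values).
    """
    params = params or SearchParams()
    if not query:
        raise ValueError("empty query")
    submat, alphabet = _matrix(params.matrix)
    q = encode_protein(query, alphabet)
    subs, flat, starts, lengths = _encoded_db(db, params.matrix)
    if not subs:
        return [], np.empty(0), np.empty(0)
    raw = sw_score_batch(
        q, flat, starts, lengths, submat, params.gap_open, params.gap_extend
    )
    lam, kpar = _KA_PARAMS[params.matrix]
    n_letters = params.db_size_letters or db.total_letters
    evalues = kpar * len(query) * n_letters * np.exp(-lam * raw)
    return db.ids, raw, evalues


@dataclass(frozen=True)
class Hsp:
    """One high-scoring segment pair (best local alignment with a subject).

    ``subject_aligned_subseq`` is the subject residues inside
    ``subject_range`` - the fragment re-queried by the second BLAST of the
    2bLCA protocol.  Ranges are 0-based half-open; for translated queries
    ``query_range`` is in read nucleotide coordinates on the forward strand
    and ``frame`` records the reading frame.
    """

    query_id: str
    subject_id: str
    bit_score: float
    e_value: float
    pct_identity: float
    query_range: tuple[int, int]
    subject_range: tuple[int, int]
    subject_aligned_subseq: str
    frame: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.subject_aligned_subseq) != self.subject_range[1] - self.subject_range[0]:
            raise ValueError("subject fragment length disagrees with subject_range")
        if not math.isfinite(self.e_value):
            raise ValueError("E-value must be finite")


def evalue_from_raw(raw_score: float, m: int, n: int, matrix: str = "BLOSUM62") -> tuple[float, float]:
    """(bit_score, e_value) from a raw alignment score."""
    lam, k = _KA_PARAMS[matrix]
    bits = (lam * raw_score - math.log(k)) / math.log(2.0)
    e = k * m * n * math.exp(-lam * raw_score)
    return bits, e


def search_protein(
    query: str,
    db: ReferenceDB,
    params: SearchParams = SearchParams(),
    query_id: str = "query",
) -> list[Hsp]:
    """Search an amino-acid query against every db protein.

    Returns one best HSP per subject with E <= ``max_evalue``, sorted by
    ascending E-value with ties broken by subject id.
    """
    if len(db) == 0:
        return []
    ids, raw_scores, evalues = protein_scores(query, db, params)
    hits: list[Hsp] = []
    for k, sid in enumerate(ids):
        if evalues[k] > params.max_evalue or raw_scores[k] <= 0:
            continue
        hits.append(traceback_hsp(query, sid, db, params, query_id))
    hits.sort(key=lambda h: (h.e_value, h.subject_id))
    return hits


def traceback_hsp(
    query: str,
    subject_id: str,
    db: ReferenceDB,
    params: SearchParams = SearchParams(),
    query_id: str = "query",
) -> Hsp:
    """Full alignment of one query-subject pair as an :class:`Hsp`."""
    submat, alphabet = _matrix(params.matrix)
    q = encode_protein(query, alphabet)
    s = encode_protein(db[subject_id].seq, alphabet)
    raw, qs, qe, ss, se, matches, aln_len = sw_traceback(
        q, s, submat, params.gap_open, params.gap_extend
    )
    n_letters = params.db_size_letters or db.total_letters
    bits, e = evalue_from_raw(raw, len(query), n_letters, params.matrix)
    return Hsp(
        query_id=query_id,
        subject_id=subject_id,
        bit_score=bits,
        e_value=e,
        pct_identity=matches / aln_len if aln_len else 0.0,
        query_range=(qs, qe),
        subject_range=(ss, se),
        subject_aligned_subseq=db[subject_id].seq[ss:se],
    )


def search_translated(
    read: NucRead,
    db: ReferenceDB,
    params: SearchParams = SearchParams(),
    min_len_aa: int = 20,
) -> list[Hsp]:
    """Translated (BLASTx-like) search of a nucleotide read.

    Equals the union of :func:`search_protein` over the read's six-frame
    stop-free peptides, with query coordinates mapped back to the forward
    strand of the read and a single best HSP kept per subject.
    """
    best: dict[str, Hsp] = {}
    for pep in six_frame_orfs(read, min_len_aa=min_len_aa):
        for h in search_protein(pep.seq, db, params, query_id=read.read_id):
            qs_aa, qe_aa = h.query_range
            if pep.frame > 0:
                nt = (pep.start + 3 * qs_aa, pep.start + 3 * qe_aa)
            else:
                nt = (pep.end - 3 * qe_aa, pep.end - 3 * qs_aa)
            h = replace(h, query_range=nt, frame=pep.frame)
            prev = best.get(h.subject_id)
            if prev is None or (h.e_value, -h.bit_score) < (prev.e_value, -prev.bit_score):
                best[h.subject_id] = h
    hits = sorted(best.values(), key=lambda h: (h.e_value, h.subject_id))
    return hits


_TABULAR_COLS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def load_tabular_hits(path, db: ReferenceDB) -> list[Hsp]:
    """Adapter for 12-column BLAST tabular output (outfmt 6).

    Subject fragments are reconstructed from the db by slicing the
    subject's sequence with the (1-based, inclusive) tabular coordinates.
    An unknown subject id, or coordinates beyond the subject length, is an
    error because the fragment cannot be reconstructed.
    """
    df = pd.read_csv(path, sep="\t", names=_TABULAR_COLS, comment="#")
    hits = []
    for row in df.itertuples():
        sid = str(row.sseqid)
        if sid not in db:
            raise ValueError(f"subject {sid!r} absent from reference db")
        seq = db[sid].seq
        ss, se = int(row.sstart) - 1, int(row.send)
        if ss < 0 or se > len(seq) or ss >= se:
            raise ValueError(
                f"subject range {row.sstart}..{row.send} outside {sid!r} "
                f"(length {len(seq)})"
            )
        hits.append(
            Hsp(
                query_id=str(row.qseqid),
                subject_id=sid,
                bit_score=float(row.bitscore),
                e_value=float(row.evalue),
                pct_identity=float(row.pident) / 100.0,
                query_range=(int(row.qstart) - 1, int(row.qend)),
                subject_range=(ss, se),
                subject_aligned_subseq=seq[ss:se],
            )
        )
    hits.sort(key=lambda h: (h.e_value, h.subject_id))
    return hits
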