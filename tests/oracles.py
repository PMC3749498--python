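"""Independent reference implementations used only by the test suite.

Everything here deliberately avoids the package's own compute paths: local
alignment goes through Biopython's PairwiseAligner (or a pure-Python DP at
tiny sizes), translation through a hand-written codon table, clustering
and matrix building through naive quadratic enumeration.
"""

from __future__ import annotations

import math

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

# --- local alignment ------------------------------------------------------

_KA = {"BLOSUM62": (0.3176, 0.134)}


def biopython_aligner(gap_open: float = 11.0, gap_extend: float = 1.0) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -gap_open
    al.extend_gap_score = -gap_extend
    return al


def sw_score_biopython(query: str, subject: str) -> float:
    return float(biopython_aligner().score(query, subject))


def sw_score_python(query: str, subject: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Pure-Python affine-gap Smith-Waterman, for tiny instances only."""
    mat = substitution_matrices.load("BLOSUM62")
    m, n = len(query), len(subject)
    NEG = -1e30
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend, H[i][j - 1] - gap_open)
            F[i][j] = max(F[i - 1][j] - gap_extend, H[i - 1][j] - gap_open)
            s = mat[query[i - 1], subject[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def evalue(raw: float, m: int, n_letters: int) -> float:
    """Karlin-Altschul E-value in the exact arithmetic order the engine uses."""
    lam, k = _KA["BLOSUM62"]
    return k * m * n_letters * float(np.exp(np.float64(-lam * raw)))


# --- translation ----------------------------------------------------------

_CODON_TABLE = {}
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _CODON_TABLE[_b1 + _b2 + _b3] = _AA[16 * _i + 4 * _j + _k]

_COMP = str.maketrans("ACGTN", "TGCAN")


def translate_naive(nt: str) -> str:
    """Codon-by-codon translation; any codon containing N becomes X."""
    out = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i : i + 3]
        out.append("X" if "N" in codon else _CODON_TABLE[codon])
    return "".join(out)


def six_frame_naive(nt: str, min_len: int) -> set[tuple[int, str]]:
    """(frame, peptide) pairs of all stop-free stretches >= min_len."""
    rc = nt.translate(_COMP)[::-1]
    out = set()
    for strand, seq in ((1, nt), (-1, rc)):
        for off in range(3):
            aa = translate_naive(seq[off:])
            for chunk in aa.split("*"):
                if len(chunk) >= min_len:
                    out.add((strand * (off + 1), chunk))
    return out


# --- duplicate clustering -------------------------------------------------


def dedup_oracle(reads, prefix_len: int, min_identity: float):
    """Greedy duplicate clustering re-coded with edlib-free identity
    (pure-Python Needleman-Wunsch at unit costs)."""

    def nw_identity(a: str, b: str) -> float:
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        # unit-cost NW distance and alignment length via DP
        la, lb = len(a), len(b)
        D = [[0] * (lb + 1) for _ in range(la + 1)]
        for i in range(la + 1):
            D[i][0] = i
        for j in range(lb + 1):
            D[0][j] = j
        for i in range(1, la + 1):
            for j in range(1, lb + 1):
                D[i][j] = min(
                    D[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
                    D[i - 1][j] + 1,
                    D[i][j - 1] + 1,
                )
        # traceback for matches / alignment length
        i, j, matches, aln = la, lb, 0, 0
        while i > 0 or j > 0:
            if i > 0 and j > 0 and D[i][j] == D[i - 1][j - 1] + (a[i - 1] != b[j - 1]):
                matches += a[i - 1] == b[j - 1]
                i, j, aln = i - 1, j - 1, aln + 1
            elif i > 0 and D[i][j] == D[i - 1][j] + 1:
                i, aln = i - 1, aln + 1
            else:
                j, aln = j - 1, aln + 1
        return matches / aln if aln else 0.0

    order = sorted(reads, key=lambda r: (-len(r.seq), r.read_id))
    exemplars = []
    cmap = {}
    for r in order:
        if len(r.seq) < prefix_len:
            exemplars.append(r)
            continue
        joined = None
        for ex in exemplars:
            if len(ex.seq) >= prefix_len and ex.seq[:prefix_len] == r.seq[:prefix_len]:
                if nw_identity(r.seq, ex.seq) >= min_identity:
                    joined = ex
                    break
        if joined is None:
            exemplars.append(r)
        else:
            cmap[r.read_id] = joined.read_id
    kept_ids = {e.read_id for e in exemplars}
    return kept_ids, cmap


# --- 2bLCA ----------------------------------------------------------------


def lca_strings(lineage_strings):
    """LCA by label-prefix arithmetic on '; '-joined strings."""
    split = [tuple(x.strip() for x in s.split(";")) for s in lineage_strings]
    first = split[0]
    out = []
    for depth in range(len(first)):
        label = first[depth]
        if all(len(s) > depth and s[depth] == label for s in split):
            out.append(label)
        else:
            break
    return "; ".join(out)


def assign_2blca_oracle(read, db, b1_max_evalue=1e-5, min_read_len=100, min_len_aa=20):
    """Literal re-implementation of the dual-search LCA protocol on top of
    Biopython's aligner.  Returns (status, lineage string, frozenset H)."""
    from ncldvscope.qc import six_frame_orfs  # translation shared; search is not

    if len(read.seq) <= min_read_len:
        return ("too_short", None, frozenset())
    aligner = biopython_aligner()
    ids = sorted(p.protein_id for p in db)
    n_letters = sum(len(p.seq) for p in db)
    best = None  # (evalue, peptide_order, subject_id, peptide)
    for order, pep in enumerate(six_frame_orfs(read, min_len_aa=min_len_aa)):
        for sid in ids:
            raw = float(aligner.score(pep.seq, db[sid].seq))
            if raw <= 0:
                continue
            e = evalue(raw, len(pep.seq), n_letters)
            key = (e, order, sid)
            if best is None or key < best[0:3]:
                best = (e, order, sid, pep)
    if best is None or best[0] > b1_max_evalue:
        return ("no_hit", None, frozenset())
    e_star, _, best_sid, best_pep = best
    # subject fragment of the best alignment
    aln = aligner.align(best_pep.seq, db[best_sid].seq)[0]
    s_start = int(aln.aligned[1][0][0])
    s_end = int(aln.aligned[1][-1][1])
    fragment = db[best_sid].seq[s_start:s_end]
    support = {best_sid}
    for sid in ids:
        raw = float(aligner.score(fragment, db[sid].seq))
        if raw <= 0:
            continue
        if evalue(raw, len(fragment), n_letters) <= e_star:
            support.add(sid)
    lineages = [str(db[s].lineage) for s in support]
    domains = {l.split(";")[0].strip() for l in lineages}
    status = "ambiguous" if len(domains & {"Bacteria", "Archaea", "Eukaryota", "Viruses"}) > 1 else "assigned"
    return (status, lca_strings(lineages), frozenset(support))


# --- matrix building ------------------------------------------------------


def build_matrix_oracle(assignments_by_sample, depth):
    """Quadratic ancestor-counting: for every (node, read) pair test the
    prefix relation directly."""
    nodes = set()
    per_sample = {}
    for sample, assignments in assignments_by_sample.items():
        lineages = [
            tuple(a.lineage.ranks)
            for a in assignments
            if a.status == "assigned" and a.lineage is not None
        ]
        per_sample[sample] = lineages
        for lin in lineages:
            for d in range(1, min(depth, len(lin)) + 1):
                nodes.add(lin[:d])
    counts = {}
    for node in nodes:
        for sample, lineages in per_sample.items():
            c = sum(1 for lin in lineages if lin[: len(node)] == node)
            counts[("; ".join(node), sample)] = c
    return counts
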