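"""Read quality control: 454 artificial-duplicate removal and six-frame
translation.

454 pyrosequencing emits "artificial duplicates": re-reads of the same
template that share their 5' start and are nearly identical over their
length.  They are removed by greedy clustering: reads are visited in
descending length (ties broken lexically by id) and a read joins the first
exemplar that shares its first ``prefix_len`` nucleotides and aligns to it
at >= ``min_identity`` global identity; exemplars are kept, members dropped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import edlib
from Bio.Seq import Seq

from .model import NucRead

log = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class DedupParams:
    """Duplicate-clustering thresholds (>=5 identical starting nucleotides
    and >=97% overall identity by default)."""

    prefix_len: int = 5
    min_identity: float = 0.97

    def __post_init__(self) -> None:
        if self.prefix_len < 1:
            raise ValueError("prefix_len must be >= 1")
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0, 1]")


@dataclass(frozen=True)
class Peptide:
    """A stop-free translated stretch of a read.

    ``start``/``end`` are 0-based half-open coordinates on the *forward*
    strand of the read, for all six frames (+1,+2,+3,-1,-2,-3).
    """

    peptide_id: str
    read_id: str
    frame: int
    start: int
    end: int
    seq: str

    def __post_init__(self) -> None:
        if "*" in self.seq:
            raise ValueError("peptide contains a stop character")
        if self.frame not in (1, 2, 3, -1, -2, -3):
            raise ValueError("frame must be in +-{1,2,3}")


def global_identity(a: str, b: str) -> float:
    """Fraction of matching columns in a global (NW) alignment of a vs b."""
    res = edlib.align(a, b, mode="NW", task="path")
    matches = 0
    aln_len = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        aln_len += n
        if op == "=":
            matches += n
    return matches / aln_len if aln_len else 0.0


def _duplicate_identity(read_seq: str, exemplar_seq: str) -> float:
    # 454 duplicates share start points: align the shorter read globally
    # against the equally long prefix of the exemplar (end-gap-free from 0).
    n = min(len(read_seq), len(exemplar_seq))
    return global_identity(read_seq[:n], exemplar_seq[:n])


def remove_duplicates(
    reads: list[NucRead], params: DedupParams = DedupParams()
) -> tuple[list[NucRead], dict[str, str]]:
    """Greedy duplicate clustering within one sample/run.

    Returns the kept exemplars (input order preserved) and a map from each
    *dropped* read id to the id of the exemplar it clustered with.  Reads
    shorter than ``prefix_len`` cannot share a well-defined start prefix
    and are kept unconditionally.
    """
    order = sorted(reads, key=lambda r: (-len(r.seq), r.read_id))
    exemplars_by_prefix: dict[str, list[NucRead]] = {}
    short_kept: list[NucRead] = []
    cluster_map: dict[str, str] = {}
    kept_ids = set()
    for read in order:
        if len(read.seq) < params.prefix_len:
            log.warning(
                "read %s shorter than prefix_len=%d: kept unconditionally",
                read.read_id,
                params.prefix_len,
            )
            short_kept.append(read)
            kept_ids.add(read.read_id)
            continue
        prefix = read.seq[: params.prefix_len]
        bucket = exemplars_by_prefix.setdefault(prefix, [])
        joined = None
        for exemplar in bucket:
            if _duplicate_identity(read.seq, exemplar.seq) >= params.min_identity:
                joined = exemplar
                break
        if joined is None:
            bucket.append(read)
            kept_ids.add(read.read_id)
        else:
            cluster_map[read.read_id] = joined.read_id
    kept = [r for r in reads if r.read_id in kept_ids]
    return kept, cluster_map


def six_frame_orfs(read: NucRead, min_len_aa: int = 20) -> list[Peptide]:
    """Translate a read in all six frames and emit every maximal stop-free
    stretch of length >= ``min_len_aa``.

    The standard genetic code is used and ``N`` codons translate to ``X``.
    Reverse-strand peptide coordinates are reported on the forward strand.
    """
    if len(read.seq) < 3:
        return []
    peptides: list[Peptide] = []
    rc = str(Seq(read.seq).reverse_complement())
    n = len(read.seq)
    counter = 0
    for strand, seq in ((1, read.seq), (-1, rc)):
        for offset in range(3):
            frame = strand * (offset + 1)
            usable = seq[offset : offset + 3 * ((n - offset) // 3)]
            if not usable:
                continue
            aa = str(Seq(usable).translate())
            for m in re.finditer(r"[^*]+", aa):
                if m.end() - m.start() < min_len_aa:
                    continue
                # coordinates of the stretch on its own strand
                s_nt = offset + 3 * m.start()
                e_nt = offset + 3 * m.end()
                if strand == 1:
                    start, end = s_nt, e_nt
                else:
                    start, end = n - e_nt, n - s_nt
                peptides.append(
                    Peptide(
                        peptide_id=f"{read.read_id}|f{frame:+d}|{counter}",
                        read_id=read.read_id,
                        frame=frame,
                        start=start,
                        end=end,
                        seq=m.group(0),
                    )
                )
                counter += 1
    return peptides
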