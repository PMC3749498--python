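"""End-to-end per-sample orchestration of the abundance workflow.

One call takes raw reads for a sample through duplicate removal,
six-frame translation, marker scanning with 2bLCA binning, density
computation and - when a cell count is available - rescaling to absolute
genome concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .markers import (
    AbundanceEstimate,
    DensityRecord,
    MarkerHit,
    MarkerProfile,
    absolute_abundance,
    marker_density,
    ncldv_prokaryote_ratio,
    scan_markers,
)
from .model import CellCounts, NucRead, ReferenceDB, SampleStats
from .qc import DedupParams, remove_duplicates, six_frame_orfs


@dataclass
class SampleResult:
    sample_id: str
    n_reads_in: int
    n_reads_kept: int
    duplicate_fraction: float
    hits: list[MarkerHit]
    densities: list[DensityRecord]
    ratio: float
    abundance: list[AbundanceEstimate] = field(default_factory=list)


def process_sample(
    reads: Sequence[NucRead],
    sample_stats: SampleStats,
    profiles: Sequence[MarkerProfile],
    db: ReferenceDB,
    cell_counts: Optional[CellCounts] = None,
    dedup_params: DedupParams = DedupParams(),
    min_orf_len_aa: int = 30,
    marker_max_evalue: float = 1e-3,
    b1_max_evalue: float = 1e-5,
    ratio_mode: str = "mean",
) -> SampleResult:
    """Run the abundance workflow for one sample.

    ``sample_stats.total_bp`` should describe the *deduplicated* data; if
    it describes the raw data it is recomputed from the kept reads.
    """
    kept, cluster_map = remove_duplicates(list(reads), dedup_params)
    kept_bp = sum(len(r) for r in kept)
    stats = SampleStats(
        sample_id=sample_stats.sample_id,
        total_bp=kept_bp,
        n_reads=len(kept),
        depth_zone=sample_stats.depth_zone,
    )
    peptides = [
        pep for read in kept for pep in six_frame_orfs(read, min_len_aa=min_orf_len_aa)
    ]
    hits = scan_markers(
        peptides,
        profiles,
        db,
        sample_id=stats.sample_id,
        max_evalue=marker_max_evalue,
        b1_max_evalue=b1_max_evalue,
    )
    densities = marker_density(hits, {stats.sample_id: stats}, profiles)
    ratio = ncldv_prokaryote_ratio(
        densities, profiles, sample_id=stats.sample_id, mode=ratio_mode
    )
    abundance = (
        absolute_abundance(ratio, cell_counts) if cell_counts is not None else []
    )
    return SampleResult(
        sample_id=stats.sample_id,
        n_reads_in=len(reads),
        n_reads_kept=len(kept),
        duplicate_fraction=len(cluster_map) / len(reads) if reads else 0.0,
        hits=hits,
        densities=densities,
        ratio=ratio,
        abundance=abundance,
    )
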