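"""File formats: FASTA, lineage TSVs, sample metadata, run configuration.

All tabular formats are plain TSV with a header line; coordinates in every
interface are 0-based half-open.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    CellCounts,
    Lineage,
    NucRead,
    ReferenceDB,
    ReferenceProtein,
    SampleStats,
    parse_lineage,
)

PathLike = Union[str, Path]


class FastaParseError(ValueError):
    pass


def read_fasta(path: PathLike, sample_id: str) -> list[NucRead]:
    """Load nucleotide reads from a FASTA file.

    Sequences are upper-cased; ``N`` is allowed.  A malformed record (for
    example a sequence line before any header) raises
    :class:`FastaParseError` naming the offending line.
    """
    path = Path(path)
    _check_fasta_syntax(path)
    reads = []
    for rec in SeqIO.parse(str(path), "fasta"):
        reads.append(NucRead(rec.id, sample_id, str(rec.seq).upper()))
    return reads


def _check_fasta_syntax(path: Path) -> None:
    with open(path) as fh:
        seen_header = False
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if len(line) == 1:
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
                seen_header = True
            elif not seen_header:
                raise FastaParseError(
                    f"{path}:{lineno}: sequence data before first '>' header"
                )


def write_fasta(records: Iterable[tuple[str, str]], path: PathLike) -> None:
    """Write (id, sequence) pairs as FASTA."""
    seq_records = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    SeqIO.write(seq_records, str(path), "fasta")


def read_protein_fasta(path: PathLike) -> dict[str, str]:
    _check_fasta_syntax(Path(path))
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def load_reference_db(
    fasta_path: PathLike,
    lineage_tsv_path: PathLike,
    sep: str = ";",
) -> ReferenceDB:
    """Load a reference protein set (FASTA) with its lineage table (TSV).

    The TSV has columns ``protein_id``, ``lineage`` and optionally
    ``source_group`` (viral/cellular, default cellular).  Every FASTA id
    must have a lineage row; offending ids are listed in the error.
    """
    seqs = read_protein_fasta(fasta_path)
    table = pd.read_csv(lineage_tsv_path, sep="\t", dtype=str)
    if "protein_id" not in table.columns or "lineage" not in table.columns:
        raise ValueError("lineage TSV needs 'protein_id' and 'lineage' columns")
    if table["protein_id"].duplicated().any():
        dups = table.loc[table["protein_id"].duplicated(), "protein_id"].tolist()
        raise ValueError(f"duplicate lineage rows for: {dups}")
    lineages = {
        row.protein_id: parse_lineage(row.lineage, sep=sep)
        for row in table.itertuples()
    }
    groups = (
        dict(zip(table["protein_id"], table["source_group"]))
        if "source_group" in table.columns
        else {}
    )
    missing = sorted(set(seqs) - set(lineages))
    if missing:
        raise ValueError(f"proteins without lineage rows: {missing}")
    proteins = [
        ReferenceProtein(pid, seq, lineages[pid], groups.get(pid, "cellular"))
        for pid, seq in seqs.items()
    ]
    return ReferenceDB(proteins)


def save_reference_db(db: ReferenceDB, fasta_path: PathLike, lineage_tsv_path: PathLike) -> None:
    write_fasta(((p.protein_id, p.seq) for p in db), fasta_path)
    pd.DataFrame(
        {
            "protein_id": [p.protein_id for p in db],
            "lineage": [str(p.lineage) for p in db],
            "source_group": [p.source_group for p in db],
        }
    ).to_csv(lineage_tsv_path, sep="\t", index=False)


def load_sample_stats(path: PathLike) -> dict[str, SampleStats]:
    """Sample-stats TSV: sample_id, total_bp, n_reads, depth_zone."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples():
        out[row.sample_id] = SampleStats(
            sample_id=str(row.sample_id),
            total_bp=int(row.total_bp),
            n_reads=int(row.n_reads),
            depth_zone=str(row.depth_zone),
        )
    return out


def load_cell_counts(path: PathLike) -> dict[str, CellCounts]:
    """Cell-count TSV: sample_id, fc_cells_per_ml, microscopy_cells_per_ml."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples():
        fc = getattr(row, "fc_cells_per_ml", None)
        mic = getattr(row, "microscopy_cells_per_ml", None)
        out[row.sample_id] = CellCounts(
            sample_id=str(row.sample_id),
            fc_cells_per_ml=None if pd.isna(fc) else float(fc),
            microscopy_cells_per_ml=None if pd.isna(mic) else float(mic),
        )
    return out


@dataclass
class RunConfig:
    """Thresholds for a pipeline run; loadable from YAML.

    Defaults mirror the published protocol: duplicate clustering at >=5
    identical starting nucleotides and >=97% identity, B1 E-value cutoff
    1e-5, marker scan cutoff 1e-3, 0.9 pre-filter pass-through.
    """

    dedup_prefix_len: int = 5
    dedup_min_identity: float = 0.97
    min_read_len: int = 100
    min_orf_len_aa: int = 20
    b1_max_evalue: float = 1e-5
    marker_max_evalue: float = 1e-3
    passthrough_fraction: float = 0.9
    network_min_total_reads: int = 5
    network_depth: int = 5
    network_rho_min: float = 0.7
    network_q_max: float = 0.05
    network_n_perm: int = 1000
    network_n_boot: int = 1000
    network_top_k: int = 1000
    hgt_max_evalue: float = 1e-5
    hgt_exclusion_levels: int = 3
    lineage_sep: str = ";"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def write_run_metadata(path: PathLike, config: RunConfig, **extra) -> None:
    """Persist seed, parameters and package version next to the outputs."""
    from . import __version__

    meta = {"version": __version__, "config": asdict(config), **extra}
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
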