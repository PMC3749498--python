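"""Single-copy marker-gene scanning and genome-abundance estimation.

Marker genes that occur once per genome make hit counts a proxy for genome
counts: the density of a marker (hits per Mbp of metagenome) is
proportional to the abundance of the genomes carrying it.  The NCLDV to
prokaryote genome ratio r is the ratio of the group summaries of those
densities, and multiplying by a measured prokaryotic cell concentration C
and the pre-filter pass-through fraction phi gives an absolute
concentration A = r * phi * C in genomes per ml of sea water.

Profiles are position-specific score matrices (log-odds bits per alignment
column); a hit is the best ungapped window placement with
E = len(peptide) * L * 2**(-score) at or below the scan threshold (1e-3 by
default).  Each hit is then taxonomically binned with the 2bLCA protocol
so that, e.g., a cellular marker homolog carried by a virus counts in the
viral bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._align import pssm_best_window
from .annotate import assign_2blca_protein, classify_bin
from .model import CellCounts, ReferenceDB, SampleStats
from .qc import Peptide

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_PSSM_ALPHA = AA20 + "X"
_AA_LUT = np.full(128, len(AA20), dtype=np.int64)  # unknowns -> X column
for _i, _ch in enumerate(AA20):
    _AA_LUT[ord(_ch)] = _i


def encode_peptide(seq: str) -> np.ndarray:
    return _AA_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class MarkerProfile:
    """A marker-gene scoring profile.

    ``pssm`` has one row per reference-alignment column and one column per
    residue of ``ACDEFGHIKLMNPQRSTVWYX`` (scores in bits; the X column is
    zero).  ``ref_alignment_len`` is the reference multiple-alignment
    length L used for gene-size normalization of densities.
    """

    name: str
    group: str  # "ncldv" or "cellular"
    pssm: np.ndarray
    family_scope: Optional[str] = None

    def __post_init__(self) -> None:
        if self.group not in ("ncldv", "cellular"):
            raise ValueError("group must be 'ncldv' or 'cellular'")
        if self.pssm.ndim != 2 or self.pssm.shape[1] != len(_PSSM_ALPHA):
            raise ValueError("pssm must be L x 21 (ACDEFGHIKLMNPQRSTVWYX)")
        if self.pssm.shape[0] < 1:
            raise ValueError("ref_alignment_len must be >= 1")

    @property
    def ref_alignment_len(self) -> int:
        return int(self.pssm.shape[0])


def pssm_from_sequences(
    seqs: Sequence[str], pseudocount: float = 1.0
) -> np.ndarray:
    """Log-odds position-score matrix from equal-length aligned sequences.

    Column probabilities (with a symmetric pseudocount) are scored in bits
    against a uniform 1/20 background; X scores 0 everywhere.
    """
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("profile sequences must be pre-aligned (equal length)")
    L = lengths.pop()
    counts = np.full((L, 20), pseudocount, dtype=np.float64)
    for s in seqs:
        enc = encode_peptide(s)
        for pos, a in enumerate(enc):
            if a < 20:
                counts[pos, a] += 1.0
    probs = counts / counts.sum(axis=1, keepdims=True)
    pssm = np.zeros((L, 21), dtype=np.float64)
    pssm[:, :20] = np.log2(probs / 0.05)
    return pssm


def save_marker_profile(profile: MarkerProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#name\t{profile.name}\n")
        fh.write(f"#group\t{profile.group}\n")
        if profile.family_scope:
            fh.write(f"#family_scope\t{profile.family_scope}\n")
        fh.write("pos\t" + "\t".join(_PSSM_ALPHA) + "\n")
        for i, row in enumerate(profile.pssm):
            fh.write(f"{i}\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def load_marker_profile(path) -> MarkerProfile:
    """Load the TSV position-score table format written by
    :func:`save_marker_profile`."""
    meta = {}
    rows = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].partition("\t")
                meta[key] = val
            elif header is None:
                header = line.split("\t")
                if header[1:] != list(_PSSM_ALPHA):
                    raise ValueError(f"{path}: unexpected residue columns")
            else:
                rows.append([float(v) for v in line.split("\t")[1:]])
    if "name" not in meta or "group" not in meta:
        raise ValueError(f"{path}: missing #name/#group metadata")
    return MarkerProfile(
        name=meta["name"],
        group=meta["group"],
        pssm=np.asarray(rows, dtype=np.float64),
        family_scope=meta.get("family_scope"),
    )


def load_hmm_profile(path, group: str, family_scope: Optional[str] = None) -> MarkerProfile:
    """Convert a HMMER3 profile-HMM into a position-score matrix.

    Match-state emission probabilities are turned into log-odds bits
    against the model background; insert/delete transitions are dropped
    (the built-in scorer is ungapped).
    """
    import pyhmmer  # optional heavyweight dependency; imported lazily

    with pyhmmer.plan7.HMMFile(str(path)) as fh:
        hmm = fh.read()
    bg = pyhmmer.plan7.Background(hmm.alphabet)
    emissions = np.asarray(hmm.match_emissions)[1:, :20]  # row 0 is the dummy state
    freqs = np.asarray(bg.residue_frequencies)[:20]
    hmm_alpha = hmm.alphabet.symbols[:20]
    order = [hmm_alpha.index(ch) for ch in AA20]
    pssm = np.zeros((emissions.shape[0], 21), dtype=np.float64)
    with np.errstate(divide="ignore"):
        pssm[:, :20] = np.log2(
            np.maximum(emissions[:, order], 1e-12) / np.maximum(freqs[order], 1e-12)
        )
    return MarkerProfile(name=hmm.name.decode(), group=group, pssm=pssm,
                         family_scope=family_scope)


@dataclass(frozen=True)
class MarkerHit:
    """One peptide matching one marker profile (best window, binned)."""

    marker_name: str
    read_id: str
    sample_id: str
    e_value: float
    bin: str
    score_bits: float = 0.0


def profile_evalue(score_bits: float, peptide_len: int, L: int) -> float:
    return peptide_len * L * math.pow(2.0, -score_bits)


def scan_markers(
    peptides: Iterable[Peptide],
    profiles: Sequence[MarkerProfile],
    db: ReferenceDB,
    sample_id: str,
    max_evalue: float = 1e-3,
    b1_max_evalue: float = 1e-5,
) -> list[MarkerHit]:
    """Scan peptides against every marker profile.

    At most one hit per (read, marker) is emitted (best E-value across the
    read's peptides); each emitted hit is then 2bLCA-annotated against
    ``db`` and binned with :func:`~ncldvscope.annotate.classify_bin`.
    """
    best: dict[tuple[str, str], tuple[float, float, Peptide]] = {}
    for pep in peptides:
        enc = encode_peptide(pep.seq)
        for prof in profiles:
            score = pssm_best_window(enc, prof.pssm)
            e = profile_evalue(score, len(pep.seq), prof.ref_alignment_len)
            if e > max_evalue:
                continue
            key = (pep.read_id, prof.name)
            prev = best.get(key)
            if prev is None or e < prev[0]:
                best[key] = (e, score, pep)
    hits = []
    for (read_id, marker_name), (e, score, pep) in sorted(best.items()):
        assignment = assign_2blca_protein(
            pep.seq, db, query_id=pep.peptide_id, b1_max_evalue=b1_max_evalue
        )
        hits.append(
            MarkerHit(
                marker_name=marker_name,
                read_id=read_id,
                sample_id=sample_id,
                e_value=e,
                bin=classify_bin(assignment),
                score_bits=score,
            )
        )
    return hits


@dataclass(frozen=True)
class DensityRecord:
    """Marker-gene density in one sample: hits per Mbp, optionally
    normalized by the reference alignment length."""

    sample_id: str
    marker_name: str
    bin: str
    n_hits: int
    density: float
    normalized_density: float


def marker_density(
    hits: Iterable[MarkerHit],
    sample_stats: dict[str, SampleStats],
    profiles: Sequence[MarkerProfile],
) -> list[DensityRecord]:
    """Per-(sample, marker, bin) densities: d = n_hits * 1e6 / total_bp."""
    by_profile = {p.name: p for p in profiles}
    counts: dict[tuple[str, str, str], int] = {}
    for h in hits:
        key = (h.sample_id, h.marker_name, h.bin)
        counts[key] = counts.get(key, 0) + 1
    records = []
    for (sample_id, marker_name, bin_), n in sorted(counts.items()):
        st = sample_stats[sample_id]
        if st.total_bp == 0:
            raise ValueError(f"sample {sample_id}: total_bp is zero")
        d = n * 1e6 / st.total_bp
        L = by_profile[marker_name].ref_alignment_len
        records.append(
            DensityRecord(sample_id, marker_name, bin_, n, d, d / L)
        )
    return records


_DEFAULT_BINS = {"ncldv": ("NCLDV",), "cellular": ("Bacteria", "Archaea")}


def group_summary(
    densities: Iterable[DensityRecord],
    profiles: Sequence[MarkerProfile],
    group: str,
    mode: str = "median",
    sample_id: Optional[str] = None,
    bins: Optional[tuple[str, ...]] = None,
    normalized: bool = False,
) -> float:
    """Summary (median or mean) of per-marker densities for one group.

    Markers of the group with no hits contribute a density of zero, so
    small samples are not biased upward.  ``bins`` restricts which
    taxonomic bins count (defaults: NCLDV bin for the ncldv group,
    Bacteria+Archaea for the cellular group).  With ``sample_id`` the
    summary is per sample, otherwise densities are pooled by summing
    per-marker hit densities across samples' records.
    """
    group_profiles = [p for p in profiles if p.group == group]
    if not group_profiles:
        raise ValueError(f"no profiles in group {group!r}")
    use_bins = bins if bins is not None else _DEFAULT_BINS[group]
    per_marker = {p.name: 0.0 for p in group_profiles}
    for rec in densities:
        if rec.marker_name not in per_marker or rec.bin not in use_bins:
            continue
        if sample_id is not None and rec.sample_id != sample_id:
            continue
        value = rec.normalized_density if normalized else rec.density
        per_marker[rec.marker_name] += value
    values = np.array(list(per_marker.values()))
    if mode == "median":
        return float(np.median(values))
    if mode == "mean":
        return float(values.mean())
    raise ValueError("mode must be 'median' or 'mean'")


def ncldv_prokaryote_ratio(
    densities: Iterable[DensityRecord],
    profiles: Sequence[MarkerProfile],
    sample_id: Optional[str] = None,
    mode: str = "mean",
    normalized: bool = False,
) -> float:
    """r: the NCLDV to prokaryote marker-density ratio (genome ratio)."""
    densities = list(densities)
    num = group_summary(densities, profiles, "ncldv", mode, sample_id,
                        normalized=normalized)
    den = group_summary(densities, profiles, "cellular", mode, sample_id,
                        normalized=normalized)
    if den == 0:
        return float("nan")
    return num / den


@dataclass(frozen=True)
class AbundanceEstimate:
    """Absolute NCLDV genome concentration A = r * phi * C (per ml)."""

    sample_id: str
    r: float
    cells_per_ml: float
    passthrough_fraction: float
    genomes_per_ml: float
    count_source: str  # "fc" or "microscopy"


def absolute_abundance(r: float, cell_counts: CellCounts) -> list[AbundanceEstimate]:
    """Rescale a relative ratio r to genomes per ml.

    One estimate is emitted per available cell count (flow cytometry and
    microscopy are reported separately, never averaged).
    """
    if r < 0:
        raise ValueError("r must be >= 0")
    out = []
    phi = cell_counts.passthrough_fraction
    for source, c in (
        ("fc", cell_counts.fc_cells_per_ml),
        ("microscopy", cell_counts.microscopy_cells_per_ml),
    ):
        if c is None:
            continue
        out.append(
            AbundanceEstimate(
                sample_id=cell_counts.sample_id,
                r=r,
                cells_per_ml=c,
                passthrough_fraction=phi,
                genomes_per_ml=r * phi * c,
                count_source=source,
            )
        )
    if not out:
        raise ValueError(
            f"sample {cell_counts.sample_id}: no cell count available for rescaling"
        )
    return out


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation between two per-sample density vectors, with its
    two-sided p-value.  Zero-variance input yields (nan, nan)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r), float(p)


def density_frame(densities: Iterable[DensityRecord]) -> pd.DataFrame:
    """DensityRecords as a tidy DataFrame (for TSV export)."""
    return pd.DataFrame([vars(d) for d in densities])
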