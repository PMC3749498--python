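"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure the pipeline assumes -
single-copy marker genes embedded in genomes, lineage-annotated reference
proteins with a divergence ladder along a taxonomy, 454-style artificial
duplicates sharing 5' starts, and compositional taxon-by-sample count
matrices with latent shared drivers - at desk scale (kilobase genomes,
thousands of reads).  They make no attempt to mimic real marine taxon
frequencies or real marker sequences; their purpose is exact scoring of
recovery, so every emitted read, protein and matrix row carries a
provenance label.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .markers import AA20, MarkerProfile, pssm_from_sequences
from .model import (
    CellCounts,
    Lineage,
    NucRead,
    ReferenceDB,
    ReferenceProtein,
    SampleStats,
)
from .network import TaxonSampleMatrix

_NCLDV_FAMILY_CYCLE = (
    "Mimiviridae",
    "Phycodnaviridae",
    "Marseilleviridae",
    "Iridoviridae",
    "Asfarviridae",
    "Poxviridae",
)

_CODONS = {
    "A": ("GCT", "GCC", "GCA", "GCG"), "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"), "E": ("GAA", "GAG"), "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"), "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"), "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"), "M": ("ATG",),
    "N": ("AAT", "AAC"), "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"), "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"), "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",), "Y": ("TAT", "TAC"),
}
_STOP_SPACER = "TAATAGTGA"  # keeps translated genes as separate ORFs


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _mutate_protein(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in AA20 if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def back_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(_CODONS[a][rng.integers(len(_CODONS[a]))] for a in protein)


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimTaxonomy:
    """A rooted labeled taxonomy with the four domains at level 1 and the
    NCLDV families placed under Viruses."""

    leaves: tuple[Lineage, ...]
    depth: int
    branching: int
    seed: int

    def leaves_under(self, domain: str) -> list[Lineage]:
        return [l for l in self.leaves if l.domain == domain]


def make_taxonomy(seed: int, depth: int = 4, branching: int = 2) -> SimTaxonomy:
    """Deterministic random taxonomy: each domain carries a full
    ``branching``-ary subtree with ``branching**(depth-1)`` leaves.

    Under Viruses the level-2 clade containing the NCLDV families is named
    "dsDNA viruses, no RNA stage" and its children cycle through the NCLDV
    family names; everything else gets collision-free synthetic labels.
    """
    if depth < 2:
        raise ValueError("depth must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9001]))
    suffix = rng.integers(0, 16**4)
    leaves: list[Lineage] = []

    def expand(prefix: tuple[str, ...], level: int) -> None:
        if level == depth:
            leaves.append(Lineage(prefix))
            return
        for k in range(branching):
            if prefix[0] == "Viruses" and level == 1:
                label = (
                    "dsDNA viruses, no RNA stage"
                    if k == 0
                    else f"virus clade {k}.{suffix:04x}"
                )
            elif (
                prefix[0] == "Viruses"
                and level == 2
                and prefix[1] == "dsDNA viruses, no RNA stage"
            ):
                label = _NCLDV_FAMILY_CYCLE[k % len(_NCLDV_FAMILY_CYCLE)]
            else:
                label = f"{prefix[-1][:3]}.{level}.{k}.{suffix:04x}"
            expand(prefix + (label,), level + 1)

    for domain in ("Bacteria", "Archaea", "Eukaryota", "Viruses"):
        expand((domain,), 1)
    return SimTaxonomy(tuple(leaves), depth, branching, seed)


# ---------------------------------------------------------------------------
# markers, genomes, reference database
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimMarker:
    """A synthetic single-copy marker family with per-leaf variants."""

    name: str
    group: str  # "ncldv" or "cellular"
    length_aa: int
    ancestral: str
    variants: dict[str, str]  # lineage string -> leaf variant


@dataclass(frozen=True)
class SimGenome:
    lineage: Lineage
    seq: str
    # (marker_name, nt_start, nt_end) for every embedded marker gene
    marker_coords: tuple[tuple[str, int, int], ...]


@dataclass(frozen=True)
class SimCommunity:
    """Genomes with relative abundances and a planted NCLDV fraction.

    ``ncldv_fraction`` is the planted NCLDV:prokaryote *genome count*
    ratio; ``cells_per_ml`` the planted prokaryotic cell concentration.
    """

    genomes: tuple[SimGenome, ...]
    abundances: np.ndarray
    ncldv_fraction: float
    cells_per_ml: float

    def __post_init__(self) -> None:
        if not math.isclose(float(np.sum(self.abundances)), 1.0, rel_tol=1e-9):
            raise ValueError("abundances must sum to 1")


def _leaf_variants(
    rng: np.random.Generator,
    taxonomy: SimTaxonomy,
    leaves: Sequence[Lineage],
    ancestral: str,
    edge_rate: float,
) -> dict[str, str]:
    """Evolve a protein down the taxonomy: every internal edge applies a
    fixed substitution rate, so sibling leaves sit ~2*edge_rate apart."""
    node_seq: dict[tuple[str, ...], str] = {(): ancestral}

    def seq_for(path: tuple[str, ...]) -> str:
        if path not in node_seq:
            parent = seq_for(path[:-1])
            node_seq[path] = _mutate_protein(rng, parent, edge_rate)
        return node_seq[path]

    return {str(leaf): seq_for(leaf.ranks) for leaf in leaves}


def make_markers(
    taxonomy: SimTaxonomy,
    seed: int,
    n_ncldv: int = 6,
    n_cellular: int = 8,
    length_aa: int = 100,
    edge_rate: float = 0.10,
) -> list[SimMarker]:
    """Synthetic marker families: NCLDV markers evolve over the NCLDV
    leaves, cellular markers over all cellular leaves (single copy in all
    cellular organisms).  All markers share one nt gene length so that
    density ratios estimate genome ratios without length bias."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9002]))
    ncldv_leaves = [l for l in taxonomy.leaves_under("Viruses") if _is_ncldv_leaf(l)]
    cellular_leaves = [
        l
        for d in ("Bacteria", "Archaea", "Eukaryota")
        for l in taxonomy.leaves_under(d)
    ]
    markers = []
    for i in range(n_ncldv):
        anc = _random_protein(rng, length_aa)
        markers.append(
            SimMarker(
                name=f"ncldv_marker_{i}",
                group="ncldv",
                length_aa=length_aa,
                ancestral=anc,
                variants=_leaf_variants(rng, taxonomy, ncldv_leaves, anc, edge_rate),
            )
        )
    for i in range(n_cellular):
        anc = _random_protein(rng, length_aa)
        markers.append(
            SimMarker(
                name=f"cellular_marker_{i}",
                group="cellular",
                length_aa=length_aa,
                ancestral=anc,
                variants=_leaf_variants(rng, taxonomy, cellular_leaves, anc, edge_rate),
            )
        )
    return markers


def _is_ncldv_leaf(lineage: Lineage) -> bool:
    from .model import NCLDV_FAMILIES

    return any(r in NCLDV_FAMILIES for r in lineage.ranks)


def profiles_from_markers(markers: Sequence[SimMarker]) -> list[MarkerProfile]:
    """Position-score profiles built from each marker's variant alignment
    (substitution-only evolution keeps variants aligned)."""
    return [
        MarkerProfile(
            name=m.name,
            group=m.group,
            pssm=pssm_from_sequences(list(m.variants.values())),
        )
        for m in markers
    ]


def make_reference_db(
    taxonomy: SimTaxonomy,
    markers: Sequence[SimMarker],
    seed: int,
    n_proteins_per_leaf: int = 1,
    filler_len_aa: int = 100,
    leaves: Optional[Sequence[Lineage]] = None,
) -> tuple[ReferenceDB, dict[str, str]]:
    """Reference proteins for a set of leaves: each leaf contributes its
    marker variants plus ``n_proteins_per_leaf`` unrelated random proteins.

    Returns the db and a ground-truth map protein_id -> lineage string.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9003]))
    use_leaves = list(leaves) if leaves is not None else list(taxonomy.leaves)
    proteins: list[ReferenceProtein] = []
    truth: dict[str, str] = {}
    for li, leaf in enumerate(use_leaves):
        group = "viral" if leaf.domain == "Viruses" else "cellular"
        for m in markers:
            var = m.variants.get(str(leaf))
            if var is None:
                continue
            pid = f"L{li}_{m.name}"
            proteins.append(ReferenceProtein(pid, var, leaf, group))
            truth[pid] = str(leaf)
        for k in range(n_proteins_per_leaf):
            pid = f"L{li}_rand{k}"
            proteins.append(
                ReferenceProtein(pid, _random_protein(rng, filler_len_aa), leaf, group)
            )
            truth[pid] = str(leaf)
    return ReferenceDB(proteins), truth


def make_genome(
    rng: np.random.Generator,
    leaf: Lineage,
    markers: Sequence[SimMarker],
    extra_proteins: Sequence[str],
) -> SimGenome:
    """Concatenate back-translated genes separated by stop-codon spacers -
    one copy of each applicable marker per genome.

    Filler genes flank the marker block so that every marker sits in the
    genome interior and all markers see the same read-capture window
    (markers at a sequence end would be reached by fewer read placements).
    """
    first_fill = list(extra_proteins[:1])
    rest_fill = list(extra_proteins[1:])
    genes: list[tuple[Optional[str], str]] = [(None, p) for p in first_fill]
    for m in markers:
        var = m.variants.get(str(leaf))
        if var is not None:
            genes.append((m.name, var))
    genes.extend((None, p) for p in rest_fill)
    parts = []
    coords = []
    pos = 0
    for name, prot in genes:
        gene = back_translate(rng, prot)
        if name is not None:
            coords.append((name, pos, pos + len(gene)))
        parts.append(gene)
        pos += len(gene)
        parts.append(_STOP_SPACER)
        pos += len(_STOP_SPACER)
    return SimGenome(leaf, "".join(parts), tuple(coords))


@dataclass(frozen=True)
class CommunityBundle:
    """Everything one desk-scale study needs: taxonomy, markers, profiles,
    a lineage-annotated reference db with ground truth, and the community."""

    taxonomy: SimTaxonomy
    markers: tuple[SimMarker, ...]
    profiles: tuple[MarkerProfile, ...]
    db: ReferenceDB
    truth: dict[str, str]
    community: SimCommunity


def make_community(
    seed: int,
    ncldv_fraction: float = 0.03,
    cells_per_ml: float = 1.0e6,
    n_bacteria: int = 3,
    n_archaea: int = 1,
    n_eukaryota: int = 1,
    n_ncldv: int = 2,
    eukaryote_fraction: float = 0.02,
    n_ncldv_markers: int = 6,
    n_cellular_markers: int = 4,
    marker_len_aa: int = 100,
    prok_filler_genes: int = 8,
    viral_filler_genes: int = 2,
    strains_per_taxon: int = 6,
) -> CommunityBundle:
    """Build a full synthetic study: genomes carry one copy of each
    applicable marker; NCLDV genomes are present at ``ncldv_fraction`` of
    the prokaryotic genome count and eukaryotes at ``eukaryote_fraction``.

    Each taxon is represented by ``strains_per_taxon`` co-abundant strain
    genomes: identical proteins, independent codon choices.  Synonymous
    divergence keeps independent same-start reads from clustering with one
    another in the duplicate filter, as in real communities where the
    sequenced genome space dwarfs the read count.
    """
    taxonomy = make_taxonomy(seed)
    markers = make_markers(
        taxonomy, seed, n_ncldv=n_ncldv_markers, n_cellular=n_cellular_markers,
        length_aa=marker_len_aa,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9004]))

    chosen: list[Lineage] = []
    for domain, n in (
        ("Bacteria", n_bacteria),
        ("Archaea", n_archaea),
        ("Eukaryota", n_eukaryota),
    ):
        pool = taxonomy.leaves_under(domain)
        idx = rng.choice(len(pool), size=min(n, len(pool)), replace=False)
        chosen.extend(pool[i] for i in sorted(idx))
    ncldv_pool = [l for l in taxonomy.leaves_under("Viruses") if _is_ncldv_leaf(l)]
    idx = rng.choice(len(ncldv_pool), size=min(n_ncldv, len(ncldv_pool)), replace=False)
    chosen.extend(ncldv_pool[i] for i in sorted(idx))

    db, truth = make_reference_db(taxonomy, markers, seed, leaves=chosen)

    genomes = []
    weights = []
    n_prok = n_bacteria + n_archaea
    for leaf in chosen:
        if leaf.domain == "Viruses":
            filler_n, w = viral_filler_genes, ncldv_fraction / n_ncldv
        elif leaf.domain == "Eukaryota":
            filler_n, w = prok_filler_genes, eukaryote_fraction / max(n_eukaryota, 1)
        else:
            filler_n, w = prok_filler_genes, 1.0 / n_prok
        filler = [_random_protein(rng, 100) for _ in range(filler_n)]
        for _ in range(strains_per_taxon):
            genomes.append(make_genome(rng, leaf, markers, filler))
            weights.append(w / strains_per_taxon)
    abundances = np.asarray(weights, dtype=float)
    abundances /= abundances.sum()
    community = SimCommunity(
        genomes=tuple(genomes),
        abundances=abundances,
        ncldv_fraction=ncldv_fraction,
        cells_per_ml=cells_per_ml,
    )
    return CommunityBundle(
        taxonomy, tuple(markers), tuple(profiles_from_markers(markers)),
        db, truth, community,
    )


def make_flat_community(
    seed: int,
    n_genomes: int = 4,
    genome_len: int = 500_000,
    cells_per_ml: float = 1.0e6,
) -> SimCommunity:
    """Marker-free community of large random genomes.

    With a genome space this large, two independently drawn reads almost
    never share a 5' start, so the only near-identical same-start reads in
    a simulated sample are the injected artificial duplicates - the right
    substrate for scoring duplicate removal against the planted rate.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9007]))
    genomes = []
    for i in range(n_genomes):
        arr = rng.integers(0, 4, size=genome_len)
        seq = _NT[arr].tobytes().decode("ascii")
        genomes.append(
            SimGenome(Lineage(("Bacteria", f"FlatTaxon_{i}")), seq, ())
        )
    return SimCommunity(
        genomes=tuple(genomes),
        abundances=np.full(n_genomes, 1.0 / n_genomes),
        ncldv_fraction=0.0,
        cells_per_ml=cells_per_ml,
    )


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadOrigin:
    read_id: str
    genome_index: int
    start: int
    is_duplicate: bool
    exemplar_id: Optional[str]
    n_mutations: int


@dataclass(frozen=True)
class SimReadSet:
    reads: tuple[NucRead, ...]
    origins: dict[str, ReadOrigin]
    duplication_rate: float
    error_rate: float
    seed: int


_NT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate_nt(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _NT[_NT != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode("ascii"), len(hits)


def simulate_sample(
    community: SimCommunity,
    n_reads: int,
    sample_id: str = "sim",
    read_len: int = 350,
    error_rate: float = 0.005,
    dup_rate: float = 0.16,
    depth_zone: str = "SRF",
    cell_count_sigma: float = 0.05,
    seed: int = 0,
) -> tuple[SimReadSet, SampleStats, CellCounts]:
    """Draw reads from the community (genomes weighted by abundance x
    length, uniform start positions, uniform substitution errors) and
    inject 454-style artificial duplicates: a duplicate re-reads an
    earlier read's template from the same 5' start with small extra
    divergence and is flagged in the provenance map.

    The measured cell count is the planted concentration with lognormal
    noise of the given sigma.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9005]))
    glens = np.array([len(g.seq) for g in community.genomes], dtype=float)
    w = community.abundances * glens
    w /= w.sum()
    n_dup = int(round(n_reads * dup_rate))
    n_unique = n_reads - n_dup

    def extract(genome_seq: str, start: int, length: int) -> str:
        # genomes are treated as circular (as bacterial chromosomes and
        # NCLDV genomes typically are): every position is covered by the
        # same number of read placements, so read yield per genome region
        # is exactly proportional to abundance x length
        end = start + length
        if end <= len(genome_seq):
            return genome_seq[start:end]
        return genome_seq[start:] + genome_seq[: end - len(genome_seq)]

    reads: list[NucRead] = []
    origins: dict[str, ReadOrigin] = {}
    templates: list[tuple[int, int, int]] = []  # genome, start, length
    for i in range(n_unique):
        g = int(rng.choice(len(glens), p=w))
        gl = len(community.genomes[g].seq)
        length = min(read_len, gl)
        start = int(rng.integers(0, gl))
        raw = extract(community.genomes[g].seq, start, length)
        seq, nmut = _mutate_nt(rng, raw, error_rate)
        rid = f"{sample_id}_r{i}"
        reads.append(NucRead(rid, sample_id, seq))
        origins[rid] = ReadOrigin(rid, g, start, False, None, nmut)
        templates.append((g, start, length))
    for j in range(n_dup):
        src = int(rng.integers(0, n_unique)) if n_unique else 0
        g, start, length = templates[src]
        # duplicates share the 5' start; length may shrink a little
        length = max(length - int(rng.integers(0, max(length // 20, 1))), 30)
        raw = extract(community.genomes[g].seq, start, length)
        # total divergence from the exemplar (its errors plus ours) stays
        # well inside the >=97% identity criterion that defines the artifact
        extra = rng.uniform(0.0, 0.008)
        seq, nmut = _mutate_nt(rng, raw, error_rate + extra)
        rid = f"{sample_id}_d{j}"
        reads.append(NucRead(rid, sample_id, seq))
        origins[rid] = ReadOrigin(rid, g, start, True, f"{sample_id}_r{src}", nmut)
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    stats = SampleStats(
        sample_id=sample_id,
        total_bp=sum(len(r) for r in reads),
        n_reads=len(reads),
        depth_zone=depth_zone,
    )
    c = community.cells_per_ml * float(
        np.exp(rng.normal(0.0, cell_count_sigma))
    )
    counts = CellCounts(sample_id=sample_id, fc_cells_per_ml=c)
    return (
        SimReadSet(tuple(reads), origins, dup_rate, error_rate, seed),
        stats,
        counts,
    )


# ---------------------------------------------------------------------------
# coupled count matrices for the network stage
# ---------------------------------------------------------------------------


def make_coupled_matrix(
    n_taxa: int,
    n_samples: int,
    coupled_pairs: int = 2,
    effect: float = 2.0,
    seed: int = 0,
    base_mean: float = 30.0,
    overdispersion_sigma: float = 0.7,
) -> tuple[TaxonSampleMatrix, list[tuple[str, str]]]:
    """Lognormal-Poisson counts with planted coupled taxon pairs.

    Baseline: count(i, j) ~ Poisson(exp(m_i + sigma * eps_ij)) with
    independent eps.  Each coupled pair shares a per-sample latent factor
    g_pj scaled by ``effect`` in the log-rate, so its two rows co-vary;
    ``effect`` = 0 plants nothing.  Returns the matrix (rows are sibling
    lineages, so no parent-child exclusions apply) and the planted edges.
    """
    if n_samples < 6:
        raise ValueError("need n_samples >= 6")
    if 2 * coupled_pairs > n_taxa:
        raise ValueError("too many coupled pairs for n_taxa")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9006]))
    m = np.log(base_mean) + rng.normal(0.0, 0.5, size=n_taxa)
    log_rate = m[:, None] + overdispersion_sigma * rng.normal(
        0.0, 1.0, size=(n_taxa, n_samples)
    )
    truth = []
    taxa = [f"Bacteria; SimTaxon_{i:03d}" for i in range(n_taxa)]
    for p in range(coupled_pairs):
        i, j = 2 * p, 2 * p + 1
        # bounded shared factor: an unbounded one would zero out most
        # samples at large effects and destroy the rank signal
        g = rng.uniform(-1.0, 1.0, size=n_samples)
        log_rate[i] += effect * g
        log_rate[j] += effect * g
        truth.append((taxa[i], taxa[j]))
    counts = rng.poisson(np.exp(log_rate)).astype(float)
    df = pd.DataFrame(counts, index=taxa, columns=[f"s{j}" for j in range(n_samples)])
    zones = {f"s{j}": "SRF" for j in range(n_samples)}
    totals = {f"s{j}": int(counts[:, j].sum()) for j in range(n_samples)}
    return TaxonSampleMatrix(df, zones, totals), truth
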