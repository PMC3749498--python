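"""Domain types shared by every pipeline stage.

The unit of analysis is a pyrosequencing read from a size-fractionated
(0.2-1.6 um) marine metagenome.  Taxonomy is represented as NCBI-style
semicolon-delimited lineage paths (e.g. ``Viruses; dsDNA viruses, no RNA
stage; Mimiviridae``); all taxonomic reasoning in the package is prefix
algebra on these paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

NUC_ALPHABET = frozenset("ACGTN")

#: Top-level labels treated as domains of life (viruses counted as a domain).
DOMAINS = ("Bacteria", "Archaea", "Eukaryota", "Viruses")

#: Families making up the nucleo-cytoplasmic large DNA virus (NCLDV) group.
#: "Megaviridae" is the proposed name for the family containing Mimivirus;
#: NCBI prints the node as "Mimiviridae", so both spellings are recognized.
NCLDV_FAMILIES = (
    "Megaviridae",
    "Mimiviridae",
    "Phycodnaviridae",
    "Marseilleviridae",
    "Iridoviridae",
    "Ascoviridae",
    "Asfarviridae",
    "Poxviridae",
)


class LineageFormatError(ValueError):
    """Raised for malformed semicolon lineage strings."""


@dataclass(frozen=True)
class Lineage:
    """An ordered taxonomy path from the root.

    ``ranks`` holds labels from the most general (domain) downward.  The
    empty lineage (``ranks == ()``) is the root and is an ancestor of every
    lineage.
    """

    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        for r in self.ranks:
            if not r:
                raise LineageFormatError("empty label in lineage")

    @property
    def depth(self) -> int:
        return len(self.ranks)

    @property
    def domain(self) -> Optional[str]:
        return self.ranks[0] if self.ranks else None

    def truncate(self, depth: int) -> "Lineage":
        return Lineage(self.ranks[:depth])

    def prefixes(self, max_depth: Optional[int] = None) -> Iterable["Lineage"]:
        """Yield every non-root ancestor-or-self, optionally capped at a depth."""
        stop = self.depth if max_depth is None else min(max_depth, self.depth)
        for d in range(1, stop + 1):
            yield Lineage(self.ranks[:d])

    def __str__(self) -> str:
        return "; ".join(self.ranks)


ROOT = Lineage(())


def parse_lineage(text: str, sep: str = ";") -> Lineage:
    """Parse a semicolon-delimited lineage path.

    Labels are stripped of surrounding whitespace; a single trailing
    separator (as printed in some NCBI dumps) is tolerated, but an empty
    label *between* separators is a format error.
    """
    if not text or not text.strip():
        raise LineageFormatError("empty lineage string")
    raw = text.strip()
    if raw.endswith(sep):
        raw = raw[: -len(sep)]
    labels = [label.strip() for label in raw.split(sep)]
    if any(not label for label in labels):
        raise LineageFormatError(f"empty label in lineage: {text!r}")
    return Lineage(tuple(labels))


def is_ancestor(a: Lineage, b: Lineage) -> bool:
    """True iff ``a`` is an ancestor-or-equal of ``b`` (prefix relation)."""
    return a.ranks == b.ranks[: a.depth]


def lca(lineages: Iterable[Lineage]) -> Lineage:
    """Last common ancestor: the longest common prefix of all lineages.

    Returns the root lineage when even the domains disagree.  Raises on an
    empty input because the LCA of nothing is undefined.
    """
    it = iter(lineages)
    try:
        first = next(it)
    except StopIteration:
        raise ValueError("lca() of an empty set of lineages")
    common = list(first.ranks)
    for lin in it:
        limit = min(len(common), lin.depth)
        i = 0
        while i < limit and common[i] == lin.ranks[i]:
            i += 1
        del common[i:]
        if not common:
            break
    return Lineage(tuple(common))


@dataclass(frozen=True)
class NucRead:
    """One metagenomic read (nucleotide, uppercase ACGTN)."""

    read_id: str
    sample_id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.read_id}: empty sequence")
        bad = set(self.seq) - NUC_ALPHABET
        if bad:
            raise ValueError(
                f"read {self.read_id}: illegal nucleotide(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReferenceProtein:
    """A lineage-annotated reference protein (UniProt-style entry)."""

    protein_id: str
    seq: str
    lineage: Lineage
    source_group: str = "cellular"  # "viral" or "cellular"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"protein {self.protein_id}: empty sequence")
        if self.lineage.depth < 1:
            raise ValueError(f"protein {self.protein_id}: rootless lineage")
        if self.source_group not in ("viral", "cellular"):
            raise ValueError(f"protein {self.protein_id}: bad source_group")


@dataclass(frozen=True)
class SampleStats:
    """Per-sample sequencing totals and the depth zone of the cast."""

    sample_id: str
    total_bp: int
    n_reads: int
    depth_zone: str  # SRF, DCM or OMZ

    def __post_init__(self) -> None:
        if self.total_bp < self.n_reads:
            raise ValueError(
                f"sample {self.sample_id}: total_bp < n_reads is impossible"
            )
        if self.depth_zone not in ("SRF", "DCM", "OMZ"):
            raise ValueError(
                f"sample {self.sample_id}: depth_zone must be SRF/DCM/OMZ"
            )


@dataclass(frozen=True)
class CellCounts:
    """Prokaryotic cell concentrations used to rescale relative abundances.

    ``passthrough_fraction`` is the assumed fraction of prokaryotic cells
    passing the 1.6-um glass-fiber pre-filter (default 0.9).
    """

    sample_id: str
    fc_cells_per_ml: Optional[float] = None
    microscopy_cells_per_ml: Optional[float] = None
    passthrough_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 < self.passthrough_fraction <= 1.0:
            raise ValueError("passthrough_fraction must be in (0, 1]")
        for v in (self.fc_cells_per_ml, self.microscopy_cells_per_ml):
            if v is not None and v < 0:
                raise ValueError("cell counts must be >= 0")

    @property
    def any_count(self) -> Optional[float]:
        """Flow-cytometry count when present, else microscopy."""
        if self.fc_cells_per_ml is not None:
            return self.fc_cells_per_ml
        return self.microscopy_cells_per_ml


class ReferenceDB:
    """An indexed, lineage-annotated protein reference set."""

    def __init__(self, proteins: Iterable[ReferenceProtein]):
        self._by_id: dict[str, ReferenceProtein] = {}
        for p in proteins:
            if p.protein_id in self._by_id:
                raise ValueError(f"duplicate protein id {p.protein_id!r}")
            self._by_id[p.protein_id] = p
        # stable, lexically sorted order so search tie-breaks are deterministic
        self._order = sorted(self._by_id)
        self.total_letters = sum(len(p.seq) for p in self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._by_id

    def __getitem__(self, protein_id: str) -> ReferenceProtein:
        return self._by_id[protein_id]

    def __iter__(self):
        for pid in self._order:
            yield self._by_id[pid]

    @property
    def ids(self) -> list[str]:
        return list(self._order)

    def lineage_of(self, protein_id: str) -> Lineage:
        return self._by_id[protein_id].lineage

    def subset(self, predicate) -> "ReferenceDB":
        return ReferenceDB(p for p in self if predicate(p))
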