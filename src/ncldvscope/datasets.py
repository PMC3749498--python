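"""Bundled study metadata.

The quality-controlled per-sample sequencing totals of the 17 Tara Oceans
0.2-1.6 um metagenomes (sample name, depth zone, total bp, read count, G+C%,
average read size, predicted ORF counts) are shipped as a small TSV so that
per-Mbp densities and sanity checksums can be computed without any download.
The raw reads themselves live in the Sequence Read Archive (ERA155562,
ERA155563) and are not bundled.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .model import SampleStats


def load_top_sample_table() -> pd.DataFrame:
    """The per-sample sequencing summary of the 17 study metagenomes."""
    with resources.files("ncldvscope.data").joinpath("top_samples.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def top_sample_stats() -> dict[str, SampleStats]:
    """The bundled table as :class:`~ncldvscope.model.SampleStats` objects."""
    df = load_top_sample_table()
    return {
        row.sample_id: SampleStats(
            sample_id=str(row.sample_id),
            total_bp=int(row.total_bp),
            n_reads=int(row.n_reads),
            depth_zone=str(row.depth_zone),
        )
        for row in df.itertuples()
    }


def total_sequenced_bp() -> int:
    """Sum of the per-sample total sizes (the data set is ~2.8 billion bp)."""
    return int(load_top_sample_table()["total_bp"].sum())


#: where a user can place the study's deposited 712-taxa x 17-sample
#: read-count matrix (supplementary data; not redistributable here)
SUPPLEMENTARY_MATRIX_PATH = "data/top_taxon_sample_matrix.tsv"


def reproduce_supplementary_analysis(matrix_path) -> dict:
    """Re-run the first co-occurrence screen on the study's deposited
    taxon x sample matrix.

    Returns the number of taxa surviving the <5-reads filter, the Spearman
    correlation between the Mimiviridae and Oomycetes rows, and the number
    of method-1 associations at q < 0.05.
    """
    from .network import (
        NetworkParams,
        TaxonSampleMatrix,
        filter_and_normalize,
        method1_pipeline,
    )

    zones = {s.sample_id: s.depth_zone for s in top_sample_stats().values()}
    matrix = TaxonSampleMatrix.from_tsv(matrix_path, zones=zones)
    filtered = filter_and_normalize(matrix, min_total_reads=5)

    def find_row(suffix):
        hits = [t for t in filtered.taxa if t.rstrip(". ").endswith(suffix)]
        if len(hits) != 1:
            raise ValueError(f"expected one row ending in {suffix!r}, got {hits}")
        return hits[0]

    mimi = find_row("Mimiviridae")
    oomy = find_row("Oomycetes") if any(
        t.rstrip(". ").endswith("Oomycetes") for t in filtered.taxa
    ) else find_row("oomycetes")
    from .network import _spearman_with_p

    norm = filtered.normalized
    rho, _ = _spearman_with_p(norm.loc[mimi].values, norm.loc[oomy].values)
    edges = method1_pipeline(matrix, NetworkParams())
    n_assoc = sum(1 for e in edges if e.q < 0.05)
    return {
        "n_taxa_filtered": len(filtered.taxa),
        "rho_mimiviridae_oomycetes": rho,
        "n_method1_q05": n_assoc,
    }
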