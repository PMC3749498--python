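"""Taxon co-occurrence network inference on compositional count matrices.

Two complementary approaches are implemented:

* **Method 1** - Spearman rank correlation between all taxon pairs across
  all samples, two-sided p-values from the asymptotic t approximation, and
  a tail-area false discovery rate (q-values, Grenander-based null
  proportion estimate).  An association passes at |rho| > 0.7 and q < 0.05.

* **Method 2** - a more stringent protocol on a reduced sample set
  (OMZ casts excluded) and with parent-child taxon pairs removed: edges
  are scored by Spearman (rho') and by symmetrized Kullback-Leibler
  divergence; the top- and bottom-ranking edges per measure are evaluated
  against a permutation-renormalization ("ReBoot") null that preserves the
  compositional bias introduced by normalizing counts to column totals;
  the two per-measure p-values are combined with Brown's method for
  dependent tests and corrected by Benjamini-Hochberg (q'-values).

Relative abundances are compositional: normalizing to a fixed total
induces spurious negative correlation, which is why the null permutes taxon
rows and *then* renormalizes columns instead of permuting normalized
values directly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotate import STATUS_ASSIGNED, TaxonAssignment
from .model import Lineage, is_ancestor, parse_lineage

log = logging.getLogger(__name__)


class TaxonSampleMatrix:
    """Read counts per taxonomy node (rows) per sample (columns).

    Rows are lineage path strings; a read assigned at or below a node
    counts toward that node, so rows are hierarchically nested.  The
    ``normalized`` view divides each column by its column total (the
    compositional view used for network inference); ``relative_abundance``
    divides by the per-sample total read count when sample totals are
    known.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        zones: Optional[dict[str, str]] = None,
        sample_totals: Optional[dict[str, int]] = None,
    ):
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(float)
        self.zones = dict(zones or {})
        self.sample_totals = dict(sample_totals or {})

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def normalized(self) -> pd.DataFrame:
        colsums = self.counts.sum(axis=0)
        safe = colsums.replace(0, np.nan)
        return self.counts.div(safe, axis=1).fillna(0.0)

    def relative_abundance(self) -> pd.DataFrame:
        if not self.sample_totals:
            raise ValueError("sample totals unknown")
        totals = pd.Series(self.sample_totals, dtype=float)
        return self.counts.div(totals[self.counts.columns], axis=1)

    def drop_zones(self, zones: set[str]) -> "TaxonSampleMatrix":
        keep = [s for s in self.samples if self.zones.get(s) not in zones]
        return TaxonSampleMatrix(
            self.counts[keep], self.zones, self.sample_totals
        )

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "lineage"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        path,
        zones: Optional[dict[str, str]] = None,
        sample_totals: Optional[dict[str, int]] = None,
    ) -> "TaxonSampleMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, zones, sample_totals)


def build_matrix(
    assignments_by_sample: dict[str, Sequence[TaxonAssignment]],
    depth: int = 5,
    zones: Optional[dict[str, str]] = None,
    sample_totals: Optional[dict[str, int]] = None,
) -> TaxonSampleMatrix:
    """Aggregate 2bLCA assignments into a taxon x sample count matrix.

    Rows are all taxonomy nodes of depth <= ``depth`` receiving at least
    one read *at or below* themselves in any sample; a read assigned to a
    deeper lineage therefore also counts toward every ancestor row.
    """
    counts: dict[str, dict[str, int]] = {}
    for sample_id, assignments in assignments_by_sample.items():
        for a in assignments:
            if a.status != STATUS_ASSIGNED or a.lineage is None:
                continue
            for node in a.lineage.prefixes(max_depth=depth):
                row = counts.setdefault(str(node), {})
                row[sample_id] = row.get(sample_id, 0) + 1
    samples = sorted(assignments_by_sample)
    df = pd.DataFrame(
        [[counts.get(t, {}).get(s, 0) for s in samples] for t in sorted(counts)],
        index=sorted(counts),
        columns=samples,
        dtype=float,
    )
    if sample_totals is None:
        sample_totals = {s: len(assignments_by_sample[s]) for s in samples}
    return TaxonSampleMatrix(df, zones, sample_totals)


def filter_and_normalize(
    matrix: TaxonSampleMatrix, min_total_reads: int = 5
) -> TaxonSampleMatrix:
    """Drop taxa with fewer than ``min_total_reads`` reads in total.

    The threshold is strict (< 5 dropped, exactly 5 kept).  Columns of the
    normalized view re-normalize automatically after the drop.
    """
    totals = matrix.counts.sum(axis=1)
    keep = totals[totals >= min_total_reads].index
    return TaxonSampleMatrix(
        matrix.counts.loc[keep], matrix.zones, matrix.sample_totals
    )


@dataclass(frozen=True)
class Edge:
    """A taxon-pair association with statistics from both methods."""

    taxon_a: str
    taxon_b: str
    rho: Optional[float] = None
    p: Optional[float] = None
    q: Optional[float] = None
    rho_prime: Optional[float] = None
    kl: Optional[float] = None
    p_rho: Optional[float] = None
    p_kl: Optional[float] = None
    p_combined: Optional[float] = None
    q_prime: Optional[float] = None
    method1_pass: bool = False
    method2_pass: bool = False


@dataclass(frozen=True)
class NetworkParams:
    min_total_reads: int = 5
    depth: int = 5
    rho_min: float = 0.7
    q_max: float = 0.05
    n_perm: int = 1000
    n_boot: int = 1000
    top_k: int = 1000
    exclude_zones: frozenset[str] = frozenset({"OMZ"})
    seed: int = 0
    reboot_z_mode: str = "null_sd"  # or "pooled"


def _spearman_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with the two-sided asymptotic
    t-approximation p-value; rho = +-1 maps to p = 0."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return float("nan"), float("nan")
    rho = float(rx @ ry) / denom
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def spearman_edges(matrix: TaxonSampleMatrix) -> list[Edge]:
    """Spearman rho and p for every unordered taxon pair (method 1 scores).

    Pairs involving a constant row are skipped (rho undefined) and logged.
    """
    norm = matrix.normalized
    if norm.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    values = norm.values
    taxa = list(norm.index)
    constant = np.ptp(values, axis=1) == 0
    if constant.any():
        log.info("skipping %d constant taxa in spearman_edges", constant.sum())
    edges = []
    idx = [i for i in range(len(taxa)) if not constant[i]]
    for a_pos, i in enumerate(idx):
        for j in idx[a_pos + 1 :]:
            rho, p = _spearman_with_p(values[i], values[j])
            edges.append(Edge(taxon_a=taxa[i], taxon_b=taxa[j], rho=rho, p=p))
    return edges


def _pava_decreasing(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted pool-adjacent-violators fit of a non-increasing sequence."""
    vals = []
    weights = []
    for yi, wi in zip(y, w):
        vals.append(float(yi))
        weights.append(float(wi))
        while len(vals) > 1 and vals[-2] < vals[-1]:
            v = (vals[-1] * weights[-1] + vals[-2] * weights[-2]) / (
                weights[-1] + weights[-2]
            )
            wsum = weights[-1] + weights[-2]
            vals = vals[:-2] + [v]
            weights = weights[:-2] + [wsum]
    # expand blocks back to element level
    out_list = []
    i = 0
    for v, wsum in zip(vals, weights):
        # number of elements in this block: accumulate original weights
        acc = 0.0
        count = 0
        while i < len(y) and acc < wsum - 1e-12:
            acc += w[i]
            i += 1
            count += 1
        out_list.extend([v] * count)
    return np.asarray(out_list)


def grenander_eta0(pvals: np.ndarray) -> float:
    """Estimate the null proportion eta0 as the Grenander decreasing
    density of the p-values (the slope of the least concave majorant of
    the ECDF) evaluated at the upper end of the p-value range."""
    p = np.sort(np.asarray(pvals, dtype=float))
    m = len(p)
    if m == 0:
        return 1.0
    uniq, counts = np.unique(p, return_counts=True)
    knots = np.concatenate(([0.0], uniq))
    cum = np.concatenate(([0.0], np.cumsum(counts) / m))
    widths = np.diff(knots)
    if not len(widths) or widths[-1] == 0:
        return 1.0  # every p-value is zero
    slopes = np.diff(cum) / widths
    fitted = _pava_decreasing(slopes, widths)
    # evaluate the pooled density in the upper range rather than at the
    # very last knot (a single wide terminal gap makes that estimate wild)
    eval_at = min(0.75, float(knots[-1]))
    idx = int(np.searchsorted(knots[1:], eval_at, side="left"))
    idx = min(idx, len(fitted) - 1)
    return float(min(1.0, max(0.0, fitted[idx])))


def tail_area_qvalues(pvals: Sequence[float]) -> np.ndarray:
    """Tail-area false discovery rate (q-values).

    q(p) = eta0 * p * m / rank(p), clipped to [0, 1] and made monotone
    non-decreasing in p, with eta0 the Grenander-based estimate of the
    proportion of true nulls.  With eta0 = 1 this is the Benjamini-Hochberg
    adjusted p-value.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    m = len(p)
    eta0 = grenander_eta0(p)
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(m)
    # ties get the largest rank of the tied block (tail area at that p)
    sorted_p = p[order]
    rank_vals = np.arange(1, m + 1, dtype=float)
    for i in range(m - 2, -1, -1):
        if sorted_p[i] == sorted_p[i + 1]:
            rank_vals[i] = rank_vals[i + 1]
    ranks[order] = rank_vals
    q = np.clip(eta0 * p * m / ranks, 0.0, 1.0)
    # enforce monotonicity: q non-decreasing in p
    q_sorted = q[order]
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q[order] = q_sorted
    return q


def kl_score(row_a: np.ndarray, row_b: np.ndarray, eps: float = 1e-9) -> float:
    """Symmetrized Kullback-Leibler divergence between two taxon profiles.

    Each row is shifted by a pseudocount and rescaled to a probability
    vector over samples; the score is 0.5*(KL(a||b) + KL(b||a)) >= 0.
    Low values rank as co-presence, high values as exclusion.
    """
    a = np.asarray(row_a, dtype=float) + eps
    b = np.asarray(row_b, dtype=float) + eps
    a = a / a.sum()
    b = b / b.sum()
    return float(0.5 * (np.sum(a * np.log(a / b)) + np.sum(b * np.log(b / a))))


def _measure_matrix(A: np.ndarray, B: np.ndarray, measure: str) -> np.ndarray:
    """Row-wise association measure between paired row-blocks A and B."""
    if measure == "spearman":
        ra = np.apply_along_axis(stats.rankdata, 1, A)
        rb = np.apply_along_axis(stats.rankdata, 1, B)
        ra = ra - ra.mean(axis=1, keepdims=True)
        rb = rb - rb.mean(axis=1, keepdims=True)
        denom = np.sqrt((ra * ra).sum(axis=1) * (rb * rb).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (ra * rb).sum(axis=1) / denom
        return np.where(denom == 0, 0.0, out)
    if measure == "kl":
        eps = 1e-9
        a = A + eps
        b = B + eps
        a = a / a.sum(axis=1, keepdims=True)
        b = b / b.sum(axis=1, keepdims=True)
        return 0.5 * (
            (a * np.log(a / b)).sum(axis=1) + (b * np.log(b / a)).sum(axis=1)
        )
    raise ValueError("measure must be 'spearman' or 'kl'")


def reboot_edge(
    matrix: TaxonSampleMatrix,
    taxon_a: str,
    taxon_b: str,
    measure: str = "spearman",
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
    z_mode: str = "null_sd",
) -> float:
    """Permutation-renormalization ("ReBoot") p-value for one edge.

    Null distribution: the two taxon *count* rows are independently
    permuted across samples while the rest of the matrix is unchanged,
    every column is renormalized (restoring the compositional bias), and
    the measure is recomputed - ``n_perm`` times.  Bootstrap distribution:
    sample columns are resampled with replacement and the measure
    recomputed - ``n_boot`` times.  The p-value is the two-sided normal
    tail of the z-score comparing the bootstrap mean against the null
    (``z_mode='null_sd'``: z = (mean_boot - mean_null)/sd_null;
    ``z_mode='pooled'``: z = (mean_boot - mean_null)/sqrt(var_null +
    var_boot)).  A degenerate (constant) null yields p = 1.
    """
    counts = matrix.counts
    a = counts.loc[taxon_a].values.astype(float)
    b = counts.loc[taxon_b].values.astype(float)
    colsums = counts.values.sum(axis=0)
    rest = colsums - a - b
    n = len(a)
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, abs(hash((taxon_a, taxon_b))) % (2**31)])
    )
    # --- null: permute rows, renormalize columns, rescore ---
    perm_a = np.array([rng.permutation(n) for _ in range(n_perm)])
    perm_b = np.array([rng.permutation(n) for _ in range(n_perm)])
    A = a[perm_a]
    B = b[perm_b]
    new_colsums = rest[None, :] + A + B
    safe = np.where(new_colsums == 0, 1.0, new_colsums)
    null_scores = _measure_matrix(A / safe, B / safe, measure)
    if __debug__ and n_perm > 0:
        # renormalized permuted matrix preserves the normalized column sums
        full = counts.values.copy()
        full[matrix.taxa.index(taxon_a)] = A[0]
        full[matrix.taxa.index(taxon_b)] = B[0]
        cs = full.sum(axis=0)
        renorm = full / np.where(cs == 0, 1.0, cs)
        assert np.all(np.abs(renorm.sum(axis=0)[cs > 0] - 1.0) < 1e-9)
    # --- bootstrap: resample columns with replacement ---
    norm_a = a / np.where(colsums == 0, 1.0, colsums)
    norm_b = b / np.where(colsums == 0, 1.0, colsums)
    boot_idx = rng.integers(0, n, size=(n_boot, n))
    boot_scores = _measure_matrix(norm_a[boot_idx], norm_b[boot_idx], measure)
    var_null = float(np.var(null_scores))
    if var_null == 0.0:
        log.info("degenerate ReBoot null for (%s, %s): p = 1", taxon_a, taxon_b)
        return 1.0
    delta = float(np.mean(boot_scores)) - float(np.mean(null_scores))
    if z_mode == "null_sd":
        z = delta / math.sqrt(var_null)
    elif z_mode == "pooled":
        z = delta / math.sqrt(var_null + float(np.var(boot_scores)))
    else:
        raise ValueError("z_mode must be 'null_sd' or 'pooled'")
    return float(2.0 * stats.norm.sf(abs(z)))


def combine_brown(
    p_rho: float, p_kl: float, covariance: float = 0.0
) -> float:
    """Brown's combination of two dependent p-values.

    Psi = -2(ln p_rho + ln p_kl) with E[Psi] = 4 and Var[Psi] = 8 + 2*cov,
    where cov is the covariance of the two -2 ln p statistics (estimated
    empirically across the candidate edge set).  P' is the upper tail of a
    scaled chi-square with scale c = Var/(2E) and f = 2E^2/Var degrees of
    freedom, evaluated at Psi/c.  cov = 0 reduces to Fisher's method.
    """
    tiny = np.finfo(float).tiny
    for p in (p_rho, p_kl):
        if not 0.0 <= p <= 1.0:
            raise ValueError("p-values must be in [0, 1]")
    if p_rho == 0.0 or p_kl == 0.0:
        log.info("zero p-value clipped to %.3g in Brown combination", tiny)
    p_rho = max(p_rho, tiny)
    p_kl = max(p_kl, tiny)
    psi = -2.0 * (math.log(p_rho) + math.log(p_kl))
    e = 4.0
    # each -2 ln p is chi-square(2) with variance 4 under the null, so a
    # valid covariance lies in [-4, 4]; empirical estimates from a
    # signal-enriched candidate set can exceed this and are clamped
    covariance = max(-4.0, min(4.0, covariance))
    var = 8.0 + 2.0 * covariance
    var = max(var, 1e-12)
    c = var / (2.0 * e)
    f = 2.0 * e * e / var
    return float(stats.chi2.sf(psi / c, df=f))


def brown_covariance(p_rho: Sequence[float], p_kl: Sequence[float]) -> float:
    """Empirical covariance of -2 ln p across candidate edges."""
    tiny = np.finfo(float).tiny
    x = -2.0 * np.log(np.maximum(np.asarray(p_rho, dtype=float), tiny))
    y = -2.0 * np.log(np.maximum(np.asarray(p_kl, dtype=float), tiny))
    if len(x) < 2:
        return 0.0
    return float(np.cov(x, y)[0, 1])


def method1_pipeline(
    matrix: TaxonSampleMatrix, params: NetworkParams = NetworkParams()
) -> list[Edge]:
    """All-sample Spearman screen with tail-area q-values."""
    filtered = filter_and_normalize(matrix, params.min_total_reads)
    edges = spearman_edges(filtered)
    if not edges:
        return []
    q = tail_area_qvalues([e.p for e in edges])
    out = []
    for e, qi in zip(edges, q):
        out.append(
            replace(
                e,
                q=float(qi),
                method1_pass=bool(abs(e.rho) > params.rho_min and qi < params.q_max),
            )
        )
    return out


def _parent_child(a: str, b: str) -> bool:
    la, lb = parse_lineage(a), parse_lineage(b)
    return is_ancestor(la, lb) or is_ancestor(lb, la)


def method2_pipeline(
    matrix: TaxonSampleMatrix, params: NetworkParams = NetworkParams()
) -> list[Edge]:
    """The stringent two-measure protocol with the ReBoot null.

    Steps: drop excluded-zone samples; score every non-parent-child,
    non-constant taxon pair by Spearman rho' and symmetrized KL; retain
    the union of the top_k and bottom_k edges per measure; ReBoot each
    retained edge per measure; combine the two p-values with Brown's
    method (covariance estimated across the candidate set); BH-correct to
    q'-values.
    """
    reduced = matrix.drop_zones(set(params.exclude_zones))
    reduced = filter_and_normalize(reduced, params.min_total_reads)
    if len(reduced.samples) < 3:
        raise ValueError("fewer than 3 samples remain after zone exclusion")
    norm = reduced.normalized
    values = norm.values
    taxa = list(norm.index)
    constant = np.ptp(values, axis=1) == 0
    scored: list[tuple[int, int, float, float]] = []
    for i in range(len(taxa)):
        if constant[i]:
            continue
        for j in range(i + 1, len(taxa)):
            if constant[j] or _parent_child(taxa[i], taxa[j]):
                continue
            rho, _ = _spearman_with_p(values[i], values[j])
            kl = kl_score(values[i], values[j])
            scored.append((i, j, rho, kl))
    if not scored:
        return []
    k = min(params.top_k, len(scored))
    by_rho = sorted(scored, key=lambda t: t[2])
    by_kl = sorted(scored, key=lambda t: t[3])
    candidates = {(t[0], t[1]) for t in by_rho[:k]} | {(t[0], t[1]) for t in by_rho[-k:]}
    candidates |= {(t[0], t[1]) for t in by_kl[:k]} | {(t[0], t[1]) for t in by_kl[-k:]}
    lookup = {(t[0], t[1]): (t[2], t[3]) for t in scored}
    cand = sorted(candidates)
    p_rho_list = []
    p_kl_list = []
    for i, j in cand:
        p_rho_list.append(
            reboot_edge(reduced, taxa[i], taxa[j], "spearman",
                        params.n_perm, params.n_boot, params.seed,
                        params.reboot_z_mode)
        )
        p_kl_list.append(
            reboot_edge(reduced, taxa[i], taxa[j], "kl",
                        params.n_perm, params.n_boot, params.seed,
                        params.reboot_z_mode)
        )
    cov = brown_covariance(p_rho_list, p_kl_list)
    p_comb = [
        combine_brown(pr, pk, cov) for pr, pk in zip(p_rho_list, p_kl_list)
    ]
    _, q_prime, _, _ = multipletests(p_comb, method="fdr_bh")
    edges = []
    for (i, j), pr, pk, pc, qp in zip(cand, p_rho_list, p_kl_list, p_comb, q_prime):
        rho, kl = lookup[(i, j)]
        edges.append(
            Edge(
                taxon_a=taxa[i],
                taxon_b=taxa[j],
                rho_prime=rho,
                kl=kl,
                p_rho=pr,
                p_kl=pk,
                p_combined=pc,
                q_prime=float(qp),
                method2_pass=bool(qp < params.q_max),
            )
        )
    return edges


def edges_frame(edges: Iterable[Edge]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in edges])


def export_graphml(edges: Iterable[Edge], path, passing_only: bool = True) -> None:
    """Write the association network as GraphML (taxa as nodes)."""
    import networkx as nx

    g = nx.Graph()
    for e in edges:
        if passing_only and not (e.method1_pass or e.method2_pass):
            continue
        attrs = {
            k: v for k, v in vars(e).items()
            if k not in ("taxon_a", "taxon_b") and v is not None
        }
        g.add_edge(e.taxon_a, e.taxon_b, **attrs)
    nx.write_graphml(g, str(path))
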