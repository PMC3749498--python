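# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not
demonstrate. No number below is asserted from memory: every empirical
claim is computed by the test suite or by `scripts/acceptance.py`.

## Duplicate removal

454 pyrosequencing emits artificial duplicates: re-reads of one template
sharing their 5′ start at near-perfect identity. The filter is a greedy
single-pass clustering: reads sorted by descending length (ties broken
lexically by id); a read joins the first retained exemplar that shares its
first `prefix_len` (default 5) nucleotides and aligns to the equally long
prefix of that exemplar at ≥ `min_identity` (default 0.97) global
identity, where identity = matching columns / alignment length of a
Needleman–Wunsch alignment (computed with edlib). Exemplars are kept,
members dropped, and each dropped read maps to exactly one exemplar. The
published tool this emulates does not document its tie-breaking; the
explicit order here makes the operation deterministic and idempotent.
Reads shorter than `prefix_len` have no well-defined start prefix and are
kept unconditionally (logged). Identity is anchored at position 0 because
the artifact being removed shares start points; a free local alignment
would also merge overlapping non-duplicate reads.

## Homology search and E-values

The built-in engine computes Smith–Waterman local alignments against every
database protein (BLOSUM62; gap of length k costs 11 + (k−1)·1) and
converts raw score S to E = K·m·n·e^(−λS) with the *ungapped*
Karlin–Altschul parameters for BLOSUM62 (λ = 0.3176, K = 0.134), m the
query length and n the database length in letters. Using ungapped
parameters for gapped alignments is deliberate: in this workflow absolute
E-values only gate fixed thresholds (10⁻⁵ for annotation, 10⁻³ for marker
scans) and define the adaptive 2bLCA cutoff, so internal consistency is
what matters, not parity with a particular external engine; users needing
engine parity can feed 12-column tabular output through
`load_tabular_hits`. One best HSP is kept per query–subject pair; equal
E-values break lexically by subject id so runs are reproducible. The
kernels are numba-compiled (a batch score-only scan plus a single-pair
traceback); the test suite cross-checks scores against Biopython's
independent C implementation and, at tiny sizes, a pure-Python dynamic
program.

Translated (BLASTx-like) search is defined as the union of protein
searches over all six-frame stop-free peptides of length ≥ `min_len_aa`
(default 20 for annotation), with coordinates mapped back to the forward
strand. The standard genetic code is used throughout: the bacterial code
differs only in start-codon handling, which is irrelevant for stop-free
stretches. `N` translates to `X`.

## 2bLCA annotation

Reads of length ≤ 100 bp are not annotated (`too_short`). A first
translated search (B1) at E ≤ 10⁻⁵ either fails (`no_hit`) or yields a
best HSP with E-value E\*. The subject residues inside that HSP — not the
read — are re-searched against the same database (B2), and every subject
with E ≤ E\* forms the homolog set H. This per-protein adaptive cutoff is
the method's core: a read matching a slowly evolving protein pulls in a
wide H and lands at a deep ancestor, a read matching a unique protein
keeps H = {best} and retains a specific lineage. The B2 query's own source
protein always satisfies E ≤ E\* and is asserted into H. The assignment is
the longest common prefix (LCA) of H's lineages; if H spans more than one
of Bacteria/Archaea/Eukaryota/Viruses the read is `ambiguous` (viruses
counted as a domain, since the downstream bins separate NCLDV from the
three cellular domains). Whether the original protocol collapsed multiple
HSPs per subject is unstated; H here has set-of-subjects semantics, one
best HSP each.

Binning: an assignment is NCLDV iff its domain is Viruses and any
configured NCLDV family label appears in the path (both the "Megaviridae"
and NCBI's "Mimiviridae" spellings are recognized); other viruses fall
outside the four bins and are logged, cellular domains map directly, and
ambiguous/no-hit pass through. A marker hit is counted in its *bin*, not
its profile's group, so a cellular-marker homolog carried by a virus
counts on the viral side.

## Marker profiles and densities

Profiles are position-specific score matrices: one row per reference
alignment column, log₂-odds of column residue probabilities against a
uniform 1/20 background (TSV format; HMMER3 profile HMMs can be converted
via their match emissions, dropping transitions — the built-in scorer is
ungapped). A peptide's score is its best ungapped window placement
(partial overlaps allowed); E = m·L·2^(−score) with m the peptide length
and L the profile length, thresholded at 10⁻³. One hit per (read, marker)
is kept at the best E.

Density is exactly d = hits·10⁶/total_bp per (sample, marker, bin), with
the gene-size-normalized variant d/L also computed (longer genes collect
more reads; dividing by the reference alignment length removes that).
Group summaries include zero densities for markers without hits —
omitting them would bias small samples upward. Per-sample ratios default
to the mean across markers; the pooled overview uses the median; both are
exposed. The prokaryote summary counts cellular-marker hits binned
Bacteria or Archaea; eukaryote-binned hits are excluded.

Rescaling is pure arithmetic: A = r·φ·C, with φ = 0.9 the assumed
fraction of prokaryotic cells passing a 1.6 µm glass-fiber pre-filter.
When both flow-cytometry and microscopy counts exist, two estimates are
emitted rather than averaged.

## Co-occurrence networks

The taxon × sample matrix counts, for every taxonomy node of depth ≤ 5
(nodes of *at most* the target depth, since published association tables
print taxa of varying depth), the reads annotated at or below that node.
Taxa with fewer than 5 total reads are dropped (strictly: 5 survives);
columns are then normalized to their totals, which closes the data
compositionally — the reason for the null model below.

**Method 1**: Spearman ρ with average ranks on the normalized rows, for
every pair of non-constant taxa; two-sided p from t = ρ√((n−2)/(1−ρ²))
with n−2 degrees of freedom (p = 0 at ρ = ±1); tail-area false-discovery
q-values. The q-value estimator fits the null proportion η₀ as the
Grenander decreasing-density estimate of the p-values — the left slope of
the least concave majorant of their ECDF, pooled by weighted isotonic
regression and evaluated at p = 0.75 rather than at the last knot (the
terminal-gap slope is wildly unstable) — then sets q(p) = η₀·p·m/rank(p),
clipped to [0,1] and made monotone. With η₀ = 1 this is exactly
Benjamini–Hochberg. Parent–child pairs are *not* excluded here (published
method-1 results contain such pairs).

**Method 2**: oxygen-minimum-zone samples are dropped (their biome
contrast otherwise dominates), parent–child pairs excluded, and all
remaining pairs scored by ρ′ and by symmetrized Kullback–Leibler
divergence of the pseudocounted (ε = 10⁻⁹), row-rescaled profiles (low KL
ranks as co-presence, high as exclusion). The union of the `top_k` top-
and bottom-ranking edges per measure is retained. For each retained edge
and measure, the ReBoot procedure builds a null by permuting the edge's
two *count* rows across samples, renormalizing every column (restoring
the compositional bias), and rescoring — `n_perm` times — and a bootstrap
distribution by resampling columns with replacement `n_boot` times. The
p-value is the two-sided normal tail of
z = (mean_boot − mean_null)/sd_null. A pooled-variance variant
(sd = √(var_null + var_boot)) is available but not the default: both
variances approximate the score's sampling variance, so pooling makes z
approximately N(0, ½) under independence and deflates the type-I rate to
~0.006 at the 0.05 level; the null-referenced form is calibrated (the
acceptance suite measures the empirical rate on independent rows and
requires [0.03, 0.08]). Degenerate (zero-variance) nulls report p = 1.

The two per-measure p-values are combined with Brown's method:
Ψ = −2(ln p_ρ + ln p_KL), E[Ψ] = 4, Var[Ψ] = 8 + 2·cov, with cov the
empirical covariance of the −2 ln p statistics across the candidate edge
set, clamped to [−4, 4] — the attainable range for two χ²₂ variables;
estimates outside it arise from selection inflation in the
signal-enriched candidate set and would invalidate the scaled-χ² fit
(c = Var/2E, f = 2E²/Var). cov = 0 recovers Fisher's method; cov = 4
makes the combination of two identical p-values return p itself.
Benjamini–Hochberg over the combined P′ gives q′; edges pass at
q′ < 0.05. With a fixed seed the whole method-2 output is bit-reproducible
(each edge draws from a seed sequence keyed by the run seed and the taxon
pair, so results are independent of candidate order).

`top_k` defaults to 1000 as in the large-matrix setting it was designed
for (≈0.5% of ~185k pairs); the desk-scale experiments use `top_k` = 10 of
435–1770 pairs, proportionally more generous.

## HGT screen

For each viral peptide, the best cellular homolog at E ≤ 10⁻⁵ (by E, then
bit score, then lexical id) is identified; that cellular protein is then
searched against the combined cellular+viral database with every subject
sharing its first three lineage labels masked (a query shallower than
three levels masks on its full depth), and the pair is a candidate iff
the best surviving hit is viral. A residual tie between a viral and a
cellular best hit rejects the candidate (conservative). Masking strength
decreases as the required prefix grows: raising `exclusion_levels` masks
fewer relatives, so the candidate set is monotone non-increasing in it —
and monotone non-increasing in a *stricter* E-value cutoff. Candidates
are a screen only; phylogenetic confirmation is out of scope.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of (parameters, seed) and label every
emitted entity with its ground truth.

*Taxonomy*: a balanced labeled tree (default depth 4, branching 2) with
the four domains at level 1 and the NCLDV families placed under a "dsDNA
viruses, no RNA stage" clade. *Markers*: protein families evolved down
the tree at 10% substitutions per edge (siblings ≈ 80% identity), one
ancestral sequence per family; profiles are built from the leaf-variant
alignments (substitution-only evolution keeps them aligned). All marker
genes share one length (100 aa = 300 nt) so the density-ratio estimator
is free of gene-length bias by construction. *Communities*: genomes are
concatenations of back-translated genes with stop-codon spacers — one
copy of each applicable marker, flanked by filler genes so every marker
sits in the genome interior and sees the same read-capture window.
Default scale: 3 bacterial + 1 archaeal + 1 eukaryotic + 2 NCLDV taxa, 6
NCLDV and 4 cellular marker families, prokaryote genomes ≈ 3.7 kb and
viral ≈ 2.5 kb, each taxon represented by 6 co-abundant strain genomes
(identical proteins, independent codon choices). The strain structure
matters: with only a few kb of distinct sequence, independent reads
frequently share an exact 5′ start at ≥97% identity and the duplicate
filter would preferentially remove high-coverage (prokaryote) reads;
synonymous strain divergence (~20–25% nt) restores the realistic
condition that only true re-reads look like duplicates. *Reads*: drawn
from genomes with probability ∝ abundance × length, start positions
uniform on the *circle* (bacterial chromosomes and NCLDV genomes are
typically circular; linear sampling would make per-bp coverage scale as
L/(L−readlen), biasing the viral:prokaryote ratio by ~5% at these genome
sizes). Default read length 350 bp (the study's per-sample averages span
~250–400 bp), uniform substitution errors at 0.5% per base; no
homopolymer indel model — 454 indel artifacts are out of scope beyond the
duplicate mechanism. Duplicates re-read an earlier template from the same
5′ start with up to ~2% total divergence, safely inside the ≥97%
criterion that defines the artifact, and may be slightly shorter.
Measured cell counts get 5% lognormal noise (flow-cytometry-scale
measurement error). *Count matrices*: independent lognormal-Poisson
counts (base mean 30, overdispersion σ = 0.7); each planted coupled pair
adds a shared per-sample factor, uniform on [−1, 1] scaled by `effect`,
to both rows' log-rates. The factor is bounded deliberately: an unbounded
Gaussian factor at large effects zero-inflates counts (shared-zero ties
destroy the rank signal), and a pair that dominates its column totals has
its shared signal cancelled by compositional closure (normalized value →
ε_a/(ε_a+ε_b)).

None of this mimics real marine taxon frequencies, real marker genes, or
real lineage-specific codon usage; passing the recovery experiments shows
the *pipeline* is correct and calibrated under its stated assumptions
(single-copy markers, equal marker detectability across groups,
compositional counts), not that those assumptions hold in any particular
ocean sample.

## Experiment sizes and statistical design

Chosen once, from power analysis, to fit a single CPU:

- *Annotation equivalence*: 50 reads (homologs at 0–10% divergence, exact
  back-translations, random reads, sub-100 bp reads) vs a 32-protein
  four-domain database; the oracle re-runs the full protocol on
  Biopython's aligner with the E-value arithmetic reproduced literally,
  so agreement is exact, not approximate.
- *Abundance recovery*: 20 samples at planted ratios 0.002–0.06 (the
  observed field range), 6 000 reads each. Viral marker hits number
  ≈ 4 600·f per sample; Poisson counting noise then predicts the lowest
  one or two fractions fall outside ±25% while ≥16/20 samples recover —
  which is what the experiment requires. Duplicate removal runs inside
  this pipeline at the default 16% planted rate.
- *Network calibration*: 500 independent-row edges (100 taxa × 15
  samples), 200 permutations + 200 bootstraps per edge per measure
  (scaled from the 1000/1000 production default; the p-value comes from a
  z-score, so resampling depth affects only moment estimates). Power: 20
  replicates of a 60-taxon matrix with one strongly coupled pair
  (effect 3, σ = 0.3, base mean 100), requiring recovery at q′ < 0.05 in
  ≥ 18.
- *Duplicate ground truth*: 10 000 reads over 2 Mb of marker-free genome
  (so coincidental same-start pairs are negligible), planted rate
  recovered within ±2 points.
- *HGT ground truth*: 5 planted transfers (95% identity copies in five
  cellular lineages) among 20 decoys and 5 homolog-free viral peptides:
  exactly the planted pairs must surface, with zero false positives.

## Known limitations

- E-values are internally consistent, not calibrated to any external
  search engine; fixed-threshold decisions transfer, absolute E-values do
  not.
- The ReBoot p-value is a normal-tail approximation from null moments; at
  15 samples it cannot go below ~10⁻⁵ per measure, which bounds how small
  q′ can get on small candidate sets.
- The Grenander η₀ estimate is evaluated at p = 0.75; p-value sets whose
  alternatives reach into that region will deflate η₀ and loosen q-values.
- The built-in scanner is ungapped; marker homologs with indels relative
  to the profile lose score linearly.
- The duplicate filter's greedy order is a stated convention, not a claim
  about the original tool's behaviour; per-sample duplicate percentages
  from the original instrument runs are not reproducible targets.
- Marker-count and genome-size choices in the generator are desk-scale;
  they preserve the estimator's structure (group means of equal-length
  single-copy markers) but not field effect sizes.
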