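# Methods

## The statistic and its coordinate conventions

All tracks live in 0-based half-open coordinates (the BED convention): a
point at position *p* is inside segment [*s*, *e*) iff *s* ≤ *p* < *e*, so
a point at a segment's end coordinate is never contained and a point at its
start always is. Overlapping gene regions of one disease are **not**
merged: the statistic counts gene regions, and each gene is an independent
unit of disease association. Duplicate positions within one TF track are
collapsed — a genomic position either carries a binding location or it does
not — and the universe is the set union of all TF tracks' positions.

The default per-cell statistic is *segments hit*: the number of a disease's
gene regions containing at least one of the TF's binding locations. A
second mode, *points in segments*, counts total containments (a point in
two overlapping windows counts twice) and is meant for point-like chromatin
features (e.g. nucleosome centres carrying a histone modification) counted
in symmetric windows around TSSs.

## Region transforms

`extend_segments` grows gene regions by flanks clamped to chromosome
bounds. Two standard settings: 150 bp upstream (default, strand-aware) to
absorb TSS-annotation differences between gene builds when the TF points
are target-gene TSSs; and 5 kb symmetric flanks when the TF points are raw
predicted binding sites, which often sit near but outside the gene.
Strand-awareness for the upstream extension is configurable; asymmetric
flanks on a strandless segment are an error rather than a guess.
`tss_window` replaces each gene by [TSS − f, TSS + f) with TSS = start on
'+' and end − 1 on '−'; f defaults to 2 kb.

## Null models

Both analytic tests condition on: gene regions fixed, each TF's location
count n_t fixed, locations placed among the N universe positions. m_d is
the number of universe positions inside ≥ 1 region of disease d (counted
once even if a position lies in several overlapping regions of the same
disease — the placement null is about positions, not containments).

**Hypergeometric.** X ~ Hypergeom(N, m_d, n_t); E = n_t·m_d/N;
Var = n_t·m_d·(N − m_d)·(N − n_t)/(N²·(N − 1)); exact tails
p_over = P(X ≥ b), p_under = P(X ≤ b) via scipy. Var = 0 (e.g. n_t = N)
yields an undefined z, carried as NaN and rendered as missing — never as
z = 0.

**Binomial (differential).** p_td = m_d·Σ_d′ b_td′ / (n_t·Σ_d′ m_d′), the
TF's mean per-universe-position rate of falling inside disease region sets,
applied to disease d's m_d positions; X ~ Binom(n_t, p_td). The algebraic
consequence Σ_d E_td = Σ_d b_td (row-sum conservation) holds to machine
precision and is asserted in the tests at 1e-9 relative. p is clipped into
[0, 1] with a logged warning; clipping never occurs on well-formed inputs
and indicates a degenerate fixture. A row with all-zero observations has
p = 0 everywhere and an undefined (NaN) z rather than an error. An
alternative margin-based expectation (R_t·C_d/G) exists in the literature
of contingency tables; it is not implemented — the per-TF average-rate
form is the one that makes each cell differential against the TF's own
average.

**Statistic/test mismatch.** The observed statistic counts regions hit
while the analytic nulls model point counts. These coincide exactly when
every gene region contains at most one universe position — true for
TSS-style tracks with one point per target gene, the main intended scheme —
and are approximate otherwise. The permutation null is the reference for
the general case: n_t positions drawn uniformly without replacement from
the universe per replicate, statistic recomputed, empirical mean/sd/z and
add-one tail p-values p = (r + 1)/(n_reps + 1). It is seeded and
bit-reproducible; n_reps ≥ 100 enforced, 1000 default, 2000 used in the
agreement checks.

**Significance.** Two one-sided tests per cell. Defaults: alpha 0.05,
Bonferroni over the pooled family of 2·T·D one-sided p-values; BH over the
same pool as an option. These defaults are a design choice of this package.

## Co-citation gene lists

With N documents, m mentioning disease d, n mentioning gene g, the joint
count k is Hypergeom(N, m, n) under independence; the association p-value
is the upper tail P(X ≥ k). The Bonferroni family defaults to the number
of genes tested for that disease (per-disease correction); the
`universe_size` parameter switches to any other family (e.g. genes ×
diseases) — the choice is explicit because different reasonable families
exist. Threshold: corrected p strictly < 0.02. Catalog filters: gene-count
threshold is inclusive (≥ min_genes, default 20; 10 recommended for the
5 kb-flank scheme), citation threshold strict (> 300). Curated lists bypass
the statistics entirely.

## Clustering and rendering

Rows and columns of the z-matrix are clustered independently:
Euclidean distance between z-profiles, unweighted average linkage (UPGMA).
NaN z cells are imputed as 0 for the distance computation only (they carry
no differential signal) and rendered grey. Average-linkage heights are
non-decreasing; this is asserted on every run. Determinism: axis labels
are sorted lexicographically before linkage, so the tree does not depend on
input order; leaf ordering recursively places the tighter (lower merge
height) subtree first, ties broken by smallest leaf label. Trees export as
Newick with branch lengths derived from merge heights. `cut_tree` cuts by
cluster count or height, with cluster ids numbered left-to-right along the
leaf order.

The heatmap clips z at ±z_cap (default 8.0, configurable; chosen so that
strong but plausible signals, |z| ≈ 5–8 in the synthetic studies, still
modulate colour) on a diverging map anchored black at 0 with blue→cyan for
under- and red→yellow for over-representation; significance dots overlay
flagged cells. The HTML output embeds the full per-cell table (observed,
expected, z, both p-values) as JSON with hover detail; a tiled map UI is
out of scope.

## Cluster drill-down

A cluster selection is a set of TF rows × disease columns. "Gene g is
relevant to pair (t, d)" is operationalised as: g is in disease d's list
AND TF t has ≥ 1 binding location in g's extended region — the drill-down
must use the same extension as the count matrix for the rates to agree.
Hit rate = relevant pairs / selected pairs. `top_genes` sorts by rate
descending (ties alphabetical) and truncates after rank k but includes every
gene tied with the k-th. Disease effect size defaults to mean
(observed − expected) over the selected TFs, with mean z as an option.
Overlap partitions are exact membership-pattern (Venn) counts over 2–6
labelled gene sets.

## The synthetic study

The generator produces a complete down-scaled study with known truth:

- genome: 4 chromosomes × 10 Mb; 1000 non-overlapping 2 kb genes placed
  round-robin with jittered starts, random strands;
- diseases: 15 lists of 50–100 genes, sampled without replacement within a
  disease and independently across diseases, so lists share genes — the
  sharing is what makes the differential null meaningful;
- TFs: 20 tracks; each TF targets each gene independently with probability
  0.2 and emits one point at the target's TSS (~200 targets per TF, the
  same order as a top-1000 target list against a ~20k-gene genome, scaled
  to the 1000-gene universe);
- planted blocks: for block TFs, the probability of targeting a gene in any
  of the block diseases' lists is multiplied by the enrichment factor
  (clipped below 1); truth (block memberships, per-pair multipliers,
  per-gene flags) is emitted as JSON.

Because every point is a TSS and genes do not overlap, each gene region
holds ≤ 1 universe position — the regime where the analytic tests are
exact. Under multiplier 1 the pooled rate of |z| ≥ 1.96 over 20 seeds sits
inside [0.03, 0.07] (measured by the acceptance suite), and a multiplier-5
block of 5 TFs × 4 diseases is recovered by a k = 2 cut of either axis with
mean adjusted Rand index ≥ 0.9 over 20 seeds.

What the generator does *not* emulate: real TF targets are not independent
Bernoulli draws (motif similarity correlates TFs), disease lists have
skewed sizes and literature biases, gene density varies along chromosomes,
and binding-site tracks (as opposed to TSS tracks) put many points per
gene, breaking the ≤1-position regime. Passing tests therefore demonstrate
correctness and calibration of the machinery under the stated placement
null, not robustness to annotation noise in real data.

The co-citation simulator draws m ~ U[500, 5000], n ~ U[200, 2000] per
term against N documents, k hypergeometric under the null plus a planted
excess (clipped at min(m, n)). With N = 500 000 and a planted excess of 50
joint documents, planted pairs are recovered exactly at Bonferroni p < 0.02
while the family-wise false-positive rate over null tables stays at or
below 0.02 (the discrete, conservative test keeps it near the nominal
level).

## Numerical and scale choices

- Exact tails come from scipy's hypergeom/binom; tests pin them to
  pmf-enumeration oracles (math.comb / Fraction) at 1e-10 relative.
- Intersection counting uses sorted per-chromosome position arrays and
  binary search; tests pin it to a brute-force double loop on 100 random
  fixtures.
- Problem sizes in the test and acceptance runs (1000 genes, 20 × 15
  matrices, 20 seeds, 2000 permutation replicates) are chosen so the whole
  suite completes in seconds while keeping per-cell counts large enough
  (E ≈ 15) for z-calibration to be meaningful.
- Seeds: every stochastic component takes an explicit seed; the CLI records
  it in run metadata, and identical seed + inputs give byte-identical
  outputs.

## Known limitations

- The analytic nulls are approximations whenever a gene region can hold
  several universe positions (binding-site tracks with 5 kb flanks); use
  the permutation null there.
- The binomial differential null conditions on the TF's own row total, so a
  TF with very few in-region locations anywhere has little power and an
  all-zero row is undefined by construction.
- Curated disease catalogs are taken at face value; no ontology-aware
  deduplication of related disease terms is attempted, so correlated
  columns are expected and visible as clusters.
- Heatmaps render as single images or one HTML page; very large matrices
  (thousands × thousands) need external tiling, which is out of scope.
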