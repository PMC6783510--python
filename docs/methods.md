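# Methods

## Model and procedure

tfgmr screens compound-induced expression profiles against a pair of
antagonistic functional gene modules. The pipeline has four stages.

**Module construction.** Core genes come from a term→gene annotation
table for the two phenotype terms (for vasodilation, GO:0097755 /
GO:0097756); co-expressed partners come from pre-computed co-expression
query exports (gene, score, p-value per row), kept when score > 0 and
p < 0.01 — both inequalities strict, as the thresholds are stated.
Within a module, a co-expressed gene that is also core counts once, as
core. Genes appearing in both candidate modules are removed from *both*:
a gene cannot evidence dilation and constriction simultaneously, and the
TES contrast assumes disjoint modules. Term propagation through
is_a/part_of descendants is available but off by default — the
annotation table is used as given unless an ontology graph is supplied
and propagation is requested explicitly. Web queries (co-expression
search engines, GO browsers) are deliberately out of scope; their
exports are consumed as files so runs are reproducible offline.

**Ranking.** Genes are ordered by a treatment-vs-control score:
log fold change, pooled-variance t, or moderated t (default). The
moderated t shrinks each gene's pooled variance s² (df residual degrees
of freedom) toward a prior: s²_post = (d0·s0² + df·s²)/(d0 + df), with
(d0, s0²) estimated by a method-of-moments fit of the scaled-F marginal
s² ~ s0²·F(df, d0) to the observed gene-wise variances; degenerate
moment fits fall back to complete shrinkage (all genes share the mean
variance). With the two replicates per group typical of compound
compendia this stabilises the denominator the way empirical-Bayes
moderated statistics do. Scores are used as enrichment weights as-is (no
rescaling), per GSEA convention. Exact score ties are broken by gene id
ascending so ranked lists are platform-independent.

**Enrichment and the TES index.** The weighted KS running sum and ES are
as in the README. Numerical conventions:

- The ES is the deviation of maximal absolute value; when the positive
  and negative extremes tie exactly in magnitude, the earlier list
  position wins. (Such ties are structural — e.g. ±1/2 when only two
  genes are misses — not coincidences of continuous data. Near-ties
  within one ulp are resolved by floating-point rounding; the magnitude
  of ES is unaffected.)
- Leading edge: hits at positions ≤ peak for ES ≥ 0, hits strictly after
  the peak for ES < 0 (mirror definition).
- Module members absent from a profile's universe are dropped for that
  profile with a logged count, not an error; a module with *no* member
  present is an error (and in compendium ranking excludes that compound
  with a warning).
- All hit weights zero with exponent > 0 is an error rather than a
  silent 0/0.
- Weighting exponent p defaults to 1, the default of the GSEA
  implementations this statistic follows; p = 0 (classic KS) and other
  non-negative values are exposed as configuration.

**Null and significance.** The null redraws |PFGM| and |NFGM| genes
uniformly without replacement from the ranked list's gene universe —
module sizes counted after intersection with that universe, the same
sets the observed ES uses — and recomputes TES on the same list, B =
1000 times by default. The two draws are independent and may overlap
each other (the simplest faithful reading of size-preserving member
resampling); a disjoint joint draw is available as an option. The
nominal p uses an add-one estimator, p = (1 + #{null ≥ observed})/(1 +
B), so p > 0 always; it is one-sided (greater) by default because a
large TES is the alternative of interest when screening for the positive
phenotype, with a two-sided variant on |TES| available. Per-compound
null seeds are sha256-derived from the master seed and the compound id,
so results are independent of compound iteration order and rescoring a
subset reproduces the same numbers.

**Mechanism inference.** Leading-edge sets of significant compounds are
compared pairwise with the two-sided Fisher exact test
(point-probability definition, via scipy). The universe defaults to the
union of the two modules — leading edges are subsets of the modules, so
the full measured universe would make every overlap look extreme — and
can be switched to the measured universe; the choice is recorded in the
run metadata. ORA is a one-sided hypergeometric upper tail P[X ≥
overlap] per term with BH adjustment across tested terms, replacing
web-service annotation with a user-supplied GMT collection (term
membership depends on database versions, so pinning the collection in a
file is what makes runs comparable). The pipeline selects compounds for
mechanism analysis by nominal p < α (default 0.05); selection by an
experimental potency readout, as an ex-vivo follow-up would do, is
outside a purely transcriptomic screen.

## Synthetic compendia

The generator emulates a compound-treatment microarray compendium at
desk scale: per-gene baselines ~ Normal(7, 1) on a log2-intensity-like
scale, per-measurement Gaussian noise (SD 1.0 by default), and an
independent control group per compound (matching per-compound
versus-control differential expression). Defaults — 200 genes, 10
compounds, 2 replicates per group, modules of 20/20, effect size 1.0,
one planted vasodilator — are the package's standard study conditions: 2
replicates mirrors the duplicate arrays typical of public compound
compendia, and effect size 1.0 at noise SD 1.0 is a moderate, realistic
per-gene z ≈ 1 shift. A planted vasodilator adds +effect to
positive-module genes and −effect to negative-module genes in its
treatment samples only; a vasoconstrictor mirrors the signs; null
compounds get no shift. All randomness derives from one master seed
(per-compound streams hashed from seed + compound index), making emitted
files byte-identical across runs.

What the generator does *not* model: probe-level artifacts,
batch/chip effects, heavy-tailed or intensity-dependent noise,
gene–gene correlation outside the planted modules, and partial or
off-module compound effects. Passing tests on these compendia therefore
demonstrate correctness of the statistics and the machinery — not that
real compounds with subtle, correlated transcriptional effects will be
detected at these rates.

## Tolerances, sizes, and degenerate inputs

- Test problem sizes: oracle equivalence uses ≥1000 random instances at
  N ≤ 20 (where brute force is exact and instant); null calibration uses
  500 null compounds at B = 200 draws; planted-signal recovery uses 20
  seeds at B = 1000. These sizes keep the full suite under a minute on
  one CPU while leaving Monte-Carlo error well below the asserted
  margins (calibration is checked against 0.05 + 3·SE).
- Numerical comparisons against oracles use absolute tolerance 1e-12 on
  ES; Fisher p against exact rational enumeration uses relative 1e-6
  (scipy's two-sided summation tolerates last-ulp pmf comparisons).
- Degenerate inputs are contract errors, not silent results: matrices
  with duplicate genes, unlabeled samples or non-numeric cells; ranked
  lists shorter than 2; modules with no gene in a list; all-hit
  membership (P_miss undefined); resampling from a universe not larger
  than the combined modules; TES inputs outside [−1, 1].
- Missing expression values are rejected by default; optional row-mean
  imputation is logged.

## Known limitations and open choices

- The published reference top-candidate table contains one row whose
  printed index differs from the difference of its printed (2-decimal)
  enrichment scores by 0.01 (0.40 vs 0.39) — a rounding artifact in the
  source table; the package reproduces the self-consistent rows exactly.
- GMT carries no core/co-expressed distinction, so a module pair
  re-loaded from GMT reports all members as core; the provenance TSV
  written alongside preserves origins.
- The moderated t uses a single global shrinkage fit; it does not model
  intensity-dependent variance trends.
- Nominal p-values are per-compound permutation estimates; no
  multiplicity correction is applied across compounds in the ranking
  (the screen's purpose is ordering, with significance as a filter), and
  no normalized ES or cross-set FDR machinery is included.
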