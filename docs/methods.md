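# Methods

This note documents the models and procedures implemented in `exopattern`,
the defaults chosen where the workflow leaves choices open, and what the
synthetic cohort does and does not emulate.

## Variant representation and classification

A variant is identified by its trim-normalized key `(chrom, pos, ref, alt)`:
shared trailing bases are removed first, then shared leading bases with the
position advanced, always retaining at least one base per allele.  This
normalization is idempotent and needs no reference genome; full left
alignment against a FASTA is deliberately out of scope, so two
representations of the same indel in different repeat registers are *not*
unified.  A variant is an SNV iff both alleles are single bases; everything
else is an INDEL.  Multi-allelic records are split into one record per
alternate before any analysis.

**Novelty.** A variant is *novel* iff its key is absent from the population
catalog, or present with allele frequency below `af_threshold`
(default 0.01).  The low-frequency clause encodes the common practice of
treating rare cataloged variants like novel ones; a cataloged variant with
unknown frequency counts as known.

**Damaging.** A nonsynonymous SNV is *damaging* iff its consensus
deleteriousness score (ConDel-like, in [0, 1]) is ≥ `cutoff`
(default 0.522, the published ConDel operating point).  Variants without a
score are never damaging.

## Gene-affection ordination

Per sample and stratum, the affected-gene set contains every gene annotated
to a qualifying variant: SNVs qualify when splice-site, or exonic with a
nonsynonymous/stopgain/stoploss consequence (synonymous excluded); INDELs
qualify when exonic or splice-site.  Splice-site variants qualify
unconditionally because exonic-consequence labels are generally unavailable
for them.  Sets are stacked into a binary samples × genes scoring matrix
over the union of genes (columns lexicographic).

**Distance.** Default Jaccard (`1 − |∩|/|∪|` over 1-columns, 0 for two
all-zero rows), the conventional choice for sparse binary data; Euclidean is
available since generic distance tools default to it.

**NMDS.** Kruskal's scheme, authored here: (1) classical-scaling
(Torgerson) initialization — double-center `−½ J D² J`, take the top-k
spectral coordinates with negative eigenvalues clipped; (2) iterate: compute
configuration distances, fit disparities by isotonic regression (PAVA, via
`scipy.optimize.isotonic_regression`) of distances taken in dissimilarity
order, evaluate stress-1, update the configuration by the Guttman transform
`X ← n⁻¹ B(d̂/d) X`.  Ties in the dissimilarities follow Kruskal's primary
approach: within a tie block the current distances are taken in ascending
order (per-iteration lexsort on `(δ, d)`), so ties carry no penalty.
Stopping: stress below 1e-12, stress decrement below `tol` (default 1e-8 —
the decrement tracks the stress magnitude under the linear convergence
observed here, so a 1e-8 decrement tolerance leaves embeddable
configurations well below 1e-6 stress), or `max_iter` (500).  An iteration
that would increase stress terminates the run on the previous configuration,
which makes the recorded trace non-increasing by construction.  `n_starts`
(default 4) runs the classical start plus seeded Gaussian perturbations of
it (σ = 0.1 × RMS coordinate) and keeps the lowest final stress; the
embedding dimension must satisfy `k ≤ n − 1`.  `sklearn`'s non-metric MDS is
used in the test suite as an independent reference, never in the
implementation path.

**Hierarchical clustering** is a naive O(n³) agglomeration (n = number of
samples, ≤ 5 in the intended setting) with average (UPGMA), complete, or
single linkage computed from the original pairwise dissimilarities.  Ties
break toward the lexicographically smallest cluster pair.  The dendrogram is
exported as Newick with branch lengths equal to merge-height differences;
scipy's `linkage` serves as the test oracle.

## Editing signature

Substitution spectra are 4×4 ref × alt counts; transitions are A↔G and C↔T,
transversions the rest, so the two classes already pool complementary
substitution pairs and strand is ignored.  The novelty-stratified test puts
(transitions, transversions) × (novel, known) in a 2×2 table and computes a
two-sided Fisher exact p by the point-probability method (sum of tables
whose hypergeometric probability does not exceed the observed one's, with a
1 + 1e-7 relative guard), via `scipy.stats.fisher_exact`; brute-force
enumeration over all small tables is the test oracle.  A zero margin yields
p = 1 with a warning.  The reported odds ratio is the sample cross-product
ratio and is flagged as such.

## Identity-by-state somatic inference

`result = (∩ tumor keys) ∩ catalog − (∪ control keys)`, requiring ≥ 2
tumors and ≥ 1 control.  Matching against the positive somatic catalog is by
exact normalized key by default; a position-only mode exists because
external somatic catalogs sometimes represent alleles differently, and its
provenance records which catalog entries matched.  The filter is monotone:
controls only remove, catalog entries only add.  Controls are treated as
germline references without genotype-quality weighting.

## Network analysis

Subnetworks are induced on the query genes (`direct`), optionally admitting
non-query nodes adjacent to ≥ 2 query genes (`plus_bridges`) — the mode the
pipeline uses by default, since the interesting hubs are often proteins that
are not themselves mutated.  Centrality conventions, chosen because the
measures' names do not fix them and rank order is the comparison surface:
degree = incident edges; betweenness = Brandes on unweighted BFS,
unnormalized, endpoints excluded; closeness = Wasserman–Faust composite
`((r−1)/(n−1)) · ((r−1)/Σ d(v,u))` over the r reachable nodes, 0 for
isolated nodes.  These are computed with `networkx`; exhaustive shortest-path
enumeration on small random graphs is the test oracle.  Largest-component
percentages count query genes in the largest connected component (query
genes absent from the graph are singletons; size ties break toward the
lexicographically smallest component).

## Enrichment

Upper-tail hypergeometric p per term (`scipy.stats.hypergeom.sf`), BH
step-up q-values (`statsmodels`), significance at q < α (default 0.05).
The universe defaults to all genes carrying any qualifying variant in the
cohort — enrichment is universe-sensitive and the workflow's annotation
sources are external, so an explicit universe override is provided.  Terms
annotating fewer than 3 universe genes are excluded by default.  The
gene-family contrast (e.g. olfactory receptors vs histone/actin families)
is codified as a two-sided Fisher test on (affected, unaffected) ×
(family, reference family); the original analysis did not name its test, so
this choice is ours and printed family-contrast p-values from that analysis
are not treated as reproducible targets.

## Synthetic cohort

The generator emulates the study design the analysis assumes — two tumor
exomes (`P17`, `P61`) and three related controls (`P39`, `P26`, `P84`) —
with all randomness from one seed (byte-identical bundles per seed).

* **Pedigree and germline.** An explicit two-branch pedigree: grandparents
  `A1×A2` have children `B1`, `B2`; `B1×S1` → `P61`, `P39`; `B2×S2` →
  `P17`, `P26`; `P84` is an unrelated founder.  Founder variants are
  gene-dropped (transmission probability ½ per meiosis), so siblings share
  half their rare germline variants in expectation.  A population
  common-variant pool (allele frequencies uniform on [0.05, 0.95]; founders
  carry each variant with probability equal to its frequency) provides the
  identity-by-state background real exomes share; without it, every sample
  pair would be near-maximally distant and the ordination geometry would be
  degenerate.
* **Scale.** Default sizes are roughly one tenth of a ~100× exome's
  per-sample burden (6000 germline variants/sample, 25% INDELs, 1500
  genes); absolute burdens are platform- and coverage-dependent scale
  knobs, and all planted contrasts are scale-free.  The
  `CohortConfig.small()` preset (1200 germline variants, 400 genes) is the
  size used for the repeated-simulation recovery studies in the test suite.
* **Somatic signal.** Each tumor receives 600 somatic SNVs plus enough
  somatic INDELs to multiply its expected INDEL burden by
  `indel_burden_multiplier` (default 2.0, echoing the observed tumor INDEL
  excess); a fraction `somatic_share_prob` (0.6) is shared by both tumors,
  and shared somatic variants enter the positive catalog with probability
  `catalog_overlap_prob` (0.8) alongside background entries drawn from
  never-used keys (so IBS precision against truth is exact at overlap 1).
* **Editing signature.** Substitution types are drawn in two stages —
  transition vs transversion Bernoulli (novel 0.825, known 0.68, the
  reported fraction ranges), then a uniform choice within the class — a
  two-class model, deliberately not a 12-rate or trinucleotide-context one.
* **Planted enrichment.** Tumor somatic INDELs are exonic more often (0.30)
  and, when exonic, target two planted 30-gene term pools with probability
  0.6.  These effect sizes were chosen by design-time power analysis so the
  planted terms clear BH q < 0.05 in tumor INDEL sets while random control
  sets do not.
* **Network.** Erdős–Rényi background at mean degree 6 plus one hub wired
  to tumor nonsynonymous-hit genes with probability 0.4 and to other genes
  with probability 0.02, giving the hub an expected degree far above the
  background maximum.

**What passing recovery tests show — and do not.** The generator reproduces
the *statistical structure* of the workflow's inputs (burden contrasts,
IBD/IBS sharing, the two-class transition excess, planted enrichment, hub
centrality), not real exome data: there is no sequencing error, no
coverage or mappability variation, no mutational hotspots or
trinucleotide context, no linkage disequilibrium, single-gene variant
annotations, and independent variant sites.  Recovery results therefore
validate the pipeline's logic and statistics, not caller or annotator
behavior on real reads.

## Numerical and degenerate-input conventions

All-equal dissimilarities warn (`degenerate ties`) and embed at stress 0;
an all-zero distance vector is an error in `stress1`; empty induced
subnetworks warn instead of failing; an edgeless graph's largest-component
percentage is `100/|query|`; a zero-margin 2×2 table gives p = 1 with a
warning; an empty Ti/Tv stratum is an error naming the stratum.  Catalog
frequencies written with 6 significant digits; BED export is 0-based
half-open with name `ref>alt`.

## Problem sizes used in validation

The acceptance script simulates the stratified Ti/Tv test at 5097 novel +
43634 known substitutions and ordinates the default five-sample cohort.
The repeated-simulation studies in the test suite run 100 seeds of the
reduced-size cohort; the Fisher/hypergeometric enumeration checks cover all
2×2 tables with total ≤ 40 and hypergeometric grids with N ≤ 40; betweenness
is cross-checked on 50 random graphs of ≤ 8 nodes; linkage heights on random
6×6 matrices.  These sizes keep the whole validation battery to a few
minutes on one core.

## Known limitations

No reference-FASTA left-alignment (see above); single-sample VCFs only (no
multi-sample genotype semantics); untyped, unweighted, undirected
interaction edges; no GO-hierarchy propagation in enrichment; the Venn
partition supports 2–5 sets; formal kinship estimation (F-statistics, IBD
segments) is out of scope — the IBS filter is set logic, not a genetic
model.
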