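# Methods

`clonetracer` reconstructs the subclonal architecture of a tumour from
multi-region whole-genome sequencing: which clones exist, how they are
related, where they sit in the body, and which mutational processes wrote
their mutations. This note documents the models and procedures the package
implements, the parameters that matter, and the limits of what its
synthetic-cohort tests demonstrate.

## Cancer cell fractions

The observed variant allele fraction f of a somatic SNV in a sample with
tumour purity ρ, local tumour total copy number n_t and normal copy number
n_n (2 on autosomes) relates to the fraction of tumour cells carrying the
mutation (CCF) through the mutation multiplicity m (number of chromosomal
copies bearing the variant):

    f = m · ρ · CCF / (ρ·n_t + (1 − ρ)·n_n)

We invert this the standard way: m̂ = f·(ρ·n_t + (1−ρ)·n_n)/ρ, then
m = clamp(round(m̂), 1, n_major), then CCF = f·(ρ·n_t + (1−ρ)·n_n)/(m·ρ).
For segments carrying two copy-number states, n_t is the fraction-weighted
total and the multiplicity ceiling is the larger of the two major alleles;
single-state attribution of one SNV from one sample is not identifiable, so
no attempt is made. CCFs above 1 are *kept* (clipping would bias cluster
medians toward 1) and flagged above a ceiling of 1.2 as likely copy-number
mis-specification. Loci with zero depth or no covering segment in any
sample are retained in the matrix but marked unusable — never silently
dropped.

Somatic evidence filtering keeps variants with caller score (TLOD dialect)
≥ 7, inclusive: a variant scoring exactly the threshold passes. When joint
calling emits one score per sample, the per-variant scalar is the maximum
across samples by default (configurable to minimum).

**Purity refinement.** Truncal mutations are carried by every tumour cell,
so the truncal cluster's median CCF must be 1. We refine ρ per sample by
1-D root finding (Brent) on the median-CCF-versus-ρ curve, which is
monotone decreasing; multiplicities are re-derived at each trial ρ. If no
root exists in (0, 1] the input purity is kept with a warning. The
procedure is idempotent to < 1e-6.

**Segment QC.** Within each sample, a segment whose truncal-SNV median CCF
deviates from the genome-wide truncal median by more than 0.15 is flagged
(below: overcorrected, i.e. copy number called too high; above:
undercorrected). Segments with fewer than 10 truncal SNVs are never
flagged; the multiplicity clamp partially absorbs integer-doubling errors,
so the screen is most sensitive to wrong loss calls.

**Low-purity imputation.** Samples too impure to segment reliably receive
a consensus profile: donor profiles are re-cut to the union of their
breakpoints and each unified segment takes the modal donor state, ties
resolved toward the purest donor.

## Clone clustering

Usable loci are clustered in the S-dimensional CCF space with sklearn's
variational Bayesian Gaussian mixture: up to 15 components, diagonal
covariance, 1000 iterations, Dirichlet-process weight prior, fixed seed.
One deliberate deviation from sklearn defaults: the component-variance
prior is set to 0.02 — the square of the per-locus CCF noise SD (~0.14) at
the ~90× depth and mid-range purity this pipeline targets. sklearn's
default prior (the full-data variance, an order of magnitude larger)
biases components broad and systematically under-splits clones.

The mixture fit is followed by deterministic curation, the programmatic
counterpart of by-eye cluster editing:

* *split*: a cluster is split along a sample axis when a 2-component 1-D
  Gaussian mixture beats 1 component by BIC **and** the two parts' medians
  separate by ≥ 0.18 in some sample, recursively;
* *merge*: clusters whose medians lie within 0.10 of each other in every
  sample (max-norm) are indistinguishable at the noise scale and merged;
* clusters below 20 members are absorbed into the nearest survivor.

Both thresholds derive from the same noise argument: ~1.5 noise SDs is the
scale at which two clusters count as distinct clones, and half that is the
scale at which they certainly do not. Manual `merge_clusters` /
`split_cluster` operations remain available and are audit-logged; splits
must leave both parts at the minimum size.

Clones are labelled A, B, C, … by descending mutation count. The truncal
clone is the largest cluster whose median CCF is ≥ 1 − δ (δ = 0.10) in
every tumour-bearing sample — a definition by CCF, not size, because the
ancestral clone need not carry the most mutations.

## Tree construction

Two constraints score a candidate tree against the cluster medians:

* **sum rule** (pigeonhole): per clone and sample, daughters' CCFs summing
  beyond the parent's CCF + ε is one violation (ε = 0.05 absolute, with an
  inclusive boundary — a strict inequality on noisy reals is untestable);
* **crossing rule**: a clone pair whose CCF ordering flips between samples
  (beyond ε both ways) must branch; placing such a pair on one
  root-to-leaf path is one violation, counted once per pair regardless of
  how many sample pairs exhibit the flip, because the rule is topological.

For K ≤ 8 clones every rooted labelled tree (K^(K−2) of them, enumerated
via Prüfer sequences) is scored and the minimum taken. Ties break by fewer
crossing violations, then by fewer edges where a child outweighs its
parent in mutation count (the "smaller daughter descends" resolution of
sum-rule conflicts), then by the lexicographically smallest parent vector —
making the search deterministic and input-order invariant.

Above the exhaustive limit a heuristic is used: clones are inserted in
descending total-CCF order (by the sum rule an ancestor dominates each
descendant in every sample, so high-CCF clones belong near the root), each
insertion greedily minimising the partial score, followed by
steepest-descent reparenting, a bounded sideways-move escape for
star-shaped plateaus, and four extra restarts with seeded random insertion
orders. The heuristic matches the exhaustive optimum on all tested
instances up to K = 6 and on 146/147 random instances up to K = 8; it is
documented as a heuristic and the exhaustive path remains available.

## Clone maps, spread and seeding

Raw medians are projected per sample onto the tree-consistent set: values
clipped to [0, 1], then, walking root-down, any sibling set outsumming its
parent is scaled down proportionally. This least-squares-flavoured
projection is one defensible reading of "corrected for visualisation";
output JSON labels it as such. Raw values are preserved alongside.

From corrected compositions:

* **direction**: sample x gave rise to sample y when some clone is
  strictly subclonal in x (CCF in (δ, 1−δ)) and clonal in y (≥ 1−δ), and
  every clone clonal in x stays present (> δ) in y. The second condition
  is a guard against ordering sibling samples on hand-supplied maps;
  compositions produced by the projection already satisfy it. Pairs
  qualifying in both directions are ambiguous and left unordered.
* **polyclonality**: a sample where some clone has ≥ 2 children each
  present above δ.
* **seeding**: for a metastasis sample, the maximally derived clones
  present (> δ) — present clones with no present descendant. More than one
  such clone means multiple seeding events from distinct branches; each
  clone's candidate sources are the primary samples where it is present.

Anatomical adjacency is deliberately out of scope: the package reports
clone-level evidence and leaves spatial interpretation to the analyst.

## Genome metrics

Ploidy is the base-pair-length- and fraction-weighted mean total copy
number; whole-genome duplication is called when ploidy strictly exceeds 3
(2.80 is negative, 4.0 positive). Percent subclonality is the share of
analysed bases in segments carrying a second state — exactly what a
Battenberg-style table encodes as subclonal. Both are invariant under
splitting any segment at an interior point. Telomeric allele imbalance
inspects the segment containing each arm's telomeric end (majority state):
minor copy 0 with major ≥ 1 is LOH, total above the rounded ploidy is a
gain; interstitial events are excluded by construction. Driver genes (BED
intervals) take the call of their majority-overlap segment: total < 2 Del,
> 2 Amp, = 2 neutral, subclonal segments flagged. The evolutionary
distance between two samples is the size of the symmetric difference of
their SNV presence sets; the presence rule (alt reads ≥ 3 and VAF ≥ 0.05)
is our choice, exposed as parameters, since no standard exists. Whether
ploidy should be purity-corrected is left open; we report tumour-segment
ploidy and say so in output metadata.

## Mutational signatures

SNVs are binned per clone or per user-declared connected tree subsection
(subsections must partition the clones; overlaps and disconnected sets are
rejected). Each bin becomes a 96-channel trinucleotide catalogue on the
pyrimidine-strand convention — purine-reference mutations are
reverse-complemented, so complementary descriptions land in one channel —
plus six-type conversion proportions. Exposures against a reference matrix
(96 × S, columns summing to 1; COSMIC can be dropped in as a TSV) are
fitted by non-negative least squares on channel proportions, iteratively
removing signatures whose normalised weight falls below 0.06 and
refitting, then rescaling so weights sum to at most 1 — the behaviour of
standard refitting tools. Fits on bins under 50 SNVs warn. The fit is
scale-invariant by construction. A generated synthetic reference (peaked
columns plus one flat, HRD-like column) supports testing without any
download; it is labelled synthetic and is not COSMIC.

## The synthetic cohort generator

The simulator produces the data the pipeline must invert, with full ground
truth, emulating multi-region prostate-cancer WGS cohorts: 2–9 samples per
patient across prostate / seminal-vesicle / lymph-node sites, one truncal
clone plus branching subclones, purities 0.10–0.90 (or fixed), depth
Poisson around a target (default 88×; only a median depth is typically
reported, so Poisson is the simple standard choice), clonal and subclonal
copy-number segments with optional whole-genome doubling, and per-branch
signature mixtures.

* **Tree**: uniform over rooted labelled trees (uniform Prüfer sequence),
  root = clone 0.
* **Clone fractions**: per sample, Dirichlet(α = 1) stick-breaking down
  the tree; each non-root clone's subtree is zeroed with probability
  `sparsity` (default 0.3), emulating whole lineages absent from a region.
  The sum rule holds exactly by construction, with equality only where
  sibling fractions vanish.
* **Detectability screens**: fraction sets are redrawn until every clone
  owns ≥ 5% of some sample's cells and every clone pair separates by
  ≥ 0.2 in some sample (max-norm on true CCFs). Both follow from the noise
  scale of the emulated data — per-locus CCF SD is ~0.14 at 90×, so clones
  closer than ~1.5 SDs everywhere are not distinct, reportable clones, and
  no method (nor manual curation) would resolve them. Without the screen,
  "true K" is ill-defined for a non-trivial fraction of draws.
* **Reads**: multiplicity uniform on {1..n_major} (the least-informative
  choice, and exactly what the CCF engine inverts), total reads Poisson,
  alt reads binomial at the expected VAF; infeasible multiplicity draws
  (VAF > 1) are resampled downward. SNV counts per clone default to 200 in
  the test cohorts; real per-clone counts span roughly 250–4600, so tests
  run at the low end of the realistic range for speed.
* **Copy number**: random per-chromosome segmentation (Poisson segment
  counts), baseline 1+1 doubled to 2+2 under WGD, optional ±1 clonal
  perturbation, and segments marked subclonal by a greedy-with-top-up
  selection that hits a target base fraction to within one small segment.

Everything is bit-reproducible for a fixed seed; simulated VCF scores are
stored at float32 precision so writer→reader round-trips are exact.

**What passing tests do and do not show.** The generator realises exactly
the generative model the CCF engine inverts: binomial noise, known copy
number, known purity, no mapping artefacts, no FFPE damage, no germline
leakage, no structural variants, and clone separations at or above the
detectability screen. Recovery rates measured here (e.g. clone-count
recovery in ≥ 18/20 cohorts at depth 100, median RMSE ≤ 0.05) are
therefore upper bounds on real-data performance, not estimates of it. The
screens make the benchmark well-posed; they do not make real tumours
well-behaved.

## Problem sizes and numerical choices

Tests and the acceptance script use cohorts of 3–6 clones, 2–3 samples and
60–200 SNVs per clone on a 100 Mb toy genome (22-chromosome GRCh38-scale
lengths where segment statistics matter) — sizes chosen so the full suite
completes in well under a minute per module while every statistical check
retains power; all rates are quantified over 20–100 independent seeds.
Degenerate inputs are handled explicitly: empty trees, non-spanning parent
relations and cycles are rejected at construction; a clustering with no
component above the minimum size collapses to a single cluster rather than
failing; exposure fits where every weight falls below the cutoff keep the
single best-supported signature. Tolerances: rule ε = 0.05, clonality
δ = 0.10, fraction-sum validation 1e-6, purity root-finding xtol 1e-6.

## Known limitations

* The greedy tree search can miss the optimum above the exhaustive limit
  (one miss in 147 stress instances); exhaustive mode is exact but costs
  K^(K−2) evaluations (~5 s at K = 8).
* CCFs are computed per sample against that sample's own segment; loci
  whose copy number differs across samples get per-sample multiplicities,
  and no cross-sample reconciliation is attempted.
* The corrected-CCF projection is proportional, not a true Euclidean
  projection onto the polytope; the difference is negligible for
  visualisation and the raw medians are always preserved.
* Transition inference reports clone-level evidence only; it cannot
  distinguish invasive spread from metastatic seeding between adjacent
  regions without anatomical context.
* Six-type proportions and catalogues assume SNVs only; indels, DBS and
  copy-number signatures are out of scope.
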