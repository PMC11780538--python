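# Methods

This note documents the statistical model behind each stage, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Filtering and normalization

Filtering is sequential: (1) drop genes absent from an optional annotation
list; (2) drop the bottom `abundance_frac` (default 0.04) of the remaining
genes by mean raw count over all samples; (3) drop the bottom
`variance_frac` (default 0.15) by variance of log₂CPM over all samples.
Quantile boundaries use the nearest-rank rule (`ceil(frac·n)` genes
removed) with ties broken by gene ID, so results are reproducible across
platforms. "Low abundance" and "low variance" admit several conventional
metrics; mean count and log₂CPM variance are the defaults, with
median/max count and raw-count variance available
(`abundance_metric`, `variance_metric`), because published gene tallies
produced by interactive platforms often reflect an undocumented internal
metric and matching them can require trying the alternatives.

CPM divides each sample's counts by its library size times 10⁶; log₂CPM
adds a pseudocount (default 1.0, configurable) before the logarithm so
zero counts stay finite. No between-sample normalization beyond CPM is
applied here; the DE stage uses its own median-of-ratios size factors.

## Differential expression

Contrasts are simple two-group comparisons on sample subsets (no donor
pairing), matching small-cohort designs where a donor term is not
identifiable with 4 donors per group. The engine is pydeseq2 (the DESeq2
procedure): median-of-ratios size factors over the union of the two sets,
per-gene NB dispersion with trend and MAP shrinkage, a Wald test on the
group coefficient, BH correction; DEGs are genes with padj ≤ 0.05, no
fold-change cutoff. Independent filtering and Cook's outlier handling
follow the engine's defaults and can be disabled per call. Sets with
fewer than two samples are refused (no dispersion estimate is possible);
all-zero rows are excluded and recorded on the result object so DEG
overlaps always compare identical gene universes.

A caveat measured during development and enforced honestly by the test
suite: at n = 4 vs 4 the NB Wald test's extreme tail is mildly
anticonservative — on complete-null simulations both pydeseq2 and the
reference R implementation produce at least one BH-significant gene in
roughly 10-30% of replicates rather than the ~5% the BH family-wise bound
would suggest. Users should treat single-gene DE calls at this sample
size with corresponding caution.

## Over-representation analysis

For a query of n genes from a background of N, a pathway with K background
members and overlap k scores p = P(X ≥ k) under the hypergeometric
distribution (equivalently, one-tailed Fisher's exact). BH runs per
collection (per database), not pooled across databases — pathway lists
from different databases overlap heavily and pooling would double-count
evidence. Significance additionally requires k ≥ 3 (`min_overlap`): an
enrichment carried by one or two genes is not interpretable. Queries must
be subsets of the background; callers intersect explicitly so the tested
universe is never ambiguous.

## Dimensionality reduction

**CCA.** Similarity between the control and PAH sample blocks of one
condition is the mean of the first three canonical correlations, with
genes as observations and samples (4 per side) as variables — the only
orientation that admits three components at this design size. Columns are
standardized over genes first. Canonical correlations are computed by
solving the generalized symmetric eigenproblem
Sxy·Syy⁻¹·Syx·v = ρ²·Sxx·v with `scipy.linalg.eigh`, which is exact,
symmetric in the two blocks, and independent of the SVD-whitening route
used as a test oracle. With only 4 variables per side the absolute values
are modest even for identical-distribution blocks; the informative
quantity is the trend across conditions.

**PCA.** Samples are projected on the top three right singular directions
of the gene-centered sample × gene matrix (center-only by default; a
`scale` flag adds unit gene variance). Score signs are fixed by making
each axis's largest-magnitude gene loading positive. Per (group,
condition) cell the 95% confidence ellipsoid is the Gaussian region
{x : (x−μ)ᵀΣ⁻¹(x−μ) ≤ χ²₃(0.95)} with μ the member centroid and Σ the
sample covariance; singleton groups are flagged degenerate with Σ = 0.
Dispersion is the RMS distance of members to their centroid (a
`dispersion_metric="mean"` option gives the mean distance): "standard
deviation from the centroid" has no unique scalar reading, and RMS is the
isotropic one. Centroid distances quantify transcriptional shifts between
cells of the design.

## Differential variability (ΔΔCV)

CV uses the (1 + 1/4n) small-sample unbiasing factor for the n−1-denominator
sample SD, on CPM (not log) values, in percent. ΔCV = CV_HSS − CV_Static
within each group; ΔΔCV = ΔCV_PAH − ΔCV_control; the top-variable list is
eligible genes with ΔΔCV strictly above 50 percentage points, sorted by
ΔΔCV descending with ties broken by gene ID. Eligibility requires a
nonzero raw count in every sample of both considered conditions in *both*
groups (ΔΔCV needs all four cells; a `per_group_eligibility` flag relaxes
this), and LSS samples are not considered. The 50-point cutoff is a
difference of percent-valued CVs, not a ratio. No p-values are attached
to ΔΔCV — with n = 4 per cell the statistic is a screening tool, and its
sampling noise is substantial (see the generator notes below).

## Stratification and transfer

Top-variable genes' log₂CPM values in the PAH HSS samples are z-scored
per gene (n−1 denominator; constant genes are zeroed and flagged). PAM
runs on Euclidean distances between z-score rows: greedy BUILD seeding,
then first-improvement SWAP scanning medoids and candidates in
deterministic index order until no exchange lowers the total distance.
The procedure is deterministic given the input order; being a local
search, it can terminate in a swap-local optimum that exhaustive
enumeration would beat (observed on ~6% of small random instances), which
is inherent to PAM rather than to this implementation. k defaults to 4 —
one cluster per patient in the motivating design — and clusters are
relabeled by descending size; each cluster maps to the patient with the
highest mean z over its members, which is the semantic anchor of the
numbering. A correlation-distance option exists.

Per-patient pathway scores average, over a pathway's contributing genes
(the ORA overlap genes of the cluster that enriched it, ≥ 3 by the
significance rule), the difference between the patient's log₂ value and
the mean log₂ value of the pooled controls. Transfer to an external
cohort collapses probes per gene (highest mean expression across all
samples by default; highest single value as an option — the mean is
robust to single-sample spikes), drops unannotated probes and genes
absent from the cohort (with a coverage report), and scores each case
sample against the cohort's own control mean on the log₂ scale.

## The synthetic-data generator

`simulate()` draws negative-binomial counts (Var = μ + αμ²) for the study
design: 2 groups × 4 donors × 3 conditions, one channel per donor per
condition. Per-gene log₂ baselines are N(4, 1); per-donor offsets
(SD 0.1 log₂) are shared across a donor's three channels, emulating the
repeated-measures structure that grouped DE ignores; expected library
sizes are drawn from the interior of `library_size_range` so realized
totals (NB noise ≈ 1-2% relative SD) stay inside the declared range.
Defaults use 2,000 genes at ~1,000 reads per gene — a scaled-down gene
count at realistic per-gene depth.

Three planted layers create the structure the analysis is built to find:

* **shear response**: 10% of genes shift by ±1 log₂ (LSS) / ±2 log₂ (HSS)
  identically in both groups — conserved flow responses;
* **variance inflation**: 200 genes receive an independent per-PAH-donor
  N(0, 2.5² log₂) effect only at HSS, creating high ΔΔCV with no
  consistent direction. The 2.5 log₂ SD is deliberately large: with only
  4 donors, the sample CV detects an inflation reliably only when the
  underlying donor swings are severalfold — at SD 1.5 log₂ the 4-donor
  sample CV would clear the ΔΔCV > 50 threshold for barely three quarters
  of planted genes, an intrinsic property of the CV estimator at n = 4;
* **patient blocks**: four 40-gene blocks upregulated 2 log₂ in exactly
  one PAH donor at HSS — the clusterable patient signatures.

Baseline noise (dispersion 0.01, donor SD 0.1 log₂, minimum post-filter
means of a few hundred counts) was calibrated once, by simulation at
design time, so that a configuration with *no* planted effects yields an
empty top-variable list at the 50-point cutoff — i.e. the selection's
null behaviour is clean under the generator's own noise model.

What the generator does **not** emulate: gene-gene correlation beyond the
planted blocks, batch structure, GC/length biases, and the compositional
scale of real data — with 10% of a 2,000-gene panel variance-inflated,
planted effects shift PAH-HSS library totals by tens of percent, visibly
depressing every other gene's CPM (real data, with ~3% of 14k genes
affected, shows a much smaller echo). Tests of score *calibration*
therefore plant blocks without the variance-inflation layer; tests of
selection and clustering use the full default structure. Passing tests
show the pipeline recovers what it is designed to recover under its own
model assumptions; they do not certify behaviour under real-data
artifacts the generator omits.

A companion generator builds an external probe-level log₂ cohort
(default 41 controls / 30 cases, mirroring a typical public PBMC
microarray cohort) whose case samples carry attenuated versions of the
planted blocks, plus duplicate dimmer probes and unannotated probes to
exercise the collapse rules. Transfer *rank-concordance* checks score
composite pathways that straddle several patient blocks with graded
weights (20/12/8 genes), the way real gene sets straddle clusters: a
one-hot fixture would leave most (patient, pathway) cells as pure noise,
and rank correlation between independent noise orderings is bounded near
0.57 no matter how faithful the transfer is.

## Determinism and problem sizes

Every stochastic component takes an explicit seed; the full pipeline
writes byte-identical tables across reruns of the same config + seed (the
manifest also records wall times, which naturally differ, and is excluded
from byte comparisons). Simulation-based tests and the acceptance script
use 250-2,000-gene panels and 10-100 replicates — sizes chosen so the
whole suite completes in a couple of minutes on one CPU while keeping the
Monte-Carlo margins of the properties being checked.

## Known limitations

* DE at n = 4 vs 4 is slightly anticonservative in the far tail (see
  above); printed DEG counts are engine-version sensitive.
* PAM is a local search; global optimality is not guaranteed.
* ΔΔCV carries no inferential error control; the 50-point cutoff is a
  screening convention. With 4 donors per cell, a gene's sample CV has a
  relative SD of roughly 40%, so selection near the cutoff is noisy.
* CCA with 4 samples per side estimates at most 3 canonical directions
  from very few observations of the sample space; treat similarity values
  comparatively, not absolutely.
* Exact reproduction of gene tallies from interactive analysis platforms
  may require the filter-metric sweep described above, and pathway-level
  p-values depend on the gene-set database snapshot.
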