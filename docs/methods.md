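# Methods

## Model and assumptions

The package assumes each co-expression program in a genes × arrays matrix
is a *characteristic mode*: a rank-one component s·**u**·**v**ᵀ whose
right factor **v** (the eigengene) is the program's profile over arrays
and whose left factor **u** scores each gene's participation. Comparing
two data sets then reduces to (i) matching eigengenes across data sets
and (ii) thresholding the paired gene loadings. The method needs the two
data sets to hold *comparable* conditions in aligned order (same time
points, or at least an alignable grid); it does not interpolate or warp
time. All analysis is on log-scale expression after two-way polishing, so
every gene contributes one unit of variance and loadings are comparable
across genes.

## Two-way polishing

Each polishing iteration standardizes columns (centre, divide by the
n−1 standard deviation) and then centres each row and divides by its root
sum of squares. Two iterations are the default; the map is contractive in
practice and one extra iteration moves entries by < 1e-6 on typical
inputs (tested). The iteration count is exposed because the two sweeps do
not commute and the fixed point is only reached in the limit. Zero-
variance columns or zero-norm rows abort with the offending label — they
indicate degenerate input (a constant array or a constant gene) that must
be filtered first.

## The SVD-p statistic

For an r × c subset matrix A, SVD-p is the upper-tail probability, under
F(ν₁, ν₂) with ν₁ = r + c − 2 and ν₂ = rc − 2r − c + 2, of the raw
leading-component variance ratio F̂ = s₁²/(‖A‖²_F − s₁²). The degrees of
freedom count the free parameters of the rank-one bilinear model
A = s·u·vᵀ + E (r + c − 2) and the residual dimension. The calibration is
deliberately *not* a mean-square ratio: plugging the unscaled ratio into
the F reference is an ad hoc device, and SVD-p is not a p-value — but it
is exactly what gives the statistic its operating characteristics. On a
large mixed gene set the ratio sits far below the F quantiles (SVD-p ≈ 1);
it crosses a small threshold only when the swept subset is genuinely
dominated by one pattern; and at equal tightness a larger subset scores
lower, because both df grow with r. A conventionally scaled mean-square
ratio (available as `svdp(..., scaled=True)` for sensitivity analysis)
is so liberal at these matrix sizes that even i.i.d. noise scores below
0.05 once r exceeds a few dozen, which would pin every cutoff sweep at
zero; the raw-ratio form is therefore the default and the form used by
the pipeline.

Degenerate cases: an exact rank-one subset has zero residual and is
reported as f = +∞, SVD-p = 0; subsets smaller than 3 genes, or with
rc − 2r − c + 2 < 1, are rejected.

## Cutoff determination

A cutoff line sweeps outward from zero along one half-axis. The candidate
positions are zero followed by the distinct loading values in the sweep
direction — the subset of genes strictly beyond the line only changes at
those values, so this gene-quantile grid makes the search exact (verified
against brute-force evaluation at every distinct loading) and fast. At
each position the SVD-p of (chart genes beyond the line) × (all arrays of
the axis's data set) is evaluated; the first position at or below
φ = 0.05 is the cutoff. If φ is never reached, the sweep stops when fewer
than `min_genes_floor` (default 3, the working lower limit of a module)
remain beyond the line and returns the last position that kept the floor.
Genes exactly on the cutoff stay inside (open interval "beyond"), which
makes the fallback count well defined. The ±y cutoffs are evaluated on
data set 1's matrix and the ±x cutoffs on data set 2's, matching the
axis-to-data-set correspondence of the chart.

## Primary clusters, pairing, chart

PCL assignment uses the projection identity A·vⱼ = sⱼ·uⱼ, so the score of
gene i for eigengene j is |sⱼ·u_{ij}|; ties break toward the lower
component index (more variance). Retention keeps components 1..k (k
explicit, or the smallest k reaching the 60% cumulative-variance target);
genes of discarded PCLs are by default reintroduced at their next-largest
projection among retained components — this reduces information loss but
can admit noise, so it is switchable. Sign ambiguity of singular vectors
is resolved deterministically: with an array covariate (time, age) each
(uⱼ, vⱼ) is flipped so corr(vⱼ, covariate) ≥ 0, otherwise so the largest-
magnitude element of vⱼ is positive. "Up"/"down" module labels refer to
these oriented axes.

Pairing correlates candidate eigengene profiles (all retained components
by default; an explicit candidate or manual pair list in the config
stands in for visual selection of "meaningful" components when conditions
are similar but not equivalent). Significance uses the t transform on
m − 2 df; the |r| ≥ 0.6 floor guards against spurious matches that are
significant only because m is large. Matching is greedy one-to-one by
|r| — the data sets analysed here never produce conflicting strong
correlations, so any consistent rule would do. An unmatched candidate is
paired with the highest-index empty-PCL component of the other data set
(falling back to the last component); the partner axis then carries only
noise loadings, so all modules from that chart are one-sided by
construction.

The chart takes the union of the pair's two PCLs over the shared gene
universe (verbatim ids, or an ortholog map); a negative pair correlation
negates x so conservation lies on the main diagonal. After the four
cutoffs, blocks classify as conserved (concordant corners), one-sided
divergent (edges), or opposite divergent (discordant corners); blocks
below `min_module_size` (default 5) are discarded while the cutoff-search
floor stays at 3 — the two numbers play different roles and are both
exposed.

## Module coherence

A module's tightness is the mean pairwise Pearson correlation of its
genes across arrays, per data set. Its empirical p is the add-one
fraction (1 + #{null ≥ observed})/(n + 1) over n random gene sets
(default 500) of uniform size in [10, 500], drawn from the full analysed
universe — a pooled null rather than size-matched nulls, which matches
how the reference numbers were produced and keeps the resolution at
1/(n + 1).

## The simulation benchmark

The generator emulates a two-species comparison: 338 orthologous genes ×
18 hourly arrays per species, six planted classes of 30 genes (sine in
both / mouse / human; gamma(shape 9, rate 2) density in mouse and the
same curve 1.5 h later in human; beta(6, 6) density in both) and 218
pattern-free genes per species. Unstated details fixed here: the sine
completes one period over the grid (sin(2πt/18), phase 0); the beta
density is evaluated at t/(n+1); the gamma uses the shape/rate
convention (mode 4 h). Profiles are standardized to zero mean and unit
variance over the grid and scaled by `amplitude`, so amplitude/noise_sd
is the per-entry pattern-to-noise sd ratio. Noise is i.i.d. Gaussian with
sd 0.6 by default — chosen once so that the planted eigengene patterns
are clearly recognizable while the data-driven cutoffs remain strictly
interior and recovered modules sit at ≈ 30 genes (at sd 0.5 the half-
plane gene sets already satisfy φ and the cutoffs collapse to zero; at
sd ≥ 0.7 modules shrink well below the planted size). A user-supplied
residual matrix can replace the Gaussian noise to emulate realistic
correlated residuals.

What passing the benchmark does and does not show: the i.i.d. noise has
no gene-gene or array-array correlation structure, no heavy tails, and no
batch effects, so recovery here demonstrates the machinery (pairing,
empty-PCL devices, cutoff selection, block classification) rather than
robustness to real microarray artefacts. Benchmark analysis settings:
three retained/candidate components per species (one per planted pattern
family), φ = 0.05, module floor 5.

## Comparison baseline

`comparison.pam` is a deterministic PAM (k-medoids, BUILD + SWAP) whose
silhouette widths agree with R's `cluster::pam` to four decimals on this
data; `select_k_by_silhouette` picks k by the average silhouette width.
On the benchmark the selected k is 2–4, short of the four true groups
(three pattern groups plus the diffuse null group, which silhouette
cannot represent as a cluster of its own) — the under-counting failure
that motivates pattern-level comparison. It is a baseline only, never
used for decisions.

## Numerical choices and limitations

- F tail probabilities go through `scipy.stats.f.sf` (regularized
  incomplete beta), stable for the large ν₂ this pipeline produces;
  agreement with direct quadrature of the F density is tested to 1e-6.
- All randomness (simulation, null sets, heatmap subsampling) flows
  through explicit integer seeds; a pipeline run is a pure function of
  (inputs, config).
- Determinism of signs relies on the orientation convention; across BLAS
  implementations singular vectors may differ by more than sign only for
  (near-)degenerate singular values, which the planted benchmark avoids.
- Modules from different pattern pairs may overlap (a gene has one PCL
  per data set but can enter two charts); within one chart modules are
  disjoint.
- Known limitations: conditions must be alignable across data sets; genes
  carrying several patterns can be lost to a single PCL; there is no
  principled rule for how many PCLs to keep or whether to reallocate —
  the 60% target and reallocation default are recommendations, exposed in
  the config.
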