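# Methods

This note documents the models, statistics and numerical choices behind
`spatialplex`, the assumptions they rest on, and what the synthetic-data
tests do and do not establish about real tissue.

## Data model

A sample is a table of segmented cells: 0-based centroid coordinates on
the image pixel grid and one mean 8-bit (0–255) intensity per marker.
The physical scale is a single constant, 0.45 µm/pixel by default; every
µm↔pixel conversion in the package goes through
`neighborhood.radius_in_pixels`, which truncates (10 µm → 22 px,
20 µm → 44 px at 0.45 µm/px). Region (zone) annotations enter either as
named polygons or as an integer label mask (0 = interstitial); when both
are present the mask wins, and a cell belongs to the region containing
its centroid pixel.

## Lognormal shrinkage

Marker intensities from immunofluorescence are well described on the log
scale by a mixture of Gaussians (negative/background and one or more
positive modes). Per marker we fit a 1-D Gaussian mixture to
`log(1 + x)` — the +1 offset admits the zeros that 8-bit means contain —
with `G_i` initial components (default 20). Components whose converged
weight falls below 10⁻³ are dropped and the weights renormalized, giving
`G_f ≤ G_i`; `G_f` strictly below `G_i` for every marker is the
diagnostic that the fit was not starved of components. Fits are seeded
and, above 50 000 cells, use a seeded subsample of that size.

Each value is then assigned to its maximum-responsibility component
(ties broken toward the lower-mean component, deterministically) and
contracted toward that component's mean:
`y = µ_k + (1 − λ)(x − µ_k)`. `λ = 0` is the identity on the log scale,
`λ = 1` collapses components to points; the default `λ = 0.8` keeps
within-component order while compressing within-mode spread. The
contraction factor is deliberately exposed as configuration — the
contracts tested are the identity and collapse limits, idempotence at
`λ = 1`, order preservation below it, and that the output stays inside
the input log-range — rather than any single magic value.

Per-cell marker positivity (needed only for the ≥30 % / ≥70 %-of-cells
summary conventions) is defined without any manual gate: a cell is
positive when its assigned component's mean exceeds the marker's mixture
grand mean `Σ w_k µ_k`. This is deterministic and threshold-free; it is a
package convention, since no gating step exists upstream.

## Nested clustering and cluster characterization

The global pass embeds the shrunk matrix to 2-D with UMAP
(`n_neighbors = 30`, `min_dist = 0`, fixed `random_state`) and clusters
the embedding with HDBSCAN. `min_cluster_size` is the analysis's main
resolution knob (default 200, sensible range roughly 100–300 for
10⁵–10⁶-cell samples); `min_samples` is pinned to 10 so the density
estimate, not the reporting floor, decides what is noise — leaving
`min_samples` at its library default (equal to `min_cluster_size`)
degenerates to all-noise labelings at realistic sizes. Outliers get the
label −1: a garbage collector at the global level. Clusters flagged as
artifacts (tiling borders, tissue folds and similar have unique
phenotypes and footprints) can be excluded manually by id; excluded
cells are dropped from every downstream statistic but kept in the table.

Mapping global clusters to broad lineages is explicit user input (a
dict, or a callable for programmatic use such as ground-truth majority
vote on synthetic data) — no automatic ontology matching. Each lineage
is then re-clustered independently on its own marker subpanel, excluding
global noise; a lineage without a subpanel passes through. At the
subclass level −1 means "an average cell of that lineage", not junk.

Each cluster is characterized against all other non-excluded cells:
a Welch two-sample t-test per marker, significant at `α = 0.05`
Bonferroni-corrected over the markers tested, and a robust effect size
`(median_in − median_out) / pooled MAD` with the pooled MAD the
root-mean-square of the two groups' MADs. The ranked marker list keeps
significant markers with positive effect, largest first. The precise
effect-size formula is a package choice; what is contractually tested is
the ranking behavior (a marker shifted +3 pooled MADs ranks above one
shifted +1.5, a null cluster yields an empty list, rescaling a marker's
intensities does not move its rank).

## Cell-type summaries

Clusters mapped to the same cell type are summarized two ways. Frequency
bands: for each (type, marker), the fraction of the type's clusters whose
significant list contains the marker, bucketed into 70–100 %, 50–69 %
and 30–49 % (below 30 % omitted; 0.70 boundary inclusive). Top ranks:
the median of the marker's 1-based rank across the type's clusters,
reporting markers with median rank in [1, 5] (at most five, ordered by
median then name). A cluster whose list omits the marker contributes no
rank by default; imputing rank `m + 1` instead is available as
configuration. Both computations are verified against brute-force
recounts on randomized profiles. The light-chain ratio is the per-sample
kappa/lambda cell-count ratio with the cohort mean and SD (ddof = 1)
across samples; a zero-lambda sample is reported as undefined rather
than dropped silently.

## Neighborhood analysis

For focal type i, target j and radius r, every cell other than type-i
cells is "near" if it lies within r of at least one i-cell (Euclidean,
centroid to centroid), giving a near/far × j/not-j 2×2 table, a
two-sided Fisher exact test, and the enrichment ratio
(proportion of j among near) / (proportion of j among far) — 20 % vs 5 %
gives 4 — with its log as the symmetric view. For the self pair i = j
all cells are tallied but a cell never counts as its own neighbor (an
i-cell needs a second i-cell in range), so self-aggregation is measured
without trivial self-hits. Degenerate margins have fixed conventions:
no j cells at all → ratio 0, p = 1; no far cells at all → p undefined
(NaN), which marks the pair not evaluable; all j near with far cells
present → ratio +∞ with the exact Fisher p.

Cohort consensus is the strict max-p rule: a pair is significant only if
the maximum p over every sample containing both types and over both
radii (10 and 20 µm) is at or below `α_family / m`. The family size m
defaults to the number of ordered pairs actually tested and is logged in
every consensus table so any realized threshold is reproducible —
consistency note: with `α = 0.05`, m = 6177 reproduces a corrected
threshold of 8.094544277157197 × 10⁻⁶ exactly. m is never hard-coded.
The rule is monotone (adding a sample can only remove calls), which the
suite asserts, and deliberately conservative: simulation places the
falsely-significant consensus rate under complete spatial randomness
well below 1 %.

The median nearest-neighbor distance i→j (median over i-cells of the
distance to the nearest j-cell, × pixel size) is reported as a
descriptive companion without a test; it is directional, and is
calibrated against the Poisson closed form `median = √(ln 2 / (π ρ))`.

## Overlap analysis

Every cell of a population receives an interaction disc of radius r
pixels, rasterized on the native pixel grid: a pixel belongs to a disc
when its center lies inside or on the circle. Cell coordinates are
snapped to the nearest pixel first, so stamping uses one fixed integer
kernel and coverage counting is exact integer arithmetic — this is what
lets an exhaustive per-pixel oracle reproduce the production counts
bit for bit, and it matches the pixel-grid framing of the statistic
(a rasterized r = 22 disc covers 1517 px vs π·22² ≈ 1520.5, a 0.23 %
discretization error). The total tissue area A is the union of discs
over all cells of the sample; border effects are ignored since a ≪ A.

Same-type: `o_i` is the count of pixels covered by ≥ 2 discs of the
type, and the observed ratio `o_i / (pixels covered ≥ 1)` is compared to
the binomial expectation `P(K > 1) / P(K > 0)`, `K ~ Bin(n_i, a/A)` with
a one disc's area — interpreted as the expected fraction of doubly-hit
pixels among hit pixels under uniform placement. Significance comes from
bootstrap: `n_boot` (default 1000, configurable) uniform placements of
`n_i` points on the tissue support (pixels with coverage ≥ 1, not the
bounding box), p = fraction of replicate ratios ≥ observed.

Cross-type: `o_ij = |a_i ∩ a_j| / |a_i ∪ a_j|` (Jaccard of the two
binary footprints, symmetric by construction), with
`p = P[K > ⌊o_ij · min(n_i, n_j)⌋]`, `K ~ Bin(min(n_i, n_j),
max(a_i, a_j)/A)` — strict inequality on the floored product. One
degenerate case is pinned: when the intersection is empty the strict
tail would be `P[K > 0]`, which is small whenever coverage is sparse, so
zero observed overlap would come out "significant"; since an observed
overlap of zero can never exceed the null expectation, p is set to 1
there. The null is conservative (simulated empirical α under CSR sits
well below nominal), so significant overlaps are understatements rather
than flukes. Consensus across samples and radii uses the same max-p
Bonferroni rule as the neighborhood test.

## Zonal analysis

Per sample and per (region, type), a 2×2 in-region/out × type/other
Fisher test. Interstitial cells are never a region of their own but
always count toward the out-of-region margin. The log odds ratio uses
the Haldane–Anscombe +0.5 correction so its sign is usable at zero
cells. Aggregation requires the sign to agree in every sample containing
both region and type and the max p to clear `α / (#regions × #types)` —
a Bonferroni family kept separate from the pairwise analyses (the two
analyses answer different questions; sharing one family is a
configuration change away via `n_tests`). The two descriptive matrices
are row-normalized type-across-region percentages (pooled over samples)
and column-normalized region compositions (per-sample percentages
averaged over the samples containing the region, then renormalized).

## Synthetic data: what it emulates and what it does not

The generator emulates the statistical shape of segmented hyperplexed
data: multinomial type abundances; homogeneous Poisson, Thomas-style
clustered (Gaussian offspring around Poisson parents) and
partner-coupled (Gaussian displacement from a sampled partner) point
patterns with exact counts (out-of-field points are re-drawn, not
clipped); two-component lognormal marker mixtures exponentiated, clipped
to [0, 255] and rounded to integers last; polygonal zones with an
interstitial residual; and seeded multi-sample cohorts
(sample i uses seed base + i). `plant_colocalization` relocates an exact
`round(f · n_b)` of type-b cells uniformly into discs around random
type-a cells, recording ground truth. Default mixture scales (positive
mode around log 80–90 with log-SD ≈ 0.45–0.5, negative mode around log 6
with log-SD 0.6, positive fractions 0.9–0.97) were chosen once as
realistic for mean 8-bit immunofluorescence intensities; the preset
cohort fixes the kappa:lambda plasma-cell abundance at 1.5:1, emulating
the light-chain balance reported for normal nodal tissue.

What it does not emulate: segmentation errors, signal crossbleed between
neighboring cells, staining gradients and tiling artifacts, cell-size
variation, spatially varying density, or any pixel-level image content.
Passing tests therefore demonstrate the correctness and calibration of
the statistics under their stated assumptions — not robustness to those
real-data pathologies, which the artifact-flagging step exists to handle
case by case.

## Problem sizes and numerical choices

The simulation-based checks use cohorts scaled so the whole suite runs
comfortably on one CPU: type-I error from 200 CSR cohorts of 6 samples ×
2 types × 2000 cells on a 2000-px field (chosen so both near and far
margins stay populated at 44 px); cross-overlap calibration from 400 CSR
runs of 300 + 300 + 300 cells on a 600-px field; power from 50 cohorts
of 3000 cells on a 3000-px field with an 80 %-abundant background type —
a sparse-population regime in which the overlap null has power, mirroring
real tissue where any single type is a small fraction of cells; nested
recovery on 5000 cells with two lineages × three subtypes. UMAP runs
with a fixed `random_state` (single-threaded, reproducible); given the
residual stochasticity of embeddings across library versions, clustering
is accepted on ground-truth purity and agreement, never on label
identity. Mixture fits, bootstraps and generators all take explicit
seeds; identical seeds give bit-identical outputs.

## Known limitations

* The near/far dichotomization saturates when a focal type is so
  abundant that discs of radius r tile the tissue (no far cells); such
  pairs are reported as not evaluable rather than forced.
* The cross-overlap binomial null treats disc placements as independent
  Bernoulli pixel hits; it is conservative, so power against weak
  co-localization at high coverage is limited (by design — the
  neighborhood test covers that regime).
* Rasterization snaps centroids to the pixel grid: sub-pixel geometry is
  deliberately out of scope, consistent with coordinates that originate
  from a pixel-level segmentation.
* The zonal Fisher test treats cells as independent; clustered types can
  inflate single-sample significance, which the cross-sample
  sign-consistency + max-p aggregation exists to absorb.
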