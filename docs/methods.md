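# Methods

This document defines every quantity the package computes, in the order
the analysis pipeline produces them.

## Study system and rationale

*Heliconia tortuosa* is an understorey herb of tropical premontane
forest whose pollen is moved almost exclusively by traplining
hummingbirds — habitat specialists such as *Phaethornis guy* that
forage along repeated long-distance routes. Because the plant itself is
sessile, the movement behaviour of these pollinators determines how far
pollen travels across a fragmented countryside of forest patches,
regenerating stands, fencerows and pasture. The package quantifies the
landscape from the pollinator's point of view (functional connectivity)
and asks which description of that landscape best predicts the genetic
composition of the pollen arriving at a plant.

## Landcover and habitat definitions

The landscape is a 10 m raster with five classes: mature forest,
regenerating forest, narrow forest elements (fencerows, riparian
strips), arable land and pasture. Trapliner habitat is defined two
ways:

- **narrow** — mature forest only;
- **broad** — mature forest + regenerating forest + narrow elements.

Agriculture and pasture are never habitat. Patches are connected
components of the binary habitat grid (8-connectivity by default:
diagonally adjacent forest is traversable by a flying bird).
Inter-patch gaps are measured edge-to-edge in metres; on the raster the
gap between two patches is approximated as the minimum centre-to-centre
pixel distance minus one cell width, floored at zero.

A **sampling site** is the per-axis median of the coordinates of the
maternal plants sampled there. The **focal patch** is the habitat patch
containing the site. The **local landscape** is the 1 km-radius disk
around the site — the assumed maximum daily movement range of a
trapliner.

## Connectivity metrics

All metrics derive from an incidence-function-model sum over habitat
pixels,

    S_i = sum_{j != i} exp(-alpha * d_ij) * A_j * p_j

with `i` the sampling-site pixel, `d_ij` the centre-to-centre distance,
`A_j = 1` (each 10 m pixel contributes 0.01 ha) and `alpha = 1/282`
m⁻¹, the inverse mean home-range length of *Phaethornis guy*. `p_j`
encodes whether the pollinator can reach the patch containing pixel
`j`.

### Intra-patch metrics (3, narrow habitat, log-transformed)

1. **total area** — hectares of the entire focal patch;
2. **area within radius** — hectares of the focal patch inside the 1 km
   disk (site pixel excluded, as in all pixel sums);
3. **distance-weighted area** — `sum exp(-alpha d_ij)` over focal-patch
   pixels, in hectares. An elongated patch scores lower than a round
   patch of equal area.

### Local landscape metrics (2 × 2 × 3 = 12)

The factorial crosses:

- habitat definition: narrow | broad;
- distance weighting: unweighted (`k_ij = 1`) | kernel
  (`k_ij = exp(-alpha d_ij)`);
- gap-crossing mode:
  - **unlimited** — `p = 1` everywhere; gaps are ignored;
  - **threshold** — `p = 1` only for patches whose 25 m buffers overlap
    (edge-to-edge gap ≤ 50 m) with the focal patch, directly or through
    stepping-stone chains; `p = 0` otherwise;
  - **probabilistic** — `p = exp(-lambda * d_k)` with
    `lambda = log(2)/50` m⁻¹, so the crossing probability halves per
    50 m of open gap. `d_k` is the minimum **summed** gap distance from
    patch `k` to the focal patch: shortest paths on the complete
    patch-gap graph, where traversing habitat is free and only open
    gaps accumulate cost (computed with Dijkstra's algorithm).

Two structural consequences are used as test invariants: for a fixed
landscape, `unlimited ≥ threshold` and `unlimited ≥ probabilistic`
(dropping `p` below 1 can only shrink the sum), `unweighted ≥ kernel`,
and `broad ≥ narrow`. As `lambda → 0` the probabilistic metric recovers
the unlimited one; as `lambda → ∞` it retains only patches reachable
with zero open gap.

## Pollen-pool genetics

For each seed with a genotyped mother, the paternal (pollen) haplotype
is obtained per microsatellite locus by subtracting the maternal
genotype:

- the seed carries one allele the mother lacks → that allele is
  paternal (resolved);
- the seed is homozygous, or the mother is → forced (resolved);
- mother and seed are the same heterozygote {A, B} → either allele may
  be paternal (ambiguous);
- the seed shares no allele with the mother → incompatibility error
  (configurable to "treat as missing").

Haplotypes pool per site (years combined). Allele counts weight
resolved alleles 1 and each allele of an ambiguous pair ½. **Haplotype
diversity** is Nei's gene diversity averaged over loci with at least
two contributions:

    h = mean_L ( 1 - sum_a p_{L,a}^2 )

optionally with the `n/(n-1)` small-sample correction.

The pollinator-community response is the **proportion of high-mobility
hummingbirds** among mist-net captures, shrunk toward ½ by four
pseudo-observations: `(n_high + 2) / (n_total + 4)`, strictly inside
(0, 1) for any counts. Biparental inbreeding (`t_m − t_s`, multilocus
minus single-locus outcrossing rate) is estimated externally and passed
through as a response column.

## Model comparison

Each response is regressed on each metric in turn — the metrics are
alternative single-predictor explanations, never additive terms,
because they are strongly intercorrelated. Proportions (the capture
proportion and h) are arcsine-square-root transformed; all variables
are then standardized (sample SD, n−1), so slopes are beta
coefficients and `r² = beta²`.

Models are ranked within a set (the 3 intra-patch metrics, or the 12
local metrics, per response) by small-sample AICc with `k = 3`
(intercept, slope, residual variance) and the Gaussian log-likelihood
at the ML variance RSS/n:

    AICc = -2 logL + 2k + 2k(k+1)/(n-k-1)

Relative support is the Akaike weight
`w_m = exp(-ΔAICc_m/2) / sum_n exp(-ΔAICc_n/2)`, and factor-level
support is the summed weight over all local models sharing a level of
habitat definition, weighting, or gap mode (sums over a factor's
levels partition 1).

The published model-comparison summaries for the study system are
shipped in `pollenscape.reference_tables`; recomputing the weights from
their AICc columns reproduces the published weights to within one unit
in the third decimal (the propagated bound of the tables' 2-decimal
AICc rounding). This validates the inference arithmetic end to end.

## Synthetic data generator

Everything downstream of field data can be exercised with the synthetic
generator, which is a pure function of its configuration and seed:

- **landscapes** — pasture matrix, quasi-elliptical mature patches with
  lognormal radii, regenerating forest hugging mature edges, straight
  narrow elements of configured width;
- **sites and plants** — sites on mature forest, five maternal plants
  within 100 m, site = median plant coordinate (snapped to the patch if
  the median falls off habitat);
- **genotypes** — per-locus allele frequencies drawn from a symmetric
  Dirichlet (defaults: 11 loci, 10 alleles, concentration 5 — typical
  microsatellite variability), individuals in Hardy-Weinberg
  proportions; one regional gene pool is shared across the landscapes
  of an ensemble;
- **pollination** — pollen donors at 1 per hectare of broad habitat;
  each seed's father is sampled with probability proportional to
  `exp(-alpha d) * exp(-lambda d_k)`, i.e. the same distance ×
  gap-crossing kernel the probabilistic metric encodes; the seed
  receives one maternal and one paternal allele per locus;
- **responses** — capture counts Binomial with a logistic link on a
  chosen metric, and biparental inbreeding linear in a chosen metric
  with Gaussian noise, so regression sign and ranking behaviour have a
  known ground truth.

### Gap-gradient ensembles (parameter recovery)

Testing whether the analysis can *recover* the generating gap-crossing
behaviour requires landscapes in which gap structure varies while
everything it is usually confounded with stays fixed.
`gap_gradient_tile` builds such a landscape: a small focal mature disc
ringed by five fixed-distance satellite patches, each connected by a
corridor whose forest hedge length sets the summed open gap (drawn
uniformly over 20–330 m); the habitat displaced by a shorter hedge is
re-attached behind the satellite, so total habitat area and all centre
distances are constant across tiles. Fathers are drawn under the
probabilistic kernel; with 200 such tiles per ensemble, the
probabilistic local metric is the top-weight model for haplotype
diversity in ~95 % of replicate ensembles, so the replicated study in
`scripts/acceptance.py` clears its 60 % pass bar with wide margin.

## Numerical conventions

- Rasters: north-up, origin = map coordinate of the pixel (0, 0)
  centre; site→pixel mapping by rounding.
- Gap distance: boundary pixels only (the minimum is always attained
  there), KD-tree nearest-neighbour queries.
- Patch labels: row-major first-seen order, deterministic.
- All randomness flows through one seeded NumPy generator per run.
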