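# Methods

This note records the statistical model behind `herdlevels`, the choices made
where the design was genuinely open, and what the synthetic data generator
does and does not emulate.

## Distance-distribution thresholding

Inter-individual distances are pooled over all snapshots, within snapshot and
zone, for seen non-infant individuals only (infants track their mothers and
would distort the within-unit spacing; tree-hidden horses carry a tree
coordinate, not their own, and contribute no distances). Distances below
0.01 m are floored to it so the log transform is safe; the count of floored
pairs is reported.

The log10 distances are modelled as a k-component Gaussian mixture fitted by
EM. Everything downstream is on the log10 scale because every derived
quantity (peaks, valley) is expressed as a power of ten. Model-selection uses
BIC with `3k − 1` free parameters; the default rule takes the smallest k at
which BIC has essentially converged (relative drop `< 1e-3`), with plain
argmin available. A two-tier society yields k = 2; all threshold derivations
require it.

EM numerical choices:

* log-likelihood is asserted non-decreasing at every iteration (a failed
  assertion is a bug, not a data property);
* convergence at per-observation gain `< 1e-8`; iteration cap 2000;
* restarts: one deterministic start at evenly spaced quantile means with the
  pooled sd, one deterministic start from 1-D k-means means, and the
  remaining starts at random quantile levels with jittered sds. The random-
  quantile and k-means starts exist because a minority mode holding ~5–10%
  of the mass a full log-unit from the main mass is never found from
  interior quantile starts alone — all such starts converge to a merged
  two-component split of the main mass with lower likelihood than the
  anchored solution;
* components with vanishing variance abort the restart; if every restart
  degenerates the fit errors out;
* samples beyond `max_n` (default 100,000) are subsampled with the fit's
  seed before EM. The thresholds are functionals of the distribution, not of
  n, so this changes only Monte-Carlo error; it keeps the fit at interactive
  speed on the ~10⁶ distances a full survey produces. Data are sorted before
  subsampling so fits are invariant to input order.

The valley is the crossing of the two *weighted* component densities between
the means: equating log-densities gives a quadratic in x whose in-interval
root is taken; `v12 = 10^root`. The weighted-density convention (rather than
the mixture-density minimum) is used because it reproduces the published
intersection value exactly from the published parameters. Nested or
single-dominant component pairs have no in-interval root and raise an error
("no valley between peaks").

## Unit detection

The simple ratio index for a dyad is `together / either`, counted per
snapshot: `together` when both were observed and closer than `v12` —
with the tree convention: all horses under one tree are mutually together,
and a seen horse closer than `v12` to a tree's centre is together with that
tree's occupants; `either` when at least one of the two was observed (seen
or tree-hidden). `0/0` is defined as 0.

The membership threshold defaults to the upper edge of the widest empty
interval among the positive SRI values (the automatic analogue of reading
the bimodal association histogram by eye) and can be overridden. Membership
comparisons use `>=`.

Units are connected components of the thresholded SRI graph, reduced to
complete subgraphs by iterative peeling: remove the member with the fewest
within-component edges, breaking ties by lowest summed SRI and then
lexicographic id (fixed order makes the partition deterministic and
invariant to relabelling). Peeled members and singletons are solitary. A
unit with no adult females is an all-male unit (AMU); otherwise a harem.
Membership is treated as static over the study window; temporal
fission–fusion of membership is out of scope.

The 30%-out-of-frame filter drops a snapshot when more than the given
fraction of *available* horses (all with visibility other than `absent`)
were out of frame; the boundary case is kept. "Available" is not defined
operationally in field protocols; counting every horse known to be at the
site that snapshot is the natural reading. Coordinates are assumed already
projected to planar metres; the package does no geodesy.

## Herd-level analysis

Unit centres are the mean positions of observed non-infant members (tree
centres substituting for hidden horses); a unit whose members split evenly
across zones in one snapshot is dropped for that snapshot, otherwise the
majority zone is used.

**Time-shift permutation.** Each unit × day receives one shift from
{−30, 0, +30} minutes per replicate; a shifted fix whose (date, time) does
not match an observed sampling slot is dropped for that replicate. The
statistic is the median inter-unit centre distance over co-present
(date, time, zone) groups, all pairs by default (nearest-unit optional — the
field convention is ambiguous between the two; all-pairs is the default
because the published quartiles are all-pairs-sized). One-sided p with the
+1 correction: aggregation means *smaller* observed medians. A two-sample KS
test comparing pooled observed vs pooled permuted distances is reported
alongside. Replicates with no co-present pairs are resampled and counted.

**UDOI.** Utilization distributions are Gaussian KDEs on a shared grid
(default 5 m in the API, 20 m in the pipeline defaults for speed; bandwidth
`href = σ n^(−1/6)` with σ the pooled coordinate sd, both configurable —
no field convention exists). Home ranges are the highest-density cells
capturing 95% of mass, ties included, so a uniform UD keeps its full
support and the identical-uniform calibration equals 1 exactly.
`UDOI(i,j) = A_ij · Σ UD_i·UD_j · cell_area` with `A_ij` the overlap area of
the two 95% ranges. Units with fewer than 5 fixes are omitted with a
warning. Each UD is renormalized on its grid (integral 1 ± 1e−3 asserted in
tests).

**Welch split test.** Nearest-unit distances per unit-snapshot, stratified
at a calendar date, compared with Welch's unequal-variance t-test.

## Unit-level network and permutation inference

Per snapshot and zone, co-present units with centre distance strictly below
`p2` are linked and groups are the connected components (chained proximity —
"gambit of the group"). Solitary individuals are excluded. Unit-level SRI:
together = snapshots sharing a group; either = snapshots with at least one
of the two at the site (cross-zone co-presence counts toward either only).
The comparison network is `1/d̄²` per dyad with `d̄` the mean centre distance
over co-present same-zone snapshots (a member-dyad averaging basis is
provided as an option; centre distances are the default since the network's
nodes are units). The Mantel test correlates upper triangles under joint
row/column permutation, one-sided, +1-corrected, with exhaustive enumeration
available for small matrices.

**Data-stream permutation.** A swap picks a (snapshot, zone) stratum with at
least two groups and a donor group of ≥ 2 units, and moves one unit to
another group of the stratum. This conserves each unit's presence pattern
and the per-stratum group count (donor groups of size 1 are never emptied).
Networks are recorded after every swap along the accumulated chain, after a
burn-in of 1000 unrecorded swaps (chain-with-burn-in is the convention of
the data-stream literature; both the burn-in and recording cadence are
configurable). Together-counts are maintained incrementally and verified in
tests against from-scratch recounts. The SD test compares the edge-weight
standard deviation (dyads with observable either-counts) right-tailed
against the null networks.

**MRQAP-DSP.** The response and predictors are vectorized over the upper
triangle with an intercept column. For each term, the term is residualized
on all the others (QR projection), the residual matrix is permuted by
simultaneous row/column relabelling, and the full-model coefficient of the
permuted residual (Frisch–Waugh form) is tabulated; three tails are
reported: `p(β≥r)`, `p(β≤r)`, `p(|β|≤|r|)` (the last is the probability of a
permuted coefficient at least as large in magnitude — the two-sided test).
Exhaustive enumeration over all node permutations is available for n ≤ ~8.
Collinear predictors are rejected by rank check. The standard dyadic design
offers |size_i − size_j|, type similarity (0 same, 1 different),
|strength_i − strength_j|, and location overlap = the proportion of shared
observation days on which the two units used the same zone.

**Nodal DSP.** OLS coefficients, SEs and t-values, plus a per-predictor
permutation p by the Freedman–Lane scheme: fit the model without the focal
predictor, permute its residuals, add them back to the reduced fit, refit,
compare |t|. The intercept gets no permutation p. Strength centrality is the
full weighted row sum of the SRI network. The harem/AMU indicator is coded
+1/−1. Two standard designs mirror common usage: type + mean-centred
observation count over all units; size + stallion count + observation count
over harems only.

## The synthetic society generator

The generator emulates the *statistical* structure a drone survey of a
two-tier herd produces:

* a fixed roster: 23 units of 2–9 non-infant horses (~9% AMUs) plus 5
  solitary males, ~126 individuals; membership constant, whole units appear
  at the site together;
* 12 snapshots/day at 30-min cadence over 19 days, two disjoint zones;
* herd mode: per snapshot, unit centres pack around a wandering herd centre
  (Gaussian cloud, scale `0.28 × 10^log10_inter_mu`, reflected random walk)
  with a hard minimum-separation floor `10^(inter_mu − 1.7·inter_sigma)`
  (~46 m at defaults) and an expansion-only per-snapshot dispersion factor
  `10^(0.15·|Z|)` (herds string out but do not over-compact);
* members displaced isotropically (Gaussian) so the *median* within-unit
  pair distance is `10^log10_intra_mu`;
* persistent spatial structure: AMUs and solitaries carry a radial
  periphery factor (default 1.6), harems a size gradient scaled by
  (periphery − 1) — large harems central — each with a fixed per-unit
  log-normal idiosyncrasy; placement order is randomized per snapshot so
  sequential packing does not correlate with identity;
* loose attachment: per-snapshot unit absence and day-level zone-split
  propensity both increase with the radial factor, so peripheral units are
  also seen less and split off more — this coupling is what gives the
  unit-level network its realistic heterogeneity;
* dropout: whole-unit tree-hidden snapshots (co-resting, tree centre
  recorded), independent per-individual out-of-frame loss;
* null mode: identical roster, schedule and dropout (shared seed streams),
  but each unit follows its own independent reflected walk over the day's
  zone — no inter-unit attraction.

Calibration is by construction: the member scale follows from the Rayleigh
median, and the two centre-cloud constants (packing scale 0.28, separation
exponent 1.7) were fixed once so that, at default conditions, a
two-component mixture fitted to the emitted distances recovers the planted
modes — they are generator constants, not user parameters.

What the generator does **not** emulate: behavioural trajectories (gait,
foraging, leadership), dominance interactions, temporal membership change,
terrain, and the exact shapes of real distance distributions — in
particular, within-unit log distances are log-Rayleigh (slightly
left-skewed) rather than exactly Gaussian, which is why single-unit data,
while unimodal, can still earn k = 2 from BIC at small n. Tests passing on
synthetic data therefore show the *pipeline's* correctness and calibration
under the assumed structure, not field-data robustness.

## Problem sizes used in the test suite

The suite runs the full-size generator (19 days) where the claim concerns
default conditions (mixture recovery, unit recovery, herd-test power and
type-I error at 200 replicates over 20 seeds) and scaled-down societies
(4 days, 8 snapshots/day) for structural checks where size is irrelevant.
Permutation regressions use 1000 permutations in calibration runs and
exhaustive enumeration (n = 5 nodes) for oracle agreement.

## Known limitations

* Static unit membership; individuals that switch units blur the SRI gap.
* The valley derivation requires exactly two components; deeper hierarchies
  (a v23 valley) are an extension point, not implemented.
* The time-shift null preserves within-day trajectories only at the
  surveyed cadence; irregular sampling grids would need slot matching rules
  beyond (date, time) equality.
* UDOI depends on bandwidth and grid; defaults are conventional, not
  optimized.
* Data-stream permutation assumes group counts per stratum are meaningful;
  with very sparse strata the chain mixes slowly.
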