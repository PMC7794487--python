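# herdlevels

Detection and analysis of **multilevel animal societies** from snapshot
positional data.

Many social mammals — equids among them — live in two-tiered societies: small
stable **units** (harems of one or two stallions with mares and young, or
all-male "bachelor" units) that in turn aggregate into a loose higher-level
**herd**. Aerial (drone) surveys make it possible to record the positions of
every identified individual at a site simultaneously, many times a day. This
package turns such repeated position snapshots into a quantitative test of
multilevel structure, with no hand-picked association distance.

## The method

1. **Distance thresholding.** Pool all same-snapshot, same-zone
   inter-individual distances and fit their log10 values with a
   two-component Gaussian mixture by EM,
   `f(x) = Σ_i w_i N(x; μ_i, σ_i²)`. In a two-tier society the histogram is
   bimodal: the peaks `p1 = 10^μ1` and `p2 = 10^μ2` are the typical
   within-unit and between-unit spacings. The valley
   `v12 = 10^x*` — where `w1 N(x*; μ1, σ1²) = w2 N(x*; μ2, σ2²)` between the
   means — separates intra- from inter-unit association.
2. **Unit detection.** Score every dyad with the simple ratio index
   (SRI = snapshots together within `v12` / snapshots at least one was
   observed, with horses hidden under one tree counted as together). The
   positive SRI values are sharply bimodal; the widest gap gives a
   membership threshold, and units are the maximal *completely connected*
   groups at that threshold (members not linked to every other member are
   peeled off as solitary).
3. **Herd test.** Compute unit centres (mean member position) per snapshot
   and ask whether units actually attract each other: each unit's daily
   trajectory is randomly shifted by −30/0/+30 min and inter-unit distances
   recomputed; aggregation shows as an observed median distance smaller than
   the time-shifted null. Kernel home-range overlap (UDOI) checks that units
   share a range rather than holding territories.
4. **Unit-level network.** Per snapshot, units closer than `p2` (directly or
   chained through another unit) form groups; pooling snapshots gives a
   unit-level SRI network. Its structure is tested with data-stream
   permutations (membership swaps within snapshot × zone strata, edge-weight
   SD test), MRQAP with double-semi-partialing for dyadic predictors, and
   nodal DSP regressions of strength centrality.

A synthetic society generator (`herdlevels.simulate`) produces datasets with
exactly this structure — stable units around a wandering herd centre,
peripheral bachelor units, per-snapshot dropout, zone splits — together with
their ground truth, plus a matched *null* variant with no inter-unit
attraction, so the whole pipeline is testable end to end without field data.

## Worked example

```python
from herdlevels import *

table, truth = generate(SocietyConfig(seed=1))       # synthetic herd society
table = filter_snapshots(table)                      # 30% out-of-frame rule
dists = pairwise_distances(table)                    # 852,586 distances

fit = fit_mixture(dists, k=2, seed=1)                # EM on log10 distances
thr = derive_thresholds(fit)
print(fit.means, thr.p1, thr.v12, thr.p2)

assoc = intra_unit_association(table, thr.v12)       # dyadic SRI at v12
part = partition_units(assoc, meta=table.meta)       # clique units
track = unit_centres(table, part)
res = timeshift_permutation(track, n_perm=1000, seed=1)
net = unit_sri(snapshot_groups(track, thr.p2))
r, p = mantel(net.sri, distance_network(track).to_numpy(), seed=1)
```

Output for seed 1:

```
w  = [0.0707 0.9293]   mu = [1.0282 2.1388]   sd = [0.3258 0.2232]
p1 = 10.7 m   v12 = 32.0 m   p2 = 137.7 m
units = 23   solitaries = 5        (ground truth recovered exactly, ARI = 1.0)
observed median inter-unit distance = 145.5 m, time-shift p = 0.000999
unit-level edge weight = 0.458 ± 0.118,  Mantel r (SRI vs 1/d²) = 0.80
```

The mixture recovers the planted spacing modes (true log10 means 1.02 and
2.09); the valley lands at 32 m because the synthetic herd's tiers, while at
the planted modes, have their own overlap geometry. The time-shift p-value
says none of 1000 trajectory randomizations produced a median inter-unit
distance as small as observed — the units aggregate. On the matched null
generator (`herd_attraction="null"`) the same test is non-significant.

The same pipeline runs from the shell:

```sh
herdlevels simulate --seed 1 --out sim/
herdlevels pipeline --seed 1 --out results/      # all stages + manifest
herdlevels thresholds distances.csv --plot hist.png
```

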