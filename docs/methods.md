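# Methods

## The model

All three engines share one two-step skeleton over a sparse pairwise weight
map `W[(demand k, supply j)]`, defined only for block pairs whose road
travel time satisfies `d_kj ≤ d0`:

1. **Supply–demand ratio.** For each block `j` with supply `S_j > 0`:
   `R_j = S_j / Σ_k D_k · W[k, j]`, the supply at `j` divided by the
   weighted population able to reach it. When no weighted demand reaches
   `j`, `R_j = 0` — an unreachable clinic provides no accessibility (this
   also avoids NaN propagation).
2. **Accessibility.** For each demand block `i`:
   `A_i = Σ_j R_j · W[i, j]` over in-catchment supply blocks.

The methods differ only in `W`:

- `2sfca`: a distance weight `f(d)` — the indicator (1 inside the
  catchment) by default, optionally Gaussian `exp(-d²/2β²)`.
- `2svca`: binary — 1 iff both blocks have ≥ 1 provider record with
  strictly positive download *and* upload speed.
- `e2svca`: the step-wise weight of `x = min(b_iu, b_id, b_ju, b_jd)`,
  the binding speed of a two-way video link. There is **no** distance
  decay inside the catchment for the virtual methods: membership is binary
  by `d0`. Both steps share the same `d0`; no supply-side/demand-side
  distinction is made.

Because both steps use the same weights, the engines obey the conservation
identity `Σ_i D_i·A_i = Σ_{j: denom_j>0} S_j` — the population-weighted
total accessibility equals the supply that is reachable by any weighted
demand. This is the principal engine test (checked to 1e-9 relative on 200
random fixtures) alongside exact equivalence (1e-12) with an independently
written triple-loop reference implementation.

### Weight schedule

The default schedule comes from 1-to-1 Zoom video-call bandwidth tiers:

| speed x (Mbps)  | weight |
|-----------------|--------|
| [0, 0.6)        | 0      |
| [0.6, 1.2)      | 0.33   |
| [1.2, 3.0)      | 0.66   |
| [3.0, ∞)        | 1.0    |

Bins are closed on the left, open on the right (the only boundary
convention the tier definitions admit: 0.6 Mbps *sustains* basic video).
Published schedules print a sentinel upper bound such as 9999.0 on the top
bin; the implementation treats the top bin as unbounded so the function is
total. The 1080p tier's upload requirement is simplified to equal its
download requirement (3.0 Mbps); this lives in the default schedule
constant, not in code — any `{"breaks": [...], "weights": [...]}` JSON
config may replace it.

### Speed metrics

Per-provider speeds are aggregated per block and per direction
independently. The modal set is the set of values attaining maximal
provider count, with exact equality on parsed decimals (FCC-style speeds
are coarse decimals; no epsilon). When all frequencies tie, the modal set
is the whole value set, so `min_f = min_a` and `max_f = max` of all values
— the natural completion of a definition usually stated only for a unique
mode. `avg` is retained as the baseline that earlier virtual-catchment
work used and is never a default: a single gigabit offering can drag the
mean far above what most households can buy (the worked example's upload
list averages 126.78 Mbps against a modal speed of 3.0).

Blocks with no broadband record get weight 0 in the broadband modes rather
than raising: real FCC extracts have gaps, and a block that cannot be
scored should depress, not crash, the analysis. `validate_study_area`
reports such blocks (plus duplicate ids and orphan references) so the gap
is visible.

## Travel times

OD times come either from a long-format CSV (origin, destination, minutes)
or from shortest paths on a directed road graph whose edge weights are
minutes directly — no speed-limit/length conversion, keeping the module
agnostic to whichever routing engine produced a real deployment's matrix.
Centroids attach to the network by nearest-node Euclidean snapping with a
deterministic smallest-id tie-break (real studies delegate this to the
routing engine; snapping is this package's documented choice). An absent
OD pair always means *unreachable* — outside every catchment — never 0
minutes. Dijkstra runs once per distinct origin node with an optional
cutoff at the largest catchment size; a full national-scale cross-product
(~2.8×10¹⁰ pairs for ~167k blocks) is out of scope by design.

## Post-processing

- Per-capita scaling multiplies scores by a factor (1,000 by default) and
  records the composed factor on the result.
- Min-max normalization and summary statistics default to
  **report-region blocks only**: buffer blocks exist to absorb edge
  effects during computation and would distort minima and maxima.
- Classification uses half-open bins with the top class closed at its
  upper bound; defaults are raw breaks (0, 2, 3, 4, 5, 8] and normalized
  quintiles (0, 0.2, …, 1]. Scores are classed unrounded; map legends that
  print "2.01–3.00" imply two-decimal rounding before classing, a
  presentational difference this package does not reproduce. A score above
  the top break is an error naming the block, not a silent clamp.
- Differencing (`a − b`) requires identical block sets, catchment size and
  scaling; the zero class uses exact float equality by default because
  identical-input pipelines here are bit-deterministic. A tolerance is
  exposed for cross-implementation comparisons.
- The summary standard deviation is the population form by default
  (`sample_std=True` switches to n−1).

## Synthetic study areas

The generator emulates the *structure* of the real inputs, not their
geography: a rows×cols lattice of unit blocks whose outer ring is a buffer
(one block wide by default, standing in for the mile-buffer a real study
draws); log-normal populations (median ≈ 40, σ_log = 1 — census block
populations are strongly right-skewed); doctors Poisson-drawn around 2
cluster centers with exponential decay (intensity 6 at center, e-folding 2
blocks), emulating a downtown concentration; 1–8 providers per block drawn
from six tiers spanning legacy ADSL (1.5/0.6 Mbps) to fiber
(1000/1000 Mbps); and a 5% digital-divide mixing probability under which a
block's every offered speed is uniform in [0.05, 0.55] Mbps — below the
lowest video tier. When the probability is positive, at least one report
block is guaranteed to be a divide block so the zero bin is always
exercised. Road edges connect lattice neighbours with traversal minutes
uniform in [1, 4].

One integer seed drives every draw; identical configs give byte-identical
outputs. What the generator does **not** emulate: real street topology,
polygon geometry, population/broadband vintage mismatches, provider churn,
or spatially correlated broadband quality. Passing tests therefore show
the *engines and plumbing* are correct under realistic marginal
distributions; they do not validate conclusions about any real region.

## Numerical and design notes

- Accessibility sums run in input block order with plain float64
  accumulation; fixtures are small enough that ordering effects sit far
  below the 1e-9 conservation tolerance.
- The worked-example study area pins the two published ten-provider speed
  lists (downloads 2…1000, uploads 0.5…1000) to their original 15-digit
  block ids so metric values can be recomputed from raw records end to
  end. A companion figure sometimes quoted for that upload list — a mean
  of 6.8 after dropping the two extreme values — is arithmetically
  inconsistent with the remaining eight values (8.475) and is documented
  here rather than reproduced.
- Desk-scale defaults (8×8 grid, ≤ 25-block oracle fixtures, 200
  conservation fixtures) were chosen so the full suite runs in seconds
  while still exercising unreachability, buffer scoping, frequency ties
  and the zero bin.
- `block_id` is an opaque string everywhere, including all CSV I/O
  (`dtype=str`), preserving leading zeros; result CSVs store scores via
  `repr` and are re-read with round-trip float parsing, so score
  round-trips are bit exact.

## Limitations

Latency, jitter, packet loss and peak-hour contention are not modelled —
advertised maximum speeds are taken at face value, as in the underlying
data. No variable catchment sizes, M2SFCA-style distance penalties, or
demand segmentation by digital literacy. Choropleth rendering is out of
scope; exports are CSV and GeoJSON points for styling in GIS tools.
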