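# e2svca — telehealth accessibility with virtual catchment area models

Measuring access to telehealth needs more than travel time: a video visit
only happens if *both* the patient's and the provider's broadband can carry
it. This package implements three two-step catchment area models over
census-block-style areal units, for health-geography analysts who work with
block-level population, provider and FCC Form 477-style broadband data:

- **2SFCA** — the classic Two-Step Floating Catchment Area model. For each
  supply block *j*, compute the supply–demand ratio
  *R<sub>j</sub> = S<sub>j</sub> / Σ<sub>k∈{d<sub>kj</sub>≤d₀}</sub> D<sub>k</sub>*;
  for each demand block *i*, accessibility is
  *A<sub>i</sub> = Σ<sub>j∈{d<sub>ij</sub>≤d₀}</sub> R<sub>j</sub>*,
  where *S<sub>j</sub>* is doctors, *D<sub>k</sub>* is population and *d₀*
  the travel-time catchment (an optional distance-decay weight *f(d)* is
  supported).
- **2SVCA** — the Two-Step Virtual Catchment Area model: the same two
  steps, but weighted by a binary broadband joint function
  *f(b<sub>i</sub>b<sub>j</sub>) ∈ {0, 1}* — 1 iff both blocks have at
  least one Internet provider, regardless of speed.
- **E2SVCA** — the Enhanced 2SVCA: the binary weight is replaced by a
  step-wise function of *x = min(b<sub>iu</sub>, b<sub>id</sub>,
  b<sub>ju</sub>, b<sub>jd</sub>)* — the minimum of patient upload/download
  and provider upload/download speeds — graded against video-call bandwidth
  tiers (default: 0 below 0.6 Mbps, 0.33 from 0.6, 0.66 from 1.2, 1.0 from
  3.0 Mbps).

Because FCC-style data reports one speed per provider per block, a block
needs a single representative speed. Four aggregation metrics are provided:
`avg` (the mean — a poor summary, dominated by gigabit outliers), `min_a`
(minimum available: worst case), `min_f` and `max_f` (minimum/maximum of the
most-frequent speeds: common and optimal cases).

The package also ships a deterministic synthetic study-area generator
(lattice blocks, clustered doctors, multi-provider speed mixtures with a
digital-divide component, buffer ring, random-minutes road lattice), a
shortest-path OD matrix builder, CSV/GeoJSON readers and writers, and
post-processing (per-capita scaling, min-max normalization, class breaks,
method differencing, summary statistics).

## Worked example

```python
import e2svca as m

area = m.generate(m.ScenarioConfig(seed=7))          # 8x8 grid, 1-block buffer
snap = m.snap_to_graph(area.blocks, area.graph)
od = m.od_matrix(area.graph, snap, snap, cutoff=10)  # 10-minute catchment

res2 = m.compute(area.blocks, od, m.CatchmentSpec(10), "2svca",
                 records=area.records)
rese = m.compute(area.blocks, od, m.CatchmentSpec(10), "e2svca",
                 metric="min_f", records=area.records)
res2, rese = (m.per_capita_scale(r, 1000) for r in (res2, rese))

print(m.summarize(res2, area.blocks))   # mean 62.58, std 18.94, min 21.24, max 92.85
print(m.summarize(rese, area.blocks))   # mean 62.60, std 27.51, min 0.00,  max 109.38
d = m.difference(res2, rese, area.blocks)
print(d.counts)                         # {'under': 26, 'equal': 0, 'over': 10}
```

Scores are doctors per 1,000 people reachable within the catchment. The
binary 2SVCA model gives every block a positive score (every block has
*some* provider), while E2SVCA zeroes out the study area's digital-divide
block — its best offered speed is under 0.6 Mbps, too slow for any video
call — and redistributes the freed-up supply to its competitors. In the
difference `2svca − e2svca`, 10 report blocks (585 people) come out
"over" — the binary model credits them (most starkly the divide block
itself: 47.7 vs 0.0) with access their broadband cannot deliver — while the
26 "under" blocks gain under E2SVCA because the divide block no longer
competes for their doctors.

The same pipeline runs from the shell:

```sh
e2svca simulate --seed 7 --out-dir data/
e2svca odmatrix --blocks data/blocks.csv --nodes data/nodes.csv \
    --edges data/edges.csv --cutoff 10 --out data/od.csv
e2svca access --blocks data/blocks.csv --od data/od.csv \
    --method e2svca --metric min_f --broadband data/broadband.csv \
    --d0 10 --per-capita 1000 --normalize --out results.csv
e2svca diff --a results_2svca.csv --b results.csv \
    --blocks data/blocks.csv --out diff.csv
```

Repeat `--d0` for a catchment-size sweep (e.g. `--d0 15 --d0 30 --d0 45`);
each run writes a suffixed output file.

## Layout

| Module                | Purpose                                              |
|-----------------------|------------------------------------------------------|
| `e2svca.model`        | Domain types, validation, study-area consistency     |
| `e2svca.broadband`    | Speed aggregation metrics and weight functions       |
| `e2svca.travel`       | Centroid snapping, shortest-path OD matrices         |
| `e2svca.fca`          | The three two-step accessibility engines             |
| `e2svca.postprocess`  | Scaling, normalization, classes, diffs, summaries    |
| `e2svca.synth`        | Deterministic synthetic study-area generator         |
| `e2svca.io`           | CSV / JSON / GeoJSON readers and writers             |
| `e2svca.cli`          | `e2svca` command-line pipeline                       |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
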