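# glvmap

Assembly maps for microbial communities under capped generalized
Lotka–Volterra (gLV) dynamics.

A community is a set of species with intrinsic growth rates, self-regulation,
pairwise interactions, and a total-population cap at which growth becomes
zero-sum competition for space. `glvmap` enumerates every viable
subcommunity of a focal "climax" community, resolves every single-species
(or multi-species consortium) invasion between them, and assembles the
resulting directed **assembly map** — the graph of all routes by which the
community can build itself from an uncolonised state. On top of the map it
provides:

- **Markov occupancy**: treat the map as a continuous-time Markov chain with
  per-species arrival rate γ and loss rate δ, and compute the stationary
  probability of observing each subcommunity (and each community size).
- **Host interventions**: consortium arrivals (joint invasions that jump
  gaps in the map) and host feeding, modelled as a two-layer network (fed
  and unfed assembly maps joined at subcommunities viable in both) with
  path search for feed-early/wean-late assembly routes.
- **Community generation**: rejection sampling of viable climax communities
  with controlled size, connectivity, half-normal interaction strength, and
  facilitation proportion (fraction of interactions switched positive).
- **Longitudinal colonization analysis**: colonization-time extraction from
  long-format abundance tables, sparse discrete-gLV interaction regression,
  pairwise colonization-order predictability scores, a one-sample
  permutation test, a helpfulness-vs-arrival-time regression, and a
  Bayesian mixed model with a genus-level multimembership random effect.
- **Synthetic data**: archetype communities with analytically known map
  structure, and an infant-cohort simulator with known interaction ground
  truth, so the entire pipeline is testable offline.

## CLI

All functionality is exposed through one entry point:

```bash
# sample a viable climax community (JSON or CSV output)
glvmap sample --S 6 --C 0.5 --sigma 0.05 --pm 0.5 --seed 1 --out community.json

# build its assembly map (+ optional edge list / GraphML)
glvmap map --params community.json --out map.json --edgelist edges.csv

# stationary occupancy under arrival/loss rates
glvmap markov --params community.json --map map.json --gamma 20 --delta 1 \
    --out pi.csv --sizes-out sizes.csv

# consortium arrivals and host-feeding multilayer analysis
glvmap intervene --params community.json --consortium-size 2 --feed 0.1 --out-dir out/

# synthetic cohort with ground truth, then the clinical pipeline on it
glvmap simulate-cohort --archetype commensal_chain --subjects 13 --seed 0 \
    --out cohort.csv --truth-out truth.json
glvmap analyze --data cohort.csv --threshold 0.5 --nperm 10000 --seed 0 --out-dir analysis/

# replicate sweep driven by a YAML config (one summary row per community)
glvmap run --config sweep.yaml --out-dir sweep/
```

Community parameter files round-trip as JSON or as a CSV pair (vector table
`species, r, s, K_T, f` plus a square interaction matrix with species-name
headers; `A[i, j]` is the effect of species *j* on species *i*).

## Library sketch

```python
import numpy as np
from glvmap import (
    CommunityParameters, build_assembly_map, map_metrics,
    build_generator, stationary_distribution,
)

A = np.zeros((2, 2)); A[1, 0] = 0.5            # sp0 facilitates sp1
p = CommunityParameters(r=np.array([1.0, -0.1]), s=np.full(2, 0.1), A=A)
amap = build_assembly_map(p)
print(map_metrics(amap))                        # 1 forced assembly path
model = build_generator(amap, p, gamma=20.0, delta=1.0)
print(stationary_distribution(model).by_size)
```
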