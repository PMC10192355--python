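# evacsim

Agent-based tsunami evacuation simulation on synthetic urban
structures: coupled attitude dynamics and pedestrian movement, with
communication-network cluster analysis.

## The problem

Whether people evacuate before a near-field tsunami depends not only on
their own intentions but on whom they meet on the way out.  `evacsim`
models a coastal town as a population of agents, each carrying a scalar
*attitude towards evacuation* `A_i ∈ [−1, 1]`.  Agents talk to
neighbours within 15 m, update their attitudes by bounded-confidence
averaging, start walking toward a safe destination once `A_i ≥ 0.5`
(and stop again if dissuaded below it), and steer along least-cost
routes through the street network.  The package exists to study how the
*shape of the city itself* — a dense, grid-like coastal-plain lattice
versus a sparse, root-like (branching) valley network — reinforces
positive or negative attitudes and thereby decides evacuation success.
It is aimed at researchers in evacuation modelling, pedestrian
dynamics and disaster risk reduction.

## Model core

Attitudes update synchronously at each communication step `t_s` over a
directed influence graph (edges only between agents within the
communication radius whose attitudes are close enough):

    A_i(t_s+1) = A_i(t_s) + μ · Σ_j I_ε(A_i, A_j)(A_j − A_i) / Σ_j I_ε(A_i, A_j)

    I_ε(A_i, A_j) = 1  iff |A_i − A_j| < ε(A_i)     (else 0)

with an attitude-dependent bounded confidence
`ε(A) = ε_base + ε_slope (1 − A)/2` (default `0.2 + 1.0·(1 − A)/2`):
committed evacuees are narrow-minded, hesitant agents are open to
influence.  *Leading evacuees* hold a constant `A_i = 0.7` immune to
communication.  Evacuating agents move by a social-force model

    dv_i/dt = (v0 e0_i − v_i)/τ_α + Σ_{j≠i} F_ij

where the desired direction `e0_i` is the steepest descent of a
navigation field — the minimum cumulative cost to the destination set
over a 1 m land-use raster (road 1, building 4000, water 8000,
other 2000) — and `F_ij` is an anticipatory collision-avoidance force
based on the projected time to collision.  Clusters of communicating
agents are the strongly connected components of the influence graph.

## Worked example

```python
import evacsim as ev
from evacsim.navigation import navigation_field_for
from evacsim import netanalysis as na

for style in ("grid", "root"):
    city = ev.generate_city(ev.CityParams(style=style, extent=500.0, seed=1))
    nav = navigation_field_for(city)
    cfg = ev.SimulationConfig(urban=city, n_agents=500, seed=11)
    res = ev.run_simulation(cfg, nav=nav)
    print(f"{city.style:5s} completion={ev.completion_ratio(res):.3f} "
          f"behaviour_change={na.behaviour_change_ratio(res):.3f} "
          f"max_negative_cluster={na.max_negative_cluster_size(res)} "
          f"large_group_share={na.large_group_share(res):.3f}")
```

prints

```
grid  completion=0.078 behaviour_change=0.768 max_negative_cluster=45 large_group_share=0.059
root  completion=0.102 behaviour_change=0.672 max_negative_cluster=24 large_group_share=0.772
```

Reading the numbers: with identical Uniform(−1, 1) initial attitudes,
the grid-like city completes evacuation for only 7.8% of its 500
agents — 76.8% of the agents who initially intended to evacuate
(`A ≥ 0.5`) were talked out of it by a negative cluster that grew to
45 members in the dense fabric.  The root-like city evacuates more
(10.2%), its largest negative cluster stays at 24, and in the
established-flow phase 77% of its moving evacuees walk in groups of
ten or more — the branching roads gather flows into self-reinforcing
positive clusters.  Single runs are noisy; `run_ensemble` quantifies
the contrast over many seeds.

## Command line

```sh
evacsim generate --style root --extent 500 --seed 1 --out city/
evacsim simulate --urban city/ --seed 3 --out run/
evacsim ensemble --urban city/ --runs 20 --seed 3 --out ens/
evacsim analyze  --run ens/ --out analysis/
evacsim report   --runs ens/ --out report/
```

Urban models are exchanged as GeoJSON (buildings, destinations, road
centrelines) plus an ESRI ASCII land-use grid, so real geometries can
be substituted for the synthetic generators.  Every command writes a
JSON manifest with all parameters and seeds.

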