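# Methods

## Model overview

`evacsim` couples three sub-models on a shared clock:

1. **Communication / decision.**  Every `comm_interval` (default 1 s)
   a directed influence graph is rebuilt among all not-yet-evacuated
   agents: an edge `j → i` exists iff the two agents are within the
   communication radius (15 m), and `|A_i − A_j| < ε(A_i)` with strict
   inequality.  Attitudes then update synchronously by the
   bounded-confidence rule (gain `μ`), leaders stay at 0.7, and the
   evacuation decision `A_i ≥ 0.5` is re-evaluated — an evacuating
   agent whose attitude drops below the threshold halts and becomes a
   standing bystander again.
2. **Movement.**  Each `dt` (0.1 s), evacuating agents accelerate
   toward `v0 e0` with relaxation time `τ_α` plus anticipatory
   pairwise avoidance forces; `e0` is the discrete steepest-descent
   direction of the navigation field at the agent's raster cell.
   Agents within 2 m of a destination become *evacuated* and leave
   both the movement and (by default) the communication model.
3. **Navigation.**  The field is the minimum cumulative cost from the
   destination set over the 8-connected grid graph of the land-use
   cost raster (road 1, building 4000, water 8000, other 2000; 1 m
   cells).  Edge weight = step length (1 or √2 m) × mean of the two
   endpoint cell costs, matching classical raster cost-distance
   semantics.  The field is static: no congestion feedback.

A run ends at the horizon (default 1800 s; the desk-scale experiments
below use 900 s, ample for ≤700 m routes at 1.33 m/s) or as soon as
nothing can change any more (no agent evacuating and the last
attitude update was a fixed point), whichever comes first.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| communication radius | 15 | m | conversation plus line-of-sight imitation distance |
| μ (update gain) | 0.5 | – | halfway step toward the accepted-neighbour mean |
| ε(A) | 0.2 + 1.0·(1−A)/2 | – | see below |
| decision threshold | 0.5 | – | "rather positive" attitude starts evacuation |
| leader attitude | 0.7 | – | constant, immune to influence |
| comm_interval | 1 | s | one attitude update per second of movement |
| v0 | 1.33 | m/s | typical free walking speed |
| τ_α | 0.5 | s | velocity relaxation |
| dt | 0.1 | s | keeps per-step displacement below one 1 m cell (no wall tunnelling) |
| force k, τ0, cutoff | 1.5, 3 s, 10 s | – | anticipatory force scale and range |
| agent radius | 0.3 | m | body disc |
| arrival radius | 2 | m | destination capture |

The movement constants are conventional pedestrian-dynamics values;
the force model is time-to-collision based (magnitude
`k/τ_c² · e^(−τ_c/τ0)` along the predicted closest-approach
separation), so diverging agents exert no force.  Candidate pairs are
searched within 6 m — at that distance the force is already two orders
of magnitude below the relaxation term.

**The bounded-confidence form.**  ε must be attitude-dependent for the
reinforcement mechanism to exist: committed evacuees (high A, small ε)
can hold a shared attitude against a surrounding negative crowd, while
hesitant agents (low A, large ε) can be recruited by a passing group —
or dragged down by a converged negative mass.  The linear form
`ε(A) = ε_base + ε_slope(1−A)/2` is the simplest with that property.
Defaults `ε_base = 0.2`, `ε_slope = 1.0` were calibrated once so that
all three legs of the mechanism operate at desk scale: (i) a
percolating idle crowd in the dense city drags moderately positive
agents below threshold before they escape; (ii) small communication
islands in the sparse city leave its positives unharmed; (iii) a
moving group at A ≈ 0.6 can still recruit bystanders near A ≈ 0.3.
Narrower windows (e.g. base 0.1, slope 0.8) leave the attitude
dynamics too weak to change outcomes at 500 agents: both city styles
then complete at roughly the frozen-attitude baseline.  Note that
ε(0) = 0.7 puts a converged neutral crowd exactly at the strict
acceptance boundary of a leader at 0.7, so leader influence on such a
crowd switches on through the crowd's residual spread — one reason the
leader experiments are reported as relative improvement factors.

## Synthetic cities

The generators are controlled stand-ins for two real urban archetypes;
they reproduce *structural contrasts*, not any particular city's
geometry (street spacing, widths and block sizes are tunable
parameters, not claims of fidelity).

**Grid style** — orthogonal streets every 50 m, 6 m wide, coast along
one edge, blocks subdivided into ~12 m lots at 50% occupancy, and few
destinations (default 2) where inland-running streets leave the
domain.  Agents are placed only in buildings of the coastal
inundation band (default: the 20% of the domain nearest the coast),
emulating a low-lying plain city whose at-risk population is packed
near the shore.  At 500 agents this band's point density
(~0.008 m⁻²) sits above the continuum-percolation threshold for
15 m discs (~0.0064 m⁻²), so the idle communication graph forms
components of order 10² — the substrate for large negative clusters.

**Root style** — a trunk from the coastal valley mouth, primary
branches splitting uphill within a configurable angle, and twigs
ending at many destinations (default 6) on the inland edge; roads are
12 m wide.  Dead-end lanes leave the through-roads in pairs every
~50 m, with small hamlets (~9 m lots) clustered at the lane ends.
Hamlets are separated by more than the communication radius, so the
idle graph is an archipelago of islands of ~5–25 agents; negative
clusters cannot grow beyond an island, while each hamlet's positives
depart together and merge on the mains — the flow-gathering that
protects and recruits moderately positive evacuees.

The inundation zone is a plain coastal band (a fraction of the domain
depth); there is no hydrodynamic model.  Buildings clipped by roads
are dropped so agents never start on road cells.  Rasterisation is a
pure function of the vector geometry (roads win over buildings on
overlap, which the generators avoid by construction).

## Stochastic experiments

*Attitudes mode*: initial positions are placed once per configuration
(area-weighted uniform inside buildings); each run redraws the
Uniform(−1, 1) attitude vector (and leader assignment, if any) from
seeds derived from the master seed.  *Leaders mode*: the attitude
vector of the median-completion run (lower median for even ensembles)
is fixed and only the leader assignment is redrawn — sampling without
replacement with an exact count per run (e.g. exactly 500 leaders for
10% of 5000 agents).  Box summaries use linearly interpolated
quartiles, whiskers at the most extreme data within 1.5×IQR, fliers
beyond.

Desk-scale study conditions: 500 m square domains, 500 agents, 20 runs
per ensemble, 900 s horizon.  The two relative-difference conventions
(mean of per-pair differences over shared seeds, and difference of
ensemble means) are both reported, since either reading is defensible
for a paired ensemble.

## Analysis metrics

* **Clusters** are strongly connected components of the snapshot
  influence graph (scipy's strong connectivity; cross-checked against
  networkx and a brute-force mutual-reachability oracle in the test
  suite).
* **Large-group share**: the group-size timeseries counts evacuating
  agents in induced clusters of ≥ 10 members ("evacuating cluster
  size": the graph is restricted to the moving crowd).  The scalar
  summary averages the per-snapshot share between the 0.5 and 0.95
  quantiles of the arrival-time distribution — the established-flow
  phase.  Earlier snapshots are dominated by the departure transient
  (in the grid city the whole inundation band sets off as one
  percolated crowd), which reflects where people happen to live rather
  than how the street structure organises flows.  `phase=None` gives
  the whole-run aggregate.
* **Behaviour-change ratio**: among agents with initial A ≥ 0.5, the
  fraction not evacuated at the horizon.
* **Evacuated-attitude histogram**: initial attitudes of evacuated
  agents (bin width 0.1), plus the share with 0.2 ≤ A₀ ≤ 0.8 — the
  moderately positive band whose fate distinguishes the two
  structures.
* **Cluster trajectories**: cluster centres/sizes filtered by mean
  attitude (positive ≥ 0.5, negative < 0) and minimum size 2.
* **Time normalisation** divides by the last arrival time (an
  alternative normalisation by path length / v0 was considered and
  rejected as it ignores decision delays).

## What the synthetic data does and does not show

The generators emulate the structural features the mechanism needs —
density above/below the communication-percolation threshold, flow
dispersion versus flow gathering, few versus many exits — under
controlled, identical attitude distributions.  They do not reproduce
real street geometry, terrain, heterogeneous walking speeds,
demographic attitude trends, vehicles, or the tsunami itself, and the
populations are 10× smaller than a real district's.  Passing the
mechanism tests therefore shows that the implemented dynamics produce
the structure-dependent reinforcement on cities *built to contrast
those structures*; it does not by itself validate predictions for any
real city.  Absolute completion percentages at desk scale depend on
the calibrated ε and the generators' densities and should be read as
orders of magnitude, not forecasts.

## Numerical choices and degenerate inputs

* Explicit Euler at dt = 0.1 s; speeds hard-capped at 1.3 × v0.
* Already-overlapping discs get a time-to-collision floor of 0.01 s
  when evaluating the force magnitude (direction: current separation).
* Buildings and water block *entry*; agents start inside buildings and
  may move freely until they exit (blocked moves slide along the
  offending axis).  A standing bystander directly in a doorway can
  permanently pin an evacuee inside — rare (≲ 0.5% of agents) and
  accepted as model behaviour.
* Zero-attitude-change fixed points with no one moving end the run
  early; padded snapshots repeat the frozen state.
* Destination cells have zero desired direction; unreachable cells
  (infinite cumulative cost) get a zero vector and a warning at run
  start.
* Empty rasters, unknown land-use codes, destinations off the raster,
  and placement with no eligible buildings raise typed errors.
* Strict inequality in the indicator is honoured exactly; boundary
  tests use binary-representable attitudes.

## Known limitations

* The attitude model's parameters (μ, ε form) are calibrated to the
  mechanism, not to behavioural data.
* One attitude update per second couples the two clocks rigidly;
  interaction-frequency effects (e.g. conversation duration) are not
  modelled.
* The navigation field is static — no congestion-aware rerouting, no
  time-dependent hazard.
* Communication islands in the root generator are a deliberate
  archetype; real valley towns have intermediate connectivities.
* At 500 agents several contrasts (notably the leader-gain asymmetry)
  are statistically delicate; full-scale runs (5000 agents) sharpen
  them at ~10× the cost.
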