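# hierspread

Agent-based simulation of innovation spread through corporate
hierarchies, modeled as a dosage-threshold contagion (an SIR elaboration
with dose memory) on multilayer organizational networks.

## The problem

New practices spread through organizations along two kinds of channel:
formal administrative lines (departments and their managers) and
informal co-working relationships. Both can be represented as layers of
a multilayer network — a staff layer plus management layers, coupled by
reporting edges — and the question is which structures, and which choices
of initial adopters ("seeds"), let an innovation reach and keep the
largest share of the organization.

`hierspread` provides, for researchers in computational social science
and network epidemiology:

* the **dosage contagion engine** with hierarchical dose override,
* **synthetic hierarchy generators** (random geometric staff layer,
  fluid-communities partition, pluggable manager-layer wiring),
* **readers and fixtures for empirical org networks** (node/edge CSV,
  per-layer statistics, Line-Org- and Project-style generators),
* **seed-selection strategies** (random, degree, VoteRank, onion layer),
* **adoption metrics** (peak adoption, consensus times, survival curves)
  and config-driven experiment drivers with a CLI.

## The model

Each node holds a state S (unaware/susceptible), I (adopter, actively
promoting) or R (rejector; absorbing) plus an individual threshold
d\* ~ N(1, 0.5) truncated positive, and a memory of its last T = 5
received doses. Each micro-step a uniformly random *listener* hears one
uniformly random neighbor (*speaker*):

* an infected speaker confers a dose ~ N(0.5, 0.25) truncated at 0;
  any other speaker confers a zero dose;
* **hierarchy override**: an infected speaker on a *higher* layer
  confers a dose equal to the listener's own threshold — an
  organizational mandate that switches the listener immediately but
  leaves it unsupported, and so at risk of abandoning;
* with D the sum of the memory window, a susceptible listener adopts
  when D ≥ d\*; an infected listener with D < d\* abandons (I → R) with
  probability r = 1/T = 0.2 per activation.

An *epoch* is N micro-steps (one expected activation per node). With
r = 0 the dynamics reduce to an SI consensus process; disabling the
override yields the "flat network" ablation used to isolate the value of
the hierarchy. The hot loop is a numba kernel doing tens of millions of
micro-steps per second; a pure-Python reference path implements the
identical update and is cross-checked in the tests.

## Worked example

```python
from hierspread import (
    SyntheticConfig, build_synthetic_hierarchy,
    DosageParams, SeedSpec, run_ensemble,
)

cfg = SyntheticConfig(n_staff=1000, k_avg=20.0,
                      manager_topology="isolated", rng_seed=42)
graph, partition = build_synthetic_hierarchy(cfg)
print(graph)
print("mean community size:", round(float(partition.sizes().mean()), 3))

params = DosageParams()                                 # T=5, r=0.2
spec = SeedSpec(strategy="random", level=2, count=15)   # 0.015N managers
summary = run_ensemble(graph, params, spec, 200, list(range(200)))
print(f"mean peak adoption: {summary.i_max_mean:.3f} +/- {summary.i_max_se:.3f}")
```

prints

```
LayeredGraph(n=1060, edges=10391, layers=[1, 2])
mean community size: 16.667
mean peak adoption: 0.330 +/- 0.005
```

A thousand staff placed on a random geometric graph are partitioned into
60 communities (mean size 16.667 = 1000/60 exactly), each headed by one
of 60 managers. Seeding 15 random managers, the innovation peaks at
about a third of the organization before the removal process eventually
extinguishes it — roughly two and a half times the reach of the same
seed budget on the bare staff network (peak ≈ 0.14), which is the
headline effect of the management layer. (Peak fractions for the synthetic hierarchy are conventionally
normalized by the staff-layer size N; `summary.i_max_mean` here is the
fraction of all 1060 nodes.)

The same engine runs on empirical networks read from CSV:

```sh
hierspread generate-network --kind lineorg --n-staff 1000 \
    --out-nodes nodes.csv --out-edges edges.csv
hierspread stats nodes.csv edges.csv
hierspread simulate nodes.csv edges.csv --runs 200 \
    --seed-level 2 --seed-count 16
hierspread table2 --runs 300
```

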