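# wgdsim

An agent-based evolution simulator for studying the consequences of
**whole-genome duplication (WGD)** under environmental challenge.

Populations of *digital organisms* (DOs) live on a toroidal grid of food
sources.  Each organism carries a digit-string genome over the alphabet
{0, 1, 2, 3} that encodes a gene regulatory network (GRN): genes are not
pre-specified but discovered in the random string by a grammar (a TATA box
`1010`, 5–50 four-digit cis-elements, a reserved kind word, and a
kind-specific coding payload).  Gene products — transcription factors,
an RNA polymerase, signaling equations over environmental sensors, and
structural products that promote or repress the *replication* and
*movement* actuators — interact through per-step concentration dynamics.
Organisms forage, pay energy for movement and upkeep, die below zero
energy, and replicate once their energy reaches 20,000 units.  Offspring
genomes mutate by per-digit substitution (10⁻⁴/base) and, while the WGD
operator is active, are duplicated outright with probability 0.40; the
operator is permanently removed once polyploids match non-polyploids in
number.  Environmental challenges are delivered as food-removal events,
either recurring (a fraction *f* of all sources every 60 steps once the
population reaches 1000) or one-off at a fixed step.

The package is aimed at researchers in molecular evolution and artificial
life who want a controllable, fully reproducible sandbox for questions
like: when does polyploidy pay off?  It tracks, per organism and step,

* **STGD** — substitutions per 10 kb against the direct parent,
* **LTGD** — substitutions per 10 kb against the time-0 founder
  (each duplicated block compared to the founder),
* **ED** — expression distance, the relative change of the mean
  gene-product concentration between consecutive steps (ED > 30% flags an
  unstable expression pattern),

and classifies replicate experiments into extinction / polyploids-larger /
non-polyploids-larger outcome tables.

## Worked example

```python
from wgdsim import SimulationConfig, run_simulation

cfg = SimulationConfig.desk(master_seed=1)   # 200x200 grid, 20 kb genomes
res = run_simulation(cfg)
```

Running `python examples/03_single_run.py` (the same computation) prints:

```
end step        : 60 (population_explosion)
equalization    : step 37 (WGD operator removed at 37)
final population: 1003 polyploid / 997 non-polyploid

trajectory (every 10 steps):
 step  n_polyploid  n_nonpolyploid  n_food  n_removed
    0            0             200    1200          0
   10           66             259    1382          0
   20          187             366    1365          0
   30          372             485    1199          0
   40          637             630     925          0
   50          856             834     599          0
   60         1003             997     295          0
```

Reading this: from 200 clonal non-polyploid founders the population grows
on abundant food; 40% of replications produce polyploid offspring, so the
polyploid subpopulation catches up with the non-polyploid one at step 37,
at which point the WGD operator is removed.  With no food removal the run
ends when the population reaches the configured cap ("growing too big" —
the stable-environment outcome).  The `examples/` directory holds one
short script per capability: the gene grammar, GRN dynamics, single runs,
and replicate food-removal experiments.

A thin command-line interface mirrors the library:

```bash
wgdsim genome generate --length 100000 --seed 1 --out founders.txt
wgdsim run --profile desk --seed 1 --out out/
wgdsim experiment --profile desk --scenario dynamic --levels 0,0.5,0.7,0.85 \
    --replicates 10 --out exp/
```

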