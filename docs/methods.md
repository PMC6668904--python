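# Model and methods

This note documents the simulator's model, the defaults and why they were
chosen, the numerical conventions, and what the scaled-down test
conditions do and do not show.

## Genomes and the gene grammar

A genome is a string over {0, 1, 2, 3}, one digit per nucleotide; initial
genomes are uniform random strings of 100,000 digits (20,000 in the desk
profile).  Genes are discovered by a left-to-right, non-overlapping scan:

* promoter: the TATA word `1010`, followed by 5–50 four-digit
  cis-elements;
* coding region: a reserved four-digit **kind word**, then a
  kind-specific payload.  No interspersed digits are allowed.

The cis block is terminated by the first 4-aligned reserved kind word; an
embedded TATA word, or a block shorter than 5 or longer than 50 words,
aborts the parse, and scanning resumes one digit after the failed TATA
occurrence (this maximizes gene recovery and is matched by the naive
reference scanner used in the tests).  Thirteen kind words are reserved
(see `genome.DEFAULT_KIND_WORDS`): promoting/repressing structural pairs
for the replication and movement actuators plus inert attack/defense/
search stubs, one regulatory word, one polymerase word, one signaling
word.  The table is configurable; the cis vocabulary is every other
4-digit word except `1010`.

Payload conventions (all 0-based, half-open spans):

* every product identity is the first five payload digits read base-4
  (0–1023) reduced modulo 1000 — a four-letter alphabet has only 256
  four-digit words, so identities (up to 1000 per genome) must come from
  a five-digit field;
* regulatory genes: a four-digit target cis word plus a sign digit whose
  parity selects activator (even) or repressor (odd), which makes the two
  classes equally frequent on random genomes;
* polymerase genes: a four-digit bound motif plus one digit;
* signaling genes: a two-digit length field *v* (base-4, 0–15) giving
  3 + *v* elements (clipped to 3–20), then one fixed eight-digit slot per
  element — four digits of sensor address (reduced modulo the number of
  sensors at evaluation time) and four digits of weight (0–255 mapped to
  −128…127, so equations can inhibit as well as promote).

With this table, random 100 kb genomes carry ≈ 210 genes on average
(tests use the acceptance band 130–230, bracketing the typical
150–200).  Two mutation operators act on genomes: per-digit substitution
(each digit independently replaced by a different digit, default
10⁻⁴/digit) and whole-genome duplication (concatenation with itself),
which exactly doubles gene content because the grammar is local.

## GRN dynamics

The GRN state of an organism is a table of product concentrations
(identity → non-negative level, capped at 100 units).  On creation, the
products of the first 12 regulatory genes in genome order are set to 10
units (all of them if fewer exist).  Each step applies, in order:

1. **decay** — every concentration is multiplied by (1 − *d*), with *d*
   drawn once per identity at simulation start, uniform in [0.05, 0.25]
   (range configurable).  Multiplicative decay keeps concentrations
   non-negative without clamping;
2. **signaling** — each signaling equation computes
   ⌊Σ weightᵢ · sensor(addressᵢ)⌋ mod 1000 over the five sensor slots
   (own energy, nearby food count, nearby organism count, two reserved
   zero slots); every encoded identity named this way gains one unit;
3. **expression** — a gene's level is the signed sum of the
   concentrations of the transcription factors bound to its promoter
   cis-elements (repeats count with multiplicity), gated to zero unless
   some polymerase product is present.  The level formula is the minimal
   signed-sum reading of combinatorial TF control and is isolated in one
   function so it can be swapped;
4. **translation** — every gene whose level reaches the threshold
   (default 1 unit) adds its level to its product's concentration
   (dosage = expression level), clipped at the cap.

Stages are synchronous: expression reads the post-decay, post-signaling
table.  Whether signaling precedes decay is not observable at fixed
point; the chosen order makes a quiescent network relax geometrically to
the constant-input fixed point *L*/*d*, which the tests verify.  Two GRN
implementations exist — a dict-based reference and a vectorized compiled
form used by the simulator — and the tests require them to agree step for
step on random genomes.

## World and organisms

The world is a torus (default 1000×1000 cells; one food source per cell
at most; several organisms may share a cell).  Food sources store
10,000–20,000 energy units, grow by 300 per step, and at 20,000 divide
into two 10,000-unit sources, the child placed on a uniformly chosen
food-free Moore neighbor (division is deferred while all eight are
occupied).  An organism that enters a cell with food assimilates the full
store and the source is removed.

Per agent step (agents updated in a fresh uniformly shuffled order each
step to remove ordering bias): sense → GRN step → eat → move →
replication decision → replication.  Sensor neighborhood counts are read
from the start-of-phase state (synchronous sensing); feeding is exclusive
first-come in the shuffled order.  Movement occurs iff the
movement-promoting product outweighs the repressing one (fair coin on
ties), toward the neighbor closest (Chebyshev, Euclidean tie-break) to
the richest sensed food within the sensing radius (default 5 cells,
Moore), or to a uniformly random neighbor when none is sensed.  A move
costs 70 units; every organism additionally pays a metabolic **upkeep**
of 70 units per step.  Upkeep is a deliberate extension of the
movement-only energy accounting: without it, organisms whose GRN
represses movement never spend energy and are immortal, and famine can
then never eliminate a population.  Setting upkeep equal to one
movement's cost (movers pay double) is the simplest rate that makes
starvation complete within a study horizon; it can be set to 0 to
recover pure movement-only accounting.

Replication requires energy ≥ 20,000 and the replication-promoting
product to outweigh its repressor (fair coin on ties).  The offspring
inherits the genome; while the WGD operator is active the genome is first
duplicated with probability 0.40 (ploidy doubles; lineages can accumulate
multiple WGDs across generations), then substitutions are applied over
the possibly doubled genome.  Parent energy is split evenly with the
offspring: the literal alternative (offspring copies the parent's energy)
creates energy from nothing and makes populations explode unconditionally;
it remains available as `offspring_energy: copy`.  The offspring lands on
a random Moore neighbor with a freshly bootstrapped GRN.  Organisms are
removed when energy drops below 0.  The WGD operator is removed
permanently the first time polyploids (ploidy ≥ 2) are at least as
numerous as non-polyploids.

## Scenarios, stopping, and randomness

Food removal is `none`, `dynamic` (⌊f·N⌋ sources deleted uniformly
without replacement at every multiple of 60 steps once total population
has reached 1000 — the trigger latches permanently) or `fixed` (once, at
step 300).  The floor-count rule makes the removed fraction exact.  Runs
stop at `max_steps`, on total extinction, on one-class extinction (only
once the WGD operator is gone, and only when enabled — recurring-removal
experiments that score *total* extinction disable it), or when the
population reaches the cap (`population_explosion`, the concrete form of
"growing too big"; disabled for recurring-removal experiments, where the
cap then merely suppresses replication).  All randomness derives from one
master seed through four named child streams (genome, world, agents,
scheduler), so trajectories are byte-identical across replays and logging
verbosity cannot perturb them.

## Study conditions and the desk profile

The full-scale (`paper`) profile: 1000×1000 grid, 200 clonal founders of
one viable random 100 kb genome (a founder must parse ≥ 1 polymerase,
signaling, replication-promoting and movement-promoting gene and ≥ 12
regulatory genes), initial energy 10,000, population cap 20,000, up to
2000 steps.  The `desk` profile scales this to a 200×200 grid, 20 kb
genomes, a 2000-organism cap and 500 steps, and is what the test suite
and the acceptance script run.  Two desk parameters have no full-scale
counterpart to inherit and are fixed by qualitative regime matching:
`n_food_init` = 1200 is the smallest supply at which no-removal runs
reliably reach the population cap before the food collapses (the
stable-environment regime), and
`founder_min_regulatory` = 2 because a random 20 kb genome carries only
a few regulatory genes, so the 12-gene founder requirement is
unattainable at that length (GRN bootstrap degrades gracefully).

## Metrics

* STGD: Hamming distance to the direct parent × 10,000 / length; across
  a duplication generation each child half is compared against the whole
  parent (halves are positionally homologous by construction).
* LTGD: the genome is cut into 2ᵏ founder-length blocks, block-wise
  Hamming distances are summed, × 10,000 / length.
* ED: |m₍t₎ − m₍t−1₎| / m₍t−1₎ where m is the mean concentration over
  all encoded identities, zeros included; 0 when both means are 0, ∞ when
  a zero mean becomes nonzero.  ED ≤ 0.30 counts as stable (strict
  inequality flags instability); "adapted and stable" means energy ≥
  20,000 and the last W = 10 consecutive ED values ≤ 0.30.
* Group comparisons use Welch's two-sample t-test; trajectory summaries
  average per genome and bin by 100 steps.
* Experiment summaries count end states as exact rational fractions of
  extinction / polyploid-larger / non-polyploid-larger / tie.

## What the desk conditions show — and what they do not

The desk profile compresses the full-scale dynamics: 200 founders on a
25× smaller grid graze much harder per cell, so growth to the cap takes
~50–100 steps instead of hundreds, equalization of the ploidy classes
happens around steps 25–60 (comfortably inside the full-scale 100–200
band when food is abundant), and famine after heavy removals sets in
within ~100 steps.  Two known scale artifacts follow:

* under recurring 85% removal the population collapses by more than 99%,
  but a handful of energy-rich organisms whose replication is repressed
  (so they cannot shed energy by splitting) can outlast the 500-step
  horizon; binary total-extinction counts therefore undershoot the
  full-scale expectation;
* in stable environments the outcome classification happens only ~20–40
  steps after the WGD operator is removed when runs stop at the cap;
  desk comparisons therefore run the full horizon so that competition
  between the ploidy classes has time to act.

Passing desk-scale tests demonstrates the mechanics (grammar, GRN,
energetics, scheduling, metrics, reproducibility) and the qualitative
regimes (exponential food growth, explosion under stability, collapse
under recurring removal, early equalization at WGD rate 0.40).  They do
not demonstrate quantitative outcome percentages at full scale, nor
real-biology claims: genomes are random strings, there is no gene loss,
no recombination, no sub-/neofunctionalization, and the synthetic world's
food economics are far simpler than any ecology.

## Other numerical choices and limitations

* Concentrations are capped at 100 units to bound translation feedback;
  the expression threshold is 1 unit.  Both are config knobs.
* Ties in movement targeting are broken deterministically (energy, then
  distance, then coordinate order) before any random choice, preserving
  replay stability.
* The identity space (1000) exceeds the cis vocabulary (≤ 243 usable
  words), so distinct products can share binding words; binding sums over
  all factors targeting a word.
* `selection_disabled` runs (free energy, no upkeep or movement cost, no
  food dependence) are provided for mutational-null experiments: with
  selection off, polyploid and non-polyploid substitution distances are
  statistically indistinguishable, as the substitution operator is
  ploidy-blind by construction.
* Attack, defense and search actuators parse but have no behavioral
  effect; their sensor slots read 0.
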