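"""The digital organism: sensing, movement, feeding, replication, death.

A DO carries a genome, an energy store, a position on the grid and the
compiled GRN of its genome.  Behavior is driven by opposing structural
gene products: movement happens when the movement-promoting product
outweighs the repressing one, replication (once the 20,000-unit energy
threshold is reached) when the replication-promoting product outweighs its
repressor, with a fair coin on exact ties.  Moving into a neighboring cell
costs 70 energy units; an organism whose energy drops below zero dies.
At replication the offspring inherits the genome, with a 40% chance of a
whole-genome duplication while the WGD operator is active, followed by
per-digit substitutions at 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import (
    Gene,
    GeneKind,
    apply_substitutions,
    scan_genes,
    whole_genome_duplicate,
)
from .grn import CompiledGRN, sensor_vector
from .world import (
    GridWorld,
    _MOORE_1,
    consume_food_at,
    neighborhood,
    toroidal_chebyshev,
    toroidal_delta,
)

DEFAULT_MOVE_COST = 70.0
DEFAULT_REPLICATION_THRESHOLD = 20_000.0
DEFAULT_WGD_RATE = 0.40
DEFAULT_SUBSTITUTION_RATE = 1e-4


@dataclass
class DigitalOrganism:
    id: int
    genome: np.ndarray
    genes: list[Gene]
    grn: CompiledGRN
    energy: float
    position: tuple[int, int]
    ploidy: int = 1
    parent_id: int | None = None
    birth_step: int = 0
    stgd: float = 0.0  # substitutions per 10 kb vs direct parent, set at birth
    ltgd: float = 0.0  # substitutions per 10 kb vs the t0 founder, set at birth
    alive: bool = True
    prev_mean_conc: float | None = None  # previous-step mean concentration (ED)
    last_ed: float = 0.0
    stable_run: int = 0  # consecutive steps with ED <= 0.30

    @property
    def is_polyploid(self) -> bool:
        return self.ploidy >= 2


@dataclass
class WgdOperatorState:
    """The WGD operator: active at a fixed rate until permanently removed."""

    rate: float = DEFAULT_WGD_RATE
    active: bool = True


def update_wgd_operator(
    state: WgdOperatorState, n_polyploid: int, n_nonpolyploid: int
) -> WgdOperatorState:
    """Permanently remove the operator once polyploids have caught up."""
    if n_polyploid < 0 or n_nonpolyploid < 0:
        raise ValueError("population counts must be non-negative")
    if state.active and n_polyploid > 0 and n_polyploid >= n_nonpolyploid:
        state.active = False
    return state


def sense(do: DigitalOrganism, world: GridWorld, radius: int) -> np.ndarray:
    """Sensor vector: own energy plus food/DO counts within the Moore radius."""
    food_hits, ids = neighborhood(world, do.position, radius, exclude_id=do.id)
    return sensor_vector(max(do.energy, 0.0), len(food_hits), len(ids))


def _food_in_radius(
    world: GridWorld, x: int, y: int, radius: int
) -> list[tuple[int, int]]:
    """Food cells in the Moore radius (tight inner loop for the simulator)."""
    food = world.food
    w, h = world.width, world.height
    hits: list[tuple[int, int]] = []
    for dx in range(-radius, radius + 1):
        cx = (x + dx) % w
        for dy in range(-radius, radius + 1):
            cell = (cx, (y + dy) % h)
            if cell in food:
                hits.append(cell)
    return hits


def _best_food_target(
    world: GridWorld,
    pos: tuple[int, int],
    food_positions: list[tuple[int, int]],
) -> tuple[int, int] | None:
    """Highest-energy food; ties broken by distance, then lexicographically."""
    best = None
    best_key = None
    for fp in food_positions:
        key = (
            -world.food[fp],
            toroidal_chebyshev(pos, fp, world.width, world.height),
            fp,
        )
        if best_key is None or key < best_key:
            best, best_key = fp, key
    return best


def act_move(
    do: DigitalOrganism,
    world: GridWorld,
    rng: np.random.Generator,
    radius: int = 5,
    move_cost: float = DEFAULT_MOVE_COST,
    food_nearby: list[tuple[int, int]] | None = None,
) -> bool:
    """Move one Moore cell if the movement-promoting product dominates.

    The destination is the neighbor nearest to the highest-energy food
    source within the sensing radius, or a uniformly random neighbor when
    no food is sensed.  Returns whether the organism moved.
    ``food_nearby`` may carry a precomputed list of in-range food cells.
    """
    plus = do.grn.actuator_concentration(GeneKind.STRUCT_MOVE_PLUS)
    minus = do.grn.actuator_concentration(GeneKind.STRUCT_MOVE_MINUS)
    if plus < minus:
        return False
    if plus == minus and rng.random() >= 0.5:
        return False
    x, y = do.position
    if food_nearby is None:
        food_nearby = _food_in_radius(world, x, y, radius)
    food_nearby = [fp for fp in food_nearby if fp != do.position]
    if food_nearby:
        target = _best_food_target(world, do.position, food_nearby)
        best_key = None
        best_cells: list[tuple[int, int]] = []
        for dx, dy in _MOORE_1:
            cell = world.wrap((x + dx, y + dy))
            ex = toroidal_delta(cell[0], target[0], world.width)
            ey = toroidal_delta(cell[1], target[1], world.height)
            # Chebyshev distance first (steps to reach), Euclidean to break ties
            key = (max(abs(ex), abs(ey)), ex * ex + ey * ey)
            if best_key is None or key < best_key:
                best_key, best_cells = key, [cell]
            elif key == best_key:
                best_cells.append(cell)
        dest = best_cells[rng.integers(len(best_cells))]
    else:
        dx, dy = _MOORE_1[rng.integers(8)]
        dest = world.wrap((x + dx, y + dy))
    do.position = world.move_organism(do.id, do.position, dest)
    do.energy -= move_cost
    return True


def act_eat(do: DigitalOrganism, world: GridWorld) -> float:
    """Assimilate the food source on the organism's cell, if any."""
    gained = consume_food_at(world, do.position)
    if gained is None:
        return 0.0
    do.energy += gained
    return gained


def decide_replicate(
    do: DigitalOrganism,
    rng: np.random.Generator,
    threshold: float = DEFAULT_REPLICATION_THRESHOLD,
) -> bool:
    """Energy gate plus the replication-promoting/repressing product balance."""
    if do.energy < threshold:
        return False
    plus = do.grn.actuator_concentration(GeneKind.STRUCT_REPL_PLUS)
    minus = do.grn.actuator_concentration(GeneKind.STRUCT_REPL_MINUS)
    if plus > minus:
        return True
    if plus < minus:
        return False
    return bool(rng.random() < 0.5)


@dataclass
class ReplicationContext:
    """Simulation-level parameters a replication event needs."""

    decay_rates: np.ndarray
    substitution_rate: float = DEFAULT_SUBSTITUTION_RATE
    expression_threshold: float = 1.0
    concentration_cap: float = 100.0
    bootstrap_value: float = 10.0
    bootstrap_tfs: int = 12
    offspring_energy: str = "split"  # "split" (conserving) or "copy" (literal)
    kind_words: dict[str, str] | None = None
    n_sensors: int = 5


def replicate(
    do: DigitalOrganism,
    wgd_state: WgdOperatorState,
    ctx: ReplicationContext,
    world: GridWorld,
    rng: np.random.Generator,
    new_id: int,
    step: int = 0,
) -> DigitalOrganism:
    """Create the offspring of ``do`` and place it on a neighboring cell.

    The offspring genome is the parent's, optionally whole-genome
    duplicated (while the operator is active, with probability
    ``wgd_state.rate``), then substituted per digit.  Energy is split
    evenly between parent and offspring unless ``offspring_energy="copy"``.
    """
    genome = do.genome
    ploidy = do.ploidy
    if wgd_state.active and rng.random() < wgd_state.rate:
        genome = whole_genome_duplicate(genome)
        ploidy *= 2
    genome, _ = apply_substitutions(genome, ctx.substitution_rate, rng)
    if ctx.offspring_energy == "split":
        half = do.energy / 2.0
        do.energy = half
        child_energy = half
    else:
        child_energy = do.energy
    dx, dy = _MOORE_1[rng.integers(8)]
    pos = world.wrap((do.position[0] + dx, do.position[1] + dy))
    genes = scan_genes(genome, ctx.kind_words)
    grn = CompiledGRN(
        genes,
        ctx.decay_rates,
        threshold=ctx.expression_threshold,
        cap=ctx.concentration_cap,
        n_sensors=ctx.n_sensors,
    )
    grn.bootstrap(ctx.bootstrap_value, ctx.bootstrap_tfs)
    child = DigitalOrganism(
        id=new_id,
        genome=genome,
        genes=genes,
        grn=grn,
        energy=child_energy,
        position=pos,
        ploidy=ploidy,
        parent_id=do.id,
        birth_step=step,
    )
    world.place_organism(child.id, pos)
    return child
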