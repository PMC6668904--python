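"""Toroidal grid world: food growth, division, and removal schedules.

Food sources sit one per cell and store 10,000-20,000 energy units.  Every
step a source gains 300 units; at 20,000 it divides, placing a 10,000-unit
child in a free neighboring cell (deferred when all eight neighbors hold
food).  Environmental challenges remove a fraction of all sources either
recurrently (every ``period`` steps once the population has reached a
trigger size) or once at a fixed step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FOOD_CAP = 20_000.0
FOOD_GROWTH = 300.0
FOOD_SPLIT_ENERGY = 10_000.0

_MOORE_1 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class GridWorld:
    """A torus of ``width`` x ``height`` cells holding food and organisms."""

    width: int = 1000
    height: int = 1000
    food: dict[tuple[int, int], float] = field(default_factory=dict)
    organisms: dict[tuple[int, int], set[int]] = field(default_factory=dict)

    def wrap(self, pos: tuple[int, int]) -> tuple[int, int]:
        return (pos[0] % self.width, pos[1] % self.height)

    def add_food(self, pos: tuple[int, int], energy: float) -> None:
        pos = self.wrap(pos)
        if pos in self.food:
            raise ValueError(f"cell {pos} already holds a food source")
        if not 0.0 <= energy <= FOOD_CAP:
            raise ValueError("food energy must be in [0, 20000]")
        self.food[pos] = energy

    def place_organism(self, do_id: int, pos: tuple[int, int]) -> tuple[int, int]:
        pos = self.wrap(pos)
        self.organisms.setdefault(pos, set()).add(do_id)
        return pos

    def move_organism(
        self, do_id: int, old: tuple[int, int], new: tuple[int, int]
    ) -> tuple[int, int]:
        old, new = self.wrap(old), self.wrap(new)
        cell = self.organisms.get(old)
        if cell is not None:
            cell.discard(do_id)
            if not cell:
                del self.organisms[old]
        return self.place_organism(do_id, new)

    def remove_organism(self, do_id: int, pos: tuple[int, int]) -> None:
        pos = self.wrap(pos)
        cell = self.organisms.get(pos)
        if cell is not None:
            cell.discard(do_id)
            if not cell:
                del self.organisms[pos]


@dataclass
class RemovalSchedule:
    """Food-removal scenario: ``none``, ``dynamic`` or ``fixed``.

    Dynamic removals delete ``floor(fraction * N)`` sources at every
    multiple of ``period`` steps once the total population has reached
    ``pop_trigger`` (the trigger latches permanently).  Fixed removal
    happens exactly once, at ``fixed_step``.
    """

    mode: str = "none"
    fraction: float = 0.0
    period: int = 60
    pop_trigger: int = 1000
    fixed_step: int = 300
    armed: bool = False
    fired: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("none", "dynamic", "fixed"):
            raise ValueError(f"unknown removal mode {self.mode!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("removal fraction must be in [0, 1]")


def step_food(world: GridWorld, rng: np.random.Generator) -> None:
    """Grow every source by 300 units (clipped) and divide full sources."""
    full: list[tuple[int, int]] = []
    for pos in sorted(world.food):
        e = min(world.food[pos] + FOOD_GROWTH, FOOD_CAP)
        world.food[pos] = e
        if e >= FOOD_CAP:
            full.append(pos)
    for pos in full:
        x, y = pos
        free = [
            world.wrap((x + dx, y + dy))
            for dx, dy in _MOORE_1
            if world.wrap((x + dx, y + dy)) not in world.food
        ]
        if not free:
            continue  # division deferred until a neighbor frees up
        child = free[rng.integers(len(free))]
        world.food[pos] = FOOD_SPLIT_ENERGY
        world.food[child] = FOOD_SPLIT_ENERGY


def remove_food(
    world: GridWorld,
    schedule: RemovalSchedule,
    step: int,
    population_size: int,
    rng: np.random.Generator,
) -> int:
    """Apply the scheduled removal for this step; returns sources removed."""
    if schedule.mode == "none" or schedule.fraction == 0.0:
        return 0
    due = False
    if schedule.mode == "dynamic":
        if not schedule.armed and population_size >= schedule.pop_trigger:
            schedule.armed = True
        due = schedule.armed and step % schedule.period == 0
    elif schedule.mode == "fixed":
        if not schedule.fired and step == schedule.fixed_step:
            schedule.fired = True
            due = True
    if not due or not world.food:
        return 0
    sources = sorted(world.food)
    n_remove = int(schedule.fraction * len(sources))
    if n_remove == 0:
        return 0
    chosen = rng.choice(len(sources), size=n_remove, replace=False)
    for i in chosen:
        del world.food[sources[i]]
    return n_remove


def consume_food_at(world: GridWorld, pos: tuple[int, int]) -> float | None:
    """Assimilate and delete the source at ``pos``; None if the cell is empty."""
    pos = world.wrap(pos)
    return world.food.pop(pos, None)


def neighborhood(
    world: GridWorld,
    pos: tuple[int, int],
    radius: int,
    exclude_id: int | None = None,
) -> tuple[list[tuple[int, int]], list[int]]:
    """Food positions and organism ids in the Moore neighborhood of ``pos``.

    Wraps around the torus; ``exclude_id`` (the querying organism) is left
    out of the returned ids.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    x, y = world.wrap(pos)
    food_hits: list[tuple[int, int]] = []
    ids: list[int] = []
    for dx in range(-radius, radius + 1):
        for dy in range(-radius, radius + 1):
            cell = world.wrap((x + dx, y + dy))
            if cell in world.food:
                food_hits.append(cell)
            for did in world.organisms.get(cell, ()):
                if did != exclude_id:
                    ids.append(did)
    return food_hits, sorted(ids)


def food_snapshot(world: GridWorld, step: int) -> list[tuple[int, int, int, float]]:
    """Rows (step, x, y, energy) for every food source, in cell order."""
    return [(step, x, y, world.food[(x, y)]) for x, y in sorted(world.food)]


def write_food_snapshots(path, snapshots) -> None:
    """Write food-state rows (as from :func:`food_snapshot`) to a CSV file."""
    with open(path, "w") as fh:
        fh.write("step,x,y,energy\n")
        for step, x, y, energy in snapshots:
            fh.write(f"{step},{x},{y},{energy:g}\n")


def toroidal_delta(a: int, b: int, size: int) -> int:
    """Signed shortest displacement from a to b on a ring of ``size`` cells."""
    d = (b - a) % size
    if d > size // 2:
        d -= size
    return d


def toroidal_chebyshev(
    a: tuple[int, int], b: tuple[int, int], width: int, height: int
) -> int:
    return max(
        abs(toroidal_delta(a[0], b[0], width)),
        abs(toroidal_delta(a[1], b[1], height)),
    )
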