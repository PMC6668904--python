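"""Simulation orchestration: the per-step loop, experiments, stopping rules.

One step executes: food growth -> scheduled food removal -> shuffled agent
updates (sense, GRN step, eat, move, replication decision, replication)
-> WGD-operator check -> metric logging -> stopping rules.  All randomness
flows from one master seed through four named child streams (genome,
world, agents, scheduler), so a run is exactly reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .config import ScenarioConfig, SimulationConfig
from .genome import GeneKind, random_viable_genome, scan_genes
from .grn import CompiledGRN, draw_decay_rates, sensor_vector
from .organism import (
    DigitalOrganism,
    ReplicationContext,
    WgdOperatorState,
    act_eat,
    act_move,
    decide_replicate,
    replicate,
    update_wgd_operator,
)
from .world import GridWorld, RemovalSchedule, remove_food, step_food

END_MAX_STEPS = "max_steps"
END_EXTINCTION_ALL = "extinction_all"
END_EXTINCTION_ONE_CLASS = "extinction_one_class"
END_POPULATION_EXPLOSION = "population_explosion"
END_EQUALIZATION = "equalization"


@dataclass
class RunResult:
    end_step: int
    end_cause: str
    n_polyploid: int
    n_nonpolyploid: int
    counts: pd.DataFrame  # step, n_polyploid, n_nonpolyploid, n_food, n_removed
    records: pd.DataFrame | None
    grn_traces: list[dict] | None
    equalization_step: int | None
    wgd_removed_step: int | None
    config: SimulationConfig

    @property
    def outcome(self) -> str:
        return _metrics.classify_outcome(self.n_polyploid, self.n_nonpolyploid)


def toroidal_window_sum(arr: np.ndarray, radius: int) -> np.ndarray:
    """Exact Moore-window sums of a 2-D grid with wrap-around."""
    if radius == 0:
        return arr.copy()
    out = arr
    for axis in (0, 1):
        padded = np.concatenate(
            [out.take(range(out.shape[axis] - radius, out.shape[axis]), axis=axis),
             out,
             out.take(range(radius), axis=axis)],
            axis=axis,
        )
        c = padded.cumsum(axis=axis)
        zero = np.zeros_like(c.take([0], axis=axis))
        c = np.concatenate([zero, c], axis=axis)
        hi = c.take(range(2 * radius + 1, c.shape[axis]), axis=axis)
        lo = c.take(range(0, c.shape[axis] - 2 * radius - 1), axis=axis)
        out = hi - lo
    return out


def equalization_step(counts: pd.DataFrame) -> int | None:
    """First step at which polyploids have caught up with non-polyploids."""
    hit = counts[
        (counts["n_polyploid"] >= counts["n_nonpolyploid"])
        & (counts["n_polyploid"] > 0)
    ]
    if hit.empty:
        return None
    return int(hit["step"].iloc[0])


class Simulation:
    """A single running simulation; ``run_simulation`` is the usual entry."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        ss = np.random.SeedSequence(config.master_seed)
        genome_ss, world_ss, agents_ss, sched_ss = ss.spawn(4)
        self.genome_rng = np.random.default_rng(genome_ss)
        self.world_rng = np.random.default_rng(world_ss)
        self.agents_rng = np.random.default_rng(agents_ss)
        self.sched_rng = np.random.default_rng(sched_ss)

        self.decay_rates = draw_decay_rates(
            self.genome_rng, config.decay_low, config.decay_high
        )
        self.founder_genome = random_viable_genome(
            config.genome_length,
            self.genome_rng,
            min_regulatory=config.founder_min_regulatory,
            kind_words=config.kind_words,
        )
        self.founder_genes = scan_genes(self.founder_genome, config.kind_words)

        self.world = GridWorld(width=config.width, height=config.height)
        self._init_food()
        self.ctx = ReplicationContext(
            decay_rates=self.decay_rates,
            substitution_rate=config.substitution_rate,
            expression_threshold=config.expression_threshold,
            concentration_cap=config.concentration_cap,
            bootstrap_value=config.bootstrap_value,
            bootstrap_tfs=config.bootstrap_tfs,
            offspring_energy=config.offspring_energy,
            kind_words=config.kind_words,
        )
        self.wgd_state = WgdOperatorState(rate=config.wgd_rate, active=True)
        self.schedule = RemovalSchedule(
            mode=config.scenario.mode,
            fraction=config.scenario.fraction,
            period=config.scenario.period,
            pop_trigger=config.scenario.pop_trigger,
            fixed_step=config.scenario.fixed_step,
        )
        self.population: list[DigitalOrganism] = []
        self._next_id = 0
        self._init_population()
        self.step = 0
        self.wgd_removed_step: int | None = None
        self._counts_rows: list[tuple] = []
        self._record_rows: list[tuple] = []
        self._grn_traces: list[dict] = []
        self._log_counts(n_removed=0)

    # -- initialization ----------------------------------------------------
    def _init_food(self) -> None:
        cfg = self.config
        n_cells = cfg.width * cfg.height
        n = min(cfg.n_food_init, n_cells)
        flat = self.world_rng.choice(n_cells, size=n, replace=False)
        energies = self.world_rng.uniform(cfg.food_init_low, cfg.food_init_high, n)
        for f, e in zip(flat.tolist(), energies.tolist()):
            self.world.add_food((f % cfg.width, f // cfg.width), min(e, 20_000.0))

    def _init_population(self) -> None:
        cfg = self.config
        for _ in range(cfg.n_do_init):
            pos = (
                int(self.world_rng.integers(cfg.width)),
                int(self.world_rng.integers(cfg.height)),
            )
            genome = self.founder_genome  # clonal founders share the genome
            genes = self.founder_genes
            grn = CompiledGRN(
                genes,
                self.decay_rates,
                threshold=cfg.expression_threshold,
                cap=cfg.concentration_cap,
            )
            grn.bootstrap(cfg.bootstrap_value, cfg.bootstrap_tfs)
            do = DigitalOrganism(
                id=self._next_id,
                genome=genome,
                genes=genes,
                grn=grn,
                energy=cfg.initial_energy,
                position=pos,
            )
            self._next_id += 1
            self.world.place_organism(do.id, pos)
            self.population.append(do)

    # -- logging -----------------------------------------------------------
    def class_counts(self) -> tuple[int, int]:
        n_poly = sum(1 for d in self.population if d.is_polyploid)
        return n_poly, len(self.population) - n_poly

    def _log_counts(self, n_removed: int) -> None:
        n_poly, n_non = self.class_counts()
        self._counts_rows.append(
            (self.step, n_poly, n_non, len(self.world.food), n_removed)
        )

    def _log_record(self, do: DigitalOrganism) -> None:
        self._record_rows.append(
            (
                self.step,
                do.id,
                do.parent_id,
                "polyploid" if do.is_polyploid else "nonpolyploid",
                do.ploidy,
                do.energy,
                do.position[0],
                do.position[1],
                do.stgd,
                do.ltgd,
                do.last_ed,
                do.energy >= self.config.replication_threshold,
                do.stable_run >= self.config.stability_window,
                do.alive,
            )
        )

    # -- the step ----------------------------------------------------------
    def run_step(self) -> int:
        """Advance one time step; returns the number of food sources removed."""
        cfg = self.config
        self.step += 1
        if not cfg.selection_disabled:
            step_food(self.world, self.world_rng)
        n_removed = remove_food(
            self.world, self.schedule, self.step, len(self.population),
            self.world_rng,
        )

        # Synchronous sensing: neighborhood counts read the state at the
        # start of the agent phase (removes update-order bias from sensors).
        food_count, do_count = self._sensor_grids()

        order = self.sched_rng.permutation(len(self.population))
        survivors: list[DigitalOrganism] = []
        newborns: list[DigitalOrganism] = []
        pop_size = len(self.population)
        for i in order.tolist():
            do = self.population[i]
            x, y = do.position
            sensors = sensor_vector(
                max(do.energy, 0.0),
                int(food_count[x, y]),
                max(int(do_count[x, y]) - 1, 0),
            )
            do.grn.step(sensors)
            mean = do.grn.mean_concentration()
            if do.prev_mean_conc is None:
                do.last_ed = 0.0
            else:
                do.last_ed = _metrics.expression_distance(mean, do.prev_mean_conc)
            do.prev_mean_conc = mean
            do.stable_run = (
                do.stable_run + 1
                if do.last_ed <= _metrics.ED_STABILITY_THRESHOLD
                else 0
            )
            if not cfg.selection_disabled:
                act_eat(do, self.world)
                # A zero in the start-of-phase food-count grid proves the
                # neighborhood scan would come up empty (food is never added
                # during the agent phase), so it can be skipped.
                hint = [] if food_count[x, y] == 0 else None
                act_move(
                    do,
                    self.world,
                    self.agents_rng,
                    radius=cfg.sensing_radius,
                    move_cost=cfg.move_cost,
                    food_nearby=hint,
                )
                # Metabolic upkeep: a baseline drain so that starvation is
                # lethal even for organisms whose GRN represses movement.
                do.energy -= cfg.upkeep_cost
                if do.energy < 0:
                    do.alive = False
                    self.world.remove_organism(do.id, do.position)
                    if cfg.log_records:
                        self._log_record(do)
                    continue
            threshold = (
                -np.inf if cfg.selection_disabled else cfg.replication_threshold
            )
            if pop_size + len(newborns) < cfg.population_cap and decide_replicate(
                do, self.agents_rng, threshold=threshold
            ):
                child = replicate(
                    do,
                    self.wgd_state,
                    self.ctx,
                    self.world,
                    self.agents_rng,
                    new_id=self._next_id,
                    step=self.step,
                )
                self._next_id += 1
                child.stgd = _metrics.stgd(child.genome, do.genome)
                child.ltgd = _metrics.ltgd(child.genome, self.founder_genome)
                newborns.append(child)
            if cfg.log_records:
                self._log_record(do)
            if cfg.log_grn_traces:
                self._grn_traces.append(
                    {
                        "step": self.step,
                        "do_id": do.id,
                        "concentrations": do.grn.concentrations(),
                    }
                )
            survivors.append(do)
        self.population = survivors + newborns

        n_poly, n_non = self.class_counts()
        was_active = self.wgd_state.active
        update_wgd_operator(self.wgd_state, n_poly, n_non)
        if was_active and not self.wgd_state.active:
            self.wgd_removed_step = self.step
        self._log_counts(n_removed)
        return n_removed

    def _sensor_grids(self) -> tuple[np.ndarray, np.ndarray]:
        cfg = self.config
        food_grid = np.zeros((cfg.width, cfg.height), dtype=np.int64)
        for (x, y) in self.world.food:
            food_grid[x, y] = 1
        do_grid = np.zeros((cfg.width, cfg.height), dtype=np.int64)
        for do in self.population:
            do_grid[do.position] += 1
        r = cfg.sensing_radius
        return toroidal_window_sum(food_grid, r), toroidal_window_sum(do_grid, r)

    # -- stopping ----------------------------------------------------------
    def _stop_cause(self) -> str | None:
        cfg = self.config
        n_poly, n_non = self.class_counts()
        if n_poly + n_non == 0:
            return END_EXTINCTION_ALL
        if (
            cfg.stop_on_class_extinction
            and not self.wgd_state.active
            and (n_poly == 0 or n_non == 0)
        ):
            return END_EXTINCTION_ONE_CLASS
        if cfg.stop_at_population_cap and n_poly + n_non >= cfg.population_cap:
            return END_POPULATION_EXPLOSION
        if cfg.stop_at_equalization and n_poly > 0 and n_poly >= n_non:
            return END_EQUALIZATION
        return None

    def result(self, end_cause: str) -> RunResult:
        counts = pd.DataFrame(
            self._counts_rows,
            columns=["step", "n_polyploid", "n_nonpolyploid", "n_food", "n_removed"],
        )
        records = None
        if self.config.log_records:
            records = pd.DataFrame(
                self._record_rows,
                columns=[
                    "step",
                    "do_id",
                    "parent_id",
                    "ploidy_class",
                    "ploidy",
                    "energy",
                    "x",
                    "y",
                    "stgd",
                    "ltgd",
                    "ed",
                    "adapted",
                    "stable",
                    "alive",
                ],
            )
        n_poly, n_non = self.class_counts()
        return RunResult(
            end_step=self.step,
            end_cause=end_cause,
            n_polyploid=n_poly,
            n_nonpolyploid=n_non,
            counts=counts,
            records=records,
            grn_traces=self._grn_traces if self.config.log_grn_traces else None,
            equalization_step=equalization_step(counts),
            wgd_removed_step=self.wgd_removed_step,
            config=self.config,
        )


def run_simulation(config: SimulationConfig) -> RunResult:
    """Run one simulation to completion under the configured stopping rules."""
    sim = Simulation(config)
    cause = END_MAX_STEPS
    for _ in range(config.max_steps):
        sim.run_step()
        stop = sim._stop_cause()
        if stop is not None:
            cause = stop
            break
    return sim.result(cause)


@dataclass
class ExperimentResult:
    summaries: dict[float, _metrics.ExperimentSummary]
    runs: dict[float, list[RunResult]]
    failures: list[tuple[float, int, str]]  # (level, replicate, error)


def run_experiment(
    config: SimulationConfig,
    reduction_levels: list[float],
    n_replicates: int,
    seeds: list[int] | None = None,
) -> ExperimentResult:
    """Run a replicate grid of simulations over food-reduction levels.

    Each (level, replicate) cell gets its own child seed derived from the
    configuration's master seed unless explicit ``seeds`` (one per
    replicate) are given.  Per-run failures are recorded, not fatal.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if seeds is not None and len(seeds) != n_replicates:
        raise ValueError("need exactly one seed per replicate")
    ss = np.random.SeedSequence(config.master_seed)
    summaries: dict[float, _metrics.ExperimentSummary] = {}
    runs: dict[float, list[RunResult]] = {}
    failures: list[tuple[float, int, str]] = []
    for level in reduction_levels:
        level_runs: list[RunResult] = []
        finals: list[tuple[int, int]] = []
        for rep in range(n_replicates):
            if seeds is not None:
                seed = seeds[rep]
            else:
                seed = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
            scenario = dataclasses.replace(config.scenario, fraction=level)
            run_cfg = dataclasses.replace(
                config, scenario=scenario, master_seed=seed
            )
            try:
                res = run_simulation(run_cfg)
            except Exception as exc:  # recorded, not fatal to other runs
                failures.append((level, rep, repr(exc)))
                continue
            level_runs.append(res)
            finals.append((res.n_polyploid, res.n_nonpolyploid))
        runs[level] = level_runs
        if finals:
            summaries[level] = _metrics.summarize_experiment(finals)
    return ExperimentResult(summaries=summaries, runs=runs, failures=failures)


def summary_table(summaries: dict[float, _metrics.ExperimentSummary]) -> pd.DataFrame:
    """Outcome fractions per reduction level, in the layout of the study's
    summary tables (rows: outcome; columns: food-reduction level)."""
    rows = {
        "Extinction (for all DOs)": "extinction",
        "Polyploid population bigger than non-polyploid population": "polyploid_larger",
        "Non-polyploid population bigger than polyploid population": "nonpolyploid_larger",
        "Tie": "tie",
    }
    data = {}
    for level in sorted(summaries):
        s = summaries[level].as_dict()
        data[f"{level:.0%} food reduction"] = [s[key] for key in rows.values()]
    return pd.DataFrame(data, index=list(rows))
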