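"""Per-time-step gene-regulatory-network dynamics of one digital organism.

The GRN state is a concentration table mapping product identities (0-999)
to non-negative concentrations.  One step applies, in order:

1. decay       — every concentration is multiplied by ``1 - decay_rate``;
2. signaling   — each signaling equation maps the sensor vector to an
                 identity; encoded identities gain one concentration unit;
3. expression  — each gene's level is the signed sum of the concentrations
                 of the transcription factors bound to its promoter
                 cis-elements, gated to zero when no polymerase product is
                 present;
4. translation — genes whose level reaches the threshold add their level
                 to their product's concentration (dosage = level), capped.

Two implementations are provided: a dict-based reference
(:func:`step_grn` and friends, mirroring the definitions one-to-one) and a
vectorized :class:`CompiledGRN` used by the simulator.  They are checked
against each other in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genome import (
    Gene,
    GeneKind,
    N_IDENTITIES,
    REGULATORY_KINDS,
    SignalingEquation,
)

#: Sensor slot layout.  Slots 3 and 4 are reserved for the inert
#: attack/defense inputs and always read zero.
SENSOR_OWN_ENERGY = 0
SENSOR_N_FOOD = 1
SENSOR_N_DOS = 2
N_SENSORS = 5

DEFAULT_BOOTSTRAP_TFS = 12
DEFAULT_BOOTSTRAP_VALUE = 10.0
DEFAULT_THRESHOLD = 1.0
DEFAULT_CAP = 100.0


def sensor_vector(
    own_energy: float, n_food_nearby: int, n_dos_nearby: int
) -> np.ndarray:
    """Build the standard 5-slot sensor vector."""
    if own_energy < 0 or n_food_nearby < 0 or n_dos_nearby < 0:
        raise ValueError("sensor readings must be non-negative")
    v = np.zeros(N_SENSORS)
    v[SENSOR_OWN_ENERGY] = own_energy
    v[SENSOR_N_FOOD] = n_food_nearby
    v[SENSOR_N_DOS] = n_dos_nearby
    return v


def draw_decay_rates(
    rng: np.random.Generator, low: float = 0.05, high: float = 0.25
) -> np.ndarray:
    """Per-identity decay rates, drawn once at simulation initialization."""
    if not (0.0 < low <= high < 1.0):
        raise ValueError("decay range must satisfy 0 < low <= high < 1")
    return rng.uniform(low, high, size=N_IDENTITIES)


@dataclass
class GRNState:
    """Concentrations plus the expression levels computed this step."""

    concentrations: dict[int, float] = field(default_factory=dict)
    expression_levels: dict[int, float] = field(default_factory=dict)
    step: int = 0


def bootstrap_tfs(
    genes: Sequence[Gene],
    value: float = DEFAULT_BOOTSTRAP_VALUE,
    n_tfs: int = DEFAULT_BOOTSTRAP_TFS,
) -> dict[int, float]:
    """Initial concentrations of a newly created organism.

    The first ``n_tfs`` regulatory genes in genome order have their product
    concentrations set to ``value``; with fewer regulatory genes, all of
    them are activated.
    """
    conc: dict[int, float] = {}
    count = 0
    for gene in genes:
        if gene.kind in REGULATORY_KINDS:
            conc[gene.identity] = value
            count += 1
            if count >= n_tfs:
                break
    return conc


def evaluate_signaling(
    equations: Sequence[SignalingEquation], sensors: Sequence[float]
) -> list[int]:
    """Identity named by each equation: floor(sum w*s) mod 1000.

    Sensor addresses are reduced modulo the number of sensors.
    """
    sensors = np.asarray(sensors, dtype=float)
    n = sensors.size
    out = []
    for eq in equations:
        total = sum(w * float(sensors[addr % n]) for addr, w in eq.elements)
        out.append(int(math.floor(total)) % N_IDENTITIES)
    return out


def apply_signaling(
    conc: Mapping[int, float],
    identities: Sequence[int],
    encoded: set[int],
    cap: float = DEFAULT_CAP,
) -> dict[int, float]:
    """Add one unit per named identity that the genome encodes."""
    out = dict(conc)
    for ident in identities:
        if ident in encoded:
            out[ident] = min(out.get(ident, 0.0) + 1.0, cap)
    return out


def cis_lookup(genes: Sequence[Gene]) -> dict[int, list[tuple[int, int]]]:
    """Map each cis word value to the (identity, sign) of the TFs binding it."""
    table: dict[int, list[tuple[int, int]]] = {}
    for gene in genes:
        if gene.kind in REGULATORY_KINDS:
            table.setdefault(gene.target_cis, []).append((gene.identity, gene.sign))
    return table


def polymerase_identities(genes: Sequence[Gene]) -> set[int]:
    return {g.identity for g in genes if g.kind is GeneKind.POLYMERASE}


def expression_level(
    gene: Gene,
    conc: Mapping[int, float],
    lookup: Mapping[int, list[tuple[int, int]]],
    poly_ids: set[int],
) -> float:
    """Signed sum of bound-TF concentrations over the promoter cis words.

    Without any polymerase product in the concentration table the level is
    zero regardless of bound factors (polymerase gating).
    """
    if not any(conc.get(i, 0.0) > 0.0 for i in poly_ids):
        return 0.0
    level = 0.0
    for word in gene.cis_words:
        for ident, sign in lookup.get(word, ()):
            level += sign * conc.get(ident, 0.0)
    return level


def step_grn(
    genes: Sequence[Gene],
    state: GRNState,
    sensors: Sequence[float],
    decay_rates: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    cap: float = DEFAULT_CAP,
) -> GRNState:
    """Reference one-step GRN update (decay, signaling, expression, translation)."""
    encoded = {g.identity for g in genes}
    # 1. decay
    conc = {
        i: c * (1.0 - float(decay_rates[i])) for i, c in state.concentrations.items()
    }
    # 2. signaling
    equations = [g.equation for g in genes if g.kind is GeneKind.SIGNALING]
    hits = evaluate_signaling(equations, sensors)
    conc = apply_signaling(conc, hits, encoded, cap)
    # 3. expression, read from the post-decay post-signaling table
    lookup = cis_lookup(genes)
    poly_ids = polymerase_identities(genes)
    levels = {
        idx: expression_level(gene, conc, lookup, poly_ids)
        for idx, gene in enumerate(genes)
    }
    # 4. translation
    for idx, gene in enumerate(genes):
        lv = levels[idx]
        if lv >= threshold:
            conc[gene.identity] = min(conc.get(gene.identity, 0.0) + lv, cap)
    conc = {i: min(max(c, 0.0), cap) for i, c in conc.items()}
    return GRNState(concentrations=conc, expression_levels=levels, step=state.step + 1)


class CompiledGRN:
    """Vectorized GRN for one genome, used by the simulator.

    Concentrations live in a dense vector over the genome's encoded
    identities.  The per-step update is identical to :func:`step_grn`.
    """

    def __init__(
        self,
        genes: Sequence[Gene],
        decay_rates: np.ndarray,
        threshold: float = DEFAULT_THRESHOLD,
        cap: float = DEFAULT_CAP,
        n_sensors: int = N_SENSORS,
    ) -> None:
        self.genes = list(genes)
        self.threshold = float(threshold)
        self.cap = float(cap)
        ids = sorted({g.identity for g in self.genes})
        self.identities = np.asarray(ids, dtype=np.int64)
        self.n_products = len(ids)
        self._id2idx = np.full(N_IDENTITIES, -1, dtype=np.int64)
        self._id2idx[self.identities] = np.arange(self.n_products)
        self.conc = np.zeros(self.n_products)
        self._decay = decay_rates[self.identities] if self.n_products else np.zeros(0)

        lookup = cis_lookup(self.genes)
        n_genes = len(self.genes)
        B = np.zeros((n_genes, self.n_products))
        gene_prod = np.zeros(n_genes, dtype=np.int64)
        for gi, gene in enumerate(self.genes):
            gene_prod[gi] = self._id2idx[gene.identity]
            for word in gene.cis_words:
                for ident, sign in lookup.get(word, ()):
                    B[gi, self._id2idx[ident]] += sign
        self._B = B
        self._gene_prod = gene_prod
        self._poly_idx = np.asarray(
            sorted({self._id2idx[i] for i in polymerase_identities(self.genes)}),
            dtype=np.int64,
        )
        # Signaling equations as one weight matrix over the sensor slots.
        eqs = [g.equation for g in self.genes if g.kind is GeneKind.SIGNALING]
        S = np.zeros((len(eqs), n_sensors))
        for ei, eq in enumerate(eqs):
            for addr, w in eq.elements:
                S[ei, addr % n_sensors] += w
        self._S = S
        # Per-kind product index lists for actuator readouts.
        self._kind_idx: dict[GeneKind, np.ndarray] = {}
        for kind in GeneKind:
            kidx = sorted({self._id2idx[g.identity] for g in self.genes if g.kind is kind})
            self._kind_idx[kind] = np.asarray(kidx, dtype=np.int64)
        self.levels = np.zeros(n_genes)
        self.step_index = 0

    def bootstrap(
        self,
        value: float = DEFAULT_BOOTSTRAP_VALUE,
        n_tfs: int = DEFAULT_BOOTSTRAP_TFS,
    ) -> None:
        self.conc[:] = 0.0
        for ident, c in bootstrap_tfs(self.genes, value, n_tfs).items():
            self.conc[self._id2idx[ident]] = c

    def concentrations(self) -> dict[int, float]:
        """Concentration table as a plain dict (nonzero entries)."""
        return {
            int(i): float(c)
            for i, c in zip(self.identities, self.conc)
            if c != 0.0
        }

    def actuator_concentration(self, kind: GeneKind) -> float:
        """Summed concentration of the products of all genes of one kind."""
        idx = self._kind_idx[kind]
        return float(self.conc[idx].sum()) if idx.size else 0.0

    def mean_concentration(self) -> float:
        """Mean over all encoded identities, zeros included (for ED)."""
        if self.n_products == 0:
            return 0.0
        return float(self.conc.sum() / self.n_products)

    def step(self, sensors: np.ndarray) -> None:
        conc = self.conc
        conc *= 1.0 - self._decay
        if self._S.shape[0]:
            outs = np.floor(self._S @ sensors).astype(np.int64) % N_IDENTITIES
            idx = self._id2idx[outs]
            idx = idx[idx >= 0]
            if idx.size:
                np.add.at(conc, idx, 1.0)
                np.clip(conc, 0.0, self.cap, out=conc)
        if self._poly_idx.size and conc[self._poly_idx].sum() > 0.0:
            levels = self._B @ conc
        else:
            levels = np.zeros(len(self.genes))
        mask = levels >= self.threshold
        if mask.any():
            np.add.at(conc, self._gene_prod[mask], levels[mask])
        np.clip(conc, 0.0, self.cap, out=conc)
        self.levels = levels
        self.step_index += 1
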