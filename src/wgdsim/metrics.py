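"""Lineage and expression metrics, and ploidy-stratified summaries.

Three per-organism metrics track evolutionary trajectories:

* STGD — short-term genetic distance: substitutions per 10 kb between an
  organism and its direct parent.  Across a duplication generation each
  half of the doubled genome is compared against the whole parent.
* LTGD — long-term genetic distance: substitutions per 10 kb between an
  organism and the time-0 founder, comparing each founder-length block of
  the (possibly repeatedly duplicated) genome against the founder.
* ED — expression distance: relative change of the mean gene-product
  concentration between consecutive steps; an ED above 30% marks an
  unstable expression pattern.

Experiment outcomes are classified per replicate (total extinction /
polyploids larger / non-polyploids larger / tie) and reported as exact
fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

PER_BASES = 10_000.0
ED_STABILITY_THRESHOLD = 0.30
ADAPTED_ENERGY = 20_000.0


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.count_nonzero(a != b))


def stgd(child: np.ndarray, parent: np.ndarray) -> float:
    """Substitutions per 10 kb between a genome and its direct parent.

    Equal lengths compare position-wise; a freshly duplicated child
    (twice the parent length) compares each half against the full parent.
    """
    if child.size == parent.size:
        if child.size == 0:
            return 0.0
        return _hamming(child, parent) * PER_BASES / child.size
    if child.size == 2 * parent.size and parent.size > 0:
        half = parent.size
        mismatches = _hamming(child[:half], parent) + _hamming(child[half:], parent)
        return mismatches * PER_BASES / child.size
    raise ValueError(
        f"incompatible genome lengths for STGD: {child.size} vs {parent.size}"
    )


def ltgd(genome: np.ndarray, ancestor: np.ndarray) -> float:
    """Substitutions per 10 kb between a genome and the time-0 ancestor.

    The genome must be ``2**k`` ancestor lengths; each ancestor-length
    block is compared against the ancestor.
    """
    if ancestor.size == 0 or genome.size == 0:
        if ancestor.size == genome.size:
            return 0.0
        raise ValueError("empty genome against non-empty ancestor")
    ratio = genome.size / ancestor.size
    k = round(math.log2(ratio)) if ratio >= 1 else -1
    if k < 0 or ancestor.size * 2**k != genome.size:
        raise ValueError(
            f"genome length {genome.size} is not a power-of-two multiple "
            f"of ancestor length {ancestor.size}"
        )
    blocks = genome.reshape(2**k, ancestor.size)
    mismatches = int(np.count_nonzero(blocks != ancestor[None, :]))
    return mismatches * PER_BASES / genome.size


def expression_distance(
    mean_t: float, mean_prev: float
) -> float:
    """Relative change of the mean gene-product concentration.

    Both means zero gives 0; a zero previous mean with a nonzero current
    one gives ``inf`` (maximal instability).
    """
    if mean_prev == 0.0:
        return 0.0 if mean_t == 0.0 else math.inf
    return abs(mean_t - mean_prev) / mean_prev


def expression_distance_tables(
    conc_t: dict[int, float],
    conc_prev: dict[int, float],
    encoded: Sequence[int],
) -> float:
    """ED computed from two concentration tables over the encoded identities."""
    n = len(encoded)
    if n == 0:
        return 0.0
    m_t = sum(conc_t.get(i, 0.0) for i in encoded) / n
    m_prev = sum(conc_prev.get(i, 0.0) for i in encoded) / n
    return expression_distance(m_t, m_prev)


def is_unstable(ed: float) -> bool:
    """An expression pattern is unstable when ED exceeds 30% (strictly)."""
    return ed > ED_STABILITY_THRESHOLD


def extract_adapted_stable(
    records: pd.DataFrame, window: int = 10
) -> list[int]:
    """Organisms currently adapted (energy >= 20,000) with a stable GRN.

    ``records`` is a step-record table with columns ``step``, ``do_id``,
    ``energy`` and ``ed``; stability means the last ``window`` consecutive
    ED values of the organism are all <= 0.30.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    out = []
    for do_id, grp in records.groupby("do_id"):
        grp = grp.sort_values("step")
        tail = grp.tail(window)
        if len(tail) < window:
            continue
        if tail["energy"].iloc[-1] < ADAPTED_ENERGY:
            continue
        if (tail["ed"] <= ED_STABILITY_THRESHOLD).all():
            out.append(do_id)
    return sorted(out)


OUTCOME_EXTINCTION = "extinction"
OUTCOME_POLYPLOID_LARGER = "polyploid_larger"
OUTCOME_NONPOLYPLOID_LARGER = "nonpolyploid_larger"
OUTCOME_TIE = "tie"


def classify_outcome(n_polyploid: int, n_nonpolyploid: int) -> str:
    if n_polyploid == 0 and n_nonpolyploid == 0:
        return OUTCOME_EXTINCTION
    if n_polyploid > n_nonpolyploid:
        return OUTCOME_POLYPLOID_LARGER
    if n_nonpolyploid > n_polyploid:
        return OUTCOME_NONPOLYPLOID_LARGER
    return OUTCOME_TIE


@dataclass(frozen=True)
class ExperimentSummary:
    """Outcome fractions per condition, as exact rationals."""

    n_simulations: int
    extinction: Fraction
    polyploid_larger: Fraction
    nonpolyploid_larger: Fraction
    tie: Fraction

    def as_dict(self) -> dict[str, float]:
        return {
            "n_simulations": self.n_simulations,
            "extinction": float(self.extinction),
            "polyploid_larger": float(self.polyploid_larger),
            "nonpolyploid_larger": float(self.nonpolyploid_larger),
            "tie": float(self.tie),
        }


def summarize_experiment(
    final_counts: Sequence[tuple[int, int]]
) -> ExperimentSummary:
    """Classify replicate end states ``(n_polyploid, n_nonpolyploid)``."""
    if not final_counts:
        raise ValueError("at least one replicate is required")
    n = len(final_counts)
    tallies = {
        OUTCOME_EXTINCTION: 0,
        OUTCOME_POLYPLOID_LARGER: 0,
        OUTCOME_NONPOLYPLOID_LARGER: 0,
        OUTCOME_TIE: 0,
    }
    for np_, nn in final_counts:
        tallies[classify_outcome(np_, nn)] += 1
    return ExperimentSummary(
        n_simulations=n,
        extinction=Fraction(tallies[OUTCOME_EXTINCTION], n),
        polyploid_larger=Fraction(tallies[OUTCOME_POLYPLOID_LARGER], n),
        nonpolyploid_larger=Fraction(tallies[OUTCOME_NONPOLYPLOID_LARGER], n),
        tie=Fraction(tallies[OUTCOME_TIE], n),
    )


def compare_groups(
    values_polyploid: Sequence[float], values_nonpolyploid: Sequence[float]
) -> tuple[tuple[float, float], float]:
    """Group means and a Welch two-sample t-test p-value.

    Raises ``ValueError`` for degenerate input (a group with fewer than two
    values, or zero variance in both groups).
    """
    a = np.asarray(values_polyploid, dtype=float)
    b = np.asarray(values_nonpolyploid, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if a.std() == 0.0 and b.std() == 0.0:
        if a.mean() == b.mean():
            return (float(a.mean()), float(b.mean())), 1.0
        raise ValueError("zero variance in both groups: t-test undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return (float(a.mean()), float(b.mean())), float(res.pvalue)


def bin_means(records: pd.DataFrame, value: str, bin_width: int = 100) -> pd.DataFrame:
    """Per-ploidy-class means of a step-record column in 100-step bins.

    Returns a tidy frame with columns ``bin``, ``ploidy_class``, ``mean``
    and ``n`` — the box-plot-ready layout used for trajectory figures.
    """
    df = records.copy()
    df["bin"] = (df["step"] // bin_width) * bin_width
    grouped = (
        df.groupby(["bin", "ploidy_class"])[value]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean", "count": "n"})
    )
    return grouped
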