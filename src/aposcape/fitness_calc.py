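"""Maternal fitness: fecundity (seed set) x fertility (germinability).

Fecundity is measured from bagged inflorescences whose full (caryopsis-
bearing) and empty spikelets are counted by weight extrapolation: three
hundred-spikelet samples are weighed, averaged and scaled to each group's
total weight.  Fertility is the germinable fraction of sown seeds.  Maternal
fitness is their product; paternal contributions are ignored, which is
appropriate for self-pollinated pseudogamous apomicts whose embryos carry no
paternal genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpikeletWeighing",
    "GerminationTrial",
    "FitnessRecord",
    "count_from_weights",
    "seed_set",
    "fecundity",
    "germinability",
    "maternal_fitness",
    "fitness_table",
    "regional_aggregate",
]


@dataclass(frozen=True)
class SpikeletWeighing:
    """Weights for one spikelet group (full or empty) of one inflorescence."""

    individual_id: str
    inflorescence_id: str
    group: str  # "full" | "empty"
    hundred_weights: tuple[float, float, float]  # grams per 100 spikelets
    total_weight: float  # grams, whole group

    def __post_init__(self) -> None:
        if self.group not in ("full", "empty"):
            raise ValueError(f"group must be 'full' or 'empty', got {self.group!r}")
        if len(self.hundred_weights) != 3:
            raise ValueError("exactly three hundred-spikelet weights are required")
        if any(w <= 0 for w in self.hundred_weights) or self.total_weight <= 0:
            raise ValueError("weights must be positive")


@dataclass(frozen=True)
class GerminationTrial:
    individual_id: str
    n_sown: int
    n_germinated: int
    horizon_days: int = 60

    def __post_init__(self) -> None:
        if not 0 <= self.n_germinated <= self.n_sown:
            raise ValueError("need 0 <= n_germinated <= n_sown")


@dataclass(frozen=True)
class FitnessRecord:
    individual_id: str
    population_id: str
    region: str
    fecundity: float
    germinability: float
    fitness: float
    seed_set_pct: float = float("nan")
    spikelets_per_infl: float = float("nan")
    n_inflorescences: int = 0


def count_from_weights(w: SpikeletWeighing) -> float:
    """Spikelet count extrapolated from hundred-spikelet weights.

    count = 100 * total_weight / mean(hundred_weights); scale-invariant in
    the weighing units.
    """
    mean_hundred = float(np.mean(w.hundred_weights))
    return 100.0 * w.total_weight / mean_hundred


def seed_set(full: float, empty: float) -> float:
    """Percentage of full spikelets, 100 * full / (full + empty)."""
    total = full + empty
    if total < 1:
        raise ValueError("need at least one spikelet")
    return 100.0 * full / total


def fecundity(
    full_empty_per_individual: Sequence[tuple[float, float]],
    estimator: str = "mean_of_individuals",
) -> float:
    """Population fecundity as a proportion of full spikelets.

    ``mean_of_individuals`` (default) averages each individual's full
    fraction, weighting plants equally regardless of spikelet totals;
    ``pooled`` divides summed full counts by summed totals.  The two differ
    whenever individuals contribute unequal totals.
    """
    fracs, fulls, totals = [], 0.0, 0.0
    for full, empty in full_empty_per_individual:
        total = full + empty
        if total <= 0:
            warnings.warn("individual with no spikelets excluded", stacklevel=2)
            continue
        fracs.append(full / total)
        fulls += full
        totals += total
    if not fracs:
        raise ValueError("no individuals with spikelet counts")
    if estimator == "pooled":
        return fulls / totals
    if estimator == "mean_of_individuals":
        return float(np.mean(fracs))
    raise ValueError(f"unknown estimator {estimator!r}")


def germinability(trials: Iterable[GerminationTrial]) -> float:
    """Population germinability: mean of per-individual germinated fractions."""
    fracs = []
    for t in trials:
        if t.n_sown == 0:
            warnings.warn("trial with zero sown seeds excluded", stacklevel=2)
            continue
        fracs.append(t.n_germinated / t.n_sown)
    if not fracs:
        raise ValueError("no usable germination trials")
    return float(np.mean(fracs))


def maternal_fitness(fecundity_prop: float, fertility_prop: float) -> float:
    """Fitness = fecundity x fertility, both proportions in [0, 1]."""
    for v in (fecundity_prop, fertility_prop):
        if not 0.0 <= v <= 1.0:
            raise ValueError("fitness components must be proportions in [0, 1]")
    return fecundity_prop * fertility_prop


def _individual_spikelet_counts(
    weighings: Sequence[SpikeletWeighing],
) -> dict[str, tuple[float, float]]:
    """Aggregate full/empty spikelet counts per individual across inflorescences."""
    acc: dict[str, dict[str, float]] = {}
    for w in weighings:
        acc.setdefault(w.individual_id, {"full": 0.0, "empty": 0.0})
        acc[w.individual_id][w.group] += count_from_weights(w)
    out = {}
    for ind, d in acc.items():
        if d["full"] + d["empty"] <= 0:
            warnings.warn(f"individual {ind!r} has no spikelets; excluded", stacklevel=2)
            continue
        out[ind] = (d["full"], d["empty"])
    return out


def fitness_table(
    weighings: Sequence[SpikeletWeighing],
    trials: Sequence[GerminationTrial],
    individual_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-individual fecundity, germinability and fitness.

    ``individual_meta`` may add ``population_id``, ``region``,
    ``n_inflorescences`` and ``spikelets_per_infl`` columns keyed by
    ``individual_id``.  Individuals missing either component are dropped
    with a warning.
    """
    counts = _individual_spikelet_counts(weighings)
    germ: dict[str, list[float]] = {}
    for t in trials:
        if t.n_sown > 0:
            germ.setdefault(t.individual_id, []).append(t.n_germinated / t.n_sown)
    rows = []
    for ind in sorted(set(counts) | set(germ)):
        if ind not in counts or ind not in germ:
            warnings.warn(
                f"individual {ind!r} lacks weighings or germination data; excluded",
                stacklevel=2,
            )
            continue
        full, empty = counts[ind]
        fec = full / (full + empty)
        g = float(np.mean(germ[ind]))
        rows.append(
            {
                "individual_id": ind,
                "seed_set_pct": seed_set(full, empty),
                "fecundity": fec,
                "germinability": g,
                "fitness": maternal_fitness(fec, g),
            }
        )
    df = pd.DataFrame(rows)
    if individual_meta is not None and not df.empty:
        df = df.merge(individual_meta, on="individual_id", how="left")
    return df


def regional_aggregate(
    records: pd.DataFrame, grouping: Sequence[str] = ("region",)
) -> pd.DataFrame:
    """Mean and standard error of every fitness component per group.

    SE is NaN for singleton groups (undefined, not zero).
    """
    grouping = list(grouping)
    for key in grouping:
        if key not in records.columns:
            raise KeyError(f"grouping key {key!r} missing from records")
    value_cols = [
        c
        for c in (
            "seed_set_pct",
            "spikelets_per_infl",
            "n_inflorescences",
            "fecundity",
            "germinability",
            "fitness",
        )
        if c in records.columns
    ]
    agg = records.groupby(grouping)[value_cols].agg(["mean", "sem", "count"])
    agg.columns = [f"{c}_{stat}" for c, stat in agg.columns]
    return agg.reset_index()
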