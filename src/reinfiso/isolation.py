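"""Stalker-style isolation indices from free-interaction stream trials.

The per-behavior index for one population x species is

    I = (C - H) / (C + H)

where ``C`` and ``H`` are the mean numbers of conspecific- and
heterospecific-directed acts of that behavior across replicates.  Total
isolation first sums all (or a chosen subset of) behavior counts within
each replicate and species, then either applies the formula per
replicate (the response variable of the heteroskedastic GLS) or averages
the replicate sums per population before applying it (the published
population-level aggregation).  Both paths are implemented and labelled.

``I`` is missing — not zero, not an error — when both means are zero,
since the ratio is undefined there.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError
from .trial_io import Behavior, Context, StreamBehaviorCount, Target

__all__ = [
    "IsolationEstimate",
    "isolation_index",
    "behavior_isolation_table",
    "total_isolation_per_replicate",
    "population_total_isolation",
    "exclude_behaviors_sensitivity",
    "apply_resident_context",
]

ALL_BEHAVIORS = frozenset(Behavior)


def isolation_index(conspecific_mean: float, heterospecific_mean: float) -> float | None:
    """Stalker isolation index on a pair of mean counts.

    Returns ``None`` when both means are zero.  Antisymmetric under
    argument swap; invariant to common positive scaling.
    """
    if conspecific_mean < 0 or heterospecific_mean < 0:
        raise DomainError(
            f"means must be >= 0, got ({conspecific_mean}, {heterospecific_mean})"
        )
    if not (np.isfinite(conspecific_mean) and np.isfinite(heterospecific_mean)):
        raise DomainError("means must be finite")
    total = conspecific_mean + heterospecific_mean
    if total == 0:
        return None
    return (conspecific_mean - heterospecific_mean) / total


@dataclass(frozen=True)
class IsolationEstimate:
    """One isolation-index estimate at behavior, replicate, or population scope."""

    scope: str  # 'behavior' | 'replicate_total' | 'population_total'
    population: str
    context: Context
    species: str
    behavior: Behavior | None
    replicate_id: str | None
    conspecific_mean: float
    heterospecific_mean: float
    i_index: float | None
    conspecific_sd: float | None = None
    heterospecific_sd: float | None = None
    n_replicates: int | None = None


def _group_counts(
    counts: Iterable[StreamBehaviorCount],
) -> dict[tuple[str, str], dict[str, object]]:
    """Index counts by (population, species), keeping replicate structure."""
    groups: dict[tuple[str, str], dict] = {}
    for c in counts:
        g = groups.setdefault(
            (c.population, c.species),
            {"context": c.context, "replicates": defaultdict(lambda: defaultdict(dict))},
        )
        g["replicates"][c.replicate_id][c.behavior][c.target] = c.count
    return groups


def _sd(values: Sequence[float]) -> float | None:
    # n-1 sample SD; undefined for a single replicate
    if len(values) < 2:
        return None
    return float(np.std(np.asarray(values, dtype=float), ddof=1))


def behavior_isolation_table(
    counts: Iterable[StreamBehaviorCount],
) -> list[IsolationEstimate]:
    """Per population x species x behavior: mean and SD of conspecific and
    heterospecific counts across replicates, and I from the means.

    A behavior absent from every replicate of a group yields no row; a
    behavior tallied as all-zero yields a row with missing I.
    """
    out: list[IsolationEstimate] = []
    for (population, species), g in sorted(_group_counts(counts).items()):
        reps = g["replicates"]
        behaviors = sorted(
            {b for rep in reps.values() for b in rep}, key=lambda b: b.value
        )
        for behavior in behaviors:
            con = [rep[behavior].get(Target.CONSPECIFIC, 0) for rep in reps.values()
                   if behavior in rep]
            het = [rep[behavior].get(Target.HETEROSPECIFIC, 0) for rep in reps.values()
                   if behavior in rep]
            c_mean, h_mean = float(np.mean(con)), float(np.mean(het))
            out.append(
                IsolationEstimate(
                    scope="behavior",
                    population=population,
                    context=g["context"],
                    species=species,
                    behavior=behavior,
                    replicate_id=None,
                    conspecific_mean=c_mean,
                    heterospecific_mean=h_mean,
                    i_index=isolation_index(c_mean, h_mean),
                    conspecific_sd=_sd(con),
                    heterospecific_sd=_sd(het),
                    n_replicates=len(con),
                )
            )
    return out


def _check_subset(behaviors: Iterable[Behavior]) -> frozenset[Behavior]:
    subset = frozenset(Behavior(b) for b in behaviors)
    if not subset:
        raise DomainError("behavior subset must be non-empty")
    return subset


def total_isolation_per_replicate(
    counts: Iterable[StreamBehaviorCount],
    behaviors: Iterable[Behavior] = ALL_BEHAVIORS,
) -> list[IsolationEstimate]:
    """Sum counts over the behavior subset within each replicate x species,
    then apply the index to the per-replicate sums.

    These per-replicate totals are the response of the heteroskedastic
    GLS fit downstream.
    """
    subset = _check_subset(behaviors)
    out: list[IsolationEstimate] = []
    for (population, species), g in sorted(_group_counts(counts).items()):
        for rep_id in sorted(g["replicates"]):
            rep = g["replicates"][rep_id]
            con = sum(
                rep[b].get(Target.CONSPECIFIC, 0) for b in subset if b in rep
            )
            het = sum(
                rep[b].get(Target.HETEROSPECIFIC, 0) for b in subset if b in rep
            )
            out.append(
                IsolationEstimate(
                    scope="replicate_total",
                    population=population,
                    context=g["context"],
                    species=species,
                    behavior=None,
                    replicate_id=rep_id,
                    conspecific_mean=float(con),
                    heterospecific_mean=float(het),
                    i_index=isolation_index(con, het),
                    n_replicates=1,
                )
            )
    return out


def population_total_isolation(
    counts: Iterable[StreamBehaviorCount],
    behaviors: Iterable[Behavior] = ALL_BEHAVIORS,
) -> list[IsolationEstimate]:
    """Average the per-replicate summed totals across replicates within each
    population x species, then apply the index to the averages.

    With a single replicate this degenerates exactly to
    :func:`total_isolation_per_replicate`.  Note this averages the summed
    counts, not the per-replicate I values.
    """
    subset = _check_subset(behaviors)
    per_rep = total_isolation_per_replicate(counts, subset)
    grouped: dict[tuple[str, str], list[IsolationEstimate]] = defaultdict(list)
    for e in per_rep:
        grouped[(e.population, e.species)].append(e)
    out: list[IsolationEstimate] = []
    for (population, species), ests in sorted(grouped.items()):
        con = [e.conspecific_mean for e in ests]
        het = [e.heterospecific_mean for e in ests]
        c_mean, h_mean = float(np.mean(con)), float(np.mean(het))
        out.append(
            IsolationEstimate(
                scope="population_total",
                population=population,
                context=ests[0].context,
                species=species,
                behavior=None,
                replicate_id=None,
                conspecific_mean=c_mean,
                heterospecific_mean=h_mean,
                i_index=isolation_index(c_mean, h_mean),
                conspecific_sd=_sd(con),
                heterospecific_sd=_sd(het),
                n_replicates=len(ests),
            )
        )
    return out


def exclude_behaviors_sensitivity(
    counts: Iterable[StreamBehaviorCount],
    drop: Iterable[Behavior],
) -> tuple[list[IsolationEstimate], list[IsolationEstimate]]:
    """Total isolation with and without a behavior subset, for refitting.

    Returns ``(full, reduced)`` per-replicate estimates, where ``reduced``
    sums only the complement of ``drop``.  Dropping every behavior is a
    domain error; dropping none returns two identical tables.
    """
    counts = list(counts)
    drop_set = frozenset(Behavior(b) for b in drop)
    keep = ALL_BEHAVIORS - drop_set
    if not keep:
        raise DomainError("cannot drop all five behaviors")
    full = total_isolation_per_replicate(counts, ALL_BEHAVIORS)
    reduced = total_isolation_per_replicate(counts, keep)
    return full, reduced


def apply_resident_context(
    estimates: Iterable[IsolationEstimate], resident_species: str
) -> list[IsolationEstimate]:
    """Recode context so every estimate for the resident species is
    sympatric, regardless of the trial population's context.

    The resident congener's entire range lies inside the focal species'
    range, so its individuals are sympatric in every trial; the focal
    species keeps the context of its source population.
    """
    out = []
    for e in estimates:
        if e.species == resident_species and e.context is not Context.SYMPATRIC:
            out.append(
                IsolationEstimate(
                    scope=e.scope,
                    population=e.population,
                    context=Context.SYMPATRIC,
                    species=e.species,
                    behavior=e.behavior,
                    replicate_id=e.replicate_id,
                    conspecific_mean=e.conspecific_mean,
                    heterospecific_mean=e.heterospecific_mean,
                    i_index=e.i_index,
                    conspecific_sd=e.conspecific_sd,
                    heterospecific_sd=e.heterospecific_sd,
                    n_replicates=e.n_replicates,
                )
            )
        else:
            out.append(e)
    return out
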