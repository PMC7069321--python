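"""Strength-of-preference (SOP) statistic and its group summaries.

For a focal individual that spent ``T_C`` seconds near the conspecific
stimulus and ``T_H`` near the heterospecific one,

    SOP = (T_C - T_H) / (T_C + T_H)

ranges from +1 (complete conspecific preference) through 0 (no
preference) to -1 (complete heterospecific preference).  Under the
Sobel-Chen reading the same number is the proportional reduction in gene
flow relative to random mating, so it is also exposed under that name.
A trial in which the fish never entered either association zone has no
preference interpretation: SOP is missing, and missing records are
excluded from summaries with a logged warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .inference import one_sample_t, wilcoxon_signed_rank
from .trial_io import Context, DichotomousTrial, Sex

__all__ = [
    "SOPRecord",
    "GroupSummary",
    "SizeMatchResult",
    "compute_sop",
    "proportional_gene_flow_reduction",
    "sop_records",
    "group_sop_summary",
    "pool_group_means",
    "size_match_check",
]

logger = logging.getLogger(__name__)


def compute_sop(t_conspecific: float, t_heterospecific: float) -> float | None:
    """Per-individual strength of preference; ``None`` when both times are 0.

    Antisymmetric under argument swap and invariant to rescaling both
    times by a common positive factor.
    """
    if t_conspecific < 0 or t_heterospecific < 0:
        raise DomainError(
            f"association times must be >= 0, got ({t_conspecific}, {t_heterospecific})"
        )
    if not (math.isfinite(t_conspecific) and math.isfinite(t_heterospecific)):
        raise DomainError("association times must be finite")
    total = t_conspecific + t_heterospecific
    if total == 0:
        return None
    return (t_conspecific - t_heterospecific) / total


#: SOP read as the proportional reduction in gene flow relative to random
#: mating (a value of 0.3 means 30% less gene flow than random mating
#: would produce).  Pure relabeling, no extra math.
proportional_gene_flow_reduction = compute_sop


@dataclass(frozen=True)
class SOPRecord:
    """Per-individual SOP with its grouping labels carried from the trial."""

    focal_id: str
    population: str
    context: Context
    sex: Sex
    sop: float | None


def sop_records(trials: Iterable[DichotomousTrial]) -> list[SOPRecord]:
    records = []
    for t in trials:
        s = compute_sop(t.t_conspecific, t.t_heterospecific)
        if s is None:
            logger.warning(
                "trial %s: zero total association time; SOP is missing", t.trial_id
            )
        records.append(SOPRecord(t.focal_id, t.population, t.context, t.sex, s))
    return records


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SE SOP for one group plus a two-sided test against zero."""

    group: dict
    n: int
    mean: float | None
    se: float | None
    test_name: str | None = None
    statistic: float | None = None
    df: float | None = None
    p_value: float | None = None
    degenerate: bool = False


_TESTS = ("t_one_sample", "wilcoxon_signed_rank")


def group_sop_summary(
    records: Iterable[SOPRecord],
    group_by: Sequence[str] = ("population", "context", "sex"),
    test: str = "t_one_sample",
) -> list[GroupSummary]:
    """Per-group mean, SE (= sample SD / sqrt(n)) and two-sided test vs 0.

    Missing SOPs are excluded; an empty group yields an ``n=0`` summary
    with missing statistics rather than an error.
    """
    if test not in _TESTS:
        raise DomainError(f"unknown test {test!r}; choose from {_TESTS}")
    rows = []
    for r in records:
        d = {"population": r.population, "context": r.context.value, "sex": r.sex.value}
        d["sop"] = r.sop
        rows.append(d)
    df = pd.DataFrame(rows)
    bad = [g for g in group_by if g not in ("population", "context", "sex")]
    if bad:
        raise DomainError(f"unknown grouping label(s): {bad}")
    out: list[GroupSummary] = []
    for key, sub in df.groupby(list(group_by), sort=True, dropna=False):
        if not isinstance(key, tuple):
            key = (key,)
        group = dict(zip(group_by, key))
        values = sub["sop"].dropna().to_numpy(dtype=float)
        n = values.size
        if n == 0:
            out.append(GroupSummary(group, 0, None, None, degenerate=True))
            continue
        mean = float(np.mean(values))
        se = float(np.std(values, ddof=1) / math.sqrt(n)) if n >= 2 else None
        if n < 2:
            out.append(GroupSummary(group, n, mean, se, degenerate=True))
            continue
        if test == "t_one_sample":
            res = one_sample_t(values, 0.0)
            out.append(
                GroupSummary(
                    group, n, mean, se, "one-sample t", res.statistic, res.df,
                    res.p_value, res.degenerate,
                )
            )
        else:
            res = wilcoxon_signed_rank(values, 0.0)
            out.append(
                GroupSummary(
                    group, n, mean, se, "Wilcoxon signed rank", res.z, None,
                    res.p_value, res.degenerate,
                )
            )
    return out


def pool_group_means(means: Sequence[float], ns: Sequence[int]) -> float:
    """n-weighted mean of group means; identical to the mean of the
    concatenated raw samples."""
    if len(means) != len(ns):
        raise DomainError(f"length mismatch: {len(means)} means vs {len(ns)} ns")
    if len(means) == 0:
        raise DomainError("need at least one group")
    ns_arr = np.asarray(ns, dtype=float)
    if np.any(ns_arr < 1):
        raise DomainError("all group sizes must be >= 1")
    return float(np.average(np.asarray(means, dtype=float), weights=ns_arr))


@dataclass(frozen=True)
class SizeMatchResult:
    """Paired size check for the two stimulus fish of each trial."""

    n_pairs: int
    z: float | None
    p_value: float | None
    within_15pct_fraction: float
    degenerate: bool


def size_match_check(
    con_lengths: Sequence[float], het_lengths: Sequence[float], threshold: float = 0.15
) -> SizeMatchResult:
    """Paired Wilcoxon signed-rank test of stimulus standard lengths plus
    the fraction of pairs matched within ``threshold`` relative length
    difference (relative to the conspecific stimulus)."""
    if len(con_lengths) != len(het_lengths):
        raise DomainError("con_lengths and het_lengths must have equal length")
    if len(con_lengths) == 0:
        raise DomainError("need at least one pair")
    con = np.asarray(con_lengths, dtype=float)
    het = np.asarray(het_lengths, dtype=float)
    within = float(np.mean(np.abs(het - con) / con <= threshold + 1e-12))
    res = wilcoxon_signed_rank(con, paired_with=het)
    return SizeMatchResult(
        n_pairs=len(con),
        z=res.z,
        p_value=res.p_value,
        within_15pct_fraction=within,
        degenerate=res.degenerate,
    )
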