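"""Synthetic mate-choice trial generators.

Two generative models mirror the two assay designs:

* Dichotomous trials use a two-stage beta allocation.  A focal fish's
  total association time is ``duration * a`` with the activity fraction
  ``a ~ Beta(mean=activity_mean, precision=activity_precision)``, and the
  conspecific share of that time is
  ``c ~ Beta(mean=(1 + beta)/2, precision=kappa)``.  Then
  ``T_C = A*c`` and ``T_H = A*(1 - c)``, so ``T_C + T_H <= duration``
  by construction and the strength of preference ``(T_C - T_H)/(T_C + T_H)
  = 2c - 1`` has expectation exactly ``beta``.  ``beta`` is therefore the
  simulator's recoverable estimand for the preference statistic.

* Stream trials draw behavior counts per replicate x species x behavior.
  The conspecific-directed count has mean ``lambda*(1 + iota)/2`` and the
  heterospecific one ``lambda*(1 - iota)/2``; with ``dispersion > 0`` the
  Poisson mean is gamma-mixed (negative-binomial-type overdispersion),
  matching field tallies whose standard deviations rival their means.
  ``iota`` is the estimand for the Stalker isolation index.

One global seed drives independent per-group substreams (derived from a
hash of the group label), so adding a group never perturbs the draws of
an existing one.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .trial_io import (
    Behavior,
    Context,
    Dataset,
    DichotomousTrial,
    Sex,
    Side,
    StreamBehaviorCount,
    Target,
)

__all__ = [
    "GroupSpec",
    "DichotomousSimConfig",
    "BehaviorRates",
    "StreamSimConfig",
    "simulate_dichotomous",
    "simulate_stream",
    "make_paper_like_dataset",
    "sop_sd",
]

GENERATOR_VERSION = "1"


def _substream(seed: int, label: str) -> np.random.Generator:
    """Independent RNG for one group, stable under group addition/removal."""
    tag = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(tag)]))


def _beta_params(mean: float, precision: float) -> tuple[float, float]:
    return mean * precision, (1.0 - mean) * precision


def sop_sd(beta: float, kappa: float) -> float:
    """Standard deviation of the per-trial preference statistic ``2c - 1``
    under the beta-share model: ``2 * sqrt(m(1-m)/(1+kappa))`` with
    ``m = (1 + beta)/2``."""
    m = (1.0 + beta) / 2.0
    return 2.0 * np.sqrt(m * (1.0 - m) / (1.0 + kappa))


@dataclass(frozen=True)
class GroupSpec:
    """One population x context x sex cell of a dichotomous design."""

    population: str
    context: Context
    sex: Sex
    n: int
    beta: float  # latent preference bias in [-1, 1]; endpoints degenerate


@dataclass
class DichotomousSimConfig:
    groups: Sequence[GroupSpec]
    kappa: float = 5.0
    activity_mean: float = 0.7
    activity_precision: float = 10.0
    trial_duration: float = 900.0
    seed: int = 0
    # matched stimulus standard lengths (mm); None disables the columns
    stimulus_length_mean: float | None = 45.0
    stimulus_length_sd: float = 5.0

    def validate(self) -> None:
        if not self.groups:
            raise ConfigError("dichotomous config needs at least one group")
        contexts: dict[str, Context] = {}
        for g in self.groups:
            if not -1.0 <= g.beta <= 1.0:
                raise ConfigError(f"group {g.population}/{g.sex}: |beta| must be <= 1")
            if g.n < 1:
                raise ConfigError(f"group {g.population}/{g.sex}: n must be >= 1")
            prev = contexts.setdefault(g.population, Context(g.context))
            if prev is not Context(g.context):
                raise ConfigError(f"population {g.population} given two contexts")
        if not 0.0 < self.activity_mean < 1.0:
            raise ConfigError("activity_mean must be in (0, 1)")
        if self.kappa <= 0 or self.activity_precision <= 0:
            raise ConfigError("kappa and activity_precision must be > 0")
        if self.trial_duration <= 0:
            raise ConfigError("trial_duration must be > 0")


def simulate_dichotomous(config: DichotomousSimConfig) -> list[DichotomousTrial]:
    """Draw one dichotomous trial per focal fish under the beta-allocation model.

    Same seed implies bit-identical output.
    """
    config.validate()
    trials: list[DichotomousTrial] = []
    for g in config.groups:
        sex = Sex(g.sex)
        ctx = Context(g.context)
        rng = _substream(config.seed, f"dich/{g.population}/{sex.value}")
        a_a, a_b = _beta_params(config.activity_mean, config.activity_precision)
        activity = rng.beta(a_a, a_b, size=g.n)
        share_mean = (1.0 + g.beta) / 2.0
        if share_mean <= 0.0 or share_mean >= 1.0:
            share = np.full(g.n, share_mean)  # degenerate endpoint beta = +/-1
        else:
            s_a, s_b = _beta_params(share_mean, config.kappa)
            share = rng.beta(s_a, s_b, size=g.n)
        total = config.trial_duration * activity
        t_con = total * share
        t_het = total * (1.0 - share)
        if config.stimulus_length_mean is not None:
            con_len = rng.normal(config.stimulus_length_mean, config.stimulus_length_sd, g.n)
            con_len = np.clip(con_len, 20.0, None)
            het_len = con_len * (1.0 + rng.uniform(-0.1, 0.1, g.n))
        for i in range(g.n):
            tid = f"{g.population}-{sex.value[0].upper()}-{i + 1:03d}"
            trials.append(
                DichotomousTrial(
                    trial_id=tid,
                    focal_id=f"fish-{tid}",
                    population=g.population,
                    context=ctx,
                    sex=sex,
                    t_conspecific=float(t_con[i]),
                    t_heterospecific=float(t_het[i]),
                    trial_duration=config.trial_duration,
                    conspecific_side=Side.LEFT if i % 2 == 0 else Side.RIGHT,
                    stimulus_con_length=(
                        float(con_len[i]) if config.stimulus_length_mean is not None else None
                    ),
                    stimulus_het_length=(
                        float(het_len[i]) if config.stimulus_length_mean is not None else None
                    ),
                )
            )
    return trials


@dataclass(frozen=True)
class BehaviorRates:
    """Expected total count per replicate and conspecific bias for one behavior."""

    lam: float  # expected conspecific + heterospecific count, >= 0
    iota: float  # conspecific bias in [-1, 1]; the estimand for I


@dataclass
class StreamSimConfig:
    populations: Sequence[tuple[str, Context]]
    behaviors: Mapping[Behavior, BehaviorRates]
    species_pair: tuple[str, str] = ("E. zonale", "E. barrenense")
    n_replicates: int = 3
    dispersion: float = 0.0  # 0 => Poisson; > 0 => gamma-mixed counts
    seed: int = 0
    # optional per-species override of the behavior map
    behaviors_by_species: Mapping[str, Mapping[Behavior, BehaviorRates]] | None = None

    def validate(self) -> None:
        if not self.populations:
            raise ConfigError("stream config needs at least one population")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if len(set(self.species_pair)) != 2:
            raise ConfigError("species_pair must be two distinct labels")
        maps = [self.behaviors]
        if self.behaviors_by_species:
            maps.extend(self.behaviors_by_species.values())
        for m in maps:
            for b, r in m.items():
                Behavior(b)
                if r.lam < 0:
                    raise ConfigError(f"behavior {b}: lambda must be >= 0")
                if not -1.0 <= r.iota <= 1.0:
                    raise ConfigError(f"behavior {b}: |iota| must be <= 1")


def _draw_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion > 0:
        mean = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
        if mean <= 0:
            return 0
    return int(rng.poisson(mean))


def simulate_stream(config: StreamSimConfig) -> list[StreamBehaviorCount]:
    """Draw overdispersed behavior counts for every replicate x species x behavior."""
    config.validate()
    counts: list[StreamBehaviorCount] = []
    for population, context in config.populations:
        ctx = Context(context)
        for species in config.species_pair:
            rates = config.behaviors
            if config.behaviors_by_species and species in config.behaviors_by_species:
                rates = config.behaviors_by_species[species]
            for j in range(config.n_replicates):
                rep_id = f"{population}-R{j + 1}"
                rng = _substream(config.seed, f"stream/{population}/{species}/{rep_id}")
                for behavior in Behavior:
                    r = rates.get(behavior)
                    if r is None:
                        continue
                    mu_con = r.lam * (1.0 + r.iota) / 2.0
                    mu_het = r.lam * (1.0 - r.iota) / 2.0
                    for target, mu in (
                        (Target.CONSPECIFIC, mu_con),
                        (Target.HETEROSPECIFIC, mu_het),
                    ):
                        counts.append(
                            StreamBehaviorCount(
                                replicate_id=rep_id,
                                population=population,
                                context=ctx,
                                species=species,
                                behavior=behavior,
                                target=target,
                                count=_draw_count(rng, mu, config.dispersion),
                            )
                        )
    return counts


# --- the study-condition dataset ------------------------------------------

# Per-cell latent preference biases for the four populations (two sympatric
# with the congener, two allopatric), chosen to match the published group
# mean preferences; n = 18 per cell except EF males (16).
_PAPER_BETAS_F = {"EF": 0.73, "LC": 0.31, "MF": 0.27, "FC": 0.02}
_PAPER_BETAS_M = {"EF": 0.30, "LC": 0.48, "MF": 0.11, "FC": 0.20}
_PAPER_CONTEXT = {
    "EF": Context.SYMPATRIC,
    "LC": Context.SYMPATRIC,
    "MF": Context.ALLOPATRIC,
    "FC": Context.ALLOPATRIC,
}
_PAPER_N = {("EF", Sex.MALE): 16}  # all other cells 18

# Stream behavior rates on the scale of the published replicate means.
# The context signal is carried by male solicitation toward heterospecific
# females in the focal species; chases are strongly conspecific-biased
# everywhere and interspecific spawning is rare (small lambda).
_STREAM_RATES_RESIDENT = {
    Behavior.SPAWN: BehaviorRates(2.5, 0.98),
    Behavior.SOLICIT_SUCCESS: BehaviorRates(40.0, 0.95),
    Behavior.SOLICIT_FAIL: BehaviorRates(180.0, 0.95),
    Behavior.CHASE_MM: BehaviorRates(130.0, 0.90),
    Behavior.CHASE_MF: BehaviorRates(100.0, 0.75),
}
_STREAM_RATES_FOCAL_SYMPATRIC = _STREAM_RATES_RESIDENT
_STREAM_RATES_FOCAL_ALLOPATRIC = {
    Behavior.SPAWN: BehaviorRates(2.5, 0.98),
    Behavior.SOLICIT_SUCCESS: BehaviorRates(40.0, 0.50),
    Behavior.SOLICIT_FAIL: BehaviorRates(180.0, 0.55),
    Behavior.CHASE_MM: BehaviorRates(130.0, 0.90),
    Behavior.CHASE_MF: BehaviorRates(100.0, 0.75),
}

FOCAL_SPECIES = "E. zonale"
RESIDENT_SPECIES = "E. barrenense"


def make_paper_like_dataset(seed: int) -> Dataset:
    """Full synthetic dataset under the study conditions: four populations
    (two per context) x two sexes with n = 18 per cell (EF males 16), and
    three stream replicates per population with overdispersed counts.

    Deterministic given ``seed``.
    """
    groups = []
    for pop, ctx in _PAPER_CONTEXT.items():
        for sex, betas in ((Sex.FEMALE, _PAPER_BETAS_F), (Sex.MALE, _PAPER_BETAS_M)):
            groups.append(
                GroupSpec(
                    population=pop,
                    context=ctx,
                    sex=sex,
                    n=_PAPER_N.get((pop, sex), 18),
                    beta=betas[pop],
                )
            )
    dich_cfg = DichotomousSimConfig(groups=groups, kappa=5.0, seed=seed)
    trials = simulate_dichotomous(dich_cfg)

    counts: list[StreamBehaviorCount] = []
    for pop, ctx in _PAPER_CONTEXT.items():
        focal_rates = (
            _STREAM_RATES_FOCAL_SYMPATRIC
            if ctx is Context.SYMPATRIC
            else _STREAM_RATES_FOCAL_ALLOPATRIC
        )
        cfg = StreamSimConfig(
            populations=[(pop, ctx)],
            behaviors=focal_rates,
            behaviors_by_species={RESIDENT_SPECIES: _STREAM_RATES_RESIDENT},
            species_pair=(FOCAL_SPECIES, RESIDENT_SPECIES),
            n_replicates=3,
            dispersion=0.35,
            seed=seed,
        )
        counts.extend(simulate_stream(cfg))

    ds = Dataset(
        trials=trials,
        stream_counts=counts,
        metadata={
            "generator": "reinfiso.synthetic.make_paper_like_dataset",
            "generator_version": GENERATOR_VERSION,
            "seed": int(seed),
        },
    )
    ds.validate()
    return ds
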