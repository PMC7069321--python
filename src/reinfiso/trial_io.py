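"""Data model and CSV I/O for the two mate-choice trial types.

Two kinds of records are handled:

* :class:`DichotomousTrial` — one focal fish given a no-contact choice
  between a conspecific and a heterospecific stimulus; the measurement
  is the time spent in each association zone during a 15-min (900 s)
  observation.
* :class:`StreamBehaviorCount` — one tallied behavior class from a
  free-interaction artificial-stream replicate, split by whether the
  behavior was directed at a conspecific or a heterospecific.

CSV interchange is comma-separated UTF-8 with a mandatory header.
Optional columns (stimulus side, stimulus standard lengths) may be
absent entirely or blank per row; blank means missing, never zero.
Neutral-zone time is not stored — it is ``duration - t_con - t_het``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConsistencyError, SchemaError, ValidationError

__all__ = [
    "Context",
    "Sex",
    "Behavior",
    "Target",
    "Side",
    "DichotomousTrial",
    "StreamBehaviorCount",
    "Dataset",
    "read_dichotomous",
    "read_stream",
    "read_dataset",
    "write_dataset",
    "DICHOTOMOUS_COLUMNS",
    "STREAM_COLUMNS",
]

# small float slack so times summing exactly to the duration round-trip
_TIME_TOL = 1e-9


class Context(str, Enum):
    """Geographic context of a population relative to the congener."""

    SYMPATRIC = "sympatric"
    ALLOPATRIC = "allopatric"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class Behavior(str, Enum):
    """The five tallied behavior classes from the stream assay."""

    SPAWN = "spawn"
    SOLICIT_SUCCESS = "solicit_success"
    SOLICIT_FAIL = "solicit_fail"
    CHASE_MM = "chase_mm"
    CHASE_MF = "chase_mf"


class Target(str, Enum):
    CONSPECIFIC = "conspecific"
    HETEROSPECIFIC = "heterospecific"


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


def _coerce_enum(enum_cls, value, what: str):
    try:
        return enum_cls(value)
    except ValueError:
        valid = ", ".join(m.value for m in enum_cls)
        raise SchemaError(
            f"unknown {what} token {value!r}; valid tokens: {valid}"
        ) from None


@dataclass(frozen=True)
class DichotomousTrial:
    """One focal individual's dichotomous-choice trial.

    ``t_conspecific`` and ``t_heterospecific`` are seconds spent in the
    conspecific and heterospecific association zones; their sum may not
    exceed ``trial_duration``.
    """

    trial_id: str
    focal_id: str
    population: str
    context: Context
    sex: Sex
    t_conspecific: float
    t_heterospecific: float
    trial_duration: float = 900.0
    conspecific_side: Side | None = None
    stimulus_con_length: float | None = None
    stimulus_het_length: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "context", _coerce_enum(Context, self.context, "context"))
        object.__setattr__(self, "sex", _coerce_enum(Sex, self.sex, "sex"))
        if self.conspecific_side is not None:
            object.__setattr__(
                self, "conspecific_side", _coerce_enum(Side, self.conspecific_side, "side")
            )
        for name in ("t_conspecific", "t_heterospecific", "trial_duration"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"trial {self.trial_id!r}: {name} is not finite")
        if self.t_conspecific < 0 or self.t_heterospecific < 0:
            raise ValidationError(
                f"trial {self.trial_id!r}: association times must be >= 0 "
                f"(got {self.t_conspecific}, {self.t_heterospecific})"
            )
        if self.trial_duration <= 0:
            raise ValidationError(f"trial {self.trial_id!r}: trial_duration must be > 0")
        total = self.t_conspecific + self.t_heterospecific
        if total > self.trial_duration + _TIME_TOL:
            raise ValidationError(
                f"trial {self.trial_id!r}: t_conspecific + t_heterospecific = {total} "
                f"exceeds trial_duration = {self.trial_duration}"
            )
        for name in ("stimulus_con_length", "stimulus_het_length"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v <= 0):
                raise ValidationError(f"trial {self.trial_id!r}: {name} must be positive")


@dataclass(frozen=True)
class StreamBehaviorCount:
    """One (replicate, species, behavior, target) tally from a stream assay."""

    replicate_id: str
    population: str
    context: Context
    species: str
    behavior: Behavior
    target: Target
    count: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "context", _coerce_enum(Context, self.context, "context"))
        object.__setattr__(self, "behavior", _coerce_enum(Behavior, self.behavior, "behavior"))
        object.__setattr__(self, "target", _coerce_enum(Target, self.target, "target"))
        if not isinstance(self.count, (int,)) or isinstance(self.count, bool):
            raise ValidationError(
                f"replicate {self.replicate_id!r}: count must be an integer, got {self.count!r}"
            )
        if self.count < 0:
            raise ValidationError(
                f"replicate {self.replicate_id!r}: count must be >= 0, got {self.count}"
            )

    @property
    def key(self) -> tuple[str, str, Behavior, Target]:
        return (self.replicate_id, self.species, self.behavior, self.target)


@dataclass
class Dataset:
    """Both trial collections plus free-form provenance metadata."""

    trials: list[DichotomousTrial] = field(default_factory=list)
    stream_counts: list[StreamBehaviorCount] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        check_population_contexts(self.trials, self.stream_counts)
        seen: set = set()
        for c in self.stream_counts:
            if c.key in seen:
                raise ConsistencyError(f"duplicate stream-count key {c.key!r}")
            seen.add(c.key)


def check_population_contexts(
    trials: Iterable[DichotomousTrial],
    stream_counts: Iterable[StreamBehaviorCount] = (),
) -> Mapping[str, Context]:
    """Verify each population maps to exactly one geographic context."""
    mapping: dict[str, Context] = {}
    for rec in list(trials) + list(stream_counts):
        prev = mapping.get(rec.population)
        if prev is None:
            mapping[rec.population] = rec.context
        elif prev is not rec.context:
            raise ConsistencyError(
                f"population {rec.population!r} appears with two contexts: "
                f"{prev.value} and {rec.context.value}"
            )
    return mapping


DICHOTOMOUS_COLUMNS = [
    "trial_id",
    "focal_id",
    "population",
    "context",
    "sex",
    "t_conspecific_s",
    "t_heterospecific_s",
    "trial_duration_s",
    "conspecific_side",
    "stimulus_con_length_mm",
    "stimulus_het_length_mm",
]
_DICHOTOMOUS_REQUIRED = DICHOTOMOUS_COLUMNS[:8]

STREAM_COLUMNS = [
    "replicate_id",
    "population",
    "context",
    "species",
    "behavior",
    "target",
    "count",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return str(value)


def read_dichotomous(path) -> list[DichotomousTrial]:
    """Read and validate a dichotomous-trial CSV; row order is preserved."""
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={"trial_id": str, "focal_id": str, "population": str},
        float_precision="round_trip",
    )
    _require_columns(df, _DICHOTOMOUS_REQUIRED, path)
    trials: list[DichotomousTrial] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        trials.append(
            DichotomousTrial(
                trial_id=str(d["trial_id"]),
                focal_id=str(d["focal_id"]),
                population=str(d["population"]),
                context=str(d["context"]),
                sex=str(d["sex"]),
                t_conspecific=float(d["t_conspecific_s"]),
                t_heterospecific=float(d["t_heterospecific_s"]),
                trial_duration=float(d["trial_duration_s"]),
                conspecific_side=_opt_str(d.get("conspecific_side")),
                stimulus_con_length=_opt_float(d.get("stimulus_con_length_mm")),
                stimulus_het_length=_opt_float(d.get("stimulus_het_length_mm")),
            )
        )
    check_population_contexts(trials)
    return trials


def read_stream(path) -> list[StreamBehaviorCount]:
    """Read and validate a long-format stream behavior-count CSV."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"replicate_id": str, "population": str, "species": str})
    _require_columns(df, STREAM_COLUMNS, path)
    counts: list[StreamBehaviorCount] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        raw = d["count"]
        if isinstance(raw, float) and not float(raw).is_integer():
            raise ValidationError(
                f"replicate {d['replicate_id']!r}: count must be an integer, got {raw}"
            )
        counts.append(
            StreamBehaviorCount(
                replicate_id=str(d["replicate_id"]),
                population=str(d["population"]),
                context=str(d["context"]),
                species=str(d["species"]),
                behavior=str(d["behavior"]),
                target=str(d["target"]),
                count=int(raw),
            )
        )
    seen: set = set()
    for c in counts:
        if c.key in seen:
            raise ConsistencyError(f"duplicate stream-count key {c.key!r}")
        seen.add(c.key)
    check_population_contexts([], counts)
    return counts


def trials_to_frame(trials: Iterable[DichotomousTrial]) -> pd.DataFrame:
    rows = []
    for t in trials:
        rows.append(
            {
                "trial_id": t.trial_id,
                "focal_id": t.focal_id,
                "population": t.population,
                "context": t.context.value,
                "sex": t.sex.value,
                "t_conspecific_s": t.t_conspecific,
                "t_heterospecific_s": t.t_heterospecific,
                "trial_duration_s": t.trial_duration,
                "conspecific_side": t.conspecific_side.value if t.conspecific_side else None,
                "stimulus_con_length_mm": t.stimulus_con_length,
                "stimulus_het_length_mm": t.stimulus_het_length,
            }
        )
    return pd.DataFrame(rows, columns=DICHOTOMOUS_COLUMNS)


def stream_to_frame(counts: Iterable[StreamBehaviorCount]) -> pd.DataFrame:
    rows = []
    for c in counts:
        rows.append(
            {
                "replicate_id": c.replicate_id,
                "population": c.population,
                "context": c.context.value,
                "species": c.species,
                "behavior": c.behavior.value,
                "target": c.target.value,
                "count": c.count,
            }
        )
    return pd.DataFrame(rows, columns=STREAM_COLUMNS)


def write_dataset(dataset: Dataset, out_dir) -> dict[str, Path]:
    """Write the two CSVs plus a JSON provenance sidecar.

    Round-trip property: ``read_dataset(write_dataset(x))`` equals ``x``
    field-for-field, including optional fields.
    """
    dataset.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trials": out_dir / "dichotomous_trials.csv",
        "stream": out_dir / "stream_counts.csv",
        "provenance": out_dir / "provenance.json",
    }
    # %.17g guarantees float64 round-trip through text
    trials_to_frame(dataset.trials).to_csv(paths["trials"], index=False, float_format="%.17g")
    stream_to_frame(dataset.stream_counts).to_csv(paths["stream"], index=False)
    paths["provenance"].write_text(json.dumps(dataset.metadata, indent=2, sort_keys=True))
    return paths


def read_dataset(in_dir) -> Dataset:
    """Read a directory written by :func:`write_dataset`."""
    in_dir = Path(in_dir)
    trials = read_dichotomous(in_dir / "dichotomous_trials.csv")
    counts = read_stream(in_dir / "stream_counts.csv")
    prov_path = in_dir / "provenance.json"
    metadata = json.loads(prov_path.read_text()) if prov_path.exists() else {}
    ds = Dataset(trials=trials, stream_counts=counts, metadata=metadata)
    ds.validate()
    return ds
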