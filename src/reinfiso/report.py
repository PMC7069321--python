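"""End-to-end pipeline orchestration and report rendering.

``run_pipeline`` sequences the whole analysis — per-individual
preference statistics and their group summaries, the nested linear model
with backward selection and post hoc contrasts, pooled-context
nonparametric comparisons with effect sizes, the isolation-index tables,
and the heteroskedastic GLS on total isolation with a behavior-exclusion
sensitivity refit — and writes machine-readable (CSV/JSON) and
human-readable (markdown) outputs.  Given the same inputs and seed the
outputs are bit-identical: nothing time- or host-dependent is recorded.

All computation runs at full precision; rounding (half-even, default two
decimals) happens only when the markdown report is rendered.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .errors import ConfigError
from .inference import (
    SOP_FULL_TERMS,
    backward_select,
    cohens_d,
    fit_total_isolation_gls,
    lsmeans_contrasts,
    mann_whitney,
)
from .isolation import (
    behavior_isolation_table,
    exclude_behaviors_sensitivity,
    population_total_isolation,
)
from .sop import group_sop_summary, pool_group_means, sop_records
from .synthetic import RESIDENT_SPECIES, make_paper_like_dataset
from .trial_io import Behavior, Dataset, read_dichotomous, read_stream

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ReinforcementReport", "run_pipeline", "render_table3_style"]


class PipelineConfig(BaseModel):
    """Configuration for one pipeline run.

    Exactly one data source per kind: either both CSV paths, or a
    simulation seed (which generates the study-condition dataset).
    """

    trials_csv: Optional[Path] = None
    stream_csv: Optional[Path] = None
    simulate_seed: Optional[int] = None
    out_dir: Optional[Path] = None
    sop_test: str = Field(default="t_one_sample")
    drop_behaviors: list[str] = Field(
        default_factory=lambda: ["solicit_success", "solicit_fail"]
    )
    variance_by: str = "context"
    resident_species: Optional[str] = None
    alpha: float = 0.05
    rounding: int = 2

    @model_validator(mode="after")
    def _one_source(self):
        files = self.trials_csv is not None and self.stream_csv is not None
        partial = (self.trials_csv is None) != (self.stream_csv is None)
        if partial:
            raise ValueError("provide both trials_csv and stream_csv, or neither")
        if files == (self.simulate_seed is not None):
            raise ValueError(
                "exactly one data source required: CSV paths or simulate_seed"
            )
        return self

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        try:
            return cls.model_validate_json(Path(path).read_text())
        except Exception as exc:  # pydantic error -> package error
            raise ConfigError(f"invalid pipeline config {path}: {exc}") from exc


@dataclass
class ReinforcementReport:
    """All pipeline outputs, each traceable to one operation."""

    sop_summary: pd.DataFrame
    pooled_sop: pd.DataFrame
    anova: pd.DataFrame
    final_terms: list[str]
    contrasts_context: pd.DataFrame
    contrasts_population_sex: pd.DataFrame
    sex_specific: pd.DataFrame  # pooled-context Mann-Whitney + Cohen's d per sex
    isolation_behavior: pd.DataFrame
    isolation_population_total: pd.DataFrame
    gls_full: dict
    gls_reduced: dict
    table3_markdown: str
    provenance: dict
    markdown: str = ""

    def write(self, out_dir) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        tables = {
            "sop_summary": self.sop_summary,
            "pooled_sop": self.pooled_sop,
            "anova": self.anova,
            "contrasts_context": self.contrasts_context,
            "contrasts_population_sex": self.contrasts_population_sex,
            "sex_specific": self.sex_specific,
            "isolation_behavior": self.isolation_behavior,
            "isolation_population_total": self.isolation_population_total,
        }
        for name, table in tables.items():
            p = out_dir / f"{name}.csv"
            table.to_csv(p, index=False)
            paths[name] = p
        blob = {
            "final_terms": self.final_terms,
            "gls_full": self.gls_full,
            "gls_reduced": self.gls_reduced,
            "provenance": self.provenance,
        }
        paths["report_json"] = out_dir / "report.json"
        paths["report_json"].write_text(json.dumps(blob, indent=2, sort_keys=True))
        paths["report_md"] = out_dir / "report.md"
        paths["report_md"].write_text(self.markdown)
        return paths


def _summaries_frame(summaries) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = dict(s.group)
        row.update(
            n=s.n, mean=s.mean, se=s.se, test=s.test_name, statistic=s.statistic,
            df=s.df, p_value=s.p_value, degenerate=s.degenerate,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _estimates_frame(estimates) -> pd.DataFrame:
    rows = []
    for e in estimates:
        rows.append(
            {
                "scope": e.scope,
                "population": e.population,
                "context": e.context.value,
                "species": e.species,
                "behavior": e.behavior.value if e.behavior else None,
                "replicate_id": e.replicate_id,
                "conspecific_mean": e.conspecific_mean,
                "conspecific_sd": e.conspecific_sd,
                "heterospecific_mean": e.heterospecific_mean,
                "heterospecific_sd": e.heterospecific_sd,
                "I": e.i_index,
                "n_replicates": e.n_replicates,
            }
        )
    return pd.DataFrame(rows)


def _gls_to_dict(fit) -> dict:
    return {
        "coefficients": {
            k: {"estimate": c.estimate, "se": c.se, "t": c.t_statistic, "p": c.p_value}
            for k, c in fit.coefficients.items()
        },
        "variance_groups": fit.variance_groups,
        "log_likelihood": fit.log_likelihood,
        "n_obs": fit.n_obs,
        "residual_df": fit.residual_df,
        "n_iter": fit.n_iter,
    }


def _fmt(x, nd: int) -> str:
    if x is None or (isinstance(x, float) and x != x):
        return "–"
    return f"{round(float(x), nd):.{nd}f}"


def render_table3_style(estimates, rounding: int = 2) -> str:
    """Markdown table of per-behavior isolation: one row per population x
    species, one column group per behavior with 'mean ± SD' for each
    target and the index; missing indices render as an en dash."""
    df = _estimates_frame([e for e in estimates if e.scope == "behavior"])
    if df.empty:
        return "(no behavior-scope estimates)\n"
    behaviors = [b.value for b in Behavior if b.value in set(df["behavior"])]
    header = ["Context", "Pop.", "Species"]
    for b in behaviors:
        header += [f"{b} con", f"{b} het", f"{b} I"]
    lines = ["| " + " | ".join(header) + " |", "|" + "---|" * len(header)]
    keys = df[["context", "population", "species"]].drop_duplicates()
    for _, key in keys.iterrows():
        sub = df[
            (df["population"] == key["population"]) & (df["species"] == key["species"])
        ].set_index("behavior")
        cells = [key["context"], key["population"], key["species"]]
        for b in behaviors:
            if b not in sub.index:
                cells += ["–"] * 3
                continue
            r = sub.loc[b]
            con = f"{r['conspecific_mean']:.1f}"
            if r["conspecific_sd"] == r["conspecific_sd"] and r["conspecific_sd"] is not None:
                con += f" ± {r['conspecific_sd']:.1f}"
            het = f"{r['heterospecific_mean']:.1f}"
            if r["heterospecific_sd"] == r["heterospecific_sd"] and r["heterospecific_sd"] is not None:
                het += f" ± {r['heterospecific_sd']:.1f}"
            cells += [con, het, _fmt(r["I"], rounding)]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def _render_markdown(report: "ReinforcementReport", nd: int) -> str:
    out = ["# Reinforcement-signature report", ""]
    out.append("## Strength of preference by population x sex")
    out.append(report.sop_summary.round(nd).to_string(index=False))
    out.append("")
    out.append("## Pooled strength of preference by context x sex")
    out.append(report.pooled_sop.round(nd).to_string(index=False))
    out.append("")
    out.append("## Linear model (after backward selection)")
    out.append(f"Final terms: {', '.join(report.final_terms) or '(intercept only)'}")
    out.append(report.anova.round(4).to_string(index=False))
    out.append("")
    out.append("## Post hoc contrasts: context")
    out.append(report.contrasts_context.round(4).to_string(index=False))
    out.append("")
    out.append("## Sex-specific pooled-context comparisons")
    out.append(report.sex_specific.round(4).to_string(index=False))
    out.append("")
    out.append("## Per-behavior isolation indices")
    out.append(report.table3_markdown)
    out.append("## Total isolation GLS (full behavior set)")
    out.append(json.dumps(report.gls_full, indent=2, sort_keys=True))
    out.append("")
    out.append("## Total isolation GLS (sensitivity: behaviors dropped)")
    out.append(json.dumps(report.gls_reduced, indent=2, sort_keys=True))
    out.append("")
    out.append("## Provenance")
    out.append(json.dumps(report.provenance, indent=2, sort_keys=True))
    out.append("")
    return "\n".join(out)


def run_pipeline(config: PipelineConfig) -> ReinforcementReport:
    """Run the full analysis; deterministic given inputs plus seed.

    Outputs are assembled in memory and written only at the end, so a
    failing stage leaves no partial files behind.
    """
    if config.simulate_seed is not None:
        dataset = make_paper_like_dataset(config.simulate_seed)
        resident = config.resident_species or RESIDENT_SPECIES
        source = {"kind": "simulated", "seed": config.simulate_seed}
    else:
        trials = read_dichotomous(config.trials_csv)
        counts = read_stream(config.stream_csv)
        dataset = Dataset(trials=trials, stream_counts=counts)
        dataset.validate()
        resident = config.resident_species
        source = {
            "kind": "files",
            "trials_csv": str(config.trials_csv),
            "stream_csv": str(config.stream_csv),
        }
    logger.info("loaded %d trials, %d stream-count rows",
                len(dataset.trials), len(dataset.stream_counts))

    # --- preference statistics -------------------------------------------
    records = sop_records(dataset.trials)
    summaries = group_sop_summary(records, ("context", "population", "sex"), config.sop_test)
    sop_summary = _summaries_frame(summaries)

    pooled_rows = []
    for (context, sex), sub in sop_summary.groupby(["context", "sex"]):
        pooled_rows.append(
            {
                "context": context,
                "sex": sex,
                "n": int(sub["n"].sum()),
                "mean": pool_group_means(sub["mean"].tolist(), sub["n"].tolist()),
            }
        )
    pooled_sop = pd.DataFrame(pooled_rows)

    # --- linear model, contrasts, sex-specific post hocs ------------------
    final_terms, _trace, fit = backward_select(records, SOP_FULL_TERMS, alpha=config.alpha)
    contrasts_ctx = lsmeans_contrasts(fit, "context") if any(
        "context" in t.effective_factors(fit.nesting) for t in fit.terms
    ) else None
    contrasts_ps = lsmeans_contrasts(fit, ("population", "sex")) if any(
        t.name == "population:sex" for t in fit.terms
    ) else None

    sex_rows = []
    rec_df = pd.DataFrame(
        {
            "context": [r.context.value for r in records],
            "sex": [r.sex.value for r in records],
            "sop": [r.sop for r in records],
        }
    ).dropna(subset=["sop"])
    for sex, sub in rec_df.groupby("sex"):
        sym = sub.loc[sub["context"] == "sympatric", "sop"].to_numpy()
        allo = sub.loc[sub["context"] == "allopatric", "sop"].to_numpy()
        if sym.size == 0 or allo.size == 0:
            continue
        mw = mann_whitney(sym, allo)
        d = cohens_d(sym, allo)
        sex_rows.append(
            {
                "sex": sex, "n_sympatric": sym.size, "n_allopatric": allo.size,
                "U": mw.u, "Z": mw.z, "p_value": mw.p_value, "cohens_d": d.d,
            }
        )
    sex_specific = pd.DataFrame(sex_rows)

    # --- isolation indices ------------------------------------------------
    behavior_table = behavior_isolation_table(dataset.stream_counts)
    pop_totals = population_total_isolation(dataset.stream_counts)
    full_reps, reduced_reps = exclude_behaviors_sensitivity(
        dataset.stream_counts, [Behavior(b) for b in config.drop_behaviors]
    )
    gls_full = fit_total_isolation_gls(
        full_reps, fixed=("context",), variance_by=config.variance_by,
        resident_species=resident,
    )
    gls_reduced = fit_total_isolation_gls(
        reduced_reps, fixed=("context",), variance_by=config.variance_by,
        resident_species=resident,
    )

    provenance = {
        "package": "reinfiso",
        "version": __version__,
        "source": source,
        "sop_test": config.sop_test,
        "drop_behaviors": sorted(config.drop_behaviors),
        "variance_by": config.variance_by,
        "resident_species": resident,
        "alpha": config.alpha,
        "dataset_metadata": dataset.metadata,
        "n_trials": len(dataset.trials),
        "n_stream_rows": len(dataset.stream_counts),
    }

    report = ReinforcementReport(
        sop_summary=sop_summary,
        pooled_sop=pooled_sop,
        anova=fit.anova.to_frame(),
        final_terms=[t.name for t in final_terms],
        contrasts_context=(
            contrasts_ctx.to_frame() if contrasts_ctx is not None else pd.DataFrame()
        ),
        contrasts_population_sex=(
            contrasts_ps.to_frame() if contrasts_ps is not None else pd.DataFrame()
        ),
        sex_specific=sex_specific,
        isolation_behavior=_estimates_frame(behavior_table),
        isolation_population_total=_estimates_frame(pop_totals),
        gls_full=_gls_to_dict(gls_full),
        gls_reduced=_gls_to_dict(gls_reduced),
        table3_markdown=render_table3_style(behavior_table, config.rounding),
        provenance=provenance,
    )
    report.markdown = _render_markdown(report, config.rounding)
    if config.out_dir is not None:
        report.write(config.out_dir)
    return report
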