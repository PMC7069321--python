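"""Statistical machinery for the reinforcement-signature analysis.

The pieces mirror how the mate-choice data are analysed in practice:

* a general linear model for the per-individual preference statistic
  with population nested within geographic context, term-wise F tests
  from Type III (marginal) sums of squares under sum-to-zero contrasts,
  and backward elimination that honours marginality;
* model-based (least-squares) cell means with Bonferroni-adjusted
  pairwise contrasts on the residual degrees of freedom;
* a generalized least squares fit of total isolation allowing a separate
  residual variance per group (default: per geographic context), fitted
  by iterated weighted least squares;
* nonparametric two-sample (Mann-Whitney U) and one-sample/paired
  (Wilcoxon signed-rank) tests with tie and continuity corrections and
  exact small-sample enumeration; the classic one-sample t; Cohen's d.

Degenerate inputs (constant response, all-zero differences, zero pooled
variance) return results flagged ``degenerate`` rather than silent NaNs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, FitError, SchemaError

__all__ = [
    "ModelTerm",
    "main_effect",
    "nested",
    "interaction",
    "SOP_FULL_TERMS",
    "AnovaRow",
    "AnovaTable",
    "LinearFit",
    "fit_linear_model",
    "fit_sop_model",
    "backward_select",
    "ContrastRow",
    "ContrastTable",
    "lsmeans_contrasts",
    "GlsCoef",
    "GlsFit",
    "fit_gls_heteroskedastic",
    "fit_total_isolation_gls",
    "MannWhitneyResult",
    "mann_whitney",
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "TTestResult",
    "one_sample_t",
    "CohensD",
    "cohens_d",
]

_EPS = 1e-12


# --------------------------------------------------------------------------
# model terms and design matrices
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelTerm:
    """One term of a linear model.

    ``kind`` is ``main``, ``nested_main`` (factors = (inner, outer)) or
    ``interaction``.  In interactions a factor that is nested expands to
    its full between-level contrast space, so e.g. population x sex
    spans context x sex as well (3 df with four populations in two
    contexts).
    """

    name: str
    kind: str
    factors: tuple[str, ...]

    def effective_factors(self, nesting: Mapping[str, str]) -> frozenset[str]:
        out: set[str] = set()
        for f in self.factors:
            out.add(f)
            if f in nesting:
                out.add(nesting[f])
        return frozenset(out)


def main_effect(factor: str) -> ModelTerm:
    return ModelTerm(factor, "main", (factor,))


def nested(inner: str, outer: str) -> ModelTerm:
    return ModelTerm(f"{inner}({outer})", "nested_main", (inner, outer))


def interaction(*factors: str) -> ModelTerm:
    return ModelTerm(":".join(factors), "interaction", tuple(factors))


#: Full model for the dichotomous-trial preference analysis: context,
#: sex, population nested within context, and the population x sex
#: interaction (which, with nesting, spans context x sex).
SOP_FULL_TERMS: tuple[ModelTerm, ...] = (
    main_effect("context"),
    main_effect("sex"),
    nested("population", "context"),
    interaction("population", "sex"),
)

DEFAULT_NESTING: Mapping[str, str] = {"population": "context"}


class _Design:
    """Sum-to-zero encoder for a fixed set of factors, reusable on new
    data frames (e.g. a reference grid for LS-means)."""

    def __init__(self, df: pd.DataFrame, factors: Sequence[str], nesting: Mapping[str, str]):
        self.nesting = dict(nesting)
        self.levels: dict[str, list] = {}
        for f in factors:
            if f not in df.columns:
                raise SchemaError(f"factor {f!r} not found in the data")
            self.levels[f] = sorted(df[f].astype(str).unique())
        # observed inner levels per outer level, for nested factors
        self.nested_levels: dict[str, dict[str, list]] = {}
        for inner, outer in self.nesting.items():
            if inner in self.levels and outer in df.columns:
                m: dict[str, list] = {}
                for o, sub in df.groupby(df[outer].astype(str)):
                    m[str(o)] = sorted(sub[inner].astype(str).unique())
                self.nested_levels[inner] = m

    def _sum_code(self, values: pd.Series, factor: str) -> np.ndarray:
        levels = self.levels[factor]
        v = values.astype(str).to_numpy()
        cols = []
        for lev in levels[:-1]:
            c = np.where(v == lev, 1.0, 0.0) - np.where(v == levels[-1], 1.0, 0.0)
            cols.append(c)
        return np.column_stack(cols) if cols else np.empty((len(v), 0))

    def _nested_code(self, df: pd.DataFrame, inner: str, outer: str) -> np.ndarray:
        v_in = df[inner].astype(str).to_numpy()
        v_out = df[outer].astype(str).to_numpy()
        cols = []
        for o in self.levels[outer]:
            inner_levels = self.nested_levels.get(inner, {}).get(o, [])
            mask = v_out == o
            for lev in inner_levels[:-1]:
                c = np.where(mask & (v_in == lev), 1.0, 0.0) - np.where(
                    mask & (v_in == inner_levels[-1]), 1.0, 0.0
                )
                cols.append(c)
        return np.column_stack(cols) if cols else np.empty((len(df), 0))

    def _factor_blocks(self, df: pd.DataFrame, factor: str) -> np.ndarray:
        """Full between-level contrast space for one factor; a nested
        factor contributes its outer factor's contrasts plus the
        within-outer contrasts."""
        if factor in self.nesting:
            outer = self.nesting[factor]
            return np.column_stack(
                [self._sum_code(df[outer], outer), self._nested_code(df, factor, outer)]
            )
        return self._sum_code(df[factor], factor)

    def term_columns(self, df: pd.DataFrame, term: ModelTerm) -> np.ndarray:
        if term.kind == "main":
            return self._sum_code(df[term.factors[0]], term.factors[0])
        if term.kind == "nested_main":
            inner, outer = term.factors
            return self._nested_code(df, inner, outer)
        if term.kind == "interaction":
            blocks = [self._factor_blocks(df, f) for f in term.factors]
            cols = blocks[0]
            for b in blocks[1:]:
                cols = np.column_stack(
                    [cols[:, i] * b[:, j] for i in range(cols.shape[1]) for j in range(b.shape[1])]
                ) if cols.shape[1] and b.shape[1] else np.empty((len(df), 0))
            return cols
        raise SchemaError(f"unknown term kind {term.kind!r}")

    def build(self, df: pd.DataFrame, terms: Sequence[ModelTerm]):
        X_parts = [np.ones((len(df), 1))]
        slices: dict[str, slice] = {}
        start = 1
        for t in terms:
            cols = self.term_columns(df, t)
            slices[t.name] = slice(start, start + cols.shape[1])
            start += cols.shape[1]
            X_parts.append(cols)
        return np.column_stack(X_parts), slices


def _factors_of(terms: Iterable[ModelTerm], nesting: Mapping[str, str]) -> list[str]:
    out: list[str] = []
    for t in terms:
        for f in t.effective_factors(nesting):
            if f not in out:
                out.append(f)
    return sorted(out)


# --------------------------------------------------------------------------
# linear model with term-wise F tests
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AnovaRow:
    term: str
    df: int
    ss: float
    f_value: float
    p_value: float
    degenerate: bool = False


@dataclass
class AnovaTable:
    rows: list[AnovaRow]
    residual_df: int
    residual_ss: float
    n_obs: int

    def row(self, term: str) -> AnovaRow:
        for r in self.rows:
            if r.term == term:
                return r
        raise KeyError(term)

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {"term": r.term, "df": r.df, "F": r.f_value, "p": r.p_value} for r in self.rows
        ]
        recs.append(
            {"term": "Residual", "df": self.residual_df, "F": np.nan, "p": np.nan}
        )
        return pd.DataFrame(recs)


@dataclass
class LinearFit:
    """Fitted least-squares model plus everything LS-means needs."""

    terms: tuple[ModelTerm, ...]
    nesting: Mapping[str, str]
    design: _Design
    data: pd.DataFrame
    response: str
    X: np.ndarray
    y: np.ndarray
    beta: np.ndarray
    term_slices: dict[str, slice]
    residual_df: int
    residual_ss: float
    anova: AnovaTable

    @property
    def sigma2(self) -> float:
        return self.residual_ss / self.residual_df if self.residual_df > 0 else float("nan")

    @property
    def cov_beta(self) -> np.ndarray:
        return self.sigma2 * np.linalg.pinv(self.X.T @ self.X)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _records_to_frame(records, response: str) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    rows = []
    for r in records:
        rows.append(
            {
                "population": r.population,
                "context": getattr(r.context, "value", r.context),
                "sex": getattr(r.sex, "value", r.sex),
                response: r.sop,
            }
        )
    return pd.DataFrame(rows)


def fit_linear_model(
    data,
    terms: Sequence[ModelTerm],
    response: str = "sop",
    nesting: Mapping[str, str] = DEFAULT_NESTING,
    ss_type: str = "III",
) -> LinearFit:
    """Least-squares fit with term-wise F tests.

    Type III (marginal) sums of squares under sum-to-zero contrasts by
    default — appropriate for the unbalanced design — with sequential
    (Type I) available via ``ss_type='I'``.
    """
    if ss_type not in ("I", "III"):
        raise DomainError("ss_type must be 'I' or 'III'")
    df = _records_to_frame(data, response)
    df = df.dropna(subset=[response]).reset_index(drop=True)
    if len(df) == 0:
        raise FitError("no non-missing response values to fit")
    factors = _factors_of(terms, nesting)
    design = _Design(df, factors, nesting)
    X, slices = design.build(df, terms)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        aliased = _find_aliased(X, slices)
        raise FitError(
            "rank-deficient design; aliased term(s): " + ", ".join(aliased or ["<intercept>"])
        )
    y = df[response].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss_full = float(resid @ resid)
    df_resid = n - p
    if df_resid <= 0:
        raise FitError(f"no residual degrees of freedom (n={n}, parameters={p})")
    ms_resid = rss_full / df_resid
    rows: list[AnovaRow] = []
    if ss_type == "III":
        for t in terms:
            keep = [i for i in range(p) if not (slices[t.name].start <= i < slices[t.name].stop)]
            ss = _rss(X[:, keep], y) - rss_full
            rows.append(_anova_row(t.name, slices[t.name], ss, ms_resid, df_resid))
    else:
        prev_cols = [0]
        prev_rss = _rss(X[:, prev_cols], y)
        for t in terms:
            prev_cols = prev_cols + list(range(slices[t.name].start, slices[t.name].stop))
            new_rss = _rss(X[:, prev_cols], y)
            rows.append(_anova_row(t.name, slices[t.name], prev_rss - new_rss, ms_resid, df_resid))
            prev_rss = new_rss
    anova = AnovaTable(rows=rows, residual_df=df_resid, residual_ss=rss_full, n_obs=n)
    return LinearFit(
        terms=tuple(terms), nesting=dict(nesting), design=design, data=df,
        response=response, X=X, y=y, beta=beta, term_slices=slices,
        residual_df=df_resid, residual_ss=rss_full, anova=anova,
    )


def _anova_row(name: str, sl: slice, ss: float, ms_resid: float, df_resid: int) -> AnovaRow:
    df_term = sl.stop - sl.start
    ss = max(ss, 0.0)
    if ms_resid < _EPS:
        # constant (or perfectly fitted) response: no variance to test
        return AnovaRow(name, df_term, ss, 0.0, 1.0, degenerate=True)
    f = (ss / df_term) / ms_resid if df_term > 0 else 0.0
    p = float(stats.f.sf(f, df_term, df_resid)) if df_term > 0 else 1.0
    return AnovaRow(name, df_term, ss, f, p)


def _find_aliased(X: np.ndarray, slices: dict[str, slice]) -> list[str]:
    aliased = []
    cols = [0]
    rank = 1
    for name, sl in slices.items():
        cols.extend(range(sl.start, sl.stop))
        new_rank = np.linalg.matrix_rank(X[:, cols])
        if new_rank - rank < sl.stop - sl.start:
            aliased.append(name)
        rank = new_rank
    return aliased


def fit_sop_model(
    records,
    terms: Sequence[ModelTerm] = SOP_FULL_TERMS,
    nesting: Mapping[str, str] = DEFAULT_NESTING,
    ss_type: str = "III",
) -> LinearFit:
    """Fit the preference statistic on the nested design (see
    :data:`SOP_FULL_TERMS`); accepts SOP records or a data frame."""
    return fit_linear_model(records, terms, response="sop", nesting=nesting, ss_type=ss_type)


# --------------------------------------------------------------------------
# backward selection
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionStep:
    anova: AnovaTable
    dropped: str | None


def backward_select(
    records,
    full_terms: Sequence[ModelTerm] = SOP_FULL_TERMS,
    alpha: float = 0.05,
    response: str = "sop",
    nesting: Mapping[str, str] = DEFAULT_NESTING,
    ss_type: str = "III",
) -> tuple[tuple[ModelTerm, ...], list[SelectionStep], LinearFit]:
    """Sequentially remove nonsignificant terms from the full model.

    Each step drops the single eligible term with the largest p > alpha;
    a term is eligible only if no retained term's effective factor set
    strictly contains its own (marginality: a retained interaction
    protects its main effects, and a retained nested term protects its
    outer factor).  Returns the final term set, the per-step trace, and
    the final fit.
    """
    terms = list(full_terms)
    trace: list[SelectionStep] = []
    while True:
        fit = fit_linear_model(records, terms, response=response, nesting=nesting, ss_type=ss_type)
        eligible = []
        for t in terms:
            eff = t.effective_factors(nesting)
            protected = any(
                o is not t and eff < o.effective_factors(nesting) for o in terms
            )
            if not protected:
                eligible.append(t)
        candidates = [
            t for t in eligible if fit.anova.row(t.name).p_value > alpha
        ]
        if not candidates:
            trace.append(SelectionStep(fit.anova, None))
            return tuple(terms), trace, fit
        worst = max(candidates, key=lambda t: fit.anova.row(t.name).p_value)
        trace.append(SelectionStep(fit.anova, worst.name))
        terms = [t for t in terms if t is not worst]
        if not terms:
            final = fit_linear_model(
                records, terms, response=response, nesting=nesting, ss_type=ss_type
            )
            trace.append(SelectionStep(final.anova, None))
            return tuple(), trace, final


# --------------------------------------------------------------------------
# least-squares means and contrasts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ContrastRow:
    pair: tuple[str, str]
    estimate: float | None
    se: float | None
    t_statistic: float | None
    df: int
    p_raw: float | None
    p_adjusted: float | None
    inestimable: bool = False


@dataclass
class ContrastTable:
    factor: tuple[str, ...]
    lsmeans: dict[str, float]
    rows: list[ContrastRow]
    family_size: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "pair": " - ".join(r.pair), "estimate": r.estimate, "se": r.se,
                    "t": r.t_statistic, "df": r.df, "p_raw": r.p_raw,
                    "p_adjusted": r.p_adjusted,
                }
                for r in self.rows
            ]
        )


def _reference_grid(fit: LinearFit) -> pd.DataFrame:
    """All estimable factor-level combinations, honouring nesting (only
    observed inner-within-outer pairs enter the grid)."""
    factors = _factors_of(fit.terms, fit.nesting)
    atoms: list[tuple[tuple[str, ...], list[tuple]]] = []
    consumed: set[str] = set()
    for inner, outer in fit.nesting.items():
        if inner in factors and outer in factors:
            pairs = sorted(
                set(zip(fit.data[inner].astype(str), fit.data[outer].astype(str)))
            )
            atoms.append(((inner, outer), pairs))
            consumed.update((inner, outer))
    for f in factors:
        if f not in consumed:
            atoms.append(((f,), [(lev,) for lev in fit.design.levels[f]]))
    rows = []
    for combo in itertools.product(*(vals for _, vals in atoms)):
        row: dict[str, str] = {}
        for (names, _), values in zip(atoms, combo):
            row.update(dict(zip(names, values)))
        rows.append(row)
    return pd.DataFrame(rows)


def lsmeans_contrasts(
    fit: LinearFit,
    factor: str | Sequence[str],
    adjust: str = "bonferroni",
) -> ContrastTable:
    """Model-based cell means for ``factor`` (a name or a pair of names),
    averaged over the other factors with equal weights, and all pairwise
    contrasts with t statistics on the residual df.

    Bonferroni multiplies each raw p by the number of contrasts emitted
    in this call (capped at 1).
    """
    if adjust not in ("bonferroni", "none"):
        raise DomainError("adjust must be 'bonferroni' or 'none'")
    target = (factor,) if isinstance(factor, str) else tuple(factor)
    model_factors = _factors_of(fit.terms, fit.nesting)
    for f in target:
        if f not in model_factors:
            raise SchemaError(f"factor {f!r} is not in the fitted model")
    grid = _reference_grid(fit)
    Xg, _ = fit.design.build(grid, fit.terms)
    cov = fit.cov_beta
    labels = grid[list(target)].astype(str).agg(":".join, axis=1)
    level_rows: dict[str, np.ndarray] = {}
    for lev in sorted(labels.unique()):
        mask = (labels == lev).to_numpy()
        level_rows[lev] = Xg[mask].mean(axis=0)
    # observed cells only; a requested level with no data is inestimable
    observed = set(
        fit.data[list(target)].astype(str).agg(":".join, axis=1).unique()
    )
    lsmeans = {lev: float(row @ fit.beta) for lev, row in level_rows.items()}
    pairs = list(itertools.combinations(sorted(level_rows), 2))
    m = len(pairs)
    rows: list[ContrastRow] = []
    for a, b in pairs:
        if a not in observed or b not in observed:
            rows.append(ContrastRow((a, b), None, None, None, fit.residual_df, None, None, True))
            continue
        L = level_rows[a] - level_rows[b]
        est = float(L @ fit.beta)
        var = float(L @ cov @ L)
        if var <= 0:
            rows.append(ContrastRow((a, b), est, 0.0, None, fit.residual_df, None, None, True))
            continue
        se = math.sqrt(var)
        t = est / se
        p_raw = float(2.0 * stats.t.sf(abs(t), fit.residual_df))
        p_adj = min(1.0, m * p_raw) if adjust == "bonferroni" else p_raw
        rows.append(ContrastRow((a, b), est, se, t, fit.residual_df, p_raw, p_adj))
    return ContrastTable(factor=target, lsmeans=lsmeans, rows=rows, family_size=m)


# --------------------------------------------------------------------------
# heteroskedastic GLS
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GlsCoef:
    estimate: float
    se: float
    t_statistic: float
    p_value: float


@dataclass
class GlsFit:
    coefficients: dict[str, GlsCoef]
    variance_groups: dict[str, float]
    log_likelihood: float
    n_obs: int
    residual_df: int
    n_iter: int
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"term": k, "estimate": c.estimate, "se": c.se, "t": c.t_statistic,
                 "p": c.p_value}
                for k, c in self.coefficients.items()
            ]
        )


def _dummy_design(df: pd.DataFrame, fixed: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design: intercept plus indicator columns for all
    non-reference levels; ':' in a name denotes an interaction."""
    names = ["Intercept"]
    cols = [np.ones(len(df))]
    factor_cols: dict[str, list[tuple[str, np.ndarray]]] = {}
    for spec in fixed:
        parts = spec.split(":")
        for f in parts:
            if f not in df.columns:
                raise SchemaError(f"fixed factor {f!r} not found in the data")
            if f not in factor_cols:
                levels = sorted(df[f].astype(str).unique())
                v = df[f].astype(str).to_numpy()
                factor_cols[f] = [
                    (f"{f}[{lev}]", (v == lev).astype(float)) for lev in levels[1:]
                ]
        if len(parts) == 1:
            for nm, c in factor_cols[parts[0]]:
                names.append(nm)
                cols.append(c)
        else:
            blocks = [factor_cols[f] for f in parts]
            for combo in itertools.product(*blocks):
                nm = ":".join(nc[0] for nc in combo)
                c = np.prod(np.column_stack([nc[1] for nc in combo]), axis=1)
                names.append(nm)
                cols.append(c)
    return np.column_stack(cols), names


def fit_gls_heteroskedastic(
    df: pd.DataFrame,
    response: str,
    fixed: Sequence[str],
    variance_by: str,
    replicate_col: str | None = None,
    replicate_correlation: float | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> GlsFit:
    """GLS with a separate residual variance per level of ``variance_by``,
    fitted by iterated weighted least squares.

    Group variances use degrees-of-freedom-corrected residual sums of
    squares (each group's squared residuals divided by its observation
    count minus its summed leverage), so the saturated two-group model
    reproduces the Welch-style closed form exactly.  An optional
    exchangeable within-replicate correlation can be supplied (fixed,
    not estimated); the default model omits it.
    """
    df = df.dropna(subset=[response]).reset_index(drop=True)
    n = len(df)
    if variance_by not in df.columns:
        raise SchemaError(f"variance grouping {variance_by!r} not found in the data")
    groups = df[variance_by].astype(str).to_numpy()
    group_levels = sorted(set(groups))
    for g in group_levels:
        if int(np.sum(groups == g)) < 2:
            raise FitError(f"variance group {g!r} has fewer than 2 observations")
    X, names = _dummy_design(df, fixed)
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise FitError("rank-deficient fixed-effect design")
    if n - p <= 0:
        raise FitError(f"no residual degrees of freedom (n={n}, parameters={p})")
    y = df[response].to_numpy(dtype=float)

    if replicate_correlation is not None and replicate_col is None:
        raise DomainError("replicate_correlation requires replicate_col")
    rep = df[replicate_col].astype(str).to_numpy() if replicate_col else None

    var = {g: 1.0 for g in group_levels}
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sig = np.array([var[g] for g in groups])
        V = np.diag(sig)
        if replicate_correlation is not None:
            rho = float(replicate_correlation)
            same = (rep[:, None] == rep[None, :]) & ~np.eye(n, dtype=bool)
            V = V + same * rho * np.sqrt(np.outer(sig, sig))
        Vinv = np.linalg.inv(V)
        XtVi = X.T @ Vinv
        cov_unscaled = np.linalg.inv(XtVi @ X)
        beta = cov_unscaled @ (XtVi @ y)
        resid = y - X @ beta
        # leverage of each observation under the current weighting
        H_diag = np.einsum("ij,ji->i", X @ cov_unscaled, XtVi)
        new_var = {}
        for g in group_levels:
            mask = groups == g
            dof = float(np.sum(mask) - np.sum(H_diag[mask]))
            if dof <= 0:
                raise FitError(f"variance group {g!r} has no residual degrees of freedom")
            new_var[g] = float(np.sum(resid[mask] ** 2) / dof)
            if new_var[g] <= 0:
                new_var[g] = _EPS
        delta = max(
            abs(new_var[g] - var[g]) / max(var[g], _EPS) for g in group_levels
        )
        var = new_var
        if delta < tol:
            converged = True
            break
    if not converged:
        raise FitError(
            f"heteroskedastic GLS did not converge after {max_iter} iterations; "
            f"last relative change {delta:.3g}, variances {var}"
        )
    sig = np.array([var[g] for g in groups])
    V = np.diag(sig)
    if replicate_correlation is not None:
        same = (rep[:, None] == rep[None, :]) & ~np.eye(n, dtype=bool)
        V = V + same * float(replicate_correlation) * np.sqrt(np.outer(sig, sig))
    Vinv = np.linalg.inv(V)
    cov_beta = np.linalg.inv(X.T @ Vinv @ X)
    beta = cov_beta @ (X.T @ Vinv @ y)
    resid = y - X @ beta
    df_resid = n - p
    coefs = {}
    for j, nm in enumerate(names):
        se = math.sqrt(max(cov_beta[j, j], 0.0))
        t = beta[j] / se if se > 0 else float("inf")
        coefs[nm] = GlsCoef(float(beta[j]), se, float(t), float(2 * stats.t.sf(abs(t), df_resid)))
    sign, logdet = np.linalg.slogdet(V)
    ll = -0.5 * (n * math.log(2 * math.pi) + logdet + float(resid @ Vinv @ resid))
    return GlsFit(
        coefficients=coefs,
        variance_groups={g: float(v) for g, v in var.items()},
        log_likelihood=ll,
        n_obs=n,
        residual_df=df_resid,
        n_iter=it,
        converged=converged,
    )


def fit_total_isolation_gls(
    estimates,
    fixed: Sequence[str] = ("context",),
    variance_by: str = "context",
    resident_species: str | None = None,
    replicate_correlation: float | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> GlsFit:
    """Heteroskedastic GLS on per-replicate total isolation.

    ``estimates`` are replicate-scope isolation estimates.  If
    ``resident_species`` is given, every observation of that species is
    coded sympatric before fitting (the resident congener's range lies
    entirely within the focal species' range).
    """
    from .isolation import apply_resident_context

    ests = list(estimates)
    if resident_species is not None:
        ests = apply_resident_context(ests, resident_species)
    rows = []
    for e in ests:
        if e.scope != "replicate_total":
            raise DomainError(
                f"expected replicate_total estimates, got scope {e.scope!r}"
            )
        rows.append(
            {
                "replicate_id": e.replicate_id,
                "population": e.population,
                "context": getattr(e.context, "value", e.context),
                "species": e.species,
                "total_isolation": e.i_index,
            }
        )
    df = pd.DataFrame(rows)
    return fit_gls_heteroskedastic(
        df,
        response="total_isolation",
        fixed=fixed,
        variance_by=variance_by,
        replicate_col="replicate_id",
        replicate_correlation=replicate_correlation,
        max_iter=max_iter,
        tol=tol,
    )


# --------------------------------------------------------------------------
# nonparametric tests, t test, effect size
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    z: float | None
    p_value: float | None  # two-sided, normal approximation
    p_exact: float | None  # two-sided, enumeration (small n, no ties)
    degenerate: bool
    n1: int
    n2: int


def _tie_counts(values: np.ndarray) -> np.ndarray:
    _, counts = np.unique(values, return_counts=True)
    return counts[counts > 1]


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> MannWhitneyResult:
    """Mann-Whitney U with tie- and continuity-corrected normal Z.

    For combined n <= 20 with no ties an exact two-sided p from full
    enumeration of group labelings is also returned.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    N = n1 + n2
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(n1 * n2 / 2.0, None, None, None, True, n1, n2)
    # U for sample a: pairs where a beats b, halves for ties
    u = float(np.sum(a[:, None] > b[None, :]) + 0.5 * np.sum(a[:, None] == b[None, :]))
    mu = n1 * n2 / 2.0
    ties = _tie_counts(pooled)
    tie_term = float(np.sum(ties**3 - ties)) / (N * (N - 1)) if ties.size else 0.0
    sigma2 = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if sigma2 <= 0:
        return MannWhitneyResult(u, None, None, None, True, n1, n2)
    sigma = math.sqrt(sigma2)
    diff = u - mu
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    z = (diff - cc) / sigma if diff != 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    p = min(p, 1.0)
    p_exact = None
    if N <= 20 and ties.size == 0:
        ranks = stats.rankdata(pooled)
        r_all = np.arange(1, N + 1, dtype=float)
        u_obs = float(np.sum(ranks[:n1])) - n1 * (n1 + 1) / 2.0
        us = np.array(
            [sum(c) - n1 * (n1 + 1) / 2.0 for c in itertools.combinations(r_all, n1)]
        )
        lo = float(np.mean(us <= u_obs + 1e-9))
        hi = float(np.mean(us >= u_obs - 1e-9))
        p_exact = min(1.0, 2.0 * min(lo, hi))
    return MannWhitneyResult(u, float(z), p, p_exact, False, n1, n2)


@dataclass(frozen=True)
class WilcoxonResult:
    w: float
    z: float | None
    p_value: float | None  # two-sided, normal approximation
    p_exact: float | None  # two-sided, sign-pattern enumeration (n <= 12)
    degenerate: bool
    n_used: int  # nonzero differences


def wilcoxon_signed_rank(
    x: Sequence[float],
    mu0: float = 0.0,
    paired_with: Sequence[float] | None = None,
) -> WilcoxonResult:
    """Wilcoxon signed-rank test of ``x`` against ``mu0``, or paired
    against a second sample.  Zero differences are dropped (the Wilcoxon
    convention); ties among absolute differences are mid-ranked with the
    variance correction; Z uses a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise DomainError("sample must be non-empty")
    if paired_with is not None:
        y = np.asarray(paired_with, dtype=float)
        if y.shape != x.shape:
            raise DomainError("paired samples must have equal length")
        d = x - y
    else:
        d = x - mu0
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, None, None, None, True, 0)
    ranks = stats.rankdata(np.abs(d))
    w = float(np.sum(ranks[d > 0]))
    mu = n * (n + 1) / 4.0
    ties = _tie_counts(np.abs(d))
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - float(np.sum(ties**3 - ties)) / 48.0
    if sigma2 <= 0:
        return WilcoxonResult(w, None, None, None, True, n)
    diff = w - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(sigma2) if diff != 0 else 0.0
    p = min(1.0, float(2.0 * stats.norm.sf(abs(z))))
    p_exact = None
    if n <= 12:
        ws = []
        for signs in itertools.product((0.0, 1.0), repeat=n):
            ws.append(float(np.dot(signs, ranks)))
        ws = np.asarray(ws)
        lo = float(np.mean(ws <= w + 1e-9))
        hi = float(np.mean(ws >= w - 1e-9))
        p_exact = min(1.0, 2.0 * min(lo, hi))
    return WilcoxonResult(w, float(z), p, p_exact, False, n)


@dataclass(frozen=True)
class TTestResult:
    statistic: float | None
    df: int
    p_value: float | None
    degenerate: bool


def one_sample_t(x: Sequence[float], mu0: float = 0.0) -> TTestResult:
    """Two-sided one-sample t test: t = (mean - mu0) / (sd / sqrt(n))."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DomainError("one-sample t needs n >= 2")
    n = x.size
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        return TTestResult(None, n - 1, None, True)
    t = (float(np.mean(x)) - mu0) / (sd / math.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return TTestResult(t, n - 1, p, False)


@dataclass(frozen=True)
class CohensD:
    d: float | None
    degenerate: bool


def cohens_d(a: Sequence[float], b: Sequence[float]) -> CohensD:
    """Standardized mean difference with the pooled standard deviation:
    (mean_a - mean_b) / s_pooled, s_pooled^2 = ((n_a-1)s_a^2 +
    (n_b-1)s_b^2) / (n_a + n_b - 2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("Cohen's d needs n >= 2 in both samples")
    va, vb = float(np.var(a, ddof=1)), float(np.var(b, ddof=1))
    s2 = ((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2)
    if s2 == 0:
        return CohensD(None, True)
    return CohensD(float((np.mean(a) - np.mean(b)) / math.sqrt(s2)), False)
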