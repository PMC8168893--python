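"""Cohort association statistics.

The study design has repeated sessions per subject, so every session-level
association is assessed with a linear mixed model carrying a
subject-specific random intercept; effect sizes are reported as Spearman
correlations computed separately on covariate-adjusted values (rank
correlation is robust to the non-Gaussian marker distributions, e.g. MMSE).

Degrees of freedom for mixed-model fixed effects use a between–within
(containment) approximation: a predictor that varies within subjects is
tested against ``n_obs − n_subjects − (k − 1)`` degrees of freedom, a
purely between-subject predictor against ``n_subjects − k``, where k is
the number of fixed-effect columns. When every subject contributes one
session the random intercept is unidentifiable and the model reduces
exactly to ordinary least squares, which is what is fitted in that limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "AssociationResult",
    "longitudinal_change",
    "compute_suvr",
    "adjust_outcome",
    "association",
    "group_trend",
    "two_sample_t",
    "fisher_exact_2x2",
    "lagwise_association_profile",
    "subject_level_view",
    "run_full_analysis",
    "GROUP_SCORES",
]

GROUP_SCORES = {"HC": 0, "SMC": 1, "MCI": 2, "AD": 3}


@dataclass
class AssociationResult:
    """One (outcome, predictor) association with its adjustment set."""

    outcome: str
    predictor: str
    covariates: tuple[str, ...]
    spearman_rho: float
    lmm_p: float
    n_sessions: int
    n_subjects: int
    coefficient: float = np.nan
    notes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# elementary operations


def longitudinal_change(baseline, followup):
    """Follow-up minus baseline; a decline is negative. NaN propagates."""
    return np.asarray(followup, dtype=float) - np.asarray(baseline, dtype=float)


def compute_suvr(mean_uptake_gm: float, mean_uptake_reference: float) -> float:
    """Standardized uptake value ratio: gray-matter tracer uptake divided by
    the composite-reference-region uptake."""
    if mean_uptake_reference <= 0:
        raise ValueError("reference-region uptake must be positive")
    return mean_uptake_gm / mean_uptake_reference


def two_sample_t(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, int, float]:
    """Pooled-variance two-sample Student's t from summary statistics.

    Returns (t, df, two-sided p) with df = n1 + n2 − 2. The pooled (not
    Welch) form is the convention for the cohort-characteristics table.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(res.statistic), int(n1 + n2 - 2), float(res.pvalue)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2×2 table [[a, b], [c, d]].

    Convention: sum of hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed
    table's.
    """
    counts = [a, b, c, d]
    if any(int(x) != x or x < 0 for x in counts):
        raise ValueError("counts must be nonnegative integers")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("each margin must be positive")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# design-matrix plumbing


def _encode(table: pd.DataFrame, col: str) -> pd.DataFrame:
    """Numeric regressor columns for one table column."""
    s = table[col]
    if col == "gender" or (s.dtype == object and set(s.dropna().unique()) <= {"M", "F"}):
        return pd.DataFrame({col: (s == "F").astype(float)})
    if col == "group" and s.dtype == object:
        return pd.DataFrame({col: s.map(GROUP_SCORES).astype(float)})
    if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
        dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
        return dummies
    return pd.DataFrame({col: s.astype(float)})


def _design(table: pd.DataFrame, cols) -> pd.DataFrame:
    parts = [_encode(table, c) for c in cols]
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=table.index)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient design; check for collinear columns among {names}")


def _fit_model(y: np.ndarray, X: pd.DataFrame, groups: np.ndarray):
    """Fit OLS (all-singleton groups) or a random-intercept mixed model.

    Regressors are centered and scaled internally for numerical stability
    and the coefficients mapped back to the original scale, so callers see
    raw-scale parameters. Returns
    (params: Series, bse: Series, kind, n_groups, ols_fit_or_None).
    """
    Xc = sm.add_constant(X, has_constant="add")
    _check_rank(Xc.to_numpy(dtype=float), list(Xc.columns))
    _, counts = np.unique(groups, return_counts=True)
    if counts.max() == 1:
        fit = sm.OLS(y, Xc).fit()
        return fit.params, fit.bse, "ols", len(counts), fit
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0).replace(0.0, 1.0)
    Xs = sm.add_constant((X - center) / scale, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, Xs, groups=groups)
        fit = None
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                fit = model.fit(reml=True, method=method)
                break
            except np.linalg.LinAlgError:
                continue
        if fit is None:
            raise np.linalg.LinAlgError("mixed-model fit failed with every optimizer")
    params = fit.fe_params.copy()
    bse = fit.bse_fe.copy()
    params[X.columns] = params[X.columns] / scale
    bse[X.columns] = bse[X.columns] / scale
    params["const"] = params["const"] - (params[X.columns] * center).sum()
    return params, bse, "mixedlm", len(counts), None


def _within_subject_varying(series: pd.Series, groups: np.ndarray) -> bool:
    df = pd.DataFrame({"v": series.to_numpy(dtype=float), "g": groups})
    spread = df.groupby("g")["v"].transform(lambda s: s.max() - s.min())
    return bool((spread > 1e-12).any())


def _predictor_p(
    params, bse, kind, name, X: pd.DataFrame, groups: np.ndarray, n_obs: int, n_groups: int, ols_fit
) -> tuple[float, float]:
    """(coefficient, two-sided p) for one fixed effect."""
    coef = float(params[name])
    if kind == "ols":
        return coef, float(ols_fit.pvalues[name])
    se = float(bse[name])
    if se == 0 or not np.isfinite(se):
        return coef, np.nan
    k = X.shape[1] + 1  # fixed effects incl. intercept
    if _within_subject_varying(X[name], groups):
        df = n_obs - n_groups - (k - 1)
    else:
        df = n_groups - k
    df = max(df, 1)
    t = coef / se
    return coef, float(2 * sps.t.sf(abs(t), df))


def _complete_rows(table: pd.DataFrame, cols) -> pd.DataFrame:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    return table.dropna(subset=list(cols))


# ---------------------------------------------------------------------------
# covariate adjustment and associations


def adjust_outcome(
    table: pd.DataFrame, outcome: str, nuisance_covariates, group_col: str = "subject_id"
) -> pd.Series:
    """Outcome minus the fixed-effect contribution of the nuisance covariates.

    Fits ``outcome ~ covariates + (1 | subject)`` and subtracts only the
    covariate terms; the intercept (and the subject effects) are retained,
    so adjusted values stay on the outcome's scale. Rows with missing
    values come back as NaN.
    """
    nuisance_covariates = tuple(nuisance_covariates)
    sub = _complete_rows(table, (outcome, group_col) + nuisance_covariates)
    if sub[group_col].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    y = sub[outcome].to_numpy(dtype=float)
    if not nuisance_covariates:
        return table[outcome].astype(float)
    X = _design(sub, nuisance_covariates)
    params, _, _, _, _ = _fit_model(y, X, sub[group_col].to_numpy())
    contrib = X.to_numpy(dtype=float) @ params[X.columns].to_numpy(dtype=float)
    out = pd.Series(np.nan, index=table.index, name=f"{outcome}_adj")
    out.loc[sub.index] = y - contrib
    return out


def association(
    table: pd.DataFrame,
    outcome: str,
    predictor: str,
    nuisance_covariates=(),
    group_col: str = "subject_id",
) -> AssociationResult:
    """Covariate-adjusted association between an outcome and a predictor.

    The Spearman ρ is computed between the nuisance-adjusted outcome and
    the predictor; the p-value comes from the full mixed model
    ``outcome ~ predictor + nuisance + (1 | subject)`` (the two are
    deliberately separate statistics).
    """
    nuisance_covariates = tuple(nuisance_covariates)
    sub = _complete_rows(table, (outcome, predictor, group_col) + nuisance_covariates)
    pred_design = _design(sub, [predictor])
    if pred_design.shape[1] == 1 and np.ptp(pred_design.iloc[:, 0].to_numpy(dtype=float)) == 0:
        raise ValueError(f"predictor {predictor!r} is constant; correlation undefined")
    adjusted = adjust_outcome(sub, outcome, nuisance_covariates, group_col)
    pred_numeric = pred_design.iloc[:, 0] if pred_design.shape[1] == 1 else None
    if pred_numeric is not None:
        rho = float(sps.spearmanr(adjusted.loc[sub.index], pred_numeric)[0])
    else:
        rho = np.nan  # multi-column categorical predictor has no single rank correlation
    y = sub[outcome].to_numpy(dtype=float)
    X = pd.concat([pred_design, _design(sub, nuisance_covariates)], axis=1)
    groups = sub[group_col].to_numpy()
    params, bse, kind, n_groups, ols_fit = _fit_model(y, X, groups)
    name = pred_design.columns[0]
    coef, p = _predictor_p(params, bse, kind, name, X, groups, len(sub), n_groups, ols_fit)
    return AssociationResult(
        outcome=outcome,
        predictor=predictor,
        covariates=nuisance_covariates,
        spearman_rho=rho,
        lmm_p=p,
        n_sessions=len(sub),
        n_subjects=int(sub[group_col].nunique()),
        coefficient=coef,
        notes={"model": kind},
    )


def group_trend(
    table: pd.DataFrame,
    outcome: str,
    nuisance_covariates=(),
    group_col: str = "subject_id",
) -> AssociationResult:
    """Dose–response trend of the outcome over the ordered disease groups.

    The group enters the mixed model as its linear severity score
    (HC=0 < SMC=1 < MCI=2 < AD=3). Pairwise two-group contrasts are also
    fitted and reported in ``notes['pairwise_p']``.
    """
    sub = _complete_rows(table, (outcome, "group", group_col) + tuple(nuisance_covariates))
    present = [g for g in GROUP_SCORES if g in set(sub["group"])]
    if len(present) < 2:
        raise ValueError("need at least 2 diagnostic groups for a trend")
    res = association(sub, outcome, "group", nuisance_covariates, group_col)
    pairwise: dict[str, float] = {}
    for i, g1 in enumerate(present):
        for g2 in present[i + 1 :]:
            pair = sub[sub["group"].isin([g1, g2])].copy()
            if pair[group_col].nunique() < 2 or pair["group"].nunique() < 2:
                continue
            pair["_is_g2"] = (pair["group"] == g2).astype(float)
            try:
                r = association(pair, outcome, "_is_g2", nuisance_covariates, group_col)
                pairwise[f"{g2}_vs_{g1}"] = r.lmm_p
            except (ValueError, np.linalg.LinAlgError):
                continue
    res.predictor = "group_score"
    res.notes["pairwise_p"] = pairwise
    return res


def lagwise_association_profile(
    table: pd.DataFrame,
    marker: str,
    nuisance_covariates=(),
    lag_columns: dict[float, str] | None = None,
    group_col: str = "subject_id",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Marker association with the cross-correlation at every lag.

    ``lag_columns`` maps lag (seconds) to the table column holding that
    lag's per-session correlation; by default columns named
    ``ccf_lag_<seconds>`` are discovered. Returns a tidy frame with one
    row per lag (rho, p, significant flag).
    """
    if lag_columns is None:
        lag_columns = {}
        for c in table.columns:
            if c.startswith("ccf_lag_"):
                lag_columns[float(c.removeprefix("ccf_lag_"))] = c
    if not lag_columns:
        raise ValueError("no per-lag cross-correlation columns found")
    rows = []
    for lag in sorted(lag_columns):
        r = association(table, lag_columns[lag], marker, nuisance_covariates, group_col)
        rows.append(
            {
                "lag_seconds": lag,
                "spearman_rho": r.spearman_rho,
                "lmm_p": r.lmm_p,
                "significant": r.lmm_p < alpha,
                "n_sessions": r.n_sessions,
            }
        )
    return pd.DataFrame(rows)


def subject_level_view(table: pd.DataFrame, group_col: str = "subject_id") -> pd.DataFrame:
    """One (earliest) session per subject, for subject-based reanalysis.

    Downstream analyses on this view use simple regression — with one row
    per subject the random intercept is vacuous.
    """
    ordered = table.sort_values([group_col, "session_id"]) if "session_id" in table.columns else table
    return ordered.groupby(group_col, as_index=False, sort=False).head(1).reset_index(drop=True)


# ---------------------------------------------------------------------------
# the full battery


def _maybe(table: pd.DataFrame, col: str) -> bool:
    return col in table.columns and table[col].notna().any()


def run_full_analysis(
    table: pd.DataFrame,
    coupling_col: str = "coupling",
    base_covariates: tuple[str, ...] = ("age", "gender"),
) -> pd.DataFrame:
    """Run the full association battery on a cohort table.

    One row per (outcome, predictor, covariate-set) cell: coupling versus
    risk factors (age, gender, group trend, APOE), coupling versus the
    amyloid and cognition markers with the standard adjustment and with
    motion / batch / amplitude / arousal-index controls, amplitude versus
    markers, and the subject-level variant. Deterministic given the table.
    """
    required = [coupling_col, "subject_id", "session_id", "group", "age", "gender"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing required columns: {missing}")
    t = table.copy()
    if "d_suvr" not in t.columns and {"suvr_base", "suvr_fu"} <= set(t.columns):
        t["d_suvr"] = longitudinal_change(t["suvr_base"], t["suvr_fu"])
    if "d_mmse" not in t.columns and {"mmse_base", "mmse_fu"} <= set(t.columns):
        t["d_mmse"] = longitudinal_change(t["mmse_base"], t["mmse_fu"])

    rows: list[dict] = []

    def add(label: str, fn) -> None:
        # degenerate cells (constant covariate, collinear design in a tiny
        # or homogeneous cohort) are skipped rather than aborting the run
        try:
            res = fn()
        except (ValueError, np.linalg.LinAlgError):
            return
        rows.append(
            {
                "analysis": label,
                "outcome": res.outcome,
                "predictor": res.predictor,
                "covariates": ",".join(res.covariates),
                "spearman_rho": res.spearman_rho,
                "lmm_p": res.lmm_p,
                "coefficient": res.coefficient,
                "n_sessions": res.n_sessions,
                "n_subjects": res.n_subjects,
            }
        )

    # risk factors
    add("risk:age", lambda: association(t, coupling_col, "age"))
    add("risk:gender", lambda: association(t, coupling_col, "gender"))
    add("risk:age|group", lambda: association(t, coupling_col, "age", ("group",)))
    add("risk:gender|group", lambda: association(t, coupling_col, "gender", ("group",)))
    add("risk:group_trend", lambda: group_trend(t, coupling_col, base_covariates))
    if _maybe(t, "apoe_e4_count"):
        add("risk:apoe", lambda: association(t, coupling_col, "apoe_e4_count", base_covariates))

    # markers under the standard and control adjustments
    markers = [m for m in ("suvr_base", "d_suvr", "mmse_base", "d_mmse") if _maybe(t, m)]
    control_sets: list[tuple[str, tuple[str, ...]]] = [("base", base_covariates)]
    for extra in ("mean_fd", "batch", "amplitude", "arousal_index"):
        if _maybe(t, extra):
            control_sets.append((f"+{extra}", base_covariates + (extra,)))
    for marker in markers:
        for label, covs in control_sets:
            add(
                f"marker:{marker}|{label}",
                lambda marker=marker, covs=covs: association(t, coupling_col, marker, covs),
            )

    # arousal-state analyses
    if _maybe(t, "amplitude"):
        add(
            "state:coupling~amplitude",
            lambda: association(t, coupling_col, "amplitude", base_covariates),
        )
        for marker in markers:
            add(
                f"state:amplitude~{marker}",
                lambda marker=marker: association(t, "amplitude", marker, base_covariates),
            )

    # subject-level variant (simple regression)
    subj = subject_level_view(t)
    for marker in markers:
        add(
            f"subject:{marker}",
            lambda marker=marker: association(subj, coupling_col, marker, base_covariates),
        )

    out = pd.DataFrame(rows)
    out.attrs["n_tests"] = len(out)
    return out
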