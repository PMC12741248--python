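"""Evaluation statistics for aging indices and protein panels.

Per-SD hazard/rate/odds ratios (Cox, Poisson, proportional-odds),
Fine-Gray competing-risks regression, Kaplan-Meier curves with the
log-rank test, Harrell's concordance, landmark analyses with delayed
entry, a per-protein mortality screen with FDR control, cross-sectional
proteomic age clocks (PAC) with age acceleration (PAA), and the
multimorbidity / frailty phenotype codings.

Conventions: exposures are standardized so estimates are per SD;
confidence intervals are Wald on the log scale; Cox evaluation fits use
Efron tie handling (lifelines), while the per-protein screen, landmark
and Fine-Gray fits use the package's Breslow Newton solver (the two
coincide without ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy import stats
from sklearn.linear_model import ElasticNetCV
from statsmodels.genmod.families import Poisson
from statsmodels.genmod.generalized_linear_model import GLM
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.multitest import multipletests

from ._coxutils import newton_cox
from .data import CovariateTable, SurvivalTable

__all__ = [
    "AssociationResult",
    "cox_hazard_ratio",
    "fine_gray_hr",
    "kaplan_meier_logrank",
    "poisson_rate_ratio",
    "ordinal_odds_ratio",
    "concordance_index",
    "landmark_hazard_ratios",
    "protein_mortality_screen",
    "PacModel",
    "train_cross_sectional_pac",
    "compute_paa",
    "multimorbidity_index",
    "frailty_category",
    "MULTIMORBIDITY_WEIGHTS",
    "FRAILTY_LEVELS",
]


@dataclass
class AssociationResult:
    """Effect estimate per SD of exposure with Wald 95% CI."""

    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_events: int
    model_label: str
    covariates: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("confidence interval does not bracket estimate")
        if self.estimate <= 0:
            raise ValueError("ratio estimates must be positive")

    def to_row(self) -> dict:
        return {
            "model": self.model_label,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p_value,
            "n": self.n,
            "n_events": self.n_events,
            "covariates": "+".join(self.covariates),
        }


def _from_log_scale(log_est, se, n, n_events, label, covariates):
    z = log_est / se if se > 0 else np.inf * np.sign(log_est)
    p = 2.0 * stats.norm.sf(abs(z))
    half = 1.959963984540054 * se
    return AssociationResult(
        estimate=float(np.exp(log_est)),
        ci_low=float(np.exp(log_est - half)),
        ci_high=float(np.exp(log_est + half)),
        p_value=float(p),
        n=int(n),
        n_events=int(n_events),
        model_label=label,
        covariates=list(covariates),
    )


def _design(covariates: CovariateTable | pd.DataFrame | None, subjects,
            columns=None) -> pd.DataFrame:
    """Numeric design matrix from a covariate table (one-hot categoricals)."""
    if covariates is None:
        return pd.DataFrame(index=list(subjects))
    table = covariates.aligned(subjects) if isinstance(
        covariates, CovariateTable) else covariates.loc[list(subjects)].reset_index()
    if "subject_id" in table.columns:
        table = table.set_index("subject_id")
    if columns is not None:
        table = table[list(columns)]
    numeric = table.select_dtypes(include=[np.number])
    categorical = table.select_dtypes(exclude=[np.number])
    parts = [numeric]
    if not categorical.empty:
        parts.append(pd.get_dummies(categorical.astype(str), drop_first=True,
                                    dtype=float))
    out = pd.concat(parts, axis=1)
    out.index = list(subjects)
    return out.astype(float)


# -----------------------------------------------------------------------------
# Cox / Fine-Gray / KM / landmark


def cox_hazard_ratio(exposure: pd.Series, survival: SurvivalTable,
                     covariates=None, covariate_columns=None,
                     label="cox") -> AssociationResult:
    """Per-SD hazard ratio from a Cox model (Efron ties, Wald CI)."""
    subjects = list(exposure.index)
    surv = survival.aligned(subjects)
    if surv["event"].sum() < 1:
        raise ValueError("no events in cohort")
    design = _design(covariates, subjects, covariate_columns)
    df = design.copy()
    df["exposure"] = exposure.to_numpy(float)
    df["time"] = surv["time"].to_numpy()
    df["event"] = surv["event"].to_numpy()
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as err:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox fit failed: {err}") from err
    log_hr = float(cph.params_["exposure"])
    se = float(cph.standard_errors_["exposure"])
    return _from_log_scale(log_hr, se, len(df), surv["event"].sum(), label,
                           design.columns)


def fine_gray_hr(exposure: pd.Series, survival: SurvivalTable,
                 covariates=None, cause_of_interest="cvd",
                 covariate_columns=None) -> AssociationResult:
    """Per-SD subdistribution hazard ratio (Fine-Gray model).

    Subjects failing from competing causes remain in the risk set after
    their event with inverse-probability-of-censoring weights
    G(t)/G(T_i) (G = Kaplan-Meier of the censoring distribution),
    implemented as a counting-process expansion fit by the weighted
    Breslow Newton solver. With no competing events this reduces
    exactly to the cause-specific Cox model. The reported standard
    error is model-based (inverse information).
    """
    subjects = list(exposure.index)
    surv = survival.aligned(subjects)
    time = surv["time"].to_numpy(float)
    event = surv["event"].to_numpy(int)
    cause = surv["cause"].to_numpy(object)
    interest = (event == 1) & (cause == cause_of_interest)
    competing = (event == 1) & ~interest
    if interest.sum() == 0:
        raise ValueError(f"no events of cause {cause_of_interest!r}")
    if interest.sum() + competing.sum() == competing.sum():
        raise ValueError("all events are competing")

    design = _design(covariates, subjects, covariate_columns)
    X = np.column_stack([exposure.to_numpy(float), design.to_numpy()]) \
        if design.shape[1] else exposure.to_numpy(float)[:, None]

    # censoring survivor function G via reversed-role Kaplan-Meier
    km = KaplanMeierFitter()
    km.fit(time, event_observed=1 - event)

    def g_at(t):
        return np.clip(km.survival_function_at_times(t).to_numpy(float),
                       1e-12, None)

    d_times = np.unique(time[interest])
    rows_X, rows_entry, rows_time, rows_event, rows_w = [], [], [], [], []
    # subjects without competing events: one interval, weight 1
    plain = ~competing
    rows_X.append(X[plain])
    rows_entry.append(np.full(plain.sum(), -1.0))
    rows_time.append(time[plain])
    rows_event.append(interest[plain].astype(int))
    rows_w.append(np.ones(plain.sum()))
    # competing-event subjects stay at risk beyond their event time with
    # weights G(t)/G(T_i), piecewise-constant between interest-event times
    comp_idx = np.flatnonzero(competing)
    if comp_idx.size and d_times.size:
        g_d = g_at(d_times)
        for i in comp_idx:
            later = d_times > time[i]
            if not later.any():
                rows_X.append(X[i:i + 1])
                rows_entry.append(np.array([-1.0]))
                rows_time.append(time[i:i + 1])
                rows_event.append(np.zeros(1, int))
                rows_w.append(np.ones(1))
                continue
            td = d_times[later]
            gw = g_d[later] / g_at(np.array([time[i]]))[0]
            starts = np.concatenate([[time[i]], td[:-1]])
            rows_X.append(np.repeat(X[i:i + 1], td.size + 1, axis=0))
            rows_entry.append(np.concatenate([[-1.0], starts]))
            rows_time.append(np.concatenate([[time[i]],
                                             np.nextafter(td, np.inf)]))
            rows_event.append(np.zeros(td.size + 1, int))
            rows_w.append(np.concatenate([[1.0], np.clip(gw, 0, 1)]))
    Xe = np.vstack(rows_X)
    entry = np.concatenate(rows_entry)
    te = np.concatenate(rows_time)
    ev = np.concatenate(rows_event)
    w = np.concatenate(rows_w)
    beta, cov = newton_cox(Xe, te, ev, weights=w, entry=entry)
    return _from_log_scale(beta[0], float(np.sqrt(cov[0, 0])), len(subjects),
                           int(interest.sum()),
                           f"fine_gray[{cause_of_interest}]", design.columns)


def kaplan_meier_logrank(groups: pd.Series, survival: SurvivalTable):
    """Product-limit curves per group and the 2-sample log-rank test.

    Returns ``(curves, chi2, p)`` with ``curves`` a dict group ->
    survival step table.
    """
    subjects = list(groups.index)
    surv = survival.aligned(subjects)
    if groups.nunique() < 2:
        raise ValueError("need at least 2 groups for a log-rank contrast")
    curves = {}
    for name, idx in groups.groupby(groups).groups.items():
        sub = surv.set_index("subject_id").loc[list(idx)]
        if len(sub) == 0 or sub["event"].sum() == 0:
            raise ValueError(f"group {name!r} is empty or has no events")
        km = KaplanMeierFitter()
        km.fit(sub["time"], sub["event"], label=str(name))
        curves[name] = km.survival_function_.reset_index()
    res = multivariate_logrank_test(surv["time"], groups.to_numpy(),
                                    surv["event"])
    return curves, float(res.test_statistic), float(res.p_value)


def landmark_hazard_ratios(exposure: pd.Series, survival: SurvivalTable,
                           covariates=None, landmarks=(1.0, 3.0, 5.0),
                           covariate_columns=None) -> dict:
    """Per-SD HRs with follow-up restarted at each landmark.

    At landmark L, subjects whose event or censoring precedes L are
    excluded and the Cox model is refit with delayed entry at L (the
    risk sets start at the landmark). Landmark 0 reproduces the plain
    Cox fit.
    """
    out = {}
    subjects = list(exposure.index)
    surv = survival.aligned(subjects)
    for L in landmarks:
        if L < 0:
            raise ValueError("landmarks must be nonnegative")
        if L == 0:
            out[L] = cox_hazard_ratio(exposure, survival, covariates,
                                      covariate_columns, label="landmark[0]")
            continue
        keep = surv["time"] > L
        kept = [s for s, k in zip(subjects, keep) if k]
        if not kept:
            raise ValueError(f"no subjects at risk after landmark {L}")
        sub_surv = surv.set_index("subject_id").loc[kept]
        if sub_surv["event"].sum() == 0:
            raise ValueError(f"no events after landmark {L}")
        design = _design(covariates, kept, covariate_columns)
        X = np.column_stack([exposure.loc[kept].to_numpy(float),
                             design.to_numpy()]) if design.shape[1] else \
            exposure.loc[kept].to_numpy(float)[:, None]
        entry = np.full(len(kept), float(L))
        beta, cov = newton_cox(X, sub_surv["time"].to_numpy(),
                               sub_surv["event"].to_numpy(), entry=entry)
        out[L] = _from_log_scale(beta[0], float(np.sqrt(cov[0, 0])),
                                 len(kept), int(sub_surv["event"].sum()),
                                 f"landmark[{L}]", design.columns)
    return out


# -----------------------------------------------------------------------------
# GLM-type outcomes


def poisson_rate_ratio(exposure: pd.Series, counts: pd.Series,
                       covariates=None, covariate_columns=None
                       ) -> AssociationResult:
    """Per-SD rate ratio from a log-link Poisson model."""
    subjects = list(exposure.index)
    y = counts.loc[subjects].to_numpy()
    if not np.all(np.equal(np.mod(y, 1), 0)) or (y < 0).any():
        raise ValueError("counts must be nonnegative integers")
    design = _design(covariates, subjects, covariate_columns)
    X = pd.concat([pd.Series(1.0, index=subjects, name="intercept"),
                   exposure.rename("exposure"), design], axis=1)
    fit = GLM(y.astype(float), X.to_numpy(), family=Poisson()).fit()
    j = 1  # exposure column
    return _from_log_scale(float(fit.params[j]), float(fit.bse[j]),
                           len(subjects), int((y > 0).sum()),
                           "poisson", design.columns)


def ordinal_odds_ratio(exposure: pd.Series, categories: pd.Series,
                       order: list, covariates=None, covariate_columns=None
                       ) -> AssociationResult:
    """Per-SD cumulative odds ratio from a proportional-odds model.

    ``order`` declares the category severity order explicitly (least to
    most severe); OR > 1 means higher odds of a more severe category.
    """
    subjects = list(exposure.index)
    cats = categories.loc[subjects]
    counts = cats.value_counts()
    for level in order:
        if counts.get(level, 0) < 3:
            raise ValueError(f"category {level!r} has fewer than 3 subjects")
    endog = pd.Series(pd.Categorical(cats, categories=order, ordered=True),
                      index=subjects, name="category")
    if endog.isna().any():
        bad = sorted(set(cats) - set(order))
        raise ValueError(f"categories outside declared order: {bad}")
    design = _design(covariates, subjects, covariate_columns)
    exog = pd.concat([exposure.rename("exposure"), design], axis=1)
    model = OrderedModel(endog, exog, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(method="bfgs", disp=0, maxiter=500, gtol=1e-8)
    return _from_log_scale(float(fit.params.iloc[0]), float(fit.bse.iloc[0]),
                           len(subjects), int((cats == order[-1]).sum()),
                           "ordinal", design.columns)


# -----------------------------------------------------------------------------
# concordance


def concordance_index(risk: pd.Series | np.ndarray, survival: SurvivalTable
                      ) -> float:
    """Harrell's C over usable pairs; risk ties count one half."""
    if isinstance(risk, pd.Series):
        surv = survival.aligned(list(risk.index))
        r = risk.to_numpy(float)
    else:
        r = np.asarray(risk, float)
        surv = survival.table
        if len(r) != len(surv):
            raise ValueError("risk length does not match survival table")
    if len(r) < 2:
        raise ValueError("need at least 2 subjects")
    if surv["event"].sum() == 0:
        raise ValueError("no usable pairs: no events")
    # lifelines orders by predicted survival; higher risk = shorter survival
    return float(_lifelines_cindex(surv["time"], -r, surv["event"]))


# -----------------------------------------------------------------------------
# per-protein screen


def protein_mortality_screen(values: pd.DataFrame, survival: SurvivalTable,
                             adjust: pd.DataFrame | None = None,
                             fdr: float = 0.05) -> pd.DataFrame:
    """Single-visit per-protein Cox screen with Benjamini-Hochberg FDR.

    ``values``: subjects x proteins matrix (one visit); each protein is
    standardized and fit in a Cox model adjusted for the columns of
    ``adjust`` (e.g. age and sex). Returns a table with per-SD log HRs,
    Wald p-values, BH-adjusted q-values and significance flags.
    """
    subjects = list(values.index)
    surv = survival.aligned(subjects)
    time = surv["time"].to_numpy(float)
    event = surv["event"].to_numpy(int)
    design = (_design(None, subjects) if adjust is None
              else _design(CovariateTable(adjust.reset_index().rename(
                  columns={adjust.index.name or "index": "subject_id"})),
                  subjects))
    A = design.to_numpy()
    rows = []
    for pid in values.columns:
        x = values[pid].to_numpy(float)
        sd = x.std(ddof=1)
        if sd == 0:
            rows.append((pid, np.nan, np.nan, 1.0))
            continue
        X = np.column_stack([(x - x.mean()) / sd, A])
        beta, cov = newton_cox(X, time, event)
        se = float(np.sqrt(cov[0, 0]))
        z = beta[0] / se
        rows.append((pid, float(beta[0]), se, float(2 * stats.norm.sf(abs(z)))))
    out = pd.DataFrame(rows, columns=["protein_id", "log_hr", "se", "p"])
    reject, q, _, _ = multipletests(out["p"].fillna(1.0), alpha=fdr,
                                    method="fdr_bh")
    out["q"] = q
    out["significant"] = reject & out["log_hr"].notna()
    out["direction"] = np.sign(out["log_hr"]).fillna(0).astype(int)
    return out


# -----------------------------------------------------------------------------
# cross-sectional aging clock (PAC / PAA)


@dataclass
class PacModel:
    """Elastic-net linear proteomic age clock trained at one visit."""

    proteins: list
    coef: np.ndarray
    intercept: float
    alpha: float
    training_subjects: list

    def predict(self, values: pd.DataFrame) -> pd.Series:
        missing = [p for p in self.proteins if p not in values.columns]
        if missing:
            raise ValueError(f"missing proteins for PAC prediction: {missing[:5]}")
        X = values[self.proteins].to_numpy(float)
        return pd.Series(X @ self.coef + self.intercept, index=values.index,
                         name="pac_age")


def train_cross_sectional_pac(values: pd.DataFrame, ages: pd.Series,
                              alpha: float = 0.5, folds: int = 10,
                              random_state=None, min_subjects: int = 50
                              ) -> PacModel:
    """Elastic-net regression of chronological age on one-visit proteins."""
    subjects = list(values.index)
    if len(subjects) < min_subjects:
        raise ValueError(f"need at least {min_subjects} subjects")
    y = ages.loc[subjects].to_numpy(float)
    X = values.to_numpy(float)
    l1 = min(max(alpha, 1e-3), 1.0)
    enet = ElasticNetCV(l1_ratio=l1, cv=folds, random_state=random_state,
                        alphas=50, max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        enet.fit(X, y)
    return PacModel(proteins=list(values.columns), coef=enet.coef_.copy(),
                    intercept=float(enet.intercept_), alpha=alpha,
                    training_subjects=subjects)


def compute_paa(predicted_ages: pd.Series, chronological_ages: pd.Series
                ) -> pd.Series:
    """Proteomic age acceleration: residual of predicted on chronological age."""
    subjects = list(predicted_ages.index)
    chron = chronological_ages.loc[subjects].to_numpy(float)
    pred = predicted_ages.to_numpy(float)
    if len(pred) != len(chron):
        raise ValueError("length mismatch")
    if np.ptp(chron) == 0:
        raise ValueError("chronological ages are constant")
    slope, intercept = np.polyfit(chron, pred, 1)
    return pd.Series(pred - (intercept + slope * chron), index=subjects,
                     name="paa")


def change_paa(late_paa: pd.Series, mid_paa: pd.Series) -> pd.Series:
    """Late-life minus midlife age acceleration."""
    return (late_paa - mid_paa.loc[late_paa.index]).rename("change_paa")


# -----------------------------------------------------------------------------
# multimorbidity and frailty coding

MULTIMORBIDITY_WEIGHTS = {
    "mi": 1, "pvd": 1, "hf": 1, "copd": 1, "ckd": 1, "diabetes": 1,
    "dementia": 1, "stroke": 2, "cancer": 2,
}

FRAILTY_LEVELS = ("robust", "prefrail", "frail")


def multimorbidity_index(conditions: dict | pd.Series) -> int:
    """Weighted chronic-condition count (stroke and cancer weigh double)."""
    if isinstance(conditions, pd.Series):
        conditions = conditions.to_dict()
    total = 0
    for name, flag in conditions.items():
        key = str(name).lower()
        if key not in MULTIMORBIDITY_WEIGHTS:
            raise ValueError(f"unknown condition {name!r}")
        total += MULTIMORBIDITY_WEIGHTS[key] * int(bool(flag))
    return total


def frailty_category(component_count: int, complete: bool = True):
    """Fried phenotype: >=3 frail, 1-2 prefrail, 0 robust (if complete).

    A count of zero with incomplete component data is indeterminate and
    returns ``None`` (missing), not robust.
    """
    if not 0 <= component_count <= 5:
        raise ValueError("component count must be within 0..5")
    if component_count >= 3:
        return "frail"
    if component_count >= 1:
        return "prefrail"
    return "robust" if complete else None
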