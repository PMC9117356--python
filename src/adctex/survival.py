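"""Survival inference chain: Kaplan-Meier, log-rank, backward-selected
linear screening of imaging features, Cox model augmentation of clinical
risk scores, and AIC model comparison.

The screening stage regresses log overall survival of deceased subjects on
all candidate imaging features and backward-eliminates by p-value; the
surviving features are then offered to a Cox proportional-hazards model
alongside a clinical risk score (DS-GPA groups or RPA classes, entered as
indicator variables against the best-prognosis reference).  The clinical
score is protected — it is the model being augmented — and only imaging
features can be eliminated.  Models are compared by Akaike's information
criterion, AIC = -2*loglik + 2*k; lower is better, and comparisons are only
permitted between fits on identical subject sets.

Cox fitting is delegated to ``statsmodels`` (partial likelihood, Efron or
Breslow ties); Kaplan-Meier and log-rank go through ``lifelines``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times
import statsmodels.api as sm
from statsmodels.duration.hazard_regression import PHReg

__all__ = [
    "CoxFit",
    "SelectionTrace",
    "KaplanMeierResult",
    "validate_clinical",
    "kaplan_meier",
    "log_rank",
    "fit_cox",
    "backward_select_linear",
    "backward_select_cox",
    "compare_aic",
    "score_design",
    "CLINICAL_COLUMNS",
    "SCORE_REFERENCE",
]

CLINICAL_COLUMNS = (
    "subject_id",
    "os_months",
    "event",
    "dsgpa_group",
    "rpa_class",
)

#: best-prognosis level used as the dummy-coding reference for each score
SCORE_REFERENCE = {"dsgpa_group": "III", "rpa_class": "I"}
_SCORE_LEVELS = {"dsgpa_group": ("I", "II", "III"), "rpa_class": ("I", "II", "III")}


def validate_clinical(table: pd.DataFrame) -> pd.DataFrame:
    """Check the clinical table contract; returns the validated frame."""
    missing = [c for c in CLINICAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"clinical table lacks columns {missing}")
    if (table["os_months"] <= 0).any():
        raise ValueError("overall survival must be positive")
    if not table["event"].isin((0, 1)).all():
        raise ValueError("event indicator must be 0 or 1")
    for col, levels in _SCORE_LEVELS.items():
        bad = set(table[col].dropna()) - set(levels)
        if bad:
            raise ValueError(f"{col} has unknown levels {sorted(bad)}")
    return table


# ---------------------------------------------------------------------------
# results containers


@dataclass
class KaplanMeierResult:
    group: str | None
    times: np.ndarray
    survival: np.ndarray
    median: float  # NaN when the curve never reaches 0.5
    median_ci: tuple[float, float]
    n: int
    n_events: int


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    pvalues: np.ndarray
    loglik: float
    k: int
    aic: float
    ties: str
    n: int
    n_events: int
    subject_key: int  # hash of the subject index, for AIC comparability

    def __post_init__(self) -> None:
        if not np.isclose(self.aic, -2.0 * self.loglik + 2.0 * self.k):
            raise ValueError("AIC inconsistent with log-likelihood and k")
        if np.any(self.ci_lower > self.hr) or np.any(self.ci_upper < self.hr):
            raise ValueError("confidence bounds do not bracket the hazard ratios")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "HR": self.hr,
                "HR_lower95": self.ci_lower,
                "HR_upper95": self.ci_upper,
                "p": self.pvalues,
            },
            index=self.names,
        )


@dataclass
class SelectionTrace:
    """Ordered record of a backward-elimination run."""

    steps: list[dict] = field(default_factory=list)  # removed, p, crit before/after
    surviving: list[str] = field(default_factory=list)
    alpha_remove: float = 0.10

    def removed(self) -> list[str]:
        return [s["removed"] for s in self.steps]


# ---------------------------------------------------------------------------
# univariate stage


def kaplan_meier(
    table: pd.DataFrame, group: str | None = None
) -> dict[str, KaplanMeierResult]:
    """Product-limit survival curve(s) with median OS and Greenwood 95% CI.

    With ``group`` a column name, one curve per level; otherwise a single
    curve keyed ``"all"``.  No events at all leaves the median NaN.
    """
    table = validate_clinical(table)
    if int(table["event"].sum()) == 0:
        warnings.warn("no events: survival curve is flat, median undefined",
                      stacklevel=2)
    out: dict[str, KaplanMeierResult] = {}
    if group is None:
        groups = {"all": table}
    else:
        groups = {str(k): g for k, g in table.groupby(group, observed=True)}
    for key, sub in groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(sub["os_months"], sub["event"])
        med = float(kmf.median_survival_time_)
        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
        out[key] = KaplanMeierResult(
            group=None if group is None else key,
            times=kmf.survival_function_.index.to_numpy(dtype=float),
            survival=kmf.survival_function_.iloc[:, 0].to_numpy(),
            median=med if np.isfinite(med) else float("nan"),
            median_ci=(lo, hi),
            n=len(sub),
            n_events=int(sub["event"].sum()),
        )
    return out


def log_rank(table: pd.DataFrame, group: str) -> tuple[float, float]:
    """Log-rank test across the levels of ``group``: (chi2, p)."""
    table = validate_clinical(table)
    counts = table[group].value_counts()
    if (counts == 0).any() or len(counts) < 2:
        raise ValueError(f"log-rank needs >= 2 non-empty groups in '{group}'")
    res = multivariate_logrank_test(
        table["os_months"], table[group], table["event"]
    )
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox fitting


def score_design(table: pd.DataFrame, score: str) -> pd.DataFrame:
    """Indicator columns for a clinical score vs its best-prognosis reference."""
    if score not in SCORE_REFERENCE:
        raise ValueError(f"unknown clinical score '{score}'")
    ref = SCORE_REFERENCE[score]
    cols = {}
    for level in _SCORE_LEVELS[score]:
        if level == ref:
            continue
        cols[f"{score}_{level}"] = (table[score] == level).astype(float)
    return pd.DataFrame(cols, index=table.index)


def fit_cox(
    table: pd.DataFrame,
    covariates: pd.DataFrame,
    ties: str = "efron",
) -> CoxFit:
    """Maximize the Cox partial likelihood over the given covariates.

    ``covariates`` is a numeric design matrix aligned with ``table``.  A
    covariate without variation raises (it cannot be identified); wildly
    diverging coefficients are reported as a separation error naming the
    covariate.  AIC = -2*partial-loglik + 2*k.
    """
    table = validate_clinical(table)
    if int(table["event"].sum()) == 0:
        raise ValueError("Cox model needs at least one event")
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method '{ties}'")
    X = covariates.astype(float)
    if X.shape[1] == 0:
        raise ValueError("no covariates to fit")
    if not X.index.equals(table.index):
        raise ValueError("covariates are not aligned with the clinical table")
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"covariate(s) without variation: {const}")
    # fit on standardized columns for numerical stability, then map back;
    # the partial likelihood is invariant to affine rescaling of covariates
    arr = np.asarray(X, dtype=float)
    scale = arr.std(axis=0, ddof=0)
    arr_std = (arr - arr.mean(axis=0)) / scale
    model = PHReg(
        np.asarray(table["os_months"], dtype=float),
        arr_std,
        status=np.asarray(table["event"], dtype=int),
        ties=ties,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=False)
    beta_std = np.asarray(res.params)
    if not np.all(np.isfinite(beta_std)) or np.any(np.abs(beta_std) > 50):
        bad = [
            c
            for c, b in zip(X.columns, beta_std)
            if not np.isfinite(b) or abs(b) > 50
        ]
        raise ValueError(
            f"Cox fit did not converge (possible separation) for covariate(s) {bad}"
        )
    beta = beta_std / scale
    se = np.asarray(res.bse) / scale
    z = 1.959963984540054  # Phi^-1(0.975)
    ll = float(model.loglike(beta_std))
    k = int(beta.size)
    return CoxFit(
        names=list(X.columns),
        coef=beta,
        se=se,
        hr=np.exp(beta),
        ci_lower=np.exp(beta - z * se),
        ci_upper=np.exp(beta + z * se),
        pvalues=np.asarray(res.pvalues),
        loglik=ll,
        k=k,
        aic=-2.0 * ll + 2.0 * k,
        ties=ties,
        n=len(table),
        n_events=int(table["event"].sum()),
        subject_key=int(pd.util.hash_pandas_object(table.index).sum() % (2**63)),
    )


# ---------------------------------------------------------------------------
# backward selection


def backward_select_linear(
    features: pd.DataFrame,
    table: pd.DataFrame,
    alpha_remove: float = 0.10,
    prescreen: bool = False,
    prescreen_p: float = 0.5,
) -> SelectionTrace:
    """Backward-eliminated OLS of log(OS) on imaging features (deceased only).

    Starting from all candidates, repeatedly drop the feature with the
    largest p-value >= ``alpha_remove`` and refit, until every remaining
    feature is below the threshold.  Columns that are constant or that make
    the design rank-deficient are removed up front with a warning.  With
    ``prescreen`` (for p approaching n), features whose univariate OLS
    p-value exceeds ``prescreen_p`` are dropped before selection starts.
    """
    table = validate_clinical(table)
    dead = table["event"] == 1
    if int(dead.sum()) < 3:
        raise ValueError("too few deceased subjects for the linear stage")
    y = np.log(table.loc[dead, "os_months"].to_numpy(dtype=float))
    X = features.loc[table.index[dead]].astype(float)

    drop = [c for c in X.columns if X[c].nunique() <= 1 or X[c].isna().any()]
    if drop:
        warnings.warn(f"dropping unusable feature column(s): {drop}", stacklevel=2)
        X = X.drop(columns=drop)
    # greedy removal of collinear columns
    while X.shape[1] > 1:
        arr = np.column_stack([np.ones(len(X)), X.to_numpy()])
        if np.linalg.matrix_rank(arr) == arr.shape[1]:
            break
        c = X.columns[-1]
        warnings.warn(f"dropping collinear feature column '{c}'", stacklevel=2)
        X = X.drop(columns=c)

    if prescreen and X.shape[1] >= int(dead.sum()):
        keep = []
        for c in X.columns:
            p = sm.OLS(y, sm.add_constant(X[[c]].to_numpy())).fit().pvalues[1]
            if p <= prescreen_p:
                keep.append(c)
        X = X[keep]

    trace = SelectionTrace(alpha_remove=alpha_remove)
    current = list(X.columns)
    while current:
        fit = sm.OLS(y, sm.add_constant(X[current].to_numpy())).fit()
        pvals = pd.Series(fit.pvalues[1:], index=current)
        worst = pvals.idxmax()
        if pvals[worst] < alpha_remove:
            break
        reduced = [c for c in current if c != worst]
        if reduced:
            fit_after = sm.OLS(
                y, sm.add_constant(X[reduced].to_numpy())
            ).fit()
            aic_after = float(fit_after.aic)
        else:
            aic_after = float(sm.OLS(y, np.ones((len(y), 1))).fit().aic)
        trace.steps.append(
            {
                "removed": worst,
                "p_at_removal": float(pvals[worst]),
                "crit_before": float(fit.aic),
                "crit_after": aic_after,
            }
        )
        current = reduced
    trace.surviving = current
    return trace


def backward_select_cox(
    table: pd.DataFrame,
    score: str,
    features: pd.DataFrame,
    alpha_remove: float = 0.10,
    ties: str = "efron",
) -> tuple[CoxFit, SelectionTrace]:
    """Augment a clinical score with backward-selected imaging features.

    The score's indicator columns are protected in every step; only imaging
    features are candidates for elimination (by Wald p >= ``alpha_remove``).
    An empty candidate list returns the clinical-score-only fit unchanged.

    A candidate that makes the partial likelihood unidentifiable (collinear
    or separating, so the fit diverges on it) cannot be retained on any
    evidence; such candidates are eliminated with a warning and recorded in
    the trace.  Divergence on a protected score column is re-raised.
    """
    table = validate_clinical(table)
    protected = score_design(table, score)
    features = features.loc[table.index].astype(float)
    candidates = list(features.columns)
    trace = SelectionTrace(alpha_remove=alpha_remove)

    def fit_with(cands: list[str]) -> CoxFit:
        design = pd.concat([protected, features[cands]], axis=1)
        return fit_cox(table, design, ties=ties)

    def fit_dropping_unidentifiable(cands: list[str]) -> tuple[CoxFit, list[str]]:
        while True:
            try:
                return fit_with(cands), cands
            except ValueError as exc:
                bad = [c for c in cands if c in str(exc)]
                if not bad:
                    raise
                warnings.warn(
                    f"eliminating unidentifiable candidate '{bad[0]}': {exc}",
                    stacklevel=3,
                )
                trace.steps.append(
                    {
                        "removed": bad[0],
                        "p_at_removal": float("nan"),
                        "crit_before": float("nan"),
                        "crit_after": float("nan"),
                        "reason": "nonconvergence",
                    }
                )
                cands = [c for c in cands if c != bad[0]]

    fit, candidates = fit_dropping_unidentifiable(candidates)
    while candidates:
        pvals = pd.Series(fit.pvalues, index=fit.names).loc[candidates]
        worst = pvals.idxmax()
        if pvals[worst] < alpha_remove:
            break
        reduced = [c for c in candidates if c != worst]
        fit_after, reduced = fit_dropping_unidentifiable(reduced)
        trace.steps.append(
            {
                "removed": worst,
                "p_at_removal": float(pvals[worst]),
                "crit_before": fit.aic,
                "crit_after": fit_after.aic,
            }
        )
        candidates, fit = reduced, fit_after
    trace.surviving = candidates
    return fit, trace


def compare_aic(fits: dict[str, CoxFit]) -> pd.DataFrame:
    """AIC comparison table; refuses fits on different subject sets."""
    if not fits:
        raise ValueError("nothing to compare")
    keys = {f.subject_key for f in fits.values()}
    if len(keys) > 1:
        raise ValueError("AIC comparison requires identical subject sets")
    df = pd.DataFrame(
        {
            "loglik": {name: f.loglik for name, f in fits.items()},
            "k": {name: f.k for name, f in fits.items()},
            "AIC": {name: f.aic for name, f in fits.items()},
        }
    )
    df["dAIC"] = df["AIC"] - df["AIC"].min()
    df["best"] = df["AIC"] == df["AIC"].min()
    return df.sort_values("AIC")
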