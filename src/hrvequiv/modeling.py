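"""Random-intercept linear mixed models, Rubin pooling, and per-country GLMs.

The confirmatory model regresses each outcome on log-RMSSD with age, gender,
BMI and device type as covariates and a random intercept for country,
estimated by REML through statsmodels' MixedLM.  On top of that fit this
module adds the quantities the analysis reports and statsmodels does not
expose for mixed models: Satterthwaite-type per-coefficient degrees of
freedom, the intraclass correlation, conditional R-squared, Rubin's-rules
pooling across imputed datasets with the Barnard-Rubin small-sample df, and
Bonferroni adjustment.

Model objects follow the statsmodels convention: build from data, ``fit()``
returns a results object carrying estimates, uncertainties and ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelSpec",
    "ModelFit",
    "PooledEstimate",
    "fit_lmm",
    "pool_rubin",
    "compute_icc",
    "conditional_r2",
    "bonferroni_adjust",
    "fit_country_glm",
    "MixedOutcomeModel",
    "PooledMIModel",
    "PooledMIResults",
]


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one confirmatory model."""

    outcome: str
    predictor: str = "log_rmssd"
    covariates: tuple = ("age", "gender", "bmi", "device")
    categorical: tuple = ("gender", "device")
    cluster: str = "country"
    reml: bool = True
    alpha: float = 0.05
    n_tests: int = 7
    treatment_reference: str | None = None

    def rhs_terms(self, data: pd.DataFrame) -> list:
        """Right-hand-side formula terms, dropping single-level categoricals."""
        terms = []
        for name in (self.predictor, *self.covariates):
            if name not in data.columns:
                continue
            if name in self.categorical or data[name].dtype == object:
                if data[name].nunique() < 2:
                    warnings.warn(f"dropping constant factor {name!r}")
                    continue
                if name == self.predictor and self.treatment_reference is not None:
                    terms.append(
                        f"C({name}, Treatment(reference='{self.treatment_reference}'))"
                    )
                else:
                    terms.append(f"C({name})")
            else:
                terms.append(name)
        return terms

    def formula(self, data: pd.DataFrame) -> str:
        return f"{self.outcome} ~ " + " + ".join(self.rhs_terms(data))


@dataclass
class ModelFit:
    """One REML fit: estimates, variance components and derived diagnostics."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    df: pd.Series
    sigma2_cluster: float
    sigma2_resid: float
    icc: float
    r2_conditional: float
    converged: bool
    singular: bool
    nobs: int
    n_params: int
    resid_skew: float
    resid_kurtosis: float

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * stats.t.sf(np.abs(self.tvalues), self.df), index=self.params.index
        )

    def term(self, needle: str) -> str:
        """Full design-matrix name of the term containing ``needle``."""
        for name in self.params.index:
            if needle in name:
                return name
        raise KeyError(needle)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "B": self.params,
                "SE": self.bse,
                "t": self.tvalues,
                "df": self.df,
                "p": self.pvalues,
            }
        )


def _variance_component_cov(ns: np.ndarray, s2u: float, s2e: float) -> np.ndarray:
    """Inverse expected information for (sigma2_cluster, sigma2_resid).

    Uses the marginal-covariance form of the information (the fixed-effect
    projection correction is negligible at these sizes); closed form for a
    single random intercept.
    """
    a = 1.0 / (s2e + ns * s2u)
    i11 = 0.5 * np.sum(ns**2 * a**2)
    i12 = 0.5 * np.sum(ns * a**2)
    i22 = 0.5 * (np.sum(ns - 1) / s2e**2 + np.sum(a**2))
    info = np.array([[i11, i12], [i12, i22]])
    return np.linalg.inv(info)


def _beta_cov(Xg: list, sums: list, ns: np.ndarray, s2u: float, s2e: float) -> np.ndarray:
    """(X' V^-1 X)^-1 for block-diagonal V = s2e I + s2u J per cluster."""
    p = Xg[0].shape[1]
    M = np.zeros((p, p))
    for X, s, n in zip(Xg, sums, ns):
        shrink = s2u / (s2e + n * s2u)
        M += (X.T @ X - shrink * np.outer(s, s)) / s2e
    return np.linalg.inv(M)


def _satterthwaite_df(Xg, sums, ns, s2u, s2e, nobs, p):
    """Satterthwaite-type df per coefficient: 2 f^2 / Var(f), f = c'Vb(theta)c."""
    resid_df = max(nobs - p, 1)
    if s2u <= 1e-10 * s2e:
        return np.full(p, float(resid_df))
    cov_theta = _variance_component_cov(ns, s2u, s2e)
    h_u = max(s2u, 1e-8 * s2e) * 1e-4
    h_e = s2e * 1e-4

    def diag_vb(u, e):
        return np.diag(_beta_cov(Xg, sums, ns, u, e))

    f0 = diag_vb(s2u, s2e)
    g_u = (diag_vb(s2u + h_u, s2e) - diag_vb(max(s2u - h_u, 0.0), s2e)) / (
        s2u + h_u - max(s2u - h_u, 0.0)
    )
    g_e = (diag_vb(s2u, s2e + h_e) - diag_vb(s2u, s2e - h_e)) / (2 * h_e)
    out = np.empty(p)
    for j in range(p):
        g = np.array([g_u[j], g_e[j]])
        var_f = float(g @ cov_theta @ g)
        out[j] = 2.0 * f0[j] ** 2 / var_f if var_f > 0 else resid_df
    return np.clip(out, 1.0, resid_df)


def fit_lmm(dataset: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """REML random-intercept fit with Satterthwaite df, ICC and conditional R2."""
    import statsmodels.formula.api as smf

    data = dataset.dropna(subset=[spec.outcome])
    groups = data[spec.cluster]
    if groups.nunique() < 2:
        raise ValueError("need at least 2 clusters")
    formula = spec.formula(data)
    singular = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, data, groups=groups)
        try:
            res = model.fit(reml=spec.reml, method="lbfgs")
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"rank-deficient design for {formula!r}: {exc}") from exc
        singular = any("singular" in str(w.message).lower() for w in caught)

    X = model.exog
    names = model.exog_names
    nobs, p = X.shape
    s2e = float(res.scale)
    s2u = float(np.asarray(res.cov_re)[0, 0])
    codes = pd.Categorical(groups).codes
    Xg = [X[codes == g] for g in range(codes.max() + 1)]
    sums = [x.sum(axis=0) for x in Xg]
    ns = np.array([x.shape[0] for x in Xg], dtype=float)

    df = pd.Series(_satterthwaite_df(Xg, sums, ns, s2u, s2e, nobs, p), index=names)
    # fixed effects and their covariance from the closed-form GLS expressions
    # at the REML variance estimates; self-consistent at the singular
    # (sigma2_cluster -> 0) boundary, where they reduce exactly to OLS
    y = np.asarray(model.endog, dtype=float)
    yg = [y[codes == g] for g in range(codes.max() + 1)]
    cov_beta = _beta_cov(Xg, sums, ns, s2u, s2e)
    rhs = np.zeros(p)
    for Xb, yb, s, n_g in zip(Xg, yg, sums, ns):
        shrink = s2u / (s2e + n_g * s2u)
        rhs += (Xb.T @ yb - shrink * s * yb.sum()) / s2e
    params = pd.Series(cov_beta @ rhs, index=names)
    bse = pd.Series(np.sqrt(np.diag(cov_beta)), index=names)

    fixed_pred = X @ params.to_numpy()
    var_fixed = float(np.var(fixed_pred, ddof=0))
    resid = np.asarray(model.endog) - fixed_pred
    return ModelFit(
        spec=spec,
        params=params,
        bse=bse,
        df=df,
        sigma2_cluster=s2u,
        sigma2_resid=s2e,
        icc=compute_icc(s2u, s2e),
        r2_conditional=(var_fixed + s2u) / (var_fixed + s2u + s2e),
        converged=bool(res.converged),
        singular=singular,
        nobs=nobs,
        n_params=p,
        resid_skew=float(stats.skew(resid)),
        resid_kurtosis=float(stats.kurtosis(resid)),
    )


def compute_icc(sigma2_cluster: float, sigma2_resid: float) -> float:
    """Share of outcome variance attributable to the clustering level."""
    if sigma2_cluster < 0 or sigma2_resid < 0:
        raise ValueError("variance components must be non-negative")
    tot = sigma2_cluster + sigma2_resid
    if tot == 0:
        return float("nan")
    return sigma2_cluster / tot


def conditional_r2(fit: ModelFit, var_fixed: float | None = None) -> float:
    """Variance explained by fixed plus random effects (Gaussian decomposition)."""
    return fit.r2_conditional if var_fixed is None else (
        (var_fixed + fit.sigma2_cluster)
        / (var_fixed + fit.sigma2_cluster + fit.sigma2_resid)
    )


def bonferroni_adjust(p_values, k: int):
    """p_adj = min(1, k p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    out = np.minimum(1.0, k * p)
    return float(out) if np.isscalar(p_values) else out


@dataclass
class PooledEstimate:
    """A Rubin-pooled coefficient across m imputed-data fits."""

    term: str
    qbar: float
    within: float
    between: float
    total: float
    df: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total))

    @property
    def t(self) -> float:
        return self.qbar / self.se

    @property
    def p(self) -> float:
        return float(2.0 * stats.t.sf(abs(self.t), self.df))


def pool_rubin(estimates, variances, df_com: float = np.inf, term: str = "") -> PooledEstimate:
    """Rubin's rules with the Barnard-Rubin small-sample df adjustment.

    ``estimates`` are the m point estimates, ``variances`` their squared
    standard errors, ``df_com`` the complete-data df of the underlying test.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = q.size
    if m < 2:
        raise ValueError("pooling needs m >= 2 fits")
    if u.size != m:
        raise ValueError("mismatched estimate/variance lengths")
    qbar = float(np.mean(q))
    w = float(np.mean(u))
    b = float(np.var(q, ddof=1))
    t = w + (1.0 + 1.0 / m) * b
    if b <= 0 or not np.isfinite(df_com):
        df = float(df_com) if np.isfinite(df_com) else float("inf")
        if b > 0 and not np.isfinite(df_com):
            lam = (1.0 + 1.0 / m) * b / t
            df = (m - 1) / lam**2
    else:
        lam = (1.0 + 1.0 / m) * b / t
        df_old = (m - 1) / lam**2
        df_obs = (df_com + 1.0) / (df_com + 3.0) * df_com * (1.0 - lam)
        df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    return PooledEstimate(term, qbar, w, b, t, df, m)


class MixedOutcomeModel:
    """statsmodels-style wrapper: one outcome, one complete dataset."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        self.data = data
        self.spec = spec

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str, **kwargs):
        return cls(data, ModelSpec(outcome=outcome, **kwargs))

    def fit(self) -> ModelFit:
        return fit_lmm(self.data, self.spec)


@dataclass
class PooledMIResults:
    """Rubin-pooled results across the m imputed datasets."""

    spec: ModelSpec
    fits: list
    pooled: dict
    mean_icc: float
    mean_r2_conditional: float

    def estimate(self, needle: str) -> PooledEstimate:
        for name, est in self.pooled.items():
            if needle in name:
                return est
        raise KeyError(needle)

    def summary(self) -> pd.DataFrame:
        rows = {
            name: {
                "B": e.qbar,
                "SE": e.se,
                "t": e.t,
                "df": e.df,
                "p": e.p,
                "within_var": e.within,
                "between_var": e.between,
            }
            for name, e in self.pooled.items()
        }
        out = pd.DataFrame(rows).T
        out.attrs["icc"] = self.mean_icc
        out.attrs["r2_conditional"] = self.mean_r2_conditional
        return out


class PooledMIModel:
    """Fit the same mixed model on each imputed dataset and pool by Rubin's rules."""

    def __init__(self, datasets, spec: ModelSpec):
        if len(datasets) < 2:
            raise ValueError("need at least 2 imputed datasets")
        self.datasets = list(datasets)
        self.spec = spec

    def fit(self) -> PooledMIResults:
        fits = [fit_lmm(d, self.spec) for d in self.datasets]
        names = list(fits[0].params.index)
        for f in fits[1:]:
            if list(f.params.index) != names:
                raise ValueError("imputed-data fits have mismatched specifications")
        pooled = {}
        for name in names:
            df_com = float(np.mean([f.df[name] for f in fits]))
            pooled[name] = pool_rubin(
                [f.params[name] for f in fits],
                [f.bse[name] ** 2 for f in fits],
                df_com=df_com,
                term=name,
            )
        return PooledMIResults(
            spec=self.spec,
            fits=fits,
            pooled=pooled,
            mean_icc=float(np.mean([f.icc for f in fits])),
            mean_r2_conditional=float(np.mean([f.r2_conditional for f in fits])),
        )


def fit_country_glm(dataset: pd.DataFrame, country: str, spec: ModelSpec) -> pd.DataFrame:
    """Ordinary least squares on one country's subset, same predictors.

    Constant factors (e.g., a single device type within a country) are dropped
    with a warning; p-values carry a Bonferroni column over ``spec.n_tests``.
    """
    import statsmodels.formula.api as smf

    sub = dataset[dataset[spec.cluster] == country]
    if sub.empty:
        raise ValueError(f"no rows for country {country!r}")
    formula = spec.formula(sub)
    res = smf.ols(formula, sub).fit()
    out = pd.DataFrame(
        {
            "B": res.params,
            "SE": res.bse,
            "t": res.tvalues,
            "df": float(res.df_resid),
            "p": res.pvalues,
        }
    )
    out["p_bonferroni"] = bonferroni_adjust(out["p"].to_numpy(), spec.n_tests)
    return out
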