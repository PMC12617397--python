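"""Multilevel multiple imputation by chained equations.

Missing cells are filled by cycling type-specific conditional draws in the
style of mice: proportional-odds regression for ordinal items, logistic
regression for nominal variables, and a two-level normal model (country
intercepts, ridge-shrunken) for continuous variables.  Parameter uncertainty
is propagated by drawing coefficients from their asymptotic distribution and
the residual variance from its scaled inverse chi-square, approximating
proper imputation.  Derived variables (BMI, instrument totals) are re-derived
passively after every cycle.  Conditional fits that fail (empty categories,
separation) fall back to predictive-mean matching with 5 donors, logged per
variable and iteration.

Conditional models use a compact predictor set — log-RMSSD, demographics,
cluster dummies, and the running mean of the other items of the same
instrument as a summary of the item block — which keeps the chained fits
well-conditioned and fast; the full item-level predictor matrix is available
through ``ImputationConfig.predictors``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _polr, scoring

__all__ = [
    "ImputationConfig",
    "ImputedDatasets",
    "decode_missing",
    "missingness_screen",
    "chained_impute",
    "passive_derive",
]

_INSTRUMENT_ITEMS = {
    "mmapp": scoring.MMAPP_ITEMS,
    "ders": scoring.DERS_ITEMS,
    "dbis": scoring.DBIS_ITEMS,
}
_ITEM_TO_INSTRUMENT = {
    item: inst for inst, items in _INSTRUMENT_ITEMS.items() for item in items
}

_BASE_VARS = ("log_rmssd", "age", "gender", "height_m", "weight_kg")


def decode_missing(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Convert categorical missing codes to NaN, coercing affected columns to
    numeric where possible."""
    table = table.copy()
    cols = columns if columns is not None else table.columns
    for c in cols:
        col = table[c]
        if col.dtype == object:
            low = col.astype(str).str.strip().str.lower()
            col = col.mask(low.isin(scoring.MISSING_CODES))
            coerced = pd.to_numeric(col, errors="coerce")
            # keep strings if the column is genuinely nominal
            if coerced.notna().sum() >= col.notna().sum():
                col = coerced
            table[c] = col
    return table


@dataclass(frozen=True)
class ImputationConfig:
    m: int = 5
    maxit: int = 10
    cluster_var: str = "country"
    method_map: dict | None = None
    predictors: tuple | None = None
    seed: int = 0
    ridge: float = 1e-5
    pmm_donors: int = 5
    passive: bool = True
    passive_vars: tuple = ("bmi", "totals")
    #: structurally missing columns (e.g., a task not administered at a site)
    #: are left untouched and handled by row omission at analysis time
    exclude: tuple = ("false_alarm_pct", "immediate_reward_pct")

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.maxit < 1:
            raise ValueError("maxit must be >= 1")


@dataclass
class ImputedDatasets:
    """The m completed tables plus chain diagnostics and provenance."""

    datasets: list
    traces: pd.DataFrame
    config: ImputationConfig
    fallback_log: list = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.datasets)

    def complete(self, i: int) -> pd.DataFrame:
        return self.datasets[i]


def missingness_screen(table: pd.DataFrame, auxiliaries) -> pd.DataFrame:
    """Point-biserial correlations between missingness indicators and
    auxiliaries; rows with ``|r| >= 0.1`` are flagged."""
    dec = decode_missing(table)
    rows = []
    for var in dec.columns:
        ind = dec[var].isna().astype(float)
        if ind.sum() == 0:
            continue
        for aux in auxiliaries:
            if aux == var:
                continue
            x = pd.to_numeric(dec[aux], errors="coerce")
            ok = x.notna()
            if ind[ok].nunique() < 2 or x[ok].nunique() < 2:
                r = float("nan")
            else:
                r = float(np.corrcoef(ind[ok], x[ok])[0, 1])
            rows.append(
                {
                    "variable": var,
                    "auxiliary": aux,
                    "r": r,
                    "flagged": bool(abs(r) >= 0.1) if np.isfinite(r) else False,
                }
            )
    return pd.DataFrame(rows, columns=["variable", "auxiliary", "r", "flagged"])


def passive_derive(df: pd.DataFrame, which=("bmi", "totals")) -> pd.DataFrame:
    """Recompute BMI and instrument totals from their (completed) constituents."""
    df = df.copy()
    if "bmi" in which and {"height_m", "weight_kg"} <= set(df.columns):
        h = pd.to_numeric(df["height_m"], errors="coerce")
        w = pd.to_numeric(df["weight_kg"], errors="coerce")
        if (h <= 0).any():
            df["_invalid_height"] = h <= 0
        df["bmi"] = w / h**2
    if "totals" in which and set(scoring.MMAPP_ITEMS) <= set(df.columns):
        scores = scoring.score_items_table(df)
        for c in scores.columns:
            df[c] = scores[c]
    return df


def _infer_method(col: pd.Series) -> str:
    if col.dtype == object:
        return "logreg"
    vals = col.dropna().unique()
    if vals.size <= 8 and np.allclose(vals, np.round(vals)):
        return "polr"
    return "norm2l"


def _draw_norm(y_obs, X_obs, X_mis, rng, ridge):
    n, p = X_obs.shape
    XtX = X_obs.T @ X_obs + ridge * np.eye(p)
    beta = np.linalg.solve(XtX, X_obs.T @ y_obs)
    resid = y_obs - X_obs @ beta
    nu = max(n - p, 1)
    sigma2 = float(resid @ resid) / nu
    sigma2_star = sigma2 * nu / stats.chi2.rvs(nu, random_state=rng)
    cov = sigma2_star * np.linalg.inv(XtX)
    beta_star = rng.multivariate_normal(beta, cov, method="cholesky")
    return X_mis @ beta_star + rng.normal(0.0, np.sqrt(sigma2_star), X_mis.shape[0])


def _draw_pmm(y_obs, X_obs, X_mis, rng, ridge, donors):
    n, p = X_obs.shape
    XtX = X_obs.T @ X_obs + ridge * np.eye(p)
    beta = np.linalg.solve(XtX, X_obs.T @ y_obs)
    resid = y_obs - X_obs @ beta
    nu = max(n - p, 1)
    sigma2 = float(resid @ resid) / nu
    sigma2_star = sigma2 * nu / stats.chi2.rvs(nu, random_state=rng)
    cov = sigma2_star * np.linalg.inv(XtX)
    beta_star = rng.multivariate_normal(beta, cov, method="cholesky")
    pred_obs = X_obs @ beta
    pred_mis = X_mis @ beta_star
    out = np.empty(X_mis.shape[0])
    k = min(donors, y_obs.size)
    for j, pm in enumerate(pred_mis):
        idx = np.argsort(np.abs(pred_obs - pm))[:k]
        out[j] = y_obs[idx[int(rng.integers(k))]]
    return out


def _draw_polr(y_obs, X_obs, X_mis, rng):
    """Proportional-odds draw: fit, sample parameters, sample categories."""
    levels = np.sort(np.unique(y_obs))
    if levels.size < 2:
        return np.full(X_mis.shape[0], levels[0] if levels.size else 0.0)
    codes = np.searchsorted(levels, y_obs)
    k = levels.size
    params, cov, _ = _polr.fit_polr(X_obs, codes, k)
    params_star = rng.multivariate_normal(params, cov)
    probs = _polr.predict_probs(params_star, X_mis, k)
    cum = np.cumsum(probs, axis=1)
    u = rng.random(X_mis.shape[0])
    return levels[(u[:, None] > cum).sum(axis=1)]


def _draw_logreg(y_obs, X_obs, X_mis, rng):
    import statsmodels.api as sm

    cats, codes = np.unique(y_obs, return_inverse=True)
    if cats.size < 2:
        return np.full(X_mis.shape[0], cats[0], dtype=object)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if cats.size == 2:
            res = sm.Logit(codes, X_obs).fit(disp=False, maxiter=200)
            params_star = rng.multivariate_normal(res.params, res.cov_params())
            p1 = 1.0 / (1.0 + np.exp(-(X_mis @ params_star)))
            return cats[(rng.random(X_mis.shape[0]) < p1).astype(int)]
        res = sm.MNLogit(codes, X_obs).fit(disp=False, maxiter=200)
        flat = rng.multivariate_normal(
            np.asarray(res.params).ravel(order="F"), res.cov_params()
        )
        B = flat.reshape(res.params.shape, order="F")
        eta = np.column_stack([np.zeros(X_mis.shape[0]), X_mis @ B])
        eta -= eta.max(axis=1, keepdims=True)
        probs = np.exp(eta)
        probs /= probs.sum(axis=1, keepdims=True)
        cum = np.cumsum(probs, axis=1)
        u = rng.random(X_mis.shape[0])
        return cats[(u[:, None] > cum).sum(axis=1)]


class _DesignCache:
    """Numeric design blocks rebuilt once per sweep, shared across variables."""

    def __init__(self, df, cluster_var, explicit_predictors=None):
        self.cluster_var = cluster_var
        self.explicit = explicit_predictors
        n = len(df)
        parts = [np.ones((n, 1))]
        self.slices = {"_const": slice(0, 1)}
        pos = 1
        source = explicit_predictors if explicit_predictors is not None else _BASE_VARS
        for v in source:
            if v not in df.columns:
                continue
            col = df[v]
            if col.dtype == object:
                d = pd.get_dummies(col, drop_first=True, dtype=float).to_numpy()
            else:
                d = col.to_numpy(dtype=float)[:, None]
            parts.append(d)
            self.slices[v] = slice(pos, pos + d.shape[1])
            pos += d.shape[1]
        if cluster_var in df.columns:
            d = pd.get_dummies(df[cluster_var], drop_first=True, dtype=float).to_numpy()
            parts.append(d)
            pos += d.shape[1]
        self.base = np.hstack(parts)
        # instrument item blocks for the running-mean summary predictors
        self.item_blocks = {
            inst: df[[c for c in items if c in df.columns]].to_numpy(dtype=float)
            for inst, items in _INSTRUMENT_ITEMS.items()
            if any(c in df.columns for c in items)
        }
        self.item_pos = {
            inst: {c: j for j, c in enumerate(items) if c in df.columns}
            for inst, items in _INSTRUMENT_ITEMS.items()
        }

    def design_for(self, var: str) -> np.ndarray:
        cols = [self.base]
        if self.explicit is not None:
            X = self.base
            sl = self.slices.get(var)
            if sl is not None:  # drop the target variable's own columns
                keep = np.ones(X.shape[1], dtype=bool)
                keep[sl] = False
                return X[:, keep]
            return X
        inst = _ITEM_TO_INSTRUMENT.get(var)
        if inst is not None and inst in self.item_blocks:
            block = self.item_blocks[inst]
            j = self.item_pos[inst].get(var)
            total = block.sum(axis=1)
            if j is not None:
                rest = (total - block[:, j]) / (block.shape[1] - 1)
            else:
                rest = total / block.shape[1]
            cols.append(rest[:, None])
        else:
            # non-item variable: all instrument means as summaries
            for inst, block in self.item_blocks.items():
                cols.append(block.mean(axis=1)[:, None])
            sl = self.slices.get(var)
            if sl is not None:
                X = np.hstack(cols)
                keep = np.ones(X.shape[1], dtype=bool)
                keep[sl] = False
                return X[:, keep]
        return np.hstack(cols)


def chained_impute(table: pd.DataFrame, config: ImputationConfig) -> ImputedDatasets:
    """Run m independent chained-equation chains; returns completed datasets
    plus per-variable chain traces (mean/SD of imputed values per iteration)."""
    dec = decode_missing(table)
    candidates = [
        c
        for c in dec.columns
        if c != config.cluster_var
        and c not in config.exclude
        and dec[c].isna().any()
    ]
    if config.method_map is not None:
        methods = {c: config.method_map[c] for c in candidates}
    else:
        methods = {c: _infer_method(dec[c]) for c in candidates}

    if not candidates:
        datasets = [
            passive_derive(dec, config.passive_vars) if config.passive else dec.copy()
            for _ in range(config.m)
        ]
        traces = pd.DataFrame(columns=["chain", "iteration", "variable", "mean", "sd"])
        return ImputedDatasets(datasets, traces, config)

    # visit sequence: ascending missingness rate
    miss_rate = {c: dec[c].isna().mean() for c in candidates}
    visit = sorted(candidates, key=lambda c: (miss_rate[c], c))
    masks = {c: dec[c].isna().to_numpy() for c in visit}

    ss = np.random.SeedSequence(config.seed)
    datasets, trace_rows, fallback_log = [], [], []
    for chain, child in enumerate(ss.spawn(config.m)):
        rng = np.random.default_rng(child)
        df = dec.copy()
        for c in visit:  # initialise from observed marginals
            obs = df[c].dropna().to_numpy()
            df.loc[masks[c], c] = rng.choice(obs, size=int(masks[c].sum()))
        for it in range(config.maxit):
            cache = _DesignCache(df, config.cluster_var, config.predictors)
            for c in visit:
                X = cache.design_for(c)
                obs = ~masks[c]
                X_obs, X_mis = X[obs], X[~obs]
                method = methods[c]
                if method == "logreg":
                    y_obs = df.loc[obs, c].to_numpy()
                else:
                    y_obs = df.loc[obs, c].to_numpy(dtype=float)
                try:
                    if method == "norm2l":
                        imp = _draw_norm(y_obs, X_obs, X_mis, rng, config.ridge)
                    elif method == "polr":
                        imp = _draw_polr(y_obs, X_obs, X_mis, rng)
                    elif method == "logreg":
                        imp = _draw_logreg(y_obs, X_obs, X_mis, rng)
                    else:
                        raise KeyError(f"unknown method {method!r} for {c}")
                except (np.linalg.LinAlgError, RuntimeError, ValueError) as exc:
                    if method not in ("norm2l", "polr"):
                        raise
                    fallback_log.append((chain, it, c, str(exc)))
                    imp = _draw_pmm(
                        y_obs, X_obs, X_mis, rng, config.ridge, config.pmm_donors
                    )
                df.loc[masks[c], c] = imp
                # refresh the cached item block so later items see the update
                inst = _ITEM_TO_INSTRUMENT.get(c)
                if inst is not None and inst in cache.item_blocks:
                    j = cache.item_pos[inst].get(c)
                    if j is not None:
                        cache.item_blocks[inst][masks[c], j] = np.asarray(imp, float)
                elif c in cache.slices and cache.explicit is None:
                    sl = cache.slices[c]
                    if sl.stop - sl.start == 1 and method != "logreg":
                        cache.base[masks[c], sl.start] = np.asarray(imp, float)
                if method != "logreg":
                    vals = np.asarray(imp, dtype=float)
                    trace_rows.append(
                        (
                            chain, it, c, float(np.mean(vals)),
                            float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
                        )
                    )
            if config.passive:
                df = passive_derive(df, config.passive_vars)
        if config.passive:
            df = passive_derive(df, config.passive_vars)
        datasets.append(df)
    traces = pd.DataFrame(
        trace_rows, columns=["chain", "iteration", "variable", "mean", "sd"]
    )
    return ImputedDatasets(datasets, traces, config, fallback_log)
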