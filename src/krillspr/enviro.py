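"""Environment-length stage: Pearson screening and a random-intercept LMM.

The response is cell-level mean krill length (one row per stratum x year x
month cell) and the linear predictor combines a stratum factor with sea-ice
concentration (SIC, %), sea-surface temperature (SST, degC), chlorophyll-a
(Chla, mg/m3) and the SST x Chla interaction; a random intercept per year
absorbs interannual variability:

    mean_length ~ C(stratum) + sic + sst + chla + sst:chla + (1 | year)

Estimation is restricted maximum likelihood for the single-variance-
component model: the variance ratio var_year/var_resid is profiled by
one-dimensional optimisation, with a generalised-least-squares solve for the
fixed effects at each candidate.  Confidence intervals and p-values use a
Wald t approximation with residual degrees of freedom n - p.

For ranking candidate mean structures, AIC/BIC are computed from the ML
log-likelihood evaluated at the REML estimates, because REML likelihoods are
not comparable across fixed-effect structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .biology import ParameterError

__all__ = [
    "UndefinedCorrelationError",
    "SingularDesignError",
    "ComparabilityError",
    "pearson_r",
    "LengthMixedLM",
    "LengthMixedLMResults",
    "CANDIDATE_FORMULAS",
    "fit_candidates",
    "rank_models",
]


class UndefinedCorrelationError(ValueError):
    """Pearson correlation undefined (zero variance or too few pairs)."""


class SingularDesignError(ValueError):
    """Fixed-effects design matrix is rank deficient."""


class ComparabilityError(ValueError):
    """Model fits are not on the same response rows."""


def pearson_r(x, y) -> tuple[float, float, float]:
    """Product-moment correlation with a two-sided t test on n - 2 df.

    Missing values are removed pairwise.  Returns ``(r, t, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise UndefinedCorrelationError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the inputs")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    if abs(r) >= 1.0:
        t = math.inf if r > 0 else -math.inf
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return r, float(t), float(p)


#: Candidate mean structures for the model-ranking stage (response is the
#: cell mean length; model 5 is the full structure used for inference).
CANDIDATE_FORMULAS = {
    "m1": "mean_length ~ C(stratum)",
    "m2": "mean_length ~ C(stratum) + sst",
    "m3": "mean_length ~ C(stratum) + sic + sst",
    "m4": "mean_length ~ C(stratum) + sic + sst + chla",
    "m5": "mean_length ~ C(stratum) + sic + sst + chla + sst:chla",
}


class LengthMixedLM:
    """Random-intercept linear mixed model fit by profiled REML.

    Parameters
    ----------
    endog : array_like
        Response vector (cell mean length, mm).
    exog : DataFrame or ndarray
        Fixed-effects design matrix including the intercept column.
    groups : array_like
        Grouping labels for the random intercept (year).
    """

    def __init__(self, endog, exog, groups, model_name: str = "lmm"):
        y = np.asarray(endog, dtype=float).ravel()
        if isinstance(exog, pd.DataFrame):
            self.exog_names = list(exog.columns)
            X = exog.to_numpy(dtype=float)
        else:
            X = np.asarray(exog, dtype=float)
            self.exog_names = [f"x{i}" for i in range(X.shape[1])]
        groups = np.asarray(groups)
        if not (len(y) == X.shape[0] == len(groups)):
            raise ParameterError("endog, exog and groups must have equal length")
        self._check_rank(X)
        self.endog = y
        self.exog = X
        self.group_labels, self.group_idx = np.unique(groups, return_inverse=True)
        self.model_name = model_name

    def _check_rank(self, X: np.ndarray) -> None:
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # name candidate aliased columns via pivoted QR
            from scipy.linalg import qr

            _, r, piv = qr(X, pivoting=True, mode="economic")
            diag = np.abs(np.diag(r))
            tol = diag.max() * max(X.shape) * np.finfo(float).eps
            aliased = [self.exog_names[piv[i]] if hasattr(self, "exog_names") else str(piv[i])
                       for i in range(X.shape[1]) if diag[i] < tol]
            raise SingularDesignError(
                f"design matrix is rank deficient; aliased columns: {aliased}"
            )

    @classmethod
    def from_formula(
        cls, formula: str, data: pd.DataFrame, groups: str = "year"
    ) -> "LengthMixedLM":
        """Build from a patsy formula for the fixed effects.

        The random intercept grouping is the ``groups`` column of ``data``.
        """
        y, X = patsy.dmatrices(formula, data, return_type="dataframe")
        model = cls(
            y.to_numpy().ravel(), X, data[groups].to_numpy(), model_name=formula
        )
        return model

    # -- REML machinery ----------------------------------------------------

    def _profile(self, lam: float):
        """GLS solve at variance ratio lam = var_year / var_resid."""
        y, X = self.endog, self.exog
        n, p = X.shape
        Z = np.zeros((n, self.group_labels.size))
        Z[np.arange(n), self.group_idx] = 1.0
        V = np.eye(n) + lam * (Z @ Z.T)
        c, low = cho_factor(V)
        Vi_y = cho_solve((c, low), y)
        Vi_X = cho_solve((c, low), X)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        r = y - X @ beta
        Vi_r = Vi_y - Vi_X @ beta
        quad = float(r @ Vi_r)
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise SingularDesignError("X' V^-1 X is not positive definite")
        sigma2 = quad / (n - p)
        # REML criterion (negative log restricted likelihood up to a constant)
        crit = 0.5 * ((n - p) * math.log(sigma2) + logdet_v + logdet_x)
        return {
            "beta": beta,
            "sigma2": sigma2,
            "quad": quad,
            "logdet_v": logdet_v,
            "logdet_x": logdet_x,
            "XtViX": XtViX,
            "Vi_r": Vi_r,
            "Z": Z,
            "crit": crit,
        }

    def fit(self) -> "LengthMixedLMResults":
        """Profile the variance ratio and return the fitted results."""
        n, p = self.exog.shape
        group_sizes = np.bincount(self.group_idx)
        identifiable = not np.all(group_sizes == 1)

        def crit(log_lam: float) -> float:
            return self._profile(math.exp(log_lam))["crit"]

        opt = minimize_scalar(crit, bounds=(-12.0, 12.0), method="bounded")
        best_log_lam = float(opt.x)
        # compare against the OLS boundary lam -> 0
        at_zero = self._profile(0.0)
        if at_zero["crit"] <= opt.fun + 1e-10:
            lam = 0.0
            prof = at_zero
            boundary = True
        else:
            lam = math.exp(best_log_lam)
            prof = self._profile(lam)
            boundary = lam < 1e-7
        sigma2 = prof["sigma2"]
        var_year = lam * sigma2
        cov_beta = sigma2 * np.linalg.inv(prof["XtViX"])
        bse = np.sqrt(np.diag(cov_beta))
        df_resid = n - p
        tvals = prof["beta"] / bse
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
        tcrit = stats.t.ppf(0.975, df_resid)

        # full REML log-likelihood (with constants) and ML log-likelihood at
        # the REML estimates, for reporting and cross-model ranking
        loglik_reml = -0.5 * (
            (n - p) * math.log(2 * math.pi * sigma2)
            + prof["logdet_v"]
            + prof["logdet_x"]
            - p * math.log(sigma2)
            + prof["quad"] / sigma2
        )
        loglik_ml = -0.5 * (
            n * math.log(2 * math.pi * sigma2)
            + prof["logdet_v"]
            + prof["quad"] / sigma2
        )
        k_params = p + 2  # fixed effects + two variance components
        aic = -2.0 * loglik_ml + 2.0 * k_params
        bic = -2.0 * loglik_ml + k_params * math.log(n)

        # conditional fit: BLUP random intercepts u = lam * Z' V^-1 r
        u = lam * (prof["Z"].T @ prof["Vi_r"])
        fitted = self.exog @ prof["beta"] + prof["Z"] @ u
        resid = self.endog - fitted
        rmse = float(np.sqrt(np.mean(resid**2)))
        ss_tot = float(np.sum((self.endog - self.endog.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan

        params = pd.Series(prof["beta"], index=self.exog_names)
        return LengthMixedLMResults(
            model=self,
            params=params,
            bse=pd.Series(bse, index=self.exog_names),
            tvalues=pd.Series(tvals, index=self.exog_names),
            pvalues=pd.Series(pvals, index=self.exog_names),
            ci_low=params - tcrit * bse,
            ci_high=params + tcrit * bse,
            var_year=float(var_year),
            var_resid=float(sigma2),
            loglik=float(loglik_reml),
            loglik_ml=float(loglik_ml),
            aic=float(aic),
            bic=float(bic),
            rmse=rmse,
            r2=float(r2),
            nobs=n,
            df_resid=df_resid,
            boundary=bool(boundary),
            identifiable=bool(identifiable),
            random_effects=pd.Series(u, index=self.group_labels),
            fitted=fitted,
        )


@dataclass(frozen=True)
class LengthMixedLMResults:
    """Fixed-effect estimates, Wald-t intervals, variance components, fit stats."""

    model: LengthMixedLM
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    var_year: float
    var_resid: float
    loglik: float
    loglik_ml: float
    aic: float
    bic: float
    rmse: float
    r2: float
    nobs: int
    df_resid: int
    boundary: bool
    identifiable: bool
    random_effects: pd.Series
    fitted: np.ndarray

    def conf_int(self) -> pd.DataFrame:
        return pd.DataFrame({"low": self.ci_low, "high": self.ci_high})

    def summary(self) -> str:
        head = [
            f"Random-intercept LMM (REML): {self.model.model_name}",
            f"nobs={self.nobs}  groups={self.random_effects.size}  "
            f"df_resid={self.df_resid}",
            f"var_year={self.var_year:.4f}  var_resid={self.var_resid:.4f}"
            + ("  [boundary]" if self.boundary else "")
            + ("" if self.identifiable else "  [NON-IDENTIFIABLE]"),
            f"loglik(REML)={self.loglik:.2f}  AIC={self.aic:.2f}  "
            f"BIC={self.bic:.2f}  RMSE={self.rmse:.3f}  R2={self.r2:.3f}",
            "-" * 72,
            f"{'term':<28}{'coef':>10}{'se':>9}{'t':>8}{'p':>9}"
            f"{'[0.025':>9}{'0.975]':>9}",
        ]
        body = [
            f"{name:<28}{self.params[name]:>10.4f}{self.bse[name]:>9.4f}"
            f"{self.tvalues[name]:>8.2f}{self.pvalues[name]:>9.4f}"
            f"{self.ci_low[name]:>9.4f}{self.ci_high[name]:>9.4f}"
            for name in self.params.index
        ]
        return "\n".join(head + body)


def fit_candidates(
    panel: pd.DataFrame,
    formulas: Optional[dict[str, str]] = None,
    groups: str = "year",
) -> dict[str, LengthMixedLMResults]:
    """Fit every candidate mean structure on one panel."""
    formulas = formulas or CANDIDATE_FORMULAS
    return {
        name: LengthMixedLM.from_formula(f, panel, groups=groups).fit()
        for name, f in formulas.items()
    }


def rank_models(fits: Sequence[LengthMixedLMResults]) -> pd.DataFrame:
    """Rank fitted models by AIC (ascending), ties broken by BIC.

    All fits must be on the same response rows; differing row sets raise a
    :class:`ComparabilityError`.
    """
    fits = list(fits)
    if not fits:
        raise ParameterError("need at least one fit to rank")
    ref = fits[0].model.endog
    for fit in fits[1:]:
        y = fit.model.endog
        if y.shape != ref.shape or not np.allclose(y, ref):
            raise ComparabilityError("fits are not on the same response rows")
    table = pd.DataFrame(
        {
            "model": [f.model.model_name for f in fits],
            "aic": [f.aic for f in fits],
            "bic": [f.bic for f in fits],
            "rmse": [f.rmse for f in fits],
            "r2": [f.r2 for f in fits],
        }
    )
    table = table.sort_values(["aic", "bic"], kind="mergesort").reset_index(drop=True)
    table.index = pd.RangeIndex(1, len(table) + 1, name="rank")
    return table
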