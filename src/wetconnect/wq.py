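"""Standardized mixed-effects assessment of wetland connectivity vs water quality.

This module links watershed percentages of the four connectivity classes
(Riparian, NRShw, NRMid, NRDeep) to in-stream constituent concentrations
with linear mixed-effects models whose slopes may vary randomly across
regions.  The quantity of interest is the *standardized population-mean
slope*: the fixed-effect coefficient on mean-0 / s.d.-1 scales, i.e. the
s.d. change in the response per one-s.d. change in the predictor, averaged
over region-specific random slopes.

The preparation pipeline runs in a fixed, logged order:

    censored-row removal -> response transform -> standardization ->
    VIF screen -> REML fit -> backward selection -> slope extraction

* **Censoring.** TSS, Al and NO3 carry zeros / detection-limit values that
  inflate the residual distribution; affected rows are removed (the limits
  must be declared per constituent — there is no automatic detection).
* **Transforms.** All responses are natural-log transformed except pH,
  which is raised to the fourth power (and is exempt from the positivity
  requirement of the log branch).
* **Backward selection** eliminates random slopes first (REML
  likelihood-ratio tests at alpha = 0.05; fixed structure held constant,
  so REML likelihoods are comparable), then non-class fixed covariates
  (ML refits, since REML likelihoods are not comparable across fixed
  structures).  The four wetland-class fixed effects are always retained
  so their slopes can be extracted even when not significant.  The random
  intercept by region is always retained.  Random-effect LRT p-values are
  used without a boundary correction (a documented simplification that
  makes those tests conservative).

Estimation uses REML via :class:`statsmodels...MixedLM`; random slopes
enter as independent variance components.

The module is organised statsmodels-style: build a
:class:`ConnectivityWQModel` from a site table, call :meth:`fit`, and read
estimates from the returned :class:`ConnectivityWQResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CLASS_PCT_COLS",
    "CONSTITUENTS",
    "CENSORED_CONSTITUENTS",
    "TransformError",
    "StandardizationError",
    "SingularityError",
    "ConvergenceError",
    "transform_response",
    "drop_censored",
    "standardize",
    "vif_screen",
    "simulate_wq",
    "analytic_response_sd",
    "ConnectivityWQModel",
    "ConnectivityWQResults",
    "select_grouping",
]

#: watershed class-percentage predictor columns, in connectivity order
CLASS_PCT_COLS = ["pct_Riparian", "pct_NRShw", "pct_NRMid", "pct_NRDeep"]

#: the eleven constituents and their functional groups
CONSTITUENTS = {
    "cond": "acidification", "Ca": "acidification", "Mg": "acidification",
    "Al": "acidification", "pH": "acidification", "ANC": "acidification",
    "DOC": "brownification", "colour": "brownification",
    "NO3": "eutrophication",
    "turb": "sedimentation", "TSS": "sedimentation",
}

#: constituents subject to censored-row removal
CENSORED_CONSTITUENTS = ("TSS", "Al", "NO3")

ALPHA = 0.05


class TransformError(ValueError):
    """Non-positive values reached the log transform; names offending rows."""


class StandardizationError(ValueError):
    """A column to standardize is constant."""


class SingularityError(ValueError):
    """Predictors are perfectly collinear."""


class ConvergenceError(RuntimeError):
    """A mixed-model fit failed to converge."""


# ---------------------------------------------------------------------------
# preparation pipeline
# ---------------------------------------------------------------------------

def transform_response(values: pd.Series | np.ndarray, constituent: str) -> np.ndarray:
    """ln(x) for every constituent except pH, which becomes pH**4."""
    arr = np.asarray(values, dtype=float)
    if constituent == "pH":
        return arr**4
    bad = np.flatnonzero(~(arr > 0))
    if bad.size:
        raise TransformError(
            f"{constituent}: non-positive values at rows {bad[:10].tolist()} "
            "cannot be log transformed (remove them upstream)"
        )
    return np.log(arr)


def drop_censored(
    data: pd.DataFrame,
    constituent: str,
    detection_limits: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Remove zero / detection-limit rows for TSS, Al and NO3.

    Other constituents pass through untouched.  Returns the filtered frame
    and the number of rows removed.
    """
    if constituent not in CENSORED_CONSTITUENTS:
        return data, 0
    values = data[constituent].astype(float)
    mask = values == 0
    limit = (detection_limits or {}).get(constituent)
    if limit is not None:
        mask |= np.isclose(values, limit)
    kept = data.loc[~mask]
    return kept, int(mask.sum())


def standardize(
    data: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(x - mean) / sd per column; returns the frame and a (mean, sd) ledger."""
    out = data.copy()
    ledger = []
    for col in columns:
        vals = out[col].astype(float)
        mean, sd = float(vals.mean()), float(vals.std(ddof=1))
        if not sd > 0:
            raise StandardizationError(f"column '{col}' is constant (sd = {sd})")
        out[col] = (vals - mean) / sd
        ledger.append({"column": col, "mean": mean, "sd": sd})
    return out, pd.DataFrame(ledger)


def vif_screen(predictors: pd.DataFrame, threshold: float = 2.0) -> tuple[pd.Series, bool]:
    """Variance inflation factors, VIF_j = 1 / (1 - R^2_j).

    ``R^2_j`` comes from regressing predictor j on all the others (with an
    intercept).  Returns the per-predictor VIFs and a flag that is True
    when any VIF reaches ``threshold`` (a warning sign, not fatal).
    Perfectly collinear predictors raise :class:`SingularityError`.
    """
    from statsmodels.stats.outliers_influence import variance_inflation_factor
    import statsmodels.api as sm

    if predictors.shape[1] < 2:
        raise ValueError("VIF needs at least two predictors")
    if predictors.shape[0] <= predictors.shape[1]:
        raise ValueError("VIF needs more rows than predictors")
    X = sm.add_constant(predictors.astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise SingularityError("predictors are perfectly collinear")
    vifs = pd.Series(
        [variance_inflation_factor(X.to_numpy(), i + 1)
         for i in range(predictors.shape[1])],
        index=list(predictors.columns),
        name="VIF",
    )
    return vifs, bool((vifs >= threshold).any())


# ---------------------------------------------------------------------------
# simulator
# ---------------------------------------------------------------------------

def simulate_wq(
    slopes: tuple[float, ...] = (0.4, 0.2, 0.1, -0.2),
    covariate_effects: tuple[float, ...] = (0.3,),
    random_intercept_sd: float = 0.3,
    random_slope_sd: tuple[float, ...] | float = 0.1,
    resid_sd: float = 0.7,
    n_sites: int = 1500,
    n_regions: int = 9,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a site table from the standardized mixed-model form.

    Class percentages are drawn right-skewed (beta-distributed, most
    watersheds holding little wetland of any one class, as in real
    watershed summaries) and covariates log-normally; both are
    standardized internally before building the linear predictor, so
    ``slopes`` act on mean-0/s.d.-1 predictors.  Region random intercepts
    and independent random slopes (one s.d. per class predictor) are
    Gaussian; the residual is Gaussian with ``resid_sd``.

    Returns the table (raw percentage / covariate columns, the response
    ``y``, and ``region``) plus a truth dict containing the generating
    parameters and the analytic standardized slopes
    ``beta / sd(y)`` that a pipeline standardizing the response estimates.
    """
    if n_sites < 50 or n_regions < 2:
        raise ValueError("need n_sites >= 50 and n_regions >= 2")
    rng = np.random.default_rng(seed)
    slopes = tuple(slopes)
    if isinstance(random_slope_sd, (int, float)):
        random_slope_sd = tuple(float(random_slope_sd) for _ in slopes)
    covariate_effects = tuple(covariate_effects)

    data = pd.DataFrame({"region": rng.integers(0, n_regions, size=n_sites)})
    X_std = {}
    for col in CLASS_PCT_COLS:
        raw = 100.0 * rng.beta(0.8, 8.0, size=n_sites)  # right-skewed 0-100%
        data[col] = raw
        X_std[col] = (raw - raw.mean()) / raw.std(ddof=1)
    cov_cols = [f"cov{i + 1}" for i in range(len(covariate_effects))]
    for col in cov_cols:
        raw = rng.lognormal(0.0, 1.0, size=n_sites)
        data[col] = raw
        X_std[col] = (raw - raw.mean()) / raw.std(ddof=1)

    region = data["region"].to_numpy()
    intercepts = rng.normal(0.0, random_intercept_sd, size=n_regions)
    y = intercepts[region].astype(float)
    for col, beta, sd_b in zip(CLASS_PCT_COLS, slopes, random_slope_sd):
        b_region = rng.normal(0.0, sd_b, size=n_regions)
        y += (beta + b_region[region]) * X_std[col]
    for col, beta in zip(cov_cols, covariate_effects):
        y += beta * X_std[col]
    y += rng.normal(0.0, resid_sd, size=n_sites)
    data["y"] = y

    sd_y = analytic_response_sd(
        slopes, covariate_effects, random_intercept_sd, random_slope_sd, resid_sd
    )
    truth = {
        "slopes": dict(zip(CLASS_PCT_COLS, slopes)),
        "covariate_effects": dict(zip(cov_cols, covariate_effects)),
        "random_intercept_sd": random_intercept_sd,
        "random_slope_sd": dict(zip(CLASS_PCT_COLS, random_slope_sd)),
        "resid_sd": resid_sd,
        "sd_y": sd_y,
        "slopes_std_response": {
            col: beta / sd_y for col, beta in zip(CLASS_PCT_COLS, slopes)
        },
    }
    return data, truth


def analytic_response_sd(
    slopes, covariate_effects, random_intercept_sd, random_slope_sd, resid_sd
) -> float:
    """s.d. of the simulated response under the generating model.

    Predictors are independent and standardized, so
    var(y) = sum(beta^2) + sigma_int^2 + sum(sigma_slope^2) + sigma_res^2.
    """
    if isinstance(random_slope_sd, (int, float)):
        random_slope_sd = tuple(float(random_slope_sd) for _ in slopes)
    var = (
        sum(b**2 for b in slopes)
        + sum(b**2 for b in covariate_effects)
        + random_intercept_sd**2
        + sum(s**2 for s in random_slope_sd)
        + resid_sd**2
    )
    return float(np.sqrt(var))


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

@dataclass
class SlopeEstimate:
    """Standardized population-mean slope for one wetland class."""

    class_name: str
    mean_slope: float
    se: float
    had_random_component: bool

    @property
    def significant(self) -> bool:
        """True iff mean_slope +/- 2*se excludes zero."""
        return abs(self.mean_slope) > 2.0 * self.se


class ConnectivityWQModel:
    """Mixed-effects model of one constituent on the four class percentages.

    Parameters
    ----------
    data : DataFrame
        Site table holding the response constituent, the four class
        percentage columns, any covariates, and the grouping column.
    response : str
        Constituent column name (drives the transform choice and censored
        handling).
    class_cols, covariates : lists of str
        Predictor columns; the four class columns are always retained as
        fixed effects during selection, covariates are removable.
    group_col : str
        Regional grouping factor for the random effects.
    detection_limits : dict, optional
        Declared detection-limit value per censored constituent.
    standardize_response : bool
        Standardize the (transformed) response as well as the predictors
        (the default; slopes then read as s.d.-per-s.d.).

    Examples
    --------
    >>> model = ConnectivityWQModel.from_dataframe(tbl, response="DOC")
    >>> res = model.fit()
    >>> res.slopes()  # one standardized mean slope per class
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        class_cols: list[str] | None = None,
        covariates: list[str] | None = None,
        group_col: str = "region",
        detection_limits: dict[str, float] | None = None,
        standardize_response: bool = True,
        transform: str | None = "auto",
        alpha: float = ALPHA,
    ) -> None:
        self.data = data
        self.response = response
        self.class_cols = list(class_cols) if class_cols is not None else list(CLASS_PCT_COLS)
        self.covariates = list(covariates) if covariates is not None else []
        self.group_col = group_col
        self.detection_limits = detection_limits or {}
        self.standardize_response = standardize_response
        # "auto": ln for known constituents (power4 for pH), none otherwise
        # (e.g. simulated responses already on model scale)
        if transform == "auto":
            if response == "pH":
                transform = "power4"
            elif response in CONSTITUENTS:
                transform = "ln"
            else:
                transform = None
        if transform not in (None, "ln", "power4"):
            raise ValueError(f"unknown transform '{transform}'")
        self.transform = transform
        self.alpha = alpha
        self.prep_report: dict = {}

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, **kwargs) -> "ConnectivityWQModel":
        """Build a model, auto-detecting ``cov*`` covariate columns."""
        covariates = kwargs.pop(
            "covariates",
            [c for c in data.columns if c.startswith("cov")],
        )
        return cls(data, response, covariates=covariates, **kwargs)

    # -- preparation ----------------------------------------------------
    def prepare(self) -> pd.DataFrame:
        """Run the fixed-order pipeline; returns the modelling frame."""
        predictors = self.class_cols + self.covariates
        needed = [self.response, self.group_col] + predictors
        work = self.data[needed].dropna().copy()

        work, n_censored = drop_censored(work, self.response, self.detection_limits)
        if self.transform == "power4":
            work[self.response] = transform_response(work[self.response], "pH")
        elif self.transform == "ln":
            # route through the ln branch regardless of the column name
            name = self.response if self.response != "pH" else "pH_as_ln"
            work[self.response] = transform_response(work[self.response], name)

        to_scale = list(predictors)
        if self.standardize_response:
            to_scale = [self.response] + to_scale
        work, ledger = standardize(work, to_scale)
        vifs, vif_flag = vif_screen(work[predictors])

        self.prep_report = {
            "order": ["drop_censored", "transform", "standardize", "vif"],
            "n_rows": len(work),
            "n_censored_removed": n_censored,
            "scaling_ledger": ledger,
            "vif": vifs,
            "vif_flag": vif_flag,
        }
        return work

    # -- fitting --------------------------------------------------------
    def _fit_mixed(self, frame, fixed, random_slopes, reml=True):
        """One MixedLM fit: random intercept + independent random slopes."""
        import statsmodels.formula.api as smf

        rhs = " + ".join(fixed) if fixed else "1"
        vc = {term: f"0 + {term}" for term in random_slopes}
        model = smf.mixedlm(
            f"Q('{self.response}') ~ {rhs}",
            data=frame,
            groups=frame[self.group_col],
            re_formula="1",
            vc_formula=vc or None,
        )
        last_exc: Exception | None = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # lbfgs is fastest but can report an infinite likelihood at the
            # zero-variance boundary; fall back to sturdier optimizers
            for method in ("lbfgs", "bfgs", "powell"):
                try:
                    fit = model.fit(reml=reml, method=method, maxiter=500)
                except (np.linalg.LinAlgError, ValueError) as exc:
                    last_exc = exc
                    continue
                if np.isfinite(fit.llf):
                    return fit
        raise ConvergenceError(
            f"{self.response}: mixed fit failed"
            + (f": {last_exc}" if last_exc else " (non-finite likelihood)")
        )

    def fit(
        self,
        backward_select: bool = True,
        maximal_random: bool = True,
        reml: bool = True,
    ) -> "ConnectivityWQResults":
        """Prepare the data, fit, and (optionally) backward-select.

        The maximal model carries a random intercept plus one independent
        random slope per predictor (classes and covariates).  Selection
        removes random slopes first (REML LRTs), then non-class fixed
        covariates (ML LRTs), one least-significant term per round at
        ``alpha``; the class fixed effects and the random intercept are
        never candidates.  A term whose reduced fit fails to converge is
        skipped with a note in the trace.
        """
        frame = self.prepare()
        fixed = self.class_cols + self.covariates
        random_slopes = list(fixed) if maximal_random else []
        trace: list[dict] = []

        fit = self._fit_mixed(frame, fixed, random_slopes, reml=reml)

        if backward_select:
            # phase 1: random slopes, REML LRTs (fixed structure constant)
            while random_slopes:
                pvals = {}
                for term in random_slopes:
                    reduced_terms = [t for t in random_slopes if t != term]
                    try:
                        reduced = self._fit_mixed(frame, fixed, reduced_terms, reml=True)
                    except ConvergenceError as exc:
                        trace.append({"phase": "random", "term": term,
                                      "action": "skipped", "note": str(exc)})
                        continue
                    lrt = max(0.0, 2.0 * (fit.llf - reduced.llf))
                    pvals[term] = stats.chi2.sf(lrt, df=1)
                if not pvals:
                    break
                worst = max(pvals, key=pvals.get)
                if pvals[worst] <= self.alpha:
                    break
                random_slopes.remove(worst)
                trace.append({"phase": "random", "term": worst,
                              "action": "removed", "p": pvals[worst]})
                fit = self._fit_mixed(frame, fixed, random_slopes, reml=True)

            # phase 2: fixed covariates, ML refits (classes never removed)
            removable = [c for c in fixed if c not in self.class_cols]
            while removable:
                full_ml = self._fit_mixed(frame, fixed, random_slopes, reml=False)
                pvals = {}
                for term in removable:
                    reduced_fixed = [t for t in fixed if t != term]
                    reduced_random = [t for t in random_slopes if t != term]
                    try:
                        reduced = self._fit_mixed(
                            frame, reduced_fixed, reduced_random, reml=False
                        )
                    except ConvergenceError as exc:
                        trace.append({"phase": "fixed", "term": term,
                                      "action": "skipped", "note": str(exc)})
                        continue
                    lrt = max(0.0, 2.0 * (full_ml.llf - reduced.llf))
                    pvals[term] = stats.chi2.sf(lrt, df=1)
                if not pvals:
                    break
                worst = max(pvals, key=pvals.get)
                if pvals[worst] <= self.alpha:
                    break
                fixed.remove(worst)
                removable.remove(worst)
                if worst in random_slopes:
                    random_slopes.remove(worst)
                trace.append({"phase": "fixed", "term": worst,
                              "action": "removed", "p": pvals[worst]})
            fit = self._fit_mixed(frame, fixed, random_slopes, reml=reml)

        assert all(c in fixed for c in self.class_cols)
        return ConnectivityWQResults(
            model=self, result=fit, frame=frame,
            fixed_terms=list(fixed), random_slope_terms=list(random_slopes),
            selection_trace=trace,
        )


@dataclass
class ConnectivityWQResults:
    """Fitted connectivity/water-quality model.

    ``params`` / ``bse`` expose the standardized fixed-effect estimates
    and their standard errors; :meth:`slopes` returns the four class
    slopes with the 2-standard-error significance rule applied;
    :meth:`summary` prints a compact table.  ``aic`` comes from the ML
    refit (AIC is not meaningful on REML likelihoods across models).
    """

    model: ConnectivityWQModel
    result: object  # statsmodels MixedLMResults (REML)
    frame: pd.DataFrame
    fixed_terms: list[str]
    random_slope_terms: list[str]
    selection_trace: list[dict] = field(default_factory=list)
    _ml_cache: object = field(default=None, repr=False)

    @property
    def ml_result(self):
        """ML refit of the selected structure (lazy; used for AIC)."""
        if self._ml_cache is None:
            self._ml_cache = self.model._fit_mixed(
                self.frame, self.fixed_terms, self.random_slope_terms, reml=False
            )
        return self._ml_cache

    @property
    def params(self) -> pd.Series:
        return self.result.fe_params

    @property
    def bse(self) -> pd.Series:
        with warnings.catch_warnings():
            # cov_params can carry tiny negative diagonals at variance
            # boundaries; the affected entries come back NaN
            warnings.simplefilter("ignore", RuntimeWarning)
            return self.result.bse_fe

    @property
    def llf(self) -> float:
        return float(self.result.llf)

    @property
    def aic(self) -> float:
        # params covers fixed effects + random-effect (co)variances; +1 for
        # the residual variance, which statsmodels profiles out
        k = len(self.ml_result.params) + 1
        return float(-2.0 * self.ml_result.llf + 2.0 * k)

    @property
    def random_effect_variances(self) -> pd.Series:
        res = self.result
        out = {"intercept": float(res.cov_re.iloc[0, 0])} if res.cov_re.size else {}
        if getattr(res, "vcomp", None) is not None and len(res.vcomp):
            for name, v in zip(res.model.exog_vc.names, res.vcomp):
                out[name] = float(v)
        return pd.Series(out, name="variance")

    def _term_name(self, col: str) -> str:
        # formula interface may quote odd column names
        for cand in (col, f"Q('{col}')"):
            if cand in self.params.index:
                return cand
        raise KeyError(col)

    def slopes(self) -> pd.DataFrame:
        """Standardized population-mean slope per wetland class.

        ``significant`` applies the two-standard-error rule: the interval
        mean_slope +/- 2*se must exclude zero.  A slope of 0.5 reads as a
        half-s.d. response change per one-s.d. predictor change.
        """
        rows = []
        for col in self.model.class_cols:
            name = self._term_name(col)
            est = SlopeEstimate(
                class_name=col.removeprefix("pct_"),
                mean_slope=float(self.params[name]),
                se=float(self.bse[name]),
                had_random_component=col in self.random_slope_terms,
            )
            rows.append({
                "class": est.class_name,
                "mean_slope": est.mean_slope,
                "se": est.se,
                "significant": est.significant,
                "had_random_component": est.had_random_component,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Connectivity water-quality model: {self.model.response}",
            f"  n sites: {len(self.frame)}   groups: "
            f"{self.frame[self.model.group_col].nunique()} "
            f"({self.model.group_col})",
            f"  fixed terms: {', '.join(self.fixed_terms)}",
            "  random: intercept"
            + (f" + slopes({', '.join(self.random_slope_terms)})"
               if self.random_slope_terms else ""),
            f"  REML llf: {self.llf:.2f}   AIC (ML): {self.aic:.2f}",
            "",
            self.slopes().to_string(index=False, float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)

    def plot_slopes(self, ax=None):
        """Dot-and-interval plot of the class mean slopes (+/- 2 se)."""
        import matplotlib.pyplot as plt

        slopes = self.slopes()
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        x = np.arange(len(slopes))
        for i, row in slopes.iterrows():
            filled = "o" if row["significant"] else "o"
            ax.errorbar(
                x[i], row["mean_slope"], yerr=2 * row["se"], fmt=filled,
                mfc="black" if row["significant"] else "white", color="black",
                capsize=3,
            )
        ax.axhline(0.0, ls="--", lw=0.8, color="grey")
        ax.set_xticks(x, slopes["class"])
        ax.set_ylabel("standardized mean slope")
        ax.set_title(self.model.response)
        return ax


def select_grouping(
    data: pd.DataFrame,
    response: str,
    groupings: list[str],
    **model_kwargs,
) -> tuple[str, pd.DataFrame]:
    """Choose the grouping variable by minimal AIC (ML fits).

    Fits the same model under each candidate grouping column and returns
    the winner plus the full AIC table.
    """
    if not groupings:
        raise ValueError("need at least one candidate grouping")
    rows = []
    for group_col in groupings:
        model = ConnectivityWQModel.from_dataframe(
            data, response, group_col=group_col, **model_kwargs
        )
        res = model.fit(backward_select=False)
        rows.append({"grouping": group_col, "aic": res.aic})
    table = pd.DataFrame(rows)
    best = table.loc[table["aic"].idxmin(), "grouping"]
    return str(best), table
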