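"""Mixed-model inference on sweep output.

Two questions drive the models: does a metric's value depend on the number
of traits used to compute it, and — holding the trait number at four — on
how correlated those traits are? Both are fitted as

    metric ~ polynomial(predictor, degree)  +  (1 | plot)

for degree 1..4 by maximum likelihood (ML, not REML, so AIC is comparable
across fixed-effect structures), with the minimum-AIC degree selected and
ties broken toward the lower degree. The random plot intercept absorbs the
repeated measures each plot contributes across trait subsets. p-values are
adjusted across a model family with the Benjamini-Hochberg step-up rule.

The entry points follow the statsmodels convention: build a model object
from data, call ``fit()``, read estimates off the returned results object.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

PREDICTORS = ("k", "min_corr", "max_corr", "mean_corr")


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sort ascending, set q_(i) = min_{j >= i} m * p_(j) / j capped at 1, and
    return the adjusted values in the original order. Controls the false
    discovery rate at the level at which the adjusted values are thresholded.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D array of p-values")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


@dataclass
class ModelFit:
    """One fitted polynomial mixed model (a single degree)."""

    response: str
    predictor: str
    degree: int
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    re_variance: float
    llf: float
    aic: float
    n_obs: int
    n_groups: int
    lr_pvalue: float            # likelihood-ratio test vs intercept-only
    adj_pvalue: float | None = None
    x_center: float = 0.0

    @property
    def n_params(self) -> int:
        # fixed effects + random-intercept variance (if any) + residual variance
        return len(self.params) + (1 if self.n_groups > 1 else 0) + 1

    def predict(self, x: np.ndarray) -> np.ndarray:
        xc = np.asarray(x, dtype=float) - self.x_center
        return sum(
            self.params.iloc[p] * xc**p for p in range(self.degree + 1)
        )


def _design(x: np.ndarray, degree: int) -> tuple[np.ndarray, list[str]]:
    cols = np.column_stack([x**p for p in range(degree + 1)])
    names = ["Intercept"] + [f"x^{p}" for p in range(1, degree + 1)]
    return cols, names


def _fit_one(
    data: pd.DataFrame, response: str, predictor: str, group: str, degree: int
) -> ModelFit:
    y = data[response].to_numpy(dtype=float)
    x = data[predictor].to_numpy(dtype=float)
    center = float(x.mean())
    xmat, names = _design(x - center, degree)
    groups = data[group].to_numpy()
    n_groups = len(np.unique(groups))

    def _null_llf() -> float:
        x0, _ = _design(x - center, 0)
        if n_groups > 1:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return sm.MixedLM(y, x0, groups=groups).fit(reml=False).llf
        return sm.OLS(y, x0).fit().llf

    if n_groups > 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(y, xmat, groups=groups).fit(reml=False)
        if not res.converged:
            # boundary solutions (RE variance ~ 0) report non-convergence but
            # are valid ML fits; only reject if the likelihood is unusable
            logger.debug("degree-%d fit stopped at a boundary", degree)
        if not np.isfinite(res.llf):
            raise RuntimeError(f"degree-{degree} mixed fit failed")
        params = pd.Series(res.fe_params, index=names)
        bse = pd.Series(np.asarray(res.bse_fe), index=names)
        pvals = pd.Series(
            2 * stats.norm.sf(np.abs(params / bse.replace(0, np.nan))), index=names
        )
        re_var = float(np.asarray(res.cov_re).ravel()[0])
        llf = float(res.llf)
    else:
        # single plot: no grouping left, degrade to OLS
        res = sm.OLS(y, xmat).fit()
        params = pd.Series(res.params, index=names)
        bse = pd.Series(res.bse, index=names)
        pvals = pd.Series(res.pvalues, index=names)
        re_var = 0.0
        llf = float(res.llf)

    if not np.isfinite(params).all():
        raise RuntimeError(f"degree-{degree} fit is singular")
    n_params = len(params) + (1 if n_groups > 1 else 0) + 1
    aic = 2.0 * n_params - 2.0 * llf
    lr = max(0.0, 2.0 * (llf - _null_llf()))
    lr_p = float(stats.chi2.sf(lr, df=degree)) if degree > 0 else 1.0
    return ModelFit(
        response=response,
        predictor=predictor,
        degree=degree,
        params=params,
        bse=bse,
        pvalues=pvals,
        re_variance=re_var,
        llf=llf,
        aic=aic,
        n_obs=len(y),
        n_groups=n_groups,
        lr_pvalue=lr_p,
        x_center=center,
    )


class MetricTrendModel:
    """metric ~ polynomial(predictor) with a per-plot random intercept.

    Parameters
    ----------
    data : DataFrame
        One row per observation with the response, predictor and grouping
        columns present and no missing values in them.
    response, predictor, group : str
        Column names; ``group`` identifies the plot for the random intercept.
    degrees : sequence of int
        Polynomial degrees to fit and compare by AIC (default 1..4).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        predictor: str,
        group: str = "plot_key",
        degrees=(1, 2, 3, 4),
    ):
        cols = [response, predictor, group]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise KeyError(f"columns missing from data: {missing}")
        df = data.dropna(subset=[response, predictor]).copy()
        if df.empty:
            raise ValueError("no complete observations to fit")
        if df[predictor].nunique() < 2:
            raise ValueError(f"predictor {predictor!r} has no variance")
        self.data = df
        self.response = response
        self.predictor = predictor
        self.group = group
        self.degrees = tuple(degrees)

    def fit(self) -> "MetricTrendResults":
        fits: list[ModelFit] = []
        for deg in self.degrees:
            if self.data[self.predictor].nunique() <= deg:
                logger.warning(
                    "degree %d skipped: only %d distinct predictor values",
                    deg, self.data[self.predictor].nunique(),
                )
                continue
            try:
                fits.append(
                    _fit_one(
                        self.data, self.response, self.predictor,
                        self.group, deg,
                    )
                )
            except Exception as exc:
                logger.warning("degree %d skipped: %s", deg, exc)
        if not fits:
            raise RuntimeError("no polynomial degree could be fitted")
        return MetricTrendResults(self, fits)


class MetricTrendResults:
    """Fits at every degree plus the AIC-selected one.

    ``selected`` is the minimum-AIC fit, ties (within 1e-6) broken toward
    the lower degree. ``summary()`` renders a compact comparison plus the
    selected model's coefficient table.
    """

    def __init__(self, model: MetricTrendModel, fits: list[ModelFit]):
        self.model = model
        self.fits = sorted(fits, key=lambda f: f.degree)
        self.selected = min(self.fits, key=lambda f: (round(f.aic, 6), f.degree))

    @property
    def aic_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "degree": [f.degree for f in self.fits],
                "aic": [f.aic for f in self.fits],
                "llf": [f.llf for f in self.fits],
                "lr_pvalue": [f.lr_pvalue for f in self.fits],
                "selected": [f is self.selected for f in self.fits],
            }
        )

    @property
    def params(self) -> pd.Series:
        return self.selected.params

    @property
    def bse(self) -> pd.Series:
        return self.selected.bse

    def predict(self, x) -> np.ndarray:
        return self.selected.predict(np.asarray(x, dtype=float))

    def summary(self) -> str:
        s = self.selected
        lines = [
            f"Metric trend model: {s.response} ~ poly({s.predictor}, "
            f"degree={s.degree}) + (1 | {self.model.group})",
            f"n_obs = {s.n_obs}, groups = {s.n_groups}, "
            f"RE variance = {s.re_variance:.4g}",
            "",
            "AIC comparison:",
            self.aic_table.to_string(index=False, float_format="%.3f"),
            "",
            "Selected coefficients (predictor centred at "
            f"{s.x_center:.3f}):",
        ]
        coef = pd.DataFrame(
            {"estimate": s.params, "se": s.bse, "p": s.pvalues}
        )
        lines.append(coef.to_string(float_format="%.4g"))
        lines.append(
            f"LR test vs intercept-only: p = {s.lr_pvalue:.4g}"
            + (
                f" (BH-adjusted {s.adj_pvalue:.4g})"
                if s.adj_pvalue is not None
                else ""
            )
        )
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Observed values and the selected polynomial, for diagnostics."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.model.data
        ax.scatter(
            df[self.model.predictor], df[self.model.response],
            s=8, alpha=0.3, label="observations",
        )
        grid = np.linspace(
            df[self.model.predictor].min(), df[self.model.predictor].max(), 200
        )
        ax.plot(grid, self.predict(grid), color="C3",
                label=f"degree {self.selected.degree}")
        ax.set_xlabel(self.model.predictor)
        ax.set_ylabel(self.model.response)
        ax.legend()
        return ax


def _plot_key(df: pd.DataFrame) -> pd.Series:
    return df["study"].astype(str) + "/" + df["plot"].astype(str)


class TraitNumberModel(MetricTrendModel):
    """How a metric changes with the number of traits used to compute it."""

    @classmethod
    def from_sweep(
        cls,
        sweep: pd.DataFrame,
        metric: str,
        distance: str | None = None,
        k_range: tuple[int, int] | None = None,
        degrees=(1, 2, 3, 4),
    ) -> "TraitNumberModel":
        df = sweep[sweep["metric"] == metric].copy()
        if distance is not None:
            df = df[df["distance"] == distance]
        if k_range is not None:
            df = df[(df["k"] >= k_range[0]) & (df["k"] <= k_range[1])]
        if df["k"].nunique() < 2:
            raise ValueError("need at least 2 distinct trait numbers")
        df["plot_key"] = _plot_key(df)
        return cls(df, response="value", predictor="k", group="plot_key",
                   degrees=degrees)


class TraitCorrelationModel(MetricTrendModel):
    """How a metric at fixed trait number responds to trait correlation.

    Joins 4-trait sweep records to their correlation summaries and regresses
    the metric on the chosen summary (min_corr, max_corr or mean_corr).
    """

    @classmethod
    def from_sweep(
        cls,
        sweep: pd.DataFrame,
        correlations: pd.DataFrame,
        metric: str,
        predictor: str = "mean_corr",
        distance: str | None = None,
        degrees=(1, 2, 3, 4),
        min_subsets: int = 10,
    ) -> "TraitCorrelationModel":
        if predictor not in ("min_corr", "max_corr", "mean_corr"):
            raise ValueError(f"unknown correlation predictor {predictor!r}")
        df = sweep[(sweep["metric"] == metric) & (sweep["k"] == 4)].copy()
        if distance is not None:
            df = df[df["distance"] == distance]
        df = df.merge(correlations, on="subset", how="inner")
        if df["subset"].nunique() < min_subsets:
            raise ValueError(
                f"only {df['subset'].nunique()} 4-trait subsets with "
                f"correlations; need >= {min_subsets}"
            )
        df["plot_key"] = _plot_key(df)
        return cls(df, response="value", predictor=predictor, group="plot_key",
                   degrees=degrees)


def adjust_family(results: list[MetricTrendResults]) -> pd.DataFrame:
    """BH-adjust the selected models' LR p-values across one family of tests.

    The family is whatever list of fitted results one analysis run produced
    (every metric x predictor combination of a pipeline pass). Adjusted
    p-values are written back onto each ``selected`` fit and returned as a
    table.
    """
    raw = np.array([r.selected.lr_pvalue for r in results])
    adj = benjamini_hochberg(raw)
    rows = []
    for r, a in zip(results, adj):
        r.selected.adj_pvalue = float(a)
        rows.append(
            {
                "response": r.selected.response,
                "metric": r.model.data["metric"].iloc[0]
                if "metric" in r.model.data else r.selected.response,
                "predictor": r.selected.predictor,
                "degree": r.selected.degree,
                "aic": r.selected.aic,
                "p_raw": r.selected.lr_pvalue,
                "p_adj": float(a),
                "n": r.selected.n_obs,
            }
        )
    return pd.DataFrame(rows)
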