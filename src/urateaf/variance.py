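"""Variance decomposition of serum urate on dichotomized exposures.

Multivariable ordinary least squares of continuous serum urate (mmol/L)
on the 0/1 exposure matrix; per exposure it reports the adjusted beta
(urate difference between risk groups), its t-based 95% CI, and the
percent variance explained as a partial R-squared.

Two variance-share definitions are available:

``partial`` (default)
    (SSE_without - SSE_with) / SSE_without — proportional reduction in
    residual sum of squares when the exposure enters the otherwise-full
    model; equals the squared partial correlation.
``semipartial``
    (SSE_without - SSE_with) / SST — share of the *total* outcome
    variance; for mutually orthogonal predictors these shares sum to
    the model R-squared.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .af import CollinearityError, _check_rank
from .coding import BinaryDesign

__all__ = ["UrateVarianceModel", "UrateVarianceResults"]


class UrateVarianceModel:
    """OLS model of serum urate on binary exposures."""

    def __init__(self, design: BinaryDesign, exposures: list[str] | None = None):
        if design.urate is None:
            raise ValueError("design carries no continuous urate column")
        self.design = design
        self.exposures = list(exposures) if exposures is not None \
            else list(design.exposures.columns)
        p = len(self.exposures)
        if design.n < p + 2:
            raise ValueError(f"need at least p+2={p + 2} rows, have {design.n}")

    def fit(self) -> "UrateVarianceResults":
        X = sm.add_constant(
            self.design.exposures[self.exposures].to_numpy(dtype=float),
            has_constant="add")
        _check_rank(X, self.exposures)
        y = self.design.urate.to_numpy(dtype=float)
        res = sm.OLS(y, X).fit()
        return UrateVarianceResults(self, res, X, y)


class UrateVarianceResults:
    def __init__(self, model: UrateVarianceModel, smres, X, y):
        self.model = model
        self._res = smres
        self._X, self._y = X, y
        self.exposures = model.exposures
        self.params = pd.Series(smres.params, index=["const"] + self.exposures)
        self.bse = pd.Series(smres.bse, index=self.params.index)
        self.df_resid = int(smres.df_resid)
        self.sse = float(smres.ssr)
        self.sst = float(smres.centered_tss)
        self.rsquared = float(smres.rsquared)

    def beta(self, exposure: str) -> tuple[float, tuple[float, float]]:
        """Adjusted urate difference between risk groups (mmol/L), 95% CI."""
        b, se = self.params[exposure], self.bse[exposure]
        t = stats.t.ppf(0.975, self.df_resid)
        return float(b), (float(b - t * se), float(b + t * se))

    def _sse_without(self, exposure: str) -> float:
        keep = [0] + [i + 1 for i, e in enumerate(self.exposures) if e != exposure]
        res = sm.OLS(self._y, self._X[:, keep]).fit()
        return float(res.ssr)

    def partial_r2(self, exposure: str, kind: str = "partial") -> float:
        """Percent variance explained by one exposure (see module doc)."""
        if exposure not in self.exposures:
            raise KeyError(exposure)
        sse_w = self._sse_without(exposure)
        if kind == "partial":
            return 100.0 * (sse_w - self.sse) / sse_w
        if kind == "semipartial":
            return 100.0 * (sse_w - self.sse) / self.sst
        raise ValueError(f"unknown kind {kind!r}")

    def variance_table(self, kind: str = "partial") -> pd.DataFrame:
        """Report frame: adjusted beta (95% CI) and partial R^2 (%)."""
        rows = []
        for e in self.exposures:
            b, (lo, hi) = self.beta(e)
            rows.append({"exposure": e, "beta": b, "beta_lo": lo, "beta_hi": hi,
                         "partial_r2_pct": self.partial_r2(e, kind=kind)})
        return pd.DataFrame(rows).set_index("exposure")

    def summary(self) -> str:
        tab = self.variance_table()
        return "\n".join([
            "Serum-urate variance model (multivariable OLS)",
            f"  n = {len(self._y)}  R^2 = {self.rsquared:.4f}",
            "",
            tab.round(4).to_string(),
        ])
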