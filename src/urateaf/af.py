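"""Attributable-fraction engine.

Fits the multivariable logistic model of hyperuricaemia on the coded
exposures and derives, per exposure:

* adjusted odds ratio (Wald 95% CI);
* population attributable fraction,
  ``PAF = f_cases * (OR - 1) / OR`` with the fully adjusted OR and the
  exposure frequency among cases;
* average attributable fraction, the Shapley value of the model-based
  counterfactual attributable fraction over all removal orderings of
  the modelled exposures (exact by subset enumeration for k <= 9,
  Monte-Carlo permutation sampling otherwise);
* nonparametric bootstrap confidence intervals obtained by resampling
  individuals and refitting the whole pipeline.

The counterfactual AF of a set S of exposures is
``AF(S) = (Pbar - Pbar0) / Pbar`` where Pbar is the mean fitted case
probability on the observed design and Pbar0 the mean fitted
probability after setting every exposure in S to zero for everyone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .coding import BinaryDesign, DegenerateDesignError

__all__ = [
    "SeparationError",
    "CollinearityError",
    "compute_paf",
    "compute_paf_per_allele",
    "AttributableFractionModel",
    "AFResults",
    "AFResult",
    "bootstrap_intervals",
    "stratified_af",
    "per_allele_paf_table",
]

Z975 = 1.959963984540054


class SeparationError(RuntimeError):
    """Logistic fit failed to converge / perfectly separated."""


class CollinearityError(ValueError):
    """Exposure matrix is rank deficient."""


# ------------------------------ PAF formula -------------------------------

def compute_paf(f_cases: float, or_hat: float) -> float:
    """Population attributable fraction from the exposure frequency among
    cases and the (adjusted) odds ratio: ``f_cases * (OR - 1) / OR``.

    Negative values (protective exposures, OR < 1) are returned as-is.
    """
    if not 0.0 <= f_cases <= 1.0:
        raise ValueError(f"f_cases must lie in [0, 1], got {f_cases}")
    if not np.isfinite(or_hat) or or_hat <= 0.0:
        raise ValueError(f"odds ratio must be finite and > 0, got {or_hat}")
    return f_cases * (or_hat - 1.0) / or_hat


def compute_paf_per_allele(freq_risk_allele_cases: float,
                           or_per_allele: float) -> float:
    """Per-allele PAF under the additive model: same formula with the
    risk-allele frequency among case chromosomes."""
    return compute_paf(freq_risk_allele_cases, or_per_allele)


# ------------------------------ model fit ---------------------------------

def _check_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise CollinearityError naming offending columns (constant or
    linearly dependent exposures)."""
    const = [n for n, col in zip(names, X[:, 1:].T) if np.ptp(col) == 0]
    if const:
        raise CollinearityError(f"constant exposure column(s): {const}")
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify dependent columns via QR pivots
        _, R, piv = _qr_pivot(X)
        bad = sorted(piv[r:])
        labels = ["const"] + names
        raise CollinearityError(
            "collinear exposure column(s): "
            f"{[labels[i] for i in bad if i > 0] or [labels[i] for i in bad]}")


def _qr_pivot(X):
    from scipy.linalg import qr
    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, list(piv)


@dataclass
class AFResult:
    """One attributable-fraction report row for a single exposure."""
    exposure: str
    or_hat: float
    or_ci: tuple[float, float]
    f_cases: float
    paf: float
    paf_ci: tuple[float, float] | None = None
    aaf: float | None = None
    aaf_ci: tuple[float, float] | None = None
    model_scope: tuple[str, ...] = ()
    stratum: str | None = None


class AttributableFractionModel:
    """Multivariable logistic model of hyperuricaemia on binary exposures.

    Parameters
    ----------
    design : BinaryDesign
        Coded outcome + exposure matrix from :func:`urateaf.coding.dichotomize`.
    exposures : list of str, optional
        Subset/ordering of exposure columns to model (default: all).
    """

    def __init__(self, design: BinaryDesign, exposures: list[str] | None = None):
        self.design = design
        self.exposures = list(exposures) if exposures is not None \
            else list(design.exposures.columns)
        if design.n_cases == 0 or design.n_controls == 0:
            raise DegenerateDesignError("need at least one case and one control")

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame, specs, hu_threshold: float = 0.42,
                    **kw) -> "AttributableFractionModel":
        from .coding import dichotomize
        return cls(dichotomize(cohort, specs, hu_threshold=hu_threshold), **kw)

    def fit(self, maxiter: int = 100, tol: float = 1e-10) -> "AFResults":
        X = sm.add_constant(
            self.design.exposures[self.exposures].to_numpy(dtype=float),
            has_constant="add")
        y = self.design.outcome.to_numpy(dtype=float)
        _check_rank(X, self.exposures)
        model = sm.Logit(y, X)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", category=RuntimeWarning)
                res = model.fit(method="newton", maxiter=maxiter, tol=tol, disp=0)
        except Exception as exc:  # PerfectSeparation or numeric failure
            raise SeparationError(
                f"logistic fit failed for exposures {self.exposures}: {exc}"
            ) from exc
        if not res.mle_retvals.get("converged", False):
            raise SeparationError(
                f"logistic fit did not converge for exposures {self.exposures}")
        if np.max(np.abs(res.params[1:]), initial=0.0) > 15:
            raise SeparationError(
                "quasi-separation: implausibly large coefficient for exposure "
                f"{self.exposures[int(np.argmax(np.abs(res.params[1:])))]}")
        return AFResults(self, res)


class AFResults:
    """Fitted attributable-fraction model: adjusted ORs, PAFs, AAFs."""

    def __init__(self, model: AttributableFractionModel, smres):
        self.model = model
        self._res = smres
        self.exposures = model.exposures
        self.design = model.design
        self.converged = bool(smres.mle_retvals.get("converged", False))
        self.params = pd.Series(smres.params, index=["const"] + self.exposures)
        self.bse = pd.Series(smres.bse, index=self.params.index)
        self.cov_params = pd.DataFrame(
            smres.cov_params(), index=self.params.index, columns=self.params.index)
        self._af_cache: dict[frozenset, float] = {}

    # -- odds ratios --------------------------------------------------------

    def odds_ratio(self, exposure: str) -> tuple[float, tuple[float, float]]:
        beta, se = self.params[exposure], self.bse[exposure]
        return float(np.exp(beta)), (float(np.exp(beta - Z975 * se)),
                                     float(np.exp(beta + Z975 * se)))

    def odds_ratios(self) -> pd.DataFrame:
        rows = []
        for e in self.exposures:
            or_, (lo, hi) = self.odds_ratio(e)
            rows.append({"exposure": e, "OR": or_, "OR_lo": lo, "OR_hi": hi})
        return pd.DataFrame(rows).set_index("exposure")

    # -- counterfactual prediction ------------------------------------------

    def _predict(self, X_exp: np.ndarray) -> np.ndarray:
        eta = self.params.iloc[0] + X_exp @ self.params.iloc[1:].to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    def predict(self, exposures: pd.DataFrame | None = None) -> np.ndarray:
        """Fitted case probabilities on the given (or observed) design."""
        if exposures is None:
            exposures = self.design.exposures
        return self._predict(exposures[self.exposures].to_numpy(dtype=float))

    def combined_af(self, removed) -> float:
        """Attributable fraction of jointly removing a set of exposures:
        ``(Pbar - Pbar0) / Pbar`` with the removed columns set to 0."""
        removed = frozenset(removed)
        unknown = removed - set(self.exposures)
        if unknown:
            raise KeyError(f"not modelled exposures: {sorted(unknown)}")
        if removed in self._af_cache:
            return self._af_cache[removed]
        X = self.design.exposures[self.exposures].to_numpy(dtype=float).copy()
        p_bar = float(self._predict(X).mean())
        for i, e in enumerate(self.exposures):
            if e in removed:
                X[:, i] = 0.0
        p0_bar = float(self._predict(X).mean())
        af = (p_bar - p0_bar) / p_bar
        self._af_cache[removed] = af
        return af

    # -- average attributable fractions --------------------------------------

    def average_af(self, exposures: list[str] | None = None,
                   mode: str = "exact", n_perm: int = 2000,
                   seed: int = 0) -> dict[str, float]:
        """Average attributable fraction per exposure.

        The sequential AF of exposure e after the set S is
        ``AF(S + {e}) - AF(S)``; the AAF averages it over removal
        orderings.  ``exact`` enumerates all orderings via the Shapley
        subset formula (k <= 9, 2**k model-prediction passes);
        ``monte_carlo`` averages over ``n_perm`` sampled orderings.
        In exact mode the AAFs sum to the combined AF of all exposures
        to machine precision.
        """
        exps = list(exposures) if exposures is not None else list(self.exposures)
        k = len(exps)
        if k < 1:
            raise ValueError("need at least one exposure")
        if mode == "exact":
            if k > 9:
                raise ValueError(
                    f"exact enumeration limited to k <= 9 (got k={k}); "
                    "use mode='monte_carlo'")
            aaf = {}
            for e in exps:
                others = [x for x in exps if x != e]
                total = 0.0
                for r in range(k):
                    w = factorial(r) * factorial(k - r - 1) / factorial(k)
                    for S in combinations(others, r):
                        total += w * (self.combined_af(frozenset(S) | {e})
                                      - self.combined_af(frozenset(S)))
                aaf[e] = total
            return aaf
        if mode == "monte_carlo":
            rng = np.random.default_rng(seed)
            acc = {e: 0.0 for e in exps}
            order = np.array(exps, dtype=object)

            def accumulate(perm, times=1):
                removed: frozenset = frozenset()
                prev = 0.0
                for e in perm:
                    removed = removed | {e}
                    cur = self.combined_af(removed)
                    acc[e] += times * (cur - prev)
                    prev = cur

            # variance reduction: when all k! orderings are enumerable and
            # the permutation budget covers them, allocate it evenly across
            # the orderings and only sample the remainder at random
            if k <= 7 and n_perm >= factorial(k):
                from itertools import permutations as _perms
                base, extra = divmod(n_perm, factorial(k))
                for perm in _perms(exps):
                    accumulate(perm, times=base)
                for _ in range(extra):
                    accumulate(rng.permutation(order))
            else:
                for _ in range(n_perm):
                    accumulate(rng.permutation(order))
            return {e: acc[e] / n_perm for e in exps}
        raise ValueError(f"unknown mode {mode!r}")

    # -- assembled table ------------------------------------------------------

    def paf(self, exposure: str) -> float:
        or_, _ = self.odds_ratio(exposure)
        return compute_paf(self.design.f_cases(exposure), or_)

    def af_table(self, aaf_mode: str = "exact", n_perm: int = 2000,
                 seed: int = 0) -> pd.DataFrame:
        """Per-exposure OR / f_cases / PAF / AAF (point estimates)."""
        aaf = self.average_af(mode=aaf_mode, n_perm=n_perm, seed=seed)
        rows = []
        for e in self.exposures:
            or_, (lo, hi) = self.odds_ratio(e)
            f = self.design.f_cases(e)
            rows.append({
                "exposure": e, "OR": or_, "OR_lo": lo, "OR_hi": hi,
                "f_cases": f, "PAF": compute_paf(f, or_), "AAF": aaf[e],
            })
        return pd.DataFrame(rows).set_index("exposure")

    def results(self, **kw) -> list[AFResult]:
        tab = self.af_table(**kw)
        return [AFResult(exposure=e, or_hat=r["OR"], or_ci=(r["OR_lo"], r["OR_hi"]),
                         f_cases=r["f_cases"], paf=r["PAF"], aaf=r["AAF"],
                         model_scope=tuple(self.exposures))
                for e, r in tab.iterrows()]

    def summary(self) -> str:
        tab = self.af_table()
        lines = [
            "Attributable-fraction model (multivariable logistic)",
            f"  n = {self.design.n}  cases = {self.design.n_cases} "
            f" controls = {self.design.n_controls}",
            f"  converged: {self.converged}",
            "",
            tab.round(4).to_string(),
        ]
        return "\n".join(lines)


# ------------------------------ bootstrap ---------------------------------

def bootstrap_intervals(design: BinaryDesign,
                        statistics: tuple[str, ...] = ("or", "paf", "aaf"),
                        n_boot: int = 1000, seed: int = 0,
                        exposures: list[str] | None = None,
                        aaf_mode: str = "exact", n_perm: int = 2000,
                        alpha: float = 0.05) -> dict:
    """Percentile bootstrap CIs for ORs / PAFs / AAFs.

    Resamples individuals with replacement and refits the full pipeline
    (logistic model, PAF formula, AAF averaging) per replicate.
    Replicates with separation or a degenerate outcome are dropped and
    counted; a warning flag is set in the metadata when more than 10%
    drop.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200 for percentile intervals")
    exps = list(exposures) if exposures is not None \
        else list(design.exposures.columns)
    rng = np.random.default_rng(seed)
    samples: dict[str, dict[str, list[float]]] = {
        s: {e: [] for e in exps} for s in statistics}
    n_dropped = 0
    idx = np.arange(design.n)
    for _ in range(n_boot):
        take = rng.choice(idx, size=design.n, replace=True)
        sub = BinaryDesign(
            outcome=design.outcome.iloc[take].reset_index(drop=True),
            exposures=design.exposures.iloc[take].reset_index(drop=True),
            urate=None if design.urate is None
            else design.urate.iloc[take].reset_index(drop=True))
        try:
            res = AttributableFractionModel(sub, exposures=exps).fit()
        except (SeparationError, CollinearityError, DegenerateDesignError):
            n_dropped += 1
            continue
        if "aaf" in statistics:
            aaf = res.average_af(mode=aaf_mode, n_perm=n_perm,
                                 seed=int(rng.integers(2**31)))
        for e in exps:
            if "or" in statistics:
                samples["or"][e].append(res.odds_ratio(e)[0])
            if "paf" in statistics:
                samples["paf"][e].append(res.paf(e))
            if "aaf" in statistics:
                samples["aaf"][e].append(aaf[e])
    qs = (100 * alpha / 2, 100 * (1 - alpha / 2))
    out = {
        "n_boot": n_boot, "n_dropped": n_dropped,
        "high_drop_warning": n_dropped > 0.1 * n_boot,
        "ci": {s: {e: tuple(np.percentile(v, qs)) if v else (np.nan, np.nan)
                   for e, v in per.items()}
               for s, per in samples.items()},
    }
    return out


# ------------------------------ stratified --------------------------------

def stratified_af(design: BinaryDesign, stratum_field_values: pd.Series | None = None,
                  drop_exposure: str | None = None,
                  **table_kw) -> dict[str, object]:
    """Run the AF pipeline within each stratum level.

    The stratum variable (e.g. sex) is removed from the model via
    ``drop_exposure``.  Strata with zero cases or controls are reported
    as degenerate without affecting the others.
    """
    strata = stratum_field_values if stratum_field_values is not None \
        else design.strata
    if strata is None:
        raise ValueError("no strata available on the design")
    out: dict[str, object] = {}
    for level in sorted(pd.unique(strata.dropna())):
        mask = strata == level
        sub = design.subset(mask)
        exps = [e for e in sub.exposures.columns if e != drop_exposure]
        try:
            res = AttributableFractionModel(sub, exposures=exps).fit()
            out[str(level)] = res.af_table(**table_kw)
        except (DegenerateDesignError, SeparationError, CollinearityError) as exc:
            out[str(level)] = f"degenerate: {exc}"
    return out


# ------------------------------ per-allele --------------------------------

def per_allele_paf_table(cohort: pd.DataFrame, snp_labels: list[str],
                         hu_threshold: float = 0.42) -> pd.DataFrame:
    """Per-allele additive-model PAFs for a panel of variants.

    Fits one multivariable logistic model of hyperuricaemia on the raw
    dosages (0/1/2) of all listed SNPs jointly; per-allele OR =
    exp(coefficient); risk-allele frequency among cases = mean case
    dosage / 2; PAF by the per-allele formula.  Variants whose fitted
    OR is < 1 are reported with the complementary (urate-raising)
    orientation so that the frequency and OR refer to the risk allele.
    """
    cols = ["urate"] + snp_labels
    df = cohort[cols].dropna()
    y = (df["urate"] >= hu_threshold).astype(int).to_numpy(dtype=float)
    X = sm.add_constant(df[snp_labels].to_numpy(dtype=float), has_constant="add")
    _check_rank(X, snp_labels)
    res = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-10, disp=0)
    rows = []
    cases = y == 1
    for i, snp in enumerate(snp_labels):
        beta = res.params[i + 1]
        dose = df[snp].to_numpy(dtype=float)
        if beta < 0:  # flip to the urate-raising allele
            beta, dose = -beta, 2.0 - dose
        or_allele = float(np.exp(beta))
        f_cases = float(dose[cases].mean() / 2.0)
        rows.append({"snp": snp, "OR_allele": or_allele,
                     "freq_risk_allele_cases": f_cases,
                     "PAF": compute_paf_per_allele(f_cases, or_allele)})
    return pd.DataFrame(rows).set_index("snp")
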