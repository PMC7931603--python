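"""Two-sample Mendelian randomization from GWAS summary statistics.

Covers the full summary-data workflow: palindromic-variant flagging,
exposure/outcome harmonization, distance-based instrument pruning,
the inverse-variance-weighted (IVW), MR-Egger and weighted-median
estimators with multiplicative random-effects standard errors,
likelihood-based multivariable MR, bidirectional MR, the
three-criterion causal decision rule, and the strict-vs-ambiguous
sensitivity comparison.

Orientation convention: after harmonization every instrument is
oriented to the exposure-increasing allele (beta_exp > 0).  MR-Egger is
sensitive to this orientation; IVW and the weighted median are not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "is_palindromic",
    "flag_palindromic",
    "harmonize",
    "prune_by_distance",
    "select_instruments",
    "InstrumentSet",
    "MREstimate",
    "MVMRResult",
    "CausalCall",
    "ivw",
    "egger",
    "weighted_median",
    "multivariable_mr",
    "bidirectional_mr",
    "causal_decision",
    "compare_runs",
    "mr_analysis",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
GENOME_WIDE_P = 5e-8
DEFAULT_WINDOW = 500_000


# ------------------------- harmonization ----------------------------------

def is_palindromic(ea: str, oa: str) -> bool:
    """True iff the allele pair is strand-ambiguous (A/T or G/C)."""
    ea, oa = ea.upper(), oa.upper()
    if ea not in _COMPLEMENT or oa not in _COMPLEMENT:
        raise ValueError(f"invalid allele pair ({ea!r}, {oa!r})")
    return _COMPLEMENT[ea] == oa


def flag_palindromic(df: pd.DataFrame) -> pd.Series:
    return pd.Series(
        [is_palindromic(a, b) for a, b in zip(df["EA"], df["OA"])],
        index=df.index, name="palindromic")


@dataclass
class InstrumentSet:
    """Harmonized exposure-outcome instrument, oriented beta_exp > 0."""
    table: pd.DataFrame  # SNP CHR POS beta_exp se_exp beta_out se_out p_exp + flags
    dropped: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.table)

    @property
    def beta_exp(self) -> np.ndarray:
        return self.table["beta_exp"].to_numpy(dtype=float)

    @property
    def se_exp(self) -> np.ndarray:
        return self.table["se_exp"].to_numpy(dtype=float)

    @property
    def beta_out(self) -> np.ndarray:
        return self.table["beta_out"].to_numpy(dtype=float)

    @property
    def se_out(self) -> np.ndarray:
        return self.table["se_out"].to_numpy(dtype=float)


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              drop_ambiguous: bool = True) -> InstrumentSet:
    """Join exposure and outcome records on SNP id and align alleles.

    If the outcome's effect/other alleles are swapped relative to the
    exposure, the outcome beta is negated and its EAF complemented.
    Alleles matching in neither orientation are retried after strand
    complement; still-unmatched records are dropped with a logged
    reason.  Palindromic variants are dropped when ``drop_ambiguous``
    (a strand flip is indistinguishable from an allele swap for them).
    Finally every pair is oriented so beta_exp > 0.
    """
    m = exposure.merge(outcome, on="SNP", suffixes=("_exp", "_out"))
    if m.empty:
        raise ValueError("no shared SNP ids between exposure and outcome sets")
    rows, dropped = [], []
    for _, r in m.iterrows():
        ea_x, oa_x = r["EA_exp"].upper(), r["OA_exp"].upper()
        ea_y, oa_y = r["EA_out"].upper(), r["OA_out"].upper()
        pal = is_palindromic(ea_x, oa_x)
        if drop_ambiguous and pal:
            dropped.append({"SNP": r["SNP"], "reason": "palindromic"})
            continue
        flip, matched = False, False
        for a, b, fl in ((ea_y, oa_y, False), (oa_y, ea_y, True)):
            if (a, b) == (ea_x, oa_x):
                matched, flip = True, fl
                break
        if not matched:  # try strand complement of the outcome alleles
            ca, cb = _COMPLEMENT[ea_y], _COMPLEMENT[oa_y]
            for a, b, fl in ((ca, cb, False), (cb, ca, True)):
                if (a, b) == (ea_x, oa_x):
                    matched, flip = True, fl
                    break
        if not matched:
            dropped.append({"SNP": r["SNP"], "reason": "allele_mismatch"})
            continue
        beta_out = -r["BETA_out"] if flip else r["BETA_out"]
        beta_exp = r["BETA_exp"]
        orient = -1.0 if beta_exp < 0 else 1.0
        rows.append({
            "SNP": r["SNP"], "CHR": r["CHR_exp"], "POS": r["POS_exp"],
            "beta_exp": orient * beta_exp, "se_exp": r["SE_exp"],
            "beta_out": orient * beta_out, "se_out": r["SE_out"],
            "p_exp": r["P_exp"], "flipped": flip, "palindromic": pal,
        })
    if not rows:
        raise ValueError("harmonization left no usable instruments")
    return InstrumentSet(
        table=pd.DataFrame(rows),
        dropped=pd.DataFrame(dropped) if dropped else None)


def prune_by_distance(table: pd.DataFrame, window: int = DEFAULT_WINDOW,
                      pos_col: str = "POS", chr_col: str = "CHR",
                      p_col: str = "p_exp") -> pd.DataFrame:
    """Greedy distance pruning: keep the smallest exposure p-value within
    any window, deterministic tie-break by position then SNP id."""
    keep_rows = []
    df = table.sort_values([p_col, pos_col, "SNP"], kind="mergesort")
    kept: dict[object, list[int]] = {}
    for _, r in df.iterrows():
        c = r[chr_col]
        if any(abs(r[pos_col] - p) <= window for p in kept.get(c, ())):
            continue
        kept.setdefault(c, []).append(r[pos_col])
        keep_rows.append(r.name)
    return table.loc[sorted(keep_rows)]


def select_instruments(exposure: pd.DataFrame, outcome: pd.DataFrame,
                       p_threshold: float = GENOME_WIDE_P,
                       min_snps: int = 3,
                       window: int = DEFAULT_WINDOW,
                       drop_ambiguous: bool = True) -> InstrumentSet:
    """Genome-wide-significant, distance-pruned, harmonized instruments.

    Requires at least ``min_snps`` surviving variants (the published
    design demanded >= 3 non-ambiguous genome-wide-significant index
    SNPs per exposure).
    """
    sig = exposure[exposure["P"] < p_threshold]
    if sig.empty:
        raise ValueError("no genome-wide-significant exposure SNPs")
    inst = harmonize(sig, outcome, drop_ambiguous=drop_ambiguous)
    pruned = prune_by_distance(inst.table, window=window)
    if len(pruned) < min_snps:
        raise ValueError(
            f"only {len(pruned)} instruments survive selection; need >= {min_snps}")
    return InstrumentSet(table=pruned.reset_index(drop=True), dropped=inst.dropped)


# ------------------------- estimators --------------------------------------

@dataclass
class MREstimate:
    method: str
    theta: float                    # mmol/L per unit exposure
    se: float
    ci95: tuple[float, float]
    p: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    Q: float | None = None
    p_het: float | None = None
    re_scale: float = 1.0           # multiplicative random-effects SE scale

    def __post_init__(self):
        z = 1.959963984540054
        if not self.ci95:
            self.ci95 = (self.theta - z * self.se, self.theta + z * self.se)


def _ci(theta: float, se: float) -> tuple[float, float]:
    z = 1.959963984540054
    return (theta - z * se, theta + z * se)


def ivw(instruments: InstrumentSet, random_effects: bool = True) -> MREstimate:
    """Inverse-variance-weighted estimate: weighted regression of outcome
    betas on exposure betas through the origin, weights 1/se_out^2.

    With one SNP this reduces to the Wald ratio.  The multiplicative
    random-effects model scales the fixed-effects SE by
    sqrt(Q / (J - 1)) when Q exceeds its degrees of freedom (never
    shrinking below fixed effects).
    """
    bx, by, sy = instruments.beta_exp, instruments.beta_out, instruments.se_out
    J = len(bx)
    if J == 0:
        raise ValueError("empty instrument set")
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx * bx))
    theta = float(np.sum(w * bx * by)) / denom
    Q = float(np.sum(w * (by - theta * bx) ** 2))
    if J == 1:
        se = float(sy[0] / abs(bx[0]))
        return MREstimate("ivw", theta, se, _ci(theta, se),
                          2 * stats.norm.sf(abs(theta) / se), 1, Q=0.0,
                          p_het=np.nan)
    scale = max(1.0, np.sqrt(Q / (J - 1))) if random_effects else 1.0
    se = float(np.sqrt(1.0 / denom) * scale)
    p = float(2 * stats.norm.sf(abs(theta) / se))
    p_het = float(stats.chi2.sf(Q, J - 1))
    return MREstimate("ivw", theta, se, _ci(theta, se), p, J,
                      Q=Q, p_het=p_het, re_scale=scale)


def egger(instruments: InstrumentSet, random_effects: bool = True) -> MREstimate:
    """MR-Egger: weighted least squares of outcome on exposure betas with a
    free intercept (directional pleiotropy), weights 1/se_out^2.
    Requires >= 3 instruments oriented beta_exp > 0; p-values use the
    t distribution with J - 2 degrees of freedom.
    """
    bx, by, sy = instruments.beta_exp, instruments.beta_out, instruments.se_out
    J = len(bx)
    if J < 3:
        raise ValueError(f"MR-Egger needs >= 3 instruments, got {J}")
    if np.any(bx <= 0):
        raise ValueError("instruments must be oriented to beta_exp > 0")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(J), bx])
    XtW = X.T * w
    A = XtW @ X
    coef = np.linalg.solve(A, XtW @ by)
    resid = by - X @ coef
    Q = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(Q / (J - 2))) if random_effects else 1.0
    cov = np.linalg.inv(A) * scale**2
    intercept, theta = float(coef[0]), float(coef[1])
    se0, se1 = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    df = J - 2
    p = float(2 * stats.t.sf(abs(theta) / se1, df))
    p0 = float(2 * stats.t.sf(abs(intercept) / se0, df))
    return MREstimate("egger", theta, se1, _ci(theta, se1), p, J,
                      intercept=intercept, intercept_se=se0, intercept_p=p0,
                      Q=Q, p_het=float(stats.chi2.sf(Q, df)), re_scale=scale)


def _weighted_median(ratio: np.ndarray, weight: np.ndarray) -> float:
    order = np.argsort(ratio)
    r, w = ratio[order], weight[order] / weight.sum()
    cum = np.cumsum(w) - 0.5 * w  # midpoint cumulative weight
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] < 0.5:
        return float(r[-1])
    k = int(np.searchsorted(cum, 0.5))
    # linear interpolation between bracketing ratios
    return float(r[k - 1] + (r[k] - r[k - 1])
                 * (0.5 - cum[k - 1]) / (cum[k] - cum[k - 1]))


def weighted_median(instruments: InstrumentSet, n_boot: int = 1000,
                    seed: int = 0) -> MREstimate:
    """Weighted median of per-SNP Wald ratios, weights beta_exp^2/se_out^2.

    Consistent when >= 50% of the weight comes from valid instruments.
    The SE is a parametric bootstrap: exposure and outcome betas are
    resampled from their Gaussian sampling distributions and the
    estimator recomputed.
    """
    bx, sx = instruments.beta_exp, instruments.se_exp
    by, sy = instruments.beta_out, instruments.se_out
    J = len(bx)
    if J == 0:
        raise ValueError("empty instrument set")
    ratio = by / bx
    weight = bx**2 / sy**2
    theta = _weighted_median(ratio, weight)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx + sx * rng.standard_normal(J)
        bys = by + sy * rng.standard_normal(J)
        bxs = np.where(bxs == 0, np.finfo(float).eps, bxs)
        boots[b] = _weighted_median(bys / bxs, bxs**2 / sy**2)
    se = float(boots.std(ddof=1))
    p = float(2 * stats.norm.sf(abs(theta) / se)) if se > 0 else (
        0.0 if theta != 0 else 1.0)
    return MREstimate("weighted_median", theta, se, _ci(theta, se), p, J)


# ------------------------- multivariable MR --------------------------------

@dataclass
class MVMRResult:
    exposures: tuple[str, ...]
    theta: np.ndarray
    se: np.ndarray
    ci95: list[tuple[float, float]]
    p: np.ndarray
    method: str
    n_snps: int
    converged: bool
    theta_wls: np.ndarray | None = None
    se_wls: np.ndarray | None = None

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "exposure": self.exposures, "theta": self.theta, "se": self.se,
            "ci_lo": [c[0] for c in self.ci95], "ci_hi": [c[1] for c in self.ci95],
            "p": self.p}).set_index("exposure")


def _mvmr_wls(bx, sx, by, sy):
    """Weighted multivariable regression fallback (weights 1/se_out^2).

    Uses the pseudoinverse so that an unidentified direction (e.g. an
    exposure with all-zero betas) yields a zero estimate with an
    infinite reported SE rather than a hard failure.
    """
    w = 1.0 / sy**2
    A = (bx.T * w) @ bx
    Ainv = np.linalg.pinv(A)
    theta = Ainv @ ((bx.T * w) @ by)
    var = np.diag(Ainv).copy()
    var[var <= 0] = np.inf
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[0]:
        # flag unidentified directions with infinite uncertainty
        null_mask = np.abs(np.diag(A)) < 1e-300
        var[null_mask] = np.inf
    return theta, np.sqrt(var)


def _mvmr_profile_nll(theta, bx, sx, by, sy):
    """Negative log-likelihood with the latent true exposure betas
    integrated out in closed form.

    Minimizing the joint quadratic over the latent betas collapses each
    SNP's contribution to ``r_j^2 / v_j`` with
    ``v_j = se_out_j^2 + sum_k theta_k^2 se_exp_jk^2`` and
    ``r_j = beta_out_j - theta . beta_exp_j``; the Gaussian
    normalisation ``log v_j`` is kept — without it the criterion is
    unbounded whenever an exposure column carries no signal.
    """
    theta = np.asarray(theta, dtype=float)
    v = sy**2 + (sx**2) @ theta**2
    r = by - bx @ theta
    return 0.5 * float(np.sum(np.log(v) + r * r / v))


def multivariable_mr(beta_exp, se_exp, beta_out, se_out,
                     exposures: tuple[str, ...] | None = None,
                     method: str = "likelihood") -> MVMRResult:
    """Multivariable MR on summary data.

    Maximizes the Gaussian likelihood in which the observed per-SNP
    exposure betas are noisy measurements of latent true betas and the
    outcome beta is Normal(sum_k theta_k * xi_kj, se_out_j^2); the
    latent betas are profiled out in closed form and the direct effects
    theta_k optimized numerically, with SEs from the observed
    information (finite-difference Hessian of the profile likelihood).
    Measurement errors across exposures are treated as independent
    (two-sample setting).  A weighted-multivariable-regression
    estimator is always computed alongside as a cross-check.
    """
    bx = np.asarray(beta_exp, dtype=float)
    sx = np.asarray(se_exp, dtype=float)
    by = np.asarray(beta_out, dtype=float)
    sy = np.asarray(se_out, dtype=float)
    if bx.ndim != 2:
        raise ValueError("beta_exp must be J x K")
    J, K = bx.shape
    if K < 2:
        raise ValueError("multivariable MR needs >= 2 exposures")
    if J < K + 1:
        raise ValueError(f"need more instruments than exposures (J={J}, K={K})")
    if not np.any(np.abs(bx) > 0):
        raise ValueError("instruments associated with no exposure")
    names = tuple(exposures) if exposures else tuple(f"x{k}" for k in range(K))

    sd = bx.std(axis=0)
    if np.all(sd > 0):
        cc = np.corrcoef(bx, rowvar=False)
        if np.any(np.abs(cc[np.triu_indices(K, 1)]) > 0.999):
            warnings.warn("exposure beta columns are (near-)collinear; "
                          "direct effects are weakly identified", stacklevel=2)

    theta_wls, se_wls = _mvmr_wls(bx, sx, by, sy)
    if method == "wls":
        theta, se, converged = theta_wls, se_wls, True
    elif method == "likelihood":
        res = optimize.minimize(
            _mvmr_profile_nll, theta_wls, args=(bx, sx, by, sy),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        if not res.success:
            raise RuntimeError(f"multivariable MR did not converge: {res.message}")
        theta = res.x
        # observed information from the profile likelihood
        h = 1e-5 * np.maximum(np.abs(theta), 1e-3)
        H = np.empty((K, K))
        for a in range(K):
            for b in range(a, K):
                ta = np.zeros(K); ta[a] = h[a]
                tb = np.zeros(K); tb[b] = h[b]
                f = _mvmr_profile_nll
                H[a, b] = H[b, a] = (
                    f(theta + ta + tb, bx, sx, by, sy)
                    - f(theta + ta - tb, bx, sx, by, sy)
                    - f(theta - ta + tb, bx, sx, by, sy)
                    + f(theta - ta - tb, bx, sx, by, sy)
                ) / (4 * h[a] * h[b])
        cov = np.linalg.pinv(H)
        var = np.diag(cov).copy()
        var[var <= 0] = np.inf
        se = np.sqrt(var)
        converged = bool(res.success)
    else:
        raise ValueError(f"unknown method {method!r}")

    p = 2 * stats.norm.sf(np.abs(theta) / se)
    z = 1.959963984540054
    ci = [(float(t - z * s), float(t + z * s)) for t, s in zip(theta, se)]
    return MVMRResult(names, np.asarray(theta, float), np.asarray(se, float),
                      ci, np.asarray(p, float), method, J, converged,
                      theta_wls=theta_wls, se_wls=se_wls)


# ------------------------- bidirectional MR --------------------------------

def bidirectional_mr(stats_a: pd.DataFrame, stats_b: pd.DataFrame,
                     p_threshold: float = GENOME_WIDE_P, min_snps: int = 3,
                     window: int = DEFAULT_WINDOW, drop_ambiguous: bool = True,
                     alpha: float = 0.05):
    """IVW in both directions with independently selected instruments.

    Returns ``(estimate_a_to_b, estimate_b_to_a, correlated_pleiotropy)``
    where the flag is attached when both direction p-values pass
    ``alpha`` — no automatic causal verdict is implied.
    """
    inst_ab = select_instruments(stats_a, stats_b, p_threshold=p_threshold,
                                 min_snps=min_snps, window=window,
                                 drop_ambiguous=drop_ambiguous)
    inst_ba = select_instruments(stats_b, stats_a, p_threshold=p_threshold,
                                 min_snps=min_snps, window=window,
                                 drop_ambiguous=drop_ambiguous)
    est_ab, est_ba = ivw(inst_ab), ivw(inst_ba)
    both = bool(est_ab.p < alpha and est_ba.p < alpha)
    return est_ab, est_ba, both


# ------------------------- decision & sensitivity ---------------------------

@dataclass
class CausalCall:
    """Three-criterion causality decision for one exposure."""
    ivw_pass: bool      # p_IVW < 0.05 / n_tests
    wm_pass: bool       # p_WM < 0.05
    egger_pass: bool    # Egger intercept p > 0.05 (no directional pleiotropy)
    causal: bool = field(init=False)
    ivw_threshold: float = 0.05 / 87

    def __post_init__(self):
        self.causal = self.ivw_pass and self.wm_pass and self.egger_pass


def causal_decision(ivw_est: MREstimate, wm_est: MREstimate,
                    egger_est: MREstimate, n_tests: int = 87) -> CausalCall:
    """All three thresholds must be met for an exposure to be called
    causal: Bonferroni-corrected IVW, nominal weighted median, and a
    non-significant Egger intercept."""
    thr = 0.05 / n_tests
    return CausalCall(
        ivw_pass=bool(ivw_est.p < thr),
        wm_pass=bool(wm_est.p < 0.05),
        egger_pass=bool(egger_est.intercept_p > 0.05),
        ivw_threshold=thr)


def compare_runs(run_strict: dict[str, float],
                 run_with_ambiguous: dict[str, float]):
    """Sensitivity comparison of per-exposure causal estimates with and
    without palindromic-SNP exclusion.

    Returns (paired DataFrame, summary dict) with the sign-concordance
    fraction and the Spearman rank correlation; the frame is the
    scatter data behind a concordance plot.
    """
    shared = sorted(set(run_strict) & set(run_with_ambiguous))
    if not shared:
        raise ValueError("no shared exposures between runs")
    df = pd.DataFrame({
        "exposure": shared,
        "theta_strict": [run_strict[e] for e in shared],
        "theta_ambiguous": [run_with_ambiguous[e] for e in shared],
    }).set_index("exposure")
    df["sign_concordant"] = np.sign(df["theta_strict"]) == np.sign(
        df["theta_ambiguous"])
    summary = {"n": len(df),
               "sign_concordance": float(df["sign_concordant"].mean())}
    if len(df) > 2:
        rho, _ = stats.spearmanr(df["theta_strict"], df["theta_ambiguous"])
        summary["spearman_rho"] = float(rho)
    return df, summary


# ------------------------- one-shot convenience -----------------------------

def mr_analysis(exposure: pd.DataFrame, outcome: pd.DataFrame,
                n_tests: int = 87, p_threshold: float = GENOME_WIDE_P,
                min_snps: int = 3, window: int = DEFAULT_WINDOW,
                drop_ambiguous: bool = True, n_boot: int = 1000,
                seed: int = 0) -> dict:
    """Instrument selection + IVW/Egger/weighted-median + causal call."""
    inst = select_instruments(exposure, outcome, p_threshold=p_threshold,
                              min_snps=min_snps, window=window,
                              drop_ambiguous=drop_ambiguous)
    est_ivw = ivw(inst)
    est_egger = egger(inst)
    est_wm = weighted_median(inst, n_boot=n_boot, seed=seed)
    call = causal_decision(est_ivw, est_wm, est_egger, n_tests=n_tests)
    return {"instruments": inst, "ivw": est_ivw, "egger": est_egger,
            "weighted_median": est_wm, "call": call}
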