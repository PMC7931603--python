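"""Synthetic cohorts and paired GWAS summary statistics.

This module generates the two kinds of input the rest of the package
consumes:

* individual-level cohorts (serum urate in mmol/L, demographics, binary
  risk exposures, SNP genotype dosages) with a linear-additive urate
  model, for the attributable-fraction and variance analyses;
* two-sample GWAS summary statistics for an exposure trait (e.g. a
  dietary habit) and for serum urate, with configurable true causal
  effect, constant directional pleiotropy, and an upstream mediator
  (BMI) that induces correlated pleiotropy, for the Mendelian
  randomization analyses.

Both generators are fully seeded.  Each generated column draws from its
own named random stream derived from the root seed, so adding a column
to the model never perturbs the values of previously existing columns.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortConfig",
    "SummaryStatConfig",
    "GWAS_COLUMNS",
    "generate_cohort",
    "generate_summary_stats",
    "generate_mediation_stats",
    "write_gwas",
    "read_gwas",
    "write_cohort",
    "read_cohort",
]

GWAS_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P"]

#: allele pairs that cannot be confused by a strand flip
_NON_PALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
#: ambiguous (palindromic) pairs: the complement equals the other allele
_PALINDROMIC = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named child stream of the root seed (stable under column addition)."""
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), zlib.crc32(name.encode())))
    )


def _check_finite(obj, label: str) -> None:
    arr = np.asarray(obj, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite value in config field {label!r}: {obj!r}")


def _check_prop(x: float, label: str) -> None:
    _check_finite(x, label)
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{label} must lie in [0, 1], got {x}")


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

#: exposures whose indicator is derived from a generated demographic column
#: rather than drawn from a configured prevalence
DERIVED_EXPOSURES = ("male", "bmi_high", "age_50")


@dataclass
class CohortConfig:
    """Parameters of the linear-additive serum-urate cohort model.

    Default values emulate a large UK-style general-population cohort:
    hyperuricaemia (urate >= 0.42 mmol/L) prevalence of roughly 8-12%,
    a strong male-sex urate shift (~0.075 mmol/L), a common
    urate-raising SLC2A9 allele (frequency 0.77), and the usual
    environmental exposures (alcohol, diuretics, diet non-adherence).
    """

    n_individuals: int = 20_000
    sex_male_frac: float = 0.43
    age_mean: float = 56.7
    age_sd: float = 8.0
    bmi_mean: float = 27.4
    bmi_sd: float = 4.7
    #: (label, risk-allele frequency, additive urate effect in mmol/L/allele)
    snp_specs: list[tuple[str, float, float]] = field(
        default_factory=lambda: [("SLC2A9_rs12498742", 0.77, 0.023)]
    )
    #: urate shift (mmol/L) applied when the exposure indicator is 1
    exposure_effects: dict[str, float] = field(default_factory=lambda: {
        "male": 0.075,
        "bmi_high": 0.040,
        "age_50": 0.009,
        "alcohol": 0.009,
        "diuretic": 0.049,
        "diet_nonadherence": 0.005,
    })
    #: prevalence of the drawn (non-derived) binary exposures
    exposure_prevalences: dict[str, float] = field(default_factory=lambda: {
        "alcohol": 0.70,
        "diuretic": 0.07,
        "diet_nonadherence": 0.90,
    })
    #: optional latent-Gaussian-copula correlation between drawn exposures
    exposure_correlation: float = 0.0
    urate_intercept: float = 0.20
    urate_noise_sd: float = 0.075
    kidney_disease_frac: float = 0.02
    energy_mean_kj: float = 8500.0
    energy_sd_kj: float = 2200.0
    #: gout mode adds a urate-lowering-therapy exposure and a gout flag
    gout_mode: bool = False
    gout_ult_treated_frac: float = 0.34
    gout_ult_effect: float = -0.133
    gout_intercept_shift: float = 0.06
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        _check_prop(self.sex_male_frac, "sex_male_frac")
        _check_prop(self.exposure_correlation, "exposure_correlation")
        _check_prop(self.kidney_disease_frac, "kidney_disease_frac")
        _check_prop(self.gout_ult_treated_frac, "gout_ult_treated_frac")
        for lbl in ("age_mean", "age_sd", "bmi_mean", "bmi_sd",
                    "urate_intercept", "urate_noise_sd",
                    "energy_mean_kj", "energy_sd_kj",
                    "gout_ult_effect", "gout_intercept_shift"):
            _check_finite(getattr(self, lbl), lbl)
        if self.urate_noise_sd <= 0:
            raise ValueError("urate_noise_sd must be > 0")
        for label, freq, eff in self.snp_specs:
            _check_prop(freq, f"snp {label} frequency")
            _check_finite(eff, f"snp {label} effect")
        for name, eff in self.exposure_effects.items():
            _check_finite(eff, f"exposure_effects[{name}]")
            if name not in DERIVED_EXPOSURES and name not in self.exposure_prevalences:
                raise ValueError(
                    f"exposure {name!r} has an effect but no prevalence")
        for name, prev in self.exposure_prevalences.items():
            _check_prop(prev, f"exposure_prevalences[{name}]")


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate an individual-level cohort table.

    Serum urate is linear-additive on the mmol/L scale:
    ``urate = intercept + sum(dosage * per-allele effect)
    + sum(indicator * exposure effect) + N(0, noise_sd)``.
    Genotypes are binomial(2, freq) (Hardy-Weinberg).  Raw columns
    (alcohol drinks/week, diet adherence score, BMI, age ...) are
    emitted so that downstream dichotomization at the documented
    thresholds recovers exactly the indicators used to build urate.
    """
    config.validate()
    n = config.n_individuals
    seed = config.seed

    df = pd.DataFrame({"id": [f"I{i:07d}" for i in range(n)]})
    male = _stream(seed, "sex").random(n) < config.sex_male_frac
    df["sex"] = np.where(male, "male", "female")
    df["age"] = config.age_mean + config.age_sd * _stream(seed, "age").standard_normal(n)
    df["bmi"] = config.bmi_mean + config.bmi_sd * _stream(seed, "bmi").standard_normal(n)

    indicators: dict[str, np.ndarray] = {
        "male": male.astype(float),
        "bmi_high": (df["bmi"].to_numpy() >= 25.0).astype(float),
        "age_50": (df["age"].to_numpy() >= 50.0).astype(float),
    }

    # drawn binary exposures, optionally correlated through a Gaussian copula
    drawn = sorted(config.exposure_prevalences)
    if drawn:
        k = len(drawn)
        rho = config.exposure_correlation
        if rho > 0 and k > 1:
            cov = np.full((k, k), rho)
            np.fill_diagonal(cov, 1.0)
            z = _stream(seed, "exposure_copula").multivariate_normal(
                np.zeros(k), cov, size=n)
            u = stats.norm.cdf(z)
        else:
            u = np.column_stack(
                [_stream(seed, f"exposure:{name}").random(n) for name in drawn])
        for i, name in enumerate(drawn):
            indicators[name] = (u[:, i] < config.exposure_prevalences[name]).astype(float)

    dosages: dict[str, np.ndarray] = {}
    for label, freq, _eff in config.snp_specs:
        dosages[label] = _stream(seed, f"snp:{label}").binomial(2, freq, size=n)

    intercept = config.urate_intercept
    if config.gout_mode:
        intercept += config.gout_intercept_shift
        treated = (_stream(seed, "ult").random(n)
                   < config.gout_ult_treated_frac).astype(int)
        df["ult"] = treated
        df["gout_selfreport"] = (
            (_stream(seed, "gout_flag").random(n) < 0.90) | (treated == 1)
        ).astype(int)
    else:
        df["ult"] = 0
        df["gout_selfreport"] = 0

    urate = np.full(n, intercept, dtype=float)
    for label, _freq, eff in config.snp_specs:
        urate += dosages[label] * eff
    for name, eff in config.exposure_effects.items():
        if name in indicators:
            urate += indicators[name] * eff
    if config.gout_mode:
        urate += df["ult"].to_numpy() * config.gout_ult_effect
    urate += config.urate_noise_sd * _stream(seed, "urate_noise").standard_normal(n)
    df["urate"] = urate

    # raw columns consistent with the drawn indicators
    if "alcohol" in indicators:
        r = _stream(seed, "alcohol_raw")
        df["alcohol"] = np.where(indicators["alcohol"] == 1,
                                 1.5 + 18.5 * r.random(n), r.random(n))
    else:
        df["alcohol"] = 0.0
    df["diuretic"] = indicators.get("diuretic", np.zeros(n)).astype(int)
    if "diet_nonadherence" in indicators:
        r = _stream(seed, "diet_raw")
        # adherence score in [0, 1]; non-adherence = score < 0.8 (top
        # quintile of a uniform score counts as adherent)
        df["diet_score"] = np.where(indicators["diet_nonadherence"] == 1,
                                    0.8 * r.random(n), 0.8 + 0.2 * r.random(n))
    else:
        df["diet_score"] = 1.0
    df["kidney_disease"] = (
        _stream(seed, "kidney").random(n) < config.kidney_disease_frac).astype(int)
    df["energy_intake"] = np.clip(
        config.energy_mean_kj
        + config.energy_sd_kj * _stream(seed, "energy").standard_normal(n),
        500.0, None)
    for label in dosages:
        df[label] = dosages[label]
    df.attrs["energy_unit"] = "kJ"
    return df


# --------------------------------------------------------------------------
# GWAS summary statistics
# --------------------------------------------------------------------------

@dataclass
class SummaryStatConfig:
    """Parameters of the paired exposure/outcome summary-statistic model.

    Per SNP *j* the true exposure effect is ``bX_j = bD_j + m_x * bM_j``
    (direct component plus a mediator-borne component) and the true
    outcome effect is ``bY_j = theta * bX_j + c + m_y * bM_j`` with
    constant directional pleiotropy ``c``.  Observed betas add Gaussian
    noise at the GWAS standard error
    ``se = se_scale / sqrt(2 * eaf * (1 - eaf) * n)``.
    """

    n_snps_exposure: int = 30
    true_causal_effect: float = 0.05        # mmol/L per unit exposure
    pleiotropy_intercept: float = 0.0       # mmol/L, constant directional
    mediator_effect_on_exposure: float = 0.0
    mediator_effect_on_outcome: float = 0.0
    instrument_strength_range: tuple[float, float] = (0.015, 0.08)
    mediator_strength_range: tuple[float, float] = (0.02, 0.08)
    se_scale: float = 1.0
    gwas_n_exposure: int = 450_000
    gwas_n_outcome: int = 290_000
    frac_palindromic: float = 0.0
    eaf_range: tuple[float, float] = (0.1, 0.9)
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps_exposure < 1:
            raise ValueError("n_snps_exposure must be >= 1")
        if self.se_scale <= 0:
            raise ValueError("se_scale must be > 0")
        _check_prop(self.frac_palindromic, "frac_palindromic")
        for lbl in ("true_causal_effect", "pleiotropy_intercept",
                    "mediator_effect_on_exposure", "mediator_effect_on_outcome"):
            _check_finite(getattr(self, lbl), lbl)
        for lbl in ("instrument_strength_range", "mediator_strength_range",
                    "eaf_range"):
            lo, hi = getattr(self, lbl)
            _check_finite((lo, hi), lbl)
            if lo > hi or lo < 0:
                raise ValueError(f"{lbl} must be 0 <= lo <= hi")
        if self.gwas_n_exposure < 2 or self.gwas_n_outcome < 2:
            raise ValueError("gwas_n must be >= 2")


def _gwas_se(eaf: np.ndarray, n: int, se_scale: float) -> np.ndarray:
    return se_scale / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _assemble(snp, chrom, pos, ea, oa, eaf, beta, se) -> pd.DataFrame:
    return pd.DataFrame({
        "SNP": snp, "CHR": chrom, "POS": pos, "EA": ea, "OA": oa,
        "EAF": eaf, "BETA": beta, "SE": se, "P": _two_sided_p(beta, se),
    })[GWAS_COLUMNS]


def _simulate_trio(config: SummaryStatConfig):
    """Core generator: (exposure, mediator, outcome) summary-stat frames."""
    config.validate()
    n = config.n_snps_exposure
    seed = config.seed

    snp = np.array([f"rs{1000 + j}" for j in range(n)])
    chrom = np.ones(n, dtype=int)
    pos = (np.arange(n) + 1) * 2_000_000  # > 1 Mb apart: pruning is a no-op
    eaf = _stream(seed, "ss:eaf").uniform(*config.eaf_range, size=n)

    pal = _stream(seed, "ss:palindromic").random(n) < config.frac_palindromic
    pair_idx = _stream(seed, "ss:alleles").integers(0, 8, size=n)
    ea = np.empty(n, dtype=object)
    oa = np.empty(n, dtype=object)
    for j in range(n):
        pool = _PALINDROMIC if pal[j] else _NON_PALINDROMIC
        ea[j], oa[j] = pool[pair_idx[j] % len(pool)]

    lo, hi = config.instrument_strength_range
    mag = _stream(seed, "ss:beta_x").uniform(lo, hi, size=n)
    sign = np.where(_stream(seed, "ss:beta_sign").random(n) < 0.5, -1.0, 1.0)
    b_direct = mag * sign

    mx, my = config.mediator_effect_on_exposure, config.mediator_effect_on_outcome
    if mx != 0.0 or my != 0.0:
        mlo, mhi = config.mediator_strength_range
        mmag = _stream(seed, "ss:beta_m").uniform(mlo, mhi, size=n)
        msign = np.where(_stream(seed, "ss:beta_m_sign").random(n) < 0.5, -1.0, 1.0)
        b_med = mmag * msign
    else:
        b_med = np.zeros(n)

    bx_true = b_direct + mx * b_med
    # directional pleiotropy acts on the exposure-increasing allele, so the
    # constant offset is applied in that orientation (sign of the true
    # exposure effect); MR-Egger's intercept is defined the same way
    pleio = config.pleiotropy_intercept * np.where(bx_true >= 0, 1.0, -1.0)
    by_true = config.true_causal_effect * bx_true + pleio + my * b_med

    se_x = _gwas_se(eaf, config.gwas_n_exposure, config.se_scale)
    se_m = _gwas_se(eaf, config.gwas_n_exposure, config.se_scale)
    se_y = _gwas_se(eaf, config.gwas_n_outcome, config.se_scale)

    bx = bx_true + se_x * _stream(seed, "ss:noise_x").standard_normal(n)
    bm = b_med + se_m * _stream(seed, "ss:noise_m").standard_normal(n)
    by = by_true + se_y * _stream(seed, "ss:noise_y").standard_normal(n)

    exposure = _assemble(snp, chrom, pos, ea, oa, eaf, bx, se_x)
    mediator = _assemble(snp, chrom, pos, ea, oa, eaf, bm, se_m)
    outcome = _assemble(snp, chrom, pos, ea, oa, eaf, by, se_y)
    return exposure, mediator, outcome


def generate_summary_stats(config: SummaryStatConfig):
    """Paired (exposure, outcome) GWAS summary statistics."""
    exposure, _mediator, outcome = _simulate_trio(config)
    return exposure, outcome


def generate_mediation_stats(config: SummaryStatConfig):
    """(exposure, mediator, outcome) summary statistics for multivariable MR.

    With ``instrument_strength_range = (0, 0)`` and nonzero mediator
    effects this produces the full-mediation regime: every instrument's
    exposure association flows through the mediator, so univariate MR on
    the exposure is confounded by correlated pleiotropy while the
    mediator-adjusted multivariable model recovers a null direct effect.
    """
    return _simulate_trio(config)


# --------------------------------------------------------------------------
# text I/O (the de-facto whitespace-delimited GWAS dialect; TSV cohorts)
# --------------------------------------------------------------------------

def write_gwas(df: pd.DataFrame, path) -> None:
    df[GWAS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gwas(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary-stat file {path} lacks columns {missing}")
    return df[GWAS_COLUMNS]


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.attrs["energy_unit"] = "kJ"
    return df
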