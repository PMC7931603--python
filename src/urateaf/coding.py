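"""Inclusion/exclusion rules and exposure dichotomization.

All attributable-fraction machinery operates on a :class:`BinaryDesign`:
a 0/1 outcome (hyperuricaemia, serum urate >= 0.42 mmol/L for both
sexes) and a 0/1 exposure matrix.  This module turns a raw cohort table
into that design, applying cohort-profile exclusion rules first.

Boundary conventions (fixed): hyperuricaemia inclusive (>= 0.42 mmol/L),
overweight/obese inclusive (BMI >= 25 kg/m^2), age inclusive (>= 50 y),
alcohol strict (> 1 drink/week), genetic risk under a dominant model
(dosage >= 1 of the urate-raising allele).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KJ_PER_KCAL",
    "HU_THRESHOLD",
    "DegenerateDesignError",
    "Threshold",
    "DominantAllele",
    "Flag",
    "NonAdherence",
    "Equals",
    "ExposureSpec",
    "BinaryDesign",
    "default_exposure_specs",
    "apply_exclusions",
    "dichotomize",
]

log = logging.getLogger(__name__)

KJ_PER_KCAL = 4.184
HU_THRESHOLD = 0.42       # mmol/L, inclusive, both sexes
KINSHIP_CUTOFF = 0.177    # coefficients above this define an excluded pair

PROFILES = ("us_population", "ukb_recall", "ukb_ffq", "gout")


class DegenerateDesignError(ValueError):
    """Raised when coding leaves zero cases or zero controls."""


# ------------------------------ rules -------------------------------------

@dataclass(frozen=True)
class Threshold:
    value: float
    direction: str = "ge"   # ge, gt, le, lt

    def apply(self, col: pd.Series) -> pd.Series:
        op = {"ge": col.ge, "gt": col.gt, "le": col.le, "lt": col.lt}
        if self.direction not in op:
            raise ValueError(f"unknown direction {self.direction!r}")
        return op[self.direction](self.value).astype(int)


@dataclass(frozen=True)
class DominantAllele:
    """Dominant coding of a dosage column for the urate-raising allele.

    ``risk_allele_counted=True`` means the dosage counts the risk allele,
    so carriers have dosage >= 1; otherwise the risk allele is the one
    NOT counted and carriers have dosage <= 1.
    """
    risk_allele_counted: bool = True

    def apply(self, col: pd.Series) -> pd.Series:
        if self.risk_allele_counted:
            return col.ge(1).astype(int)
        return col.le(1).astype(int)


@dataclass(frozen=True)
class Flag:
    """Boolean column; ``risk_when=False`` codes absence as the risk state
    (e.g. "not treated with urate-lowering therapy")."""
    risk_when: bool = True

    def apply(self, col: pd.Series) -> pd.Series:
        b = col.astype(float).gt(0)
        return (b if self.risk_when else ~b).astype(int)


@dataclass(frozen=True)
class NonAdherence:
    """Diet non-adherence: adherence score strictly below the cutoff.

    The default cutoff 0.8 marks the top quintile of a uniform [0, 1]
    adherence score as adherent; it is a configurable convention, not a
    published constant.
    """
    cutoff: float = 0.8

    def apply(self, col: pd.Series) -> pd.Series:
        return col.lt(self.cutoff).astype(int)


@dataclass(frozen=True)
class Equals:
    value: object

    def apply(self, col: pd.Series) -> pd.Series:
        return col.eq(self.value).astype(int)


@dataclass(frozen=True)
class ExposureSpec:
    name: str
    source_field: str
    rule: object

    def apply(self, df: pd.DataFrame) -> pd.Series:
        return self.rule.apply(df[self.source_field]).rename(self.name)


def default_exposure_specs(snp_label: str = "SLC2A9_rs12498742",
                           gout_mode: bool = False,
                           include_age: bool | None = None,
                           diet_cutoff: float = 0.8) -> list[ExposureSpec]:
    """The standard exposure set: sex, BMI, genotype, diet, alcohol,
    diuretics, age, plus absence of urate-lowering therapy in gout mode
    (where age is dropped by default — it confers no risk there)."""
    if include_age is None:
        include_age = not gout_mode
    specs = [
        ExposureSpec("male", "sex", Equals("male")),
        ExposureSpec("bmi_high", "bmi", Threshold(25.0, "ge")),
        ExposureSpec(snp_label, snp_label, DominantAllele()),
        ExposureSpec("diet_nonadherence", "diet_score", NonAdherence(diet_cutoff)),
        ExposureSpec("alcohol", "alcohol", Threshold(1.0, "gt")),
        ExposureSpec("diuretic", "diuretic", Flag()),
    ]
    if include_age:
        specs.append(ExposureSpec("age_50", "age", Threshold(50.0, "ge")))
    if gout_mode:
        specs.append(ExposureSpec("ult_untreated", "ult", Flag(risk_when=False)))
    return specs


# --------------------------- exclusions -----------------------------------

def _require(df: pd.DataFrame, cols: list[str], profile: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"profile {profile!r} requires columns {missing}")


def _energy_kj(df: pd.DataFrame, energy_unit: str | None) -> pd.Series:
    unit = energy_unit or df.attrs.get("energy_unit", "kJ")
    e = df["energy_intake"].astype(float)
    return e * KJ_PER_KCAL if unit.lower() in ("kcal", "kcal/day") else e


def _prune_kin(df: pd.DataFrame, kinship: pd.DataFrame | None,
               prefer_gout: bool) -> pd.DataFrame:
    """Drop one member of every pair with kinship above the cutoff.

    Resolution: prefer keeping gout cases (gout profile); otherwise keep
    the member with a non-missing urate, then the first by id.
    """
    if kinship is None or kinship.empty:
        return df
    keep = set(df["id"])
    by_id = df.set_index("id")
    pairs = kinship[kinship["coefficient"] > KINSHIP_CUTOFF]
    for _, row in pairs.sort_values(["id1", "id2"]).iterrows():
        a, b = row["id1"], row["id2"]
        if a not in keep or b not in keep:
            continue
        drop = None
        if prefer_gout:
            def is_case(i):
                r = by_id.loc[i]
                return bool(r.get("gout_selfreport", 0)) or bool(r.get("ult", 0))
            ca, cb = is_case(a), is_case(b)
            if ca != cb:
                drop = b if ca else a
        if drop is None:
            ua = pd.notna(by_id.loc[a, "urate"]) if "urate" in by_id else True
            ub = pd.notna(by_id.loc[b, "urate"]) if "urate" in by_id else True
            if ua != ub:
                drop = b if ua else a
            else:
                drop = max(a, b)  # keep the first by id
        keep.discard(drop)
    return df[df["id"].isin(keep)]


def apply_exclusions(cohort: pd.DataFrame, profile: str,
                     kinship: pd.DataFrame | None = None,
                     energy_unit: str | None = None) -> pd.DataFrame:
    """Apply the cohort-profile inclusion/exclusion rules.

    Profiles
    --------
    ``us_population``
        drop age < 18, kidney disease, gout, urate-lowering therapy,
        daily energy outside 600-4200 kcal, and one of each
        first-degree-related pair.
    ``ukb_recall``
        drop energy intake above 18,000 kJ (women) / 20,000 kJ (men),
        kidney disease, and close kin.
    ``ukb_ffq``
        drop kidney disease and close kin only.
    ``gout``
        keep only participants who self-report gout or are on
        urate-lowering therapy; kin pruning prefers keeping gout cases.

    Rows with a missing serum urate are dropped under every profile.
    Dropped-row counts per rule are logged for auditability.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; expected one of {PROFILES}")
    df = cohort.copy()
    counts: dict[str, int] = {}

    def _apply(name: str, mask_keep: pd.Series):
        nonlocal df
        before = len(df)
        df = df[mask_keep]
        counts[name] = before - len(df)

    if "urate" in df.columns:
        _apply("missing_urate", df["urate"].notna())
    else:
        raise ValueError("cohort table lacks a 'urate' column")

    if profile == "us_population":
        _require(df, ["age"], profile)
        _apply("age_lt_18", df["age"] >= 18)
        if "kidney_disease" in df.columns:
            _apply("kidney_disease", df["kidney_disease"].fillna(0) == 0)
        if "gout_selfreport" in df.columns:
            _apply("gout", df["gout_selfreport"].fillna(0) == 0)
        if "ult" in df.columns:
            _apply("ult", df["ult"].fillna(0) == 0)
        if "energy_intake" in df.columns:
            kcal = _energy_kj(df, energy_unit) / KJ_PER_KCAL
            ok = kcal.isna() | ((kcal >= 600.0) & (kcal <= 4200.0))
            _apply("energy_window", ok)
        df = _prune_kin(df, kinship, prefer_gout=False)
    elif profile == "ukb_recall":
        _require(df, ["sex", "energy_intake"], profile)
        kj = _energy_kj(df, energy_unit)
        limit = np.where(df["sex"].eq("male"), 20_000.0, 18_000.0)
        _apply("energy_excess", kj.isna() | (kj <= limit))
        if "kidney_disease" in df.columns:
            _apply("kidney_disease", df["kidney_disease"].fillna(0) == 0)
        df = _prune_kin(df, kinship, prefer_gout=False)
    elif profile == "ukb_ffq":
        if "kidney_disease" in df.columns:
            _apply("kidney_disease", df["kidney_disease"].fillna(0) == 0)
        df = _prune_kin(df, kinship, prefer_gout=False)
    elif profile == "gout":
        _require(df, ["gout_selfreport", "ult"], profile)
        # kin pruning first, preferring gout cases, so that a case related
        # to a non-case survives into the cohort
        df = _prune_kin(df, kinship, prefer_gout=True)
        case = (df["gout_selfreport"].fillna(0) > 0) | (df["ult"].fillna(0) > 0)
        _apply("not_gout_case", case)

    out = df.reset_index(drop=True)
    out.attrs["energy_unit"] = cohort.attrs.get("energy_unit", "kJ")
    out.attrs["exclusion_counts"] = counts
    log.info("apply_exclusions(%s): dropped %s", profile, counts)
    return out


# --------------------------- dichotomization ------------------------------

@dataclass
class BinaryDesign:
    """Dichotomized outcome + exposures, with the continuous urate kept
    alongside for the variance-decomposition model."""

    outcome: pd.Series                 # 0/1 hyperuricaemia indicator
    exposures: pd.DataFrame            # 0/1 matrix, one column per exposure
    urate: pd.Series | None = None     # mmol/L, same index
    strata: pd.Series | None = None
    n_dropped: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        vals = self.exposures.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("exposure matrix must contain only 0/1")
        if not np.isin(self.outcome.to_numpy(), (0, 1)).all():
            raise ValueError("outcome must contain only 0/1")
        if not self.outcome.index.equals(self.exposures.index):
            raise ValueError("outcome/exposure index mismatch")

    @property
    def n(self) -> int:
        return len(self.outcome)

    @property
    def n_cases(self) -> int:
        return int(self.outcome.sum())

    @property
    def n_controls(self) -> int:
        return self.n - self.n_cases

    def f_cases(self, exposure: str) -> float:
        """Exposure frequency among hyperuricaemic cases."""
        cases = self.outcome == 1
        return float(self.exposures.loc[cases, exposure].mean())

    def subset(self, mask) -> "BinaryDesign":
        return BinaryDesign(
            outcome=self.outcome[mask],
            exposures=self.exposures[mask],
            urate=None if self.urate is None else self.urate[mask],
            strata=None if self.strata is None else self.strata[mask],
            meta=dict(self.meta),
        )


def dichotomize(cohort: pd.DataFrame, specs: list[ExposureSpec],
                hu_threshold: float = HU_THRESHOLD,
                stratum_field: str | None = None) -> BinaryDesign:
    """Code hyperuricaemia (urate >= threshold, inclusive, both sexes) and
    every exposure per its rule.  Complete-case: rows missing urate or any
    source field are dropped (counted in ``n_dropped``)."""
    required = ["urate"] + [s.source_field for s in specs]
    missing_cols = [c for c in dict.fromkeys(required) if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort table lacks required columns {missing_cols}")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate exposure names in spec set")

    complete = cohort[list(dict.fromkeys(required))].notna().all(axis=1)
    df = cohort[complete]
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("dichotomize: dropped %d incomplete rows", n_dropped)

    outcome = df["urate"].ge(hu_threshold).astype(int).rename("hyperuricaemia")
    exposures = pd.concat([s.apply(df) for s in specs], axis=1)
    if outcome.sum() == 0 or outcome.sum() == len(outcome):
        raise DegenerateDesignError(
            f"degenerate design: {int(outcome.sum())} cases out of {len(outcome)} rows")
    strata = df[stratum_field] if stratum_field else None
    return BinaryDesign(outcome=outcome, exposures=exposures,
                        urate=df["urate"], strata=strata,
                        n_dropped=n_dropped,
                        meta={"hu_threshold": hu_threshold})
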