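"""Synthetic cohorts: exposure, age, genotype strata and metadata.

Emulates a healthy-aging cohort stratified by age group (young < 60 <= old)
and APOE genotype (E3/E3 reference vs E3/E4 risk carriers), with an
accelerometer-derived exposure: total physical activity (TPA) as a fraction
of device wear time, a nonnegative, strongly right-skewed quantity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

STRATA = ("young-E3/E3", "young-E3/E4", "old-E3/E3", "old-E3/E4")

#: Stratum sizes of the emulated study sample (n = 113).
DEFAULT_STRATA_SIZES = {
    "young-E3/E4": 20,
    "old-E3/E4": 16,
    "young-E3/E3": 44,
    "old-E3/E3": 33,
}

DEFAULT_AGE_RANGES = {"young": (48.0, 59.0), "old": (60.0, 82.0)}

#: Fraction of male subjects per stratum, matched to the emulated sample.
_MALE_FRACTION = {
    "young-E3/E4": 4 / 20,
    "old-E3/E4": 3 / 16,
    "young-E3/E3": 12 / 44,
    "old-E3/E3": 12 / 33,
}

AGE_CUT = 60.0


def stratum_label(age_group: str, genotype: str) -> str:
    return f"{age_group}-{genotype}"


def stratum_of(cohort: pd.DataFrame) -> pd.Series:
    """Per-row stratum label 'young-E3/E3' etc."""
    return cohort["age_group"].str.cat(cohort["genotype"], sep="-")


def generate_cohort(
    strata_sizes: dict[str, int] | None = None,
    tpa_mean: float = 0.012,
    tpa_sd: float = 0.012,
    age_ranges: dict[str, tuple[float, float]] | None = None,
    age_cut: float = AGE_CUT,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw a cohort table with the requested stratum sizes.

    Exposure (``tpa``) is drawn from a gamma distribution parameterized by
    its mean and SD, which keeps it nonnegative and right-skewed (with the
    defaults mean == SD, i.e. an exponential). Ages are uniform within each
    age group's range; ``age_group`` is consistent with ``age_cut`` by
    construction. Sex, MMSE and BMI metadata are generated with realistic
    marginals but carry no signal.

    Returns a DataFrame with columns subject_id, age, age_group, genotype,
    tpa, sex, mmse, bmi.
    """
    if strata_sizes is None:
        strata_sizes = dict(DEFAULT_STRATA_SIZES)
    if age_ranges is None:
        age_ranges = dict(DEFAULT_AGE_RANGES)
    unknown = set(strata_sizes) - set(STRATA)
    if unknown:
        raise ValueError(f"unknown strata: {sorted(unknown)}")
    if any(n < 0 for n in strata_sizes.values()):
        raise ValueError("strata sizes must be >= 0")
    n_total = sum(strata_sizes.values())
    if n_total == 0:
        raise ValueError("empty cohort requested")
    if tpa_mean <= 0 or tpa_sd <= 0:
        raise ValueError("tpa_mean and tpa_sd must be > 0")

    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for label in STRATA:
        n = int(strata_sizes.get(label, 0))
        if n == 0:
            continue
        age_group, genotype = label.split("-", 1)
        lo, hi = age_ranges[age_group]
        if age_group == "young" and hi >= age_cut:
            raise ValueError("young age range must lie below the age cut")
        if age_group == "old" and lo < age_cut:
            raise ValueError("old age range must lie at or above the age cut")
        ages = rng.uniform(lo, hi, size=n)
        # gamma with requested mean/SD: shape k = (m/s)^2, scale = s^2/m
        shape = (tpa_mean / tpa_sd) ** 2
        scale = tpa_sd**2 / tpa_mean
        tpa = rng.gamma(shape, scale, size=n)
        sex = np.where(rng.random(n) < _MALE_FRACTION[label], "M", "F")
        mmse = np.clip(np.round(rng.normal(29.2, 0.9, size=n)), 26, 30)
        bmi = rng.normal(25.0, 3.5, size=n)
        for k in range(n):
            rows.append(
                {
                    "subject_id": f"sub-{idx:03d}",
                    "age": float(ages[k]),
                    "age_group": age_group,
                    "genotype": genotype,
                    "tpa": float(tpa[k]),
                    "sex": str(sex[k]),
                    "mmse": float(mmse[k]),
                    "bmi": float(bmi[k]),
                }
            )
            idx += 1
    cohort = pd.DataFrame(rows)
    validate_cohort(cohort, age_cut=age_cut)
    return cohort


def validate_cohort(cohort: pd.DataFrame, age_cut: float = AGE_CUT) -> None:
    """Raise ValueError on violated cohort invariants."""
    required = {"subject_id", "age", "age_group", "genotype", "tpa"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort is missing columns: {sorted(missing)}")
    if cohort["subject_id"].duplicated().any():
        dup = cohort.loc[cohort["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicated subject ids: {dup}")
    if (cohort["tpa"] < 0).any():
        raise ValueError("tpa must be >= 0")
    bad_geno = set(cohort["genotype"]) - {"E3/E3", "E3/E4"}
    if bad_geno:
        raise ValueError(f"unknown genotypes: {sorted(bad_geno)}")
    young = cohort["age_group"] == "young"
    if (cohort.loc[young, "age"] >= age_cut).any() or (
        cohort.loc[~young, "age"] < age_cut
    ).any():
        raise ValueError("age_group inconsistent with age cut")
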