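"""Variance-component analysis of section-level percent-CD8 measurements.

Two complementary decompositions of where the variability in percent CD8+
lives — between patients (tumor blocks) or between step sections within a
block:

* :func:`fixed_effects_anova` — an additive two-factor fixed-effects model
  ``percent ~ patient + section`` fitted by least squares, with sequential
  (type-I) sums of squares, patient entered first.  "Percent of variability
  explained" by a factor is its share of the total sum of squares.  The F
  test on the section term asks whether step depth has any systematic
  effect at all.
* :func:`random_intercept_icc` — a one-way random-intercept model in which
  each patient contributes a shared random level.  Estimation is by the
  ANOVA method of moments (with the standard harmonic-mean correction n0
  for unbalanced designs) with the patient variance truncated at zero; for
  balanced one-way layouts this coincides with REML.  The intraclass
  correlation coefficient ICC = sigma^2_patient / (sigma^2_patient +
  sigma^2_residual) summarises how interchangeable sections from the same
  block are: ICC near 1 means essentially all variation is between
  patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf


@dataclass(frozen=True)
class AnovaTable:
    """Sequential (type-I) ANOVA of percent ~ patient + section."""

    ss_patient: float
    ss_section: float
    ss_residual: float
    df_patient: int
    df_section: int
    df_residual: int
    f_section: float
    p_section: float

    @property
    def ss_total(self) -> float:
        return self.ss_patient + self.ss_section + self.ss_residual

    @property
    def pct_var_patient(self) -> float:
        """Share of total SS attributed to patient, in percent (nan if SS_total=0)."""
        return _ss_fraction(self.ss_patient, self.ss_total)

    @property
    def pct_var_section(self) -> float:
        return _ss_fraction(self.ss_section, self.ss_total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": ["patient", "section", "residual"],
                "ss": [self.ss_patient, self.ss_section, self.ss_residual],
                "df": [self.df_patient, self.df_section, self.df_residual],
                "pct_of_total_ss": [
                    self.pct_var_patient,
                    self.pct_var_section,
                    _ss_fraction(self.ss_residual, self.ss_total),
                ],
            }
        )


def _ss_fraction(ss: float, ss_total: float) -> float:
    if ss_total <= 0:
        return math.nan
    return 100.0 * ss / ss_total


@dataclass(frozen=True)
class VarianceComponents:
    """One-way random-effects variance components and the ICC."""

    sigma2_patient: float
    sigma2_residual: float

    @property
    def icc(self) -> float:
        total = self.sigma2_patient + self.sigma2_residual
        if total <= 0:
            return math.nan
        return self.sigma2_patient / total


def _validate(measurements: pd.DataFrame) -> pd.DataFrame:
    df = measurements
    required = {"patient_id", "percent_cd8"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurements lack columns {sorted(missing)}")
    if df["patient_id"].nunique() < 2:
        raise ValueError("need at least 2 patients")
    return df


def fixed_effects_anova(measurements: pd.DataFrame) -> AnovaTable:
    """Sequential two-factor ANOVA with patient entered before section.

    Requires a ``section`` column (step-depth index, treated as a crossed
    factor with common levels across patients) alongside ``patient_id`` and
    ``percent_cd8``.
    """
    df = _validate(measurements)
    if "section" not in df.columns:
        raise ValueError("measurements lack a 'section' column")
    counts = df.groupby("patient_id")["section"].count()
    if (counts < 2).all():
        raise ValueError("need at least one patient with >= 2 sections")
    if df["section"].nunique() < 2:
        raise ValueError("need at least 2 distinct section levels")

    y = df["percent_cd8"].to_numpy(dtype=float)
    if float(np.sum((y - y.mean()) ** 2)) == 0.0:
        # exactly constant response: every SS is identically zero and the
        # variance fractions are undefined (not 0/0)
        n_pat = df["patient_id"].nunique()
        n_sec = df["section"].nunique()
        return AnovaTable(
            ss_patient=0.0, ss_section=0.0, ss_residual=0.0,
            df_patient=n_pat - 1, df_section=n_sec - 1,
            df_residual=len(df) - n_pat - n_sec + 1,
            f_section=math.nan, p_section=math.nan,
        )

    model = smf.ols(
        "percent_cd8 ~ C(patient_id) + C(section)", data=df
    ).fit()
    table = sm.stats.anova_lm(model, typ=1)
    ss_patient = float(table.loc["C(patient_id)", "sum_sq"])
    ss_section = float(table.loc["C(section)", "sum_sq"])
    ss_residual = float(table.loc["Residual", "sum_sq"])
    return AnovaTable(
        ss_patient=ss_patient,
        ss_section=ss_section,
        ss_residual=ss_residual,
        df_patient=int(table.loc["C(patient_id)", "df"]),
        df_section=int(table.loc["C(section)", "df"]),
        df_residual=int(table.loc["Residual", "df"]),
        f_section=float(table.loc["C(section)", "F"]),
        p_section=float(table.loc["C(section)", "PR(>F)"]),
    )


def random_intercept_icc(measurements: pd.DataFrame) -> VarianceComponents:
    """Method-of-moments variance components for the one-way random model.

    With k patients, n_i sections each, N total: MSB is the between-patient
    mean square, MSW the pooled within-patient mean square, and

        sigma^2_patient = max(0, (MSB - MSW) / n0),
        n0 = (N - sum n_i^2 / N) / (k - 1)

    (n0 = n for balanced designs).  sigma^2_residual = MSW.
    """
    df = _validate(measurements)
    groups = df.groupby("patient_id")["percent_cd8"]
    n_i = groups.count().to_numpy(dtype=float)
    means = groups.mean().to_numpy()
    k = n_i.size
    n_total = n_i.sum()
    grand = float(np.sum(n_i * means) / n_total)

    msb = float(np.sum(n_i * (means - grand) ** 2) / (k - 1))
    within_ss = float(
        groups.apply(lambda v: np.sum((v.to_numpy() - v.mean()) ** 2)).sum()
    )
    df_within = n_total - k
    if df_within <= 0:
        raise ValueError("need replicate sections within patients to estimate MSW")
    msw = within_ss / df_within
    n0 = (n_total - np.sum(n_i**2) / n_total) / (k - 1)
    sigma2_patient = max(0.0, (msb - msw) / n0)
    return VarianceComponents(sigma2_patient=sigma2_patient, sigma2_residual=msw)
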