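"""Resampling of step sections to test single-slide CD8 classification.

The cohort "truth" for each patient is the mean percent CD8+ across all of
that patient's sections; the candidate cut-off is the cohort median of the
truths, and a patient is CD8-high when its value is >= the cut-off (the tie
rule is a declared convention — with continuous staining values ties have
measure zero).

Two bootstrap schemes ask whether one or two sections suffice:

* ``sections_only`` — the patient set stays fixed; per replicate, draw k
  sections with replacement per patient, summarise (mean or max), classify
  against the fixed cut-off and compare with the patient's truth class.
  This isolates within-tumor (technical) heterogeneity.
* ``patients_then_sections`` — draw patients with replacement first, then
  sections within each drawn patient; truth and cut-off remain those of the
  original cohort.  This additionally propagates between-patient sampling
  variability, mimicking a future cohort of the same size.

Agreement is overall concordance; sensitivity and specificity are computed
per replicate against the truth classes.  Replicates where a class is
absent contribute an undefined sensitivity or specificity and are skipped
for that metric (the skip counts are reported).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SCHEMES = ("sections_only", "patients_then_sections")


@dataclass(frozen=True)
class TruthTable:
    """Per-patient truth values/classes plus the cohort median cut-off."""

    truth: pd.DataFrame  # columns: patient_id, true_value, true_class
    cutoff: float

    def classes(self) -> pd.Series:
        return self.truth.set_index("patient_id")["true_class"]


@dataclass(frozen=True)
class AgreementSummary:
    scheme: str
    k_sections: int
    summary_stat: str
    n_reps: int
    agreement_mean: float  # percent
    agreement_ci95: tuple[float, float]
    sensitivity_mean: float
    specificity_mean: float
    n_skipped_sensitivity: int
    n_skipped_specificity: int


def patient_truth_and_cutoff(
    measurements: pd.DataFrame, exclude_tissue_loss: bool = False
) -> TruthTable:
    """Per-patient mean over sections, cohort-median cut-off, >= rule."""
    df = measurements
    if exclude_tissue_loss and "tissue_loss" in df.columns:
        df = df[~df["tissue_loss"].astype(bool)]
    if df.empty:
        raise ValueError("empty cohort")
    means = df.groupby("patient_id")["percent_cd8"].mean()
    cutoff = float(means.median())  # midpoint convention for even counts
    truth = pd.DataFrame(
        {
            "patient_id": means.index,
            "true_value": means.to_numpy(),
            "true_class": np.where(means.to_numpy() >= cutoff, "high", "low"),
        }
    ).reset_index(drop=True)
    return TruthTable(truth=truth, cutoff=cutoff)


def _summarise(draws: np.ndarray, summary_stat: str) -> np.ndarray:
    if summary_stat == "mean":
        return draws.mean(axis=-1)
    if summary_stat == "max":
        return draws.max(axis=-1)
    raise ValueError(f"unknown summary_stat {summary_stat!r}")


def resample_section_classification(
    measurements: pd.DataFrame,
    k_sections: int,
    summary_stat: str = "mean",
    scheme: str = "sections_only",
    n_reps: int = 1000,
    seed: int = 0,
    exclude_tissue_loss: bool = False,
) -> AgreementSummary:
    """Bootstrap k-section classification against the cohort-median cut-off."""
    if k_sections < 1:
        raise ValueError("k_sections must be >= 1")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")

    df = measurements
    if exclude_tissue_loss and "tissue_loss" in df.columns:
        df = df[~df["tissue_loss"].astype(bool)]
    truth_table = patient_truth_and_cutoff(df)
    cutoff = truth_table.cutoff
    patients = truth_table.truth["patient_id"].to_numpy()
    true_high = truth_table.truth["true_class"].to_numpy() == "high"
    n_patients = patients.size

    values = {
        pid: sub["percent_cd8"].to_numpy()
        for pid, sub in df.groupby("patient_id")
    }
    rng = np.random.default_rng(seed)

    # classified[r, j]: CD8-high call for the j-th (drawn) patient in rep r
    if scheme == "sections_only":
        patient_idx = np.broadcast_to(np.arange(n_patients), (n_reps, n_patients))
    else:
        patient_idx = rng.integers(0, n_patients, size=(n_reps, n_patients))

    estimates = np.empty((n_reps, n_patients))
    if scheme == "sections_only":
        for j, pid in enumerate(patients):
            v = values[pid]
            draws = v[rng.integers(0, v.size, size=(n_reps, k_sections))]
            estimates[:, j] = _summarise(draws, summary_stat)
    else:
        # sections drawn per (rep, slot) for the patient occupying that slot
        for j in range(n_patients):
            col_pids = patient_idx[:, j]
            col_est = np.empty(n_reps)
            for pid_code in np.unique(col_pids):
                mask = col_pids == pid_code
                v = values[patients[pid_code]]
                draws = v[rng.integers(0, v.size, size=(int(mask.sum()), k_sections))]
                col_est[mask] = _summarise(draws, summary_stat)
            estimates[:, j] = col_est

    called_high = estimates >= cutoff
    slot_truth = true_high[patient_idx]  # (n_reps, n_patients)
    concordant = called_high == slot_truth

    agreement = concordant.mean(axis=1) * 100.0

    n_high = slot_truth.sum(axis=1)
    n_low = n_patients - n_high
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(
            n_high > 0, (concordant & slot_truth).sum(axis=1) / n_high, np.nan
        ) * 100.0
        spec = np.where(
            n_low > 0, (concordant & ~slot_truth).sum(axis=1) / n_low, np.nan
        ) * 100.0

    ci = tuple(np.percentile(agreement, [2.5, 97.5]))
    return AgreementSummary(
        scheme=scheme,
        k_sections=k_sections,
        summary_stat=summary_stat,
        n_reps=n_reps,
        agreement_mean=float(agreement.mean()),
        agreement_ci95=(float(ci[0]), float(ci[1])),
        sensitivity_mean=float(np.nanmean(sens)),
        specificity_mean=float(np.nanmean(spec)),
        n_skipped_sensitivity=int(np.isnan(sens).sum()),
        n_skipped_specificity=int(np.isnan(spec).sum()),
    )
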