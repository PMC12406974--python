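"""Pol II Degrader Similarity (PDS) scoring.

A drug that kills cells through degradation of RNA polymerase II shows a
characteristic functional-genetic signature: its lethality is attenuated in
PTBP1-knockout and BCL2L12-knockout cells and (being apoptotic) in
BAX/BAK double-knockout cells.  The PDS score quantifies how strongly a
drug-dose pair shares that signature.

For each genotype, the area under the fitted LED lethal-fraction curve
(AUC) is computed and the untreated same-genotype AUC subtracted (baseline
death removal).  The dependency on each knockout is ``1 − AUC_KO /
AUC_WT``; the PTBP1-KO and BCL2L12-KO dependencies are summed and the sum
divided by that of the reference condition (1 μM triptolide by default), so
a score of 1 denotes a functional-genetic signature equal to the
reference degrader's.

Conditions whose maximum observed lethal fraction stays below 0.16 —
roughly double untreated background death — are non-lethal and not scored.
Apoptotic dependence is called when the BAX/BAK DKO background shows at
least a 50% reduction in maximum lethal fraction relative to wild type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LETHALITY_THRESHOLD",
    "APOPTOTIC_REDUCTION",
    "PDSResult",
    "baseline_subtracted_auc",
    "classify_lethality",
    "classify_apoptotic",
    "ko_dependency",
    "pds_score",
    "pds_table",
    "pds_matrix",
]

#: Maximum observed lethal fraction below which a condition is non-lethal.
LETHALITY_THRESHOLD = 0.16
#: Minimum fractional reduction of max LF in BAX/BAK DKO to call death apoptotic.
APOPTOTIC_REDUCTION = 0.5
#: WT AUCs at or below this are non-scorable (dependency ratio undefined).
AUC_EPS = 1e-6

WT = "WT"
PTBP1_KO = "PTBP1-KO"
BCL2L12_KO = "BCL2L12-KO"
DKO = "BAX-BAK-DKO"

DEFAULT_REFERENCE = ("triptolide", 1.0)


@dataclass
class PDSResult:
    drug: str
    dose: float
    lethal: bool
    apoptotic: bool | None
    dep_ptbp1: float
    dep_bcl2l12: float
    raw_score: float
    pds: float
    flags: list = field(default_factory=list)


def baseline_subtracted_auc(auc_treated: float, auc_untreated: float):
    """Treated AUC minus the untreated same-genotype AUC, floored at zero.

    A treated well cannot be "less dead" than untreated in score space, so
    negative differences are floored at 0; the flag reports when that
    happened.  Returns ``(value, flag)``.
    """
    if not (np.isfinite(auc_treated) and np.isfinite(auc_untreated)):
        return np.nan, "unconverged-fit"
    diff = auc_treated - auc_untreated
    if diff < 0:
        return 0.0, "negative-baseline"
    return diff, None


def classify_lethality(max_observed_lf: float) -> bool:
    """Lethal iff the maximum observed lethal fraction reaches 0.16."""
    if not 0.0 <= max_observed_lf <= 1.0:
        raise ValueError("max observed LF must lie in [0, 1]")
    return not max_observed_lf < LETHALITY_THRESHOLD


def classify_apoptotic(max_lf_wt: float, max_lf_dko: float) -> bool | None:
    """Apoptotic iff BAX/BAK DKO reduces max LF by at least 50% versus WT."""
    if max_lf_wt == 0:
        return None
    return (max_lf_wt - max_lf_dko) / max_lf_wt >= APOPTOTIC_REDUCTION


def ko_dependency(auc_ko: float, auc_wt: float, eps: float = AUC_EPS):
    """Dependency of death on a knockout: ``1 − AUC_KO / AUC_WT``.

    Negative values (the knockout sensitizes) are preserved but flagged.
    Returns ``(value, flag)``; NaN (non-scorable) when the WT AUC is ≤ eps.
    """
    if not (np.isfinite(auc_ko) and np.isfinite(auc_wt)) or auc_wt <= eps:
        return np.nan, "non-scorable"
    dep = 1.0 - auc_ko / auc_wt
    return dep, ("sensitization" if dep < 0 else None)


def pds_score(
    auc_by_genotype: dict,
    max_lf_by_genotype: dict,
    reference_raw: float,
) -> PDSResult | dict:
    """Score one drug-dose panel given baseline-subtracted AUCs per genotype.

    ``auc_by_genotype`` maps genotype → baseline-subtracted AUC;
    ``max_lf_by_genotype`` maps genotype → max observed LF.  The raw score
    is the sum of the PTBP1-KO and BCL2L12-KO dependencies; the PDS is the
    raw score divided by ``reference_raw`` (the raw score of the reference
    condition on the same dataset).  A non-lethal panel gets a missing PDS.
    """
    flags: list = []
    lethal = classify_lethality(max_lf_by_genotype[WT])
    apoptotic = None
    if DKO in max_lf_by_genotype:
        apoptotic = classify_apoptotic(max_lf_by_genotype[WT], max_lf_by_genotype[DKO])
    if not lethal:
        return PDSResult("", np.nan, False, apoptotic, np.nan, np.nan, np.nan, np.nan,
                         flags=["non-lethal"])
    dep_p, flag_p = ko_dependency(auc_by_genotype[PTBP1_KO], auc_by_genotype[WT])
    dep_b, flag_b = ko_dependency(auc_by_genotype[BCL2L12_KO], auc_by_genotype[WT])
    flags += [f for f in (flag_p, flag_b) if f]
    raw = dep_p + dep_b
    if not np.isfinite(raw):
        return PDSResult("", np.nan, True, apoptotic, dep_p, dep_b, np.nan, np.nan, flags=flags)
    if not (np.isfinite(reference_raw) and reference_raw > 0):
        raise ValueError("reference raw score must be positive and finite")
    return PDSResult("", np.nan, True, apoptotic, dep_p, dep_b, raw, raw / reference_raw,
                     flags=flags)


def _raw_score_for(led_df: pd.DataFrame, drug: str, dose: float,
                   untreated_drug: str) -> tuple[dict, dict, list]:
    """Collect baseline-subtracted AUCs and max LFs for one drug-dose."""
    aucs: dict = {}
    max_lfs: dict = {}
    flags: list = []
    sub = led_df[(led_df["drug"] == drug) & (led_df["dose_uM"] == dose)]
    unt = led_df[led_df["drug"] == untreated_drug]
    for genotype in sub["genotype"].unique():
        row = sub[sub["genotype"] == genotype].iloc[0]
        unt_g = unt[unt["genotype"] == genotype]
        if unt_g.empty:
            raise ValueError(f"no untreated row for genotype {genotype!r}")
        auc, flag = baseline_subtracted_auc(row["auc"], unt_g.iloc[0]["auc"])
        if flag:
            flags.append(f"{genotype}:{flag}")
        aucs[genotype] = auc
        max_lfs[genotype] = row["max_observed_lf"]
    return aucs, max_lfs, flags


def pds_table(
    led_df: pd.DataFrame,
    reference: tuple[str, float] = DEFAULT_REFERENCE,
    reference_raw: float | None = None,
    untreated_drug: str = "untreated",
) -> pd.DataFrame:
    """Compute PDS scores for every drug-dose pair of a fitted-LED table.

    ``led_df`` is the one-row-per-condition output of
    :func:`pdarkit.kinetics.fit_led_table` with genotype/drug/dose_uM
    columns.  The reference raw score is computed from the reference
    condition in the same table unless supplied explicitly.
    """
    pairs = (
        led_df[led_df["drug"] != untreated_drug][["drug", "dose_uM"]]
        .drop_duplicates()
        .itertuples(index=False)
    )
    pairs = [(p.drug, p.dose_uM) for p in pairs]

    if reference_raw is None:
        ref_drug, ref_dose = reference
        if (ref_drug, ref_dose) not in pairs:
            raise ValueError(
                f"reference condition {reference!r} absent from dataset and no "
                "explicit reference_raw supplied"
            )
        aucs, max_lfs, _ = _raw_score_for(led_df, ref_drug, ref_dose, untreated_drug)
        dep_p, _ = ko_dependency(aucs[PTBP1_KO], aucs[WT])
        dep_b, _ = ko_dependency(aucs[BCL2L12_KO], aucs[WT])
        reference_raw = dep_p + dep_b
        if not (np.isfinite(reference_raw) and reference_raw > 0):
            raise ValueError("reference condition is non-scorable on this dataset")

    rows = []
    for drug, dose in pairs:
        aucs, max_lfs, flags = _raw_score_for(led_df, drug, dose, untreated_drug)
        res = pds_score(aucs, max_lfs, reference_raw)
        res.drug, res.dose = drug, dose
        res.flags = flags + res.flags
        rows.append(
            dict(
                drug=drug, dose_uM=dose, lethal=res.lethal, apoptotic=res.apoptotic,
                dep_ptbp1=res.dep_ptbp1, dep_bcl2l12=res.dep_bcl2l12,
                raw_score=res.raw_score, pds=res.pds, flags=";".join(res.flags),
            )
        )
    return pd.DataFrame(rows)


def pds_matrix(pds_df: pd.DataFrame) -> pd.DataFrame:
    """Pivot PDS scores to a drugs × doses matrix; non-lethal cells are NaN."""
    return pds_df.pivot_table(index="drug", columns="dose_uM", values="pds", dropna=False)
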