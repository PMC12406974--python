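"""Probabilistic "PD-like" drug classifier.

Each lethal drug-dose pair is placed in a 3-dimensional functional-genetic
space given by its baseline-subtracted AUC ratios versus wild type:
(PTBP1-KO/WT, BCL2L12-KO/WT, BAX-BAK-DKO/WT).  Validated Pol II degraders
(triptolide and α-amanitin at their lethal doses) define a reference
neighborhood; its base statistic is the mean pairwise Euclidean distance
among members.  The linkage ratio of a query is the factor by which that
mean changes when the query is added — a compound with a degrader-like
signature barely expands the neighborhood (ratio near or below 1).

The null distribution comes from "false expansion": a panel of
negative-control drugs with mechanisms unrelated to transcriptional
inhibition (BH3 mimetics, topoisomerase inhibitors, ER-stress inducers) is
forced into the neighborhood one compound at a time, and their linkage
ratios form the empirical null.  A query's p-value is the smoothed
left-tail rank of its ratio in that null; Benjamini–Hochberg correction
across all queried pairs yields q-values and the binary PD-like call at
q < α (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FunctionalPoint",
    "NeighborhoodModel",
    "ClassifierResult",
    "functional_coordinates",
    "neighborhood_stat",
    "linkage_ratio",
    "false_expansion_null",
    "classify_pd_like",
]

#: Negative-control drugs used to generate the false-expansion null.
DEFAULT_NEGATIVE_DRUGS = (
    "ABT-199", "ABT-263", "ABT-737",
    "etoposide", "camptothecin", "idarubicin", "topotecan", "teniposide",
    "thapsigargin", "tunicamycin", "brefeldin-A",
)
#: Validated Pol II degraders whose lethal doses define the neighborhood.
DEFAULT_MEMBER_DRUGS = ("triptolide", "alpha-amanitin")

AUC_EPS = 1e-6


@dataclass
class FunctionalPoint:
    """One drug-dose pair in (PTBP1-KO/WT, BCL2L12-KO/WT, DKO/WT) AUC-ratio space."""

    drug: str
    dose: float
    coords: np.ndarray
    lethal: bool = True

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError("functional coordinates must be a 3-vector")
        if not np.all(np.isfinite(self.coords)) or np.any(self.coords < 0):
            raise ValueError("functional coordinates must be finite and non-negative")


def functional_coordinates(
    auc_wt: float, auc_ptbp1: float, auc_bcl2l12: float, auc_dko: float,
    drug: str = "", dose: float = np.nan, eps: float = AUC_EPS,
) -> FunctionalPoint | None:
    """AUC ratios of each knockout versus wild type; None if WT AUC ≤ eps.

    Inputs are baseline-subtracted AUCs.  A vanishing WT AUC means the
    condition caused no death in wild type and is excluded (non-lethal).
    """
    if not np.isfinite(auc_wt) or auc_wt <= eps:
        return None
    coords = np.array([auc_ptbp1, auc_bcl2l12, auc_dko], dtype=float) / auc_wt
    return FunctionalPoint(drug=drug, dose=dose, coords=coords)


def neighborhood_stat(points) -> float:
    """Mean pairwise Euclidean distance among a set of functional points."""
    coords = np.vstack([p.coords for p in points])
    if len(coords) < 2:
        raise ValueError("neighborhood statistic requires at least 2 points")
    return float(np.mean(pdist(coords)))


@dataclass
class NeighborhoodModel:
    """Reference degrader neighborhood plus negative controls for the null."""

    members: list
    negatives: list
    base_stat: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("neighborhood requires at least 2 members")
        self.base_stat = neighborhood_stat(self.members)


def linkage_ratio(query: FunctionalPoint, model: NeighborhoodModel) -> float:
    """Neighborhood expansion factor when the query joins the member set."""
    if model.base_stat <= 0:
        raise ValueError("degenerate neighborhood: base statistic is 0")
    return neighborhood_stat(list(model.members) + [query]) / model.base_stat


def false_expansion_null(model: NeighborhoodModel) -> np.ndarray:
    """Null linkage ratios: each negative control inserted one at a time."""
    if not model.negatives:
        raise ValueError("false expansion requires at least one negative control")
    return np.array([linkage_ratio(p, model) for p in model.negatives])


@dataclass
class ClassifierResult:
    drug: str
    dose: float
    linkage_ratio: float
    p: float
    q: float
    pd_like: bool


def classify_pd_like(queries, model: NeighborhoodModel, alpha: float = 0.05):
    """Classify drug-dose pairs as PD-like against the false-expansion null.

    Small linkage ratios are significant (a PD-like compound barely expands
    the degrader neighborhood): ``p = (1 + #{null ≤ r}) / (1 + N_null)``
    with add-one smoothing.  BH correction runs over all queried pairs;
    PD-like iff q < alpha.  Non-lethal points should be excluded upstream.
    """
    queries = list(queries)
    if not queries:
        return []
    null = false_expansion_null(model)
    ratios = np.array([linkage_ratio(q, model) for q in queries])
    p = (1.0 + (null[None, :] <= ratios[:, None]).sum(axis=1)) / (1.0 + len(null))
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return [
        ClassifierResult(
            drug=pt.drug, dose=pt.dose, linkage_ratio=float(r),
            p=float(pi), q=float(qi), pd_like=bool(qi < alpha),
        )
        for pt, r, pi, qi in zip(queries, ratios, p, q)
    ]


def points_from_led_table(led_df: pd.DataFrame, untreated_drug: str = "untreated"):
    """Build functional points for every lethal drug-dose of a fitted-LED table.

    Uses baseline-subtracted AUCs (untreated same-genotype AUC removed).
    Non-lethal pairs (WT max observed LF below the lethality threshold) and
    pairs with vanishing WT AUC are excluded a priori.
    """
    from .pds import WT, PTBP1_KO, BCL2L12_KO, DKO, classify_lethality, _raw_score_for

    points = []
    pairs = (
        led_df[led_df["drug"] != untreated_drug][["drug", "dose_uM"]]
        .drop_duplicates()
        .itertuples(index=False)
    )
    for drug, dose in [(p.drug, p.dose_uM) for p in pairs]:
        aucs, max_lfs, _ = _raw_score_for(led_df, drug, dose, untreated_drug)
        if not classify_lethality(max_lfs[WT]):
            continue
        pt = functional_coordinates(
            aucs[WT], aucs[PTBP1_KO], aucs[BCL2L12_KO], aucs[DKO],
            drug=drug, dose=dose,
        )
        if pt is not None:
            points.append(pt)
    return points


def build_model(
    points,
    member_drugs=DEFAULT_MEMBER_DRUGS,
    negative_drugs=DEFAULT_NEGATIVE_DRUGS,
) -> NeighborhoodModel:
    """Split functional points into neighborhood members and negatives by drug."""
    members = [p for p in points if p.drug in member_drugs]
    negatives = [p for p in points if p.drug in negative_drugs]
    return NeighborhoodModel(members=members, negatives=negatives)


def results_table(results) -> pd.DataFrame:
    """Per drug-dose classifier output as a tidy frame."""
    return pd.DataFrame(
        [
            dict(drug=r.drug, dose_uM=r.dose, linkage_ratio=r.linkage_ratio,
                 p=r.p, q=r.q, pd_like=r.pd_like)
            for r in results
        ]
    )
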