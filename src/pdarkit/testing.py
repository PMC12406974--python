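"""Seeded benchmark harnesses shared by the test suite and validation scripts.

These run the pipeline's own components on synthetic libraries with known
ground truth and summarize recovery performance.  They live in the package
(not the test suite) so validation scripts can reuse them.
"""

from __future__ import annotations

import numpy as np

from .classifier import FunctionalPoint, NeighborhoodModel, classify_pd_like

__all__ = ["synthetic_library_performance"]

#: Functional-genetic centroid of a degrader-like signature: strong loss of
#: death in all three knockout backgrounds, so all AUC ratios are small.
DEGRADER_CENTROID = np.array([0.15, 0.12, 0.08])


def synthetic_library_performance(
    n_seeds: int = 100,
    n_pos: int = 10,
    n_neg: int = 10,
    n_members: int = 4,
    n_negative_drugs: int = 11,
    doses_per_negative: int = 4,
    noise_sd: float = 0.05,
    alpha: float = 0.05,
    base_seed: int = 0,
):
    """Classifier sensitivity/specificity on seeded synthetic drug libraries.

    Each replicate draws a degrader neighborhood (members near the degrader
    centroid, Gaussian noise ``noise_sd``), a false-expansion null from the
    negative-control panel (``n_negative_drugs`` drugs at
    ``doses_per_negative`` lethal doses each, far from the centroid), and a
    query library of ``n_pos`` degrader-like and ``n_neg`` unrelated
    drug-dose pairs.  Returns ``(sensitivities, specificities)`` arrays,
    one entry per seed.
    """
    sens, spec = [], []
    for k in range(n_seeds):
        rng = np.random.default_rng(base_seed + k)
        members = [
            FunctionalPoint("member", 1.0, np.abs(DEGRADER_CENTROID + rng.normal(0, noise_sd, 3)))
            for _ in range(n_members)
        ]
        negatives = [
            FunctionalPoint(f"neg{i}", float(j), rng.uniform(0.7, 1.3, 3))
            for i in range(n_negative_drugs)
            for j in range(doses_per_negative)
        ]
        model = NeighborhoodModel(members=members, negatives=negatives)
        pos_queries = [
            FunctionalPoint("pos", 1.0, np.abs(DEGRADER_CENTROID + rng.normal(0, noise_sd, 3)))
            for _ in range(n_pos)
        ]
        neg_queries = [
            FunctionalPoint("far", 1.0, rng.uniform(0.7, 1.3, 3)) for _ in range(n_neg)
        ]
        res = classify_pd_like(pos_queries + neg_queries, model, alpha=alpha)
        calls = np.array([r.pd_like for r in res])
        sens.append(calls[:n_pos].mean())
        spec.append(1.0 - calls[n_pos:].mean())
    return np.array(sens), np.array(spec)
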