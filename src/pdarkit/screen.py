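"""Gene-level death-regulator statistics for pooled knockout screens.

The screen separates live cells from apoptotic corpses after drug exposure
and sequences both populations, so guides targeting death regulators
enrich or deplete in the dead fraction.  The analysis chain:

1. depth normalization by the median-of-ratios method,
2. removal of the bottom ~2% of guides by mean normalized count,
3. per-guide log2 fold changes for a chosen sample contrast (plain
   normalized-count log-ratio with pseudocount 0.5 — a deliberate
   simplification with no dispersion shrinkage),
4. z-scoring against the distribution of non-targeting control guides,
5. median collapse of guide z-scores to gene level,
6. an empiric bootstrap p-value per gene (null medians resampled from the
   pooled guide-level scores), and
7. Benjamini–Hochberg FDR correction with hit calling at q < 0.1.

The reference library layout is 4 sgRNA per gene plus 142 non-targeting
controls; guide multiplicities other than 4 are handled (the bootstrap
null is built per observed guide count).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NONTARGETING",
    "GuideCountTable",
    "median_of_ratios_normalize",
    "filter_low_count_guides",
    "guide_log2fc",
    "zscore_to_nontargeting",
    "gene_median_collapse",
    "bootstrap_empiric_p",
    "bh_fdr",
    "call_hits",
    "run_screen",
]

#: Gene label marking non-targeting control guides.
NONTARGETING = "NONTARGETING"
DEFAULT_FDR = 0.1
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class GuideCountTable:
    """sgRNA counts: guide metadata plus per-sample (normalized) counts."""

    guides: pd.DataFrame  # columns: guide_id, gene
    counts: pd.DataFrame  # index aligned with guides, one column per sample
    size_factors: pd.Series | None = None
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.guides.index.equals(self.counts.index):
            raise ValueError("guide metadata and counts must share an index")
        if (self.counts < 0).any().any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GuideCountTable":
        """Build from a table with guide_id, gene, then one column per sample."""
        meta_cols = ["guide_id", "gene"]
        missing = set(meta_cols) - set(df.columns)
        if missing:
            raise ValueError(f"count table missing columns: {sorted(missing)}")
        samples = [c for c in df.columns if c not in meta_cols]
        return cls(guides=df[meta_cols].copy(), counts=df[samples].astype(float))

    @property
    def samples(self) -> list:
        return list(self.counts.columns)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.guides, self.counts], axis=1)


def median_of_ratios_normalize(table: GuideCountTable) -> GuideCountTable:
    """Depth-normalize counts by the median-of-ratios method.

    The reference for each guide is its geometric mean across samples
    (guides with a zero in any sample are excluded from the reference);
    each sample's size factor is the median of its count/reference ratios,
    and normalized counts are counts divided by the size factor.
    """
    counts = table.counts
    if counts.shape[1] < 2:
        raise ValueError("median-of-ratios needs at least 2 samples")
    all_nonzero = (counts > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no guide has nonzero counts in every sample")
    ref = np.exp(np.log(counts.loc[all_nonzero]).mean(axis=1))
    size_factors = counts.loc[all_nonzero].div(ref, axis=0).median(axis=0)
    return GuideCountTable(
        guides=table.guides.copy(),
        counts=counts.div(size_factors, axis=1),
        size_factors=size_factors,
        normalized=True,
        meta=dict(table.meta),
    )


def filter_low_count_guides(table: GuideCountTable, quantile: float = 0.02) -> GuideCountTable:
    """Drop guides whose mean normalized count falls strictly below the
    given quantile of all guide means (bottom ~2% by default)."""
    if quantile == 0:
        return table
    means = table.counts.mean(axis=1)
    cutoff = means.quantile(quantile)
    keep = means >= cutoff  # strictly-below-percentile removal
    return GuideCountTable(
        guides=table.guides.loc[keep].copy(),
        counts=table.counts.loc[keep].copy(),
        size_factors=table.size_factors,
        normalized=table.normalized,
        meta=dict(table.meta),
    )


def guide_log2fc(
    table: GuideCountTable,
    contrast: tuple[str, str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """Per-guide log2 fold change between two samples of a normalized table.

    ``contrast = (numerator_sample, denominator_sample)``, e.g.
    ``("dead", "live")`` for dead-fraction enrichment.
    """
    a, b = contrast
    for s in (a, b):
        if s not in table.counts.columns:
            raise ValueError(f"sample {s!r} not in count table")
    return np.log2(
        (table.counts[a] + pseudocount) / (table.counts[b] + pseudocount)
    ).rename("log2fc")


def zscore_to_nontargeting(scores: pd.Series, nontargeting_scores) -> pd.Series:
    """Z-score guide-level values against the non-targeting guide distribution."""
    nt = np.asarray(nontargeting_scores, dtype=float)
    if len(nt) < 2:
        raise ValueError("need at least 2 non-targeting scores")
    sd = nt.std(ddof=1)
    if sd == 0:
        raise ValueError("non-targeting scores have zero spread")
    return (scores - nt.mean()) / sd


def gene_median_collapse(z: pd.Series, genes: pd.Series) -> pd.Series:
    """Median guide z-score per gene (non-targeting guides excluded)."""
    keep = genes != NONTARGETING
    return z[keep].groupby(genes[keep]).median().rename("median_z")


def bootstrap_empiric_p(
    median_z: pd.Series,
    guide_z: pd.Series,
    guides_per_gene: pd.Series | int,
    B: int = 10_000,
    seed: int | None = None,
) -> pd.Series:
    """Two-sided empiric p-value per gene via bootstrap from pooled guide scores.

    For each guide multiplicity g present in the data, B null medians are
    drawn by resampling g guide-level scores (with replacement) from the
    pooled distribution; the p-value is the add-one-smoothed fraction of
    null medians at least as extreme in absolute value as the observed gene
    median.
    """
    if B < 1000:
        raise ValueError("bootstrap needs B >= 1000")
    pool = np.asarray(guide_z, dtype=float)
    pool = pool[np.isfinite(pool)]
    rng = np.random.default_rng(seed)
    if np.isscalar(guides_per_gene):
        guides_per_gene = pd.Series(int(guides_per_gene), index=median_z.index)
    if (guides_per_gene < 1).any():
        raise ValueError("every gene needs at least 1 guide")

    p = pd.Series(np.nan, index=median_z.index, name="p")
    for g, genes in median_z.groupby(guides_per_gene.reindex(median_z.index)):
        null = np.abs(
            np.median(rng.choice(pool, size=(B, int(g)), replace=True), axis=1)
        )
        null.sort()
        obs = np.abs(genes.to_numpy())
        # count of |null| >= |obs| via sorted search
        ge = B - np.searchsorted(null, obs, side="left")
        p.loc[genes.index] = (1.0 + ge) / (1.0 + B)
    return p


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p, dtype=float)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def call_hits(gene_df: pd.DataFrame, fdr: float = DEFAULT_FDR) -> pd.DataFrame:
    """Flag hits at q < fdr; direction from the sign of the gene median z."""
    out = gene_df.copy()
    out["hit"] = out["q"] < fdr
    out["direction"] = np.where(out["median_z"] > 0, "enriched", "depleted")
    return out


def run_screen(
    table: GuideCountTable,
    contrast: tuple[str, str],
    B: int = 10_000,
    seed: int | None = None,
    fdr: float = DEFAULT_FDR,
    low_count_quantile: float = 0.02,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Full screen analysis: normalize → filter → log2FC → z → collapse → p → q.

    ``contrast`` is required: e.g. ``("dead", "live")`` scores enrichment of
    knockouts among apoptotic corpses relative to surviving cells.
    Returns the gene-level table with median_z, p, q, hit and direction.
    """
    norm = median_of_ratios_normalize(table)
    norm = filter_low_count_guides(norm, quantile=low_count_quantile)
    lfc = guide_log2fc(norm, contrast, pseudocount=pseudocount)
    genes = norm.guides["gene"]
    nt_scores = lfc[genes == NONTARGETING]
    z = zscore_to_nontargeting(lfc, nt_scores)
    median_z = gene_median_collapse(z, genes)
    n_guides = genes[genes != NONTARGETING].value_counts().reindex(median_z.index)
    p = bootstrap_empiric_p(median_z, z[genes != NONTARGETING], n_guides, B=B, seed=seed)
    out = pd.DataFrame({"median_z": median_z, "p": p})
    out["q"] = bh_fdr(out["p"].to_numpy())
    out = call_hits(out, fdr=fdr)
    out.index.name = "gene"
    out.attrs["seed"] = seed
    out.attrs["contrast"] = contrast
    return out.reset_index()
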