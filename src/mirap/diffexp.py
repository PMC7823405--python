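"""Two-condition differential expression over mature-miRNA counts.

The stage reproduces the displayed artifacts of a DESeq-style analysis
without its negative-binomial testing machinery: median-of-ratios size
factors, normalized counts, log2 fold changes with a pseudocount, sample
PCA, ranked top-100/top-25 up- and down-regulated lists, and a seeded
label-permutation p-value on the fold change as the significance statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats
from sklearn.decomposition import PCA

logger = logging.getLogger("mirap")


def size_factors_median_of_ratios(raw: pd.DataFrame) -> pd.Series:
    """Median-of-ratios sample size factors.

    Rows with any zero count are excluded from the reference. For each
    remaining row the reference is the geometric mean across samples;
    a sample's factor is the median of its count/reference ratios.
    Raises when no all-positive row exists (filter low-count miRNAs first).
    """
    positive = raw[(raw > 0).all(axis=1)]
    if positive.empty:
        raise ValueError(
            "median-of-ratios needs at least one miRNA with nonzero counts in "
            "every sample; filter the count matrix first"
        )
    log_counts = np.log(positive.to_numpy(dtype=float))
    log_geomean = log_counts.mean(axis=1)
    factors = np.exp(np.median(log_counts - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=raw.columns, name="size_factor")


@dataclass
class DEResult:
    """Differential-expression outputs for condition B vs A."""

    condition_a: str
    condition_b: str
    size_factors: pd.Series
    normalized: pd.DataFrame
    table: pd.DataFrame  # base_mean, mean_a, mean_b, log2_fold_change, p_value
    top100: pd.DataFrame
    top25: pd.DataFrame
    pca_scores: pd.DataFrame | None = None
    pca_variance: np.ndarray | None = None

    def to_tsv(self, outdir) -> None:
        self.table.to_csv(f"{outdir}/de_results.tsv", sep="\t")
        self.top100.to_csv(f"{outdir}/top100.tsv", sep="\t")
        self.top25.to_csv(f"{outdir}/top25.tsv", sep="\t")
        self.size_factors.to_frame().to_csv(f"{outdir}/size_factors.tsv", sep="\t")
        if self.pca_scores is not None:
            self.pca_scores.to_csv(f"{outdir}/pca_scores.tsv", sep="\t")


def _group_log2fc(norm: np.ndarray, mask_b: np.ndarray, pseudocount: float) -> np.ndarray:
    mean_a = norm[:, ~mask_b].mean(axis=1)
    mean_b = norm[:, mask_b].mean(axis=1)
    return np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)


def normalize_and_rank(
    raw: pd.DataFrame,
    factors: pd.Series,
    conditions: dict[str, str],
    pseudocount: float = 1.0,
    n_permutations: int = 1000,
    seed: int = 0,
) -> DEResult:
    """Normalize counts, compute log2 fold changes and ranked lists.

    ``conditions`` maps each sample (column of ``raw``) to one of exactly
    two labels; fold changes are B vs A with labels ordered alphabetically.
    Significance is a two-sided label-permutation p-value on the fold change
    (add-one corrected), seeded for reproducibility.
    """
    missing = [s for s in raw.columns if s not in conditions]
    if missing:
        raise ValueError(f"samples missing from the condition table: {missing}")
    labels = [conditions[s] for s in raw.columns]
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two conditions required, got {uniq}")
    cond_a, cond_b = uniq

    normalized = raw / factors
    norm = normalized.to_numpy(dtype=float)
    mask_b = np.array([lab == cond_b for lab in labels])
    mean_a = norm[:, ~mask_b].mean(axis=1)
    mean_b = norm[:, mask_b].mean(axis=1)
    log2fc = _group_log2fc(norm, mask_b, pseudocount)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(log2fc))
    for _ in range(n_permutations):
        perm = rng.permutation(mask_b)
        exceed += np.abs(_group_log2fc(norm, perm, pseudocount)) >= np.abs(log2fc)
    p_value = (1.0 + exceed) / (1.0 + n_permutations)

    table = pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1),
            f"mean_{cond_a}": mean_a,
            f"mean_{cond_b}": mean_b,
            "log2_fold_change": log2fc,
            "p_value": p_value,
        },
        index=raw.index,
    ).sort_values("log2_fold_change", ascending=False)

    def _top(n: int) -> pd.DataFrame:
        up = table.nlargest(n, "log2_fold_change")
        down = table.nsmallest(n, "log2_fold_change")
        up = up.assign(direction="up")
        down = down.assign(direction="down")
        return pd.concat([up, down])

    result = DEResult(
        condition_a=cond_a,
        condition_b=cond_b,
        size_factors=factors,
        normalized=normalized,
        table=table,
        top100=_top(100),
        top25=_top(25),
    )
    if raw.shape[1] >= 2:
        scores, variance = pca_scores(np.log2(normalized + 1.0))
        result.pca_scores = scores
        result.pca_variance = variance
    return result


def pca_scores(log2_norm: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample coordinates on the first two principal components.

    Rows of ``log2_norm`` are miRNAs (features), columns samples. Features
    are centered; components come from the SVD of the sample x feature
    matrix. Returns per-sample PC scores and the explained-variance
    fractions (non-increasing, summing to <= 1).
    """
    if log2_norm.shape[1] < 2:
        raise ValueError("PCA requires at least two samples")
    x = log2_norm.to_numpy(dtype=float).T  # samples x features
    n_comp = min(2, x.shape[0] - 1) or 1
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(x - x.mean(axis=0))
    scores = pd.DataFrame(
        coords,
        index=pd.Index(log2_norm.columns, name="sample"),
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return scores, pca.explained_variance_ratio_


def pearson_correlation(a: pd.Series, b: pd.Series) -> float:
    """Pearson correlation over the union of indices (missing values = 0)."""
    idx = a.index.union(b.index)
    av = a.reindex(idx, fill_value=0).to_numpy(dtype=float)
    bv = b.reindex(idx, fill_value=0).to_numpy(dtype=float)
    return float(scipy_stats.pearsonr(av, bv).statistic)
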