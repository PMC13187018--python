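"""Bulk expression processing: count filtering, TMM normalization, PCA,
and fold-change + t-test differential-expression selection.

TMM (trimmed mean of M-values) estimates per-sample composition-bias
scaling factors: after library-size (CPM) scaling, the log-ratio M of each
gene between a sample and a reference sample is trimmed (30% on M, 5% on
average log-abundance A by default), and the remaining M values are
averaged with inverse delta-method-variance weights; factors are rescaled
to geometric mean 1. Differential expression between two groups uses a
pooled-variance two-sample t-test per gene on log2-normalized values, with
a signed linear-scale fold change (ratio, or -1/ratio when the second
group is higher) and joint selection at |FC| > threshold and p <= threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .io import CountMatrix

__all__ = [
    "FilterConfig",
    "NormalizedMatrix",
    "DEGResult",
    "filter_genes",
    "tmm_factors",
    "log_normalize",
    "pca_coordinates",
    "select_degs",
    "DEFAULT_FC_THRESHOLD",
    "DEFAULT_P_THRESHOLD",
]

DEFAULT_FC_THRESHOLD = 2.5
DEFAULT_P_THRESHOLD = 0.0128


@dataclass(frozen=True)
class FilterConfig:
    """Low-expression gene filter.

    All-zero genes always go. ``low_count_mode`` decides whether the
    "< threshold counts" rule applies to the total across samples (default)
    or to the maximum in any sample.
    """

    low_count_threshold: int = 20
    low_count_mode: Literal["total_across_samples", "max_in_any_sample"] = (
        "total_across_samples"
    )

    def __post_init__(self) -> None:
        if self.low_count_threshold < 0:
            raise ValueError("threshold must be >= 0")


@dataclass(frozen=True)
class NormalizedMatrix:
    """log2 CPM-style expression after TMM scaling."""

    values: pd.DataFrame  # genes x samples, log2 scale
    factors: pd.Series  # TMM scaling factor per sample, geometric mean 1
    library_sizes: pd.Series

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class DEGResult:
    """Per-gene differential-expression table plus the selection rule used."""

    table: pd.DataFrame  # columns: fold_change, t_statistic, p_value, selected
    fc_threshold: float
    p_threshold: float
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    @property
    def selected_genes(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    @property
    def n_up(self) -> int:
        sel = self.table[self.table["selected"]]
        return int((sel["fold_change"] > 0).sum())

    @property
    def n_down(self) -> int:
        sel = self.table[self.table["selected"]]
        return int((sel["fold_change"] < 0).sum())

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {"deg": self.table.rename_axis("gene").reset_index()}


def filter_genes(counts: CountMatrix, config: FilterConfig = FilterConfig()) -> CountMatrix:
    """Drop all-zero genes, then genes failing the low-count rule.

    Boundary: a gene with exactly ``threshold`` counts is retained (the
    rule is strictly "< threshold"). Raises if no genes survive.
    """
    df = counts.counts
    keep = df.sum(axis=1) > 0
    if config.low_count_mode == "total_across_samples":
        keep &= df.sum(axis=1) >= config.low_count_threshold
    else:
        keep &= df.max(axis=1) >= config.low_count_threshold
    out = df[keep]
    if out.empty:
        raise ValueError("no genes survive filtering")
    return CountMatrix(out)


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    """log2 TMM factor of one sample against the reference."""
    mask = (obs > 0) & (ref > 0)
    obs, ref = obs[mask].astype(float), ref[mask].astype(float)
    if obs.size == 0:
        return 0.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # delta-method binomial variance of M; weights are its inverse
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.allclose(m, m[0]):
        # identical composition up to depth: no trimming needed
        return float(m[0]) if abs(m[0]) > 1e-10 else 0.0

    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    w = 1.0 / v[keep]
    return float(np.sum(w * m[keep]) / np.sum(w))


def tmm_factors(
    counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """TMM composition-bias scaling factors, geometric mean 1.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean across samples (ties break by column order). A
    degenerate sample with a single expressed gene gets factor 1 with a
    warning.
    """
    df = counts.counts
    if df.shape[1] < 2:
        raise ValueError("TMM needs >= 2 samples")
    lib = df.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("every sample must have positive total count")
    # upper-quartile fraction per sample (of nonzero scale): f75 = Q3(counts)/libsize
    f75 = df.apply(lambda col: np.percentile(col[col > 0], 75) if (col > 0).any() else 0.0)
    f75 = f75 / lib
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref_name = df.columns[ref_idx]
    ref = df[ref_name].to_numpy()
    log_factors = {}
    for name in df.columns:
        if name == ref_name:
            log_factors[name] = 0.0
            continue
        col = df[name].to_numpy()
        if (col > 0).sum() <= 1:
            warnings.warn(f"sample {name!r} has <= 1 expressed gene; TMM factor set to 1")
            log_factors[name] = 0.0
            continue
        log_factors[name] = _tmm_pair(col, ref, lib[name], lib[ref_name], trim_m, trim_a)
    f = pd.Series({k: 2.0**v for k, v in log_factors.items()})[df.columns]
    f /= np.exp(np.log(f).mean())  # geometric mean 1
    return f.rename("tmm_factor")


def log_normalize(counts: CountMatrix, factors: pd.Series | None = None) -> NormalizedMatrix:
    """log2(count * 1e6 / (library_size * factor) + 1) per entry."""
    df = counts.counts.astype(float)
    lib = df.sum(axis=0)
    if factors is None:
        factors = tmm_factors(counts)
    factors = factors.reindex(df.columns)
    if (factors <= 0).any():
        raise ValueError("scaling factors must be positive")
    eff = lib * factors
    values = np.log2(df.divide(eff, axis=1) * 1e6 + 1.0)
    return NormalizedMatrix(values=values, factors=factors, library_sizes=lib)


def pca_coordinates(
    norm: NormalizedMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores on principal components of gene-wise mean-centered data.

    Sign convention: each component is flipped so its largest-magnitude
    gene loading is positive, making scores deterministic across runs.
    Returns (scores sample x component, explained variance fractions).
    """
    x = norm.values.to_numpy().T  # samples x genes
    n_components = min(n_components, min(x.shape))
    if np.allclose(x.var(axis=0), 0):
        raise ValueError("constant expression matrix: no principal components")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    for k in range(n_components):
        j = int(np.argmax(np.abs(pca.components_[k])))
        if pca.components_[k, j] < 0:
            scores[:, k] *= -1
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=norm.samples, columns=cols),
        pca.explained_variance_ratio_.copy(),
    )


def _signed_fold_change(lin_a: np.ndarray, lin_b: np.ndarray) -> np.ndarray:
    """Signed ratio of linear-scale group means (-1/ratio for down in A)."""
    ratio = lin_a / lin_b
    return np.where(ratio >= 1.0, ratio, -1.0 / ratio)


def select_degs(
    norm: NormalizedMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> DEGResult:
    """Differential expression of group A vs group B.

    Pooled-variance (Student) two-sample t-test per gene on log2-normalized
    values; fold change from linear-scale group means with the signed
    -1/ratio convention for down-regulation in A. A gene is selected iff
    |fold change| strictly exceeds ``fc_threshold`` and p <= ``p_threshold``.
    Genes with zero variance in both groups and equal means get p = 1.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    missing = (set(group_a) | set(group_b)) - set(norm.samples)
    if missing:
        raise ValueError(f"unknown sample(s) {sorted(missing)[:3]}")
    a = norm.values[list(group_a)].to_numpy()
    b = norm.values[list(group_b)].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p_val = stats.ttest_ind(a, b, axis=1, equal_var=True)
    flat = np.isnan(t_stat)
    t_stat = np.where(flat, 0.0, t_stat)
    p_val = np.where(flat, 1.0, p_val)
    # linear scale = CPM-like 2^v; group means taken on that scale
    fc = _signed_fold_change((2.0**a).mean(axis=1), (2.0**b).mean(axis=1))
    selected = (np.abs(fc) > fc_threshold) & (p_val <= p_threshold)
    table = pd.DataFrame(
        {
            "fold_change": fc,
            "t_statistic": t_stat,
            "p_value": p_val,
            "selected": selected,
        },
        index=norm.values.index,
    )
    return DEGResult(
        table=table,
        fc_threshold=fc_threshold,
        p_threshold=p_threshold,
        group_a=tuple(group_a),
        group_b=tuple(group_b),
    )
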