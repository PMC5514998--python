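"""Descriptive analyses: sample PCA and gene-set correlation structure."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .errors import TurnoverScanError
from .preprocess import ExpressionMatrix

__all__ = [
    "PcaResult",
    "pca_samples",
    "geneset_correlation",
    "geneset_trait_correlation",
]


@dataclass
class PcaResult:
    """Sample scores and the variance fraction captured by each component."""

    scores: pd.DataFrame  # samples x components
    variance_explained: np.ndarray
    n_components: int


def pca_samples(matrix: ExpressionMatrix, n_components: int = 3) -> PcaResult:
    """PCA with samples as observations and genes as (mean-centred) features.

    No unit-variance scaling is applied, so high-variance genes stay
    influential. Component signs follow a deterministic convention: the
    largest-magnitude gene loading of each component is positive.
    """
    n_samples, n_genes = matrix.values.shape[1], matrix.values.shape[0]
    if not 1 <= n_components <= min(n_samples, n_genes):
        raise TurnoverScanError(
            f"n_components must lie in [1, {min(n_samples, n_genes)}]"
        )
    X = matrix.values.to_numpy().T  # samples x genes
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    for k in range(n_components):
        j = int(np.argmax(np.abs(pca.components_[k])))
        if pca.components_[k, j] < 0:
            pca.components_[k] *= -1.0
            scores[:, k] *= -1.0
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.sample_ids, columns=cols),
        variance_explained=pca.explained_variance_ratio_.copy(),
        n_components=n_components,
    )


def _check_gene_set(profiles: pd.DataFrame, gene_set) -> list:
    gene_set = list(gene_set)
    missing = [g for g in gene_set if g not in profiles.index]
    if missing:
        raise TurnoverScanError(
            "genes absent from profiles: " + ", ".join(map(str, missing))
        )
    return gene_set


def geneset_correlation(
    profiles: pd.DataFrame, gene_set, method: str = "pearson"
) -> pd.DataFrame:
    """Pairwise gene-gene correlations across tissues for a gene set.

    Zero-variance genes get NaN correlations (an explicit undefined
    marker, never 0); the diagonal stays 1.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    gene_set = _check_gene_set(profiles, gene_set)
    if len(gene_set) < 2:
        raise TurnoverScanError("gene set must contain at least 2 genes")
    sub = profiles.loc[gene_set]
    corr = sub.T.corr(method=method)
    constant = sub.std(axis=1, ddof=0) == 0.0
    corr.loc[constant, :] = np.nan
    corr.loc[:, constant] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    return corr


def geneset_trait_correlation(
    profiles: pd.DataFrame, gene_set, trait: dict
) -> pd.DataFrame:
    """Per-gene Pearson correlation with the trait across tissues.

    Returns columns (gene, correlation, p); two-sided p from the t
    distribution with n - 2 degrees of freedom. Constant genes get NaN.
    """
    gene_set = _check_gene_set(profiles, gene_set)
    missing_t = [t for t in profiles.columns if t not in trait]
    if missing_t:
        raise TurnoverScanError(
            "trait missing tissues: " + ", ".join(map(str, missing_t))
        )
    x = np.array([trait[t] for t in profiles.columns], dtype=float)
    rows = []
    for g in gene_set:
        y = profiles.loc[g].to_numpy(dtype=float)
        if y.std(ddof=0) == 0.0 or x.std(ddof=0) == 0.0:
            rows.append((g, np.nan, np.nan))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((g, float(r), float(p)))
    return pd.DataFrame(rows, columns=["gene", "correlation", "p"])
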