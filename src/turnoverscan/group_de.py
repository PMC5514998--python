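"""Phylogenetic ANOVA: group-vs-rest differential expression on the tree.

Tissue mean profiles are not independent observations — related tissues
share expression by descent along the tissue tree. A classical ANOVA would
therefore overstate significance for groups that happen to form a clade.
Following the simulation approach of Garland et al., the observed one-way
F statistic is compared against a null distribution obtained by
re-simulating the gene's expression under Brownian motion on the tree
(with the gene's own ML variance rate) and recomputing F each time:

    p_sim = (1 + #{F_sim >= F_obs}) / (1 + n_sim)

A parametric alternative ("gls" mode) instead tests a group-indicator
coefficient by GLS under the BM covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import models
from .errors import TurnoverScanError
from .trees import TissueTree, shared_path_matrix

__all__ = ["GroupDeResult", "phyl_anova_gene", "scan_group"]


@dataclass
class GroupDeResult:
    """One gene's group-vs-rest phylogenetic ANOVA outcome."""

    gene: str
    f_obs: float
    p_sim: float
    group_mean: float
    rest_mean: float
    direction: str  # up / down (group relative to rest)


def _f_stat(y: np.ndarray, gmask: np.ndarray) -> float:
    """One-way two-group ANOVA F (df 1, n-2)."""
    n = y.shape[0]
    k, m = int(gmask.sum()), n - int(gmask.sum())
    mg, mr = y[gmask].mean(), y[~gmask].mean()
    grand = y.mean()
    ssb = k * (mg - grand) ** 2 + m * (mr - grand) ** 2
    ssw = ((y[gmask] - mg) ** 2).sum() + ((y[~gmask] - mr) ** 2).sum()
    if ssw <= 0.0:
        return np.inf if ssb > 0.0 else 0.0
    return float(ssb / (ssw / (n - 2)))


def _f_stats_batch(Y: np.ndarray, gmask: np.ndarray) -> np.ndarray:
    """Vectorized F over rows of Y (n_sim x n_tissues)."""
    n = Y.shape[1]
    k, m = int(gmask.sum()), n - int(gmask.sum())
    mg = Y[:, gmask].mean(axis=1)
    mr = Y[:, ~gmask].mean(axis=1)
    grand = Y.mean(axis=1)
    ssb = k * (mg - grand) ** 2 + m * (mr - grand) ** 2
    ssw = ((Y[:, gmask] - mg[:, None]) ** 2).sum(axis=1) + (
        (Y[:, ~gmask] - mr[:, None]) ** 2
    ).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ssb / (ssw / (n - 2))
    return np.where(ssw > 0.0, f, np.where(ssb > 0.0, np.inf, 0.0))


def _ml_bm_sigma2(y: np.ndarray, L: np.ndarray) -> float:
    """ML rate of an intercept-only BM model: r' C^-1 r / n via Cholesky."""
    from scipy.linalg import solve_triangular

    n = y.shape[0]
    M = solve_triangular(L, np.column_stack([np.ones(n), y]), lower=True,
                         check_finite=False)
    ones_w, yw = M[:, 0], M[:, 1]
    mu = float(ones_w @ yw) / float(ones_w @ ones_w)
    r = yw - mu * ones_w
    return float(r @ r) / n


def _validate_group(tissues, group) -> np.ndarray:
    group = list(group)
    unknown = [g for g in group if g not in set(tissues)]
    if unknown:
        raise TurnoverScanError("group tissues not in profiles: " + ", ".join(unknown))
    if len(group) == 0:
        raise TurnoverScanError("group must contain at least one tissue")
    if len(set(group)) >= len(tissues):
        raise TurnoverScanError("group must be a proper subset of the tissues")
    return np.array([t in set(group) for t in tissues])


def phyl_anova_gene(
    y: pd.Series,
    group,
    tree: TissueTree,
    n_sim: int = 999,
    seed: int = 0,
    gene: str = "",
) -> GroupDeResult:
    """Simulation-based phylogenetic ANOVA for one gene.

    ``y`` is indexed by tissue. Constant genes are untestable and get
    F = 0, p = 1 by decision.
    """
    if n_sim < 99:
        raise ValueError("n_sim must be >= 99")
    tissues = list(y.index)
    gmask = _validate_group(tissues, group)
    C = shared_path_matrix(tree).loc[tissues, tissues].values
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(tissues)))
    yv = y.to_numpy(dtype=float)
    gm, rm = float(yv[gmask].mean()), float(yv[~gmask].mean())
    direction = "up" if gm - rm >= 0 else "down"
    if yv.std(ddof=0) == 0.0:
        return GroupDeResult(gene, 0.0, 1.0, gm, rm, direction)
    f_obs = _f_stat(yv, gmask)
    sigma2 = _ml_bm_sigma2(yv, L)
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_sim, len(tissues)))
    sims = Z @ (np.sqrt(sigma2) * L.T)
    f_sim = _f_stats_batch(sims, gmask)
    p = (1.0 + float((f_sim >= f_obs).sum())) / (1.0 + n_sim)
    return GroupDeResult(gene, f_obs, p, gm, rm, direction)


def scan_group(
    profiles: pd.DataFrame,
    group,
    tree: TissueTree,
    n_sim: int = 999,
    p_threshold: float = 0.01,
    seed: int = 0,
    method: str = "simulation",
) -> pd.DataFrame:
    """Phylogenetic ANOVA of every gene for a tissue group.

    Returns a DataFrame (gene, f_obs, p_sim, group_mean, rest_mean,
    direction, significant). ``method="gls"`` swaps the simulation null
    for a parametric GLS test on a group indicator under BM covariance.
    """
    tissues = list(profiles.columns)
    gmask = _validate_group(tissues, group)
    C = shared_path_matrix(tree).loc[tissues, tissues].values
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(tissues)))
    rng = np.random.default_rng(seed)
    rows = []
    if method == "simulation":
        sqL_T = L.T  # scaled per gene below
        for gene, y in zip(profiles.index, profiles.to_numpy(dtype=float)):
            gm, rm = float(y[gmask].mean()), float(y[~gmask].mean())
            direction = "up" if gm - rm >= 0 else "down"
            if y.std(ddof=0) == 0.0:
                rows.append((gene, 0.0, 1.0, gm, rm, direction))
                continue
            f_obs = _f_stat(y, gmask)
            sigma2 = _ml_bm_sigma2(y, L)
            sims = rng.standard_normal((n_sim, len(tissues))) @ (np.sqrt(sigma2) * sqL_T)
            f_sim = _f_stats_batch(sims, gmask)
            p = (1.0 + float((f_sim >= f_obs).sum())) / (1.0 + n_sim)
            rows.append((gene, f_obs, p, gm, rm, direction))
    elif method == "gls":
        x = gmask.astype(float)
        for gene, y in zip(profiles.index, profiles.to_numpy(dtype=float)):
            gm, rm = float(y[gmask].mean()), float(y[~gmask].mean())
            direction = "up" if gm - rm >= 0 else "down"
            if y.std(ddof=0) == 0.0:
                rows.append((gene, 0.0, 1.0, gm, rm, direction))
                continue
            fit = models.gls_fit(x, y, C, chol=L)
            rows.append((gene, fit.t_slope ** 2, fit.p_slope, gm, rm, direction))
    else:
        raise ValueError(f"unknown method {method!r}")
    out = pd.DataFrame(
        rows, columns=["gene", "f_obs", "p_sim", "group_mean", "rest_mean", "direction"]
    )
    out["significant"] = out["p_sim"] <= p_threshold
    return out
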