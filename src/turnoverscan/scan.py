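"""Genome-wide per-gene PGLS scan against log-turnover with FDR control.

For each gene the configured evolutionary covariance models are fitted by
maximum likelihood, one is selected by AIC, and the slope of expression on
log10 turnover is tested. Multiplicity is controlled by Storey q-values
(Benjamini-Hochberg as a fallback when the pi0 estimate degenerates).
Robustness is probed by re-running the whole scan, tree included, on a
reduced tissue set and intersecting the significant gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models
from .errors import TurnoverScanError
from .preprocess import TurnoverTable
from .trees import TissueTree, expression_distance, neighbor_joining

__all__ = [
    "ScanConfig",
    "LeaveOutResult",
    "scan_genes",
    "qvalues",
    "significant_set",
    "leave_out_rescan",
]

P_CLAMP = 1e-300

#: Shortest-turnover (immune/hematopoietic) tissues of the packaged human
#: turnover table; the canonical exclusion set for the robustness re-scan.
DEFAULT_EXCLUDED_TISSUES = ("Bone marrow", "Spleen", "(CD14+) monocytes")
RESULT_COLUMNS = [
    "gene", "slope", "se", "t", "p", "q",
    "model", "model_param", "loglik", "direction",
]


@dataclass
class ScanConfig:
    """Scan settings: models to compare, FDR cutoff and trait handling."""

    q_threshold: float = 0.05
    models: tuple[str, ...] = ("BM", "LAMBDA", "OU")
    trait_scale: str = "log10"
    excluded_tissues: tuple[str, ...] = ()
    fdr_method: str = "storey"

    def __post_init__(self):
        if not 0.0 < self.q_threshold < 1.0:
            raise ValueError("q_threshold must lie in (0, 1)")
        for m in self.models:
            if m not in models.MODEL_KINDS:
                raise ValueError(f"unknown model {m!r}")
        if self.trait_scale not in ("log10", "linear"):
            raise ValueError("trait_scale must be log10 or linear")
        if self.fdr_method not in ("storey", "bh"):
            raise ValueError("fdr_method must be storey or bh")


def _trait(table: TurnoverTable, tissues, scale: str) -> np.ndarray:
    if scale == "log10":
        return models.trait_vector(table, tissues)
    return table.turnover_days.loc[list(tissues)].to_numpy(dtype=float)


def scan_genes(
    profiles: pd.DataFrame,
    table: TurnoverTable,
    tree: TissueTree,
    config: ScanConfig | None = None,
) -> pd.DataFrame:
    """Per-gene PGLS of expression on the turnover trait.

    For each gene the residual covariance model is chosen by AIC from the
    gene's marginal (intercept-only) fit — see
    :func:`turnoverscan.models.select_covariance` for why selection must
    not see the trait — and the slope is then tested by GLS under the
    selected covariance.

    Returns a DataFrame with one row per gene (columns
    ``RESULT_COLUMNS``). Constant-expression genes are untestable: their
    p and q are NaN and they are excluded from the FDR universe.
    """
    config = config or ScanConfig()
    tissues = [t for t in profiles.columns if t not in set(config.excluded_tissues)]
    if set(tissues) != set(tree.tip_labels):
        raise TurnoverScanError("profiles tissues must equal tree tip labels")
    sub = profiles[tissues]
    x = _trait(table, tissues, config.trait_scale)

    C_df = models.cov_bm(tree)
    C_bm = C_df.loc[tissues, tissues].values
    from .trees import patristic_matrix

    d_pat = patristic_matrix(tree).loc[tissues, tissues].values
    chol_bm = np.linalg.cholesky(C_bm + 1e-12 * np.eye(len(tissues)))

    rows = []
    values = sub.to_numpy(dtype=float)
    for gi, gene in enumerate(sub.index):
        y = values[gi]
        if y.std(ddof=0) == 0.0:
            rows.append((gene, 0.0, np.nan, np.nan, np.nan, np.nan,
                         None, np.nan, np.nan, "untestable"))
            continue
        spec, C_sel = models.select_covariance(
            y, kinds=config.models, C_bm=C_bm, d_patristic=d_pat
        )
        fit = models.gls_fit(
            x, y, C_sel,
            chol=chol_bm if spec.kind == "BM" else None,
            model=spec,
            n_model_params=0 if spec.kind == "BM" else 1,
        )
        direction = "negative" if fit.slope < 0 else "positive"
        rows.append((
            gene, fit.slope, float(fit.se[1]), fit.t_slope, fit.p_slope,
            np.nan, spec.kind, spec.param, fit.loglik, direction,
        ))
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    out["q"] = qvalues(out["p"].to_numpy(), method=config.fdr_method)
    return out


def qvalues(p: np.ndarray, method: str = "storey") -> np.ndarray:
    """FDR q-values for a vector of p-values (NaNs passed through).

    Storey's procedure estimates the null proportion
    ``pi0 = min(1, #{p > 0.5} / (0.5 m))`` and sets
    ``q_(i) = min_{j >= i} pi0 * m * p_(j) / j``. When the pi0 estimate is
    degenerate (zero, i.e. no p exceeds 0.5) the Benjamini-Hochberg
    procedure (pi0 = 1) is used instead. p-values are clamped below at
    1e-300 first to avoid underflow.
    """
    p = np.asarray(p, dtype=float)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0.0) | (pv > 1.0)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    m = pv.size
    if m == 0:
        return out
    pv = np.maximum(pv, P_CLAMP)
    if method == "storey":
        pi0 = min(1.0, float((pv > 0.5).sum()) / (0.5 * m))
        if pi0 <= 0.0:
            pi0 = 1.0  # degenerate estimate: fall back to BH
    elif method == "bh":
        pi0 = 1.0
    else:
        raise ValueError(f"unknown FDR method {method!r}")
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * pi0 * m / np.arange(1, m + 1)
    qv = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.minimum(qv, 1.0)
    q = np.empty(m)
    q[order] = qv
    out[mask] = q
    return out


def significant_set(
    results: pd.DataFrame, q_threshold: float = 0.05
) -> tuple[list, int, int]:
    """Genes with q <= threshold, plus negative/positive slope counts."""
    hits = results[results["q"] <= q_threshold]
    genes = hits["gene"].tolist()
    n_negative = int((hits["slope"] < 0).sum())
    n_positive = int((hits["slope"] >= 0).sum())
    return genes, n_negative, n_positive


def default_tree_builder(profiles: pd.DataFrame) -> TissueTree:
    """NJ on 1 - Pearson distances between tissue mean profiles."""
    return neighbor_joining(expression_distance(profiles, method="pearson"))


@dataclass
class LeaveOutResult:
    """Full-scan vs reduced-scan significant sets and their overlap."""

    set_full: list
    set_reduced: list
    overlap: list
    results_full: pd.DataFrame = field(repr=False)
    results_reduced: pd.DataFrame = field(repr=False)
    direction_agreement: pd.DataFrame = field(repr=False)


def leave_out_rescan(
    profiles: pd.DataFrame,
    table: TurnoverTable,
    config: ScanConfig | None = None,
    excluded: tuple[str, ...] = (),
    tree_builder=default_tree_builder,
) -> LeaveOutResult:
    """Re-run the scan without ``excluded`` tissues and intersect hits.

    The tissue tree is *rebuilt* on the reduced set (not pruned), mirroring
    a full re-run of the pipeline. Requires >= 6 remaining tissues. For
    human data keyed to the packaged turnover table, the canonical choice
    is ``excluded=DEFAULT_EXCLUDED_TISSUES`` (the shortest-turnover
    immune/hematopoietic tissues).
    """
    from dataclasses import replace

    config = replace(config or ScanConfig(), excluded_tissues=())
    excluded = tuple(excluded)
    unknown = [t for t in excluded if t not in profiles.columns]
    if unknown:
        raise TurnoverScanError("excluded tissues not present: " + ", ".join(unknown))
    remaining = [t for t in profiles.columns if t not in set(excluded)]
    if len(remaining) < 6:
        raise TurnoverScanError(
            f"only {len(remaining)} tissues would remain; need at least 6"
        )

    full_tree = tree_builder(profiles)
    res_full = scan_genes(profiles, table, full_tree, config)
    reduced = profiles[remaining]
    red_tree = tree_builder(reduced)
    res_red = scan_genes(reduced, table, red_tree, config)

    set_full, _, _ = significant_set(res_full, config.q_threshold)
    set_red, _, _ = significant_set(res_red, config.q_threshold)
    overlap = [g for g in set_full if g in set(set_red)]

    sf = res_full.set_index("gene").loc[overlap, "slope"]
    sr = res_red.set_index("gene").loc[overlap, "slope"]
    agree = pd.DataFrame(
        {
            "gene": overlap,
            "slope_full": sf.to_numpy(),
            "slope_reduced": sr.to_numpy(),
            "direction_agrees": np.sign(sf.to_numpy()) == np.sign(sr.to_numpy()),
        }
    )
    return LeaveOutResult(
        set_full=set_full,
        set_reduced=set_red,
        overlap=overlap,
        results_full=res_full,
        results_reduced=res_red,
        direction_agreement=agree,
    )
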