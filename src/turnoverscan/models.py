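"""Phylogenetic generalized least squares (PGLS) machinery.

The comparative model treats each gene's per-tissue expression vector y as
one observation of a multivariate normal whose covariance among tissues is
induced by an evolutionary process on the tissue tree:

* **BM** (Brownian motion): ``Cov(y_i, y_j) = sigma^2 * C[i, j]`` where C is
  the shared root-to-MRCA path length matrix.
* **LAMBDA** (Pagel's lambda): off-diagonal entries of C multiplied by
  ``lambda`` in [0, 1]; ``lambda = 0`` is independence, ``lambda = 1`` pure BM.
* **OU** (stationary Ornstein-Uhlenbeck): ``Cov = sigma^2 * exp(-alpha * d)``
  with d the patristic distance; valid on non-ultrametric trees, with the
  stationary variance ``sigma^2/(2 alpha)`` absorbed into sigma^2.

For a gene y and trait x the regression ``y = b0 + b1 * x + eps``,
``eps ~ N(0, sigma^2 V(theta))`` is fitted by GLS with sigma^2 profiled out
by maximum likelihood and the scalar model parameter theta (lambda or
alpha) maximized by bounded 1-D search; models are compared by AIC.

All linear algebra goes through a Cholesky factor of V (never an explicit
inverse), with a small diagonal jitter retried once if factorization fails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular
from scipy.optimize import minimize_scalar

from .errors import TurnoverScanError
from .trees import TissueTree, patristic_matrix, shared_path_matrix

__all__ = [
    "CovModelSpec",
    "GlsFit",
    "trait_vector",
    "cov_bm",
    "cov_lambda",
    "cov_ou",
    "ou_alpha_bounds",
    "gls_fit",
    "fit_model",
    "select_model",
]

MODEL_KINDS = ("BM", "LAMBDA", "OU")
ALPHA_MIN = 1e-4
_JITTER = 1e-8
_PARAM_XATOL = 1e-7  # bracket tolerance of the bounded Brent search


@dataclass(frozen=True)
class CovModelSpec:
    """Evolutionary covariance model: kind plus its scalar parameter."""

    kind: str
    param: float | None = None

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "LAMBDA" and not (0.0 <= self.param <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")
        if self.kind == "OU" and self.param <= 0.0:
            raise ValueError("alpha must be positive")


@dataclass
class GlsFit:
    """Result of one GLS regression under a fixed covariance model."""

    beta: np.ndarray  # (intercept, slope)
    se: np.ndarray
    sigma2_hat: float  # ML estimate, rss_gls / n
    loglik: float
    df_resid: int
    t_slope: float
    p_slope: float
    model: CovModelSpec | None
    aic: float

    @property
    def slope(self) -> float:
        return float(self.beta[1])


def trait_vector(table, tissues) -> np.ndarray:
    """log10 turnover (days), ordered to match ``tissues``.

    ``table`` is a :class:`turnoverscan.preprocess.TurnoverTable`.
    """
    missing = [t for t in tissues if t not in table.turnover_days.index]
    if missing:
        raise TurnoverScanError(
            "tissues missing from turnover table: " + ", ".join(map(str, missing))
        )
    return np.log10(table.turnover_days.loc[list(tissues)].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# covariance structures


def cov_bm(tree: TissueTree) -> pd.DataFrame:
    """Unit-rate Brownian-motion covariance: the shared-path matrix."""
    return shared_path_matrix(tree)


def cov_lambda(C: np.ndarray | pd.DataFrame, lam: float) -> np.ndarray:
    """Pagel's lambda transform: scale off-diagonals by lam, keep diagonal."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    C = np.asarray(C, dtype=float)
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


def ou_alpha_bounds(tree_or_C) -> tuple[float, float]:
    """Search bounds [alpha_min, 50 / mean root-to-tip depth] for OU alpha."""
    if isinstance(tree_or_C, TissueTree):
        C = shared_path_matrix(tree_or_C).values
    else:
        C = np.asarray(tree_or_C, dtype=float)
    mean_depth = float(np.mean(np.diag(C)))
    return ALPHA_MIN, 50.0 / max(mean_depth, 1e-12)


def cov_ou(tree: TissueTree, alpha: float, *, d: np.ndarray | None = None) -> np.ndarray:
    """Stationary OU covariance exp(-alpha * patristic distance), unit diagonal."""
    lo, hi = ou_alpha_bounds(tree)
    if not (lo <= alpha <= hi):
        raise ValueError(f"alpha {alpha} outside bounds [{lo:.4g}, {hi:.4g}]")
    if d is None:
        d = patristic_matrix(tree).values
    return np.exp(-alpha * np.asarray(d, dtype=float))


def _cholesky_jittered(C: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        jitter = _JITTER * float(np.mean(np.diag(C)))
        return np.linalg.cholesky(C + jitter * np.eye(C.shape[0]))


# ---------------------------------------------------------------------------
# GLS


def gls_fit(
    x: np.ndarray,
    y: np.ndarray,
    C: np.ndarray | pd.DataFrame,
    *,
    chol: np.ndarray | None = None,
    model: CovModelSpec | None = None,
    n_model_params: int = 0,
) -> GlsFit:
    """GLS regression of y on [1, x] with residual covariance sigma^2 * C.

    sigma^2 is profiled by ML (divide by n); standard errors use the
    unbiased residual variance (divide by n - 2). The log-likelihood is the
    profile likelihood at the ML sigma^2. Solved via Cholesky factorization
    of C and triangular solves.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if x.shape[0] != n:
        raise ValueError("x and y length mismatch")
    if n < 4:
        raise TurnoverScanError(f"need at least 4 observations, got {n}")
    C = np.asarray(C, dtype=float)
    L = _cholesky_jittered(C) if chol is None else chol

    X = np.column_stack([np.ones(n), x])
    M = solve_triangular(L, np.column_stack([X, y]), lower=True, check_finite=False)
    Xw, yw = M[:, :2], M[:, 2]
    XtX = Xw.T @ Xw
    if np.linalg.cond(XtX) > 1e12:
        raise TurnoverScanError("design matrix is singular (constant trait?)")
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (Xw.T @ yw)
    r = yw - Xw @ beta
    rss = float(r @ r)
    logdet = 2.0 * float(np.log(np.diag(L)).sum())

    sigma2_ml = rss / n
    if sigma2_ml > 0.0:
        loglik = -0.5 * (n * math.log(2.0 * math.pi * sigma2_ml) + logdet + n)
    else:  # exact fit: degenerate likelihood
        loglik = math.inf
    df_resid = n - 2
    s2 = rss / df_resid
    se = np.sqrt(np.maximum(s2 * np.diag(XtX_inv), 0.0))
    if se[1] > 0.0:
        t_slope = float(beta[1] / se[1])
        p_slope = float(2.0 * stats.t.sf(abs(t_slope), df_resid))
    else:
        t_slope = math.copysign(math.inf, beta[1]) if beta[1] != 0.0 else 0.0
        p_slope = 0.0 if beta[1] != 0.0 else 1.0
    k = 2 + 1 + n_model_params  # regression params + sigma^2 + model params
    aic = 2.0 * k - 2.0 * loglik
    return GlsFit(
        beta=beta,
        se=se,
        sigma2_hat=sigma2_ml,
        loglik=loglik,
        df_resid=df_resid,
        t_slope=t_slope,
        p_slope=p_slope,
        model=model,
        aic=aic,
    )


def _optimize_scalar(objective, lo: float, hi: float):
    """Maximize ``objective`` on [lo, hi]; endpoints always evaluated."""
    res = minimize_scalar(
        lambda v: -objective(v),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": _PARAM_XATOL},
    )
    if not res.success:
        raise TurnoverScanError(
            f"1-D ML search failed on [{lo}, {hi}]: best {-res.fun} at {res.x}"
        )
    candidates = [(float(res.x), -float(res.fun))]
    candidates += [(v, objective(v)) for v in (lo, hi)]
    return max(candidates, key=lambda c: c[1])


def fit_model(
    x: np.ndarray,
    y: np.ndarray,
    tree: TissueTree,
    kind: str,
    *,
    C_bm: np.ndarray | None = None,
    d_patristic: np.ndarray | None = None,
    chol_bm: np.ndarray | None = None,
) -> GlsFit:
    """Fit one evolutionary covariance model, maximizing its scalar
    parameter by profile ML where the model has one.

    ``C_bm``, ``d_patristic`` and ``chol_bm`` may be precomputed once per
    tree and shared across genes (they do not depend on y).
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    if kind == "BM":
        C = shared_path_matrix(tree).values if C_bm is None else C_bm
        return gls_fit(
            x, y, C, chol=chol_bm, model=CovModelSpec("BM"), n_model_params=0
        )
    if kind == "LAMBDA":
        C = shared_path_matrix(tree).values if C_bm is None else C_bm
        diag = np.diag(np.diag(C))
        offd = C - diag

        def ll(lam: float) -> float:
            return gls_fit(x, y, lam * offd + diag).loglik

        lam, _ = _optimize_scalar(ll, 0.0, 1.0)
        return gls_fit(
            x, y, lam * offd + diag, model=CovModelSpec("LAMBDA", lam), n_model_params=1
        )
    # OU
    d = patristic_matrix(tree).values if d_patristic is None else d_patristic
    C = shared_path_matrix(tree).values if C_bm is None else C_bm
    lo, hi = ou_alpha_bounds(C)

    def ll(alpha: float) -> float:
        return gls_fit(x, y, np.exp(-alpha * d)).loglik

    alpha, _ = _optimize_scalar(ll, lo, hi)
    return gls_fit(
        x, y, np.exp(-alpha * d), model=CovModelSpec("OU", alpha), n_model_params=1
    )


def null_loglik(y: np.ndarray, C: np.ndarray) -> float:
    """Profile log-likelihood of an intercept-only (no-trait) GLS model."""
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    L = _cholesky_jittered(np.asarray(C, dtype=float))
    M = solve_triangular(L, np.column_stack([np.ones(n), y]), lower=True,
                         check_finite=False)
    ones_w, yw = M[:, 0], M[:, 1]
    mu = float(ones_w @ yw) / float(ones_w @ ones_w)
    r = yw - mu * ones_w
    rss = float(r @ r)
    if rss <= 0.0:
        return math.inf
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    return -0.5 * (n * math.log(2.0 * math.pi * rss / n) + logdet + n)


def select_covariance(
    y: np.ndarray,
    tree: TissueTree | None = None,
    kinds: tuple[str, ...] = MODEL_KINDS,
    *,
    C_bm: np.ndarray | None = None,
    d_patristic: np.ndarray | None = None,
) -> tuple[CovModelSpec, np.ndarray]:
    """Choose the evolutionary covariance for y from its *marginal*
    distribution (intercept-only ML fit), by AIC.

    Selecting the covariance without reference to any candidate predictor
    keeps the subsequent slope test honest: when selection and testing
    share one regression fit, genes whose chance association with a
    tree-structured trait is best absorbed by a near-independence
    covariance get both selected and tested under it, which badly inflates
    small p-values. Returns the winning model spec and its covariance
    matrix.
    """
    if C_bm is None:
        C_bm = shared_path_matrix(tree).values
    candidates: list[tuple[float, int, int, CovModelSpec, np.ndarray]] = []
    for kind in kinds:
        if kind == "BM":
            ll = null_loglik(y, C_bm)
            k = 2  # mu, sigma2
            candidates.append((2.0 * k - 2.0 * ll, 0, _KIND_ORDER[kind],
                               CovModelSpec("BM"), C_bm))
        elif kind == "LAMBDA":
            diag = np.diag(np.diag(C_bm))
            offd = C_bm - diag
            lam, ll = _optimize_scalar(
                lambda l: null_loglik(y, l * offd + diag), 0.0, 1.0
            )
            k = 3
            candidates.append((2.0 * k - 2.0 * ll, 1, _KIND_ORDER[kind],
                               CovModelSpec("LAMBDA", lam), lam * offd + diag))
        elif kind == "OU":
            if d_patristic is None:
                d_patristic = patristic_matrix(tree).values
            lo, hi = ou_alpha_bounds(C_bm)
            alpha, ll = _optimize_scalar(
                lambda a: null_loglik(y, np.exp(-a * d_patristic)), lo, hi
            )
            k = 3
            candidates.append((2.0 * k - 2.0 * ll, 1, _KIND_ORDER[kind],
                               CovModelSpec("OU", alpha), np.exp(-alpha * d_patristic)))
        else:
            raise ValueError(f"unknown model kind {kind!r}")
    best = min(candidates, key=lambda c: (c[0], c[1], c[2]))
    return best[3], best[4]


_KIND_ORDER = {k: i for i, k in enumerate(MODEL_KINDS)}


def select_model(fits: list[GlsFit]) -> GlsFit:
    """Pick the fit with minimal AIC.

    Ties are broken toward fewer parameters, then by the fixed kind order
    BM < LAMBDA < OU.
    """
    if not fits:
        raise ValueError("select_model needs at least one fit")

    def key(f: GlsFit):
        n_params = 0 if f.model is None or f.model.kind == "BM" else 1
        kind = f.model.kind if f.model is not None else "BM"
        return (f.aic, n_params, _KIND_ORDER[kind])

    return min(fits, key=key)
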