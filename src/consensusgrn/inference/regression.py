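"""Per-gene regression networks: elastic net with (λ2, L1-fraction) tuning
and a GENIE3-style random-forest importance ranking.

Elastic net semantics: for each ridge penalty λ2, a coordinate-descent
solution path over the L1 penalty is computed; the path solution whose
L1-norm fraction (relative to the L1 norm of the λ1→0 solution) is nearest
each grid value s is the candidate model.  (λ2, s) are chosen per target
gene by 6-fold cross-validation and the winning pair is refit on all data.
The model's R² = 1 − mean((y−ŷ)²)/var(y) is evaluated on the winner's
out-of-fold predictions — on standardized data an in-sample R² of a fitted
model is non-negative by construction, so only the cross-validated form can
flag the regularization artifacts that the negative-R² discard rule is
meant to remove.  Surviving coefficients are normalized per target by the
maximum absolute coefficient and edges pooled over targets, ranked by |β̃|.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet

from ..datatypes import ExpressionMatrix, RankedNetwork, TFList, ValidationError
from ._common import network_from_directed, require_condition_medians

logger = logging.getLogger("consensusgrn")

LAMBDA2_GRID = (0.0, 0.001, 0.01, 0.05, 0.1, 0.5, 1.0, 1.5, 2.0, 10.0, 100.0)
S_GRID = tuple(round(0.1 * i, 1) for i in range(1, 10))


@dataclass
class ElasticNetConfig:
    lambda2_grid: tuple = LAMBDA2_GRID
    s_grid: tuple = S_GRID
    folds: int = 6
    n_lambda1: int = 25        # log-spaced L1 path resolution
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lambda2_grid or not self.s_grid:
            raise ValidationError("hyperparameter grids must be nonempty")
        if self.folds < 2:
            raise ValidationError("need >= 2 CV folds")


def _sk_params(lam1: float, lam2: float) -> tuple[float, float]:
    """Map penalties (λ1·||β||₁ + λ2·||β||₂²) onto sklearn's
    (alpha, l1_ratio) with objective 1/(2n)||y−Xβ||² + α·l1·||β||₁
    + α(1−l1)/2·||β||₂²."""
    alpha = lam1 + 2.0 * lam2
    if alpha == 0:
        return 0.0, 1.0
    return alpha, lam1 / alpha


def _ridge_solution(x: np.ndarray, y: np.ndarray, lam2: float) -> np.ndarray:
    """The λ1→0 endpoint of the path: ridge (or least squares at λ2=0)."""
    n, p = x.shape
    if lam2 == 0:
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        return beta
    a = x.T @ x / n + 2.0 * lam2 * np.eye(p)
    return np.linalg.solve(a, x.T @ y / n)


def _l1_path(x: np.ndarray, y: np.ndarray, lam2: float,
             n_lambda1: int) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients along a decreasing-λ1 path at fixed λ2, plus the
    L1-norm fraction of each solution relative to the λ1→0 endpoint."""
    n = x.shape[0]
    lam1_max = np.max(np.abs(x.T @ y)) / n
    if lam1_max <= 0:
        lam1_max = 1e-3
    lam1s = np.concatenate([
        np.geomspace(lam1_max, lam1_max * 1e-4, n_lambda1 - 1), [0.0]])
    ref = _ridge_solution(x, y, lam2)
    ref_l1 = np.sum(np.abs(ref))
    betas = np.empty((len(lam1s), x.shape[1]))
    model = None
    xf = np.asfortranarray(x, dtype=np.float64)
    yf = np.ascontiguousarray(y, dtype=np.float64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, lam1 in enumerate(lam1s):
            if lam1 == 0.0:
                betas[i] = ref
                continue
            alpha, l1_ratio = _sk_params(lam1, lam2)
            if model is None:
                model = ElasticNet(alpha=alpha, l1_ratio=l1_ratio,
                                   fit_intercept=False, warm_start=True,
                                   max_iter=5000, tol=1e-6)
            else:
                model.set_params(alpha=alpha, l1_ratio=l1_ratio)
            model.fit(xf, yf, check_input=False)
            betas[i] = model.coef_
    if ref_l1 <= 0:
        fracs = np.zeros(len(lam1s))
    else:
        fracs = np.sum(np.abs(betas), axis=1) / ref_l1
    return betas, fracs


def _path_at_fractions(x, y, lam2, s_grid, n_lambda1) -> np.ndarray:
    """One coefficient vector per s in the grid (nearest path solution)."""
    betas, fracs = _l1_path(x, y, lam2, n_lambda1)
    out = np.empty((len(s_grid), x.shape[1]))
    for si, s in enumerate(s_grid):
        out[si] = betas[np.argmin(np.abs(fracs - s))]
    return out


@dataclass
class GeneModelFit:
    target: str
    beta: np.ndarray
    beta_norm: np.ndarray = field(init=False)
    r2: float = 0.0
    lambda2: float = 0.0
    s: float = 0.0

    def __post_init__(self) -> None:
        m = np.max(np.abs(self.beta)) if self.beta.size else 0.0
        self.beta_norm = self.beta / m if m > 0 else np.zeros_like(self.beta)


def fit_gene_model(y: np.ndarray, x: np.ndarray, target: str,
                   cfg: ElasticNetConfig) -> GeneModelFit | None:
    """CV-tuned elastic net for one target; None when the winner's
    cross-validated R² is negative."""
    n = len(y)
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(n)
    folds = np.array_split(order, cfg.folds)
    n_l2, n_s = len(cfg.lambda2_grid), len(cfg.s_grid)
    sse = np.zeros((n_l2, n_s))
    for fold in folds:
        test = np.zeros(n, dtype=bool)
        test[fold] = True
        xtr, ytr, xte, yte = x[~test], y[~test], x[test], y[test]
        for li, lam2 in enumerate(cfg.lambda2_grid):
            coefs = _path_at_fractions(xtr, ytr, lam2, cfg.s_grid, cfg.n_lambda1)
            pred = xte @ coefs.T
            sse[li] += np.sum((yte[:, None] - pred) ** 2, axis=0)
    li, si = np.unravel_index(np.argmin(sse), sse.shape)
    lam2, s = cfg.lambda2_grid[li], cfg.s_grid[si]
    var_y = np.var(y, ddof=1)
    if var_y <= 0:
        return None
    r2 = 1.0 - (sse[li, si] / n) / var_y
    if r2 < 0:
        return None
    beta = _path_at_fractions(x, y, lam2, cfg.s_grid, cfg.n_lambda1)[si]
    fit = GeneModelFit(target=target, beta=beta, lambda2=lam2, s=s)
    fit.r2 = r2
    return fit


def infer_elasticnet(em: ExpressionMatrix, tfs: TFList,
                     cfg: ElasticNetConfig | None = None) -> RankedNetwork:
    """Elastic-net network over all target genes, edges scored |β̃|."""
    require_condition_medians(em, "elastic net")
    cfg = cfg or ElasticNetConfig()
    if len(em.column_ids) < cfg.folds:
        raise ValidationError(
            f"{len(em.column_ids)} columns < {cfg.folds} CV folds"
        )
    genes = em.gene_ids
    tf_members = [t for t in tfs if t in set(genes)]
    x_all = em.values.loc[tf_members].to_numpy(float).T  # columns x TFs
    rows = []
    n_discarded = 0
    for target in genes:
        predictors = [t for t in tf_members if t != target]
        if not predictors:
            continue
        cols = [tf_members.index(t) for t in predictors]
        fit = fit_gene_model(em.values.loc[target].to_numpy(float),
                             x_all[:, cols], target, cfg)
        if fit is None:
            n_discarded += 1
            continue
        for tf, b in zip(predictors, fit.beta_norm):
            if b != 0:
                rows.append((tf, target, abs(b)))
    if n_discarded:
        logger.info("elastic net: discarded %d model(s) with negative R2",
                    n_discarded)
    scored = pd.DataFrame(rows, columns=["regulator", "target", "score"])
    return network_from_directed("elasticnet", scored, len(tf_members), len(genes))


def infer_genie3(em: ExpressionMatrix, tfs: TFList, n_trees: int = 1000,
                 seed: int = 0, check_flags: bool = True) -> RankedNetwork:
    """GENIE3-style network: per target gene, a random forest regression on
    TF expression with sqrt-size candidate-split subsets; edge score is the
    forest's variance-reduction importance of each TF, normalized per target
    to sum to 1, pooled over targets."""
    if check_flags:
        require_condition_medians(em, "GENIE3")
    genes = em.gene_ids
    tf_members = [t for t in tfs if t in set(genes)]
    if len(tf_members) < 2:
        raise ValidationError("GENIE3 needs at least 2 TFs in the matrix")
    x_all = em.values.loc[tf_members].to_numpy(float).T
    rng = np.random.default_rng(seed)
    rows = []
    for target in genes:
        predictors = [t for t in tf_members if t != target]
        if not predictors:
            continue
        cols = [tf_members.index(t) for t in predictors]
        k = int(np.ceil(np.sqrt(len(predictors))))
        forest = RandomForestRegressor(
            n_estimators=n_trees, max_features=k,
            random_state=int(rng.integers(2 ** 31 - 1)), n_jobs=1,
        )
        forest.fit(x_all[:, cols], em.values.loc[target].to_numpy(float))
        importances = forest.feature_importances_
        total = importances.sum()
        if total > 0:
            importances = importances / total
        for tf, w in zip(predictors, importances):
            if w > 0:
                rows.append((tf, target, float(w)))
    scored = pd.DataFrame(rows, columns=["regulator", "target", "score"])
    return network_from_directed("genie3", scored, len(tf_members), len(genes))
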