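"""Mutual-information networks: Gaussian-copula MI from Spearman
correlations, CLR z-score combination, and ARACNE data-processing-inequality
pruning."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from ..datatypes import ExpressionMatrix, RankedNetwork, TFList, ValidationError
from ._common import network_from_symmetric, require_replicate_level

logger = logging.getLogger("consensusgrn")

RHO2_CLIP = 1.0 - 1e-12


def estimate_spearman_mi(em: ExpressionMatrix) -> pd.DataFrame:
    """Pairwise MI under the Gaussian copula: MI = -1/2 ln(1 - rho^2) with
    rho the Spearman correlation (rho^2 clipped just below 1)."""
    require_replicate_level(em, "MI estimation")
    arr = em.values.to_numpy(float)
    if np.any(arr.std(axis=1) == 0):
        const = list(em.values.index[arr.std(axis=1) == 0])
        raise ValidationError(f"constant gene(s) in MI input: {const[:5]}")
    rho = spearmanr(arr, axis=1).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-variable case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    mi = -0.5 * np.log(1.0 - np.minimum(rho ** 2, RHO2_CLIP))
    np.fill_diagonal(mi, 0.0)  # self-MI undefined; excluded from all uses
    return pd.DataFrame(mi, index=em.values.index, columns=em.values.index)


def clr_scores(mi: pd.DataFrame) -> pd.DataFrame:
    """CLR: per-gene z-scores of MI against the gene's marginal MI
    distribution (diagonal excluded), clipped at 0, combined as
    sqrt(z_i^2 + z_j^2)."""
    arr = mi.to_numpy(float).copy()
    p = arr.shape[0]
    off = ~np.eye(p, dtype=bool)
    mean = np.array([arr[i, off[i]].mean() for i in range(p)])
    sd = np.array([arr[i, off[i]].std(ddof=0) for i in range(p)])
    zero_sd = sd == 0
    if zero_sd.any():
        logger.warning("CLR: %d gene(s) with zero MI spread; their z set to 0",
                       int(zero_sd.sum()))
    sd_safe = np.where(zero_sd, 1.0, sd)
    z = (arr - mean[:, None]) / sd_safe[:, None]
    z[zero_sd, :] = 0.0
    z = np.maximum(z, 0.0)
    score = np.sqrt(z ** 2 + z.T ** 2)
    np.fill_diagonal(score, 0.0)
    return pd.DataFrame(score, index=mi.index, columns=mi.columns)


def infer_clr(mi: pd.DataFrame, tfs: TFList) -> RankedNetwork:
    return network_from_symmetric("clr", clr_scores(mi), tfs, threshold=0.0)


def dpi_prune(mi: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """ARACNE pruning: in every triangle of present edges (MI > 0) mark the
    strictly smallest edge for removal when it is below the other two minus
    ``eps``; ties remove nothing.  All marks are applied simultaneously."""
    arr = mi.copy().astype(float)
    p = arr.shape[0]
    present = arr > 0
    remove = np.zeros_like(present)
    for i in range(p):
        for j in range(i + 1, p):
            if not present[i, j]:
                continue
            for k in range(j + 1, p):
                if not (present[i, k] and present[j, k]):
                    continue
                a, b, c = arr[i, j], arr[i, k], arr[j, k]
                lo = min(a, b, c)
                others = sorted([a, b, c])[1:]
                if lo < others[0] - eps and lo < others[1] - eps:
                    if a == lo and a < b and a < c:
                        remove[i, j] = remove[j, i] = True
                    elif b == lo and b < a and b < c:
                        remove[i, k] = remove[k, i] = True
                    elif c == lo and c < a and c < b:
                        remove[j, k] = remove[k, j] = True
    arr[remove] = 0.0
    return arr


def infer_aracne(mi: pd.DataFrame, tfs: TFList, eps: float = 0.0) -> RankedNetwork:
    """ARACNE network: DPI-pruned MI, TF-incident edges ranked by MI."""
    if eps < 0:
        raise ValidationError("eps must be >= 0")
    pruned = dpi_prune(mi.to_numpy(float), eps=eps)
    mat = pd.DataFrame(pruned, index=mi.index, columns=mi.columns)
    return network_from_symmetric("aracne", mat, tfs, threshold=0.0)
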