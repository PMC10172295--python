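"""Graphical Gaussian model via shrinkage partial correlations.

The correlation matrix is shrunk toward the identity with the analytic
(Schäfer–Strimmer) shrinkage intensity, inverted, and converted to partial
correlations; every TF-incident pair with |pcor| above a numerical zero is
emitted as a network edge ranked by |pcor|.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..datatypes import ExpressionMatrix, RankedNetwork, TFList, ValidationError
from ._common import network_from_symmetric, require_condition_medians


def shrinkage_intensity(x: np.ndarray) -> float:
    """Analytic optimal shrinkage of the correlation matrix toward I.

    lambda* = sum_{i!=j} Var(r_ij) / sum_{i!=j} r_ij^2, clipped to [0, 1],
    with Var(r_ij) estimated from the empirical variance of the products of
    standardized observations.
    """
    p, n = x.shape
    if n < 3:
        raise ValidationError("shrinkage estimate needs at least 3 columns")
    xs = (x - x.mean(axis=1, keepdims=True))
    sd = xs.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    xs = xs / sd
    r = xs @ xs.T / (n - 1)
    # w_kij = xs_ik * xs_jk; Var(r_ij) = n / (n-1)^3 * sum_k (w_kij - wbar_ij)^2
    w2_sum = (xs ** 2) @ (xs ** 2).T          # sum_k w_kij^2
    wbar = r * (n - 1) / n
    var_r = n / (n - 1.0) ** 3 * (w2_sum - n * wbar ** 2)
    off = ~np.eye(p, dtype=bool)
    denom = np.sum(r[off] ** 2)
    if denom <= 0:
        return 1.0
    lam = float(np.sum(var_r[off]) / denom)
    return min(1.0, max(0.0, lam))


def shrunk_partial_correlations(x: np.ndarray) -> tuple[np.ndarray, float]:
    """Partial correlations from the shrunk correlation matrix."""
    p, n = x.shape
    xs = x - x.mean(axis=1, keepdims=True)
    sd = xs.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    xs = xs / sd
    r = xs @ xs.T / (n - 1)
    np.fill_diagonal(r, 1.0)
    lam = shrinkage_intensity(x)
    r_shrunk = (1.0 - lam) * r + lam * np.eye(p)
    omega = np.linalg.inv(r_shrunk)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return pcor, lam


def infer_ggm(em: ExpressionMatrix, tfs: TFList) -> RankedNetwork:
    """GGM network: TF-incident pairs with non-zero shrinkage partial
    correlation, ranked by |pcor| descending."""
    require_condition_medians(em, "GGM")
    if len(em.column_ids) < 3:
        raise ValidationError("GGM needs at least 3 columns")
    pcor, _ = shrunk_partial_correlations(em.values.to_numpy(float))
    mat = pd.DataFrame(np.abs(pcor), index=em.values.index,
                       columns=em.values.index)
    return network_from_symmetric("ggm", mat, tfs, threshold=1e-12)
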