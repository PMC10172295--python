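"""Networks from decompositions of the Pearson correlation matrix G:
network deconvolution (eigenvalue transform removing transitive paths) and
network silencing (matrix transform estimating direct interactions)."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..datatypes import RankedNetwork, TFList, ValidationError
from ._common import network_from_symmetric

logger = logging.getLogger("consensusgrn")


@dataclass
class DeconvolutionConfig:
    beta: float = 0.9       # target spectral radius when rescaling is needed
    decrement: float = 0.05
    floor: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.beta < 1):
            raise ValidationError("beta must lie in (0, 1)")
        if self.decrement <= 0 or self.floor <= 0:
            raise ValidationError("decrement and floor must be > 0")


def deconvolve_matrix(g: np.ndarray, cfg: DeconvolutionConfig | None = None,
                      zero_diagonal: bool = False) -> np.ndarray:
    """Invert the transitive closure G_obs = G_dir + G_dir² + ... by the
    eigenvalue map λ_dir = λ_obs / (1 + λ_obs).

    The observed matrix (diagonal zeroed) is eigendecomposed; when the
    unscaled map is well-defined and the direct matrix's largest eigenvalue
    is < 1 it is applied as-is — this makes the transform an exact inverse
    of the closure.  Otherwise the spectrum is rescaled to radius β first,
    and β is decremented by ``cfg.decrement`` until the largest direct
    eigenvalue falls below 1 (error at the floor).

    ``zero_diagonal`` is set by the correlation-matrix entry point (a unit
    self-similarity diagonal carries no interaction information); a matrix
    that is itself a transitive closure must keep its diagonal for the
    transform to invert the closure exactly.
    """
    cfg = cfg or DeconvolutionConfig()
    g = np.asarray(g, float).copy()
    if not np.allclose(g, g.T, atol=1e-10):
        raise ValidationError("deconvolution input must be symmetric")
    if zero_diagonal:
        np.fill_diagonal(g, 0.0)
    lam, u = np.linalg.eigh(g)
    # unscaled transform, valid when no eigenvalue is at/below -1
    if lam.min() > -1.0 + 1e-9:
        lam_dir = lam / (1.0 + lam)
        if lam_dir.max() < 1.0:
            return (u * lam_dir) @ u.T
    radius = np.max(np.abs(lam))
    if radius == 0:
        return np.zeros_like(g)
    beta = cfg.beta
    while beta >= cfg.floor - 1e-12:
        scaled = lam * (beta / radius)
        lam_dir = scaled / (1.0 + scaled)
        if lam_dir.max() < 1.0:
            if beta != cfg.beta:
                logger.info("deconvolution: beta decremented to %.2f", beta)
            return (u * lam_dir) @ u.T
        beta -= cfg.decrement
    raise ValidationError("deconvolution did not converge before the beta floor")


def deconvolve(g: pd.DataFrame, tfs: TFList,
               cfg: DeconvolutionConfig | None = None) -> RankedNetwork:
    direct = deconvolve_matrix(g.to_numpy(float), cfg, zero_diagonal=True)
    mat = pd.DataFrame(np.abs(direct), index=g.index, columns=g.columns)
    return network_from_symmetric("deconvolution", mat, tfs, threshold=1e-12)


COND_LIMIT = 1e12


def silence_matrix(g: np.ndarray) -> np.ndarray:
    """Silencing transform S = (G − I + D((G−I)·G)) · G⁻¹, with the
    Moore–Penrose pseudoinverse when G is close to singular."""
    g = np.asarray(g, float)
    if not np.allclose(g, g.T, atol=1e-10):
        raise ValidationError("silencing input must be symmetric")
    p = g.shape[0]
    eye = np.eye(p)
    d = np.diag(np.diag((g - eye) @ g))
    if np.linalg.cond(g) > COND_LIMIT:
        logger.warning("silencing: G near-singular; using pseudoinverse")
        g_inv = np.linalg.pinv(g)
    else:
        g_inv = np.linalg.inv(g)
    return (g - eye + d) @ g_inv


def silence(g: pd.DataFrame, tfs: TFList) -> RankedNetwork:
    s = silence_matrix(g.to_numpy(float))
    s = 0.5 * (np.abs(s) + np.abs(s).T)  # emit a symmetric edge strength
    np.fill_diagonal(s, 0.0)
    mat = pd.DataFrame(s, index=g.index, columns=g.columns)
    return network_from_symmetric("silencing", mat, tfs, threshold=1e-12)
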