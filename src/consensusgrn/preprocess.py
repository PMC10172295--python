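"""Expression preprocessing: count filtering, TMM normalization factors,
log2-CPM transformation, per-condition median collapse and gene-wise
standardization.

TMM (trimmed mean of M-values) follows the canonical edgeR algorithm:
pairwise log-ratios against a reference library, doubly trimmed (30% on
M-values, 5% on A-values) and combined with inverse-variance precision
weights; factors are rescaled so their geometric mean is 1.  voom's
per-observation precision weights are deliberately omitted: every
downstream method consumes unweighted correlations or regressions on
standardized values, where such weights have no entry point, so plain
log2-CPM with a +0.5 offset is used instead.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, ExpressionMatrix, SampleMetadata, ValidationError

logger = logging.getLogger("consensusgrn")


def cpm(cm: CountMatrix) -> pd.DataFrame:
    """Counts per million, using raw library sizes."""
    lib = cm.counts.sum(axis=0).to_numpy(float)
    return cm.counts / lib * 1e6


def filter_low_counts(cm: CountMatrix, cpm_threshold: float = 1.0,
                      min_samples: int = 9) -> CountMatrix:
    """Keep genes with CPM >= ``cpm_threshold`` in at least ``min_samples``
    samples; the sample set is unchanged."""
    if min_samples > len(cm.sample_ids):
        raise ValidationError(
            f"min_samples={min_samples} exceeds the {len(cm.sample_ids)} samples"
        )
    if cpm_threshold <= 0:
        keep = (cm.counts > 0).any(axis=1)
    else:
        keep = (cpm(cm) >= cpm_threshold).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValidationError(
            "low-count filter removed every gene; lower cpm_threshold or min_samples"
        )
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_low_counts: dropped %d/%d genes", n_drop, len(keep))
    return CountMatrix(cm.counts.loc[keep])


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """TMM factor of one library against the reference (log2 scale -> 2**f)."""
    both = (obs > 0) & (ref > 0)
    if not both.any():
        raise ValidationError("sample shares no expressed gene with the reference")
    o, r = obs[both].astype(float), ref[both].astype(float)
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m, hi_m = int(np.floor(n * trim_m)) + 1, n - int(np.floor(n * trim_m))
    lo_a, hi_a = int(np.floor(n * trim_a)) + 1, n - int(np.floor(n * trim_a))
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(cm: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05,
                reference: str | None = None) -> pd.Series:
    """Per-sample TMM normalization factors (geometric mean 1).

    The reference library defaults to the sample whose 75th-percentile
    CPM is closest to the mean 75th percentile across samples.
    """
    if len(cm.sample_ids) < 2:
        raise ValidationError("TMM needs at least 2 samples")
    counts = cm.counts.to_numpy(float)
    lib = counts.sum(axis=0)
    if reference is None:
        uq = np.array([np.quantile(counts[:, j] / lib[j], 0.75)
                       for j in range(counts.shape[1])])
        ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_j = cm.sample_ids.index(reference)
    factors = np.array([
        _tmm_pair(counts[:, j], counts[:, ref_j], lib[j], lib[ref_j], trim_m, trim_a)
        for j in range(counts.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.sample_ids, name="tmm_factor")


def log_normalize(cm: CountMatrix, factors: pd.Series) -> ExpressionMatrix:
    """log2 CPM with a +0.5 count offset on TMM-effective library sizes:

        value = log2( (count + 0.5) / (libsize * factor + 1) * 1e6 )
    """
    f = factors.reindex(cm.sample_ids)
    if f.isna().any() or (f <= 0).any():
        raise ValidationError("factors must be positive and cover every sample")
    eff = cm.counts.sum(axis=0).to_numpy(float) * f.to_numpy(float)
    values = np.log2((cm.counts.to_numpy(float) + 0.5) / (eff + 1.0) * 1e6)
    return ExpressionMatrix(pd.DataFrame(values, index=cm.gene_ids,
                                         columns=cm.sample_ids))


def condition_medians(em: ExpressionMatrix, meta: SampleMetadata) -> ExpressionMatrix:
    """Collapse replicate columns to one median column per condition."""
    if em.collapsed_to_medians:
        raise ValidationError("matrix is already condition-collapsed")
    cols = {}
    for cond in meta.condition_ids:
        samples = [s for s in meta.samples_of_condition(cond) if s in em.values.columns]
        if not samples:
            raise ValidationError(f"condition {cond!r} has no samples in the matrix")
        cols[cond] = em.values[samples].median(axis=1)
    out = pd.DataFrame(cols, index=em.values.index)
    return ExpressionMatrix(out, collapsed_to_medians=True,
                            standardized=em.standardized)


def standardize_genewise(em: ExpressionMatrix, tol: float = 1e-12) -> ExpressionMatrix:
    """Per-gene z-score (mean 0, sd 1 with n-1 denominator); near-constant
    genes (sd < tol) are dropped with a warning."""
    arr = em.values.to_numpy(float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] >= tol
    if not keep.any():
        raise ValidationError("every gene has zero variance; cannot standardize")
    if (~keep).any():
        logger.warning("standardize_genewise: dropped %d zero-variance gene(s): %s",
                       int((~keep).sum()),
                       list(em.values.index[~keep][:10]))
    z = (arr[keep] - mu[keep]) / sd[keep]
    out = pd.DataFrame(z, index=em.values.index[keep], columns=em.values.columns)
    return ExpressionMatrix(out, collapsed_to_medians=em.collapsed_to_medians,
                            standardized=True)


def preprocess_pipeline(cm: CountMatrix, meta: SampleMetadata,
                        cpm_threshold: float = 1.0, min_samples: int = 9
                        ) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.Series]:
    """Full preprocessing: filter -> TMM -> log2-CPM; returns the
    replicate-level and the condition-median standardized matrices plus the
    TMM factors.  CLR/ARACNE consume the replicate-level matrix, every other
    inference method the condition-median one."""
    filtered = filter_low_counts(cm, cpm_threshold=cpm_threshold,
                                 min_samples=min_samples)
    factors = tmm_factors(filtered)
    logged = log_normalize(filtered, factors)
    replicates = standardize_genewise(logged)
    medians = standardize_genewise(condition_medians(logged, meta))
    return replicates, medians, factors
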