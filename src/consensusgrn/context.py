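"""Mutant-context subnetwork: differential-expression gene selection by
intersecting several tests at BH FDR 0.05, tree-ensemble inference on the
context samples, and intersection with the consensus network.

Two in-package genome-wide tests are run and intersected ("significant
under all tests"): a moderated t-statistic on log-CPM with empirical-Bayes
variance shrinkage (limma-style scaled-inverse-chi-square prior fit by the
method of moments on log residual variances), and a negative-binomial Wald
test with a method-of-moments common dispersion, both fully vectorised
across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .consensus import density_cutoff, trim_to_density
from .datatypes import (
    ConsensusNetwork,
    ContextNetwork,
    CountMatrix,
    ExpressionMatrix,
    RankedNetwork,
    SampleMetadata,
    TFList,
    ValidationError,
)
from .inference.regression import infer_genie3
from .preprocess import filter_low_counts, log_normalize, tmm_factors

logger = logging.getLogger("consensusgrn")

DEFAULT_TESTS = ("moderated_t", "nb_wald")


@dataclass
class DEResult:
    """Per-gene DE calls: log2 fold-change, per-test raw and BH-adjusted
    p-values, and the all-tests intersection flag."""

    table: pd.DataFrame  # index: gene; log2fc, p_<test>, padj_<test>, significant
    tests: tuple
    alpha: float
    contrast: tuple

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moments fit of the scaled-inv-chi2 prior (d0, s0^2) to observed
    residual variances with ``df`` degrees of freedom each."""
    z = np.log(np.maximum(s2, 1e-12))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_t_test(logcpm: pd.DataFrame, group: np.ndarray) -> pd.DataFrame:
    """Two-group moderated t on log-CPM values; returns log2fc and p."""
    a = logcpm.to_numpy(float)[:, group == 1]
    b = logcpm.to_numpy(float)[:, group == 0]
    n1, n2 = a.shape[1], b.shape[1]
    if min(n1, n2) < 2:
        raise ValidationError("moderated t needs >= 2 replicates per group")
    diff = a.mean(axis=1) - b.mean(axis=1)
    df = n1 + n2 - 2
    s2 = ((a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1))
          / df)
    d0, s0_2 = _fit_variance_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    tstat = diff / np.maximum(se, 1e-12)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df=df_total)
    return pd.DataFrame({"log2fc": diff, "p": p}, index=logcpm.index)


def _nb_group_fit(y: np.ndarray, lib: np.ndarray, alpha_disp: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene NB MLE of the group log-mean (offset = log library size).

    Solves sum_j (y - mu)/(1 + a*mu) = 0 for beta with mu = exp(beta)*N_j
    by vectorised Newton; returns (beta, Fisher information)."""
    tot = y.sum(axis=1)
    beta = np.log(np.maximum(tot, 0.5) / lib.sum())
    a = alpha_disp[:, None]
    for _ in range(25):
        mu = np.exp(beta)[:, None] * lib[None, :]
        f = np.sum((y - mu) / (1.0 + a * mu), axis=1)
        fp = -np.sum(mu * (1.0 + a * y) / (1.0 + a * mu) ** 2, axis=1)
        step = f / np.minimum(fp, -1e-12)
        step = np.clip(step, -5.0, 5.0)
        beta = beta - step
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = np.exp(beta)[:, None] * lib[None, :]
    info = np.sum(mu / (1.0 + a * mu), axis=1)
    return beta, info


def nb_wald_test(counts: pd.DataFrame, group: np.ndarray) -> pd.DataFrame:
    """Two-group NB Wald test with a method-of-moments per-gene dispersion
    pooled across groups; returns log2fc and p."""
    y = counts.to_numpy(float)
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        raise ValidationError("empty library in NB test")
    scale = np.exp(np.mean(np.log(lib)))
    pseudo = y * (scale / lib)[None, :]
    num = np.zeros(y.shape[0])
    den = np.zeros(y.shape[0])
    for g in (0, 1):
        sub = pseudo[:, group == g]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += v - m
        den += m ** 2
    disp = np.clip(num / np.maximum(den, 1e-12), 1e-8, 10.0)
    # with 2-3 replicates the per-gene MoM estimate is extremely noisy and
    # biased low; floor it at the across-gene median so that no gene is
    # tested with a near-Poisson variance it does not have
    common = float(np.median(disp))
    disp = np.maximum(disp, common)
    b1, i1 = _nb_group_fit(y[:, group == 1], lib[group == 1], disp)
    b0, i0 = _nb_group_fit(y[:, group == 0], lib[group == 0], disp)
    se = np.sqrt(1.0 / np.maximum(i1, 1e-12) + 1.0 / np.maximum(i0, 1e-12))
    z = (b1 - b0) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"log2fc": (b1 - b0) / np.log(2.0), "p": p},
                        index=counts.index)


def call_de_genes(cm: CountMatrix, meta: SampleMetadata, contrast: tuple,
                  alpha: float = 0.05, min_cpm: float = 1.0,
                  min_samples: int = 4, tests: tuple = DEFAULT_TESTS
                  ) -> DEResult:
    """Differential expression between two genotypes; significant = BH-adjusted
    p <= alpha under every configured test."""
    ref, alt = contrast
    genotype = meta.table["genotype"].astype(str)
    keep_samples = list(meta.table.index[genotype.isin([ref, alt])])
    for label in (ref, alt):
        n = int((genotype == label).sum())
        if n == 0:
            raise ValidationError(f"genotype {label!r} absent from metadata")
        if n < 2:
            raise ValidationError(f"genotype {label!r} has fewer than 2 replicates")
    sub = cm.subset_samples(keep_samples)
    sub = filter_low_counts(sub, cpm_threshold=min_cpm, min_samples=min_samples)
    group = (genotype.loc[keep_samples] == alt).to_numpy().astype(int)

    factors = tmm_factors(sub)
    logcpm = log_normalize(sub, factors).values

    results = {}
    for test in tests:
        if test == "moderated_t":
            results[test] = moderated_t_test(logcpm, group)
        elif test == "nb_wald":
            results[test] = nb_wald_test(sub.counts, group)
        else:
            raise ValidationError(f"unknown DE test {test!r}")

    table = pd.DataFrame(index=sub.gene_ids)
    table["log2fc"] = results[tests[0]]["log2fc"]
    sig = np.ones(len(table), dtype=bool)
    for test in tests:
        p = results[test]["p"].to_numpy()
        padj = multipletests(p, method="fdr_bh")[1]
        table[f"p_{test}"] = p
        table[f"padj_{test}"] = padj
        sig &= padj <= alpha
    table["significant"] = sig
    logger.info("call_de_genes %s vs %s: %d/%d significant under all %d tests",
                ref, alt, int(sig.sum()), len(table), len(tests))
    return DEResult(table=table, tests=tuple(tests), alpha=alpha,
                    contrast=(ref, alt))


def infer_context_grn(em: ExpressionMatrix, de: DEResult, tfs: TFList,
                      seed: int = 0, n_trees: int = 1000,
                      density: float = 0.1) -> RankedNetwork:
    """GENIE3-style inference restricted to DE genes (DE TFs as predictors),
    on the context samples' replicate-level standardized matrix, trimmed to
    the subnetwork's 10% density."""
    de_genes = [g for g in de.significant_genes if g in set(em.gene_ids)]
    if not de_genes:
        raise ValidationError("no significant DE gene available for context inference")
    de_tfs = [t for t in tfs if t in set(de_genes)]
    if len(de_tfs) < 2:
        raise ValidationError(f"need >= 2 DE TFs, found {len(de_tfs)}")
    if len(de_genes) < 3:
        raise ValidationError(f"need >= 3 DE genes, found {len(de_genes)}")
    sub = em.subset_genes(de_genes)
    net = infer_genie3(sub, TFList(tuple(de_tfs)), n_trees=n_trees, seed=seed,
                       check_flags=False)
    net.method = "context_genie3"
    return trim_to_density(net, density)


def intersect_with_consensus(context: RankedNetwork,
                             consensus: ConsensusNetwork) -> ContextNetwork:
    """Edge set = context ∩ consensus; weights are the context importances."""
    ctx_idx = context.edge_index()
    cons_idx = consensus.edge_index()
    common = ctx_idx.intersection(cons_idx)
    if len(common) == 0:
        logger.warning("context/consensus intersection is empty")
    ctx = context.edges.set_index(["regulator", "target"])
    edges = (ctx.loc[list(common), ["score"]]
             .rename(columns={"score": "weight"})
             .reset_index()
             .sort_values(["regulator", "target"], kind="stable")
             .reset_index(drop=True)
             if len(common) else
             pd.DataFrame(columns=["regulator", "target", "weight"]))
    prov = (consensus.edges.set_index(["regulator", "target"])
            .loc[list(common)].reset_index()
            if len(common) else pd.DataFrame())
    return ContextNetwork(edges=edges, provenance=prov)
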