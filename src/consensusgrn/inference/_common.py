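"""Shared helpers for assembling RankedNetworks from score matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..datatypes import ExpressionMatrix, RankedNetwork, TFList, ValidationError


def total_possible_edges(n_tfs: int, n_genes: int) -> int:
    """Directed candidate edges: a TF may regulate every other gene
    (other TFs included) but not itself."""
    return n_tfs * (n_genes - 1)


def require_condition_medians(em: ExpressionMatrix, method: str) -> None:
    if not (em.standardized and em.collapsed_to_medians):
        raise ValidationError(
            f"{method} requires the standardized condition-median matrix"
        )


def require_replicate_level(em: ExpressionMatrix, method: str) -> None:
    if not em.standardized or em.collapsed_to_medians:
        raise ValidationError(
            f"{method} requires the standardized replicate-level matrix"
        )


def network_from_symmetric(method: str, scores: pd.DataFrame, tfs: TFList,
                           threshold: float = 0.0) -> RankedNetwork:
    """Emit a directed TF->gene edge for every TF incidence of a symmetric
    score matrix; a TF-TF pair yields both directions with the same score.
    Entries with score <= ``threshold`` are omitted."""
    genes = list(scores.index)
    tf_members = [t for t in tfs if t in set(genes)]
    if not tf_members:
        raise ValidationError("no TF present in the score matrix")
    arr = scores.to_numpy(float)
    gene_pos = {g: i for i, g in enumerate(genes)}
    rows = []
    for tf in tf_members:
        i = gene_pos[tf]
        vals = arr[i]
        for j, g in enumerate(genes):
            if g == tf:
                continue
            s = vals[j]
            if s > threshold:
                rows.append((tf, g, s))
    scored = pd.DataFrame(rows, columns=["regulator", "target", "score"])
    e_total = total_possible_edges(len(tf_members), len(genes))
    return RankedNetwork.from_scores(method, scored, e_total)


def network_from_directed(method: str, scored: pd.DataFrame, n_tfs: int,
                          n_genes: int) -> RankedNetwork:
    scored = scored[scored["score"] > 0].reset_index(drop=True)
    return RankedNetwork.from_scores(method, scored,
                                     total_possible_edges(n_tfs, n_genes))


def pearson_correlation(em: ExpressionMatrix) -> pd.DataFrame:
    """Gene-gene Pearson correlation matrix G (unit diagonal)."""
    arr = em.values.to_numpy(float)
    g = np.corrcoef(arr)
    np.fill_diagonal(g, 1.0)
    return pd.DataFrame(g, index=em.values.index, columns=em.values.index)
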