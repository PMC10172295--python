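"""Planted-edge recovery metrics for synthetic benchmarks: AUROC/AUPR of a
network's scores against the ground-truth edge set, with a permutation test
on the AUROC."""

from __future__ import annotations

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .datatypes import ConsensusNetwork, RankedNetwork, ValidationError
from .simulate import GroundTruthGRN


def edge_recovery_arrays(net, grn: GroundTruthGRN
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Labels and scores over every candidate TF->gene edge of the planted
    universe; edges absent from the network score 0."""
    if isinstance(net, ConsensusNetwork):
        scored = dict(zip(zip(net.edges["regulator"], net.edges["target"]),
                          net.edges["weight"]))
    elif isinstance(net, RankedNetwork):
        scored = dict(zip(zip(net.edges["regulator"], net.edges["target"]),
                          net.edges["score"]))
    else:
        raise ValidationError(f"cannot evaluate a {type(net).__name__}")
    truth = grn.edge_set()
    y, s = [], []
    for tf in grn.tf_ids:
        for gene in grn.gene_ids:
            if gene == tf:
                continue
            y.append((tf, gene) in truth)
            s.append(scored.get((tf, gene), 0.0))
    return np.asarray(y, dtype=int), np.asarray(s, dtype=float)


def planted_auroc(net, grn: GroundTruthGRN) -> float:
    y, s = edge_recovery_arrays(net, grn)
    return float(roc_auc_score(y, s))


def planted_aupr(net, grn: GroundTruthGRN) -> float:
    y, s = edge_recovery_arrays(net, grn)
    return float(average_precision_score(y, s))


def auroc_permutation_pvalue(net, grn: GroundTruthGRN, n_shuffles: int = 100,
                             seed: int = 0) -> tuple[float, float]:
    """One-sided permutation p for AUROC > 0.5: shuffle the edge labels
    ``n_shuffles`` times; p = (#{AUROC_perm >= AUROC_obs} + 1)/(n + 1)."""
    y, s = edge_recovery_arrays(net, grn)
    observed = float(roc_auc_score(y, s))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(y)
        if roc_auc_score(perm, s) >= observed:
            exceed += 1
    return observed, (exceed + 1) / (n_shuffles + 1)
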