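"""Regulator discovery: strength scores over curated target sets, top-k
extraction with explicit tie expansion, the Monte-Carlo overlap test, and
gold-standard benchmarking.

The regulator strength of a TF for a target gene set of k genes is the sum
of its edge weights into that set, C(TF) = sum_j w_TFj.  The overlap of the
top-k regulator lists of two gene sets is tested against sets of the same
cardinalities drawn without replacement from the network's own target
universe (nodes with at least one incoming edge); the empirical p-value is
(r + 1)/(n + 1) with r the number of the n Monte-Carlo iterations reaching
an overlap at least as large as observed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .consensus import density_cutoff
from .datatypes import (
    BenchmarkReport,
    ConsensusNetwork,
    ContextNetwork,
    GeneSet,
    GoldStandard,
    OverlapTestResult,
    RankedNetwork,
    RegulatorScoreTable,
    ValidationError,
)

logger = logging.getLogger("consensusgrn")


def _edge_weights(net) -> pd.DataFrame:
    """(regulator, target, weight) rows of any network flavour."""
    if isinstance(net, ConsensusNetwork):
        return net.edges[["regulator", "target", "weight"]]
    if isinstance(net, ContextNetwork):
        return net.edges[["regulator", "target", "weight"]]
    if isinstance(net, RankedNetwork):
        return net.edges.rename(columns={"score": "weight"})[
            ["regulator", "target", "weight"]]
    raise ValidationError(f"unsupported network type {type(net).__name__}")


def weight_matrix(net) -> pd.DataFrame:
    """Dense TF x target weight matrix (absent edges are 0)."""
    edges = _edge_weights(net)
    return edges.pivot_table(index="regulator", columns="target",
                             values="weight", fill_value=0.0, aggfunc="sum")


def regulator_strength(net, targets: GeneSet) -> RegulatorScoreTable:
    """C(TF) over the target set; sorted C descending, ties lexicographic."""
    w = weight_matrix(net)
    targets.missing_from(w.columns)
    present = [g for g in sorted(targets.members) if g in w.columns]
    if not present:
        logger.warning("no network edge touches target set %s", targets.name)
        empty = pd.DataFrame(columns=["tf", "C"])
        return RegulatorScoreTable(scores=empty, contributions=pd.DataFrame(),
                                   target_set=targets.name)
    contributions = w[present]
    c = contributions.sum(axis=1)
    scores = (pd.DataFrame({"tf": c.index, "C": c.to_numpy()})
              .sort_values(["C", "tf"], ascending=[False, True], kind="stable")
              .reset_index(drop=True))
    return RegulatorScoreTable(scores=scores, contributions=contributions,
                               target_set=targets.name)


def top_regulators(table: RegulatorScoreTable, k: int = 10) -> GeneSet:
    """The k strongest TFs; a tie spanning position k is included whole."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    scores = table.scores
    if len(scores) == 0:
        raise ValidationError("empty regulator score table")
    if len(scores) <= k:
        if len(scores) < k:
            logger.warning("only %d scored TFs for top-%d request", len(scores), k)
        return GeneSet(name=f"top{k}_{table.target_set}",
                       members=frozenset(scores["tf"]))
    threshold = scores["C"].iloc[k - 1]
    chosen = scores[scores["C"] >= threshold]
    if len(chosen) > k:
        logger.info("top_regulators: tie at rank %d expanded to %d TFs",
                    k, len(chosen))
    return GeneSet(name=f"top{k}_{table.target_set}",
                   members=frozenset(chosen["tf"]))


def _top_k_rows(w: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of rows in the top k by value, ties at the boundary
    expanded (mirrors top_regulators on a raw score vector)."""
    if len(w) <= k:
        return np.ones(len(w), dtype=bool)
    threshold = np.partition(w, -k)[-k]
    return w >= threshold


def overlap_pvalue(net, set_a: GeneSet, set_b: GeneSet, k: int = 10,
                   n_iter: int = 10000, seed: int = 0) -> OverlapTestResult:
    """Monte-Carlo empirical p for the top-k regulator overlap of two sets."""
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    w = weight_matrix(net)
    universe = list(w.columns)  # all targets in the network
    for s in (set_a, set_b):
        if len(s) > len(universe):
            raise ValidationError(
                f"gene set {s.name} larger than the network's {len(universe)} targets"
            )
    top_a = top_regulators(regulator_strength(net, set_a), k).members
    top_b = top_regulators(regulator_strength(net, set_b), k).members
    observed = len(top_a & top_b)

    arr = w.to_numpy(float)
    rng = np.random.default_rng(seed)
    na, nb = len(set_a), len(set_b)
    r = 0
    for _ in range(n_iter):
        ia = rng.choice(len(universe), size=na, replace=False)
        ib = rng.choice(len(universe), size=nb, replace=False)
        ca = arr[:, ia].sum(axis=1)
        cb = arr[:, ib].sum(axis=1)
        mask = _top_k_rows(ca, k) & _top_k_rows(cb, k)
        if int(mask.sum()) >= observed:
            r += 1
    p = (r + 1) / (n_iter + 1)
    return OverlapTestResult(observed=observed, r=r, n_iter=n_iter, p=p,
                             k=k, seed=seed)


def _network_ranks(net) -> tuple[str, pd.Series, int, bool]:
    """(name, rank per (regulator, target), E, already_trimmed)."""
    if isinstance(net, ConsensusNetwork):
        edges = net.edges
        ranks = pd.Series(np.arange(1, len(edges) + 1, dtype=float),
                          index=pd.MultiIndex.from_frame(
                              edges[["regulator", "target"]]))
        return "consensus", ranks, net.total_possible_edges, True
    if isinstance(net, RankedNetwork):
        ranks = pd.Series(net.edges["rank"].to_numpy(float),
                          index=net.edge_index())
        return net.method, ranks, net.total_possible_edges, False
    raise ValidationError(f"cannot benchmark a {type(net).__name__}")


def benchmark_against_gold(nets: list, gold: GoldStandard,
                           density: float = 0.1) -> BenchmarkReport:
    """Classify every gold-standard record per network as highly_ranked
    (present at rank <= floor(density*E)), below_threshold (present but
    deeper) or absent; sensitivity = highly-ranked positives / positives,
    and highly-ranked negatives are flagged as potential false positives."""
    gold_genes = set(gold.records["regulator"]) | set(gold.records["target"])
    any_known = False
    rows, summaries = [], []
    for net in nets:
        name, ranks, e_total, _ = _network_ranks(net)
        nodes = {g for pair in ranks.index for g in pair}
        if gold_genes & nodes:
            any_known = True
        cutoff = density_cutoff(e_total, density)
        n_pos = n_hit = n_fp = 0
        for rec in gold.records.itertuples(index=False):
            key = (rec.regulator, rec.target)
            if key in ranks.index:
                rank = float(ranks.loc[key])
                status = "highly_ranked" if rank <= cutoff else "below_threshold"
            else:
                rank, status = np.nan, "absent"
            rows.append((name, rec.regulator, rec.target, rec.label,
                         status, rank))
            if rec.label == "positive":
                n_pos += 1
                n_hit += status == "highly_ranked"
            elif status == "highly_ranked":
                n_fp += 1
        sensitivity = n_hit / n_pos if n_pos else np.nan
        summaries.append({"network": name, "sensitivity": sensitivity,
                          "n_positives": n_pos, "n_highly_ranked": n_hit,
                          "n_negative_highly_ranked": n_fp})
        if n_fp:
            logger.warning("%s: %d negative-label edge(s) highly ranked "
                           "(potential false positives)", name, n_fp)
    if not any_known:
        raise ValidationError("gold-standard genes entirely outside the "
                              "networks' gene universe")
    classification = pd.DataFrame(
        rows, columns=["network", "regulator", "target", "label", "status",
                       "rank"])
    return BenchmarkReport(classification=classification,
                           summary=pd.DataFrame(summaries), density=density)
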