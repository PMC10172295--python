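"""Borda-count consensus: trim per-method rankings to a common density and
integrate them by the arithmetic mean of ranks.

For an edge missing from some method's trimmed ranking the missing rank is
imputed as floor(density * E) + 1, one past the worst retained rank.  The
consensus is re-ranked by the mean rank and itself trimmed to
floor(density * E) edges; the edge weight used for regulator scoring is the
reciprocal of the mean rank.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ConsensusNetwork, RankedNetwork, ValidationError


def density_cutoff(total_possible_edges: int, density: float) -> int:
    return int(np.floor(density * total_possible_edges))


def trim_to_density(net: RankedNetwork, density: float = 0.1) -> RankedNetwork:
    """Keep edges with rank <= floor(density * E).

    Tied scores share the average rank, so a tie group straddling the
    cutoff is kept or dropped atomically: it survives iff its (shared)
    average rank is <= the cutoff.
    """
    if not (0 < density <= 1):
        raise ValidationError("density must lie in (0, 1]")
    cutoff = density_cutoff(net.total_possible_edges, density)
    kept = net.edges[net.edges["rank"] <= cutoff]
    return RankedNetwork(method=net.method, edges=kept.reset_index(drop=True),
                         total_possible_edges=net.total_possible_edges)


def borda_consensus(nets: list[RankedNetwork], density: float = 0.1
                    ) -> ConsensusNetwork:
    """Integrate >= 2 density-trimmed rankings by Borda count."""
    if len(nets) < 2:
        if len(nets) == 1:
            # degenerate k=1: consensus ordering is the single input
            nets = [nets[0], nets[0]]
        else:
            raise ValidationError("consensus needs at least one network")
    totals = {n.total_possible_edges for n in nets}
    if len(totals) != 1:
        raise ValidationError(
            f"inconsistent total_possible_edges across inputs: {sorted(totals)}"
        )
    e_total = totals.pop()
    cutoff = density_cutoff(e_total, density)
    missing_rank = cutoff + 1

    trimmed = [trim_to_density(n, density) for n in nets]
    methods = []
    rank_cols = {}
    for net in trimmed:
        name = net.method
        if name in rank_cols:  # duplicate method labels (k=1 degenerate or reruns)
            suffix = 2
            while f"{name}_{suffix}" in rank_cols:
                suffix += 1
            name = f"{name}_{suffix}"
        methods.append(name)
        rank_cols[name] = net.edges.set_index(["regulator", "target"])["rank"]

    union = pd.DataFrame(rank_cols)  # index: (regulator, target); NaN = missing
    k = len(methods)
    filled = union.fillna(float(missing_rank))
    r_consens = filled.mean(axis=1)

    out = filled.copy()
    out.columns = [f"rank_{m}" for m in methods]
    out["r_consens"] = r_consens
    out = out.reset_index()
    out = out.sort_values(["r_consens", "regulator", "target"],
                          kind="stable").reset_index(drop=True)
    out = out.head(cutoff)
    out["weight"] = 1.0 / out["r_consens"]
    cols = (["regulator", "target", "r_consens", "weight"]
            + [f"rank_{m}" for m in methods])
    return ConsensusNetwork(edges=out[cols], k=k,
                            total_possible_edges=e_total, density=density)
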