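"""Core domain types shared by every pipeline stage.

All containers are thin dataclasses around pandas/numpy objects.  They
validate their invariants on construction so that downstream stages can
assume consistency (unique identifiers, non-negative counts, TF-origin
edges, rank/score coherence) instead of re-checking it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger("consensusgrn")

EDGE_COLUMNS = ["regulator", "target", "score", "rank"]


class ValidationError(ValueError):
    """An input object violates a structural invariant."""


def _check_unique(ids, what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if list(ids).count(g) > 1})
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class CountMatrix:
    """Raw gene-level read counts, genes x samples."""

    counts: pd.DataFrame  # index: gene ids, columns: sample ids, int dtype

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene ids")
        _check_unique(self.counts.columns, "sample ids")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                bad = np.argwhere(np.mod(values, 1) != 0)[0]
                raise ValidationError(
                    "non-integer count at gene "
                    f"{self.counts.index[bad[0]]!r}, sample {self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValidationError(
                "negative count at gene "
                f"{self.counts.index[bad[0]]!r}, sample {self.counts.columns[bad[1]]!r}"
            )
        totals = values.sum(axis=0)
        if (totals <= 0).any():
            empty = self.counts.columns[np.asarray(totals) <= 0].tolist()
            raise ValidationError(f"samples with zero total count: {empty}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)])

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(self.counts[list(samples)])


@dataclass
class SampleMetadata:
    """Per-sample annotations: condition, replicate and covariates."""

    table: pd.DataFrame  # indexed by sample_id

    REQUIRED = ("condition_id", "replicate_index")

    def __post_init__(self) -> None:
        if self.table.index.name != "sample_id":
            if "sample_id" in self.table.columns:
                self.table = self.table.set_index("sample_id")
            else:
                self.table.index.name = "sample_id"
        _check_unique(self.table.index, "sample ids in metadata")
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
        rep = self.table["replicate_index"]
        if (rep.astype(float) < 1).any() or not np.all(np.mod(rep.astype(float), 1) == 0):
            raise ValidationError("replicate_index must be a positive integer")
        pair = self.table[["condition_id", "replicate_index"]]
        if pair.duplicated().any():
            bad = pair[pair.duplicated()].iloc[0]
            raise ValidationError(
                f"duplicate (condition_id, replicate_index): ({bad.condition_id}, {bad.replicate_index})"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def condition_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.table["condition_id"]:
            seen.setdefault(c)
        return list(seen)

    def samples_of_condition(self, condition_id) -> list[str]:
        mask = self.table["condition_id"] == condition_id
        return list(self.table.index[mask])

    def align_to(self, cm: CountMatrix) -> "SampleMetadata":
        """Reorder to the matrix's sample order; error on any mismatch."""
        missing = set(cm.sample_ids) - set(self.table.index)
        extra = set(self.table.index) - set(cm.sample_ids)
        if missing:
            raise ValidationError(f"samples missing from metadata: {sorted(missing)}")
        if extra:
            raise ValidationError(f"metadata samples absent from matrix: {sorted(extra)}")
        return SampleMetadata(self.table.loc[cm.sample_ids].copy())


@dataclass
class GeneSet:
    name: str
    members: frozenset

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def missing_from(self, universe) -> set:
        """Members absent from a gene universe (reported, never dropped silently)."""
        missing = set(self.members) - set(universe)
        if missing:
            logger.warning(
                "gene set %s: %d member(s) outside the gene universe: %s",
                self.name, len(missing), sorted(missing)[:10],
            )
        return missing

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class TFList:
    members: tuple

    def __post_init__(self) -> None:
        _check_unique(self.members, "TF ids")
        self.members = tuple(self.members)
        if not self.members:
            raise ValidationError("TF list is empty")

    def restrict_to(self, universe) -> "TFList":
        universe = set(universe)
        kept = tuple(t for t in self.members if t in universe)
        dropped = [t for t in self.members if t not in universe]
        if dropped:
            logger.warning("TF list: %d TF(s) absent after filtering: %s",
                           len(dropped), dropped[:10])
        if not kept:
            raise ValidationError("no TF from the list is present in the gene universe")
        return TFList(kept)

    def __contains__(self, gene) -> bool:
        return gene in set(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


def rank_scores(scores: np.ndarray) -> np.ndarray:
    """Rank descending-by-score with average ranks for ties (rank 1 = best)."""
    return rankdata(-np.asarray(scores, dtype=float), method="average")


@dataclass
class RankedNetwork:
    """One inference method's directed TF->gene edge ranking.

    ``total_possible_edges`` (E) is the number of directed candidate edges
    in the gene universe the network was inferred on: |TF| * (G - 1),
    i.e. a TF may regulate every other gene including other TFs, but not
    itself.
    """

    method: str
    edges: pd.DataFrame  # columns EDGE_COLUMNS
    total_possible_edges: int

    def __post_init__(self) -> None:
        if list(self.edges.columns[:4]) != EDGE_COLUMNS:
            self.edges = self.edges[EDGE_COLUMNS]
        self.edges = self.edges.reset_index(drop=True)
        if self.total_possible_edges < 1:
            raise ValidationError("total_possible_edges must be positive")
        if len(self.edges):
            if (self.edges["regulator"] == self.edges["target"]).any():
                raise ValidationError(f"{self.method}: self-edge present")
            if self.edges.duplicated(["regulator", "target"]).any():
                raise ValidationError(f"{self.method}: duplicate edge")
            ranks = self.edges["rank"].to_numpy(float)
            if ranks.min() < 1:
                raise ValidationError(f"{self.method}: ranks must start at 1")
            order = np.argsort(ranks, kind="stable")
            scores = self.edges["score"].to_numpy(float)[order]
            if np.any(np.diff(scores) > 1e-9):
                raise ValidationError(f"{self.method}: score increases with rank")

    @classmethod
    def from_scores(cls, method: str, scored: pd.DataFrame,
                    total_possible_edges: int) -> "RankedNetwork":
        """Build from a (regulator, target, score) table; ranks are assigned
        descending by score with ties sharing the average rank, and rows are
        sorted by rank then (regulator, target)."""
        scored = scored[["regulator", "target", "score"]].copy()
        scored["rank"] = rank_scores(scored["score"].to_numpy())
        scored = scored.sort_values(
            ["rank", "regulator", "target"], kind="stable"
        ).reset_index(drop=True)
        return cls(method=method, edges=scored,
                   total_possible_edges=total_possible_edges)

    @property
    def density(self) -> float:
        return len(self.edges) / self.total_possible_edges

    def edge_index(self) -> pd.Index:
        return pd.MultiIndex.from_frame(self.edges[["regulator", "target"]])

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class GoldStandard:
    """Curated positive/negative TF->target interactions."""

    records: pd.DataFrame  # columns: regulator, target, label, source

    LABELS = frozenset({"positive", "negative"})

    def __post_init__(self) -> None:
        req = ["regulator", "target", "label"]
        for col in req:
            if col not in self.records.columns:
                raise ValidationError(f"gold standard missing column {col!r}")
        if "source" not in self.records.columns:
            self.records = self.records.assign(source="")
        bad = set(self.records["label"]) - self.LABELS
        if bad:
            raise ValidationError(f"gold standard labels outside {{positive, negative}}: {sorted(bad)}")
        dup = self.records.duplicated(["regulator", "target"])
        if dup.any():
            pair = self.records[dup].iloc[0]
            raise ValidationError(
                f"duplicate gold-standard pair ({pair.regulator}, {pair.target})"
            )
        self.records = self.records.reset_index(drop=True)

    @property
    def positives(self) -> pd.DataFrame:
        return self.records[self.records["label"] == "positive"]

    @property
    def negatives(self) -> pd.DataFrame:
        return self.records[self.records["label"] == "negative"]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ExpressionMatrix:
    """Log-scale expression, genes x (samples | conditions).

    ``collapsed_to_medians`` and ``standardized`` record which preprocessing
    steps have been applied; inference methods assert on them so that the
    replicate-level methods (CLR/ARACNE) and the condition-median methods
    cannot be fed the wrong matrix.
    """

    values: pd.DataFrame
    collapsed_to_medians: bool = False
    standardized: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "column ids")
        arr = self.values.to_numpy(float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("expression matrix contains non-finite values")
        if self.standardized and arr.shape[1] > 1:
            mu = arr.mean(axis=1)
            sd = arr.std(axis=1, ddof=1)
            if np.abs(mu).max() > 1e-6 or np.abs(sd - 1).max() > 1e-6:
                raise ValidationError("matrix flagged standardized but is not")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def column_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)],
                                collapsed_to_medians=self.collapsed_to_medians,
                                standardized=self.standardized)


@dataclass
class ConsensusNetwork:
    """Borda-count integration of k ranked networks.

    ``r_consens`` is the arithmetic mean of the per-method ranks (missing
    ranks imputed as floor(density*E)+1); the edge weight is its reciprocal.
    Per-method contributing ranks are retained in ``rank_<method>`` columns.
    """

    edges: pd.DataFrame  # regulator, target, r_consens, weight, rank_<method>...
    k: int
    total_possible_edges: int
    density: float = 0.1

    def __post_init__(self) -> None:
        if len(self.edges):
            prod = self.edges["weight"] * self.edges["r_consens"]
            if np.abs(prod - 1).max() > 1e-12:
                raise ValidationError("weight * r_consens != 1")
        cutoff = int(np.floor(self.density * self.total_possible_edges))
        if len(self.edges) > cutoff:
            raise ValidationError(
                f"consensus has {len(self.edges)} edges, above the "
                f"{self.density:.0%} density cutoff {cutoff}"
            )
        self.edges = self.edges.reset_index(drop=True)

    def edge_index(self) -> pd.Index:
        return pd.MultiIndex.from_frame(self.edges[["regulator", "target"]])

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class ContextNetwork:
    """Context (e.g. mutant-specific) subnetwork of the consensus.

    Edge set is the intersection with the consensus; weights come from the
    context inference (tree-ensemble importances), not from consensus ranks.
    """

    edges: pd.DataFrame  # regulator, target, weight
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def edge_index(self) -> pd.Index:
        return pd.MultiIndex.from_frame(self.edges[["regulator", "target"]])

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class RegulatorScoreTable:
    """C(TF) = sum of edge weights from a TF into a target gene set."""

    scores: pd.DataFrame          # columns: tf, C; sorted C desc, tf lexicographic
    contributions: pd.DataFrame   # tf x target weight matrix (audit trail)
    target_set: str = ""

    def top(self, k: int = 10) -> list:
        from .regulators import top_regulators  # noqa: PLC0415 (cycle guard)
        return sorted(top_regulators(self, k).members)

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class OverlapTestResult:
    """Monte-Carlo empirical p for the overlap of two regulator top-k lists."""

    observed: int
    r: int           # iterations with overlap >= observed
    n_iter: int
    p: float
    k: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.r <= self.n_iter):
            raise ValidationError("r must lie in [0, n_iter]")
        lo, hi = 1.0 / (self.n_iter + 1), 1.0
        if not (lo - 1e-12 <= self.p <= hi + 1e-12):
            raise ValidationError("empirical p outside [1/(n+1), 1]")

    def to_dict(self) -> dict:
        return {"observed_overlap": self.observed, "r": self.r,
                "n_iter": self.n_iter, "p_value": self.p, "k": self.k,
                "seed": self.seed}


@dataclass
class BenchmarkReport:
    """Gold-standard classification of one or more networks.

    Every gold record gets one of three statuses per network:
    ``highly_ranked`` (present at rank <= floor(density*E)),
    ``below_threshold`` (present but deeper), or ``absent``.
    """

    classification: pd.DataFrame  # network, regulator, target, label, status, rank
    summary: pd.DataFrame         # per network: sensitivity, n_pos, false positives
    density: float

    STATUSES = ("highly_ranked", "below_threshold", "absent")

    def to_dict(self) -> dict:
        return {
            "density": self.density,
            "networks": self.summary.to_dict(orient="records"),
        }
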