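"""Readers and writers for every on-disk format the pipeline touches.

The single interchange format between stages is a TSV edge list with the
fixed header ``regulator  target  score  rank  method``; counts, metadata,
gold standards and score tables are TSV; TF lists and gene sets are plain
text, one gene id per line.  Every reader is the inverse of its writer on
valid objects (ids and integers bit-stable, floats to <=1e-12 relative
error via repr round-trip).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ConsensusNetwork,
    CountMatrix,
    GeneSet,
    GoldStandard,
    RankedNetwork,
    SampleMetadata,
    TFList,
    ValidationError,
)


def read_count_matrix(path, metadata_path) -> tuple[CountMatrix, SampleMetadata]:
    """Read a genes-x-samples count TSV and its paired sample metadata.

    The two files are cross-checked: every matrix sample must appear in the
    metadata and vice versa; the returned metadata is reordered to the
    matrix's sample order.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    try:
        counts = raw.apply(pd.to_numeric)
    except ValueError as exc:
        raise ValidationError(f"non-numeric count in {path}: {exc}") from exc
    arr = counts.to_numpy()
    if not np.all(np.equal(np.mod(arr, 1), 0)):
        g, s = np.argwhere(np.mod(arr, 1) != 0)[0]
        raise ValidationError(
            f"non-integer count at gene {counts.index[g]!r}, sample {counts.columns[s]!r}"
        )
    cm = CountMatrix(counts.astype(np.int64))
    meta_tbl = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta_tbl.columns:
        raise ValidationError(f"{metadata_path} lacks a sample_id column")
    meta = SampleMetadata(meta_tbl)
    return cm, meta.align_to(cm)


def write_count_matrix(cm: CountMatrix, meta: SampleMetadata,
                       counts_path, metadata_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    meta.table.to_csv(metadata_path, sep="\t", index_label="sample_id")


def write_ranked_network(net: RankedNetwork, path) -> None:
    """TSV edge list sorted by rank ascending, ties by (regulator, target)."""
    out = net.edges.sort_values(["rank", "regulator", "target"], kind="stable").copy()
    out["method"] = net.method
    with open(path, "w") as fh:
        fh.write(f"# total_possible_edges={net.total_possible_edges}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_ranked_network(path) -> RankedNetwork:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# total_possible_edges="):
            raise ValidationError(f"{path}: missing total_possible_edges header")
        total = int(first.split("=", 1)[1])
        edges = pd.read_csv(fh, sep="\t", dtype={"regulator": str, "target": str})
    if len(edges):
        methods = edges["method"].unique()
        if len(methods) != 1:
            raise ValidationError(f"{path}: mixed methods {methods}")
        method = methods[0]
    else:
        method = Path(path).stem
    return RankedNetwork(
        method=method,
        edges=edges[["regulator", "target", "score", "rank"]]
        if len(edges) else pd.DataFrame(columns=["regulator", "target", "score", "rank"]),
        total_possible_edges=total,
    )


def write_consensus_network(net: ConsensusNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# total_possible_edges={net.total_possible_edges}"
            f"\tk={net.k}\tdensity={net.density}\n"
        )
        net.edges.to_csv(fh, sep="\t", index=False)


def read_consensus_network(path) -> ConsensusNetwork:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# total_possible_edges="):
            raise ValidationError(f"{path}: missing consensus header")
        fields = dict(kv.split("=") for kv in header[2:].strip().split("\t"))
        edges = pd.read_csv(fh, sep="\t", dtype={"regulator": str, "target": str})
    return ConsensusNetwork(
        edges=edges,
        k=int(fields["k"]),
        total_possible_edges=int(fields["total_possible_edges"]),
        density=float(fields["density"]),
    )


def read_gold_standard(path) -> GoldStandard:
    tbl = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("regulator", "target", "label"):
        if col not in tbl.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return GoldStandard(tbl)


def write_gold_standard(gold: GoldStandard, path) -> None:
    gold.records.to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    """Plain text, one gene id per line; blank lines and '#' comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_tf_list(path) -> TFList:
    return TFList(tuple(read_gene_list(path)))


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_set(path, name: str | None = None) -> GeneSet:
    return GeneSet(name=name or Path(path).stem, members=frozenset(read_gene_list(path)))


def write_json_report(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
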