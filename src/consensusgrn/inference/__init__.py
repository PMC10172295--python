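"""Seven complementary GRN inference approaches, each producing a
RankedNetwork of directed TF->gene edges.

CLR and ARACNE operate on the replicate-level standardized matrix; GGM,
elastic net, GENIE3, deconvolution and silencing on the condition-median
standardized matrix.  ``infer_network`` dispatches by method name and picks
the right input.
"""

from __future__ import annotations

from ..datatypes import ExpressionMatrix, RankedNetwork, TFList, ValidationError
from ._common import pearson_correlation, total_possible_edges
from .ggm import infer_ggm, shrunk_partial_correlations
from .mi import dpi_prune, estimate_spearman_mi, infer_aracne, infer_clr
from .regression import ElasticNetConfig, infer_elasticnet, infer_genie3
from .spectral import DeconvolutionConfig, deconvolve, deconvolve_matrix, silence, silence_matrix

METHODS = ("ggm", "clr", "aracne", "elasticnet", "genie3",
           "deconvolution", "silencing")
#: methods integrated into the final consensus (ARACNE and silencing are
#: benchmarked but excluded from it)
CONSENSUS_METHODS = ("ggm", "clr", "elasticnet", "genie3", "deconvolution")

REPLICATE_LEVEL_METHODS = frozenset({"clr", "aracne"})


def infer_network(method: str, em_medians: ExpressionMatrix | None,
                  em_replicates: ExpressionMatrix | None, tfs: TFList,
                  seed: int = 0, n_trees: int = 1000,
                  enet_config: ElasticNetConfig | None = None,
                  deconv_config: DeconvolutionConfig | None = None,
                  aracne_eps: float = 0.0) -> RankedNetwork:
    """Run one inference method on the appropriate preprocessed matrix."""
    if method in REPLICATE_LEVEL_METHODS:
        if em_replicates is None:
            raise ValidationError(f"{method} needs the replicate-level matrix")
        mi = estimate_spearman_mi(em_replicates)
        if method == "clr":
            return infer_clr(mi, tfs)
        return infer_aracne(mi, tfs, eps=aracne_eps)
    if em_medians is None:
        raise ValidationError(f"{method} needs the condition-median matrix")
    if method == "ggm":
        return infer_ggm(em_medians, tfs)
    if method == "elasticnet":
        cfg = enet_config or ElasticNetConfig(seed=seed)
        return infer_elasticnet(em_medians, tfs, cfg)
    if method == "genie3":
        return infer_genie3(em_medians, tfs, n_trees=n_trees, seed=seed)
    if method in ("deconvolution", "silencing"):
        g = pearson_correlation(em_medians)
        if method == "deconvolution":
            return deconvolve(g, tfs, deconv_config)
        return silence(g, tfs)
    raise ValidationError(f"unknown method {method!r}; choose from {METHODS}")


__all__ = [
    "METHODS", "CONSENSUS_METHODS", "REPLICATE_LEVEL_METHODS",
    "infer_network", "infer_ggm", "infer_clr", "infer_aracne",
    "infer_elasticnet", "infer_genie3", "deconvolve", "silence",
    "estimate_spearman_mi", "dpi_prune", "shrunk_partial_correlations",
    "deconvolve_matrix", "silence_matrix", "pearson_correlation",
    "total_possible_edges", "ElasticNetConfig", "DeconvolutionConfig",
]
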