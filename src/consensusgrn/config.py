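"""YAML configuration: one section per pipeline stage, merged over defaults.

Every stochastic stage takes an explicit integer seed so that a fixed
config file yields byte-identical edge lists across runs.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "simulate": {
        "n_tfs": 12, "n_genes": 60, "min_regulators": 1, "max_regulators": 3,
        "n_conditions": 40, "replicates": 3, "noise_sd": 0.25,
        "nb_dispersion": 0.05, "knockout_tfs": [],
        "gold_n_pos": 20, "gold_n_neg": 20,
    },
    "preprocess": {"cpm_threshold": 1.0, "min_samples": 9},
    "infer": {"n_trees": 1000, "aracne_eps": 0.0},
    "consensus": {"density": 0.1, "methods": ["ggm", "clr", "elasticnet",
                                              "genie3", "deconvolution"]},
    "context": {"alpha": 0.05, "min_cpm": 1.0, "min_samples": 4,
                "tests": ["moderated_t", "nb_wald"]},
    "score": {"k": 10, "n_iter": 10000},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path=None) -> dict:
    if path is None:
        return copy.deepcopy(DEFAULTS)
    user = yaml.safe_load(Path(path).read_text()) or {}
    return _merge(DEFAULTS, user)


def dump_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
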