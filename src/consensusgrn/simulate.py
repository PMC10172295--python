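"""Synthetic expression compendia with planted regulatory structure.

The generator emulates the statistical shape of a multi-condition RNAseq
compendium: a two-layer ground-truth GRN (a topologically ordered TF->TF
upper layer plus a TF->target layer), per-(TF, condition) activity shifts
partly driven by condition covariates (light level, acetate, genotype),
a linear-Gaussian latent log-expression layer, and a negative-binomial
observation layer with unequal library sizes.  Knockout genotypes clamp
the knocked-out TF's latent value to its minimum and the clamp propagates
through the linear rules, mimicking an insertional mutant that is still
present in the annotation.

The desk-scale default preset (12 TFs, 60 genes, 40 conditions x 3
replicates = 120 samples) echoes a ~158-sample / ~62-condition compendium
at roughly 1/10 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import (
    CountMatrix,
    GeneSet,
    GoldStandard,
    SampleMetadata,
    TFList,
    ValidationError,
)

LOW_LIGHT = 15.0    # µmol photons m^-2 s^-1
HIGH_LIGHT = 300.0


@dataclass
class SimulationConfig:
    """Knobs of the synthetic compendium; defaults are the desk-scale preset."""

    n_tfs: int = 12
    n_genes: int = 60              # total genes, TFs included
    min_regulators: int = 1        # per-target in-degree drawn uniformly
    max_regulators: int = 3
    tf_tf_edge_prob: float = 0.15  # upper-layer TF->TF wiring density
    positive_sign_prob: float = 0.7
    effect_size_range: tuple = (0.5, 1.5)
    n_conditions: int = 40
    replicates: int = 3
    activity_sd: float = 1.0       # sd of per-(TF, condition) activity (log_e units)
    noise_sd: float = 0.25         # replicate/intrinsic Gaussian noise (log_e units)
    nb_dispersion: float = 0.05    # NB: var = mu + disp * mu^2
    library_size_range: tuple = (5e5, 2e6)
    knockout_tfs: tuple = ()       # TF ids clamped in knockout-genotype conditions
    knockout_condition_fraction: float = 0.2
    light_responsive_fraction: float = 0.5
    acetate_responsive_fraction: float = 0.25
    covariate_effect: float = 1.0
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs < 2:
            raise ValidationError("need n_tfs >= 2")
        if self.n_genes <= self.n_tfs:
            raise ValidationError("n_genes must exceed n_tfs")
        if self.max_regulators > self.n_tfs:
            raise ValidationError(
                f"max_regulators={self.max_regulators} exceeds n_tfs={self.n_tfs}"
            )
        if not (0 < self.min_regulators <= self.max_regulators):
            raise ValidationError("need 0 < min_regulators <= max_regulators")
        for name in ("activity_sd", "noise_sd", "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.n_conditions < 1 or self.replicates < 1:
            raise ValidationError("n_conditions and replicates must be positive")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruthGRN:
    """Planted network: signed, weighted TF->gene edges plus per-(TF,
    condition) activity shifts."""

    tf_ids: tuple
    gene_ids: tuple                # full universe, TFs first
    edges: pd.DataFrame            # regulator, target, sign (+/-1), effect_size
    tf_condition_activity: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        tfs = set(self.tf_ids)
        if len(self.edges):
            if not set(self.edges["regulator"]) <= tfs:
                raise ValidationError("ground-truth regulator outside the TF set")
            if (self.edges["regulator"] == self.edges["target"]).any():
                raise ValidationError("ground-truth self-edge")
            if (self.edges["effect_size"] <= 0).any():
                raise ValidationError("effect sizes must be > 0")
            tf_pos = {t: i for i, t in enumerate(self.tf_ids)}
            upper = self.edges[self.edges["target"].isin(tfs)]
            for reg, tgt in zip(upper["regulator"], upper["target"]):
                if tf_pos[reg] >= tf_pos[tgt]:
                    raise ValidationError("TF->TF edge violates topological order")

    @property
    def target_ids(self) -> tuple:
        return tuple(g for g in self.gene_ids if g not in set(self.tf_ids))

    def edge_set(self) -> set:
        return set(zip(self.edges["regulator"], self.edges["target"]))


def sample_grn(config: SimulationConfig) -> GroundTruthGRN:
    """Draw a planted GRN: each non-TF gene gets Uniform{min..max} regulators;
    TF->TF edges only from earlier to later TFs in a fixed topological order."""
    rng = np.random.default_rng(config.seed)
    tf_ids = tuple(f"TF{i+1:03d}" for i in range(config.n_tfs))
    target_ids = tuple(f"g{i+1:04d}" for i in range(config.n_genes - config.n_tfs))
    gene_ids = tf_ids + target_ids

    rows = []
    # topologically ordered TF->TF layer
    for i, reg in enumerate(tf_ids):
        for tgt in tf_ids[i + 1:]:
            if rng.random() < config.tf_tf_edge_prob:
                rows.append((reg, tgt))
    # TF->target layer
    for tgt in target_ids:
        k = int(rng.integers(config.min_regulators, config.max_regulators + 1))
        regs = rng.choice(config.n_tfs, size=k, replace=False)
        rows.extend((tf_ids[j], tgt) for j in sorted(regs))

    edges = pd.DataFrame(rows, columns=["regulator", "target"])
    edges["sign"] = np.where(rng.random(len(edges)) < config.positive_sign_prob, 1, -1)
    lo, hi = config.effect_size_range
    edges["effect_size"] = rng.uniform(lo, hi, size=len(edges))

    activity = _sample_activity(tf_ids, config, rng)
    return GroundTruthGRN(tf_ids=tf_ids, gene_ids=gene_ids, edges=edges,
                          tf_condition_activity=activity)


def _condition_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Condition covariates: light level, acetate, genotype, dataset."""
    conds = [f"cond{c+1:03d}" for c in range(config.n_conditions)]
    light = rng.choice([LOW_LIGHT, HIGH_LIGHT], size=config.n_conditions)
    acetate = rng.random(config.n_conditions) < 0.5
    genotype = np.array(["WT"] * config.n_conditions, dtype=object)
    if config.knockout_tfs:
        n_ko = max(1, int(round(config.knockout_condition_fraction * config.n_conditions)))
        ko_conds = rng.choice(config.n_conditions, size=n_ko, replace=False)
        for i, c in enumerate(ko_conds):
            tf = config.knockout_tfs[i % len(config.knockout_tfs)]
            genotype[c] = f"{tf}-ko"
    dataset = np.where(np.arange(config.n_conditions) % 2 == 0, "dsetA", "dsetB")
    return pd.DataFrame({
        "condition_id": conds, "light_level": light,
        "acetate": acetate, "genotype": genotype, "dataset": dataset,
    }).set_index("condition_id")


def _sample_activity(tf_ids, config: SimulationConfig,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Per-(TF, condition) latent activity: i.i.d. Gaussian shifts plus
    covariate-driven components for light-/acetate-responsive TFs."""
    cond = _condition_table(config, rng)
    base = rng.normal(0.0, config.activity_sd, size=(len(tf_ids), len(cond)))
    light_resp = rng.random(len(tf_ids)) < config.light_responsive_fraction
    acet_resp = rng.random(len(tf_ids)) < config.acetate_responsive_fraction
    light_sign = rng.choice([-1.0, 1.0], size=len(tf_ids))
    acet_sign = rng.choice([-1.0, 1.0], size=len(tf_ids))
    high = (cond["light_level"].to_numpy() == HIGH_LIGHT).astype(float)
    acet = cond["acetate"].to_numpy().astype(float)
    act = (base
           + np.outer(light_resp * light_sign * config.covariate_effect, high)
           + np.outer(acet_resp * acet_sign * config.covariate_effect, acet))
    tbl = pd.DataFrame(act, index=list(tf_ids), columns=cond.index)
    tbl.attrs["conditions"] = cond
    return tbl


def latent_expression(grn: GroundTruthGRN, config: SimulationConfig,
                      rng: np.random.Generator
                      ) -> tuple[pd.DataFrame, SampleMetadata]:
    """Latent log-expression per sample, propagating the linear rules in
    topological order and applying knockout clamps before propagation."""
    cond_tbl: pd.DataFrame = grn.tf_condition_activity.attrs["conditions"]
    conds = list(cond_tbl.index)
    sample_rows, sample_ids = [], []
    for cond in conds:
        for r in range(1, config.replicates + 1):
            sid = f"{cond}_r{r}"
            sample_ids.append(sid)
            sample_rows.append({
                "sample_id": sid, "condition_id": cond, "replicate_index": r,
                **cond_tbl.loc[cond].to_dict(),
            })
    meta = SampleMetadata(pd.DataFrame(sample_rows))

    n_samples = len(sample_ids)
    latent = pd.DataFrame(0.0, index=list(grn.gene_ids), columns=sample_ids)
    cond_of = [row["condition_id"] for row in sample_rows]
    genotype = np.array([row["genotype"] for row in sample_rows], dtype=object)

    act = grn.tf_condition_activity
    clamp_value = float(act.to_numpy().min()) - 2.0 * config.activity_sd

    by_target = {t: sub for t, sub in grn.edges.groupby("target")}
    # TFs in topological order, then targets: parents are final when used
    for gene in grn.tf_ids + grn.target_ids:
        noise = rng.normal(0.0, config.noise_sd, size=n_samples)
        if gene in set(grn.tf_ids):
            vals = act.loc[gene, cond_of].to_numpy() + noise
        else:
            vals = noise
        sub = by_target.get(gene)
        if sub is not None:
            for reg, sign, eff in zip(sub["regulator"], sub["sign"], sub["effect_size"]):
                vals = vals + sign * eff * latent.loc[reg].to_numpy()
        if gene in set(grn.tf_ids):
            ko = genotype == f"{gene}-ko"
            if ko.any():
                vals = np.where(ko, clamp_value, vals)
        latent.loc[gene] = vals
    return latent, meta


def simulate_compendium(grn: GroundTruthGRN, config: SimulationConfig
                        ) -> tuple[CountMatrix, SampleMetadata]:
    """Observe the latent layer as NB counts with unequal library sizes.

    Per-sample transcript proportions are softmax(baseline + latent); the
    NB mean is proportion * library size and var = mu + dispersion * mu^2
    (gamma-Poisson mixture).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    latent, meta = latent_expression(grn, config, rng)
    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd,
                          size=len(grn.gene_ids))
    raw = np.exp(baseline[:, None] + latent.to_numpy())
    props = raw / raw.sum(axis=0, keepdims=True)
    lib = rng.uniform(*config.library_size_range, size=props.shape[1])
    mu = props * lib
    shape = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape, mu * config.nb_dispersion)
    counts = rng.poisson(lam)
    # a pathological all-zero library would break downstream invariants
    zero = counts.sum(axis=0) == 0
    counts[0, zero] = 1
    cm = CountMatrix(pd.DataFrame(counts.astype(np.int64),
                                  index=list(grn.gene_ids),
                                  columns=latent.columns))
    return cm, meta


def emit_gold_standard(grn: GroundTruthGRN, n_pos: int, n_neg: int,
                       seed: int = 0) -> GoldStandard:
    """Sample a curated-style gold standard: positives from true edges,
    negatives from TF->gene pairs absent from the GRN; disjoint by
    construction."""
    rng = np.random.default_rng(seed)
    true_edges = sorted(grn.edge_set())
    if n_pos > len(true_edges):
        raise ValidationError(f"n_pos={n_pos} exceeds the {len(true_edges)} true edges")
    non_edges = sorted(
        (tf, g) for tf in grn.tf_ids for g in grn.gene_ids
        if g != tf and (tf, g) not in grn.edge_set()
    )
    if n_neg > len(non_edges):
        raise ValidationError(f"n_neg={n_neg} exceeds the {len(non_edges)} non-edges")
    pos_idx = rng.choice(len(true_edges), size=n_pos, replace=False)
    neg_idx = rng.choice(len(non_edges), size=n_neg, replace=False)
    rows = [(true_edges[i][0], true_edges[i][1], "positive", "planted edge")
            for i in sorted(pos_idx)]
    rows += [(non_edges[i][0], non_edges[i][1], "negative", "planted non-edge")
             for i in sorted(neg_idx)]
    return GoldStandard(pd.DataFrame(rows, columns=["regulator", "target",
                                                    "label", "source"]))


def tf_list_of(grn: GroundTruthGRN) -> TFList:
    return TFList(tuple(grn.tf_ids))


def planted_target_set(grn: GroundTruthGRN, tf: str, name: str = "planted"
                       ) -> GeneSet:
    """The true target set of one TF (handy for regulator-recovery checks)."""
    members = frozenset(grn.edges.loc[grn.edges["regulator"] == tf, "target"])
    return GeneSet(name=name, members=members)
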