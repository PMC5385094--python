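"""Synthetic tumor cohorts with planted lncRNA-cluster structure.

The generator emulates the statistical structure a bulk RNA-seq cohort must
have for the downstream analysis to be meaningful: a set of tumor samples
partitioned into latent clusters, per-cluster overexpressed marker lncRNAs,
protein-coding genes (PCGs) directly or inversely co-expressed with those
markers, a block of normal-tissue samples with no cluster signal, and
cluster-linked clinical covariates, age and survival.

Expression is generated on the log2(RPKM + 1) scale: every gene has a
Gaussian baseline mean, marker genes gain a fixed mean shift inside their
cluster (sign-flipped for inversely co-expressed PCGs), and i.i.d. Gaussian
noise is added before mapping back to RPKM via max(0, 2^x - 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    write_clinical,
    write_expression,
)
from .errors import ConfigError

_PROB_TOL = 1e-9


def _default_covariates() -> dict:
    """Cluster-linked categorical covariates for the 5-cluster preset.

    Probabilities follow the qualitative pattern of HPV-driven head-and-neck
    cohorts: one cluster dominated by HPV-positive tumors depleted of TP53
    mutations, two smoking-heavy laryngeal clusters enriched in TP53/NSD1 or
    KMT2D mutations, and grade/site distributions skewed accordingly.
    """
    return {
        "hpv": {
            "positive": (0.05, 0.05, 0.08, 0.08, 0.85),
            "negative": (0.95, 0.95, 0.92, 0.92, 0.15),
        },
        "TP53_mut": {
            "mut": (0.80, 0.75, 0.50, 0.50, 0.05),
            "wt": (0.20, 0.25, 0.50, 0.50, 0.95),
        },
        "NSD1_mut": {
            "mut": (0.35, 0.10, 0.10, 0.08, 0.05),
            "wt": (0.65, 0.90, 0.90, 0.92, 0.95),
        },
        "KMT2D_mut": {
            "mut": (0.15, 0.35, 0.15, 0.05, 0.10),
            "wt": (0.85, 0.65, 0.85, 0.95, 0.90),
        },
        "smoking": {
            "smoker": (0.85, 0.85, 0.65, 0.60, 0.45),
            "never": (0.15, 0.15, 0.35, 0.40, 0.55),
        },
        "grade": {
            "G1": (0.10, 0.10, 0.15, 0.30, 0.02),
            "G2": (0.45, 0.45, 0.45, 0.50, 0.18),
            "G3": (0.40, 0.40, 0.35, 0.18, 0.65),
            "G4": (0.05, 0.05, 0.05, 0.02, 0.15),
        },
        "site": {
            "larynx": (0.55, 0.50, 0.20, 0.10, 0.05),
            "tongue": (0.15, 0.20, 0.35, 0.60, 0.10),
            "tonsil": (0.05, 0.05, 0.15, 0.10, 0.70),
            "other": (0.25, 0.25, 0.30, 0.20, 0.15),
        },
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults define the reduced default preset used throughout testing:
    200 tumors in 5 clusters, 500 lncRNAs (40 markers per cluster),
    600 PCGs (30 up / 20 down per cluster), marker shift 2.0 on the log2
    scale against noise sd 0.5, and 20 normal samples.  Hazards are per
    month with a 4-fold spread between the worst and best clusters.
    """

    n_tumors: int = 200
    n_normals: int = 20
    cluster_sizes: tuple[int, ...] = (55, 50, 35, 35, 25)
    n_lnc: int = 500
    n_pcg: int = 600
    markers_per_cluster: int = 40
    pcg_up_per_cluster: int = 30
    pcg_down_per_cluster: int = 20
    marker_shift: float = 2.0
    noise_sd: float = 0.5
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 1.0
    covariate_spec: dict = field(default_factory=_default_covariates)
    age_spec: tuple[tuple[float, float], ...] = (
        (58.2, 9.0), (65.0, 9.0), (61.0, 9.0), (61.0, 9.0), (61.0, 9.0)
    )
    hazard_per_cluster: tuple[float, ...] = (0.030, 0.030, 0.020, 0.020, 0.0075)
    censor_rate: float = 0.3
    seed: int = 0

    # -- presets ----------------------------------------------------------
    @classmethod
    def full_scale(cls, seed: int = 0) -> "SimulationConfig":
        """Full-cohort preset: 426 tumors in 5 clusters."""
        return cls(
            n_tumors=426,
            cluster_sizes=(134, 126, 71, 66, 29),
            n_normals=40,
            seed=seed,
        )

    @classmethod
    def tiny(cls, seed: int = 0) -> "SimulationConfig":
        """Small 3-cluster preset for smoke tests: 60 tumors."""
        k = 3
        return cls(
            n_tumors=60,
            n_normals=10,
            cluster_sizes=(25, 20, 15),
            n_lnc=200,
            n_pcg=300,
            markers_per_cluster=20,
            pcg_up_per_cluster=15,
            pcg_down_per_cluster=10,
            covariate_spec={
                name: {cat: probs[:k] for cat, probs in cats.items()}
                for name, cats in _default_covariates().items()
            },
            age_spec=((58.2, 9.0), (65.0, 9.0), (61.0, 9.0)),
            hazard_per_cluster=(0.030, 0.020, 0.0075),
            seed=seed,
        )

    # -- validation -------------------------------------------------------
    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    def validate(self) -> None:
        k = self.n_clusters
        if k < 1 or any(s <= 0 for s in self.cluster_sizes):
            raise ConfigError("cluster_sizes must be positive")
        if sum(self.cluster_sizes) != self.n_tumors:
            raise ConfigError(
                f"cluster_sizes sum {sum(self.cluster_sizes)} != n_tumors {self.n_tumors}"
            )
        if self.n_normals < 0:
            raise ConfigError("n_normals must be >= 0")
        if self.markers_per_cluster * k > self.n_lnc:
            raise ConfigError("marker count exceeds lncRNA gene count")
        if (self.pcg_up_per_cluster + self.pcg_down_per_cluster) * k > self.n_pcg:
            raise ConfigError("planted PCG count exceeds PCG gene count")
        if self.noise_sd <= 0 or self.baseline_log_sd <= 0:
            raise ConfigError("all sds must be > 0")
        if self.marker_shift < 0:
            raise ConfigError("marker_shift must be >= 0")
        if not 0 <= self.censor_rate < 1:
            raise ConfigError("censor_rate must be in [0, 1)")
        if len(self.age_spec) != k or len(self.hazard_per_cluster) != k:
            raise ConfigError("age_spec/hazard_per_cluster must have one entry per cluster")
        if any(h <= 0 for h in self.hazard_per_cluster):
            raise ConfigError("hazards must be > 0")
        for name, cats in self.covariate_spec.items():
            probs = np.array([list(p) for p in cats.values()], dtype=float)
            if probs.shape[1] != k:
                raise ConfigError(f"covariate {name!r}: need one probability per cluster")
            sums = probs.sum(axis=0)
            if np.any(np.abs(sums - 1.0) > _PROB_TOL):
                raise ConfigError(
                    f"covariate {name!r}: per-cluster probabilities sum to {sums}, not 1"
                )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth used to plant it."""

    expression: ExpressionMatrix
    truth_labels: pd.Series            # tumor sample -> cluster in 1..k
    truth_markers: dict                # cluster -> {lnc, pcg_up, pcg_down}
    clinical: ClinicalTable
    config: SimulationConfig


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible sub-streams keyed by component
    return np.random.default_rng([int(config.seed), stream])


def _gene_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    lnc = [f"LNC{i:05d}" for i in range(config.n_lnc)]
    pcg = [f"PCG{i:05d}" for i in range(config.n_pcg)]
    return lnc, pcg


def planted_markers(config: SimulationConfig) -> dict[int, dict[str, list[str]]]:
    """Deterministic assignment of planted marker genes to clusters.

    Clusters receive disjoint, contiguous blocks of gene ids so cluster
    centroids sit at (approximately) equal pairwise distances.
    """
    lnc, pcg = _gene_ids(config)
    out: dict[int, dict[str, list[str]]] = {}
    m, up, dn = (config.markers_per_cluster, config.pcg_up_per_cluster,
                 config.pcg_down_per_cluster)
    for c in range(config.n_clusters):
        out[c + 1] = {
            "lnc": lnc[c * m: (c + 1) * m],
            "pcg_up": pcg[c * (up + dn): c * (up + dn) + up],
            "pcg_down": pcg[c * (up + dn) + up: (c + 1) * (up + dn)],
        }
    return out


def simulate_labels(config: SimulationConfig) -> pd.Series:
    """Truth cluster labels 1..k for the tumor samples."""
    config.validate()
    ids = [f"TUM{i:04d}" for i in range(config.n_tumors)]
    labels = np.repeat(np.arange(1, config.n_clusters + 1), config.cluster_sizes)
    return pd.Series(labels, index=pd.Index(ids, name="sample_id"), name="cluster")


def simulate_expression(config: SimulationConfig,
                        labels: pd.Series) -> ExpressionMatrix:
    """Expression matrix for tumors + normals under the planted model.

    value(g, s) = max(0, 2^x - 1) with x ~ Normal(mu_g + shift(g, s),
    noise_sd); shift is +marker_shift for a gene in its own cluster's
    marker or up-PCG list, -marker_shift for its down-PCG list, and 0
    elsewhere (normals never shift).
    """
    config.validate()
    counts = labels.value_counts()
    expected = pd.Series(config.cluster_sizes,
                         index=range(1, config.n_clusters + 1))
    if not counts.sort_index().equals(expected.astype(counts.dtype)):
        raise ConfigError("labels inconsistent with config.cluster_sizes")

    lnc, pcg = _gene_ids(config)
    genes = lnc + pcg
    normal_ids = [f"NRM{i:04d}" for i in range(config.n_normals)]
    samples = list(labels.index) + normal_ids
    n_genes, n_samples = len(genes), len(samples)

    rng = _rng(config, 0)
    mu = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    planted_by_cluster = planted_markers(config)
    # inversely co-expressed genes must be expressed to be repressed: give
    # them an elevated baseline so the in-cluster drop is not floored at 0
    for planted in planted_by_cluster.values():
        for g in planted["pcg_down"]:
            mu[gene_pos[g]] += config.marker_shift
    x = mu[:, None] + rng.normal(0.0, config.noise_sd, size=(n_genes, n_samples))

    col_of = {s: j for j, s in enumerate(labels.index)}
    for cluster, planted in planted_by_cluster.items():
        cols = [col_of[s] for s in labels.index[labels == cluster]]
        for g in planted["lnc"] + planted["pcg_up"]:
            x[gene_pos[g], cols] += config.marker_shift
        for g in planted["pcg_down"]:
            x[gene_pos[g], cols] -= config.marker_shift

    values = np.maximum(0.0, np.exp2(x) - 1.0)
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                         columns=samples)
    gene_class = pd.Series(["lncRNA"] * len(lnc) + ["PCG"] * len(pcg),
                           index=frame.index)
    role = pd.Series(["tumor"] * len(labels) + ["normal"] * len(normal_ids),
                     index=frame.columns)
    return ExpressionMatrix(frame, gene_class, role)


def _simulate_covariates(config: SimulationConfig, labels: pd.Series,
                         rng: np.random.Generator) -> pd.DataFrame:
    out = pd.DataFrame(index=labels.index)
    for name, cats in config.covariate_spec.items():
        categories = list(cats)
        probs = np.array([list(cats[c]) for c in categories], dtype=float)
        values = []
        for s in labels.index:
            p = probs[:, labels[s] - 1]
            values.append(categories[rng.choice(len(categories), p=p / p.sum())])
        out[name] = values
    return out


def _simulate_survival(config: SimulationConfig, labels: pd.Series,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Exponential event times per cluster with independent exponential
    censoring tuned so the marginal censoring probability is censor_rate."""
    out = pd.DataFrame(index=labels.index)
    hazards = np.array([config.hazard_per_cluster[c - 1] for c in labels])
    for endpoint in ("os", "recurrence"):
        t_event = rng.exponential(1.0 / hazards)
        if config.censor_rate > 0:
            c_rate = hazards * config.censor_rate / (1.0 - config.censor_rate)
            t_cens = rng.exponential(1.0 / c_rate)
        else:
            t_cens = np.full_like(t_event, np.inf)
        observed = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        out[f"{endpoint}_time"] = observed
        out[f"{endpoint}_event"] = event
    return out


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Full cohort: expression, truth labels/markers and clinical table."""
    config.validate()
    labels = simulate_labels(config)
    expression = simulate_expression(config, labels)

    cov = _simulate_covariates(config, labels, _rng(config, 1))
    rng_age = _rng(config, 2)
    mean = np.array([config.age_spec[c - 1][0] for c in labels])
    sd = np.array([config.age_spec[c - 1][1] for c in labels])
    cov["age"] = rng_age.normal(mean, sd)
    surv = _simulate_survival(config, labels, _rng(config, 3))

    data = pd.concat([cov, surv], axis=1)
    schema = {name: "categorical" for name in config.covariate_spec}
    schema["age"] = "continuous"
    for endpoint in ("os", "recurrence"):
        schema[f"{endpoint}_time"] = "time"
        schema[f"{endpoint}_event"] = "event"
    clinical = ClinicalTable(data, schema)
    return SyntheticCohort(expression, labels, planted_markers(config),
                           clinical, config)


def make_truth_gene_sets(cohort: SyntheticCohort, n_decoys: int = 15,
                         decoy_size: int = 25,
                         seed: int | None = None) -> GeneSetCollection:
    """Gene sets for enrichment testing: the planted per-cluster PCG lists
    plus random decoy sets drawn from the PCG universe."""
    config = cohort.config
    rng = np.random.default_rng(
        [int(config.seed if seed is None else seed), 4])
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    for cluster, planted in cohort.truth_markers.items():
        for direction in ("pcg_up", "pcg_down"):
            name = f"c{cluster}_{direction}_true"
            sets[name] = list(planted[direction])
            desc[name] = f"planted {direction} PCGs of cluster {cluster}"
    universe = [g for g in cohort.expression.gene_ids
                if cohort.expression.gene_class[g] == "PCG"]
    for d in range(n_decoys):
        name = f"decoy{d:02d}"
        sets[name] = sorted(rng.choice(universe, size=decoy_size, replace=False))
        desc[name] = "random decoy set"
    return GeneSetCollection(sets, desc)


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, str]:
    """Write expression TSV, clinical TSV and truth JSON; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": str(out / "expression.tsv"),
        "clinical": str(out / "clinical.tsv"),
        "truth": str(out / "truth.json"),
    }
    write_expression(cohort.expression, paths["expression"])
    write_clinical(cohort.clinical, paths["clinical"])
    truth = {
        "labels": {s: int(c) for s, c in cohort.truth_labels.items()},
        "markers": {str(c): m for c, m in cohort.truth_markers.items()},
        "config": cohort.config.to_dict(),
    }
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1)
    return paths
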