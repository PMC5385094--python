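"""End-to-end orchestration: simulate -> select -> cluster -> associate ->
GBA -> enrich -> survive, from a single seeded configuration.

Every stage writes its outputs as TSV under one output directory and the
run closes with a JSON manifest recording the configuration snapshot, the
seed, per-file SHA-256 digests, the selected k, per-stage row counts and
accumulated warnings.  All randomness flows from the one seed in the
configuration, so a rerun with the same config reproduces every output
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .association_stats import cluster_feature_association, welch_t
from .consensus_clustering import ConsensusParams, consensus_cluster
from .data_io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    read_clinical,
    read_expression,
    read_gmt,
    write_expression,
)
from .enrichment import enrich_all_clusters
from .errors import ConfigError, InputError
from .feature_selection import FeatureSelectionParams, select_features
from .gba import GbaThresholds, run_gba
from .survival_analysis import censor_at, km_by_group, logrank_test
from .synthetic_data import (
    SimulationConfig,
    make_truth_gene_sets,
    simulate_cohort,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    selection: FeatureSelectionParams = field(
        default_factory=lambda: FeatureSelectionParams(top_k=300))
    consensus: ConsensusParams = field(
        default_factory=lambda: ConsensusParams(n_resamples=250))
    gba: GbaThresholds = field(default_factory=GbaThresholds)
    enrichment_alpha: float = 0.05
    survival_horizon: float = 60.0
    endpoints: tuple[str, ...] = ("os", "recurrence")
    n_decoy_sets: int = 15
    seed: int = 0
    # optional real-data inputs; when unset, a cohort is simulated
    expression_path: str | None = None
    clinical_path: str | None = None
    gmt_path: str | None = None
    clinical_schema: dict | None = None

    def __post_init__(self) -> None:
        # one seed drives every stage
        self.simulation.seed = self.seed
        self.consensus.seed = self.seed

    @classmethod
    def tiny(cls, seed: int = 0) -> "PipelineConfig":
        """Smoke-test preset: 60 samples, 3 clusters, 100 resamples."""
        cfg = cls(
            simulation=SimulationConfig.tiny(seed=seed),
            selection=FeatureSelectionParams(top_k=120),
            consensus=ConsensusParams(k_min=2, k_max=4, n_resamples=100,
                                      seed=seed),
            seed=seed,
        )
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "simulation" in raw:
            sim = dict(raw["simulation"])
            for key in ("cluster_sizes", "hazard_per_cluster"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "age_spec" in sim:
                sim["age_spec"] = tuple(tuple(x) for x in sim["age_spec"])
            kwargs["simulation"] = SimulationConfig(**sim)
        if "selection" in raw:
            kwargs["selection"] = FeatureSelectionParams(**raw["selection"])
        if "consensus" in raw:
            kwargs["consensus"] = ConsensusParams(**raw["consensus"])
        if "gba" in raw:
            kwargs["gba"] = GbaThresholds(**raw["gba"])
        for key in ("enrichment_alpha", "survival_horizon", "n_decoy_sets",
                    "seed", "expression_path", "clinical_path", "gmt_path",
                    "clinical_schema"):
            if key in raw:
                kwargs[key] = raw[key]
        if "endpoints" in raw:
            kwargs["endpoints"] = tuple(raw["endpoints"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return {
            "simulation": asdict(self.simulation),
            "selection": asdict(self.selection),
            "consensus": asdict(self.consensus),
            "gba": asdict(self.gba),
            "enrichment_alpha": self.enrichment_alpha,
            "survival_horizon": self.survival_horizon,
            "endpoints": list(self.endpoints),
            "n_decoy_sets": self.n_decoy_sets,
            "seed": self.seed,
            "expression_path": self.expression_path,
            "clinical_path": self.clinical_path,
            "gmt_path": self.gmt_path,
        }


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    selected_k: int
    outputs: dict[str, str]        # relative path -> sha256
    counts: dict[str, int]
    warnings: list[str]

    def to_json(self) -> str:
        from dataclasses import asdict
        return json.dumps(asdict(self), indent=1, sort_keys=True, default=str)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, index_label=None) -> None:
    frame.to_csv(path, sep="\t", float_format="%.6g", na_rep="NA",
                 index_label=index_label, encoding="utf-8")


def compare_partitions(a: pd.Series, b: pd.Series) -> float:
    """Adjusted Rand index between two cluster assignments (1 iff identical
    up to relabeling)."""
    a, b = pd.Series(a), pd.Series(b)
    if not a.index.sort_values().equals(b.index.sort_values()):
        raise InputError("partitions cover different sample sets")
    b = b.loc[a.index]
    return float(adjusted_rand_score(a.to_numpy(), b.to_numpy()))


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------

def _load_inputs(config: PipelineConfig):
    if config.expression_path is None:
        cohort = simulate_cohort(config.simulation)
        sets = make_truth_gene_sets(cohort, n_decoys=config.n_decoy_sets)
        return cohort.expression, cohort.clinical, sets, cohort
    expr = read_expression(config.expression_path)
    if config.clinical_schema is None:
        raise ConfigError("clinical_schema is required with real inputs")
    clinical = read_clinical(config.clinical_path, config.clinical_schema)
    sets = read_gmt(config.gmt_path) if config.gmt_path else None
    return expr, clinical, sets, None


def run_full(config: PipelineConfig, out_dir) -> RunManifest:
    """Execute every stage and write outputs + manifest under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    warnings: list[str] = []
    written: list[Path] = []

    def save(frame: pd.DataFrame, name: str, index_label=None) -> None:
        path = out / name
        _write_tsv(frame, path, index_label=index_label)
        written.append(path)

    expr, clinical, gene_sets, cohort = _load_inputs(config)
    missing = expr.select_role("tumor").sample_ids.difference(clinical.sample_ids)
    if len(missing):
        raise InputError(
            f"expression/clinical sample-id mismatch, e.g. {list(missing[:5])}")
    if cohort is not None:
        path = out / "expression.tsv"
        write_expression(expr, path)
        written.append(path)

    # --- feature selection on the lncRNA tumor matrix -------------------
    lnc_tumor = expr.select_class("lncRNA").select_role("tumor")
    selected = select_features(lnc_tumor, config.selection)
    counts["genes_total_lnc"] = lnc_tumor.shape[0]
    counts["genes_selected"] = selected.shape[0]
    save(selected.values, "selected_expression.tsv", index_label="gene_id")

    # --- consensus clustering -------------------------------------------
    result = consensus_cluster(selected.log2(), config.consensus)
    labels = result.final_labels
    counts["n_tumors"] = len(labels)
    pac_table = pd.DataFrame(
        {"k": result.ks, "pac": [result.pac[k] for k in result.ks]})
    save(pac_table.set_index("k"), "pac.tsv", index_label="k")
    cdf_table = pd.concat(
        [result.cdf[k].assign(k=k) for k in result.ks], ignore_index=True)
    save(cdf_table.set_index("k"), "cdf.tsv", index_label="k")
    for k in result.ks:
        m = pd.DataFrame(result.matrices[k], index=labels.index,
                         columns=labels.index)
        save(m, f"consensus_k{k}.tsv", index_label="sample_id")
    save(labels.to_frame(), "labels.tsv", index_label="sample_id")

    # --- clinical association -------------------------------------------
    assoc_frames = []
    for name, kind in clinical.schema.items():
        if kind != "categorical":
            continue
        try:
            assoc = cluster_feature_association(
                labels, clinical.categorical(name))
        except InputError as exc:
            warnings.append(f"association[{name}]: {exc}")
            continue
        assoc_frames.append(assoc.to_frame())
    age_rows = []
    for name, kind in clinical.schema.items():
        if kind != "continuous":
            continue
        values = clinical.continuous(name).loc[labels.index]
        for cluster in sorted(labels.unique()):
            in_c = values[labels == cluster].dropna()
            out_c = values[labels != cluster].dropna()
            if len(in_c) < 2 or len(out_c) < 2:
                continue
            t, df, p = welch_t(in_c, out_c)
            age_rows.append({
                "feature": name, "cluster": cluster,
                "mean_in": in_c.mean(), "mean_out": out_c.mean(),
                "t": t, "df": df, "p_value": p,
            })
    if assoc_frames:
        save(pd.concat(assoc_frames, ignore_index=True).set_index("feature"),
             "associations.tsv", index_label="feature")
        counts["categorical_features"] = len(assoc_frames)
    if age_rows:
        save(pd.DataFrame(age_rows).set_index("feature"),
             "continuous_associations.tsv", index_label="feature")

    # --- GBA -------------------------------------------------------------
    surrogates = run_gba(expr, labels, config.gba)
    for cs in surrogates:
        counts[f"surrogates_c{cs.cluster}"] = len(cs.surrogates)
        save(cs.surrogates, f"surrogates_c{cs.cluster}.tsv",
             index_label="gene_id")
        save(cs.up_pcgs, f"up_pcgs_c{cs.cluster}.tsv", index_label="gene_id")
        save(cs.down_pcgs, f"down_pcgs_c{cs.cluster}.tsv",
             index_label="gene_id")

    # --- enrichment ------------------------------------------------------
    if gene_sets is not None:
        universe = expr.select_class("PCG").gene_ids
        tables = enrich_all_clusters(surrogates, gene_sets, universe,
                                     config.enrichment_alpha)
        for (cluster, direction), frame in tables.items():
            save(frame, f"enrichment_c{cluster}_{direction}.tsv")
    else:
        warnings.append("no gene sets supplied; enrichment skipped")

    # --- survival --------------------------------------------------------
    surv_rows = []
    for endpoint in config.endpoints:
        try:
            times, events = clinical.survival(endpoint)
        except InputError as exc:
            warnings.append(f"survival[{endpoint}]: {exc}")
            continue
        common = times.index.intersection(labels.index)
        t, e = censor_at(times.loc[common], events.loc[common],
                         config.survival_horizon)
        groups = labels.loc[common].to_numpy()
        stat, df, p = logrank_test(t, e, groups)
        surv_rows.append({"endpoint": endpoint, "statistic": stat,
                          "df": df, "p_value": p, "n": len(common)})
        curve_rows = []
        for cluster, curve in km_by_group(t, e, groups).items():
            curve_rows.append(pd.DataFrame({
                "cluster": cluster, "time": curve.times,
                "survival": curve.survival, "at_risk": curve.at_risk,
            }))
        save(pd.concat(curve_rows, ignore_index=True).set_index("cluster"),
             f"km_{endpoint}.tsv", index_label="cluster")
    if surv_rows:
        save(pd.DataFrame(surv_rows).set_index("endpoint"), "survival.tsv",
             index_label="endpoint")

    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.seed,
        version=__version__,
        selected_k=result.selected_k,
        outputs={p.name: _sha256(p) for p in sorted(written)},
        counts=counts,
        warnings=warnings,
    )
    (out / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
    return manifest
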