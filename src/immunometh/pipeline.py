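"""End-to-end pipeline driver: simulate -> select -> cluster -> centroids
-> classify -> score -> pten -> stats, each stage persisting TSV/JSON
artifacts plus a manifest.  Reruns with the same config and seed are
byte-identical except for the manifest timestamp.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import readwrite as rw
from .clustering import ConsensusSettings, build_centroids, classify_cohort, consensus_cluster
from .pten import PtenCpGSet, call_pten_cohort, integrate_pten_events, pten_event_summary
from .scoring import dichotomize_score, expression_score, methylation_score
from .selection import SelectionParams, run_selection
from .simulate import SimulationConfig, generate_reference_panel, generate_tumor_cohort, write_simulation
from .stats import association_batch, cox_screen, delta_beta_contrasts, fit_survival, km_logrank

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "select",
    "cluster",
    "centroids",
    "classify",
    "score",
    "pten",
    "stats",
)


@dataclass
class PipelineConfig:
    seed: int = 0
    mode: str = "melanoma"  # switches the stroma-filter fraction default
    k_clusters: int = 3
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    selection: SelectionParams | None = None
    clustering: ConsensusSettings | None = None
    kw_fdr_threshold: float = 1e-4
    classify_threshold: float = 0.3
    endpoint: str = "DSS"

    def __post_init__(self) -> None:
        if self.mode not in ("melanoma", "pancancer"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)
        if self.selection is None:
            self.selection = SelectionParams.for_mode(self.mode, seed=self.seed)
        if self.clustering is None:
            self.clustering = ConsensusSettings(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        sel = raw.pop("selection", None)
        clu = raw.pop("clustering", None)
        cfg = cls(
            simulation=sim,
            selection=SelectionParams(**sel) if sel else None,
            clustering=ConsensusSettings(**clu) if clu else None,
            **raw,
        )
        return cfg


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run all stages on a simulated study; returns the artifact directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "stages": [],
        "parameters": {
            "simulation": dataclasses.asdict(config.simulation),
            "selection": dataclasses.asdict(config.selection),
            "clustering": dataclasses.asdict(config.clustering),
            "k_clusters": config.k_clusters,
            "kw_fdr_threshold": config.kw_fdr_threshold,
            "classify_threshold": config.classify_threshold,
            "endpoint": config.endpoint,
        },
    }
    stage = "simulate"
    try:
        # -- simulate -------------------------------------------------------
        panel = generate_reference_panel(config.simulation)
        cohort = generate_tumor_cohort(config.simulation, panel)
        sim_dir = out / "simulate"
        sim_dir.mkdir(exist_ok=True)
        write_simulation(panel, cohort, sim_dir)
        manifest["stages"].append(stage)

        # -- select ---------------------------------------------------------
        stage = "select"
        pairs, report = run_selection(
            panel.beta,
            panel.sample_types,
            panel.signature_a,
            panel.signature_b,
            panel.annotation,
            config.selection,
        )
        rw.write_table(
            pairs.rename(columns={"probe_id": "cpg"}), out / "selected_pairs.tsv"
        )
        rw.write_json(report, out / "selection_report.json")
        logger.info("selection funnel: %s", report)
        manifest["stages"].append(stage)

        # -- cluster ----------------------------------------------------------
        stage = "cluster"
        immune_beta = cohort.beta.loc[pairs["probe_id"]]
        consensus = consensus_cluster(immune_beta, config.k_clusters, config.clustering)
        rw.write_table(
            consensus.labels.rename_axis("sample_id").reset_index(),
            out / "cluster_labels.tsv",
        )
        manifest["stages"].append(stage)

        # -- centroids --------------------------------------------------------
        stage = "centroids"
        centroids = build_centroids(
            cohort.beta,
            consensus.labels,
            pairs["probe_id"],
            kw_fdr_threshold=config.kw_fdr_threshold,
            classify_threshold=config.classify_threshold,
        )
        med = centroids.medians.copy()
        med.columns = [f"cluster_{c}" for c in med.columns]
        rw.write_beta_matrix(med.rename_axis("cpg"), out / "centroids.tsv")
        manifest["stages"].append(stage)

        # -- classify ---------------------------------------------------------
        stage = "classify"
        assignments = classify_cohort(cohort.beta, centroids)
        rw.write_table(assignments.reset_index(), out / "assignments.tsv")
        manifest["stages"].append(stage)

        # -- score ------------------------------------------------------------
        stage = "score"
        meth_scores = methylation_score(cohort.beta, pairs)
        combined_sig = pairs[["gene", "cell_type"]]
        expr_scores = expression_score(cohort.expression, combined_sig, center=True)
        rw.write_beta_matrix(
            meth_scores.values.rename_axis("sample_id"), out / "methylation_scores.tsv"
        )
        rw.write_beta_matrix(
            expr_scores.values.rename_axis("sample_id"),
            out / "expression_scores.tsv",
            value_range=None,
        )
        manifest["stages"].append(stage)

        # -- pten -------------------------------------------------------------
        stage = "pten"
        cpg_set = PtenCpGSet(
            tuple(cohort.truth.pten_cpgs["all_promoter"]),
            tuple(cohort.truth.pten_cpgs["dhs"]),
        )
        hyperm = call_pten_cohort(cohort.beta, cpg_set)
        status = integrate_pten_events(hyperm, cohort.pten_mutation, cohort.pten_cn)
        rw.write_table(status.reset_index(), out / "pten_status.tsv")
        rw.write_table(
            pten_event_summary(status, consensus.labels).reset_index(),
            out / "pten_cluster_summary.tsv",
        )
        manifest["stages"].append(stage)

        # -- stats ------------------------------------------------------------
        stage = "stats"
        contrasts = delta_beta_contrasts(meth_scores, consensus.labels)
        rw.write_table(contrasts, out / "delta_beta_contrasts.tsv")
        assoc = association_batch(
            consensus.labels,
            cohort.clinical[["til_category", "mitf_status"]],
            seed=config.seed,
        )
        rw.write_table(assoc, out / "associations.tsv")
        cox = fit_survival(
            cohort.clinical, consensus.labels, endpoint=config.endpoint
        )
        rw.write_table(cox, out / "cox_clusters.tsv")
        screen = cox_screen(
            dichotomize_score(meth_scores), cohort.clinical, endpoint=config.endpoint
        )
        rw.write_table(screen.reset_index(), out / "cox_celltype_screen.tsv")
        km = km_logrank(cohort.clinical, consensus.labels)
        rw.write_table(km.at_risk.reset_index(), out / "km_at_risk.tsv")
        rw.write_json(
            {"logrank_p": km.logrank_p, "logrank_stat": km.logrank_stat},
            out / "km_logrank.json",
        )
        manifest["stages"].append(stage)
    except Exception:
        manifest["failed_stage"] = stage
        manifest["timestamp"] = datetime.datetime.now(datetime.UTC).isoformat()
        rw.write_json(manifest, out / "manifest.json")
        logger.exception("pipeline failed at stage %r", stage)
        raise

    manifest["timestamp"] = datetime.datetime.now(datetime.UTC).isoformat()
    rw.write_json(manifest, out / "manifest.json")
    return out
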