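"""End-to-end orchestration: simulate or load, then analyse per group.

A single YAML-style config drives the run: exactly one of an ``input`` block
(expression/clinical/GMT paths) or a ``simulate`` block (cohort generator
settings) must be present. Within each (treatment arm, ER stratum) group the
pipeline filters pathways to the configured size window, computes the
delta-TSC profile, ranks pathway and gene biomarkers, runs the subsampled
leave-one-out classifier, and clusters samples; a summary report and TSV
tables are written with a YAML sidecar carrying the full config, its hash
and every seed, so a rerun of the same config is byte-identical.

Groups too small to classify (fewer than ``2 * draw_size + 1`` samples in
either class) are skipped with a named warning rather than failing the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import biomarkers, classifier, clustering, cohort, formats
from .formats import ER_STATUSES, ARMS

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serializable to YAML."""

    output_dir: str
    input: dict[str, str] | None = None  # expression/clinical/gmt paths
    simulate: dict[str, Any] | None = None  # CohortConfig overrides
    min_set_size: int = 10
    max_set_size: int = 30
    n_draws: int = 100
    draw_size: int = 5
    n_perm: int = 1000
    n_clusters: int = 2
    seed: int = 0
    group_by: tuple[str, ...] = ("arm", "er_status")
    log2_transform: bool = False

    def __post_init__(self) -> None:
        if (self.input is None) == (self.simulate is None):
            raise ValueError("config must carry exactly one of input/simulate")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        if "group_by" in raw:
            raw["group_by"] = tuple(raw["group_by"])
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _load_inputs(config: RunConfig):
    if config.simulate is not None:
        sim = dict(config.simulate)
        sim.setdefault("seed", config.seed)
        if "pathway_size_range" in sim:
            sim["pathway_size_range"] = tuple(sim["pathway_size_range"])
        cfg = cohort.CohortConfig(**sim)
        expr, labels, sets, truth = cohort.generate_cohort(cfg)
        return expr, labels, sets, truth
    paths = config.input
    expr = formats.read_expression(
        paths["expression"], dialect=paths.get("dialect", "tsv")
    )
    labels = formats.read_response_table(
        paths["clinical"], dialect=paths.get("dialect", "tsv")
    )
    sets = formats.read_gmt(paths["gene_sets"])
    return expr, labels, sets, None


def _write_sidecar(path: Path, config: RunConfig, extra: dict[str, Any]) -> None:
    payload = {"config": asdict(config), "config_hash": config.hash(), **extra}
    with open(path, "w") as handle:
        yaml.safe_dump(payload, handle, sort_keys=True)


def _biomarker_frame(results: list[biomarkers.BiomarkerResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [r.feature_name for r in results],
            "cindex": [r.cindex for r in results],
            "perm_frac": [r.perm_significance for r in results],
            "bh_adjusted": [r.bh_adjusted for r in results],
            "n_samples": [r.n_samples for r in results],
            "group": ["|".join(r.group) if r.group else "all" for r in results],
        }
    )


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full analysis; returns the run report (also written to
    ``output_dir/report.yaml`` alongside the stage TSVs)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, labels, sets, truth = _load_inputs(config)
    if config.log2_transform:
        expr = formats.log2p1(expr)
    filtered = formats.filter_sets_by_size(
        sets, config.min_set_size, config.max_set_size, expr
    )
    report: dict[str, Any] = {
        "config_hash": config.hash(),
        "n_samples": expr.n_samples,
        "n_genes": expr.n_genes,
        "n_gene_sets": len(sets),
        "n_gene_sets_after_filter": len(filtered),
        "groups": {},
        "warnings": [],
    }
    if truth is not None:
        report["simulation"] = {
            "signal_pathways": list(truth.signal_pathway_names),
            "calibration_fraction_r_gt_0.9": truth.calibration_fraction_r_gt_0_9,
            "calibration_met": truth.calibration_met,
        }

    groups = (
        [(a, e) for a in ARMS for e in ER_STATUSES]
        if config.group_by == ("arm", "er_status")
        else [None]
    )
    min_class = 2 * config.draw_size + 1
    for group in groups:
        key = "|".join(group) if group else "all"
        glabels = labels.group(*group) if group else labels
        n_resp = int(glabels.response.sum())
        n_non = len(glabels) - n_resp
        if min(n_resp, n_non) < min_class or len(filtered) == 0:
            msg = (
                f"group {key}: skipped "
                f"({n_resp} responders / {n_non} non-responders; "
                f"need >= {min_class} per class)"
            )
            logger.warning(msg)
            report["warnings"].append(msg)
            continue
        gexpr = expr.subset_samples(list(glabels.sample_ids))

        profile = classifier.delta_tsc_profile(gexpr, glabels, filtered)
        path_bio = biomarkers.pathway_biomarkers(
            profile, glabels, group, n_perm=config.n_perm, seed=config.seed
        )
        gene_bio = biomarkers.univariate_gene_biomarkers(
            gexpr, glabels, group, n_perm=config.n_perm, seed=config.seed
        )
        preds = classifier.loocv_predict(
            gexpr,
            glabels,
            filtered,
            n_draws=config.n_draws,
            draw_size=config.draw_size,
            seed=config.seed,
        )
        sim = clustering.spearman_similarity(gexpr)
        assignment, newick = clustering.ward_cluster(sim, k=config.n_clusters)
        ari = clustering.cluster_label_concordance(assignment, glabels)

        accuracy = float(
            np.mean([p.predicted == glabels.label_of(p.sample_id) for p in preds])
        )
        tag = key.replace("|", "_").replace("+", "pos").replace("-", "neg")
        _biomarker_frame(path_bio).to_csv(
            out / f"pathway_biomarkers_{tag}.tsv", sep="\t", index=False
        )
        _biomarker_frame(gene_bio).to_csv(
            out / f"gene_biomarkers_{tag}.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            {
                "sample_id": [p.sample_id for p in preds],
                "predicted": [p.predicted for p in preds],
                "votes_responder": [p.votes_responder for p in preds],
                "votes_total": [p.votes_total for p in preds],
                "vote_fraction": [p.vote_fraction for p in preds],
                "true_response": [glabels.label_of(p.sample_id) for p in preds],
            }
        ).to_csv(out / f"loocv_{tag}.tsv", sep="\t", index=False)
        (out / f"dendrogram_{tag}.nwk").write_text(newick + "\n")

        report["groups"][key] = {
            "n_samples": len(glabels),
            "n_responders": n_resp,
            "loocv_accuracy": accuracy,
            "top_pathway": path_bio[0].feature_name if path_bio else None,
            "top_pathway_cindex": path_bio[0].cindex if path_bio else None,
            "top_gene": gene_bio[0].feature_name if gene_bio else None,
            "top_gene_cindex": gene_bio[0].cindex if gene_bio else None,
            "cluster_label_ari": ari,
        }

    _write_sidecar(out / "report.yaml", config, {"report": report})
    return report
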