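"""End-to-end orchestration: filter -> DE/ORA -> dimred -> variability ->
stratify -> transfer, from a single YAML/JSON config, with a JSON manifest
recording every stage's inputs, outputs and parameters.

Given the same config and seed, every output table is byte-identical across
runs; the manifest additionally records wall times, which naturally differ.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import diffexp, dimred, enrichment, io, preprocess, stratify, variability
from .datatypes import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_CONTRASTS = [
    {"name": "static_control_vs_pah",
     "setA": {"group": "control", "condition": "Static"},
     "setB": {"group": "PAH", "condition": "Static"}},
    {"name": "lss_control_vs_pah",
     "setA": {"group": "control", "condition": "LSS"},
     "setB": {"group": "PAH", "condition": "LSS"}},
    {"name": "hss_control_vs_pah",
     "setA": {"group": "control", "condition": "HSS"},
     "setB": {"group": "PAH", "condition": "HSS"}},
    {"name": "control_lss_vs_static",
     "setA": {"group": "control", "condition": "Static"},
     "setB": {"group": "control", "condition": "LSS"}},
    {"name": "pah_lss_vs_static",
     "setA": {"group": "PAH", "condition": "Static"},
     "setB": {"group": "PAH", "condition": "LSS"}},
    {"name": "control_hss_vs_static",
     "setA": {"group": "control", "condition": "Static"},
     "setB": {"group": "control", "condition": "HSS"}},
    {"name": "pah_hss_vs_static",
     "setA": {"group": "PAH", "condition": "Static"},
     "setB": {"group": "PAH", "condition": "HSS"}},
]

DEFAULT_OVERLAPS = [
    {"name": "lss_response_overlap",
     "a": "pah_lss_vs_static", "b": "control_lss_vs_static"},
    {"name": "hss_response_overlap",
     "a": "pah_hss_vs_static", "b": "control_hss_vs_static"},
]


@dataclass
class PipelineConfig:
    counts: str
    outdir: str
    sample_sheet: str | None = None
    gmts: list[str] = field(default_factory=list)
    external_matrix: str | None = None
    external_labels: str | None = None
    annotation: str | None = None  # file of valid gene IDs, one per line
    abundance_frac: float = 0.04
    variance_frac: float = 0.15
    abundance_metric: str = "mean_count"
    variance_metric: str = "log2cpm_variance"
    pseudocount: float = 1.0
    contrasts: list[dict] = field(default_factory=lambda: list(DEFAULT_CONTRASTS))
    overlaps: list[dict] = field(default_factory=lambda: list(DEFAULT_OVERLAPS))
    de_alpha: float = 0.05
    ora_alpha: float = 0.05
    ora_min_overlap: int = 3
    cond_from: str = "Static"
    cond_to: str = "HSS"
    ddcv_cutoff: float = 50.0
    pam_k: int = 4
    pam_distance: str = "euclidean"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw: dict[str, Any] = (
                json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
            )
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for key in ("counts", "sample_sheet", "external_matrix",
                    "external_labels", "annotation"):
            val = getattr(self, key)
            if val is not None and not Path(val).exists():
                raise ValidationError(f"config path {key} = {val!r} does not exist")
        for g in self.gmts:
            if not Path(g).exists():
                raise ValidationError(f"GMT file {g!r} does not exist")
        if (self.external_matrix is None) != (self.external_labels is None):
            raise ValidationError(
                "external_matrix and external_labels must be given together"
            )
        Path(self.outdir).mkdir(parents=True, exist_ok=True)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in order and return the manifest."""
    cfg.validate()
    out = Path(cfg.outdir)
    manifest: list[dict] = []

    def record(stage: str, inputs: list[str], outputs: list[str],
               params: dict, t0: float) -> None:
        entry = {
            "stage": stage,
            "inputs": inputs,
            "outputs": outputs,
            "parameters": params,
            "wall_time_s": round(time.time() - t0, 3),
        }
        manifest.append(entry)
        logger.info("stage %s done: %s", stage, json.dumps(params, sort_keys=True))

    # ---- load ---------------------------------------------------------
    t0 = time.time()
    cm = io.read_counts(cfg.counts)
    if cfg.sample_sheet:
        ann = io.read_sample_sheet(cfg.sample_sheet)
    else:
        ann = io.infer_annotation(cm.sample_ids)
    ann.check_matches(cm)
    record("load", [cfg.counts, cfg.sample_sheet or "<inferred>"], [], {}, t0)

    # ---- filter -------------------------------------------------------
    t0 = time.time()
    annotation = None
    if cfg.annotation:
        annotation = {
            line.strip() for line in Path(cfg.annotation).read_text().splitlines()
            if line.strip()
        }
    filtered, report = preprocess.filter_genes(
        cm, annotation=annotation,
        abundance_frac=cfg.abundance_frac, variance_frac=cfg.variance_frac,
        abundance_metric=cfg.abundance_metric,
        variance_metric=cfg.variance_metric, pseudocount=cfg.pseudocount,
    )
    p_counts = out / "filtered_counts.tsv"
    p_report = out / "filter_report.json"
    io.write_counts(filtered, p_counts)
    p_report.write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True) + "\n")
    record("filter", [cfg.counts], [str(p_counts), str(p_report)],
           {"abundance_frac": cfg.abundance_frac,
            "variance_frac": cfg.variance_frac,
            "abundance_metric": cfg.abundance_metric,
            "variance_metric": cfg.variance_metric}, t0)

    background = list(filtered.gene_ids)
    E_cpm = preprocess.cpm(filtered)
    E_log = preprocess.log2cpm(filtered, cfg.pseudocount)
    collections = [io.read_gmt(g) for g in cfg.gmts]

    # ---- differential expression -------------------------------------
    de_results: dict[str, diffexp.DEResult] = {}
    for spec in cfg.contrasts:
        t0 = time.time()
        name = spec["name"]
        res = diffexp.run_de(
            filtered, ann, spec["setA"], spec["setB"], alpha=cfg.de_alpha,
            labels=(json.dumps(spec["setA"], sort_keys=True),
                    json.dumps(spec["setB"], sort_keys=True)),
        )
        de_results[name] = res
        p = out / f"de_{name}.tsv"
        io.write_table(res, p)
        record(f"de:{name}", [str(p_counts)], [str(p)],
               {"setA": spec["setA"], "setB": spec["setB"],
                "alpha": cfg.de_alpha, "n_degs": len(res.degs())}, t0)

    t0 = time.time()
    overlap_out = {}
    for spec in cfg.overlaps:
        ov = diffexp.deg_overlap(
            de_results[spec["a"]], de_results[spec["b"]], alpha=cfg.de_alpha
        )
        overlap_out[spec["name"]] = ov.to_dict()
    p_overlap = out / "deg_overlaps.json"
    p_overlap.write_text(json.dumps(overlap_out, indent=1, sort_keys=True) + "\n")
    record("deg_overlap", [], [str(p_overlap)],
           {k: v["n_non_overlapping"] for k, v in overlap_out.items()}, t0)

    # ---- ORA on each contrast's DEGs ---------------------------------
    if collections:
        for name, res in de_results.items():
            degs = sorted(set(res.degs()) & set(background))
            if not degs:
                continue
            t0 = time.time()
            outputs = []
            for coll in collections:
                ora = enrichment.run_ora(
                    degs, background, coll, alpha=cfg.ora_alpha,
                    min_overlap=cfg.ora_min_overlap,
                )
                p = out / f"ora_{name}_{coll.source}.tsv"
                io.write_table(ora, p)
                outputs.append(str(p))
            record(f"ora:{name}", [], outputs, {"n_query": len(degs)}, t0)

    # ---- dimensionality reduction ------------------------------------
    t0 = time.time()
    cca_rows = []
    for cond in sorted(set(ann.table["condition"])):
        ctrl = ann.samples_where(group="control", condition=cond)
        pah = ann.samples_where(group="PAH", condition=cond)
        sim = dimred.cca_similarity(
            E_log.subset_samples(ctrl), E_log.subset_samples(pah), condition=cond
        )
        cca_rows.append(
            {"condition": cond, "similarity": sim.similarity,
             **{f"cc{i + 1}": c
                for i, c in enumerate(sim.canonical_correlations)}}
        )
    import pandas as pd

    p_cca = out / "cca_similarity.tsv"
    io.write_table(pd.DataFrame(cca_rows).set_index("condition"), p_cca)

    scores, summaries, evr = dimred.pca3(E_log, ann)
    p_scores = out / "pca_scores.tsv"
    io.write_table(scores, p_scores)
    p_cent = out / "pca_centroid_distances.tsv"
    io.write_table(dimred.centroid_metrics(summaries), p_cent)
    p_disp = out / "pca_dispersion.tsv"
    io.write_table(dimred.dispersion_table(summaries), p_disp)
    record("dimred", [], [str(p_cca), str(p_scores), str(p_cent), str(p_disp)],
           {"explained_variance_ratio": [round(float(v), 6) for v in evr]}, t0)

    # ---- variability --------------------------------------------------
    t0 = time.time()
    vt = variability.variability_table(
        E_cpm, ann, cond_from=cfg.cond_from, cond_to=cfg.cond_to, counts=filtered
    )
    top = variability.select_top_variable(vt, cutoff=cfg.ddcv_cutoff)
    p_vt = out / "variability_table.tsv"
    io.write_table(vt, p_vt)
    p_top = out / "top_variable_genes.txt"
    p_top.write_text("\n".join(top) + ("\n" if top else ""))
    record("variability", [], [str(p_vt), str(p_top)],
           {"cutoff": cfg.ddcv_cutoff, "n_top_variable": len(top)}, t0)

    # ---- stratify -----------------------------------------------------
    stratify_outputs: list[str] = []
    pathway_gene_map: dict = {}
    if len(top) >= cfg.pam_k:
        t0 = time.time()
        pah_donors = sorted(
            set(ann.table.loc[ann.table["group"] == "PAH", "donor_id"])
        )
        patient_samples = {
            d: ann.samples_where(donor=d, condition=cfg.cond_to)[0]
            for d in pah_donors
        }
        z = stratify.zscore_over_patients(E_log, top, patient_samples)
        model = stratify.pam(z, k=cfg.pam_k, distance=cfg.pam_distance)
        p_z = out / "zscores.tsv"
        io.write_table(z, p_z)
        p_model = out / "cluster_model.json"
        model.to_json(p_model)
        stratify_outputs += [str(p_z), str(p_model)]

        ora_per_cluster: dict[int, list] = {}
        for cl in model.clusters():
            cluster_genes = model.cluster_genes(cl)
            ora_per_cluster[cl] = [
                enrichment.run_ora(
                    sorted(set(cluster_genes) & set(background)), background,
                    coll, alpha=cfg.ora_alpha, min_overlap=cfg.ora_min_overlap,
                )
                for coll in collections
            ]
            for ora in ora_per_cluster[cl]:
                p = out / f"ora_cluster{cl}_{ora.source}.tsv"
                io.write_table(ora, p)
                stratify_outputs.append(str(p))

        controls = ann.samples_where(group="control", condition=cfg.cond_to)
        scores_table = stratify.score_patient_pathways(
            E_log, model, ora_per_cluster, controls, patient_samples
        )
        p_scores2 = out / "patient_pathway_scores.tsv"
        io.write_table(scores_table, p_scores2)
        stratify_outputs.append(str(p_scores2))
        pathway_gene_map = scores_table.pathway_genes()
        record("stratify", [], stratify_outputs,
               {"k": cfg.pam_k, "n_top_variable": len(top),
                "cluster_patient_map": {str(c): p for c, p in
                                        model.cluster_patient_map.items()}}, t0)
    else:
        logger.warning(
            "only %d top-variable genes (< k=%d); skipping stratification",
            len(top), cfg.pam_k,
        )

    # ---- transfer -----------------------------------------------------
    if cfg.external_matrix and pathway_gene_map:
        t0 = time.time()
        cohort = io.read_external_cohort(cfg.external_matrix, cfg.external_labels)
        transfer = stratify.transfer_to_cohort(cohort, pathway_gene_map)
        p_tr = out / "transfer_scores.tsv"
        io.write_table(transfer.scores, p_tr)
        p_cov = out / "transfer_coverage.json"
        p_cov.write_text(json.dumps(
            {"coverage": transfer.coverage,
             "excluded_pathways": transfer.excluded_pathways},
            indent=1, sort_keys=True) + "\n")
        record("transfer", [cfg.external_matrix], [str(p_tr), str(p_cov)],
               {"n_pathways": len(pathway_gene_map)}, t0)

    p_manifest = out / "manifest.json"
    p_manifest.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return {"stages": manifest, "manifest_path": str(p_manifest)}
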