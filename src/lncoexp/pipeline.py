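"""End-to-end orchestration: simulate/load -> normalize -> filter -> DE
-> cluster -> network -> function prediction -> TF network -> qPCR."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

from . import diffexpr, enrichment, network, preprocess, qpcr, simulate
from .io_formats import (ExpressionMatrix, PipelineConfig, StudyDesign,
                         logger, read_annotation_bed, read_design,
                         read_expression_table, read_gmt, read_qpcr_table,
                         write_annotation_bed, write_design,
                         write_expression_table, write_gmt, write_qpcr_table)

INPUT_NAMES = {
    "expression": "expression.tsv",
    "design": "design.tsv",
    "annotation": "annotation.bed",
    "terms": "terms.gmt",
    "tf_targets": "tf_targets.gmt",
    "qpcr": "qpcr_ct.tsv",
}


def simulate_inputs(config: PipelineConfig, out_dir: str | Path,
                    params: simulate.SimulationParams | None = None) -> None:
    """Write a complete synthetic input tree (plus a truth record)."""
    params = params or simulate.SimulationParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, design, truth = simulate.generate_expression(params, config.seed)
    annotation = simulate.generate_annotation(params, config.seed, truth)
    terms, tfs = simulate.generate_gene_sets(truth, params, config.seed)
    ct = simulate.generate_qpcr(truth, params, config.seed)
    write_expression_table(matrix, out / INPUT_NAMES["expression"])
    write_design(design, out / INPUT_NAMES["design"])
    write_annotation_bed(annotation, out / INPUT_NAMES["annotation"])
    write_gmt(terms, out / INPUT_NAMES["terms"])
    write_gmt(tfs, out / INPUT_NAMES["tf_targets"])
    write_qpcr_table(ct, out / INPUT_NAMES["qpcr"])
    with open(out / "truth.json", "w") as fh:
        json.dump({
            "seed": truth.seed,
            "de_probes": truth.de_probes,
            "module_assignment": {p: m for p, m
                                  in truth.module_assignment.items() if m},
            "tf_links": truth.tf_links,
            "term_links": truth.term_links,
        }, fh, indent=1, sort_keys=True)


def run_pipeline(config: PipelineConfig, input_dir: str | Path,
                 output_dir: str | Path,
                 simulate_first: bool = False) -> dict:
    """Run every stage on the files in ``input_dir``; return the manifest."""
    inp, out = Path(input_dir), Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if simulate_first:
        simulate_inputs(config, inp)
    for key in ("expression", "design", "annotation", "terms", "tf_targets"):
        path = inp / INPUT_NAMES[key]
        if not path.exists():
            raise FileNotFoundError(f"missing input file: {path}")

    manifest: dict = {"stages": {}, "seed": config.seed,
                      "config": dataclasses.asdict(config)}
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()).hexdigest()

    def stage(name: str, **counts) -> None:
        logger.info("stage %s: %s", name, counts)
        manifest["stages"][name] = counts

    matrix = read_expression_table(inp / INPUT_NAMES["expression"])
    design = read_design(inp / INPUT_NAMES["design"])
    annotation = read_annotation_bed(inp / INPUT_NAMES["annotation"])
    terms = read_gmt(inp / INPUT_NAMES["terms"])
    tf_targets = read_gmt(inp / INPUT_NAMES["tf_targets"])

    if config.filter_before_normalize:
        matrix = preprocess.filter_by_flags(matrix, design,
                                            config.flag_min_fraction)
        matrix = preprocess.quantile_normalize(matrix)
    else:
        matrix = preprocess.quantile_normalize(matrix)
        matrix = preprocess.filter_by_flags(matrix, design,
                                            config.flag_min_fraction)
    write_expression_table(matrix, out / "normalized_filtered.tsv")
    stage("normalize", probes=matrix.shape[0], samples=matrix.shape[1])
    stage("filter", probes=matrix.shape[0])

    de_table = diffexpr.differential_table(matrix, design,
                                           config.t_test_mode)
    biotype = {a.probe_id: a.biotype for a in annotation}
    de_table.insert(0, "biotype",
                    [biotype.get(p, "") for p in de_table.index])
    de_calls = diffexpr.call_differential(de_table, config.fc_threshold,
                                          config.p_threshold)
    de_table.to_csv(out / "de_table.tsv", sep="\t", float_format="%.6g")
    de_calls.to_csv(out / "de_calls.tsv", sep="\t", float_format="%.6g")
    stage("de", tested=len(de_table), called=len(de_calls),
          up=int((de_calls["regulation"] == "up").sum()),
          down=int((de_calls["regulation"] == "down").sum()))

    if len(de_calls) >= 2:
        clusters = diffexpr.hierarchical_cluster(
            matrix.subset_probes(list(de_calls.index)), axis="samples")
        diffexpr.write_cluster_result(clusters, out / "sample_clusters.txt")
        stage("cluster", samples=len(clusters.labels))
    else:
        stage("cluster", samples=0)

    edges = network.build_coexpression_edges(
        matrix, annotation, list(de_calls.index), config.r_threshold,
        config.correlation_signed, config.trans_distance_bp)
    network.write_edges(edges, out / "coexpression_edges.tsv")
    network.degree_summary(edges).to_csv(out / "degree_summary.tsv",
                                         sep="\t", index=False)
    stage("network", edges=len(edges),
          cis=sum(e.mode == "cis" for e in edges),
          trans=sum(e.mode == "trans" for e in edges))

    universe = {p for p in matrix.probe_ids if biotype.get(p) == "mRNA"}
    predictions = enrichment.predict_lncrna_functions(
        edges, terms, universe, config.enrich_p_cutoff)
    rows = []
    for lnc, results in sorted(predictions.items()):
        for r in results:
            rows.append((lnc, r.set_id, r.k, r.n, r.K, r.N, r.p, r.q))
    import pandas as pd
    pd.DataFrame(rows, columns=["lncrna_probe_id", "set_id", "k", "n", "K",
                                "N", "p", "q"]).to_csv(
        out / "lncrna_functions.tsv", sep="\t", index=False,
        float_format="%.4g")
    stage("functions", lncrnas=len(predictions),
          predictions=sum(len(v) for v in predictions.values()))

    associations = enrichment.tf_lncrna_network(
        edges, tf_targets, universe, config.tf_p_cutoff,
        config.tf_fdr_cutoff, trans_only=True)
    associations.to_csv(out / "tf_associations.tsv", sep="\t", index=False,
                        float_format="%.4g")
    ranking = enrichment.rank_tfs(associations)
    ranking.to_csv(out / "tf_ranking.tsv", sep="\t", index=False,
                   float_format="%.4g")
    stage("tfnet", associations=len(associations), tfs=len(ranking))

    qpcr_path = inp / INPUT_NAMES["qpcr"]
    if qpcr_path.exists():
        ct = read_qpcr_table(qpcr_path)
        genes = [g for g in ct["gene_id"].drop_duplicates() if g != "GAPDH"]
        summaries = {}
        rows = []
        for gene in genes:
            rel = qpcr.delta_delta_ct(ct, "GAPDH", gene)
            if not rel:
                continue
            median, se, n = qpcr.summarize_patients(rel)
            summaries[gene] = median
            rows.append((gene, median, se, n))
        pd.DataFrame(rows, columns=["gene_id", "median_log2_fold",
                                    "standard_error", "n_patients"]).to_csv(
            out / "qpcr_summary.tsv", sep="\t", index=False,
            float_format="%.6g")
        concordance = qpcr.concordance_check(summaries, de_table)
        concordance.to_csv(out / "qpcr_concordance.tsv", sep="\t",
                           index=False, float_format="%.6g")
        stage("qpcr", genes=len(summaries),
              concordant=int(concordance["concordant"].sum()))
    else:
        stage("qpcr", genes=0, concordant=0)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
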