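"""End-to-end orchestration: simulate → flow / sc → tcr → clonex.

Each stage writes its outputs under its own subdirectory of the run's
output directory and never touches another stage's files. A manifest
records seeds, package version, and the SHA-256 of every output so that
reruns with the same configuration can be verified byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clonality import (ICPPanel, PatientCells, classify_expression,
                        compartmentalize, icp_burden, icp_medians,
                        lc_hc_differential)
from .config import RunConfig, stage_seed
from .flow import assign_subsets, icp_profile, mfi_ratio_heatmap, subset_fractions
from .io import (write_contigs, write_count_matrix, write_flow_csv,
                 write_flow_truth, write_sc_truth)
from .logicle import auto_logicle_params, logicle_transform
from .phenograph import knn_jaccard_graph, louvain_cluster, summarize_clusters, umap_embed
from .sc import assign_lineage, differential_expression, lognormalize, qc_filter, \
    reduce_and_cluster, score_cell_cycle, select_hvg
from .simulate import generate_flow_cohort, generate_sc_cohort, true_thresholds
from .tcr import call_clonotypes, clonotype_sharing, repertoire_metrics

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, manifest: dict | None = None):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage
        self.manifest = manifest or {}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.model_dump(),
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, *paths: Path):
        for p in paths:
            manifest["outputs"][str(p.relative_to(outdir))] = _sha256(p)
        manifest["stages"].setdefault(stage, []).extend(
            str(p.relative_to(outdir)) for p in paths
        )

    st = config.stages
    if st.clonex and not (st.tcr and st.sc):
        raise PipelineError("clonex", "requires the sc and tcr stages", manifest)

    # ---------------- simulate ----------------
    flow_cohort = sc_cohort = None
    sim_dir = outdir / "simulate"
    # with no analysis stage enabled, still emit both synthetic cohorts
    none_enabled = not (st.flow or st.cluster or st.sc or st.tcr or st.clonex)
    if st.flow or st.cluster or none_enabled:
        fcfg = config.flow_sim.model_copy(
            update={"seed": stage_seed(config.seed, "simulate")}
        )
        flow_cohort = generate_flow_cohort(fcfg)
        paths = []
        for m, truth in flow_cohort:
            paths.append(write_flow_csv(m, sim_dir / f"flow_{m.sample_id}.csv"))
            paths.append(write_flow_truth(truth, sim_dir / f"flow_{m.sample_id}_truth.json"))
        record("simulate", *paths)
    if st.sc or st.tcr or st.clonex or none_enabled:
        scfg = config.sc_sim.model_copy(
            update={"seed": stage_seed(config.seed, "simulate") + 1}
        )
        sc_cohort = generate_sc_cohort(scfg)
        paths = []
        for cm, contigs, truth in sc_cohort:
            write_count_matrix(cm, sim_dir / cm.patient)
            for name in ("matrix.mtx", "barcodes.tsv", "features.tsv"):
                paths.append(sim_dir / cm.patient / name)
            paths.append(write_contigs(
                contigs, sim_dir / cm.patient / "filtered_contig_annotations.csv"))
            paths.append(write_sc_truth(truth, sim_dir / cm.patient / "truth.json"))
        record("simulate", *paths)

    # ---------------- flow (supervised) ----------------
    if st.flow:
        try:
            fdir = outdir / "flow"
            thresholds = true_thresholds(config.flow_sim)
            frac_rows, prof_rows, profiles = [], [], []
            for m, _ in flow_cohort:
                labels = assign_subsets(m, thresholds)
                frac = subset_fractions(labels)
                frac_rows.append({"sample": m.sample_id, **frac.to_dict()})
                for prof in icp_profile(m, labels, thresholds):
                    profiles.append(prof)
                    for icp in m.panel:
                        prof_rows.append({
                            "sample": prof.sample_id, "subset": prof.subset,
                            "icp": icp,
                            "percent_positive": prof.percent_positive[icp],
                            "mfi": prof.mfi[icp],
                        })
            p1 = _write_tsv(pd.DataFrame(frac_rows), fdir / "subset_fractions.tsv")
            p2 = _write_tsv(pd.DataFrame(prof_rows), fdir / "icp_profiles.tsv")
            ratios = mfi_ratio_heatmap(profiles)
            p3 = _write_tsv(ratios.rename_axis("icp").reset_index(),
                            fdir / "mfi_ratio.tsv")
            record("flow", p1, p2, p3)
        except Exception as e:  # pragma: no cover - defensive
            raise PipelineError("flow", str(e), manifest) from e

    # ---------------- cluster (unsupervised flow) ----------------
    if st.cluster:
        try:
            cdir = outdir / "cluster"
            rng = np.random.default_rng(stage_seed(config.seed, "cluster"))
            values, sample_ids = [], []
            for m, _ in flow_cohort:
                values.append(m.values)
                sample_ids.extend([m.sample_id] * m.n_cells)
            pooled = pd.concat(values, ignore_index=True)
            sample_ids = np.array(sample_ids)
            if len(pooled) > config.max_cluster_cells:
                keep = rng.choice(len(pooled), config.max_cluster_cells, replace=False)
                keep.sort()
                pooled = pooled.iloc[keep].reset_index(drop=True)
                sample_ids = sample_ids[keep]
            markers = [m for m in config.cluster_markers if m in pooled.columns]
            transformed = pd.DataFrame(
                {mk: logicle_transform(pooled[mk].to_numpy(),
                                       auto_logicle_params(pooled[mk].to_numpy()))
                 for mk in markers}
            )
            graph = knn_jaccard_graph(transformed.to_numpy(), k=config.phenograph_k)
            labels, q = louvain_cluster(graph, seed=stage_seed(config.seed, "cluster"))
            lab_df = pd.DataFrame({"cell": np.arange(len(labels)),
                                   "sample": sample_ids, "cluster": labels})
            p1 = _write_tsv(lab_df, cdir / "labels.tsv")
            summaries = summarize_clusters(transformed, labels, sample_ids)
            rows = []
            for s in summaries:
                for mk, v in s.normalized_mean.items():
                    rows.append({"cluster": s.cluster, "kind": "marker",
                                 "name": mk, "value": v})
                for sid, v in s.abundance.items():
                    rows.append({"cluster": s.cluster, "kind": "abundance",
                                 "name": sid, "value": v})
            p2 = _write_tsv(pd.DataFrame(rows), cdir / "cluster_summary.tsv")
            edge_df = pd.DataFrame({"i": graph.edges[:, 0], "j": graph.edges[:, 1],
                                    "weight": graph.weights})
            p3 = _write_tsv(edge_df, cdir / "graph_edges.tsv")
            outputs = [p1, p2, p3]
            if config.umap:
                emb = umap_embed(transformed.to_numpy(), seed=stage_seed(config.seed, "cluster"))
                outputs.append(_write_tsv(
                    pd.DataFrame(emb, columns=["umap1", "umap2"]),
                    cdir / "embedding.tsv"))
            manifest["stages"]["cluster_modularity"] = q
            record("cluster", *outputs)
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError("cluster", str(e), manifest) from e

    # ---------------- sc ----------------
    sc_results: dict[str, dict] = {}
    if st.sc:
        try:
            sdir = outdir / "sc"
            for cm, contigs, truth in sc_cohort:
                filtered, report = qc_filter(cm, config.qc)
                norm = lognormalize(filtered)
                hvg = select_hvg(filtered, n=config.hvg_n)
                grid = reduce_and_cluster(
                    norm, hvg,
                    dims_grid=tuple(config.dims_grid),
                    res_grid=tuple(config.res_grid),
                    seed=stage_seed(config.seed, "sc"),
                    knn_k=config.sc_knn_k,
                    stability_floor=config.stability_floor,
                )
                cc = score_cell_cycle(norm, seed=stage_seed(config.seed, "sc"))
                lineages = assign_lineage(grid.labels, norm)
                pdir = sdir / cm.patient
                (pdir).mkdir(parents=True, exist_ok=True)
                (pdir / "qc_report.json").write_text(json.dumps(report.as_dict()))
                lab = pd.DataFrame({
                    "barcode": norm.barcodes,
                    "cluster": grid.labels,
                    "lineage": [lineages[c] for c in grid.labels],
                    "phase": cc["phase"].to_numpy(),
                })
                p1 = _write_tsv(lab, pdir / "clusters.tsv")
                p2 = _write_tsv(grid.report, pdir / "grid_report.tsv")
                # differential expression between the two largest clusters
                top = pd.Series(grid.labels).value_counts().index[:2]
                de = differential_expression(
                    norm,
                    np.flatnonzero(grid.labels == top[0]),
                    np.flatnonzero(grid.labels == top[1]),
                ) if len(top) > 1 else None
                outputs = [pdir / "qc_report.json", p1, p2]
                if de is not None:
                    outputs.append(_write_tsv(de, pdir / "de_top_clusters.tsv"))
                record("sc", *outputs)
                sc_results[cm.patient] = {
                    "norm": norm, "labels": grid.labels, "lineages": lineages,
                    "contigs": contigs, "truth": truth,
                }
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError("sc", str(e), manifest) from e

    # ---------------- tcr ----------------
    clonotype_tables = {}
    if st.tcr:
        try:
            if not sc_results:
                raise PipelineError("tcr", "requires the sc stage", manifest)
            tdir = outdir / "tcr"
            cluster_map = {}
            for patient, res in sc_results.items():
                table = call_clonotypes(res["contigs"], patient,
                                        barcodes=res["norm"].barcodes)
                clonotype_tables[patient] = table
                cluster_map[patient] = pd.Series(
                    res["labels"], index=res["norm"].barcodes)
                _write_tsv(table.cells, tdir / f"{patient}_clonotypes.tsv")
            tables = list(clonotype_tables.values())
            lineage_lookup = {}
            for patient, res in sc_results.items():
                lineage_lookup.update({c: l for c, l in res["lineages"].items()})
            metrics = repertoire_metrics(tables, cluster_map, lineage_lookup)
            p1 = _write_tsv(metrics["per_cluster"], tdir / "repertoire_per_cluster.tsv")
            p2 = _write_tsv(metrics["per_lineage"], tdir / "repertoire_per_lineage.tsv")
            sharing, flows = clonotype_sharing(tables, cluster_map)
            p3 = _write_tsv(sharing, tdir / "sharing_summary.tsv")
            p4 = _write_tsv(flows, tdir / "sharing_flows.tsv")
            outputs = [tdir / f"{p}_clonotypes.tsv" for p in clonotype_tables]
            record("tcr", *outputs, p1, p2, p3, p4)
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError("tcr", str(e), manifest) from e

    # ---------------- clonex ----------------
    if st.clonex:
        try:
            xdir = outdir / "clonex"
            panel = ICPPanel()
            patients = []
            for patient, res in sc_results.items():
                patients.append(PatientCells(
                    norm=res["norm"],
                    clonotypes=clonotype_tables[patient],
                    clusters=pd.Series(res["labels"], index=res["norm"].barcodes),
                ))
            medians = icp_medians(patients, panel)
            expression = classify_expression(patients, medians, panel,
                                             rule=config.he_rule)
            cells, composition = compartmentalize(patients, expression)
            burden_cells, burden_summary = icp_burden(patients, panel)
            diff = lc_hc_differential(patients, panel,
                                      min_cells=config.lc_hc_min_cells)
            p1 = _write_tsv(cells, xdir / "compartments.tsv")
            p2 = _write_tsv(composition, xdir / "compartment_composition.tsv", index=True)
            p3 = _write_tsv(medians, xdir / "icp_medians.tsv", index=True)
            p4 = _write_tsv(burden_summary, xdir / "icp_burden.tsv")
            p5 = _write_tsv(diff, xdir / "lc_hc_differential.tsv", index=True)
            record("clonex", p1, p2, p3, p4, p5)
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError("clonex", str(e), manifest) from e

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
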