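"""End-to-end orchestration: simulate -> preprocess -> DEA -> DEIRG ->
enrichment -> PPIN/MCODE -> FFL -> ROC/correlation -> survival.

Every stage writes its table under the output directory; the run report
collects only numbers recomputable from those tables.  A stage failure
aborts the run with the stage name while the MANIFEST records completed
stages.  With a fixed config and seed the report is byte-identical across
reruns.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, dea, enrich, ffl, ppin, preprocess, survival as surv
from .cohort import ExpressionCohort, TUMOR
from .errors import ConfigurationError, ImmfflError, PipelineStageError
from .synthetic import SimulationConfig, write_simulated_dataset

INPUT_KEYS = (
    "mrna_counts", "mirna_counts", "samples", "immune_genes", "gene_sets",
    "ppi_edges", "regulatory_edges", "survival", "infiltration",
)


@dataclass
class PipelineConfig:
    """Paths to all inputs plus every analysis threshold.

    Threshold defaults are the study's printed cutoffs: |log2FC| > 2 with
    BH p < 1e-4 for differential calls, enrichment q < 1e-4, PPI confidence
    > 0.9, TF evidence p <= 0.001, MCODE node-score cutoff 0.2 / degree
    cutoff 2 with haircut, two-group alpha 0.05.
    """

    out_dir: str = "immffl_run"
    inputs: dict[str, str] = field(default_factory=dict)
    simulate: dict | None = None
    fc_threshold: float = 2.0
    p_threshold: float = 1e-4
    q_cutoff: float = 1e-4
    ppi_score_cutoff: float = 0.9
    tf_p_cutoff: float = 0.001
    mcode_node_score_cutoff: float = 0.2
    mcode_degree_cutoff: int = 2
    mcode_haircut: bool = True
    min_cpm: float = 1.0
    min_frac: float = 0.2
    duplicate_policy: str = "max_mean"
    survival_method: str = "median"
    alpha: float = 0.05
    mirna_family: list[str] | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigurationError(f"unknown pipeline config key(s): {sorted(extra)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class Finding:
    level: str  # "warning" | "fatal"
    message: str


def validate_inputs(config: PipelineConfig) -> list[Finding]:
    """Consistency checks on all referenced input files.

    Fatal findings: missing files, matrix/annotation mismatch, a node
    claimed by two molecular classes, non-positive survival times.
    Warnings: empty immune list, samples without survival records.
    """
    findings: list[Finding] = []
    paths = dict(config.inputs)
    for key in INPUT_KEYS:
        if key not in paths:
            findings.append(Finding("fatal", f"missing input path '{key}'"))
    if any(f.level == "fatal" for f in findings):
        return findings
    for key, p in paths.items():
        if not Path(p).exists():
            findings.append(Finding("fatal", f"input '{key}' not found: {p}"))
    if any(f.level == "fatal" for f in findings):
        return findings

    annot = pd.read_csv(paths["samples"], sep="\t", index_col=0)
    for key in ("mrna_counts", "mirna_counts"):
        header = pd.read_csv(paths[key], sep="\t", index_col=0, nrows=0)
        missing = set(header.columns) - set(annot.index.astype(str))
        if missing:
            findings.append(
                Finding(
                    "fatal",
                    f"{key}: sample(s) absent from annotation, e.g. "
                    f"{sorted(missing)[:3]}",
                )
            )
    try:
        ffl.RegulatoryEdgeSet.read(paths["regulatory_edges"])
    except ImmfflError as exc:
        findings.append(Finding("fatal", f"regulatory edges: {exc}"))
    immune = enrich.read_gene_list(paths["immune_genes"])
    if not immune:
        findings.append(Finding("warning", "immune gene list is empty"))
    surv_df = pd.read_csv(paths["survival"], sep="\t")
    if (surv_df["time_months"] <= 0).any():
        findings.append(Finding("fatal", "survival table has non-positive times"))
    unknown = set(surv_df["sample_id"].astype(str)) - set(annot.index.astype(str))
    if unknown:
        findings.append(
            Finding("fatal", f"survival samples not in annotation: {sorted(unknown)[:3]}")
        )
    return findings


def _round(x: float, nd: int = 6) -> float:
    return float(np.round(float(x), nd))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the run report (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    report: dict = {"config": config.to_dict()}

    def stage(name: str):
        def deco(fn):
            try:
                fn()
            except Exception as exc:
                _write_manifest(out, manifest, failed=name)
                raise PipelineStageError(name, exc) from exc
            manifest.append(name)
            return None

        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        if config.simulate is not None:
            sim = SimulationConfig.from_dict({**config.simulate, "seed": config.seed})
            paths = write_simulated_dataset(sim, out / "data")
            config.inputs = {k: str(paths[k]) for k in INPUT_KEYS}
            report["simulated"] = True
        else:
            report["simulated"] = False

    @stage("validate")
    def _validate():
        findings = validate_inputs(config)
        report["findings"] = [dataclasses.asdict(f) for f in findings]
        fatal = [f for f in findings if f.level == "fatal"]
        if fatal:
            raise ConfigurationError("; ".join(f.message for f in fatal))

    @stage("preprocess")
    def _preprocess():
        for tag, key in (("mrna", "mrna_counts"), ("mirna", "mirna_counts")):
            raw = ExpressionCohort.read(config.inputs[key], config.inputs["samples"])
            n_raw = len(raw.feature_ids)
            filtered = preprocess.filter_low_counts(raw, config.min_cpm, config.min_frac)
            normed = preprocess.normalize_log2(filtered)
            collapsed, n_dup = preprocess.collapse_duplicates(
                normed, config.duplicate_policy
            )
            cohort = preprocess.batch_center(collapsed)
            cohort.values.round(6).to_csv(
                out / f"{tag}_log2.tsv", sep="\t", index_label="feature_id"
            )
            state[tag] = cohort
            report[f"n_{tag}_features_raw"] = n_raw
            report[f"n_{tag}_features_kept"] = len(cohort.feature_ids)
            report[f"n_{tag}_duplicates_collapsed"] = n_dup
        report["n_samples"] = len(state["mrna"].sample_ids)
        report["n_tumor"] = int((state["mrna"].group == TUMOR).sum())
        report["n_normal"] = report["n_samples"] - report["n_tumor"]

    @stage("dea")
    def _dea():
        for tag in ("mrna", "mirna"):
            table = dea.differential_expression(
                state[tag], config.fc_threshold, config.p_threshold
            )
            table.round(6).to_csv(out / f"dea_{tag}.tsv", sep="\t", index_label="feature_id")
            state[f"dea_{tag}"] = table
        degs = state["dea_mrna"][state["dea_mrna"]["call"] != "ns"]
        dems = state["dea_mirna"][state["dea_mirna"]["call"] != "ns"]
        state["degs"] = list(degs.index)
        state["dems"] = list(dems.index)
        report["n_degs"] = len(degs)
        report["n_degs_up"] = int((degs["call"] == "up").sum())
        report["n_degs_down"] = int((degs["call"] == "down").sum())
        report["n_dems"] = len(dems)

    @stage("deirg")
    def _deirg():
        immune = enrich.read_gene_list(config.inputs["immune_genes"])
        deirgs = enrich.intersect_immune(state["degs"], immune)
        state["deirgs"] = deirgs
        enrich.write_gene_list(deirgs, out / "deirgs.txt")
        report["n_irgs"] = len(immune)
        report["n_deirgs"] = len(deirgs)

    @stage("enrichment")
    def _enrichment():
        collection = enrich.GeneSetCollection.from_gmt(config.inputs["gene_sets"])
        universe = state["mrna"].feature_ids
        table = enrich.enrich_collection(
            state["deirgs"], collection, universe, config.q_cutoff
        )
        table.drop(columns=["overlap_genes"]).round(10).to_csv(
            out / "enrichment.tsv", sep="\t", index=False
        )
        report["n_enriched_sets"] = int(table["significant"].sum())
        report["n_deirgs_in_enriched_sets"] = len(table.attrs["covered_genes"])
        if len(table):
            report["top_enriched_set"] = str(table.iloc[0]["set_name"])

    @stage("ppin")
    def _ppin():
        edge_table = ppin.read_ppi_table(config.inputs["ppi_edges"])
        graph = ppin.build_ppin(edge_table, state["deirgs"], config.ppi_score_cutoff)
        complexes = ppin.mcode_complexes(
            graph,
            node_score_cutoff=config.mcode_node_score_cutoff,
            degree_cutoff=config.mcode_degree_cutoff,
            haircut=config.mcode_haircut,
        )
        hubs = ppin.select_hub_genes(complexes)
        state["hubs"] = hubs
        enrich.write_gene_list(hubs, out / "hub_genes.txt")
        report["ppin_nodes"] = graph.number_of_nodes()
        report["ppin_edges"] = graph.number_of_edges()
        report["n_complexes"] = len(complexes)
        top = complexes[0]
        report["top_complex_size"] = len(top.members)
        report["top_complex_edges"] = top.edge_count
        report["top_complex_density"] = _round(top.density)
        report["hub_genes"] = hubs

    @stage("ffl")
    def _ffl():
        reg = pd.read_csv(config.inputs["regulatory_edges"], sep="\t", dtype={"source": str, "target": str, "type": str})
        tf_rows = reg[reg["type"] == ffl.TF_MRNA]
        tf_table = pd.DataFrame(
            {"tf": tf_rows["source"], "target": tf_rows["target"], "p": tf_rows["p"].astype(float)}
        )
        mirna_edges = reg[reg["type"] != ffl.TF_MRNA]
        net = ffl.build_regulatory_network(
            state["hubs"], tf_table, mirna_edges, state["dems"], config.tf_p_cutoff
        )
        net.write(out / "ffl_network_edges.tsv")
        nstats = ffl.network_stats(net)
        motifs = ffl.enumerate_ffls(net)
        ranked = ffl.rank_motifs(motifs, net, family=config.mirna_family)
        pd.DataFrame(
            [
                {
                    "rank": i + 1,
                    "mirna": m.mirna_id,
                    "tf": m.tf_id,
                    "mrna": m.mrna_id,
                    "degree_sum": m.degree_sum,
                }
                for i, m in enumerate(ranked)
            ]
        ).to_csv(out / "ffl_motifs.tsv", sep="\t", index=False)
        state["top_motifs"] = ranked
        report["ffl_nodes"] = nstats.total_nodes
        report["ffl_edges"] = nstats.total_edges
        report["ffl_edges_by_type"] = {
            ffl.TF_MRNA: nstats.n_edges_tf_mrna,
            ffl.MIRNA_MRNA: nstats.n_edges_mirna_mrna,
            ffl.MIRNA_TF: nstats.n_edges_mirna_tf,
        }
        report["ffl_nodes_by_class"] = {
            "mirna": nstats.n_mirnas, "tf": nstats.n_tfs, "mrna": nstats.n_mrnas,
        }
        report["ffl_avg_degree"] = {k: _round(v) for k, v in nstats.avg_degree.items()}
        report["n_motifs"] = len(motifs)
        report["top_motifs"] = [
            {"mirna": m.mirna_id, "tf": m.tf_id, "mrna": m.mrna_id, "degree_sum": m.degree_sum}
            for m in ranked[:5]
        ]

    @stage("assoc")
    def _assoc():
        labels = state["mrna"].group.to_numpy()
        roc_rows = []
        for g in state["hubs"]:
            r = assoc.roc_auc(state["mrna"].values.loc[g].to_numpy(), labels)
            roc_rows.append(
                {"item": g, "auc": _round(r.auc), "ci_low": _round(r.ci_low),
                 "ci_high": _round(r.ci_high), "n_pos": r.n_pos, "n_neg": r.n_neg}
            )
        pd.DataFrame(roc_rows).to_csv(out / "roc.tsv", sep="\t", index=False)
        report["roc"] = {row["item"]: row["auc"] for row in roc_rows}

        infil = pd.read_csv(config.inputs["infiltration"], sep="\t", index_col=0)
        tumor_mrna = state["mrna"].subset_samples(
            [s for s in state["mrna"].sample_ids if s in set(infil.index.astype(str))]
        )
        infil = infil.loc[tumor_mrna.sample_ids]
        cell_types = [c for c in infil.columns if c != "purity"]
        corr_rows = []
        for g in state["hubs"]:
            expr = tumor_mrna.values.loc[g].to_numpy()
            for ct in cell_types:
                plain = assoc.spearman(expr, infil[ct].to_numpy())
                part = assoc.partial_spearman(
                    expr, infil[ct].to_numpy(), infil["purity"].to_numpy()
                )
                corr_rows.append(
                    {"gene": g, "cell_type": ct,
                     "rho": _round(plain.rho), "p": plain.p,
                     "rho_purity_adj": _round(part.rho), "p_purity_adj": part.p}
                )
            pur = assoc.spearman(expr, infil["purity"].to_numpy())
            corr_rows.append(
                {"gene": g, "cell_type": "purity", "rho": _round(pur.rho),
                 "p": pur.p, "rho_purity_adj": np.nan, "p_purity_adj": np.nan}
            )
        corr = pd.DataFrame(corr_rows)
        corr.to_csv(out / "infiltration_correlation.tsv", sep="\t", index=False)
        report["n_correlations"] = len(corr)
        report["n_correlations_significant"] = int(
            (corr["p"] < config.alpha).sum()
        )

    @stage("survival")
    def _survival():
        table = surv.read_survival_table(config.inputs["survival"])
        table["sample_id"] = table["sample_id"].astype(str)
        items = []
        if state["top_motifs"]:
            top = state["top_motifs"][0]
            items = [("mrna", top.mrna_id), ("mirna", top.mirna_id)]
        rows = []
        for kind, item in items:
            cohort = state[kind]
            ids = [s for s in table["sample_id"] if s in set(cohort.sample_ids)]
            if not ids or item not in cohort.values.index:
                continue
            expr = cohort.values.loc[item, ids]
            if config.survival_method == "median":
                groups = surv.dichotomize(expr, "median")
            else:
                groups, _, _ = surv.best_cutoff_split(
                    expr, table[table["sample_id"].isin(ids)]
                )
            merged = table.set_index("sample_id").loc[ids].assign(group=groups.values)
            cmp = surv.logrank_hr(merged.reset_index())
            rows.append(
                {"item": item, "hr": _round(cmp.hr, 4),
                 "hr_ci_low": _round(cmp.hr_ci[0], 4),
                 "hr_ci_high": _round(cmp.hr_ci[1], 4),
                 "chi2": _round(cmp.chi2, 4), "p": cmp.p,
                 "median_low": cmp.median_low, "median_high": cmp.median_high,
                 "n_low": cmp.n_low, "n_high": cmp.n_high}
            )
        pd.DataFrame(
            rows,
            columns=["item", "hr", "hr_ci_low", "hr_ci_high", "chi2", "p",
                     "median_low", "median_high", "n_low", "n_high"],
        ).to_csv(out / "survival_comparisons.tsv", sep="\t", index=False)
        report["survival"] = rows

    _write_manifest(out, manifest)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return report


def _write_manifest(out: Path, stages: list[str], failed: str | None = None) -> None:
    with open(out / "MANIFEST", "w") as fh:
        for s in stages:
            fh.write(f"completed\t{s}\n")
        if failed:
            fh.write(f"failed\t{failed}\n")
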