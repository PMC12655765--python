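"""End-to-end pipeline runs: panel -> QC -> correlation -> network ->
target-set similarity -> clustering (-> optional structural concordance).

A run is described by a ``RunConfig`` (YAML-serializable, CLI-overridable)
and produces a ``RunReport`` whose counts satisfy hard reconciliation
identities: retained correlation records equal network edges, and the
pair-report split (pairs sharing >= 1 target vs none) sums to C(n, 2)
over the drugs in the network. Every run writes the resolved config, all
stage artifacts, and a checksum manifest beside the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import chem as _chem
from . import cluster as _cluster
from . import correlation as _corr
from . import network as _net
from . import setsim as _setsim
from . import synthetic as _synth

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved parameters for one pipeline run."""

    mode: str = "synthetic"            # synthetic | real
    outdir: str = "pgxnet_run"
    seed: int = 0
    # synthetic-mode panel parameters (the study shape by default)
    n_drugs: int = 124
    n_genes: int = 399
    n_cell_lines: int = 60
    n_families: int = 15
    targets_per_drug: tuple[int, int] = (4, 8)
    shared_fraction: float = 0.8
    planted_r: float = 0.6
    missing_rate: float = 0.0
    # real-mode inputs
    expression_path: str | None = None
    activity_path: str | None = None
    annotations_path: str | None = None
    # retention policy
    policy: _corr.FilterPolicy = field(default_factory=_corr.FilterPolicy)
    # similarity / clustering
    index_name: str = "b_index"
    k: int | str = "auto"
    k_min: int = 2
    k_max: int = 30
    # optional structural stage
    smiles_path: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["targets_per_drug"] = list(self.targets_per_drug)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "policy" in d and isinstance(d["policy"], dict):
            d["policy"] = _corr.FilterPolicy(**d["policy"])
        if "targets_per_drug" in d:
            d["targets_per_drug"] = tuple(d["targets_per_drug"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunReport:
    """Reconciled counts and the output-file manifest of a run."""

    seed: int
    counts: dict
    chosen_k: int
    files: dict[str, str]
    structural: dict | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: RunConfig):
    if config.mode == "synthetic":
        blueprint = _synth.build_target_blueprint(
            n_drugs=config.n_drugs,
            n_genes=config.n_genes,
            n_families=config.n_families,
            targets_per_drug=config.targets_per_drug,
            shared_fraction=config.shared_fraction,
            seed=config.seed,
        )
        tissue_counts = (dict(_synth.NCI60_TISSUE_COUNTS)
                         if config.n_cell_lines == 60
                         else {"tissue": config.n_cell_lines})
        panel = _synth.generate_panel(_synth.PanelConfig(
            n_genes=config.n_genes,
            n_drugs=config.n_drugs,
            n_cell_lines=config.n_cell_lines,
            tissue_counts=tissue_counts,
            blueprint=blueprint,
            planted_r=config.planted_r,
            missing_rate=config.missing_rate,
            seed=config.seed,
        ))
        annotations: dict[str, str] = {}
        return panel.expression, panel.activity, annotations, panel
    if config.mode == "real":
        for p, name in [(config.expression_path, "expression_path"),
                        (config.activity_path, "activity_path")]:
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"real mode requires existing {name} (got {p})")
        expression = _synth.read_matrix_tsv(config.expression_path)
        activity = _synth.read_matrix_tsv(config.activity_path)
        annotations = (_net.read_annotations(config.annotations_path)
                       if config.annotations_path else {})
        return expression, activity, annotations, None
    raise ValueError(f"unknown mode {config.mode!r}")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages, write artifacts under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("stage load/simulate (mode=%s, seed=%d)", config.mode, config.seed)
    expression, activity, annotations, panel = _load_inputs(config)
    if panel is not None:
        _synth.write_panel(panel, outdir / "panel")

    logger.info("stage qc")
    activity_qc, qc_log = _corr.qc_filter_drugs(activity, config.policy)
    qc_log.to_csv(outdir / "qc_removals.tsv", sep="\t", index=False)

    logger.info("stage correlate (%d drugs x %d genes)",
                len(activity_qc), len(expression))
    records = _corr.correlate_all(expression, activity_qc, config.policy)
    _corr.write_correlation_table(records, outdir / "correlations.tsv", config.policy)
    retained = _corr.filter_records(records, config.policy)

    logger.info("stage network (%d retained edges)", len(retained))
    graph = _net.build_network(retained, annotations)
    _net.write_graphml(graph, outdir / "network.graphml")
    _net.write_sif(graph, outdir / "network.sif")
    _net.write_edge_tsv(graph, outdir / "network_edges.tsv")
    tsets = _net.target_sets(graph)
    _setsim.write_target_sets(tsets, outdir / "target_sets.tsv")

    logger.info("stage similarity (%s over %d drugs)", config.index_name, len(tsets))
    chosen_k = 0
    pair_summary = {"n_drugs": len(tsets), "n_pairs": 0,
                    "pairs_shared_ge1": 0, "pairs_shared_0": 0}
    if tsets:
        pair_table, pair_summary = _setsim.pair_report(tsets)
        pair_table.round(6).to_csv(outdir / "pair_report.tsv", sep="\t", index=False)
    if len(tsets) >= 2:
        similarity = _setsim.pairwise_similarity(tsets, config.index_name)
        _setsim.write_similarity_matrix(similarity, outdir / "similarity.tsv")

        logger.info("stage cluster")
        distance = _cluster.to_distance(similarity)
        tree = _cluster.ward_cluster(distance)
        if config.k == "auto":
            k_max = min(config.k_max, tree.n_leaves - 1)
            chosen_k = _cluster.select_k_by_inertia(
                tree, k_min=min(config.k_min, max(2, k_max - 1)), k_max=k_max)
        else:
            chosen_k = int(config.k)
        partition = _cluster.cut_tree(tree, chosen_k)
        _cluster.write_newick(tree, outdir / "tree.nwk")
        _cluster.write_partition(partition, outdir / "clusters.tsv")
        _cluster.ordered_matrix(similarity, tree).to_csv(
            outdir / "similarity_ordered.tsv", sep="\t", index_label="drug_id",
            float_format="%.6g")
    else:
        partition = pd.Series(dtype=int)

    structural = None
    if config.smiles_path:
        logger.info("stage structure")
        compounds, errors = _chem.load_compounds(config.smiles_path)
        matrices, table = _chem.pairwise_structural(compounds)
        table.round(6).to_csv(outdir / "structural_pairs.tsv", sep="\t", index=False)
        for name, mat in matrices.items():
            _setsim.write_similarity_matrix(mat, outdir / f"structural_{name}.tsv")
        name, struct_tree, coph = _chem.select_matrix_by_cophenetic(matrices)
        structural = {"n_compounds": len(compounds), "n_table_rows": len(table),
                      "skipped_lines": len(errors),
                      "selected_matrix": name, "cophenetic": coph}
        shared_ids = sorted(set(partition.index) & {c.drug_id for c in compounds})
        if chosen_k >= 2 and len(shared_ids) >= max(3, chosen_k):
            struct_part = _cluster.cut_tree(struct_tree, chosen_k)
            ari, _ = _chem.cluster_concordance(
                partition.loc[shared_ids], struct_part.loc[shared_ids])
            structural["ari_vs_target_clusters"] = ari

    counts = {
        "drugs_in": int(len(activity)),
        "drugs_after_qc": int(len(activity_qc)),
        "genes_in": int(len(expression)),
        "tested_pairs": int(records["testable"].sum()),
        "retained_edges": int(len(retained)),
        "network_drug_nodes": len(_net.drug_nodes(graph)),
        "network_gene_nodes": len(_net.gene_nodes(graph)),
        "network_edges": graph.number_of_edges(),
        **{k: int(v) for k, v in pair_summary.items()},
    }
    _verify_report_identities(counts)

    with open(outdir / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    files = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file()
        and p.name not in ("report.json", "manifest.json", "config_resolved.yaml")
    }
    report = RunReport(seed=config.seed, counts=counts,
                       chosen_k=int(chosen_k), files=files, structural=structural)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    return report


def _verify_report_identities(counts: dict) -> None:
    if counts["retained_edges"] != counts["network_edges"]:
        raise AssertionError("retained edge count does not match network edge count")
    n = counts["n_drugs"]
    expected_pairs = math.comb(n, 2)
    if counts["n_pairs"] != expected_pairs:
        raise AssertionError("pair report row count is not C(n_drugs, 2)")
    if counts["pairs_shared_ge1"] + counts["pairs_shared_0"] != expected_pairs:
        raise AssertionError("pair accounting does not sum to C(n_drugs, 2)")


def profile_pair_table(
    expression: pd.DataFrame,
    activity: pd.DataFrame,
    drug_id: str,
    gene_id: str,
    tissues: pd.Series | None = None,
    tissue_order: list[str] | None = None,
) -> pd.DataFrame:
    """Aligned per-cell-line activity/expression profile for one drug-gene pair.

    Rows are ordered by tissue group (in ``tissue_order`` when given),
    ready for a paired-profile plot; the Pearson correlation recomputed
    from the table equals the pipeline's value for the pair.
    """
    if drug_id not in activity.index:
        raise KeyError(f"unknown drug id {drug_id!r}")
    if gene_id not in expression.index:
        raise KeyError(f"unknown gene id {gene_id!r}")
    cells = list(expression.columns)
    if tissues is None:
        tissues = pd.Series("all", index=cells, name="tissue")
    table = pd.DataFrame({
        "cell_line": cells,
        "tissue": tissues.loc[cells].to_numpy(),
        "activity_z": activity.loc[drug_id, cells].to_numpy(),
        "expression_z": expression.loc[gene_id, cells].to_numpy(),
    })
    order = tissue_order or list(dict.fromkeys(table["tissue"]))
    table["tissue"] = pd.Categorical(table["tissue"], categories=order, ordered=True)
    return table.sort_values(["tissue", "cell_line"], kind="stable").reset_index(drop=True)
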