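"""Full build orchestration: run every analytic stage per dataset,
enumerate the 29 typed bipartite graphs and union them into one
multipartite association network.

Graph indices and their node types:

========  ============================  ===========
index     node types                    edge type
========  ============================  ===========
1         PROBETYPE - SYMBOL            mapping (platform-wide)
2         PROBE - SYMBOL                mapping (analysis probes)
3         PROBE - wgcna                 mapping (module membership)
4         PROBE - PROBE                 correlation (top TOM edges)
5-7       SYMBOL - pathway labels       mapping (3 pathway collections)
8-10      SYMBOL - cellEx               mapping (3 marker collections)
11        wgcna - baylor                enrichment
12-14     baylor - pathway labels       enrichment
15-17     wgcna - pathway labels        enrichment
18-20     baylor - cellEx               enrichment
21-23     wgcna - cellEx                enrichment
24        wgcna - cellprop              correlation (ME ~ proportions)
25-27     CELL - cellEx                 mapping (consensus cell names)
28        CELL - cellprop               mapping
29        wgcna - pheno                 correlation (ME ~ phenotype)
========  ============================  ===========

Stages that lack their annotation inputs are skipped: removing an input
only removes the graphs that depend on it.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import coexpr, deconv, enrichment, pheno_assoc, repertoire
from .diffexp import ContrastSpec, fit_factorial
from .graphstore import AssociationGraph, union
from .ingest import AnnotationBundle, ExpressionSet, PhenoTable, filter_probes, normalize, read_inputs

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "DatasetConfig", "BuildReport", "build_all", "build_dataset", "load_config"]

PATHWAY_LABELS = {"reactome_like": "reactomePW", "curated_like": "PalWangPW", "immune_like": "ImmunePW"}
# per-collection minimum retained enrichment results (curated pathway lists
# are held to a minimum of four, all others to three)
MIN_KEEP = {"curated_like": 4}


@dataclass
class DatasetConfig:
    id: str
    expression: str
    pheno: str
    var_types: dict[str, str]
    class_var: str = "class"
    strat_var: str = "sex"
    contrast: str = "1"  # the "edge" id scoping contrast-level nodes
    coef: str | None = None  # explicit coefficient name; default = class main effect


@dataclass
class Thresholds:
    q_cutoff: float = 0.05
    edge_frac: float = 0.10
    edge_cap: int = 2000
    min_module_size: int = 10
    max_keep: int = 10
    filter_mode: str = "variance"
    filter_q: float = 0.5
    merge_cor: float = 0.75


@dataclass
class RunConfig:
    project: str
    datasets: list[DatasetConfig]
    probe2symbol: str | None = None
    pathways: dict[str, str] = field(default_factory=dict)
    markers: dict[str, str] = field(default_factory=dict)
    predefined: str | None = None
    basis: str | None = None
    cell_name_map: dict[str, str] = field(default_factory=dict)
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [d.id for d in self.datasets]
        if len(ids) != len(set(ids)):
            raise ValueError("dataset ids must be unique")


def load_config(path: str | Path) -> RunConfig:
    """Read the YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    ann = raw.get("annotations", {})
    thr = Thresholds(**raw.get("thresholds", {}))
    datasets = [DatasetConfig(**d) for d in raw["datasets"]]
    return RunConfig(
        project=raw.get("project", "assocnet"),
        datasets=datasets,
        probe2symbol=ann.get("probe2symbol"),
        pathways=ann.get("pathways", {}),
        markers=ann.get("markers", {}),
        predefined=ann.get("predefined"),
        basis=ann.get("basis"),
        cell_name_map=ann.get("cell_name_map", {}),
        thresholds=thr,
        seed=int(raw.get("seed", 0)),
    )


@dataclass
class BuildReport:
    per_dataset: dict[str, dict] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    graph_indices: list[int] = field(default_factory=list)
    edge_types: list[str] = field(default_factory=list)
    n_nodes: int = 0
    n_edges: int = 0
    wall_time_s: float = 0.0

    def summary(self) -> str:
        lines = [f"datasets built: {len(self.per_dataset)}; failed: {len(self.errors)}"]
        for ds, info in self.per_dataset.items():
            lines.append(
                f"  {ds}: {info['n_probes_raw']} probes -> {info['n_probes_filtered']} filtered; "
                f"{info['n_modules']} modules; graphs {sorted(info['graphs'])}"
            )
        for ds, err in self.errors.items():
            lines.append(f"  {ds}: FAILED ({err})")
        lines.append(
            f"union: {self.n_nodes} nodes, {self.n_edges} edges, "
            f"indices {self.graph_indices}, edge types {self.edge_types}"
        )
        lines.append(f"wall time: {self.wall_time_s:.1f} s")
        return "\n".join(lines)


def build_dataset(
    ds: DatasetConfig,
    expr: ExpressionSet,
    pheno: PhenoTable,
    bundle: AnnotationBundle,
    thr: Thresholds,
) -> tuple[AssociationGraph, dict]:
    """All analytics and bipartite graphs for one dataset."""
    g = AssociationGraph()
    info: dict = {"graphs": set(), "warnings": []}
    sq, edge = ds.id, str(ds.contrast)
    cmap = bundle.cell_name_map

    # -- graph 1: platform-wide probe -> symbol map (global nodes)
    if bundle.probe2symbol:
        for probe, symbol in bundle.probe2symbol.items():
            pk = g.merge_node("PROBETYPE", probe)
            skey = g.merge_node("SYMBOL", symbol)
            g.merge_edge(pk, skey, "mapping", graph_index=1)
        info["graphs"].add(1)

    # -- normalize + filter
    norm = normalize(expr)
    filt = filter_probes(norm, mode=thr.filter_mode, q=thr.filter_q, pheno=pheno)
    info["n_probes_raw"] = expr.shape[0]
    info["n_probes_filtered"] = filt.shape[0]

    # -- differential expression
    de = fit_factorial(filt, pheno, ContrastSpec(coef=ds.coef))
    sym_of = bundle.probe2symbol
    universe = {sym_of[p] for p in filt.probe_ids if p in sym_of}

    # -- graph 2: analysis probes -> symbols, probes carry DE properties
    for probe in filt.probe_ids:
        row = de.table.loc[probe]
        pk = g.merge_node(
            "PROBE", probe, sq, edge,
            logfc=float(row["logfc"]), p=float(row["p"]), q=float(row["q"]),
        )
        if probe in sym_of:
            skey = g.merge_node("SYMBOL", sym_of[probe])
            g.merge_edge(pk, skey, "mapping", graph_index=2)
    if sym_of:
        info["graphs"].add(2)

    # -- co-expression modules
    beta = coexpr.pick_soft_power(filt)
    tom = coexpr.tom_matrix(filt, beta)
    assignment = coexpr.detect_modules(
        tom, filt, min_size=thr.min_module_size, merge_cor=thr.merge_cor, soft_power=beta
    )
    modules = assignment.modules()
    info["n_modules"] = len(modules)
    sig_coll = None
    if bundle.marker_collections:
        sig_coll = bundle.marker_collections[sorted(bundle.marker_collections)[0]]
    elif bundle.pathway_collections:
        sig_coll = bundle.pathway_collections[sorted(bundle.pathway_collections)[0]]
    summaries = coexpr.summarize_modules(
        filt, assignment, pheno,
        probe2symbol=sym_of or None,
        signature_collection=sig_coll, universe=universe or None,
    )
    module_symbols = {
        m: {sym_of[p] for p in assignment.members(m) if p in sym_of} for m in modules
    }

    # -- graphs 3 and 4: membership and intra-module connectivity
    for m in modules:
        met = summaries.metrics.loc[m]
        wk = g.merge_node(
            "wgcna", m, sq, edge,
            modAUC1=float(met["modAUC1"]), modAUC2=float(met["modAUC2"]),
            diffME=float(met["diffME"]), sigenrich=float(met["sigenrich"]),
        )
        members = assignment.members(m)
        for probe in members:
            g.merge_edge(("PROBE", probe, sq, edge), wk, "mapping", graph_index=3)
        info["graphs"].add(3)
        if len(members) >= 2:
            for a, b, w in coexpr.select_module_edges(tom, members, thr.edge_frac, thr.edge_cap):
                g.merge_edge(
                    ("PROBE", a, sq, edge), ("PROBE", b, sq, edge),
                    "correlation", graph_index=4, weight=float(w),
                )
            info["graphs"].add(4)

    # -- graphs 5-7: symbol -> pathway mappings (global)
    pathway_order = [r for r in ("reactome_like", "curated_like", "immune_like") if r in bundle.pathway_collections]
    pathway_order += [r for r in sorted(bundle.pathway_collections) if r not in pathway_order]
    for i, role in enumerate(pathway_order[:3]):
        label = PATHWAY_LABELS.get(role, "reactomePW")
        gi = 5 + i
        for pw_name, genes in bundle.pathway_collections[role].items():
            for sym in sorted(genes & universe):
                g.merge_edge(
                    ("SYMBOL", sym, "", ""), g.merge_node(label, pw_name),
                    "mapping", graph_index=gi,
                )
        info["graphs"].add(gi)

    # -- graphs 8-10: symbol -> cell-marker mappings (global)
    marker_order = sorted(bundle.marker_collections)
    for i, coll_name in enumerate(marker_order[:3]):
        gi = 8 + i
        for cell_label, genes in bundle.marker_collections[coll_name].items():
            ck = g.merge_node("cellEx", cell_label)
            for sym in sorted(genes & universe):
                g.merge_edge(("SYMBOL", sym, "", ""), ck, "mapping", graph_index=gi)
        info["graphs"].add(gi)

    # -- pre-defined module repertoire: scores + per-dataset tests
    rep_scores = rep_tests = None
    baylor_symbols = None
    if bundle.predefined_modules:
        rep_scores = repertoire.score_repertoire(de, bundle.predefined_modules, sym_of, thr.q_cutoff)
        rep_tests = repertoire.module_de(
            filt, bundle.predefined_modules, pheno, ContrastSpec(coef=ds.coef), sym_of
        )
        baylor_symbols = {
            name: genes & universe
            for name, genes in bundle.predefined_modules.items()
            if genes & universe
        }
        for name in sorted(baylor_symbols):
            props = {}
            if rep_scores.scores is not None and name in rep_scores.scores.index:
                props["score"] = float(rep_scores.scores.loc[name, "score"])
            if rep_tests.tests is not None and name in rep_tests.tests.index:
                row = rep_tests.tests.loc[name]
                props.update(logfc=float(row["logfc"]), p=float(row["p"]), q=float(row["q"]))
            g.merge_node("baylor", name, sq, edge, **props)

    # -- enrichment graphs
    def add_enrichment(mod_sets, mod_label, coll, coll_label, gi, min_keep):
        res = enrichment.enrich_collection(
            mod_sets, coll, universe,
            q_cutoff=thr.q_cutoff, min_keep=min_keep, max_keep=thr.max_keep,
        )
        for _, row in res.retained().iterrows():
            mk = (mod_label, row["module"], sq, edge)
            tk = g.merge_node(coll_label, row["set"])
            g.merge_edge(
                mk, tk, "enrichment", graph_index=gi,
                p=float(row["p"]), q=float(row["q"]), relaxed=bool(row["relaxed"]),
            )
        info["graphs"].add(gi)
        return res

    if baylor_symbols and module_symbols:
        add_enrichment(module_symbols, "wgcna", baylor_symbols, "baylor", 11, 3)
    for i, role in enumerate(pathway_order[:3]):
        label = PATHWAY_LABELS.get(role, "reactomePW")
        coll = bundle.pathway_collections[role]
        mk = MIN_KEEP.get(role, 3)
        if baylor_symbols:
            add_enrichment(baylor_symbols, "baylor", coll, label, 12 + i, mk)
        if module_symbols:
            add_enrichment(module_symbols, "wgcna", coll, label, 15 + i, mk)
    marker_enrichments: dict[str, enrichment.EnrichmentResult] = {}
    for i, coll_name in enumerate(marker_order[:3]):
        coll = bundle.marker_collections[coll_name]
        if baylor_symbols:
            add_enrichment(baylor_symbols, "baylor", coll, "cellEx", 18 + i, 3)
        if module_symbols:
            marker_enrichments[coll_name] = add_enrichment(
                module_symbols, "wgcna", coll, "cellEx", 21 + i, 3
            )

    # -- deconvolution: graphs 24 (ME ~ proportions) and cellprop nodes
    props = None
    if bundle.basis is not None:
        props = deconv.estimate_proportions(filt, bundle.basis)
        tests = deconv.compare_proportions(props, pheno)
        for cell in props.proportions.columns:
            g.merge_node(
                "cellprop", cmap.get(cell, cell), sq, edge,
                diffP=float(tests.loc[cell, "diffP"]), diffQ=float(tests.loc[cell, "diffQ"]),
            )
        if len(summaries.eigengenes):
            cors = pheno_assoc.correlate_me(
                summaries.eigengenes, props.proportions, q_cutoff=thr.q_cutoff
            )
            for _, row in cors[cors["keep"]].iterrows():
                g.merge_edge(
                    ("wgcna", row["module"], sq, edge),
                    ("cellprop", cmap.get(row["target"], row["target"]), sq, edge),
                    "correlation", graph_index=24,
                    weight=float(row["R"]), p=float(row["p"]), q=float(row["q"]),
                )
            info["graphs"].add(24)

    # -- graphs 25-27: consensus cell names -> collection-specific labels
    for i, coll_name in enumerate(marker_order[:3]):
        gi = 25 + i
        for cell_label in bundle.marker_collections[coll_name]:
            consensus = cmap.get(cell_label, cell_label)
            g.merge_edge(
                g.merge_node("CELL", consensus), ("cellEx", cell_label, "", ""),
                "mapping", graph_index=gi,
            )
        info["graphs"].add(gi)

    # -- graph 28: consensus cell names -> cellprop nodes
    if props is not None:
        for cell in props.proportions.columns:
            consensus = cmap.get(cell, cell)
            g.merge_edge(
                g.merge_node("CELL", consensus), ("cellprop", consensus, sq, edge),
                "mapping", graph_index=28,
            )
        info["graphs"].add(28)

    # -- graph 29: ME ~ encoded phenotype; pheno nodes carry univariate stats
    encoding = pheno_assoc.encode_pheno(pheno)
    uni = pheno_assoc.pheno_univariate(pheno)
    for var in encoding.matrix.columns:
        props_v = {}
        if var in uni.index:
            props_v = {"p": float(uni.loc[var, "p"]), "q": float(uni.loc[var, "q"])}
        g.merge_node("pheno", var, sq, edge, **props_v)
    if len(summaries.eigengenes):
        cors = pheno_assoc.correlate_me(summaries.eigengenes, encoding.matrix, q_cutoff=thr.q_cutoff)
        for _, row in cors[cors["keep"]].iterrows():
            g.merge_edge(
                ("wgcna", row["module"], sq, edge), ("pheno", row["target"], sq, edge),
                "correlation", graph_index=29,
                weight=float(row["R"]), p=float(row["p"]), q=float(row["q"]),
            )
        info["graphs"].add(29)

    info["artifacts"] = {
        "de": de, "assignment": assignment, "summaries": summaries, "tom": tom,
        "proportions": props, "repertoire_scores": rep_scores, "repertoire_tests": rep_tests,
        "marker_enrichments": marker_enrichments, "filtered": filt,
    }
    return g, info


def synthetic_run_config(
    work_dir: str | Path,
    n_datasets: int = 2,
    seed: int = 0,
    thresholds: Thresholds | None = None,
    **synth_kwargs,
) -> RunConfig:
    """Write synthetic fixtures for ``n_datasets`` datasets sharing one
    platform (probe set, signature basis, annotations) and return the
    RunConfig that builds them.

    Dataset ``i`` draws its samples from ``seed + 1000 * (i + 1)`` while
    the platform follows ``seed``, mimicking several cohorts profiled on
    the same array.
    """
    from .synthdata import SynthConfig, write_fixture_files

    work_dir = Path(work_dir)
    datasets = []
    paths0 = None
    for i in range(n_datasets):
        cfg = SynthConfig(seed=seed, sample_seed=seed + 1000 * (i + 1), **synth_kwargs)
        paths = write_fixture_files(work_dir / f"ds{i + 1}", cfg)
        if paths0 is None:
            paths0 = paths
        meta = yaml.safe_load(open(paths["meta"]))
        datasets.append(
            DatasetConfig(
                id=f"ds{i + 1}",
                expression=str(paths["expression"]),
                pheno=str(paths["pheno"]),
                var_types=meta["var_types"],
                class_var=meta["class_var"],
                strat_var=meta["strat_var"],
                contrast="1",
            )
        )
    meta0 = yaml.safe_load(open(paths0["meta"]))
    return RunConfig(
        project="synthetic",
        datasets=datasets,
        probe2symbol=str(paths0["probe2symbol"]),
        pathways={
            role: str(paths0[f"pathways_{role}"])
            for role in ("reactome_like", "curated_like", "immune_like")
        },
        markers={
            name.removeprefix("markers_"): str(paths0[name])
            for name in paths0
            if name.startswith("markers_markers_")
        },
        predefined=str(paths0["predefined"]),
        basis=str(paths0["basis"]),
        cell_name_map=meta0["cell_name_map"],
        thresholds=thresholds or Thresholds(),
        seed=seed,
    )


def write_run_config(config: RunConfig, path: str | Path) -> Path:
    """Serialize a RunConfig back to the YAML schema ``load_config`` reads."""
    from dataclasses import asdict

    raw = {
        "project": config.project,
        "seed": config.seed,
        "annotations": {
            "probe2symbol": config.probe2symbol,
            "pathways": config.pathways,
            "markers": config.markers,
            "predefined": config.predefined,
            "basis": config.basis,
            "cell_name_map": config.cell_name_map,
        },
        "thresholds": asdict(config.thresholds),
        "datasets": [asdict(d) for d in config.datasets],
    }
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
    return path


def _write_stage_outputs(out_dir: Path, ds_id: str, artifacts: dict, bundle: AnnotationBundle) -> None:
    """Per-stage TSV/CSV exports: the topTable analog, module assignment
    with kME, the eigengene matrix, proportions and repertoire scores."""
    from .diffexp import write_de_table

    d = Path(out_dir) / ds_id
    d.mkdir(parents=True, exist_ok=True)
    write_de_table(artifacts["de"], bundle.probe2symbol, d / "diffexp.tsv")
    asg = artifacts["assignment"]
    summaries = artifacts["summaries"]
    table = asg.labels.rename("module").to_frame()
    if summaries.kme is not None:
        kme = [
            summaries.kme.loc[p, m] if m in summaries.kme.columns else float("nan")
            for p, m in asg.labels.items()
        ]
        table["kME"] = kme
    table.to_csv(d / "modules.tsv", sep="\t", index_label="probe")
    summaries.eigengenes.to_csv(d / "eigengenes.csv", index_label="module")
    summaries.metrics.to_csv(d / "module_metrics.csv", index_label="module")
    if artifacts["proportions"] is not None:
        artifacts["proportions"].proportions.to_csv(d / "proportions.csv", index_label="sample")
    rep = artifacts["repertoire_scores"]
    if rep is not None and rep.scores is not None:
        rep.scores.to_csv(d / "repertoire_scores.tsv", sep="\t", index_label="module")


def build_all(
    config: RunConfig, stage_dir: str | Path | None = None
) -> tuple[AssociationGraph, BuildReport]:
    """Run every dataset, union the per-dataset graphs, report counts.

    A fatal error in one dataset is recorded and does not abort the
    others.  ``stage_dir`` optionally receives per-stage TSV/CSV
    exports for each dataset.
    """
    t0 = time.perf_counter()
    report = BuildReport()
    graphs = []
    for ds in config.datasets:
        try:
            expr, pheno, bundle = read_inputs(
                ds.expression, ds.pheno, ds.var_types, ds.class_var, ds.strat_var,
                probe2symbol_path=config.probe2symbol,
                pathway_gmts=config.pathways, marker_gmts=config.markers,
                predefined_gmt=config.predefined, basis_path=config.basis,
                cell_name_map=config.cell_name_map,
            )
            g, info = build_dataset(ds, expr, pheno, bundle, config.thresholds)
            artifacts = info.pop("artifacts", None)
            if stage_dir is not None and artifacts is not None:
                _write_stage_outputs(stage_dir, ds.id, artifacts, bundle)
            info["graphs"] = sorted(info["graphs"])
            report.per_dataset[ds.id] = info
            graphs.append(g)
        except Exception as exc:  # noqa: BLE001 - isolate per-dataset failures
            log.exception("dataset %s failed", ds.id)
            report.errors[ds.id] = str(exc)
    merged = union(graphs)
    report.graph_indices = sorted(merged.graph_indices())
    report.edge_types = sorted(merged.edge_types())
    report.n_nodes = len(merged.nodes)
    report.n_edges = len(merged.edges)
    report.wall_time_s = time.perf_counter() - t0
    return merged, report
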