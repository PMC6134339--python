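"""Virtual cells: attributing co-expression modules to cell types and
summarizing pathway-level activity per cell.

A module is linked to a cell type when both lines of evidence agree:
its eigengene correlates with that cell type's estimated proportion
(BH q < 0.05 over all module x cell pairs in the dataset) AND the
module is enriched for that cell type's marker genes in at least one
retained marker-collection result.  The probes of all modules linked to
a cell form the "virtual cell": a co-expression matrix annotated with
pathway enrichments and per-probe differential expression.  Pathway
activity per (cell, pathway) is the mean log2 fold change of the probes
shared by the virtual cell and the pathway, with up- and down-regulated
contributions kept strictly separate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .coexpr import ModuleAssignment, ModuleSummary
from .deconv import ProportionResult
from .diffexp import DEResult
from .enrichment import EnrichmentResult
from .ingest import ExpressionSet
from .pheno_assoc import correlate_me

__all__ = [
    "VirtualCell",
    "ActivityMatrix",
    "link_modules_to_cells",
    "build_virtual_cell",
    "cell_pathway_activity",
    "rank_activity",
    "meta_cell_compare",
]


@dataclass
class VirtualCell:
    cell: str
    probes: list[str]
    coexpression: pd.DataFrame  # probes x probes Pearson correlation
    pathways: pd.DataFrame  # retained enrichment rows of the linked modules
    de_overlay: pd.DataFrame  # probe -> logfc, q
    modules: list[str] = field(default_factory=list)


@dataclass
class ActivityMatrix:
    """Long-form cell/pathway activity with up and down kept separate.

    Columns: cell_instance, pathway, direction ("up"/"down"), score.
    Up-scores are >= 0 and down-scores <= 0; a (cell, pathway)
    combination with no contributing probes is simply absent.
    """

    table: pd.DataFrame

    def pivot(self, direction: str) -> pd.DataFrame:
        sub = self.table[self.table["direction"] == direction]
        return sub.pivot(index="pathway", columns="cell_instance", values="score")


def link_modules_to_cells(
    summaries: ModuleSummary,
    proportions: ProportionResult,
    marker_enrichments: dict[str, EnrichmentResult],
    cell_name_map: dict[str, str],
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Conjunction rule: ME-proportion correlation AND marker enrichment.

    ``marker_enrichments`` maps collection name -> enrichment of wgcna
    modules against that marker collection; set names are collection-
    specific cell labels resolved to consensus names via
    ``cell_name_map``.  Returns a frame (module, cell, R, cor_q,
    enrich_q) with one row per established link.
    """
    cors = correlate_me(summaries.eigengenes, proportions.proportions, q_cutoff=q_cutoff)
    cor_pass = {
        (row["module"], cell_name_map.get(row["target"], row["target"])): row
        for _, row in cors.iterrows()
        if row["keep"]
    }
    enrich_pass: dict[tuple[str, str], float] = {}
    for res in marker_enrichments.values():
        for _, row in res.retained().iterrows():
            cell = cell_name_map.get(row["set"], row["set"])
            key = (row["module"], cell)
            q = float(row["q"])
            if key not in enrich_pass or q < enrich_pass[key]:
                enrich_pass[key] = q
    rows = []
    for key in sorted(set(cor_pass) & set(enrich_pass)):
        module, cell = key
        rows.append(
            {
                "module": module,
                "cell": cell,
                "R": float(cor_pass[key]["R"]),
                "cor_q": float(cor_pass[key]["q"]),
                "enrich_q": enrich_pass[key],
            }
        )
    return pd.DataFrame(rows, columns=["module", "cell", "R", "cor_q", "enrich_q"])


def build_virtual_cell(
    links: pd.DataFrame,
    assignment: ModuleAssignment,
    expr: ExpressionSet,
    de: DEResult,
    pathway_enrichments: dict[str, EnrichmentResult],
    cell: str,
) -> VirtualCell:
    """Assemble the probe co-expression matrix and annotations for one cell."""
    linked = sorted(links.loc[links["cell"] == cell, "module"].unique())
    if not linked:
        available = sorted(links["cell"].unique())
        raise ValueError(f"no modules linked to cell {cell!r}; available cells: {available}")
    probes = sorted({p for m in linked for p in assignment.members(m)})
    x = expr.values.loc[probes].to_numpy(dtype=float)
    coexpr = pd.DataFrame(np.corrcoef(x), index=probes, columns=probes)
    frames = []
    for res in pathway_enrichments.values():
        ret = res.retained()
        frames.append(ret[ret["module"].isin(linked)])
    pathways = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["module", "set", "q"])
    )
    overlay = de.table.loc[[p for p in probes if p in de.table.index], ["logfc", "q"]]
    return VirtualCell(
        cell=cell, probes=probes, coexpression=coexpr,
        pathways=pathways, de_overlay=overlay, modules=linked,
    )


def cell_pathway_activity(
    vcells: list[VirtualCell],
    pathway_collections: dict[str, dict[str, set[str]]],
    de: DEResult,
    probe2symbol: dict[str, str],
    instance_prefix: str = "",
    q_threshold: float | None = None,
) -> ActivityMatrix:
    """Mean log2 fold change per (virtual cell, pathway), split by sign.

    All probes in the intersection contribute by default;
    ``q_threshold`` optionally restricts to probes with DE q below it.
    ``instance_prefix`` is prepended to the cell name to form the
    cell-instance label ([condition]_[dataset]_[comparison]_... style).
    """
    rows = []
    for vc in vcells:
        instance = f"{instance_prefix}{vc.cell}"
        vc_probes = [p for p in vc.probes if p in de.table.index]
        if q_threshold is not None:
            vc_probes = [p for p in vc_probes if de.table.loc[p, "q"] < q_threshold]
        vc_symbols = {p: probe2symbol.get(p) for p in vc_probes}
        for coll in sorted(pathway_collections):
            for pw in sorted(pathway_collections[coll]):
                genes = pathway_collections[coll][pw]
                probes = [p for p in vc_probes if vc_symbols[p] in genes]
                if not probes:
                    continue
                lfc = de.table.loc[probes, "logfc"].to_numpy()
                up = lfc[lfc > 0]
                down = lfc[lfc < 0]
                if up.size:
                    rows.append(
                        {"cell_instance": instance, "pathway": pw,
                         "direction": "up", "score": float(up.mean())}
                    )
                if down.size:
                    rows.append(
                        {"cell_instance": instance, "pathway": pw,
                         "direction": "down", "score": float(down.mean())}
                    )
    return ActivityMatrix(
        table=pd.DataFrame(rows, columns=["cell_instance", "pathway", "direction", "score"])
    )


def rank_activity(matrix: ActivityMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pathway scores = row sums, cell scores = column sums, signs separate.

    Returns (pathway ranking, cell ranking), each a frame with up/down
    sum columns sorted by total absolute activity descending with
    deterministic name tie-breaks.
    """
    t = matrix.table
    if not len(t):
        raise ValueError("empty activity matrix")

    def agg(group_col: str) -> pd.DataFrame:
        up = t[t["direction"] == "up"].groupby(group_col)["score"].sum()
        down = t[t["direction"] == "down"].groupby(group_col)["score"].sum()
        out = pd.DataFrame({"up": up, "down": down}).fillna(0.0)
        out["total_abs"] = out["up"].abs() + out["down"].abs()
        # stable sort after sorting the index -> deterministic name tie-break
        out = out.sort_index().sort_values("total_abs", ascending=False, kind="mergesort")
        return out

    pathway_rank = agg("pathway")
    cell_rank = agg("cell_instance")
    return pathway_rank, cell_rank


def meta_cell_compare(
    matrices: dict[str, ActivityMatrix],
    cell_filter: str = "",
) -> pd.DataFrame:
    """Cross-dataset comparison of cell-instance activity profiles.

    Collects every cell instance whose label contains ``cell_filter``
    across datasets (instance labels are prefixed with the dataset id),
    builds the pathways x instances matrix of net scores (up + down) and
    orders columns by average-linkage hierarchical clustering with
    Euclidean distance.  Combinations absent from a dataset are treated
    as 0 inside the clustering distance only.
    """
    if len(matrices) < 2:
        raise ValueError("meta-comparison needs >= 2 datasets")
    cols: dict[str, pd.Series] = {}
    for ds in sorted(matrices):
        t = matrices[ds].table
        for inst in sorted(t["cell_instance"].unique()):
            label = f"{ds}_{inst}"
            if cell_filter and cell_filter not in label:
                continue
            sub = t[t["cell_instance"] == inst]
            net = sub.groupby("pathway")["score"].sum()
            cols[label] = net
    if not cols:
        raise ValueError(f"cell filter {cell_filter!r} matches no cell instance")
    mat = pd.DataFrame(cols)
    filled = mat.fillna(0.0)
    if mat.shape[1] > 2:
        link = hierarchy.linkage(pdist(filled.to_numpy().T), method="average")
        order = hierarchy.leaves_list(link)
        mat = mat.iloc[:, order]
    return mat
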