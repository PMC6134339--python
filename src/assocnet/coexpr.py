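"""Weighted co-expression network analysis: soft power, topological
overlap, module detection, eigengenes and module metrics.

The network is unsigned: adjacency a_ij = |cor(x_i, x_j)|^beta with the
diagonal zeroed.  The topological overlap matrix combines direct
adjacency with shared neighbours,

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

with unit diagonal.  Modules are branches of the average-linkage tree of
1 - TOM obtained by a static cut, filtered by minimum size, and merged
iteratively while any two module eigengenes correlate above a threshold.
Module labels follow the conventional colour sequence in decreasing size
order; "grey" collects unassigned probes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .ingest import ExpressionSet, PhenoTable

log = logging.getLogger(__name__)

__all__ = [
    "COLOR_SEQUENCE",
    "ModuleAssignment",
    "ModuleSummary",
    "pick_soft_power",
    "tom_matrix",
    "detect_modules",
    "module_eigengene",
    "module_auc",
    "module_metrics",
    "select_module_edges",
    "summarize_modules",
]

COLOR_SEQUENCE = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]


@dataclass
class ModuleAssignment:
    labels: pd.Series  # probe -> module colour ("grey" = unassigned)
    soft_power: int
    merge_height: float  # ME-merge correlation threshold used

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def modules(self) -> list[str]:
        """Non-grey module labels in canonical (size-rank) order."""
        sizes = self.labels[self.labels != "grey"].value_counts()
        return sorted(sizes.index, key=lambda c: COLOR_SEQUENCE.index(c) if c in COLOR_SEQUENCE else 999)


@dataclass
class ModuleSummary:
    """Per-module eigengene and metrics."""

    eigengenes: pd.DataFrame  # modules x samples, unit-norm rows
    metrics: pd.DataFrame  # index module; columns modAUC1, modAUC2, diffME, sigenrich
    kme: pd.DataFrame = field(default=None)  # probes x modules correlation with ME


def _abs_corr(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = int(np.sum(sd == 0))
        raise ValueError(f"{bad} constant probe(s): filter before network construction")
    return np.abs(np.corrcoef(x))


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log10 p(k) ~ log10 k regression over binned connectivity."""
    k = np.asarray(connectivity, dtype=float)
    if np.allclose(k, k[0]):
        return np.nan
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_p = [], []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        kmean = k[mask].mean()
        freq = mask.mean()
        if kmean > 0 and freq > 0:
            log_k.append(np.log10(kmean))
            log_p.append(np.log10(freq))
    if len(log_k) < 3:
        return np.nan
    log_k, log_p = np.array(log_k), np.array(log_p)
    slope, intercept = np.polyfit(log_k, log_p, 1)
    fitted = slope * log_k + intercept
    ss_res = ((log_p - fitted) ** 2).sum()
    ss_tot = ((log_p - log_p.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return -r2 if slope > 0 else r2


def pick_soft_power(
    expr: ExpressionSet,
    powers: range = range(1, 21),
    target_r2: float = 0.8,
    default: int = 6,
) -> int:
    """Smallest power whose scale-free topology fit reaches the target R^2."""
    x = expr.values.to_numpy(dtype=float)
    if x.shape[0] < 20 or x.shape[1] < 8:
        raise ValueError("need >= 20 probes and >= 8 samples to pick a soft power")
    corr = _abs_corr(x)
    np.fill_diagonal(corr, 0.0)
    for beta in powers:
        k = (corr**beta).sum(axis=1)
        r2 = scale_free_fit(k)
        if np.isnan(r2):
            warnings.warn("degenerate connectivity; using default soft power", stacklevel=2)
            return default
        if r2 >= target_r2:
            return int(beta)
    warnings.warn(f"no power reached scale-free R^2 {target_r2}; using default {default}", stacklevel=2)
    return default


def tom_matrix(expr: ExpressionSet, beta: int) -> pd.DataFrame:
    """Topological overlap matrix of the unsigned soft-threshold network."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    x = expr.values.to_numpy(dtype=float)
    a = _abs_corr(x) ** beta
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    numer = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)  # symmetrize against roundoff
    return pd.DataFrame(tom, index=expr.values.index, columns=expr.values.index)


def module_eigengene(expr: ExpressionSet, members: list[str]) -> pd.Series:
    """First right-singular vector of the standardized member matrix.

    Unit norm; the sign is oriented so the eigengene correlates
    non-negatively with the mean standardized member profile.
    Zero-variance members are dropped with a warning.
    """
    if len(members) < 2:
        raise ValueError("module eigengene needs >= 2 members")
    sub = expr.values.loc[members].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=1)
    if np.any(sd == 0):
        warnings.warn(f"dropping {int((sd == 0).sum())} zero-variance member(s)", stacklevel=2)
        sub = sub[sd > 0]
        if sub.shape[0] < 2:
            raise ValueError("too few non-constant members for an eigengene")
        sd = sd[sd > 0]
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    mean_profile = z.mean(axis=0)
    if np.corrcoef(me, mean_profile)[0, 1] < 0:
        me = -me
    me = me / np.linalg.norm(me)
    return pd.Series(me, index=expr.values.columns)


def eigengene_variance_explained(expr: ExpressionSet, members: list[str]) -> float:
    sub = expr.values.loc[members].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=1)
    sub = sub[sd > 0]
    z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, ddof=1)[:, None]
    s = np.linalg.svd(z, compute_uv=False)
    return float(s[0] ** 2 / (s**2).sum())


def _eigengene_matrix(expr: ExpressionSet, labels: pd.Series) -> pd.DataFrame:
    mods = [m for m in labels.unique() if m != "grey"]
    rows = {}
    for m in sorted(mods):
        members = list(labels.index[labels == m])
        if len(members) >= 2:
            rows[m] = module_eigengene(expr, members)
    return pd.DataFrame(rows).T


def detect_modules(
    tom: pd.DataFrame,
    expr: ExpressionSet,
    min_size: int = 30,
    cut_height: float | None = None,
    merge_cor: float = 0.75,
    soft_power: int = 6,
) -> ModuleAssignment:
    """Static-cut module detection on the TOM dendrogram with ME merging.

    Average-linkage clustering of 1 - TOM; the tree is cut at
    ``cut_height`` (default 0.99 x the maximum merge height); branches
    smaller than ``min_size`` go grey; modules whose eigengenes
    correlate at or above ``merge_cor`` are merged iteratively until no
    pair qualifies.  Labels are colours in decreasing module size.
    """
    probes = list(tom.index)
    d = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    max_h = link[:, 2].max() if len(link) else 0.0
    height = cut_height if cut_height is not None else 0.99 * max_h
    raw = hierarchy.fcluster(link, t=height, criterion="distance")

    labels = pd.Series("grey", index=pd.Index(probes))
    sizes = pd.Series(raw).value_counts()
    kept = [c for c in sizes.index if sizes[c] >= min_size]
    for cid in kept:
        labels.iloc[np.nonzero(raw == cid)[0]] = f"M{cid}"

    if not kept:
        warnings.warn("no module reached the minimum size; all probes grey", stacklevel=2)
        return ModuleAssignment(labels=labels, soft_power=soft_power, merge_height=merge_cor)

    # iterative eigengene merge
    while True:
        mes = _eigengene_matrix(expr, labels)
        mods = list(mes.index)
        if len(mods) < 2:
            break
        cors = np.corrcoef(mes.to_numpy())
        best, best_val = None, merge_cor
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                if cors[i, j] >= best_val:
                    best, best_val = (mods[i], mods[j]), cors[i, j]
        if best is None:
            break
        a, b = best
        labels[labels == b] = a
        log.info("merged modules %s <- %s (ME cor %.3f)", a, b, best_val)

    final_sizes = labels[labels != "grey"].value_counts()
    colour_of = {m: COLOR_SEQUENCE[i % len(COLOR_SEQUENCE)] for i, m in enumerate(final_sizes.index)}
    labels = labels.map(lambda m: colour_of.get(m, "grey"))
    return ModuleAssignment(labels=labels, soft_power=soft_power, merge_height=merge_cor)


def module_auc(me: pd.Series, classes: pd.Series) -> float:
    """AUC of the eigengene as a score for the non-reference class level.

    Rank-statistic (Mann-Whitney) formulation; ties contribute 1/2.
    Reported unflipped, so values below 0.5 indicate the opposite
    direction of separation.
    """
    from .diffexp import ordered_levels

    levels = ordered_levels(classes)
    if len(levels) != 2:
        raise ValueError("AUC needs a binary class variable")
    y = (classes.astype(str) == levels[1]).to_numpy()
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("a class level has zero samples")
    from scipy.stats import rankdata

    ranks = rankdata(me.to_numpy())
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def module_metrics(
    me: pd.Series,
    pheno: PhenoTable,
    member_symbols: set[str] | None = None,
    signature_collection: dict[str, set[str]] | None = None,
    universe: set[str] | None = None,
) -> dict[str, float]:
    """modAUC1 (class), modAUC2 (strat), diffME and sigenrich for one module.

    diffME is the difference of median eigengene values, case minus
    control (non-reference minus reference level).  sigenrich is
    -log10 of the smallest BH q over hypergeometric tests of the module
    against the designated signature collection (0.0 if no collection
    is supplied or no test is possible).
    """
    classes = pheno.data[pheno.class_var].astype(str)
    strat = pheno.data[pheno.strat_var].astype(str)
    me = me.loc[pheno.sample_ids]
    from .diffexp import ordered_levels

    auc1 = module_auc(me, classes)
    auc2 = module_auc(me, strat)
    levels = ordered_levels(classes)  # case minus control
    diff_me = float(me[classes == levels[1]].median() - me[classes == levels[0]].median())

    sigenrich = 0.0
    if signature_collection and member_symbols and universe:
        from .enrichment import enrich_sets

        res = enrich_sets(member_symbols, signature_collection, universe)
        if len(res):
            qmin = max(float(res["q"].min()), 1e-300)
            sigenrich = -np.log10(qmin)
    return {"modAUC1": auc1, "modAUC2": auc2, "diffME": diff_me, "sigenrich": sigenrich}


def select_module_edges(
    tom: pd.DataFrame,
    members: list[str],
    frac: float = 0.10,
    cap: int = 2000,
) -> list[tuple[str, str, float]]:
    """Top intra-module edges by topological overlap.

    Retains n = min(cap, max(1, ceil(frac * #pairs))) edges, ranked by
    TOM descending with deterministic lexicographic tie-breaks.
    """
    if len(members) < 2:
        raise ValueError("module must have >= 2 members")
    members = sorted(members)
    sub = tom.loc[members, members].to_numpy(dtype=float)
    pairs = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            pairs.append((-sub[i, j], members[i], members[j]))
    pairs.sort()
    n_pairs = len(pairs)
    n_keep = min(cap, max(1, int(np.ceil(frac * n_pairs))))
    return [(a, b, -negw) for negw, a, b in pairs[:n_keep]]


def summarize_modules(
    expr: ExpressionSet,
    assignment: ModuleAssignment,
    pheno: PhenoTable,
    probe2symbol: dict[str, str] | None = None,
    signature_collection: dict[str, set[str]] | None = None,
    universe: set[str] | None = None,
) -> ModuleSummary:
    """Eigengenes, kME and metrics for every non-grey module."""
    mes = {}
    metrics = {}
    for mod in assignment.modules():
        members = assignment.members(mod)
        me = module_eigengene(expr, members)
        mes[mod] = me
        symbols = None
        if probe2symbol is not None:
            symbols = {probe2symbol[p] for p in members if p in probe2symbol}
        metrics[mod] = module_metrics(
            me, pheno, member_symbols=symbols,
            signature_collection=signature_collection, universe=universe,
        )
    me_df = pd.DataFrame(mes).T
    metrics_df = pd.DataFrame(metrics).T
    # kME: correlation of every probe with every module eigengene
    x = expr.values.to_numpy(dtype=float)
    kme = None
    if len(me_df):
        z = (x - x.mean(axis=1, keepdims=True))
        zsd = z.std(axis=1, ddof=1)
        zsd[zsd == 0] = np.inf
        z = z / zsd[:, None]
        m = me_df.to_numpy()
        mz = (m - m.mean(axis=1, keepdims=True)) / m.std(axis=1, ddof=1)[:, None]
        kme_vals = (z @ mz.T) / (x.shape[1] - 1)
        kme = pd.DataFrame(kme_vals, index=expr.values.index, columns=me_df.index)
    return ModuleSummary(eigengenes=me_df, metrics=metrics_df, kme=kme)
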