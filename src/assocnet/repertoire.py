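"""Pre-defined transcriptional module ("repertoire") analysis.

A fixed module repertoire (name -> gene-symbol set, read from GMT, the
same across datasets) is scored per contrast as

    score = pct_up - pct_down in [-100, 100],

where pct_up / pct_down are the percentages of member probes with
BH q below a threshold and positive / negative log fold change.  Module
differential expression summarizes each module to the mean log2
expression of its mapped probes per sample and applies the same
factorial moderated-t machinery used for probes.  Because module
composition is identical across datasets, the score matrix supports
direct meta-analysis: the consistent subset is the modules with the
same nonzero score sign in every dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .diffexp import ContrastSpec, DEResult, bh_adjust, fit_factorial
from .ingest import ExpressionSet, PhenoTable

__all__ = ["RepertoireResult", "score_repertoire", "module_de", "meta_repertoire"]


@dataclass
class RepertoireResult:
    scores: pd.DataFrame | None = None  # index module; pct_up, pct_down, score, n_probes
    tests: pd.DataFrame | None = None  # index module; logfc, t, p, q


def _map_members(defs: dict[str, set[str]], probe2symbol: dict[str, str], probes) -> dict[str, list[str]]:
    probe_set = list(probes)
    sym_of = {p: probe2symbol.get(p) for p in probe_set}
    return {
        name: [p for p in probe_set if sym_of[p] in symbols]
        for name, symbols in defs.items()
    }


def score_repertoire(
    de: DEResult,
    defs: dict[str, set[str]],
    probe2symbol: dict[str, str],
    q_cutoff: float = 0.05,
) -> RepertoireResult:
    """Percent-up minus percent-down of significantly changed member probes.

    Modules with no mapped probes are excluded (their score is
    undefined, not zero).
    """
    if not defs:
        raise ValueError("empty module definition set")
    members = _map_members(defs, probe2symbol, de.table.index)
    rows = {}
    for name in sorted(defs):
        probes = members[name]
        if not probes:
            continue
        sub = de.table.loc[probes]
        sig = sub["q"] < q_cutoff
        n = len(probes)
        pct_up = 100.0 * (sig & (sub["logfc"] > 0)).sum() / n
        pct_down = 100.0 * (sig & (sub["logfc"] < 0)).sum() / n
        rows[name] = {
            "pct_up": pct_up,
            "pct_down": pct_down,
            "score": pct_up - pct_down,
            "n_probes": n,
        }
    return RepertoireResult(scores=pd.DataFrame(rows).T)


def module_de(
    expr: ExpressionSet,
    defs: dict[str, set[str]],
    pheno: PhenoTable,
    spec: ContrastSpec | None = None,
    probe2symbol: dict[str, str] | None = None,
) -> RepertoireResult:
    """Moderated factorial test on per-module mean-expression summaries."""
    if not defs:
        raise ValueError("empty module definition set")
    probe2symbol = probe2symbol or {}
    members = _map_members(defs, probe2symbol, expr.probe_ids)
    summaries = {}
    for name in sorted(defs):
        probes = members[name]
        if probes:
            summaries[name] = expr.values.loc[probes].mean(axis=0)
    if not summaries:
        raise ValueError("no module maps to any probe on the array")
    summary_expr = ExpressionSet(values=pd.DataFrame(summaries).T, normalized=True)
    de = fit_factorial(summary_expr, pheno, spec)
    tests = de.table[["logfc", "t", "p", "q"]].copy()
    return RepertoireResult(tests=tests)


def meta_repertoire(
    results: dict[str, RepertoireResult],
) -> tuple[pd.DataFrame, list[str]]:
    """Score matrix (modules x datasets) and the direction-consistent subset.

    All datasets must have been scored against the same definition set.
    The consistent subset is the modules whose scores are nonzero and
    share the same sign in every dataset.  Rows are returned in
    average-linkage cluster order for plotting.
    """
    if len(results) < 2:
        raise ValueError("meta-analysis needs >= 2 datasets")
    frames = {ds: r.scores["score"] for ds, r in results.items()}
    keysets = [frozenset(s.index) for s in frames.values()]
    if len(set(keysets)) != 1:
        raise ValueError("mismatched module definition sets across datasets")
    matrix = pd.DataFrame(frames)
    consistent = [
        m
        for m in matrix.index
        if (matrix.loc[m] > 0).all() or (matrix.loc[m] < 0).all()
    ]
    if len(matrix) > 2:
        link = hierarchy.linkage(pdist(matrix.to_numpy()), method="average")
        order = hierarchy.leaves_list(link)
        matrix = matrix.iloc[order]
    return matrix, consistent
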