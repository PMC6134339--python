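"""Cell-type deconvolution by constrained least squares.

Bulk expression is modelled as a non-negative mixture of cell-type
reference profiles on the linear intensity scale.  Per sample the
mixing weights are the non-negative least-squares solution of
``basis @ w ~= sample`` over the probes shared between the basis and
the array, renormalized to the unit simplex.  Between-class proportion
differences are tested non-parametrically per cell type (Wilcoxon
rank-sum for two classes, Kruskal-Wallis beyond), BH-corrected across
cell types: the diffP / diffQ properties of the cellprop nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .diffexp import bh_adjust
from .ingest import ExpressionSet, PhenoTable

__all__ = ["ProportionResult", "estimate_proportions", "compare_proportions"]


@dataclass
class ProportionResult:
    proportions: pd.DataFrame  # samples x cell types, simplex rows
    tests: pd.DataFrame | None = None  # index cell type; columns diffP, diffQ


def estimate_proportions(expr: ExpressionSet, basis: pd.DataFrame) -> ProportionResult:
    """NNLS mixture weights per sample, renormalized to sum to one.

    ``basis`` is marker probes x cell types on the linear scale.  If the
    expression set is normalized (log2), intensities are restored with
    2**x - 1 before fitting.  Requires at least half the basis probes on
    the array and >= 2 shared probes per cell type.
    """
    if basis.shape[1] < 2:
        raise ValueError("signature basis needs >= 2 cell types")
    shared = [p for p in basis.index if p in set(expr.probe_ids)]
    if len(shared) < 0.5 * len(basis.index):
        raise ValueError(
            f"only {len(shared)}/{len(basis.index)} basis probes present in expression"
        )
    if len(shared) < 2 * basis.shape[1]:
        raise ValueError("fewer than 2 shared probes per cell type")
    A = basis.loc[shared].to_numpy(dtype=float)
    x = expr.values.loc[shared].to_numpy(dtype=float)
    if expr.normalized:
        x = np.power(2.0, x) - 1.0
    props = np.zeros((x.shape[1], basis.shape[1]))
    for j in range(x.shape[1]):
        w, _ = optimize.nnls(A, x[:, j])
        total = w.sum()
        if total <= 0:
            warnings.warn(
                f"all-zero mixture solution for sample {expr.sample_ids[j]!r}; "
                "falling back to uniform proportions",
                stacklevel=2,
            )
            props[j] = 1.0 / basis.shape[1]
        else:
            props[j] = w / total
    df = pd.DataFrame(props, index=expr.sample_ids, columns=list(basis.columns))
    return ProportionResult(proportions=df)


def compare_proportions(
    props: ProportionResult | pd.DataFrame,
    pheno: PhenoTable,
    class_var: str | None = None,
) -> pd.DataFrame:
    """Per-cell-type non-parametric class comparison.

    Two class levels: two-sided Wilcoxon rank-sum; more: Kruskal-Wallis.
    Returns a frame indexed by cell type with diffP (uncorrected) and
    diffQ (BH across cell types).
    """
    p_df = props.proportions if isinstance(props, ProportionResult) else props
    class_var = class_var or pheno.class_var
    classes = pheno.data[class_var].astype(str)
    levels = sorted(classes.unique())
    groups_idx = [classes.index[classes == lv] for lv in levels]
    if any(len(g) < 2 for g in groups_idx):
        raise ValueError("each class level needs >= 2 samples")
    pvals = {}
    for cell in p_df.columns:
        samples = [p_df.loc[g, cell].to_numpy() for g in groups_idx]
        if np.ptp(np.concatenate(samples)) == 0:  # fully tied data carries no evidence
            pvals[cell] = 1.0
        elif len(levels) == 2:
            stat = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
            pvals[cell] = float(stat.pvalue)
        else:
            stat = stats.kruskal(*samples)
            pvals[cell] = float(stat.pvalue)
    out = pd.DataFrame({"diffP": pd.Series(pvals)})
    out["diffQ"] = bh_adjust(out["diffP"].to_numpy())
    return out
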