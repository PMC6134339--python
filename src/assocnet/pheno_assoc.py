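"""Phenotype encoding, univariate tests and eigengene correlations.

Categorical phenotype variables are encoded as integers in alphabetical
level order (identifiers are never encoded; constant variables are
dropped).  Module eigengenes are correlated against the encoded
phenotype matrix or estimated cell proportions (Pearson by default,
Spearman optional); p-values are BH-corrected over all (module, target)
pairs in the family and edges are kept at q < 0.05 with the correlation
coefficient as edge weight.  Univariate phenotype screening tests each
variable against the class: rank-sum for numeric, Fisher exact for
categorical.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust
from .ingest import PhenoTable

log = logging.getLogger(__name__)

__all__ = ["PhenoEncoding", "encode_pheno", "correlate_me", "pheno_univariate"]


@dataclass
class PhenoEncoding:
    matrix: pd.DataFrame  # samples x encoded variables
    level_orders: dict[str, list[str]] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)


def encode_pheno(pheno: PhenoTable) -> PhenoEncoding:
    """Numeric passthrough; categorical -> alphabetical-order integer codes."""
    cols = {}
    orders: dict[str, list[str]] = {}
    excluded: list[str] = []
    for var in pheno.data.columns:
        vtype = pheno.var_types.get(var, "categorical")
        if vtype == "identifier":
            excluded.append(var)
            continue
        series = pheno.data[var]
        if series.nunique(dropna=True) < 2:
            warnings.warn(f"constant phenotype variable {var!r} dropped", stacklevel=2)
            excluded.append(var)
            continue
        if vtype == "numeric":
            cols[var] = pd.to_numeric(series)
        else:
            levels = sorted(series.astype(str).unique())
            orders[var] = levels
            cols[var] = series.astype(str).map({lv: i for i, lv in enumerate(levels)}).astype(float)
    return PhenoEncoding(matrix=pd.DataFrame(cols, index=pheno.data.index),
                         level_orders=orders, excluded=excluded)


def correlate_me(
    me_matrix: pd.DataFrame,
    targets: pd.DataFrame,
    method: str = "pearson",
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Correlate every module eigengene with every target column.

    ``me_matrix`` is modules x samples; ``targets`` samples x variables
    (encoded phenotype or cell proportions).  Returns the long-form
    edge table (module, target, R, p, q, keep) with BH over the whole
    family; zero-variance targets are skipped.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    samples = [s for s in me_matrix.columns if s in targets.index]
    if len(samples) < 4:
        raise ValueError("need >= 4 paired observations")
    rows = []
    for mod in me_matrix.index:
        me = me_matrix.loc[mod, samples].to_numpy(dtype=float)
        for var in targets.columns:
            y = targets.loc[samples, var].to_numpy(dtype=float)
            ok = ~np.isnan(y)
            if ok.sum() < 4 or np.ptp(y[ok]) == 0:
                log.info("skipping zero-variance/short target %r", var)
                continue
            if method == "pearson":
                r, p = stats.pearsonr(me[ok], y[ok])
            else:
                r, p = stats.spearmanr(me[ok], y[ok])
            rows.append({"module": mod, "target": var, "R": float(r), "p": float(p)})
    out = pd.DataFrame(rows, columns=["module", "target", "R", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["keep"] = out["q"] < q_cutoff if len(out) else []
    return out


def pheno_univariate(pheno: PhenoTable, class_var: str | None = None) -> pd.DataFrame:
    """Screen every phenotype variable against the class.

    Numeric variables: two-sided Wilcoxon rank-sum between the two class
    levels.  Categorical variables: Fisher exact (2 levels) or chi-square
    on the contingency table.  Degenerate tables yield p = 1 with a
    warning.  BH across variables.
    """
    class_var = class_var or pheno.class_var
    classes = pheno.data[class_var].astype(str)
    levels = sorted(classes.unique())
    if len(levels) != 2:
        raise ValueError("univariate screening needs a binary class")
    rows = {}
    for var in pheno.data.columns:
        if var == class_var or pheno.var_types.get(var) == "identifier":
            continue
        series = pheno.data[var]
        if pheno.var_types.get(var) == "numeric":
            a = pd.to_numeric(series[classes == levels[0]]).dropna()
            b = pd.to_numeric(series[classes == levels[1]]).dropna()
            if len(a) < 2 or len(b) < 2 or np.ptp(np.concatenate([a, b])) == 0:
                warnings.warn(f"degenerate numeric variable {var!r}: p set to 1", stacklevel=2)
                rows[var] = 1.0
            else:
                rows[var] = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        else:
            table = pd.crosstab(series.astype(str), classes)
            if table.shape[0] < 2 or table.shape[1] < 2:
                warnings.warn(f"degenerate contingency table for {var!r}: p set to 1", stacklevel=2)
                rows[var] = 1.0
            elif table.shape == (2, 2):
                rows[var] = float(stats.fisher_exact(table.to_numpy())[1])
            else:
                rows[var] = float(stats.chi2_contingency(table.to_numpy())[1])
    out = pd.DataFrame({"p": pd.Series(rows)})
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out
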