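"""Input parsing, normalization and probe filtering.

The pipeline consumes four kinds of files: a non-normalised expression
matrix (probes x samples, TSV), a phenotype table (samples x variables,
CSV), gene-set collections in GMT format, and a deconvolution signature
basis (CSV).  This module reads them into the package's in-memory
containers, aligns expression and phenotype on shared sample ids,
normalizes intensities (log2 followed by quantile normalization) and
filters uninformative probes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionSet",
    "PhenoTable",
    "AnnotationBundle",
    "read_expression",
    "read_pheno",
    "read_gmt",
    "write_gmt",
    "read_inputs",
    "normalize",
    "filter_probes",
]


@dataclass
class ExpressionSet:
    """A probes x samples intensity matrix.

    ``values`` holds raw linear intensities before normalization and
    log2-scale intensities afterwards; ``normalized`` records which.
    """

    values: pd.DataFrame  # probes x samples
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate probe id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class PhenoTable:
    """Per-sample phenotype variables with declared types.

    ``var_types`` maps each variable name to one of ``categorical``,
    ``numeric`` or ``identifier``.  ``class_var`` is the primary contrast
    (e.g. disease class) and ``strat_var`` the second stratification
    factor (e.g. sex).
    """

    data: pd.DataFrame  # samples x variables, index = sample ids
    var_types: dict[str, str]
    class_var: str
    strat_var: str

    def __post_init__(self) -> None:
        for var in (self.class_var, self.strat_var):
            if var not in self.data.columns:
                raise ValueError(f"phenotype variable {var!r} not present")
            if self.var_types.get(var) != "categorical":
                raise ValueError(f"{var!r} must be declared categorical")
            if self.data[var].nunique() < 2:
                raise ValueError(f"{var!r} needs >= 2 levels")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def levels(self, var: str) -> list[str]:
        return sorted(self.data[var].astype(str).unique())


@dataclass
class AnnotationBundle:
    """Prior-knowledge fixtures used across the pipeline.

    Three pathway collections (Reactome-like, curated-pathway-like,
    immune-like), three cell-marker collections, a pre-defined module
    repertoire, a probe-to-symbol map, a deconvolution signature basis
    and the consensus cell-name map covering every collection-specific
    cell label.
    """

    probe2symbol: dict[str, str]
    pathway_collections: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    marker_collections: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    predefined_modules: dict[str, set[str]] = field(default_factory=dict)
    basis: pd.DataFrame | None = None  # probes x cell types, linear scale
    cell_name_map: dict[str, str] = field(default_factory=dict)


def read_expression(path: str | Path) -> ExpressionSet:
    """Read a probes x samples TSV (first column probe ids, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionSet(values=df.astype(float), normalized=False)


def read_pheno(
    path: str | Path,
    var_types: dict[str, str],
    class_var: str,
    strat_var: str,
) -> PhenoTable:
    """Read a samples x variables CSV (first column sample ids)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return PhenoTable(data=df, var_types=dict(var_types), class_var=class_var, strat_var=strat_var)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file: tab-separated lines of name, description, genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: unparseable GMT line {lineno} (needs >= 3 fields)")
            name = fields[0]
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise ValueError(f"{path}: GMT line {lineno} has no genes")
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sets:
            genes = sorted(sets[name])
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_probe2symbol(path: str | Path) -> dict[str, str]:
    """Two-column TSV probe_id -> symbol; each probe maps to at most one symbol."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    probes = df.iloc[:, 0]
    if probes.duplicated().any():
        dup = probes[probes.duplicated()].iloc[0]
        raise ValueError(f"duplicate probe id in probe2symbol: {dup!r}")
    return dict(zip(probes, df.iloc[:, 1]))


def read_basis(path: str | Path) -> pd.DataFrame:
    basis = pd.read_csv(path, index_col=0)
    basis.index = basis.index.astype(str)
    return basis.astype(float)


def read_inputs(
    expression_path: str | Path,
    pheno_path: str | Path,
    var_types: dict[str, str],
    class_var: str,
    strat_var: str,
    probe2symbol_path: str | Path | None = None,
    pathway_gmts: dict[str, str | Path] | None = None,
    marker_gmts: dict[str, str | Path] | None = None,
    predefined_gmt: str | Path | None = None,
    basis_path: str | Path | None = None,
    cell_name_map: dict[str, str] | None = None,
) -> tuple[ExpressionSet, PhenoTable, AnnotationBundle]:
    """Read all inputs and align expression/phenotype on shared samples.

    Sample order follows the expression file; samples present in only one
    of the two files are dropped with a warning.  An empty intersection
    is fatal.
    """
    expr = read_expression(expression_path)
    pheno = read_pheno(pheno_path, var_types, class_var, strat_var)

    shared = [s for s in expr.sample_ids if s in set(pheno.sample_ids)]
    if not shared:
        raise ValueError("no shared samples between expression and phenotype")
    n_dropped = (len(expr.sample_ids) - len(shared)) + (len(pheno.sample_ids) - len(shared))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} unmatched sample(s) during alignment", stacklevel=2)
        log.info("alignment dropped %d sample(s)", n_dropped)
    expr = ExpressionSet(values=expr.values.loc[:, shared], normalized=expr.normalized)
    pheno = PhenoTable(
        data=pheno.data.loc[shared],
        var_types=pheno.var_types,
        class_var=pheno.class_var,
        strat_var=pheno.strat_var,
    )

    probe2symbol = read_probe2symbol(probe2symbol_path) if probe2symbol_path else {}
    bundle = AnnotationBundle(
        probe2symbol=probe2symbol,
        pathway_collections={k: read_gmt(v) for k, v in (pathway_gmts or {}).items()},
        marker_collections={k: read_gmt(v) for k, v in (marker_gmts or {}).items()},
        predefined_modules=read_gmt(predefined_gmt) if predefined_gmt else {},
        basis=read_basis(basis_path) if basis_path is not None else None,
        cell_name_map=dict(cell_name_map or {}),
    )
    return expr, pheno, bundle


def normalize(expr: ExpressionSet) -> ExpressionSet:
    """log2 transform then quantile-normalize across samples.

    Intensities <= 0 (possible after background subtraction) are handled
    by shifting the whole matrix by ``1 - min`` before the log.  After
    quantile normalization every column shares the same sorted value
    vector (the mean of the sorted input columns); rank ties within a
    column receive the mean of the target quantiles they span.
    """
    if expr.normalized:
        raise ValueError("expression set is already normalized")
    x = expr.values.to_numpy(dtype=float)
    m = x.min()
    if m <= 0:
        x = x + (1.0 - m)
    logged = np.log2(x + 1.0)

    n_probes, n_samples = logged.shape
    if n_samples < 2:
        warnings.warn("single-sample matrix: quantile normalization skipped", stacklevel=2)
        out = logged
    else:
        target = np.sort(logged, axis=0).mean(axis=1)
        out = np.empty_like(logged)
        for j in range(n_samples):
            col = logged[:, j]
            # average-rank ties -> mean of the target quantiles they span
            ranks = stats.rankdata(col, method="average") - 1.0
            lo = np.floor(ranks).astype(int)
            hi = np.ceil(ranks).astype(int)
            out[:, j] = 0.5 * (target[lo] + target[hi])
    values = pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns)
    return ExpressionSet(values=values, normalized=True)


def filter_probes(
    expr: ExpressionSet,
    mode: str = "variance",
    q: float = 0.5,
    pheno: PhenoTable | None = None,
    p_cutoff: float = 0.05,
    n_max: int = 5000,
) -> ExpressionSet:
    """Drop uninformative probes; retained probes keep their input order.

    mode="variance"
        keep probes whose variance is at or above the ``q``-th quantile
        of the per-probe variance distribution (default median).
    mode="factorial"
        keep probes whose overall F test from the two-factor fit
        (class x strat, with interaction) has nominal p < ``p_cutoff``,
        capped at the ``n_max`` largest F statistics.
    """
    if not expr.normalized:
        raise ValueError("filter_probes expects normalized expression")
    x = expr.values.to_numpy(dtype=float)
    if mode == "variance":
        v = x.var(axis=1, ddof=1)
        keep = v >= np.quantile(v, q)
    elif mode == "factorial":
        if pheno is None:
            raise ValueError("factorial filtering needs a phenotype table")
        from .diffexp import build_design  # deferred: avoids import cycle

        X = build_design(pheno)
        n, p = X.shape
        H = X @ np.linalg.pinv(X)
        Y = x.T  # samples x probes
        fitted = H @ Y
        rss = ((Y - fitted) ** 2).sum(axis=0)
        ybar = Y.mean(axis=0)
        tss = ((Y - ybar) ** 2).sum(axis=0)
        df_model, df_resid = p - 1, n - p
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ((tss - rss) / df_model) / (rss / df_resid)
        f = np.nan_to_num(f, nan=0.0, posinf=np.inf)
        pvals = stats.f.sf(f, df_model, df_resid)
        keep = pvals < p_cutoff
        if keep.sum() > n_max:
            cutoff = np.sort(f[keep])[-n_max]
            keep &= f >= cutoff
    else:
        raise ValueError(f"unknown filter mode {mode!r}")

    if keep.sum() < 10:
        raise ValueError(f"probe filter leaves {int(keep.sum())} probes (< 10)")
    values = expr.values.loc[keep]
    return replace(expr, values=values)
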