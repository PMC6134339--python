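"""Factorial linear models with empirical-Bayes moderated t-statistics.

Each probe is fit by ordinary least squares on the two-factor design
[intercept, class, strat, class:strat] with treatment (reference-level)
coding, the reference level being the alphabetically first level of each
factor.  Residual variances are then shrunk towards a common prior by
the standard empirical-Bayes scheme: the prior degrees of freedom d0 and
prior variance s0^2 are estimated by matching the first two moments of
log s^2 (digamma/trigamma inversion), the posterior variance is

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

and the moderated t for coefficient beta is beta / (s~ sqrt(v)) on
d0 + d_g degrees of freedom.  P-values are BH-adjusted across probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .ingest import ExpressionSet, PhenoTable

__all__ = ["ContrastSpec", "DEResult", "fit_factorial", "bh_adjust", "build_design"]

D0_CAP = 1e6  # stands in for an infinite-prior-df fit when moments admit no finite solution


@dataclass
class ContrastSpec:
    """Names the coefficient of interest in the factorial fit.

    By default the class main effect (the class contrast within the
    reference stratum under treatment coding) is reported.
    """

    coef: str | None = None


@dataclass
class DEResult:
    """Per-probe moderated test results for one contrast."""

    table: pd.DataFrame  # index probe; columns logfc, t, p, q, s2, df_resid, s2_post
    coef: str
    df_prior: float
    s2_prior: float
    coefficients: pd.DataFrame = field(repr=False, default=None)

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


_CONTROL_LIKE = {"control", "ctrl", "healthy", "baseline", "reference", "ref", "normal", "wt"}


def ordered_levels(values: pd.Series | list) -> list[str]:
    """Factor levels with the reference first.

    A control-like level (control, ctrl, healthy, baseline, ...) is the
    reference when present, so contrasts read case minus control;
    otherwise levels are alphabetical.
    """
    levels = sorted(pd.Series(values).astype(str).unique())
    for i, lv in enumerate(levels):
        if lv.lower() in _CONTROL_LIKE:
            levels.insert(0, levels.pop(i))
            break
    return levels


def _treatment_codes(values: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = ordered_levels(values)
    codes = np.array([levels.index(v) for v in values.astype(str)])
    return codes, levels


def build_design(pheno: PhenoTable) -> np.ndarray:
    """Design matrix [1, class, strat, class:strat], treatment coding."""
    X, _ = build_design_named(pheno)
    return X


def build_design_named(pheno: PhenoTable) -> tuple[np.ndarray, list[str]]:
    c_codes, c_levels = _treatment_codes(pheno.data[pheno.class_var])
    s_codes, s_levels = _treatment_codes(pheno.data[pheno.strat_var])
    if len(c_levels) != 2 or len(s_levels) != 2:
        raise ValueError("the default factorial design needs exactly 2 levels per factor")
    cols = [
        np.ones(len(c_codes)),
        (c_codes == 1).astype(float),
        (s_codes == 1).astype(float),
        ((c_codes == 1) & (s_codes == 1)).astype(float),
    ]
    names = [
        "intercept",
        f"{pheno.class_var}[{c_levels[1]}]",
        f"{pheno.strat_var}[{s_levels[1]}]",
        f"{pheno.class_var}[{c_levels[1]}]:{pheno.strat_var}[{s_levels[1]}]",
    ]
    return np.column_stack(cols), names


def trigamma_inverse(x: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x).copy()
    y = 0.5 + 1.0 / x  # good starting point for all x > 0
    for _ in range(60):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if np.all(np.abs(dif) < 1e-10 * y):
            break
    return float(y[0]) if scalar else y


def estimate_prior(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from the distribution of log s^2.

    If the observed spread of log s^2 is no larger than the sampling
    spread implied by d_g alone, the moment equations have no finite
    solution and d0 is capped at ``D0_CAP`` (an effectively flat prior:
    every posterior variance collapses to s0^2).
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return D0_CAP, float(np.exp(np.mean(np.log(s2[ok])))) if ok.any() else 1.0
    z = np.log(s2[ok])
    dg = df_resid
    e = z - special.digamma(dg / 2.0) + np.log(dg / 2.0)
    emean = e.mean()
    n = len(e)
    evar = ((e - emean) ** 2).sum() / (n - 1)
    excess = evar * n / (n - 1) - special.polygamma(1, dg / 2.0)
    if excess <= 0:
        d0 = D0_CAP
    else:
        d0 = float(2.0 * trigamma_inverse(excess))
        d0 = min(d0, D0_CAP)
    s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def fit_factorial(
    expr: ExpressionSet,
    pheno: PhenoTable,
    spec: ContrastSpec | None = None,
    d0_override: float | None = None,
) -> DEResult:
    """Per-probe OLS on the factorial design with moderated t for one contrast.

    ``d0_override`` forces the prior degrees of freedom (0 recovers the
    ordinary t-test exactly); by default the prior is estimated from the
    data.  Probes with missing values are dropped (complete-case).
    """
    if spec is None:
        spec = ContrastSpec()
    values = expr.values.dropna(axis=0)
    X, names = build_design_named(pheno)
    n, p = X.shape
    df_resid = n - p
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom in the factorial design")
    if np.linalg.matrix_rank(X) < p:
        # locate the first aliased column for the error message
        for j in range(1, p):
            if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
                raise ValueError(f"rank-deficient design: column {names[j]!r} is aliased")
        raise ValueError("rank-deficient design")
    coef_name = spec.coef or names[1]
    if coef_name not in names:
        raise ValueError(f"unknown coefficient {coef_name!r}; available: {names}")
    ci = names.index(coef_name)

    Y = values.to_numpy(dtype=float).T  # samples x probes
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y  # p x probes
    resid = Y - X @ B
    rss = (resid**2).sum(axis=0)
    s2 = rss / df_resid
    v = XtX_inv[ci, ci]  # unscaled variance of the contrast coefficient

    if d0_override is not None:
        d0 = float(d0_override)
        s0_2 = float(np.exp(np.mean(np.log(s2[s2 > 0])))) if np.any(s2 > 0) else 1.0
    else:
        d0, s0_2 = estimate_prior(s2, df_resid)
    if d0 > 0:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
    else:
        s2_post = s2.copy()

    beta = B[ci]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(s2_post * v)
    df_total = min(d0 + df_resid, 1e7)
    pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    bad = ~np.isfinite(t)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} probe(s) with undefined t; p set to 1", stacklevel=2)
        t = np.where(bad, 0.0, t)
        pvals = np.where(bad, 1.0, pvals)
    q = bh_adjust(pvals)

    table = pd.DataFrame(
        {
            "logfc": beta,
            "t": t,
            "p": pvals,
            "q": q,
            "s2": s2,
            "df_resid": df_resid,
            "s2_post": s2_post,
        },
        index=values.index,
    )
    coefs = pd.DataFrame(B.T, index=values.index, columns=names)
    return DEResult(table=table, coef=coef_name, df_prior=d0, s2_prior=s0_2, coefficients=coefs)


def bh_adjust(p: np.ndarray | list[float] | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    q_(i) = min_{j >= i} m * p_(j) / j, clipped at 1.  NaN entries stay
    NaN and do not count towards m.  Invariant to input permutation.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    qv = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.clip(qv, 0.0, 1.0)
    res = np.empty(m)
    res[order] = qv
    out[ok] = res
    return out


def write_de_table(de: DEResult, probe2symbol: dict[str, str], path) -> None:
    """TSV export (probe, symbol, logfc, t, p, q) — the topTable analog."""
    t = de.table.copy()
    t.insert(0, "symbol", [probe2symbol.get(pr, "") for pr in t.index])
    t[["symbol", "logfc", "t", "p", "q"]].to_csv(path, sep="\t", index_label="probe")
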