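"""Hypergeometric over-representation tests with a bounded retention policy.

Each module (a gene-symbol set) is tested against every set of an
annotation collection on a fixed universe (the symbols measured on the
filtered array).  P-values are BH-corrected within one (module x
collection) family.  Retention mirrors a curated-database policy: keep
BH-significant sets ranked by p, at most ``max_keep``; if fewer than
``min_keep`` pass, fall back to the top nominally significant sets and
flag them as relaxed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust

__all__ = ["EnrichmentResult", "hypergeom_p", "enrich_sets", "enrich_collection"]


@dataclass
class EnrichmentResult:
    """Long-form enrichment table with retention flags.

    Columns: module, set, k (overlap), n (module size), K (set size),
    N (universe), p, q, relaxed, retained.
    """

    table: pd.DataFrame

    def retained(self) -> pd.DataFrame:
        return self.table[self.table["retained"]]


def hypergeom_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size, K: annotation-set size, n: module size,
    k: observed overlap.
    """
    if not (0 <= k <= min(n, K)) or n > N or K > N:
        raise ValueError(f"invalid hypergeometric bounds k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_sets(
    module_symbols: set[str],
    collection: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Test one module against every set of a collection; BH within the family."""
    if not universe:
        raise ValueError("empty enrichment universe")
    mod = module_symbols & universe
    n = len(mod)
    N = len(universe)
    rows = []
    for name in sorted(collection):
        s = collection[name] & universe
        K = len(s)
        if K == 0:
            continue
        k = len(mod & s)
        rows.append({"set": name, "k": k, "n": n, "K": K, "N": N, "p": hypergeom_p(k, n, K, N)})
    df = pd.DataFrame(rows, columns=["set", "k", "n", "K", "N", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df


def enrich_collection(
    modules: dict[str, set[str]],
    collection: dict[str, set[str]],
    universe: set[str],
    q_cutoff: float = 0.05,
    min_keep: int = 3,
    max_keep: int = 10,
) -> EnrichmentResult:
    """Apply the retention/relaxation policy per module.

    Sets with q < ``q_cutoff`` are kept, ranked by ascending p,
    truncated at ``max_keep``.  If fewer than ``min_keep`` pass, the
    top ``min_keep`` sets with nominal p < 0.05 are kept instead and
    flagged relaxed.  The BH q is stored on every retained record
    either way.
    """
    frames = []
    for mod_name in sorted(modules):
        df = enrich_sets(modules[mod_name], collection, universe)
        if not len(df):
            continue
        df = df.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
        df["module"] = mod_name
        df["relaxed"] = False
        df["retained"] = False
        sig = df.index[df["q"] < q_cutoff]
        if len(sig) >= min_keep:
            df.loc[sig[:max_keep], "retained"] = True
        else:
            nominal = df.index[df["p"] < 0.05]
            if len(sig) > 0:
                df.loc[sig[:max_keep], "retained"] = True
            extra = [i for i in nominal if not df.loc[i, "retained"]]
            room = min_keep - int(df["retained"].sum())
            if room > 0 and extra:
                take = extra[:room]
                df.loc[take, "retained"] = True
                df.loc[take, "relaxed"] = True
        frames.append(df)
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(
            columns=["set", "k", "n", "K", "N", "p", "q", "module", "relaxed", "retained"]
        )
    cols = ["module", "set", "k", "n", "K", "N", "p", "q", "relaxed", "retained"]
    return EnrichmentResult(table=out[cols])
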