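"""Synthetic expression / phenotype / annotation fixtures with known truth.

The generator emulates a bulk blood-transcriptomics experiment:

* each sample is a mixture of cell types whose proportions lie on the
  unit simplex (Dirichlet-drawn); one cell type is shifted in cases;
* marker probes take their intensity from a cell-type signature basis,
  so expression = signature^T . proportions on the linear scale;
* planted co-expression modules ride on per-sample latent factors
  (log2-additive loadings), with one module tied to disease class and
  one to sex via multiplicative log2 effects;
* the phenotype table carries the two-factor design (class x sex) plus
  numeric covariates, one constructed to track the disease module's
  latent signal;
* multiplicative log-normal noise with a configurable SD closes the
  model.

Everything is driven by one RNG seed: the same configuration always
yields byte-identical matrices and annotation files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .graphstore import AssociationGraph
from .ingest import AnnotationBundle, ExpressionSet, PhenoTable, write_gmt

__all__ = ["SynthConfig", "GroundTruth", "generate_dataset", "generate_annotations",
           "toy_graph_fixture", "write_fixture_files"]

MODULE_LOADING = 0.5  # log2 units per latent-factor SD on member probes


@dataclass
class SynthConfig:
    """Study-condition knobs for the generator (all effects in log2 units)."""

    n_samples_per_stratum: int = 15  # per (class x sex) cell -> 60 samples
    n_celltypes: int = 5
    n_markers_per_cell: int = 30
    n_planted_modules: int = 4
    module_size: int = 50
    n_noise_probes: int = 1500
    disease_effect: float = 1.0
    sex_effect: float = 1.0
    proportion_shift: float = 0.15
    noise_sd: float = 0.5
    seed: int = 0
    # platform structure (signature baselines, annotations) follows ``seed``;
    # sampling (proportions, latent factors, noise) follows ``sample_seed``
    # when set, so several datasets can share one platform/basis
    sample_seed: int | None = None

    def __post_init__(self) -> None:
        counts = {
            "n_samples_per_stratum": self.n_samples_per_stratum,
            "n_celltypes": self.n_celltypes,
            "n_markers_per_cell": self.n_markers_per_cell,
            "n_planted_modules": self.n_planted_modules,
            "module_size": self.module_size,
            "n_noise_probes": self.n_noise_probes,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1 (got {v})")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.proportion_shift <= 1:
            raise ValueError("proportion_shift must keep proportions in [0, 1]")

    @property
    def celltypes(self) -> list[str]:
        return [f"celltype_{c}" for c in range(self.n_celltypes)]


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    proportions: pd.DataFrame  # samples x cell types, simplex rows
    signature: pd.DataFrame  # cell types x probes, linear scale
    module_membership: pd.Series  # probe -> planted module id ("" = none)
    effect_table: pd.DataFrame  # (module, factor, log2_effect)
    marker_sets: dict[str, set[str]] = field(default_factory=dict)  # cell -> marker symbols
    latent_factors: pd.DataFrame = None  # modules x samples


def _probe_names(config: SynthConfig) -> tuple[list[str], list[str], list[str]]:
    markers = [
        f"P_c{c}_m{k}"
        for c in range(config.n_celltypes)
        for k in range(config.n_markers_per_cell)
    ]
    modules = [
        f"P_mod{m}_{k}"
        for m in range(config.n_planted_modules)
        for k in range(config.module_size)
    ]
    noise = [f"P_noise_{k}" for k in range(config.n_noise_probes)]
    return markers, modules, noise


def symbol_of(probe: str) -> str:
    return "G" + probe[1:]


def generate_dataset(config: SynthConfig) -> tuple[ExpressionSet, PhenoTable, GroundTruth]:
    """Simulate one dataset under the two-factor cell-mixture model."""
    platform_rng = np.random.default_rng(config.seed)
    rng = np.random.default_rng(
        config.sample_seed if config.sample_seed is not None else config.seed
    )
    markers, module_probes, noise_probes = _probe_names(config)
    probes = markers + module_probes + noise_probes
    n_probes = len(probes)

    n_per = config.n_samples_per_stratum
    strata = [("case", "F"), ("case", "M"), ("control", "F"), ("control", "M")]
    classes, sexes = [], []
    for cls, sex in strata:
        classes += [cls] * n_per
        sexes += [sex] * n_per
    n_samples = len(classes)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    is_case = np.array([c == "case" for c in classes])
    is_male = np.array([s == "M" for s in sexes])

    # cell proportions: Dirichlet, with one cell type shifted in cases
    alpha = np.full(config.n_celltypes, 5.0)
    props = rng.dirichlet(alpha, size=n_samples)
    if config.n_celltypes > 1 and config.proportion_shift > 0:
        shifted = props.copy()
        shifted[is_case, 0] += config.proportion_shift
        shifted[is_case] /= 1.0 + config.proportion_shift
        props = shifted
    prop_df = pd.DataFrame(props, index=samples, columns=config.celltypes)

    # signature basis: marker probes bright in their own cell type
    baseline = platform_rng.uniform(50.0, 500.0, size=n_probes)
    signature = np.tile(baseline, (config.n_celltypes, 1))
    for c in range(config.n_celltypes):
        for k in range(config.n_markers_per_cell):
            p = c * config.n_markers_per_cell + k
            signature[:, p] = 0.1 * baseline[p]
            signature[c, p] = 10.0 * baseline[p]
    sig_df = pd.DataFrame(signature, index=config.celltypes, columns=probes)

    # mixture expression on the linear scale: probes x samples
    expr = signature.T @ props.T

    # planted module factors (log2-additive on member probes), centered
    # within each stratum so they stay orthogonal to the two design
    # factors and planted effects are exactly the stated log2 shifts
    latent = rng.standard_normal((config.n_planted_modules, n_samples))
    for s in range(len(strata)):
        block = slice(s * n_per, (s + 1) * n_per)
        latent[:, block] -= latent[:, block].mean(axis=1, keepdims=True)
    log2_shift = np.zeros((n_probes, n_samples))
    membership = pd.Series("", index=pd.Index(probes))
    effects = []
    offset = len(markers)
    for m in range(config.n_planted_modules):
        rows = slice(offset + m * config.module_size, offset + (m + 1) * config.module_size)
        membership.iloc[rows] = f"mod{m}"
        shift = MODULE_LOADING * latent[m]
        if m == 0:
            shift = shift + config.disease_effect * is_case
            effects.append({"module": "mod0", "factor": "class", "log2_effect": config.disease_effect})
        elif m == 1:
            shift = shift + config.sex_effect * is_male
            effects.append({"module": "mod1", "factor": "sex", "log2_effect": config.sex_effect})
        log2_shift[rows] = shift

    if config.noise_sd > 0:
        log2_shift = log2_shift + rng.normal(0.0, config.noise_sd, size=(n_probes, n_samples))
    expr = expr * np.power(2.0, log2_shift)
    expr_df = pd.DataFrame(expr, index=probes, columns=samples)

    # numeric covariates; the first tracks the disease module's latent signal
    disease_signal = MODULE_LOADING * latent[0] + config.disease_effect * is_case
    sd = disease_signal.std(ddof=0)
    sd = sd if sd > 0 else 1.0
    covariate = disease_signal + rng.normal(0.0, 0.3 * sd, size=n_samples)
    age = rng.uniform(18.0, 65.0, size=n_samples).round(1)
    pheno_df = pd.DataFrame(
        {
            "class": classes,
            "sex": sexes,
            "disease_marker": np.round(covariate, 6),
            "age": age,
            "subject_id": [f"SUBJ{i:03d}" for i in range(n_samples)],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    pheno = PhenoTable(
        data=pheno_df,
        var_types={
            "class": "categorical",
            "sex": "categorical",
            "disease_marker": "numeric",
            "age": "numeric",
            "subject_id": "identifier",
        },
        class_var="class",
        strat_var="sex",
    )
    marker_sets = {
        config.celltypes[c]: {
            symbol_of(f"P_c{c}_m{k}") for k in range(config.n_markers_per_cell)
        }
        for c in range(config.n_celltypes)
    }
    truth = GroundTruth(
        proportions=prop_df,
        signature=sig_df,
        module_membership=membership,
        effect_table=pd.DataFrame(effects, columns=["module", "factor", "log2_effect"]),
        marker_sets=marker_sets,
        latent_factors=pd.DataFrame(latent, index=[f"mod{m}" for m in range(config.n_planted_modules)], columns=samples),
    )
    return ExpressionSet(values=expr_df, normalized=False), pheno, truth


def generate_annotations(
    config: SynthConfig,
    truth: GroundTruth | None = None,
    dropout: float = 0.2,
    decoy_rate: float = 0.2,
) -> AnnotationBundle:
    """Annotation fixtures consistent with ``generate_dataset(config)``.

    Three marker collections (exact truth; truth with ``dropout``
    removed; truth with ``decoy_rate`` swapped for decoys), three
    pathway collections (one pathway per planted module plus decoy
    sets), a pre-defined module repertoire (half overlapping planted
    modules, half random) and the signature basis restricted to marker
    probes.  Collection-specific cell labels carry per-collection
    suffixes, resolved by the returned consensus cell-name map.
    """
    if truth is None:
        _, _, truth = generate_dataset(config)
    rng = np.random.default_rng(config.seed + 10_007)
    markers, module_probes, noise_probes = _probe_names(config)
    probes = markers + module_probes + noise_probes
    probe2symbol = {p: symbol_of(p) for p in probes}
    noise_symbols = sorted(symbol_of(p) for p in noise_probes)

    def cell_label(cell: str, xp: int) -> str:
        return f"{cell}.xp{xp}"

    marker_collections: dict[str, dict[str, set[str]]] = {}
    cell_name_map: dict[str, str] = {}
    # xp1: exact truth
    marker_collections["markers_xp1"] = {
        cell_label(cell, 1): set(syms) for cell, syms in truth.marker_sets.items()
    }
    # xp2: random dropout
    coll2 = {}
    for cell, syms in truth.marker_sets.items():
        syms = sorted(syms)
        n_drop = int(round(dropout * len(syms)))
        drop = set(rng.choice(syms, size=n_drop, replace=False)) if n_drop else set()
        coll2[cell_label(cell, 2)] = set(syms) - drop
    marker_collections["markers_xp2"] = coll2
    # xp3: decoy swap-in
    coll3 = {}
    for cell, syms in truth.marker_sets.items():
        syms = sorted(syms)
        n_swap = int(round(decoy_rate * len(syms)))
        out = set(syms)
        if n_swap:
            removed = rng.choice(syms, size=n_swap, replace=False)
            decoys = rng.choice(noise_symbols, size=n_swap, replace=False)
            out = (out - set(removed)) | set(decoys)
        coll3[cell_label(cell, 3)] = out
    marker_collections["markers_xp3"] = coll3
    for cell in truth.marker_sets:
        for xp in (1, 2, 3):
            cell_name_map[cell_label(cell, xp)] = cell
        cell_name_map[cell] = cell  # basis/proportion columns use consensus names

    module_symbols = {
        f"mod{m}": {
            symbol_of(f"P_mod{m}_{k}") for k in range(config.module_size)
        }
        for m in range(config.n_planted_modules)
    }
    pathway_collections: dict[str, dict[str, set[str]]] = {}
    fractions = {"reactome_like": 1.0, "curated_like": 0.8, "immune_like": 0.6}
    for coll_name, keep_frac in fractions.items():
        coll: dict[str, set[str]] = {}
        for m in range(config.n_planted_modules):
            syms = sorted(module_symbols[f"mod{m}"])
            n_keep = max(3, int(round(keep_frac * len(syms))))
            kept = syms if n_keep >= len(syms) else sorted(
                rng.choice(syms, size=n_keep, replace=False)
            )
            coll[f"{coll_name}_pathway_mod{m}"] = set(kept)
        for d in range(config.n_planted_modules):
            size = min(config.module_size, len(noise_symbols))
            coll[f"{coll_name}_decoy{d}"] = set(
                rng.choice(noise_symbols, size=size, replace=False)
            )
        pathway_collections[coll_name] = coll

    # the pre-defined repertoire mixes planted-module copies, cell-marker
    # sets (blood-module repertoires contain cell-specific modules) and
    # random decoys
    predefined: dict[str, set[str]] = {}
    for m in range(config.n_planted_modules):
        predefined[f"predef_mod{m}"] = set(module_symbols[f"mod{m}"])
    for c, cell in enumerate(sorted(truth.marker_sets)):
        predefined[f"predef_cell{c}"] = set(truth.marker_sets[cell])
    for r in range(config.n_planted_modules):
        size = min(config.module_size, len(noise_symbols))
        predefined[f"predef_rand{r}"] = set(rng.choice(noise_symbols, size=size, replace=False))

    basis = truth.signature.T.loc[markers]  # marker probes x cell types
    return AnnotationBundle(
        probe2symbol=probe2symbol,
        pathway_collections=pathway_collections,
        marker_collections=marker_collections,
        predefined_modules=predefined,
        basis=basis,
        cell_name_map=cell_name_map,
    )


def write_fixture_files(
    out_dir: str | Path,
    config: SynthConfig,
) -> dict[str, Path]:
    """Write the exact on-disk formats the pipeline reads.

    Expression TSV, phenotype CSV, probe2symbol TSV, GMT collections,
    basis CSV and a var-types YAML snippet; returns the path map.
    """
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, pheno, truth = generate_dataset(config)
    bundle = generate_annotations(config, truth)

    paths: dict[str, Path] = {}
    paths["expression"] = out / "expression.tsv"
    expr.values.to_csv(paths["expression"], sep="\t", index_label="probe_id")
    paths["pheno"] = out / "phenotype.csv"
    pheno.data.to_csv(paths["pheno"], index_label="sample_id")
    paths["probe2symbol"] = out / "probe2symbol.tsv"
    with open(paths["probe2symbol"], "w") as fh:
        fh.write("probe_id\tsymbol\n")
        for p, s in bundle.probe2symbol.items():
            fh.write(f"{p}\t{s}\n")
    for name, coll in bundle.pathway_collections.items():
        paths[f"pathways_{name}"] = out / f"pathways_{name}.gmt"
        write_gmt(coll, paths[f"pathways_{name}"])
    for name, coll in bundle.marker_collections.items():
        paths[f"markers_{name}"] = out / f"{name}.gmt"
        write_gmt(coll, paths[f"markers_{name}"])
    paths["predefined"] = out / "predefined_modules.gmt"
    write_gmt(bundle.predefined_modules, paths["predefined"])
    paths["basis"] = out / "signature_basis.csv"
    bundle.basis.to_csv(paths["basis"], index_label="probe_id")
    paths["meta"] = out / "dataset_meta.yaml"
    with open(paths["meta"], "w") as fh:
        yaml.safe_dump(
            {
                "var_types": pheno.var_types,
                "class_var": pheno.class_var,
                "strat_var": pheno.strat_var,
                "cell_name_map": bundle.cell_name_map,
                "seed": config.seed,
            },
            fh,
        )
    return paths


def toy_graph_fixture() -> AssociationGraph:
    """Hand-specified mini-graph exercising the worked path query.

    2 wgcna, 3 pheno, 6 PROBE and 6 SYMBOL nodes; exactly one
    (pheno)-(wgcna)-(PROBE)-(SYMBOL) path satisfies
    weight > 0.6 AND logfc > 2.
    """
    g = AssociationGraph()
    sq = "toy"
    w1 = g.merge_node("wgcna", "turquoise", sq, "1", modAUC1=0.9)
    w2 = g.merge_node("wgcna", "blue", sq, "1", modAUC1=0.7)
    ph = {
        1: g.merge_node("pheno", "cd4_count", sq),
        2: g.merge_node("pheno", "viral_load", sq),
        3: g.merge_node("pheno", "crp", sq),
    }
    logfc = {1: 2.5, 2: 1.0, 3: 0.5, 4: 1.5, 5: -0.3, 6: 0.2}
    pk, sk = {}, {}
    for i in range(1, 7):
        pk[i] = g.merge_node("PROBE", f"probe{i}", sq, "1", logfc=logfc[i])
        sk[i] = g.merge_node("SYMBOL", f"GENE{i}")
        g.merge_edge(pk[i], sk[i], "mapping", graph_index=2)
    g.merge_edge(ph[1], w1, "correlation", graph_index=29, weight=0.8, q=0.01)
    g.merge_edge(ph[2], w1, "correlation", graph_index=29, weight=0.5, q=0.04)
    g.merge_edge(ph[3], w2, "correlation", graph_index=29, weight=0.9, q=0.02)
    for i in (1, 2, 3):
        g.merge_edge(pk[i], w1, "mapping", graph_index=3)
    for i in (4, 5, 6):
        g.merge_edge(pk[i], w2, "mapping", graph_index=3)
    return g
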