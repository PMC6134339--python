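"""Virtual-cell linking (the conjunction rule), activity matrices and
their rankings."""

import numpy as np
import pandas as pd
import pytest

from assocnet.coexpr import ModuleAssignment, ModuleSummary
from assocnet.deconv import ProportionResult
from assocnet.diffexp import DEResult
from assocnet.enrichment import EnrichmentResult
from assocnet.virtual_cells import (
    ActivityMatrix,
    VirtualCell,
    cell_pathway_activity,
    link_modules_to_cells,
    meta_cell_compare,
    rank_activity,
)


def _summaries(me_rows: dict, samples: list[str]) -> ModuleSummary:
    me = pd.DataFrame(me_rows, index=samples).T
    return ModuleSummary(eigengenes=me, metrics=pd.DataFrame(index=list(me_rows)))


def _enrichment(rows: list[dict]) -> EnrichmentResult:
    df = pd.DataFrame(rows, columns=["module", "set", "k", "n", "K", "N", "p", "q",
                                     "relaxed", "retained"])
    return EnrichmentResult(table=df)


def _props(cols: dict, samples: list[str]) -> ProportionResult:
    return ProportionResult(proportions=pd.DataFrame(cols, index=samples))


SAMPLES = [f"s{i}" for i in range(12)]


def _setup(with_enrichment: bool, with_correlation: bool):
    rng = np.random.default_rng(0)
    signal = rng.normal(size=12)
    me_rows = {"blue": signal / np.linalg.norm(signal)}
    prop = signal - signal.min() + 0.1
    prop = prop / prop.sum() if with_correlation else rng.uniform(0.1, 0.3, 12)
    props = _props({"tcell": prop, "bcell": 1 - prop}, SAMPLES)
    enrich_rows = []
    if with_enrichment:
        enrich_rows.append(
            {"module": "blue", "set": "tcell.xp1", "k": 10, "n": 20, "K": 15,
             "N": 500, "p": 1e-9, "q": 1e-8, "relaxed": False, "retained": True}
        )
    cmap = {"tcell.xp1": "tcell", "tcell": "tcell", "bcell": "bcell"}
    return _summaries(me_rows, SAMPLES), props, {"xp1": _enrichment(enrich_rows)}, cmap


def test_link_requires_both_conditions():
    # correlation + enrichment -> linked
    s, p, e, cmap = _setup(True, True)
    links = link_modules_to_cells(s, p, e, cmap)
    assert list(links["module"]) == ["blue"] and list(links["cell"]) == ["tcell"]
    # correlation alone -> not linked
    s, p, e, cmap = _setup(False, True)
    assert len(link_modules_to_cells(s, p, e, cmap)) == 0
    # enrichment alone -> not linked
    s, p, e, cmap = _setup(True, False)
    assert len(link_modules_to_cells(s, p, e, cmap)) == 0


def _vcell(cell: str, probes: list[str]) -> VirtualCell:
    n = len(probes)
    return VirtualCell(
        cell=cell, probes=probes,
        coexpression=pd.DataFrame(np.eye(n), index=probes, columns=probes),
        pathways=pd.DataFrame(), de_overlay=pd.DataFrame(), modules=["blue"],
    )


def _de(logfc: dict) -> DEResult:
    t = pd.DataFrame({"logfc": pd.Series(logfc)})
    t["q"] = 0.01
    t["p"] = 0.01
    t["t"] = t["logfc"]
    return DEResult(table=t, coef="c", df_prior=1, s2_prior=1)


P2S = {f"p{i}": f"G{i}" for i in range(10)}
PATHS = {"coll": {"pwA": {"G0", "G1"}, "pwB": {"G2", "G3"}, "pwC": {"G8", "G9"}}}


def test_activity_mean_of_positive_logfc():
    de = _de({"p0": 1.0, "p1": 3.0, "p2": 1.0, "p3": -1.0})
    vc = _vcell("tcell", ["p0", "p1", "p2", "p3"])
    act = cell_pathway_activity([vc], PATHS, de, P2S)
    up_a = act.table[(act.table["pathway"] == "pwA") & (act.table["direction"] == "up")]
    assert up_a["score"].iloc[0] == pytest.approx(2.0)


def test_up_down_kept_separate():
    de = _de({"p2": 1.0, "p3": -1.0})
    vc = _vcell("tcell", ["p2", "p3"])
    act = cell_pathway_activity([vc], PATHS, de, P2S)
    sub = act.table[act.table["pathway"] == "pwB"]
    up = sub[sub["direction"] == "up"]["score"].iloc[0]
    down = sub[sub["direction"] == "down"]["score"].iloc[0]
    assert up == 1.0 and down == -1.0
    assert (act.table[act.table["direction"] == "up"]["score"] >= 0).all()
    assert (act.table[act.table["direction"] == "down"]["score"] <= 0).all()


def test_empty_intersection_absent_not_zero():
    de = _de({"p0": 1.0})
    vc = _vcell("tcell", ["p0"])
    act = cell_pathway_activity([vc], PATHS, de, P2S)
    assert "pwC" not in set(act.table["pathway"])


def test_rank_activity_sums_match_manual_aggregation():
    rng = np.random.default_rng(3)
    rows = []
    for cell in ["c1", "c2", "c3"]:
        for pw in ["pw1", "pw2"]:
            rows.append({"cell_instance": cell, "pathway": pw,
                         "direction": "up", "score": float(rng.uniform(0, 2))})
            rows.append({"cell_instance": cell, "pathway": pw,
                         "direction": "down", "score": float(-rng.uniform(0, 2))})
    act = ActivityMatrix(table=pd.DataFrame(rows))
    pw_rank, cell_rank = rank_activity(act)
    t = act.table
    for pw in ["pw1", "pw2"]:
        manual = t[(t["pathway"] == pw) & (t["direction"] == "up")]["score"].sum()
        assert pw_rank.loc[pw, "up"] == pytest.approx(manual)
    # ranking invariant under column (cell) permutation of the input rows
    act2 = ActivityMatrix(table=act.table.iloc[::-1].reset_index(drop=True))
    pw_rank2, cell_rank2 = rank_activity(act2)
    pd.testing.assert_frame_equal(pw_rank, pw_rank2)
    pd.testing.assert_frame_equal(cell_rank, cell_rank2)


def test_single_entry_ranks_first():
    act = ActivityMatrix(table=pd.DataFrame(
        [{"cell_instance": "c", "pathway": "pw", "direction": "up", "score": 1.5}]
    ))
    pw_rank, cell_rank = rank_activity(act)
    assert pw_rank.index[0] == "pw" and cell_rank.index[0] == "c"


class TestMetaCompare:
    def _matrix(self, scores: dict) -> ActivityMatrix:
        rows = [
            {"cell_instance": "1_tcell", "pathway": pw, "direction": "up" if v > 0 else "down",
             "score": v}
            for pw, v in scores.items()
        ]
        return ActivityMatrix(table=pd.DataFrame(rows))

    def test_identical_profiles_adjacent(self):
        m = {"d1": self._matrix({"pwA": 1.0, "pwB": 0.5}),
             "d2": self._matrix({"pwA": 1.0, "pwB": 0.5}),
             "d3": self._matrix({"pwA": -1.0, "pwB": -0.5})}
        out = meta_cell_compare(m, cell_filter="tcell")
        cols = list(out.columns)
        assert abs(cols.index("d1_1_tcell") - cols.index("d2_1_tcell")) == 1

    def test_missing_pathway_treated_as_zero_for_clustering(self):
        m = {"d1": self._matrix({"pwA": 1.0}), "d2": self._matrix({"pwB": 1.0})}
        out = meta_cell_compare(m)
        assert np.isnan(out.loc["pwB", "d1_1_tcell"])  # absent stays absent in output

    def test_filter_without_match_fatal(self):
        m = {"d1": self._matrix({"pwA": 1.0}), "d2": self._matrix({"pwA": 1.0})}
        with pytest.raises(ValueError, match="matches no"):
            meta_cell_compare(m, cell_filter="neuron")
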