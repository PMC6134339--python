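"""Co-expression network construction against brute-force oracles, plus
module detection on planted structure."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from assocnet import coexpr
from assocnet.ingest import ExpressionSet, normalize, filter_probes
from assocnet.synthdata import SynthConfig, generate_dataset
from conftest import make_expr


def tom_bruteforce(a: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap for the oracle comparison."""
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def auc_bruteforce(scores: np.ndarray, positives: np.ndarray) -> float:
    """Exhaustive concordant-pair counting with half-credit ties."""
    pos = scores[positives]
    neg = scores[~positives]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestTOM:
    def test_zero_adjacency_gives_zero_overlap(self):
        expr = make_expr(np.eye(4) * 1.0 + np.random.default_rng(0).normal(0, 1e-9, (4, 4)))
        # construct TOM directly from a zero adjacency by algebra instead
        a = np.zeros((3, 3))
        tom = tom_bruteforce(a)
        assert np.allclose(tom[~np.eye(3, dtype=bool)], 0.0)

    def test_complete_graph_overlap_is_one(self):
        n = 6
        a = np.ones((n, n)) - np.eye(n)
        tom = tom_bruteforce(a)
        assert np.allclose(tom, 1.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        expr = make_expr(rng.normal(size=(20, 15)))
        tom = coexpr.tom_matrix(expr, beta=3).to_numpy()
        a = np.abs(np.corrcoef(expr.values.to_numpy())) ** 3
        np.fill_diagonal(a, 0.0)
        assert np.allclose(tom, tom_bruteforce(a), atol=1e-12)

    def test_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(2)
        expr = make_expr(rng.normal(size=(30, 12)))
        tom = coexpr.tom_matrix(expr, beta=6).to_numpy()
        assert np.allclose(tom, tom.T)
        assert np.allclose(np.diag(tom), 1.0)
        assert tom.min() >= 0.0 and tom.max() <= 1.0

    def test_constant_probe_fatal(self):
        x = np.random.default_rng(3).normal(size=(5, 8))
        x[0] = 2.0
        with pytest.raises(ValueError, match="constant"):
            coexpr.tom_matrix(make_expr(x), beta=2)


class TestSoftPower:
    def test_default_when_degenerate(self):
        rng = np.random.default_rng(4)
        # pure noise rarely reaches scale-free fit at any power <= 20
        expr = make_expr(rng.normal(size=(50, 10)))
        with pytest.warns(UserWarning):
            beta = coexpr.pick_soft_power(expr, target_r2=0.999)
        assert beta == 6

    def test_deterministic_on_block_structure(self):
        rng = np.random.default_rng(5)
        f1, f2 = rng.normal(size=10), rng.normal(size=10)
        x = np.vstack(
            [f1 + rng.normal(0, 1e-6, 10) for _ in range(50)]
            + [f2 + rng.normal(0, 1e-6, 10) for _ in range(50)]
        )
        expr = make_expr(x)
        assert coexpr.pick_soft_power(expr) == coexpr.pick_soft_power(expr)

    def test_matches_independent_binned_fit(self, small_dataset):
        expr, _, _ = small_dataset
        filt = filter_probes(normalize(expr), q=0.5)
        chosen = coexpr.pick_soft_power(filt)

        def oracle() -> int:
            corr = np.abs(np.corrcoef(filt.values.to_numpy()))
            np.fill_diagonal(corr, 0.0)
            for beta in range(1, 21):
                k = (corr**beta).sum(axis=1)
                if coexpr.scale_free_fit(k) >= 0.8:
                    return beta
            return 6

        assert chosen == oracle()


class TestEigengene:
    def test_identical_probes_reproduce_profile(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=12)
        x = np.vstack([2 * base + 3, -1 * base, base])
        expr = make_expr(x)
        me = coexpr.module_eigengene(expr, ["p0", "p1", "p2"])
        # p1 is anti-correlated; the eigengene tracks the standardized mean
        assert abs(np.corrcoef(me, base)[0, 1]) == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.norm(me) == pytest.approx(1.0)

    def test_sign_law(self, small_dataset):
        expr, _, _ = small_dataset
        norm = normalize(expr)
        members = [p for p in norm.probe_ids if p.startswith("P_mod0")]
        me = coexpr.module_eigengene(norm, members)
        sub = norm.values.loc[members].to_numpy()
        z = (sub - sub.mean(1, keepdims=True)) / sub.std(1, ddof=1)[:, None]
        assert np.corrcoef(me, z.mean(0))[0, 1] >= 0

    def test_variance_explained_high_for_planted_module(self):
        cfg = SynthConfig(noise_sd=0.1, seed=9, n_planted_modules=1, module_size=40,
                          n_celltypes=2, n_markers_per_cell=5, n_noise_probes=50,
                          n_samples_per_stratum=8,
                          disease_effect=0.0, sex_effect=0.0)  # single latent factor
        expr, _, _ = generate_dataset(cfg)
        log2_expr = ExpressionSet(values=np.log2(expr.values), normalized=True)
        members = [p for p in log2_expr.probe_ids if p.startswith("P_mod0")]
        assert coexpr.eigengene_variance_explained(log2_expr, members) >= 0.8


class TestAUC:
    def test_perfect_separation(self):
        me = pd.Series([1, 2, 3, 4], index=list("abcd"))
        classes = pd.Series(["ctrl", "ctrl", "case", "case"], index=list("abcd"))
        assert coexpr.module_auc(me, classes) == 1.0

    def test_hand_example_three_quarters(self):
        me = pd.Series([3, 1, 2, 4], index=list("abcd"))
        classes = pd.Series(["ctrl", "ctrl", "case", "case"], index=list("abcd"))
        assert coexpr.module_auc(me, classes) == 0.75

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(6, 50))
            scores = rng.integers(0, 10, size=n).astype(float)  # force ties
            y = rng.integers(0, 2, size=n).astype(bool)
            if y.all() or not y.any():
                continue
            me = pd.Series(scores, index=[f"s{i}" for i in range(n)])
            classes = pd.Series(np.where(y, "case", "ctrl"), index=me.index)
            assert coexpr.module_auc(me, classes) == pytest.approx(
                auc_bruteforce(scores, y), abs=1e-12
            )


class TestModuleDetection:
    def test_two_planted_modules_recovered_exactly(self):
        cfg = SynthConfig(n_planted_modules=2, module_size=50, noise_sd=0.2, seed=13,
                          n_celltypes=2, n_markers_per_cell=5, n_noise_probes=100,
                          n_samples_per_stratum=8, proportion_shift=0.0)
        expr, _, truth = generate_dataset(cfg)
        norm = normalize(expr)
        members = [p for p in norm.probe_ids if p.startswith("P_mod")]
        sub = ExpressionSet(values=norm.values.loc[members], normalized=True)
        tom = coexpr.tom_matrix(sub, 6)
        asg = coexpr.detect_modules(tom, sub, min_size=10)
        assert len(asg.modules()) == 2
        ari = adjusted_rand_score(truth.module_membership.loc[members], asg.labels.loc[members])
        assert ari == 1.0

    def test_min_size_larger_than_probes_gives_all_grey(self):
        rng = np.random.default_rng(8)
        expr = make_expr(rng.normal(size=(20, 10)))
        tom = coexpr.tom_matrix(expr, 2)
        with pytest.warns(UserWarning, match="grey"):
            asg = coexpr.detect_modules(tom, expr, min_size=100)
        assert (asg.labels == "grey").all()

    def test_modules_sharing_latent_factor_merge(self):
        rng = np.random.default_rng(14)
        f = rng.normal(size=20)
        x = np.vstack(
            [f + rng.normal(0, 0.1, 20) for _ in range(15)]
            + [0.9 * f + rng.normal(0, 0.1, 20) for _ in range(15)]
        )
        expr = make_expr(x)
        tom = coexpr.tom_matrix(expr, 6)
        asg = coexpr.detect_modules(tom, expr, min_size=5, merge_cor=0.75)
        assert len(asg.modules()) == 1

    def test_labels_stable_under_probe_permutation(self):
        cfg = SynthConfig(n_planted_modules=2, module_size=30, noise_sd=0.2, seed=15,
                          n_celltypes=2, n_markers_per_cell=5, n_noise_probes=40,
                          n_samples_per_stratum=8)
        expr, _, _ = generate_dataset(cfg)
        norm = normalize(expr)
        rng = np.random.default_rng(16)
        perm = rng.permutation(norm.values.index)
        shuffled = ExpressionSet(values=norm.values.loc[perm], normalized=True)
        a1 = coexpr.detect_modules(coexpr.tom_matrix(norm, 6), norm, min_size=10)
        a2 = coexpr.detect_modules(coexpr.tom_matrix(shuffled, 6), shuffled, min_size=10)
        common = list(norm.values.index)
        ari = adjusted_rand_score(a1.labels.loc[common], a2.labels.loc[common])
        assert ari == 1.0


class TestEdgeSelection:
    def _tom(self, n: int, seed: int = 17) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        m = rng.uniform(size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        probes = [f"p{i:04d}" for i in range(n)]
        return pd.DataFrame(m, index=probes, columns=probes)

    def test_cap_binds_for_large_module(self):
        tom = self._tom(250)
        edges = coexpr.select_module_edges(tom, list(tom.index))
        assert len(edges) == 2000

    def test_ceil_rule_small_module(self):
        tom = self._tom(10)
        edges = coexpr.select_module_edges(tom, list(tom.index))
        assert len(edges) == 5  # ceil(0.1 * 45)

    def test_two_member_module_single_edge(self):
        tom = self._tom(2)
        edges = coexpr.select_module_edges(tom, list(tom.index))
        assert len(edges) == 1

    def test_edges_are_top_ranked_by_tom(self):
        tom = self._tom(12)
        edges = coexpr.select_module_edges(tom, list(tom.index), frac=0.2)
        weights = [w for _, _, w in edges]
        assert weights == sorted(weights, reverse=True)
        all_pairs = sorted(
            tom.iloc[i, j] for i in range(12) for j in range(i + 1, 12)
        )[::-1]
        assert weights == pytest.approx(all_pairs[: len(weights)])
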