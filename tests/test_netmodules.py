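import numpy as np
import pandas as pd
import pytest
from scipy import linalg

import dietexpr as dx
from dietexpr.netmodules import (UNASSIGNED, _match_modules, eigengene_matrix,
                                 scale_free_fit_index)


def _expr_from_profiles(profiles, samples=None):
    """Rows are exact per-gene sample profiles."""
    arr = np.asarray(profiles, float)
    cols = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                        columns=cols)


class TestSignedAdjacency:
    def test_limit_cases(self):
        t = np.linspace(-1, 1, 8)
        expr = _expr_from_profiles([t, t * 2 + 1, -t, np.r_[t[4:], t[:4]]])
        a = dx.signed_adjacency(expr, beta=2)
        assert a.iloc[0, 1] == pytest.approx(1.0)   # cor = 1
        assert a.iloc[0, 2] == pytest.approx(0.0)   # cor = -1
        assert np.diag(a).min() == 1.0
        assert ((a.to_numpy() >= 0) & (a.to_numpy() <= 1)).all()

    def test_zero_correlation_quarter(self):
        # two exactly uncorrelated profiles
        x = np.array([1.0, -1, 1, -1])
        y = np.array([1.0, 1, -1, -1])
        a = dx.signed_adjacency(_expr_from_profiles([x, y]), beta=2)
        assert a.iloc[0, 1] == pytest.approx(0.25, abs=1e-12)

    def test_constant_gene_handled(self, caplog):
        expr = _expr_from_profiles([[1.0, 2, 3, 4], [5.0, 5, 5, 5]])
        with caplog.at_level("WARNING"):
            a = dx.signed_adjacency(expr, beta=6)
        assert a.iloc[0, 1] == pytest.approx(0.5**6)


class TestScaleFreeFit:
    def test_power_law_degrees_fit_high(self):
        rng = np.random.default_rng(0)
        k = (1 - rng.uniform(size=4000)) ** (-1 / 1.5)  # Pareto, p(k) ~ k^-2.5
        k = k[k < 50]
        fit, slope = scale_free_fit_index(k, n_bins=10)
        assert fit > 0.9 and slope < 0

    def test_degenerate_connectivity_warns(self, caplog):
        with caplog.at_level("WARNING"):
            fit, _ = scale_free_fit_index(np.full(50, 3.0))
        assert fit == 0.0

    def test_single_candidate_returned(self, module_sim):
        expr, _, _ = module_sim
        beta, table = dx.pick_soft_threshold(expr.iloc[:80], [23])
        assert beta == 23 and len(table) == 1

    def test_noise_expression_triggers_fallback(self, caplog):
        rng = np.random.default_rng(1)
        expr = _expr_from_profiles(rng.normal(size=(60, 12)))
        with caplog.at_level("WARNING"):
            beta, table = dx.pick_soft_threshold(expr, [1, 2, 3], target=0.90)
        assert (table.fit < 0.90).all()
        assert beta == table.loc[table.fit.idxmax(), "power"]


def _tom_oracle(A):
    n = A.shape[0]
    k = A.sum(axis=0) - np.diag(A)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (l + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


class TestTopologicalOverlap:
    def test_three_gene_hand_value(self):
        A = np.full((3, 3), 0.5)
        np.fill_diagonal(A, 1.0)
        A = pd.DataFrame(A, index=list("abc"), columns=list("abc"))
        T = dx.topological_overlap(A)
        assert T.iloc[0, 1] == pytest.approx((0.25 + 0.5) / (1 + 1 - 0.5), abs=1e-12)

    def test_identity_adjacency(self):
        A = pd.DataFrame(np.eye(4))
        T = dx.topological_overlap(A)
        off = T.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for n in (4, 8, 15):
            for _ in range(5):
                M = rng.uniform(size=(n, n))
                A = (M + M.T) / 2
                np.fill_diagonal(A, 1.0)
                T = dx.topological_overlap(pd.DataFrame(A))
                assert np.allclose(T.to_numpy(), _tom_oracle(A), atol=1e-12)

    def test_asymmetric_rejected(self):
        A = pd.DataFrame([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            dx.topological_overlap(A)


def _block_expr(sizes, n_samples=20, seed=0):
    """Blocks of identical profiles; distinct blocks exactly uncorrelated."""
    base = _corr_profiles(np.eye(len(sizes)), n_samples, seed)
    rows = []
    for b, size in enumerate(sizes):
        rows += [base[b]] * size
    return _expr_from_profiles(rows)


class TestClusterAndCut:
    def test_two_perfect_blocks(self):
        expr = _block_expr([35, 35])
        A = dx.signed_adjacency(expr, 6)
        T = dx.topological_overlap(A)
        _, labels = dx.cluster_and_cut(T, dx.NetworkConfig(min_module_size=30))
        assert labels.nunique() == 2 and (labels != UNASSIGNED).all()

    def test_small_block_unassigned(self):
        expr = _block_expr([35, 10], seed=1)
        A = dx.signed_adjacency(expr, 12)
        T = dx.topological_overlap(A)
        _, labels = dx.cluster_and_cut(T, dx.NetworkConfig(min_module_size=30))
        assert (labels.iloc[35:] == UNASSIGNED).all()
        assert (labels.iloc[:35] != UNASSIGNED).all()

    def test_average_linkage_matches_hand_calculation(self):
        """5-leaf average linkage on a hand-solved dissimilarity matrix."""
        D = np.array([
            [0.0, 0.1, 0.4, 0.9, 0.95],
            [0.1, 0.0, 0.5, 0.9, 0.95],
            [0.4, 0.5, 0.0, 0.9, 0.95],
            [0.9, 0.9, 0.9, 0.0, 0.3],
            [0.95, 0.95, 0.95, 0.3, 0.0]])
        # hand: merge (0,1)@0.1; merge ({0,1},2)@(0.4+0.5)/2=0.45;
        # merge (3,4)@0.3; final @ mean of 6 cross terms = (0.9*3+0.95*3)/6
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform
        Z = hierarchy.linkage(squareform(D), method="average")
        assert Z[:, 2] == pytest.approx([0.1, 0.3, 0.45, 0.925], abs=1e-12)


class TestEigengene:
    def test_shared_profile(self):
        v = np.array([1.0, -2, 0.5, 3, -1, 0.3])
        expr = _expr_from_profiles([v, 2 * v + 1, 0.5 * v - 3])
        eg, ve = dx.module_eigengene(expr, expr.index)
        assert ve == pytest.approx(1.0)
        z = (v - v.mean()) / v.std(ddof=1)
        assert np.allclose(np.abs(eg), np.abs(z / np.linalg.norm(z)), atol=1e-10)
        assert np.corrcoef(eg, v)[0, 1] > 0  # orientation

    def test_antipodal_profiles_sign_contract(self):
        v = np.array([1.0, -2, 0.5, 3, -1, 0.3])
        expr = _expr_from_profiles([v, -v])
        eg1, ve = dx.module_eigengene(expr, expr.index)
        eg2, _ = dx.module_eigengene(expr, expr.index)
        assert ve == pytest.approx(1.0)
        assert np.allclose(eg1, eg2)  # deterministic despite symmetry

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(4)
        expr = _expr_from_profiles(rng.normal(size=(4, 7)))
        eg, ve = dx.module_eigengene(expr, expr.index)
        Z = ((expr.T - expr.mean(axis=1)) / expr.std(axis=1, ddof=1)).T.to_numpy()
        w, v = linalg.eigh(Z.T @ Z)
        lead = v[:, np.argmax(w)]
        assert np.allclose(np.abs(eg), np.abs(lead), atol=1e-10)
        assert ve == pytest.approx(w.max() / w.sum(), abs=1e-12)

    def test_sign_rule_robust_to_single_gene_flip(self):
        rng = np.random.default_rng(5)
        profile = rng.standard_normal(10)
        expr = _expr_from_profiles([profile + rng.normal(scale=0.1, size=10)
                                    for _ in range(5)])
        eg1, _ = dx.module_eigengene(expr, expr.index)
        flipped = expr.copy()
        flipped.iloc[2] = -flipped.iloc[2]
        eg2, _ = dx.module_eigengene(flipped, flipped.index)
        assert abs(np.corrcoef(eg1, eg2)[0, 1]) > 0.99

    def test_degenerate_inputs_rejected(self):
        expr = _expr_from_profiles(np.ones((3, 5)))
        with pytest.raises(ValueError):
            dx.module_eigengene(expr, expr.index)
        with pytest.raises(ValueError):
            dx.module_eigengene(expr, expr.index[:1])


def _corr_profiles(R, n_samples=40, seed=0):
    """Sample profiles with a prescribed correlation matrix via Cholesky."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(R)
    X = rng.standard_normal((R.shape[0], n_samples))
    X = (X - X.mean(axis=1, keepdims=True))
    X /= X.std(axis=1, keepdims=True)
    # orthogonalize then recombine for near-exact correlations
    Q, _ = np.linalg.qr(X.T)
    return L @ Q.T[:R.shape[0]]


class TestMerging:
    def _assignment(self, expr, sizes):
        labels, start = [], 0
        for i, s in enumerate(sizes):
            labels += [f"M{i + 1}"] * s
        return pd.Series(labels, index=expr.index)

    def test_duplicate_modules_merge(self):
        base = _corr_profiles(np.eye(2), seed=1)
        rows = [base[0]] * 10 + [base[0]] * 10
        expr = _expr_from_profiles(np.array(rows) +
                                   np.random.default_rng(2).normal(
                                       scale=0.01, size=(20, base.shape[1])))
        labels = self._assignment(expr, [10, 10])
        merged = dx.merge_similar_modules(expr, labels, threshold=0.9)
        assert merged.nunique() == 1 and set(merged) == {"M1"}

    def test_orthogonal_modules_untouched(self):
        base = _corr_profiles(np.eye(2), seed=3)
        rows = [base[0]] * 8 + [base[1]] * 8
        expr = _expr_from_profiles(rows)
        labels = self._assignment(expr, [8, 8])
        merged = dx.merge_similar_modules(expr, labels, threshold=0.9)
        pd.testing.assert_series_equal(merged, labels)

    def test_three_module_hand_iteration(self):
        """Greedy merge follows the hand-run iteration: with eigengene
        correlations r12=0.95, r13=0.92, r23=0.80, the 0.95 pair merges
        first; the merged eigengene (proportional to e1+e2) correlates with
        e3 at (r13+r23)/sqrt(2(1+r12)) ~= 0.871 < 0.9, so iteration stops
        at two modules."""
        R = np.array([[1.0, 0.95, 0.92],
                      [0.95, 1.0, 0.80],
                      [0.92, 0.80, 1.0]])
        base = _corr_profiles(R, seed=4)
        rows = [base[0]] * 6 + [base[1]] * 6 + [base[2]] * 6
        expr = _expr_from_profiles(rows)
        labels = self._assignment(expr, [6, 6, 6])
        E, _ = eigengene_matrix(expr, labels)
        C = np.corrcoef(E.to_numpy())
        assert C[0, 1] == pytest.approx(0.95, abs=0.02)
        merged = dx.merge_similar_modules(expr, labels, threshold=0.9)
        assert merged.nunique() == 2
        assert set(merged) == {"M1", "M3"}

    def test_merge_label_order_independent(self):
        R = np.array([[1.0, 0.95, 0.1], [0.95, 1.0, 0.1], [0.1, 0.1, 1.0]])
        base = _corr_profiles(R, seed=5)
        rows = [base[0]] * 5 + [base[1]] * 5 + [base[2]] * 5
        expr = _expr_from_profiles(rows)
        l1 = self._assignment(expr, [5, 5, 5])
        # permute which block carries which label
        l2 = l1.map({"M1": "M3", "M2": "M1", "M3": "M2"})
        m1 = dx.merge_similar_modules(expr, l1, 0.9)
        m2 = dx.merge_similar_modules(expr, l2, 0.9)
        # same partition irrespective of label names
        assert (pd.crosstab(m1, m2).to_numpy() > 0).sum() == m1.nunique()

    def test_unassigned_never_merges(self):
        base = _corr_profiles(np.eye(2), seed=6)
        rows = [base[0]] * 5 + [base[0]] * 5
        expr = _expr_from_profiles(rows)
        labels = pd.Series(["M1"] * 5 + [UNASSIGNED] * 5, index=expr.index)
        merged = dx.merge_similar_modules(expr, labels, 0.9)
        pd.testing.assert_series_equal(merged, labels)


class TestRobustness:
    def test_contract_and_strong_modules(self, module_sim):
        expr, meta, truth = module_sim
        cfg = dx.NetworkConfig(power=10, seed=3, resamples=15)
        net = dx.CoexpressionNetwork(expr, meta, cfg).fit(robustness=True)
        rep = net.robustness
        assert ((rep.support >= 0) & (rep.support <= 1)).all()
        full_labels = set(net.assignment.unique()) - {UNASSIGNED}
        assert full_labels <= {"M1", "M2", "M3", "M4", "M5"}
        planted = truth.module_label != "none"
        assert (rep.support[planted] >= 0.5).mean() >= 0.95

    def test_kept_exceeding_replicates_rejected(self, module_sim):
        expr, meta, _ = module_sim
        cfg = dx.NetworkConfig(power=10, kept_replicates=7, resamples=2)
        with pytest.raises(ValueError, match="replicates"):
            dx.resample_robustness(expr, meta, cfg,
                                   pd.Series(UNASSIGNED, index=expr.index))

    def test_match_rule_tiebreak(self):
        full = pd.Series(["A"] * 10 + ["B"] * 10 + [UNASSIGNED] * 5,
                         index=[f"g{i}" for i in range(25)])
        res = pd.Series([UNASSIGNED] * 25, index=full.index)
        res.iloc[0:5] = "R1"    # 5 of A's 10 genes
        res.iloc[10:15] = "R2"  # 5 of B's 10 genes
        mapping = _match_modules(res, full, match_fraction=0.10)
        assert mapping == {"R1": "A", "R2": "B"}
        # below match fraction: no match
        res2 = pd.Series([UNASSIGNED] * 25, index=full.index)
        res2.iloc[0] = "R1"
        assert _match_modules(res2, full, match_fraction=0.2) == {}


class TestEigengeneAnova:
    def _meta(self):
        rows = []
        for t in ("B", "H", "O"):
            for d in ("C", "DR", "HS"):
                for r in range(1, 7):
                    rows.append({"sample_id": f"{t}_{d}_{r}", "diet": d,
                                 "tissue": t, "replicate": r, "batch": r})
        return pd.DataFrame(rows)

    def test_tissue_signal_dominates(self):
        meta = self._meta()
        rng = np.random.default_rng(7)
        eg = meta.tissue.map({"B": 0.0, "H": 1.0, "O": 2.0}).to_numpy()
        eg = pd.Series(eg + rng.normal(scale=0.05, size=len(meta)),
                       index=meta.sample_id)
        tab = dx.eigengene_anova(eg, meta)
        p = tab.set_index("term").p
        assert p["tissue"] < p["diet"]
        assert p["tissue"] < 1e-20

    def test_unbalanced_design_rejected(self):
        meta = self._meta().iloc[:-1]
        eg = pd.Series(np.random.default_rng(8).normal(size=len(meta)),
                       index=meta.sample_id)
        with pytest.raises(ValueError, match="balanced"):
            dx.eigengene_anova(eg, meta)

    def test_bh_across_modules(self, module_sim):
        expr, meta, _ = module_sim
        net = dx.CoexpressionNetwork(expr, meta, dx.NetworkConfig(power=10)).fit()
        assert net.anova is not None
        for term, grp in net.anova.groupby("term"):
            assert (grp.p_adj >= grp.p - 1e-12).all()


class TestModuleRecovery:
    def test_planted_modules_recovered(self, module_sim):
        from sklearn.metrics import adjusted_rand_score
        expr, meta, truth = module_sim
        net = dx.CoexpressionNetwork(expr, meta, dx.NetworkConfig(power=10)).fit()
        planted = truth.module_label != "none"
        ari = adjusted_rand_score(truth.module_label[planted],
                                  net.assignment[planted])
        assert ari >= 0.8
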