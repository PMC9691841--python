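"""MI estimation, independence null, edge selection, DPI, regulon assembly."""

import numpy as np
import pandas as pd
import pytest

from mrnet.network import (
    apply_dpi,
    build_edge_list,
    edges_to_regulons,
    estimate_mi,
    fit_mi_null,
    n_candidate_pairs,
)
from mrnet.synthetic import TrueNetwork, generate_cohort


class TestEstimateMi:
    def test_symmetry_exact(self, rng):
        x = rng.standard_normal(80)
        y = 0.5 * x + rng.standard_normal(80)
        assert estimate_mi(x, y) == estimate_mi(y, x)

    def test_self_information_dominates(self, rng):
        x = rng.standard_normal(60)
        self_mi = estimate_mi(x, x)
        for _ in range(10):
            assert estimate_mi(x, rng.standard_normal(60)) <= self_mi

    def test_monotone_transform_invariance_exact(self, rng):
        x = rng.standard_normal(100)
        y = rng.standard_normal(100)
        assert estimate_mi(x, y) == estimate_mi(x ** 3, np.exp(y))
        assert estimate_mi(x, x ** 3) == estimate_mi(x, x)

    def test_nonnegative(self, rng):
        for _ in range(20):
            assert estimate_mi(rng.standard_normal(30), rng.standard_normal(30)) >= 0

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            estimate_mi(np.ones(10), np.arange(10.0))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            estimate_mi(np.array([1.0, 2.0]), np.array([3.0, 4.0]))


@pytest.fixture(scope="module")
def noise_expr():
    rng = np.random.default_rng(5)
    return pd.DataFrame(rng.standard_normal((60, 120)),
                        index=[f"G{i}" for i in range(60)])


@pytest.fixture(scope="module")
def null_model(noise_expr):
    return fit_mi_null(noise_expr, n_perm=600, n_pairs_tested=1000, seed=1)


class TestMiNull:
    def test_zero_mi_gives_p_one(self, null_model):
        assert null_model.corrected_pvalue(0.0)[0] == 1.0

    def test_p_at_95th_percentile_is_about_005(self, null_model):
        q95 = np.quantile(null_model.null_mi, 0.95)
        assert null_model.pvalue(q95)[0] == pytest.approx(0.05, abs=0.02)

    def test_bonferroni_identity(self, null_model):
        mi = np.array([0.0, 0.02, 0.1, 0.5])
        raw = null_model.pvalue(mi)
        np.testing.assert_allclose(null_model.corrected_pvalue(mi),
                                   np.minimum(1.0, raw * null_model.n_pairs_tested))

    def test_p_monotone_nonincreasing_in_mi(self, null_model):
        grid = np.linspace(0, 1.5, 200)
        p = null_model.pvalue(grid)
        assert (np.diff(p) <= 1e-12).all()

    def test_extrapolates_far_below_empirical_resolution(self, null_model):
        assert null_model.pvalue(1.5)[0] < 1e-8

    def test_too_few_permutations_rejected(self, noise_expr):
        with pytest.raises(ValueError, match="n_perm"):
            fit_mi_null(noise_expr, n_perm=50)


@pytest.fixture(scope="module")
def planted():
    """Strong planted regulons: strength 0.9, noise 0.3, n=200."""
    truth = TrueNetwork(
        regulators=["TF1", "TF2", "TF3", "TF4", "TF5"],
        regulons={f"TF{k}": [(f"G{(k - 1) * 20 + j:03d}", 1, 0.9) for j in range(20)]
                  for k in range(1, 6)},
        planted_activated=set(), planted_repressed=set(),
        genes=[f"TF{k}" for k in range(1, 6)] + [f"G{i:03d}" for i in range(150)],
    )
    cohort = generate_cohort(truth, 100, 100, effect_size=0.0, noise_sd=0.3,
                             seed=11, n_cell_types=0)
    return truth, cohort


class TestBuildEdgeList:
    def test_recovers_planted_edges_with_high_precision(self, planted):
        truth, cohort = planted
        edges = build_edge_list(cohort.expression, truth.regulators, seed=2)
        found = set(zip(edges["tf"], edges["target"]))
        true = truth.true_edges()
        assert true <= found
        assert len(found & true) / len(found) >= 0.9

    def test_zero_threshold_empty(self, planted):
        truth, cohort = planted
        edges = build_edge_list(cohort.expression, truth.regulators,
                                p_threshold=0.0, seed=2)
        assert edges.empty

    def test_no_self_or_duplicate_edges(self, planted):
        truth, cohort = planted
        edges = build_edge_list(cohort.expression, truth.regulators, seed=2)
        assert (edges["tf"] != edges["target"]).all()
        pairs = [frozenset(p) for p in zip(edges["tf"], edges["target"])]
        assert len(pairs) == len(set(pairs))

    def test_independent_pairs_never_pass_default_threshold(self, noise_expr, null_model):
        """100 independent gene pairs: none reach the 1e-8 tail cut."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            mi = estimate_mi(rng.standard_normal(120), rng.standard_normal(120))
            assert null_model.pvalue(mi)[0] > 1e-8

    def test_empty_regulators_rejected(self, noise_expr):
        with pytest.raises(ValueError, match="regulator"):
            build_edge_list(noise_expr, [], seed=0)


def _dpi_oracle(edges: pd.DataFrame, tolerance: float) -> pd.DataFrame:
    """Brute force: enumerate every ordered triple over the original list."""
    mi = {}
    for row in edges.itertuples():
        mi[(row.tf, row.target)] = row.mi
        mi[(row.target, row.tf)] = row.mi
    regulators = set(edges["tf"])
    keep = []
    for row in edges.itertuples():
        x, y = row.tf, row.target
        removed = False
        for z in regulators:
            if z in (x, y):
                continue
            if (x, z) in mi and (z, y) in mi:
                if row.mi < (1 - tolerance) * min(mi[(x, z)], mi[(z, y)]):
                    removed = True
                    break
        keep.append(not removed)
    return edges[np.array(keep)].reset_index(drop=True)


def _random_edges(rng, n_nodes=30, n_tf=8):
    tfs = [f"T{i}" for i in range(n_tf)]
    targets = [f"N{i}" for i in range(n_nodes - n_tf)]
    rows = []
    seen = set()
    for _ in range(rng.integers(20, 80)):
        tf = tfs[rng.integers(n_tf)]
        other = ([t for t in tfs if t != tf] + targets)[rng.integers(n_nodes - 1)]
        if frozenset((tf, other)) in seen:
            continue
        seen.add(frozenset((tf, other)))
        rows.append({"tf": tf, "target": other,
                     "mi": float(rng.uniform(0.01, 1.0)), "p": 1e-9})
    return pd.DataFrame(rows, columns=["tf", "target", "mi", "p"])


class TestApplyDpi:
    def test_chain_removed(self):
        edges = pd.DataFrame({"tf": ["x", "z", "x"], "target": ["z", "y", "y"],
                              "mi": [0.8, 0.7, 0.3], "p": [0.0] * 3})
        out = apply_dpi(edges, tolerance=0.1)
        assert set(zip(out["tf"], out["target"])) == {("x", "z"), ("z", "y")}

    def test_chain_kept_at_tolerance_boundary(self):
        edges = pd.DataFrame({"tf": ["x", "z", "x"], "target": ["z", "y", "y"],
                              "mi": [0.8, 0.7, 0.65], "p": [0.0] * 3})
        out = apply_dpi(edges, tolerance=0.1)
        assert len(out) == 3  # 0.65 >= 0.9 * 0.7

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        edges = _random_edges(rng)
        for tol in (0.0, 0.1, 0.3):
            out = apply_dpi(edges, tolerance=tol)
            oracle = _dpi_oracle(edges, tol)
            pd.testing.assert_frame_equal(out, oracle)

    def test_output_subset_of_input(self, rng):
        edges = _random_edges(rng)
        out = apply_dpi(edges, tolerance=0.1)
        assert len(out) <= len(edges)
        merged = out.merge(edges, on=list(edges.columns), how="left", indicator=True)
        assert (merged["_merge"] == "both").all()

    def test_empty_input(self):
        empty = pd.DataFrame(columns=["tf", "target", "mi", "p"])
        assert apply_dpi(empty).empty

    def test_bad_tolerance_rejected(self):
        with pytest.raises(ValueError):
            apply_dpi(pd.DataFrame(columns=["tf", "target", "mi", "p"]), tolerance=1.0)


class TestEdgesToRegulons:
    def test_modes_positive_for_positive_regulon(self):
        rng = np.random.default_rng(21)
        tf = rng.standard_normal(100)
        targets = {f"G{i}": tf * 0.95 + 0.1 * rng.standard_normal(100) for i in range(5)}
        expr = pd.DataFrame({"TF1": tf, **targets}).T
        edges = pd.DataFrame({"tf": "TF1", "target": list(targets),
                              "mi": rng.uniform(0.3, 1.0, 5), "p": 1e-9})
        regs = edges_to_regulons(edges, expr, min_size=3)
        assert (regs["TF1"].modes > 0).all()

    def test_min_size_filter(self, small_cohort):
        edges = pd.DataFrame({"tf": "TF01", "target": ["G00001", "G00002", "G00003"],
                              "mi": [0.5, 0.4, 0.3], "p": 1e-9})
        assert edges_to_regulons(edges, small_cohort.expression, min_size=25) == {}

    def test_max_mi_edge_has_likelihood_one(self, small_cohort):
        edges = pd.DataFrame({"tf": "TF01",
                              "target": [f"G{i + 1:05d}" for i in range(6)],
                              "mi": [0.1, 0.2, 0.9, 0.3, 0.4, 0.5], "p": 1e-9})
        regs = edges_to_regulons(edges, small_cohort.expression, min_size=5)
        reg = regs["TF01"]
        assert reg.likelihoods.max() == 1.0
        assert reg.likelihoods[reg.targets.index("G00003")] == 1.0

    def test_candidate_pair_count(self):
        assert n_candidate_pairs(20, 1000) == 20 * 999
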