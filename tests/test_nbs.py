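"""Network-based statistic: z-scoring, edge GLM, thresholding, permutations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from megconn import (
    DesignSpec,
    NetworkBasedStatistic,
    edge_glm,
    extract_components,
    nbs_test,
    select_threshold,
    zscore_edges,
)
from megconn.nbs import _max_extent


def _group_cohort(n_a, n_b, rng=None, **extra):
    n = n_a + n_b
    d = {"subject_id": [f"S{k:03d}" for k in range(n)], "group": ["A"] * n_a + ["B"] * n_b}
    if rng is not None:
        d["age_at_scan"] = rng.normal(5.8, 0.3, n)
        d["sex"] = rng.choice(["M", "F"], n)
    d.update(extra)
    return pd.DataFrame(d)


class TestZscoreEdges:
    def test_textbook_z_scores(self):
        mats = np.zeros((3, 3, 3))
        for k, v in enumerate([1.0, 2.0, 3.0]):
            mats[k, 0, 1] = mats[k, 1, 0] = v / 10  # keep within [0,1]
        z = zscore_edges(mats)
        e = np.flatnonzero((z.edge_i == 0) & (z.edge_j == 1))[0]
        np.testing.assert_allclose(z.values[:, e], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_constant_edge_flagged_and_zeroed(self):
        mats = np.zeros((3, 3, 3))
        for k in range(3):
            mats[k, 0, 1] = mats[k, 1, 0] = 0.5
        z = zscore_edges(mats)
        e = np.flatnonzero((z.edge_i == 0) & (z.edge_j == 1))[0]
        assert z.zero_variance[e]
        np.testing.assert_array_equal(z.values[:, e], 0.0)

    def test_output_standardised(self, random_wpli_stack):
        z = zscore_edges(random_wpli_stack)
        keep = ~z.zero_variance
        np.testing.assert_allclose(z.values[:, keep].mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.values[:, keep].std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_band_mismatch_rejected(self, rng):
        from megconn import ConnectivityMatrix
        from megconn.bands import ALPHA, THETA

        v = np.zeros((3, 3))
        mats = [
            ConnectivityMatrix("a", ALPHA, v, 1),
            ConnectivityMatrix("b", ALPHA, v, 1),
            ConnectivityMatrix("c", THETA, v, 1),
        ]
        with pytest.raises(ValueError, match="band mismatch"):
            zscore_edges(mats)


class TestEdgeGlm:
    def test_matches_classical_two_sample_t(self, random_wpli_stack):
        z = zscore_edges(random_wpli_stack)
        cohort = _group_cohort(10, 10)
        design = DesignSpec(
            mode="group_contrast", predictor="group", covariates=(), contrast_level="A"
        )
        es = edge_glm(z, cohort, design)
        for e in range(0, z.n_edges, 7):
            ya, yb = z.values[:10, e], z.values[10:, e]
            t_classic = stats.ttest_ind(ya, yb, equal_var=True).statistic
            assert es.t_values[z.edge_i[e], z.edge_j[e]] == pytest.approx(
                t_classic, abs=1e-10
            )
        assert es.df == 18

    def test_matches_statsmodels_with_covariates(self, random_wpli_stack, rng):
        import statsmodels.api as sm

        z = zscore_edges(random_wpli_stack)
        cohort = _group_cohort(10, 10, rng=rng)
        design = DesignSpec(
            mode="group_contrast",
            predictor="group",
            covariates=("age_at_scan", "sex"),
            contrast_level="A",
        )
        es = edge_glm(z, cohort, design)
        X = pd.DataFrame(
            {
                "g": (cohort["group"] == "A").astype(float),
                "age": cohort["age_at_scan"],
                "sexM": (cohort["sex"] == "M").astype(float),
            }
        )
        X = sm.add_constant(X)
        for e in (0, 11, 29):
            ref = sm.OLS(z.values[:, e], X).fit()
            assert es.t_values[z.edge_i[e], z.edge_j[e]] == pytest.approx(
                ref.tvalues["g"], abs=1e-10
            )

    def test_duplicate_covariate_rank_deficiency(self, random_wpli_stack, rng):
        z = zscore_edges(random_wpli_stack)
        cohort = _group_cohort(10, 10, rng=rng)
        cohort["age_copy"] = cohort["age_at_scan"]
        design = DesignSpec(
            mode="group_contrast",
            predictor="group",
            covariates=("age_at_scan", "age_copy"),
            contrast_level="A",
        )
        with pytest.raises(ValueError, match="collinear"):
            edge_glm(z, cohort, design)

    def test_permuted_predictor_t_is_student_calibrated(self, rng):
        # under a permuted (null) continuous predictor the edge t statistics
        # follow a Student-t law: about 5% exceed the two-sided critical value
        n, R = 60, 40
        mats = rng.random((n, R, R))
        mats = (mats + mats.swapaxes(1, 2)) / 2
        for m in mats:
            np.fill_diagonal(m, 0)
        z = zscore_edges(np.clip(mats, 0, 1))
        cohort = _group_cohort(30, 30, iq=rng.permutation(np.linspace(80, 120, n)))
        design = DesignSpec(mode="association", predictor="iq", covariates=())
        es = edge_glm(z, cohort, design)
        t_crit = stats.t.ppf(0.975, es.df)
        t = es.t_values[np.triu_indices(R, 1)]
        frac = np.mean(np.abs(t) > t_crit)
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_listwise_deletion_of_missing_predictor(self, random_wpli_stack):
        z = zscore_edges(random_wpli_stack)
        cohort = _group_cohort(10, 10, iq=np.r_[np.full(3, np.nan), np.arange(17.0)])
        design = DesignSpec(mode="association", predictor="iq", covariates=())
        es = edge_glm(z, cohort, design)
        assert es.df == 17 - 2  # 17 complete rows, intercept + slope


class TestSelectThreshold:
    def test_ninety_region_one_percent_gives_forty(self, rng):
        t = rng.standard_normal(4005)
        thr = select_threshold(t, 0.01)
        assert (t >= thr).sum() == 40

    def test_fifteen_edges_fraction_point_two_gives_three(self, rng):
        t = rng.standard_normal(15)
        thr = select_threshold(t, 0.2)
        assert (t >= thr).sum() == 3

    def test_all_tied_keeps_all(self):
        t = np.full(20, 1.5)
        thr = select_threshold(t, 0.1)
        assert (t >= thr).sum() == 20

    def test_tiny_edge_count_warns_and_keeps_one(self):
        with pytest.warns(UserWarning, match="keeping one edge"):
            thr = select_threshold(np.array([3.0, 1.0, 2.0]), 0.01)
        assert thr == 3.0


class TestExtractComponents:
    def test_two_components_example(self):
        comps = extract_components([(1, 2), (2, 3), (4, 5)])
        assert [(c.extent, c.nodes) for c in comps] == [
            (2, frozenset({1, 2, 3})),
            (1, frozenset({4, 5})),
        ]

    def test_empty_edge_set(self):
        assert extract_components([]) == []

    def test_path_graph(self):
        edges = [(k, k + 1) for k in range(40)]
        comps = extract_components(edges)
        assert len(comps) == 1
        assert comps[0].extent == 40
        assert len(comps[0].nodes) == 41

    def test_matches_brute_force_on_random_graphs(self, rng):
        # breadth-first-search oracle on random graphs of <= 20 nodes
        def bfs_components(edges):
            adj = {}
            for a, b in edges:
                adj.setdefault(a, set()).add(b)
                adj.setdefault(b, set()).add(a)
            seen, out = set(), []
            for start in sorted(adj):
                if start in seen:
                    continue
                queue, nodes = [start], set()
                while queue:
                    v = queue.pop()
                    if v in nodes:
                        continue
                    nodes.add(v)
                    queue.extend(adj[v] - nodes)
                seen |= nodes
                n_edges = sum(1 for a, b in edges if a in nodes)
                out.append((n_edges, frozenset(nodes)))
            return sorted(out, key=lambda t: (-t[0], min(t[1])))

        for _ in range(300):
            n_nodes = rng.integers(2, 21)
            n_edges = rng.integers(0, 2 * n_nodes)
            edges = set()
            for _ in range(n_edges):
                a, b = rng.choice(n_nodes, 2, replace=False)
                edges.add((int(min(a, b)), int(max(a, b))))
            comps = extract_components(edges)
            assert [(c.extent, c.nodes) for c in comps] == bfs_components(edges)
            if edges:
                assert _max_extent(
                    np.array([e[0] for e in edges]), np.array([e[1] for e in edges])
                ) == max(c.extent for c in comps)

    @given(st.sets(st.tuples(st.integers(0, 12), st.integers(0, 12)), max_size=25))
    def test_handshake_and_partition_invariants(self, raw_edges):
        edges = {(min(a, b), max(a, b)) for a, b in raw_edges if a != b}
        comps = extract_components(edges)
        assert sum(c.extent for c in comps) == len(edges)
        all_nodes = [n for c in comps for n in c.nodes]
        assert len(all_nodes) == len(set(all_nodes))  # components partition nodes


class TestNbsFit:
    def _stack_and_cohort(self, rng, n_a=10, n_b=10, R=15):
        n = n_a + n_b
        mats = rng.random((n, R, R))
        mats = (mats + mats.swapaxes(1, 2)) / 2
        for m in mats:
            np.fill_diagonal(m, 0)
        return zscore_edges(np.clip(mats, 0, 1)), _group_cohort(n_a, n_b, rng=rng)

    def test_p_value_convention_includes_observed(self, rng):
        z, cohort = self._stack_and_cohort(rng)
        design = DesignSpec(
            mode="group_contrast",
            predictor="group",
            covariates=(),
            contrast_level="A",
            n_permutations=200,
            target_edge_fraction=0.05,
        )
        res = nbs_test(z, cohort, design, seed=0)
        nperm = res.n_permutations_used
        for c in res.components:
            expected = (1 + int((res.null_max_extents >= c.extent).sum())) / (1 + nperm)
            assert c.p_corrected == pytest.approx(expected)
            assert c.p_corrected >= 1.0 / (1 + nperm)

    def test_deterministic_given_seed(self, rng):
        z, cohort = self._stack_and_cohort(rng)
        design = DesignSpec(
            mode="group_contrast",
            predictor="group",
            covariates=("age_at_scan", "sex"),
            contrast_level="A",
            n_permutations=150,
        )
        r1 = nbs_test(z, cohort, design, seed=7)
        r2 = nbs_test(z, cohort, design, seed=7)
        np.testing.assert_array_equal(r1.null_max_extents, r2.null_max_extents)
        assert [c.p_corrected for c in r1.components] == [
            c.p_corrected for c in r2.components
        ]

    def test_direction_flips_tested_tail(self, rng):
        z, cohort = self._stack_and_cohort(rng)
        pos = DesignSpec(
            mode="group_contrast", predictor="group", covariates=(),
            contrast_level="A", direction="positive", n_permutations=100,
        )
        neg = DesignSpec(
            mode="group_contrast", predictor="group", covariates=(),
            contrast_level="A", direction="negative", n_permutations=100,
        )
        res_p = nbs_test(z, cohort, pos, seed=0)
        res_n = nbs_test(z, cohort, neg, seed=0)
        t = res_p.edge_stats.t_values
        iu = np.triu_indices(t.shape[0], 1)
        # positive threshold selects the upper tail; negative the lower tail
        assert res_p.threshold <= t[iu].max()
        assert -res_n.threshold >= t[iu].min()

    def test_too_few_subjects_rejected(self, rng):
        mats = rng.random((4, 6, 6))
        mats = (mats + mats.swapaxes(1, 2)) / 2
        for m in mats:
            np.fill_diagonal(m, 0)
        z = zscore_edges(np.clip(mats, 0, 1))
        cohort = _group_cohort(2, 2)
        design = DesignSpec(
            mode="group_contrast", predictor="group", covariates=(), contrast_level="A"
        )
        with pytest.raises(ValueError, match="at least 6 subjects"):
            NetworkBasedStatistic(z, cohort, design)

    def test_association_mode_uses_freedman_lane(self, rng):
        z, cohort = self._stack_and_cohort(rng)
        cohort["iq"] = rng.normal(100, 15, len(cohort))
        design = DesignSpec(
            mode="association",
            predictor="iq",
            covariates=("age_at_scan",),
            n_permutations=150,
            target_edge_fraction=0.05,
        )
        res = nbs_test(z, cohort, design, seed=3)
        assert not res.exhaustive
        assert res.n_permutations_used == 150
        assert res.null_max_extents.shape == (150,)

    def test_summary_mentions_key_quantities(self, rng):
        z, cohort = self._stack_and_cohort(rng)
        design = DesignSpec(
            mode="group_contrast", predictor="group", covariates=(),
            contrast_level="A", n_permutations=100, target_edge_fraction=0.05,
        )
        res = nbs_test(z, cohort, design, seed=0)
        text = res.summary()
        assert "group" in text and "permutations" in text and "thresh" in text


class TestDesignSpecValidation:
    def test_predictor_among_covariates(self):
        with pytest.raises(ValueError, match="also listed"):
            DesignSpec(mode="association", predictor="iq", covariates=("iq",))

    def test_fraction_range(self):
        with pytest.raises(ValueError, match="target_edge_fraction"):
            DesignSpec(mode="association", predictor="iq", target_edge_fraction=1.5)

    def test_minimum_permutations(self):
        with pytest.raises(ValueError, match="100"):
            DesignSpec(mode="association", predictor="iq", n_permutations=50)
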