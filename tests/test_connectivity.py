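"""KS statistic, raw/scaled scores, aggregation, enrichment, permutation p."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import sigconn as sc
from sigconn.errors import CoverageError, InputError
from conftest import ks_bruteforce


class TestKsStatistic:
    @pytest.mark.parametrize(
        "ranks,n,es",
        [
            ((1, 2), 10, 0.8),    # tags at the very top: es = 1 - t/n
            ((9, 10), 10, -0.9),  # tags at the very bottom
        ],
    )
    def test_boundary_examples(self, ranks, n, es):
        r = sc.ks_statistic(ranks, n)
        assert r.es == pytest.approx(es)
        assert r.a >= 0 and r.b >= 0

    def test_tie_resolves_to_positive_branch(self):
        r = sc.ks_statistic((3, 7), 10)
        assert r.a == pytest.approx(0.3) and r.b == pytest.approx(0.3)
        assert r.es == pytest.approx(0.3) and r.es > 0

    @pytest.mark.parametrize("bad", [(2, 1), (0, 3), (3, 11), (3, 3)])
    def test_invalid_ranks_rejected(self, bad):
        with pytest.raises(InputError):
            sc.ks_statistic(bad, 10)

    @given(st.data())
    def test_matches_bruteforce_oracle(self, data):
        n = data.draw(st.integers(2, 50))
        t = data.draw(st.integers(1, n))
        ranks = sorted(data.draw(st.permutations(range(1, n + 1)))[:t])
        assert sc.ks_statistic(ranks, n).es == ks_bruteforce(ranks, n)

    @given(st.data())
    def test_es_bounded_by_one(self, data):
        n = data.draw(st.integers(2, 60))
        t = data.draw(st.integers(1, n))
        ranks = sorted(data.draw(st.permutations(range(1, n + 1)))[:t])
        assert abs(sc.ks_statistic(ranks, n).es) <= 1


def _profile_from_ranks(ranks_by_probe, iid="i0", cpd="c", cell="L"):
    return sc.InstanceProfile(iid, cpd, cell, pd.Series(ranks_by_probe))


class TestInstanceConnectivity:
    def _profile(self):
        # 10 probes; query-up tags at top ranks, query-down tags at bottom
        ranks = {f"p{i}": i for i in range(1, 11)}
        return _profile_from_ranks(ranks)

    def test_opposite_signs_add(self):
        prof = self._profile()
        q = sc.GeneSignature(up_tags=("p1", "p2"), down_tags=("p9", "p10"))
        res = sc.instance_connectivity(prof, q)
        assert res.ks_up.es == pytest.approx(0.8)
        assert res.ks_down.es == pytest.approx(-0.9)
        assert res.s == pytest.approx(1.7)

    def test_same_strict_sign_gives_null(self):
        prof = self._profile()
        q = sc.GeneSignature(up_tags=("p1", "p2"), down_tags=("p3", "p4"))
        res = sc.instance_connectivity(prof, q)
        assert res.ks_up.es > 0 and res.ks_down.es > 0
        assert res.s == 0.0

    def test_swap_negates_nonzero_s(self):
        prof = self._profile()
        q = sc.GeneSignature(up_tags=("p1", "p2"), down_tags=("p9", "p10"))
        s = sc.instance_connectivity(prof, q).s
        s_swapped = sc.instance_connectivity(prof, q.swapped()).s
        assert s_swapped == pytest.approx(-s)

    def test_one_sided_queries_keep_sign_convention(self):
        prof = self._profile()
        up_only = sc.instance_connectivity(prof, sc.GeneSignature(up_tags=("p1", "p2")))
        down_only = sc.instance_connectivity(
            prof, sc.GeneSignature(down_tags=("p1", "p2"))
        )
        assert up_only.s == pytest.approx(0.8)
        # same tags as down set: instance raises them, so discordant
        assert down_only.s == pytest.approx(-0.8)

    def test_absent_tags_raise_coverage_error(self):
        prof = self._profile()
        with pytest.raises(CoverageError):
            sc.instance_connectivity(prof, sc.GeneSignature(up_tags=("nope",)))


class TestScaleScores:
    def test_worked_example(self):
        factors, c = sc.scale_scores([1.7, -1.7, 0.5, 0.0])
        assert factors.p_max == pytest.approx(1.7)
        assert factors.q_min == pytest.approx(-1.7)
        assert c == pytest.approx([1.0, -1.0, 0.5 / 1.7, 0.0])

    def test_all_zero(self):
        factors, c = sc.scale_scores([0.0, 0.0])
        assert factors.p_max == 0.0 and factors.q_min == 0.0
        assert (c == 0).all()

    @given(
        st.lists(st.floats(-3, 3), min_size=1, max_size=40),
        st.floats(0.1, 50),
    )
    def test_scale_invariance(self, scores, lam):
        _, c1 = sc.scale_scores(scores)
        _, c2 = sc.scale_scores([lam * s for s in scores])
        assert np.allclose(c1, c2)

    @given(st.lists(st.floats(-3, 3), min_size=1, max_size=40))
    def test_bounds_and_extremes(self, scores):
        _, c = sc.scale_scores(scores)
        assert np.all(np.abs(c) <= 1 + 1e-12)
        s = np.asarray(scores)
        if (s > 0).any():
            assert np.isclose(c.max(), 1.0)
        if (s < 0).any():
            assert np.isclose(c.min(), -1.0)


def _conn(iid, s, c):
    return sc.InstanceConnectivity(instance_id=iid, ks_up=None, ks_down=None, s=s, c=c)


class TestAggregateCompound:
    def test_mean_of_member_scores(self):
        meta = pd.DataFrame(
            {"compound": ["d", "d", "d"], "cell_line": ["L", "L", "L"]},
            index=pd.Index(["i0", "i1", "i2"], name="instance_id"),
        )
        scores = [_conn("i0", 1.0, 1.0), _conn("i1", -1.0, -1.0), _conn("i2", 0.3, 0.2941)]
        groups = sc.aggregate_compound(scores, meta, sc.QueryConfig())
        assert len(groups) == 1
        assert groups[0].similarity_mean == pytest.approx((1 - 1 + 0.2941) / 3)
        assert groups[0].n == 3

    def test_singleton_group(self):
        meta = pd.DataFrame(
            {"compound": ["d"], "cell_line": ["L"]},
            index=pd.Index(["i0"], name="instance_id"),
        )
        groups = sc.aggregate_compound([_conn("i0", -0.4, -0.4)], meta, sc.QueryConfig())
        assert groups[0].similarity_mean == pytest.approx(-0.4)
        assert groups[0].n == 1

    def test_exclude_null_instances(self):
        meta = pd.DataFrame(
            {"compound": ["d"] * 3, "cell_line": ["L"] * 3},
            index=pd.Index(["i0", "i1", "i2"], name="instance_id"),
        )
        scores = [_conn("i0", 0.5, 0.5), _conn("i1", 0.0, 0.0), _conn("i2", 0.0, 0.0)]
        cfg = sc.QueryConfig(include_null_instances=False)
        groups = sc.aggregate_compound(scores, meta, cfg)
        assert groups[0].similarity_mean == pytest.approx(0.5)
        assert groups[0].n == 3
        assert groups[0].n_nonnull == 1

    def test_group_by_compound_merges_cell_lines(self):
        meta = pd.DataFrame(
            {"compound": ["d", "d"], "cell_line": ["PC3", "MCF7"]},
            index=pd.Index(["i0", "i1"], name="instance_id"),
        )
        scores = [_conn("i0", 1.0, 1.0), _conn("i1", 0.5, 0.5)]
        groups = sc.aggregate_compound(scores, meta, sc.QueryConfig(group_by="compound"))
        assert len(groups) == 1 and groups[0].n == 2


class TestSetEnrichment:
    def test_group_at_top(self):
        assert sc.set_enrichment([1, 2, 3], 3, 100) == pytest.approx(0.97)

    def test_group_at_bottom(self):
        # b-branch: b = max(99/100 - 0, 100/100 - 1/2) = 0.99
        assert sc.set_enrichment([99, 100], 2, 100) == pytest.approx(-0.99)

    def test_small_worked_case_bruteforce(self):
        assert sc.set_enrichment([1, 3], 2, 5) == pytest.approx(ks_bruteforce([1, 3], 5))
        assert sc.set_enrichment([1, 3], 2, 5) == pytest.approx(0.4)


class TestPermutationP:
    def test_exact_enumeration_worked_case(self):
        # N=5, members at (1,3), es=+0.4; qualifying pairs by exhaustive
        # enumeration with the KS oracle: (1,2)->0.6, (1,3)->0.4, (2,3)->0.4
        cfg = sc.QueryConfig(direction_rule="signed")
        obs = sc.set_enrichment([1, 3], 2, 5)
        expected = [
            ks_bruteforce(list(pair), 5) for pair in itertools.combinations(range(1, 6), 2)
        ]
        count = sum(1 for e in expected if e > 0 and e >= obs)
        assert count == 3
        assert sc.permutation_p(obs, 2, 5, cfg) == pytest.approx(3 / 10)

    def test_sampling_converges_to_exact(self):
        cfg = sc.QueryConfig(direction_rule="signed", n_perm=100_000, seed=5)
        obs = sc.set_enrichment([1, 3], 2, 5)
        rng = np.random.default_rng(cfg.seed)
        null = sc.sample_null_enrichment(2, 5, cfg.n_perm, rng)
        p_hat = sc.permutation_p(obs, 2, 5, cfg, null_es=null)
        se = math.sqrt(0.3 * 0.7 / cfg.n_perm)
        assert abs(p_hat - 0.3) <= 3 * se

    def test_maximal_observed_has_minimal_exact_p(self):
        # members at the top n positions: no other subset is strictly more
        # extreme, so the exact p is 1/C(N, n)
        cfg = sc.QueryConfig(direction_rule="signed")
        obs = sc.set_enrichment([1, 2], 2, 8)
        assert sc.permutation_p(obs, 2, 8, cfg) == pytest.approx(1 / math.comb(8, 2))

    def test_absolute_rule_counts_both_tails(self):
        cfg_abs = sc.QueryConfig(direction_rule="absolute")
        cfg_sig = sc.QueryConfig(direction_rule="signed")
        obs = sc.set_enrichment([1, 2], 2, 8)
        assert sc.permutation_p(obs, 2, 8, cfg_abs) >= sc.permutation_p(obs, 2, 8, cfg_sig)

    def test_pseudo_count_mode_avoids_zero(self):
        cfg = sc.QueryConfig(direction_rule="signed", pseudo_count=True)
        obs = sc.set_enrichment([1, 2], 2, 8)
        p = sc.permutation_p(obs, 2, 8, cfg)
        total = math.comb(8, 2)
        assert p == pytest.approx(2 / (total + 1))


class TestRankResults:
    def _group(self, key, p, enr, mean=0.0):
        return sc.CompoundResult(
            group_key=key, compound=key, cell_line="", n=1,
            similarity_mean=mean, n_nonnull=1, enrichment=enr, p_value=p,
        )

    def test_p_then_enrichment(self):
        groups = [
            self._group("a", 0.001, 0.90),
            self._group("b", 0.001, 0.95),
            self._group("c", 0.010, 0.99),
        ]
        ranked = sc.rank_results(groups)
        assert [g.group_key for g in ranked] == ["b", "a", "c"]
        assert [g.rank for g in ranked] == [1, 2, 3]

    def test_full_tie_falls_back_to_key(self):
        groups = [self._group(k, 0.5, 0.5, 0.1) for k in ["z", "m", "a"]]
        assert [g.group_key for g in sc.rank_results(groups)] == ["a", "m", "z"]

    def test_single_group(self):
        assert sc.rank_results([self._group("only", 0.2, 0.1)])[0].rank == 1


class TestRunQuery:
    def test_scalar_and_batch_paths_agree(self, tiny_db):
        q = sc.GeneSignature(up_tags=("pA", "pB"), down_tags=("pE", "pF"))
        result = sc.run_query(tiny_db, q, sc.QueryConfig(seed=1))
        for _, row in result.instances.iterrows():
            scalar = sc.instance_connectivity(tiny_db.profile(row["instance_id"]), q)
            assert row["ks_up"] == pytest.approx(scalar.ks_up.es)
            assert row["ks_down"] == pytest.approx(scalar.ks_down.es)
            assert row["s"] == pytest.approx(scalar.s)

    def test_missing_tags_dropped_and_counted(self, tiny_db):
        q = sc.GeneSignature(up_tags=("pA", "missing1"), down_tags=("pF", "missing2"))
        result = sc.run_query(tiny_db, q, sc.QueryConfig(seed=1))
        assert result.provenance["dropped_up_tags"] == 1
        assert result.provenance["dropped_down_tags"] == 1

    def test_no_overlap_raises(self, tiny_db):
        q = sc.GeneSignature(up_tags=("x1",), down_tags=("x2",))
        with pytest.raises(CoverageError):
            sc.run_query(tiny_db, q)

    def test_connectivity_scores_bounded_on_random_db(self):
        rng = np.random.default_rng(21)
        probes = [f"p{i:03d}" for i in range(60)]
        profiles = []
        for k in range(20):
            perm = rng.permutation(60) + 1
            profiles.append(
                sc.InstanceProfile(f"i{k}", f"c{k % 5}", "L", pd.Series(perm, index=probes))
            )
        db = sc.build_database(profiles)
        q = sc.GeneSignature(up_tags=tuple(probes[:5]), down_tags=tuple(probes[5:10]))
        result = sc.run_query(db, q, sc.QueryConfig(seed=2, n_perm=500))
        assert (result.instances["c"].abs() <= 1 + 1e-12).all()
        assert (result.results["similarity_mean"].abs() <= 1 + 1e-12).all()
        assert (result.results["enrichment"].abs() <= 1 + 1e-12).all()

    def test_antisymmetry_of_group_means(self, small_sim):
        _, db, truth = small_sim
        q = sc.make_planted_query(truth, 1)
        cfg = sc.QueryConfig(seed=9, n_perm=300)
        fwd = sc.run_query(db, q, cfg).results.set_index("group_key")
        rev = sc.run_query(db, q.swapped(), cfg).results.set_index("group_key")
        for key in fwd.index:
            assert fwd.loc[key, "similarity_mean"] == pytest.approx(
                -rev.loc[key, "similarity_mean"], abs=1e-12
            )
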