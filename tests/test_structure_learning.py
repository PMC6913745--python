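import itertools
import math

import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist

from bedsidebn.structure_learning import (ConstraintSet, CyclicWhitelistError,
                                          Dag, ScoreParams, bdeu_local,
                                          g2_test, hill_climb, mmhc, mmpc,
                                          score_dag)

from conftest import make_cohort


def chain_cohort(n, seed=0, flip=0.05):
    """a -> b -> c with strong (1 - flip) copy CPTs."""
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 2, n)
    b = np.where(rng.random(n) < flip, 1 - a, a)
    c = np.where(rng.random(n) < flip, 1 - b, b)
    return make_cohort({"a": a, "b": b, "c": c})


def independent_cohort(n, k=2, seed=0):
    rng = np.random.default_rng(seed)
    return make_cohort({f"x{i}": rng.integers(0, 2, n) for i in range(k)})


def all_dags(nodes):
    """Every DAG over the given nodes (exhaustive oracle, tiny n only)."""
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    for subset in itertools.chain.from_iterable(
            itertools.combinations(pairs, k) for k in range(len(pairs) + 1)):
        arcs = tuple(subset)
        if any((v, u) in arcs for u, v in arcs):
            continue
        try:
            yield Dag(tuple(nodes), arcs)
        except ValueError:
            continue


# --------------------------------------------------------------------------
# G2
# --------------------------------------------------------------------------


class TestG2:
    def test_diagonal_table_closed_form(self):
        c = make_cohort({"x": [0] * 5 + [1] * 5, "y": [0] * 5 + [1] * 5})
        stat, df, p = g2_test(c, "x", "y")
        assert stat == pytest.approx(20 * math.log(2))
        assert df == 1
        assert p == pytest.approx(chi2_dist.sf(20 * math.log(2), 1))

    def test_observed_equals_expected_gives_zero(self):
        c = make_cohort({"x": [0, 0, 1, 1] * 3, "y": [0, 1] * 6})
        stat, df, _ = g2_test(c, "x", "y")
        assert stat == pytest.approx(0.0)
        assert df == 1

    def test_chain_conditional_independence_detected(self):
        c = chain_cohort(2000, seed=3)
        stat, df, p = g2_test(c, "a", "c", ("b",))
        assert p > 0.05
        # independent oracle: per-stratum log-likelihood-ratio chi-square
        oracle = 0.0
        oracle_df = 0
        codes = {v: c.codes(v) for v in "abc"}
        for b_val in (0, 1):
            mask = codes["b"] == b_val
            tab = np.zeros((2, 2))
            for x, y in zip(codes["a"][mask], codes["c"][mask]):
                tab[x, y] += 1
            if tab.sum() == 0:
                continue
            oracle_df += 1
            exp = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
            nz = tab > 0
            oracle += 2 * (tab[nz] * np.log(tab[nz] / exp[nz])).sum()
        assert stat == pytest.approx(oracle, rel=1e-9)
        assert df == oracle_df

    def test_marginal_dependence_on_chain_endpoints(self):
        c = chain_cohort(2000, seed=3)
        _, _, p = g2_test(c, "a", "c")
        assert p < 1e-6

    def test_empty_cohort_errors(self):
        c = make_cohort({"x": [], "y": []}, states={"x": ("0", "1"), "y": ("0", "1")})
        with pytest.raises(ValueError):
            g2_test(c, "x", "y")

    def test_rejects_overlapping_variables(self):
        c = chain_cohort(10)
        with pytest.raises(ValueError):
            g2_test(c, "a", "a")
        with pytest.raises(ValueError):
            g2_test(c, "a", "b", ("a",))


# --------------------------------------------------------------------------
# MMPC
# --------------------------------------------------------------------------


class TestMmpc:
    def test_independent_pair_has_empty_sets(self):
        c = independent_cohort(2000, k=2, seed=11)
        cpc = mmpc(c)
        assert cpc == {"x0": (), "x1": ()}
        # cross-check: the marginal test itself is insignificant
        _, _, p = g2_test(c, "x0", "x1")
        assert p > 0.05

    def test_chain_candidates(self):
        c = chain_cohort(2000, seed=1)
        cpc = mmpc(c)
        assert cpc["a"] == ("b",)
        assert cpc["b"] == ("a", "c")
        assert cpc["c"] == ("b",)

    def test_blacklisted_both_ways_never_candidate(self):
        c = chain_cohort(2000, seed=1)
        constraints = ConstraintSet(frozenset({("a", "b"), ("b", "a")}))
        cpc = mmpc(c, constraints=constraints)
        assert "b" not in cpc["a"] and "a" not in cpc["b"]

    def test_empty_cohort_errors(self):
        c = make_cohort({"x": [], "y": []}, states={"x": ("0", "1"), "y": ("0", "1")})
        with pytest.raises(ValueError):
            mmpc(c)


# --------------------------------------------------------------------------
# BDeu
# --------------------------------------------------------------------------


class TestBdeu:
    def test_two_row_closed_form(self):
        c = make_cohort({"x": [0, 1]})
        assert bdeu_local(c, "x", (), ess=1.0) == pytest.approx(math.log(1 / 8))

    def test_empty_cohort_scores_zero(self):
        c = make_cohort({"x": []}, states={"x": ("0", "1")})
        assert bdeu_local(c, "x", (), 1.0) == 0.0
        assert bdeu_local(c, "x", (), 7.3) == 0.0

    def test_score_equivalence_single_arc(self):
        rng = np.random.default_rng(9)
        c = make_cohort({"a": rng.integers(0, 2, 40), "b": rng.integers(0, 2, 40)})
        ab = score_dag(Dag(("a", "b"), (("a", "b"),)), c)
        ba = score_dag(Dag(("a", "b"), (("b", "a"),)), c)
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_empty_dag_decomposes(self):
        c = chain_cohort(100)
        empty = Dag(("a", "b", "c"), ())
        expected = sum(bdeu_local(c, v, (), 1.0) for v in "abc")
        assert score_dag(empty, c) == pytest.approx(expected)

    def test_dependent_pair_prefers_one_arc(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 2, 500)
        b = np.where(rng.random(500) < 0.05, 1 - a, a)
        c = make_cohort({"a": a, "b": b})
        scores = {
            "empty": score_dag(Dag(("a", "b"), ()), c),
            "ab": score_dag(Dag(("a", "b"), (("a", "b"),)), c),
            "ba": score_dag(Dag(("a", "b"), (("b", "a"),)), c),
        }
        assert max(scores, key=scores.get) in ("ab", "ba")

    def test_covered_arc_reversal_invariance(self):
        # u -> v with pa(v) = pa(u) + {u}: reversal keeps the score
        rng = np.random.default_rng(17)
        for trial in range(20):
            n = 60
            c = make_cohort({v: rng.integers(0, 2, n) for v in "zuv"})
            d1 = Dag(("u", "v", "z"), (("z", "u"), ("z", "v"), ("u", "v")))
            d2 = Dag(("u", "v", "z"), (("z", "u"), ("z", "v"), ("v", "u")))
            assert score_dag(d1, c) == pytest.approx(score_dag(d2, c), abs=1e-9)

    def test_ess_must_be_positive(self):
        c = make_cohort({"x": [0, 1]})
        with pytest.raises(ValueError):
            bdeu_local(c, "x", (), 0.0)


# --------------------------------------------------------------------------
# hill climbing and MMHC
# --------------------------------------------------------------------------


class TestHillClimb:
    def test_independent_variables_give_empty_graph(self):
        c = independent_cohort(2000, k=3, seed=4)
        dag = hill_climb(c)
        assert dag.arcs == ()
        # oracle: every single-arc addition has negative gain
        empty_score = score_dag(Dag(dag.nodes, ()), c)
        for u in dag.nodes:
            for v in dag.nodes:
                if u != v:
                    one = Dag(dag.nodes, ((u, v),))
                    assert score_dag(one, c) < empty_score

    def test_whitelisted_arc_forced(self):
        c = independent_cohort(500, k=3, seed=4)
        constraints = ConstraintSet(whitelist=frozenset({("x0", "x2")}))
        dag = hill_climb(c, constraints)
        assert ("x0", "x2") in dag.arcs

    def test_coupled_pair_gets_exactly_one_arc(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 2, 800)
        b = np.where(rng.random(800) < 0.02, 1 - a, a)
        c = make_cohort({"a": a, "b": b})
        dag = hill_climb(c)
        assert len(dag.arcs) == 1
        # enumerate-and-compare: the learner reaches the global optimum
        best = max(all_dags(("a", "b")), key=lambda d: score_dag(d, c))
        assert score_dag(dag, c) == pytest.approx(score_dag(best, c), abs=1e-9)

    def test_cyclic_whitelist_rejected(self):
        with pytest.raises(CyclicWhitelistError):
            ConstraintSet(whitelist=frozenset({("a", "b"), ("b", "a")}))

    def test_random_constraint_compliance(self):
        rng = np.random.default_rng(100)
        nodes = ("a", "b", "c", "d")
        for trial in range(100):
            c = make_cohort({v: rng.integers(0, 2, 80) for v in nodes})
            pairs = [(u, v) for u in nodes for v in nodes if u != v]
            black = {p for p in pairs if rng.random() < 0.2}
            white = set()
            for p in pairs:
                if p not in black and (p[1], p[0]) not in white and rng.random() < 0.1:
                    white.add(p)
            try:
                constraints = ConstraintSet(frozenset(black), frozenset(white))
            except ValueError:
                continue
            dag = hill_climb(c, constraints)
            assert not (set(dag.arcs) & black)
            assert white <= set(dag.arcs)


class TestMmhc:
    def test_chain_skeleton_recovered(self):
        c = chain_cohort(2000, seed=6)
        dag = mmhc(c)
        assert dag.skeleton() == {frozenset("ab"), frozenset("bc")}
        # exhaustive oracle over all 25 DAGs on 3 nodes
        best = max(all_dags(("a", "b", "c")), key=lambda d: score_dag(d, c))
        assert best.skeleton() == dag.skeleton()
        assert score_dag(dag, c) == pytest.approx(score_dag(best, c), abs=1e-9)

    def test_finds_global_optimum_on_four_nodes(self):
        rng = np.random.default_rng(12)
        a = rng.integers(0, 2, 1500)
        b = np.where(rng.random(1500) < 0.05, 1 - a, a)
        d = rng.integers(0, 2, 1500)
        e = np.where(rng.random(1500) < 0.05, 1 - d, d)
        c = make_cohort({"a": a, "b": b, "d": d, "e": e})
        learned = mmhc(c)
        best = max(all_dags(("a", "b", "d", "e")), key=lambda g: score_dag(g, c))
        assert score_dag(learned, c) >= score_dag(best, c) - 1e-9

    def test_blacklist_respected_on_study_style_constraints(self, gt_spec,
                                                            small_cohort):
        from bedsidebn.cli import _constraints
        from bedsidebn import synthetic_cohort as syn
        cohort = small_cohort.drop_variable(syn.OUTCOME).subset(range(400))
        constraints = _constraints(gt_spec)
        dag = mmhc(cohort, constraints=constraints)
        for u, v in dag.arcs:
            assert v not in ("high_age", "male_gender")
            assert u != "estimate"

    def test_empty_cohort_errors(self):
        c = make_cohort({"x": [], "y": []}, states={"x": ("0", "1"), "y": ("0", "1")})
        with pytest.raises(ValueError):
            mmhc(c)

    def test_acyclic_and_deterministic(self):
        c = chain_cohort(500, seed=13)
        d1 = mmhc(c)
        d2 = mmhc(c)
        assert d1.arcs == d2.arcs  # fixed enumeration order => reproducible
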