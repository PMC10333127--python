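"""Pruning likelihoods, marginal ancestral states, constraints and ML fitting."""

import numpy as np
import pytest

import paleoparity as pp
from paleoparity.mk_inference import ZeroLikelihoodError
from ._oracles import enum_loglik_and_marginals, random_timetree


def two_state_er(rate):
    return pp.build_generator("EER_ER").bind([rate])


class TestClosedForms:
    def test_rate_to_zero_two_tips_same_state(self):
        # no change possible: L -> P(root=0) = 0.5 under a flat root prior
        t = pp.TimeTree.from_newick("(A:1,B:1);")
        tips = {"A": np.array([1.0, 0]), "B": np.array([1.0, 0])}
        ll = pp.prune_loglik(t, tips, two_state_er(1e-9))
        assert ll == pytest.approx(np.log(0.5), abs=1e-6)

    def test_rate_to_infinity_independence(self):
        # P(t) -> 1/2 everywhere: L = sum_s 0.5 * 0.5^2 * 2 = 0.25
        t = pp.TimeTree.from_newick("(A:1,B:1);")
        tips = {"A": np.array([1.0, 0]), "B": np.array([1.0, 0])}
        ll = pp.prune_loglik(t, tips, two_state_er(500.0))
        assert ll == pytest.approx(np.log(0.25), abs=1e-4)

    def test_symmetric_root_marginal(self):
        t = pp.TimeTree.from_newick("(A:0.5,B:0.5);")
        tips = {"A": np.array([1.0, 0]), "B": np.array([0.0, 1.0])}
        m = pp.marginal_asr(t, tips, two_state_er(0.7))
        assert m[{"A", "B"}] == pytest.approx([0.5, 0.5])


class TestEnumerationOracle:
    @pytest.mark.parametrize("model", ["ER_ind", "CARD_sw", "EER_ARD"])
    def test_matches_brute_force(self, model):
        rng = np.random.default_rng(11)
        g = pp.build_generator(model)
        for _ in range(3):
            t = random_timetree(4, rng)
            q = g.bind(rng.uniform(0.2, 2.0, g.k))
            n = g.n_states
            tips = {l: np.ones(n) / n * 0 + _rand_prior(rng, n)
                    for l in t.leaf_labels()}
            prior = np.full(n, 1 / n)
            ll_bf, marg_bf = enum_loglik_and_marginals(t, tips, q, prior)
            assert pp.prune_loglik(t, tips, q) == pytest.approx(ll_bf, abs=1e-9)
            m = pp.marginal_asr(t, tips, q)
            for clade, vec in marg_bf.items():
                assert m[clade] == pytest.approx(vec, abs=1e-9)


def _rand_prior(rng, n):
    v = rng.uniform(0.05, 1.0, n)
    return v / v.sum()


class TestInvariances:
    def test_reroot_invariance_of_total_loglik(self):
        """Same unrooted tree rooted on two different edges: equal likelihood
        under a reversible generator with its stationary root prior."""
        q = pp.build_generator("ER_ind").bind([0.6])
        tips = {l: _rand_prior(np.random.default_rng(i), 6)
                for i, l in enumerate("ABCD")}
        # unrooted quartet with path lengths preserved across rootings
        t1 = pp.TimeTree.from_newick("((A:0.2,B:0.3):0.25,(C:0.4,D:0.5):0.25);")
        t2 = pp.TimeTree.from_newick("(A:0.2,(B:0.3,((C:0.4,D:0.5):0.5):0.0):0.0);")
        ll1 = pp.prune_loglik(t1, tips, q, root_prior="stationary")
        ll2 = pp.prune_loglik(t2, tips, q, root_prior="stationary")
        assert ll1 == pytest.approx(ll2, abs=1e-9)

    def test_rescale_rate_invariance(self):
        rng = np.random.default_rng(12)
        t = random_timetree(6, rng)
        g = pp.build_generator("CER_ind")
        tips = {l: _rand_prior(rng, 6) for l in t.leaf_labels()}
        rates = np.array([0.4, 0.9])
        c = 25.0
        t_scaled = t.copy()
        for nd in t_scaled.dtree.preorder_node_iter():
            if nd.parent_node is not None:
                nd.edge.length *= c
        ll1 = pp.prune_loglik(t, tips, g.bind(rates))
        ll2 = pp.prune_loglik(t_scaled, tips, g.bind(rates / c))
        assert ll1 == pytest.approx(ll2, abs=1e-9)

    def test_reroot_equals_no_reroot_for_reversible(self):
        rng = np.random.default_rng(13)
        t = random_timetree(5, rng)
        q = pp.build_generator("CSYM_ind").bind([0.3, 0.5, 0.8, 1.1])
        tips = {l: _rand_prior(rng, 6) for l in t.leaf_labels()}
        m1 = pp.marginal_asr(t, tips, q, root_prior="stationary", method="no_reroot")
        m2 = pp.marginal_asr(t, tips, q, root_prior="stationary", method="reroot")
        for clade, vec in m1:
            assert m2[clade] == pytest.approx(vec, abs=1e-8)

    def test_reroot_rejected_for_nonreversible(self):
        t = pp.TimeTree.from_newick("((A:1,B:1):1,C:2);")
        q = pp.build_generator("CARD_ind").bind(np.linspace(0.2, 1.6, 8))
        tips = {l: np.full(6, 1 / 6) for l in "ABC"}
        with pytest.raises(ValueError, match="reversible"):
            pp.marginal_asr(t, tips, q, method="reroot")

    def test_marginals_sum_to_one_and_zero_rate_point_mass(self):
        t = pp.TimeTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        tips = {l: np.array([1.0, 0, 0, 0, 0, 0]) for l in "ABCD"}
        q = pp.build_generator("ER_ind").bind([1e-9])
        m = pp.marginal_asr(t, tips, q)
        for _, vec in m:
            assert vec.sum() == pytest.approx(1.0, abs=1e-9)
            assert vec[0] == pytest.approx(1.0, abs=1e-5)


class TestConstraints:
    def _setup(self):
        t = pp.TimeTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        tips = {"A": np.array([1.0, 0]), "B": np.array([1.0, 0]),
                "C": np.array([0.0, 1]), "D": np.array([0.0, 1])}
        return t, tips, two_state_er(0.3)

    def test_all_states_allowed_is_noop(self):
        t, tips, q = self._setup()
        base = pp.prune_loglik(t, tips, q)
        same = pp.prune_loglik(t, tips, q,
                               constraints={frozenset("ABCD"): [0, 1]})
        assert same == pytest.approx(base)

    def test_constrained_state_has_zero_mass(self):
        t, tips, q = self._setup()
        m = pp.marginal_asr(t, tips, q, constraints={frozenset("AB"): [0]})
        assert m[{"A", "B"}][1] == 0.0
        assert m[{"A", "B"}][0] == 1.0

    def test_zero_likelihood_signalled(self):
        # a zero-rate generator makes change impossible: constraining a node
        # to the unobserved state gives likelihood exactly 0
        t, tips, _ = self._setup()
        q0 = np.zeros((2, 2))
        ll = pp.prune_loglik(t, tips, q0, constraints={frozenset("AB"): [1]})
        assert ll == -np.inf
        tips_same = {l: np.array([1.0, 0]) for l in "ABCD"}
        with pytest.raises(ZeroLikelihoodError):
            pp.marginal_asr(t, tips_same, q0, constraints={frozenset("AB"): [1]})

    def test_consistent_constraint_barely_changes_loglik(self):
        t, tips, q = self._setup()
        m = pp.marginal_asr(t, tips, q)
        top = int(np.argmax(m[{"A", "B"}]))
        base = pp.prune_loglik(t, tips, q)
        con = pp.prune_loglik(t, tips, q, constraints={frozenset("AB"): [top]})
        assert con <= base + 1e-12
        # constraining to one state multiplies the likelihood by its marginal
        assert con == pytest.approx(base + np.log(m[{"A", "B"}][top]), abs=1e-9)


class TestFit:
    def test_fit_recovers_rate_and_is_deterministic(self):
        rng = np.random.default_rng(14)
        tree = pp.simulate_tree(0.06, 0.02, 24, seed=15)
        tree = pp.rescale_tree(tree, "unit_height")
        g = pp.build_generator("EER_ER")
        q = g.bind([0.8])
        n_chars = 150
        tips = {l: np.zeros((n_chars, 2)) for l in tree.leaf_labels()}
        for ci in range(n_chars):
            h = pp.simulate_history(tree, q, seed=1000 + ci)
            for l, s in h.tip_states.items():
                tips[l][ci, s] = 1.0
        fit = pp.fit_mk(tree, tips, g, n_restarts=3, seed=16)
        assert fit.rates[0] == pytest.approx(0.8, rel=0.25)
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)
        assert fit.loglik == pytest.approx(max(fit.restart_logliks))
        fit2 = pp.fit_mk(tree, tips, g, n_restarts=3, seed=16)
        assert fit2.rates == pytest.approx(fit.rates)
        assert fit2.restart_logliks == pytest.approx(fit.restart_logliks)

    def test_saturated_data_flagged_at_bound(self):
        t = pp.TimeTree.from_newick("(A:0.001,B:0.001);")
        tips = {"A": np.array([1.0, 0]), "B": np.array([0.0, 1])}
        fit = pp.fit_mk(t, tips, pp.build_generator("EER_ER"), n_restarts=2, seed=17)
        assert fit.at_bound

    def test_invalid_generator_rejected(self):
        t = pp.TimeTree.from_newick("(A:1,B:1);")
        tips = {"A": np.array([1.0, 0]), "B": np.array([1.0, 0])}
        with pytest.raises(ValueError):
            pp.prune_loglik(t, tips, np.array([[0.5, 0.5], [0.5, -0.5]]))
        with pytest.raises(KeyError):
            pp.prune_loglik(t, {"A": np.array([1.0, 0])}, two_state_er(0.5))


class TestFactorization:
    def test_ind_loglik_is_sum_of_components(self):
        """With both components fully observed, the amalgamated _ind likelihood
        factorizes into reproduction x eggshell component likelihoods."""
        rng = np.random.default_rng(18)
        t = random_timetree(6, rng)
        space = pp.build_space()
        g6 = pp.build_generator("CER_ind")
        q6 = g6.bind([0.4, 0.9])
        states = {l: int(rng.integers(6)) for l in t.leaf_labels()}
        tips6 = {l: np.eye(6)[s] for l, s in states.items()}
        ll6 = pp.prune_loglik(t, tips6, q6)
        q2 = np.array([[-0.4, 0.4], [0.4, -0.4]])
        q3 = 0.9 * (np.ones((3, 3)) - 3 * np.eye(3))
        tips2 = {l: np.eye(2)[s // 3] for l, s in states.items()}
        tips3 = {l: np.eye(3)[s % 3] for l, s in states.items()}
        ll_sum = pp.prune_loglik(t, tips2, q2) + pp.prune_loglik(t, tips3, q3)
        assert ll6 == pytest.approx(ll_sum, abs=1e-8)


def test_node_marginals_table_roundtrip(tmp_path):
    t = pp.TimeTree.from_newick("((A:1,B:1):1,C:2);")
    tips = {l: np.array([1.0, 0]) for l in "ABC"}
    m = pp.marginal_asr(t, tips, two_state_er(0.5), state_labels=("absent", "present"))
    df = m.table()
    assert set(df.columns) == {"clade", "n_tips", "absent", "present"}
    m.to_tsv(tmp_path / "m.tsv")
    assert (tmp_path / "m.tsv").read_text().startswith("clade")
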