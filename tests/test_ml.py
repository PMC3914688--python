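"""Likelihood engine: pruning correctness, search, bootstrap, clade queries."""

import itertools

import numpy as np
import pytest

from mitojack.alignment import ColumnLabel, SiteMatrix
from mitojack.ml import (MIN_BRANCH, PartitionedLikelihood, SubstitutionModel,
                         bootstrap, discrete_gamma_rates, encode_matrix,
                         log_likelihood, ml_search, monophyly)
from mitojack.simulate import EvolutionScenario, PartitionSpec, simulate_alignment
from mitojack.trees import parse_newick

CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def nt_matrix(taxa, rows):
    labels = [ColumnLabel("g", "1", i) for i in range(len(rows[0]))]
    data = np.array([list(r) for r in rows], dtype="<U1")
    return SiteMatrix(list(taxa), data, labels)


def enumeration_lnl(matrix, tree, model):
    """Sum over all internal-state assignments, category by category."""
    lam, U, Uinv = model.eigensystem()
    rates = discrete_gamma_rates(model.alpha, model.ncat)
    nodes = tree.postorder()
    internals = [n for n in nodes if not n.is_tip]
    rows = {t: "".join(matrix.data[i]) for i, t in enumerate(matrix.taxa)}
    total = 0.0
    for site in range(matrix.n_columns):
        site_l = 0.0
        for r in rates:
            P = {id(n): U @ np.diag(np.exp(lam * n.length * r)) @ Uinv
                 for n in nodes if n.parent is not None}
            s = 0.0
            for combo in itertools.product(range(model.n_states),
                                           repeat=len(internals)):
                assign = dict(zip(map(id, internals), combo))
                p = model.frequencies[assign[id(tree.root)]]
                for n in nodes:
                    if n.parent is None:
                        continue
                    child = (assign[id(n)] if not n.is_tip
                             else CODE[rows[n.name][site]])
                    p *= P[id(n)][assign[id(n.parent)], child]
                s += p
            site_l += s / model.ncat
        total += np.log(site_l)
    return total


class TestPruningCorrectness:
    @pytest.mark.parametrize("newick,seed", [
        ("((A:0.12,B:0.3):0.08,(C:0.2,D:0.05):0.11);", 1),
        ("((A:0.05,B:0.4):0.1,(C:0.3,(D:0.15,E:0.2):0.07):0.02);", 2),
        ("(A:0.2,B:0.1,(C:0.25,(D:0.1,E:0.3):0.12):0.05);", 3),
    ])
    def test_matches_enumeration(self, newick, seed):
        rng = np.random.default_rng(seed)
        tree = parse_newick(newick)
        taxa = sorted(tree.tip_names())
        rows = ["".join(rng.choice(list("ACGT"), size=5)) for _ in taxa]
        m = nt_matrix(taxa, rows)
        model = SubstitutionModel.gtr(
            exchangeabilities=rng.uniform(0.5, 4.0, 6),
            frequencies=rng.dirichlet(np.ones(4) * 5), alpha=0.7)
        lnl = log_likelihood(m, tree, models=[model])
        assert abs(lnl - enumeration_lnl(m, tree, model)) < 1e-8

    def test_identical_sequences_at_zero_length(self):
        m = nt_matrix(["X", "Y"], ["A", "A"])
        tree = parse_newick(f"(X:{MIN_BRANCH},Y:{MIN_BRANCH});")
        model = SubstitutionModel.gtr(alpha=1e6)
        assert log_likelihood(m, tree, models=[model]) == pytest.approx(
            np.log(0.25), abs=1e-6)

    def test_gtr_reduces_to_jukes_cantor_closed_form(self):
        rng = np.random.default_rng(5)
        n, d = 3000, 0.42
        x = rng.choice(list("ACGT"), size=n)
        y = x.copy()
        p_diff = 0.75 * (1 - np.exp(-4 * d / 3))
        flip = rng.random(n) < p_diff
        # draw replacement uniformly among the three other bases
        for i in np.nonzero(flip)[0]:
            y[i] = rng.choice([b for b in "ACGT" if b != x[i]])
        m = nt_matrix(["X", "Y"], ["".join(x), "".join(y)])
        tree = parse_newick(f"(X:{d/2},Y:{d/2});")
        jc = SubstitutionModel.gtr(alpha=1e6)  # equal rates/frequencies
        lnl = log_likelihood(m, tree, models=[jc])
        match = int((x == y).sum())
        p_same = 0.25 + 0.75 * np.exp(-4 * d / 3)
        closed = (match * np.log(0.25 * p_same)
                  + (n - match) * np.log(0.25 * (1 - p_same) / 3))
        assert abs(lnl - closed) < 1e-4 * abs(closed)

    def test_missing_data_partial_is_one(self):
        full = nt_matrix(["X", "Y"], ["AC", "AC"])
        with_missing = nt_matrix(["X", "Y", "Z"], ["AC", "AC", "??"])
        tree2 = parse_newick("(X:0.1,Y:0.1);")
        tree3 = parse_newick("(X:0.1,Y:0.1,Z:0.3);")
        model = SubstitutionModel.gtr(alpha=0.9)
        assert log_likelihood(with_missing, tree3, models=[model]) == \
            pytest.approx(log_likelihood(full, tree2, models=[model]))


class TestInvariances:
    def setup_method(self):
        rng = np.random.default_rng(11)
        self.taxa = ["a", "b", "c", "d", "e"]
        self.rows = ["".join(rng.choice(list("ACGT"), size=40))
                     for _ in self.taxa]
        self.model = SubstitutionModel.gtr(
            frequencies=[0.4, 0.1, 0.2, 0.3], alpha=0.6)

    def test_invariant_under_rerooting(self):
        m = nt_matrix(self.taxa, self.rows)
        t1 = parse_newick("((a:0.1,b:0.2):0.05,(c:0.1,d:0.3):0.04,e:0.2);")
        # same unrooted tree expressed from a different vertex
        t2 = parse_newick("((c:0.1,d:0.3):0.04,(a:0.1,b:0.2):0.05,e:0.2);")
        t3 = parse_newick("(c:0.1,d:0.3,((a:0.1,b:0.2):0.05,e:0.2):0.04);")
        l1 = log_likelihood(m, t1, models=[self.model])
        for t in (t2, t3):
            assert log_likelihood(m, t, models=[self.model]) == pytest.approx(l1)

    def test_invariant_under_tip_order(self):
        order = [3, 1, 4, 0, 2]
        m1 = nt_matrix(self.taxa, self.rows)
        m2 = nt_matrix([self.taxa[i] for i in order],
                       [self.rows[i] for i in order])
        t = parse_newick("((a:0.1,b:0.2):0.05,(c:0.1,d:0.3):0.04,e:0.2);")
        assert log_likelihood(m2, t, models=[self.model]) == pytest.approx(
            log_likelihood(m1, t, models=[self.model]))

    def test_pattern_compression_changes_nothing(self):
        # duplicating columns must add their contributions exactly
        m1 = nt_matrix(self.taxa, self.rows)
        m2 = nt_matrix(self.taxa, [r + r for r in self.rows])
        t = parse_newick("((a:0.1,b:0.2):0.05,(c:0.1,d:0.3):0.04,e:0.2);")
        assert log_likelihood(m2, t, models=[self.model]) == pytest.approx(
            2 * log_likelihood(m1, t, models=[self.model]))

    def test_ry_relabeling_symmetry(self):
        rng = np.random.default_rng(3)
        rows = ["".join(rng.choice(["R", "Y"], size=60)) for _ in range(4)]
        flipped = [r.replace("R", "x").replace("Y", "R").replace("x", "Y")
                   for r in rows]
        labels = [ColumnLabel("g", "3", i) for i in range(60)]
        m1 = SiteMatrix(list("abcd"), np.array([list(r) for r in rows]),
                        labels, ["ry"] * 60)
        m2 = SiteMatrix(list("abcd"), np.array([list(r) for r in flipped]),
                        labels, ["ry"] * 60)
        t = parse_newick("((a:0.1,b:0.2):0.07,c:0.1,d:0.3);")
        model = SubstitutionModel.binary(frequencies=[0.5, 0.5], alpha=1.0)
        assert log_likelihood(m2, t, models=[model]) == pytest.approx(
            log_likelihood(m1, t, models=[model]))


class TestGamma:
    def test_rates_average_one_and_increase(self):
        for alpha in (0.1, 0.5, 1.0, 5.0):
            r = discrete_gamma_rates(alpha, 4)
            assert r.mean() == pytest.approx(1.0)
            assert (np.diff(r) > 0).all()

    def test_large_alpha_is_rate_homogeneous(self):
        # category means of gamma(a) spread like 1/sqrt(a)
        r = discrete_gamma_rates(1e6, 4)
        assert np.allclose(r, 1.0, atol=5e-3)


@pytest.fixture(scope="module")
def simulated():
    tree = parse_newick(
        "((((a:0.08,b:0.08):0.05,(c:0.08,d:0.08):0.05):0.06,"
        "(e:0.1,f:0.1):0.07):0.05,g:0.15,h:0.15);")
    scen = EvolutionScenario(tree, [PartitionSpec("p", 3000, alpha=0.6)])
    matrix, true_tree = simulate_alignment(scen, seed=4)
    return matrix, true_tree


class TestSearchAndBootstrap:
    def test_recovers_generating_topology(self, simulated):
        matrix, true_tree = simulated
        res = ml_search(matrix)
        assert set(res.tree.bipartitions()) == set(true_tree.bipartitions())

    def test_hill_climb_never_decreases_from_true_tree(self, simulated):
        matrix, true_tree = simulated
        groups = encode_matrix(matrix)
        from mitojack.ml import default_models
        engine = PartitionedLikelihood(groups, default_models(groups),
                                       true_tree.copy().unroot(), matrix.taxa)
        initial = engine.lnl()
        final = engine.search(max_rounds=5)
        assert final >= initial - 1e-6

    def test_single_replicate_supports_are_all_or_nothing(self, simulated):
        matrix, _ = simulated
        res = ml_search(matrix)
        tree, freqs = bootstrap(matrix, res, replicates=1, seed=5)
        assert set(freqs.values()) <= {0.0, 100.0}

    def test_strong_signal_gives_high_support(self, simulated):
        matrix, true_tree = simulated
        res = ml_search(matrix)
        _, freqs = bootstrap(matrix, res, replicates=20, seed=2)
        q = monophyly(res.tree, {"a", "b", "c", "d"}, freqs)
        assert q.monophyletic and q.support >= 95.0

    def test_small_taxon_sets_return_trivial_tree(self):
        m = nt_matrix(["x", "y", "z"], ["ACGT", "ACGT", "ACGA"])
        res = ml_search(m)
        assert set(res.tree.tip_names()) == {"x", "y", "z"}


class TestMonophyly:
    def test_examples(self):
        t = parse_newick("((A,B),(C,D));")
        assert monophyly(t, {"A", "B"}).monophyletic
        assert not monophyly(t, {"A", "C"}).monophyletic
        # complement rule on the unrooted tree
        assert monophyly(t, {"C", "D"}).monophyletic

    def test_unknown_taxon_raises(self):
        t = parse_newick("((A,B),(C,D));")
        with pytest.raises(KeyError):
            monophyly(t, {"A", "Z"})

    def test_absent_clade_reports_replicate_frequency(self):
        t = parse_newick("((A,B),(C,D));")
        # bipartitions are canonically keyed by the side without the smallest
        # tip name: {A,C} | {B,D} is stored as {B,D}
        freqs = {frozenset({"B", "D"}): 34.0}
        q = monophyly(t, {"A", "C"}, freqs)
        assert not q.monophyletic and q.support == 34.0
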