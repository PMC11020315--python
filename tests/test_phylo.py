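"""Time calibration, Mk likelihood, model fitting and stochastic mapping."""

import itertools
import math

import dendropy
import numpy as np
import pytest
from scipy.linalg import expm

from zahnreihen import (
    AllocationError,
    CharacterMatrix,
    DegenerateDataError,
    ValidationError,
    akaike_weights,
    calibrate_equal,
    fit_mk,
    mk_loglik,
    model_averaged_maps,
    simmap_sample,
)
from zahnreihen.phylo import _TreeArrays, _allocate
from zahnreihen.simulate import MkSimSpec, random_calibrated_tree, simulate_mk_tips

S3 = ("one_generation", "two_generations", "three_plus")


def _q(rng, k=3, scale=0.3):
    Q = np.abs(rng.normal(scale, scale / 2, (k, k)))
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _er(q, k=3):
    Q = np.full((k, k), q)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def brute_force_loglik(tree, chars, Q, prior):
    """Exhaustive sum over all internal-state assignments."""
    arr = _TreeArrays(tree)
    k = chars.k
    P = [expm(Q * t) for t in arr.edge_len]
    internals = [i for i in range(arr.n) if not arr.is_tip[i]]
    tips = {i: chars.state_index(arr.labels[i]) for i in range(arr.n) if arr.is_tip[i]}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        st = dict(zip(internals, assign))
        st.update(tips)
        p = prior[st[arr.root]]
        for j in range(arr.n):
            if j != arr.root:
                p *= P[j][st[arr.parent[j]], st[j]]
        total += p
    return math.log(total)


class TestCalibration:
    def test_cherry_with_distinct_fads(self):
        ct = calibrate_equal("(A,B);", {"A": 130.0, "B": 125.0}, root_extension=5.0)
        ages = ct.ages()
        assert ages["A"] == 130.0 and ages["B"] == 125.0
        assert ct.root_age == 135.0

    def test_equal_redistribution_on_simultaneous_fads(self):
        # hand-worked: both internal nodes split the 6 Myr extension equally
        ct = calibrate_equal(
            "((A,B),C);", {"A": 100.0, "B": 100.0, "C": 100.0}, root_extension=6.0
        )
        ages = ct.ages()
        internal = sorted(v for k, v in ages.items() if k not in "ABC")
        assert internal == pytest.approx([103.0, 106.0])

    def test_distinct_fads_make_redistribution_a_noop(self):
        ct = calibrate_equal(
            "((A,B),C);", {"A": 100.0, "B": 90.0, "C": 80.0}, root_extension=5.0
        )
        ages = ct.ages()
        # basic node ages: max of descendant FADs; only the root moves
        assert ages["A"] == 100.0 and ages["B"] == 90.0 and ages["C"] == 80.0
        assert ct.root_age == 105.0

    def test_missing_taxon_age_names_the_taxon(self):
        with pytest.raises(ValidationError, match="B"):
            calibrate_equal("(A,B);", {"A": 100.0})

    def test_fad_must_not_predate_lad(self):
        with pytest.raises(ValidationError, match="FAD"):
            calibrate_equal("(A,B);", {"A": (90.0, 100.0), "B": 100.0})

    def test_ages_strictly_decrease_rootward_with_positive_extension(self):
        ct = calibrate_equal(
            "(((A,B),(C,D)),E);",
            {t: 100.0 for t in "ABCDE"},
            root_extension=10.0,
        )
        for node in ct.tree.preorder_node_iter():
            if node.parent_node is not None:
                assert node.parent_node.age > node.age

    def test_root_to_tip_paths_equal_root_age_minus_fad(self):
        fads = {"A": 100.0, "B": 100.0, "C": 95.0, "D": 100.0}
        ct = calibrate_equal("((A,B),(C,D));", fads, root_extension=8.0)
        for leaf in ct.tree.leaf_node_iter():
            dist = 0.0
            node = leaf
            while node.parent_node is not None:
                dist += node.edge.length
                node = node.parent_node
            assert dist == pytest.approx(ct.root_age - fads[leaf.taxon.label])


class TestMkLikelihood:
    def test_zero_rates_cherry_is_root_prior_mass(self):
        tree = dendropy.Tree.get(data="(A:1,B:1);", schema="newick")
        chars = CharacterMatrix({"A": S3[0], "B": S3[0]}, states=S3)
        assert mk_loglik(tree, chars, np.zeros((3, 3))) == pytest.approx(math.log(1 / 3))

    @pytest.mark.parametrize("q,t", [(0.3, 1.0), (0.05, 10.0), (1.2, 0.4)])
    def test_two_state_single_branch_closed_form(self, q, t):
        # known root (delta prior), one branch: P(no change) = (1 + e^{-2qt})/2
        tree = dendropy.Tree.get(data=f"(A:{t});", schema="newick")
        chars = CharacterMatrix({"A": "s0"}, states=("s0", "s1"))
        Q = _er(q, 2)
        ll = mk_loglik(tree, chars, Q, root_prior=[1.0, 0.0])
        assert ll == pytest.approx(math.log((1 + math.exp(-2 * q * t)) / 2), abs=1e-12)

    @pytest.mark.parametrize(
        "newick",
        [
            "((A:1.0,B:2.0):0.5,(C:1.5,D:0.7):1.1);",
            "(((A:0.3,B:0.9):0.2,C:1.4):0.6,(D:0.5,E:2.0):0.3);",
            "((A:1.0,B:1.0,C:1.0):0.5,D:2.0);",  # polytomy, hard
        ],
    )
    def test_pruning_equals_exhaustive_enumeration(self, newick):
        tree = dendropy.Tree.get(data=newick, schema="newick")
        rng = np.random.default_rng(11)
        Q = _q(rng)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        chars = CharacterMatrix(
            {t: S3[i % 3] for i, t in enumerate(tips)}, states=S3
        )
        prior = np.full(3, 1 / 3)
        assert mk_loglik(tree, chars, Q, root_prior=prior) == pytest.approx(
            brute_force_loglik(tree, chars, Q, prior), abs=1e-10
        )

    def test_missing_tip_state_contributes_no_information(self):
        tree = dendropy.Tree.get(data="(A:1.0,B:1.0);", schema="newick")
        rng = np.random.default_rng(3)
        Q = _q(rng)
        one = CharacterMatrix({"A": S3[0], "B": None}, states=S3)
        single = dendropy.Tree.get(data="(A:1.0);", schema="newick")
        only_a = CharacterMatrix({"A": S3[0]}, states=S3)
        assert mk_loglik(tree, one, Q) == pytest.approx(mk_loglik(single, only_a, Q))

    def test_reroot_invariance_for_reversible_q(self):
        newick = "((A:1.0,B:2.0):0.5,(C:1.5,D:0.7):1.1);"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        rng = np.random.default_rng(7)
        Q = _q(rng)
        Q = (Q + Q.T) / 2.0  # symmetric: reversible with flat stationary dist
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        chars = CharacterMatrix(
            {"A": S3[0], "B": S3[1], "C": S3[2], "D": S3[0]}, states=S3
        )
        ll = mk_loglik(tree, chars, Q)
        tree2 = dendropy.Tree.get(data=newick, schema="newick")
        edge = tree2.find_node_with_taxon_label("C").edge
        tree2.reroot_at_edge(edge, length1=0.75, length2=0.75)
        assert mk_loglik(tree2, chars, Q) == pytest.approx(ll, abs=1e-8)

    def test_invalid_generator_rejected(self):
        tree = dendropy.Tree.get(data="(A:1,B:1);", schema="newick")
        chars = CharacterMatrix({"A": S3[0], "B": S3[1]}, states=S3)
        bad = np.array([[0.5, -0.5, 0.0], [0.1, -0.2, 0.1], [0.0, 0.3, -0.3]])
        with pytest.raises(ValidationError):
            mk_loglik(tree, chars, bad)


@pytest.fixture(scope="module")
def dataset():
    tree = random_calibrated_tree(30, seed=3, root_age=100.0)
    tips, _ = simulate_mk_tips(
        MkSimSpec(tree=tree, Q=_er(0.01), root_state=S3[0], seed=7)
    )
    return tree, tips


class TestFitting:
    def test_free_parameter_counts(self, dataset):
        tree, tips = dataset
        fits = {m: fit_mk(tree, tips, m, seed=0) for m in ("ER", "SYM", "ARD")}
        assert [fits[m].k_params for m in ("ER", "SYM", "ARD")] == [1, 3, 6]

    def test_nested_models_order_loglik(self, dataset):
        tree, tips = dataset
        ll = [fit_mk(tree, tips, m, seed=1).log_likelihood for m in ("ER", "SYM", "ARD")]
        assert ll[2] >= ll[1] - 1e-6 >= ll[0] - 2e-6

    def test_fitted_q_is_a_generator(self, dataset):
        tree, tips = dataset
        for m in ("ER", "SYM", "ARD"):
            Q = fit_mk(tree, tips, m, seed=2).Q
            assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
            off = Q - np.diag(np.diag(Q))
            assert np.all(off >= 0)

    def test_monomorphic_tips_are_degenerate(self):
        tree = random_calibrated_tree(8, seed=1)
        tips = CharacterMatrix({t: S3[0] for t in tree.tip_labels()}, states=S3)
        with pytest.raises(DegenerateDataError):
            fit_mk(tree, tips, "ER")


class TestAkaikeWeights:
    def test_equal_aics_give_equal_weights(self):
        from zahnreihen.phylo import RateModelFit

        fits = [
            RateModelFit(m, np.zeros((3, 3)), -5.0, 20.0, 1, S3) for m in ("ER", "SYM", "ARD")
        ]
        ws = [f.akaike_weight for f in akaike_weights(fits)]
        assert ws == pytest.approx([1 / 3] * 3)

    def test_two_point_aic_gap(self):
        from zahnreihen.phylo import RateModelFit

        fits = [
            RateModelFit("ER", np.zeros((2, 2)), -4.0, 10.0, 1, S3[:2]),
            RateModelFit("SYM", np.zeros((2, 2)), -5.0, 12.0, 1, S3[:2]),
        ]
        ws = [round(f.akaike_weight, 3) for f in akaike_weights(fits)]
        assert ws == [0.731, 0.269]

    def test_single_model_gets_weight_one(self):
        from zahnreihen.phylo import RateModelFit

        (fit,) = akaike_weights([RateModelFit("ER", np.zeros((2, 2)), -4.0, 10.0, 1, S3[:2])])
        assert fit.akaike_weight == pytest.approx(1.0)


class TestStochasticMapping:
    def test_zero_rates_give_constant_maps(self):
        tree = random_calibrated_tree(6, seed=5)
        tips = CharacterMatrix({t: S3[0] for t in tree.tip_labels()}, states=S3)
        maps = simmap_sample(tree, tips, np.zeros((3, 3)), n_maps=5, seed=0)
        for m in maps:
            assert set(m.node_states.values()) == {S3[0]}
            for segs in m.histories.values():
                assert {s for s, _ in segs} == {S3[0]}

    def test_same_seed_reproduces_the_map_collection(self):
        tree = random_calibrated_tree(10, seed=9)
        tips, _ = simulate_mk_tips(
            MkSimSpec(tree=tree, Q=_er(0.01), root_state=S3[0], seed=3)
        )
        a = simmap_sample(tree, tips, _er(0.01), n_maps=4, seed=11)
        b = simmap_sample(tree, tips, _er(0.01), n_maps=4, seed=11)
        assert all(
            x.node_states == y.node_states and x.histories == y.histories
            for x, y in zip(a, b)
        )

    def test_tip_states_always_match_observations_and_dwells_sum(self):
        tree = random_calibrated_tree(12, seed=2)
        tips, _ = simulate_mk_tips(
            MkSimSpec(tree=tree, Q=_er(0.02), root_state=S3[0], seed=4)
        )
        maps = simmap_sample(tree, tips, _er(0.02), n_maps=10, seed=1)
        arr = _TreeArrays(tree)
        for m in maps:
            for taxon, state in tips.data.items():
                assert m.node_states[taxon] == state
            for j in range(arr.n):
                if j != arr.root:
                    assert m.dwell_total(arr.labels[j]) == pytest.approx(
                        arr.edge_len[j], abs=1e-9
                    )
            for label, segs in m.histories.items():
                assert segs[-1][0] == m.node_states[label]

    def test_node_sampling_matches_analytic_conditional_on_cherry(self):
        # tips in opposite states; flat prior; exact root conditional known
        q, t1, t2, n = 0.3, 1.0, 2.0, 4000
        tree = dendropy.Tree.get(data=f"(A:{t1},B:{t2});", schema="newick")
        chars = CharacterMatrix({"A": "s0", "B": "s1"}, states=("s0", "s1"))

        def p(t, same):
            return 0.5 * (1 + math.exp(-2 * q * t)) if same else 0.5 * (1 - math.exp(-2 * q * t))

        num0 = p(t1, True) * p(t2, False)
        num1 = p(t1, False) * p(t2, True)
        exact = num0 / (num0 + num1)
        maps = simmap_sample(tree, chars, _er(q, 2), n_maps=n, seed=8)
        freq = np.mean([m.node_states["nd2"] == "s0" for m in maps])
        se = math.sqrt(exact * (1 - exact) / n)
        assert abs(freq - exact) <= 3 * se


class TestModelAveraging:
    def test_largest_remainder_allocation(self):
        assert _allocate(np.array([0.5, 0.3, 0.2]), 1000).tolist() == [500, 300, 200]
        thirds = _allocate(np.array([1 / 3, 1 / 3, 1 / 3]), 1000)
        assert thirds.sum() == 1000

    def test_budget_below_model_count_is_an_allocation_error(self):
        tree = random_calibrated_tree(8, seed=0)
        tips, _ = simulate_mk_tips(
            MkSimSpec(tree=tree, Q=_er(0.02), root_state=S3[0], seed=0)
        )
        fits = akaike_weights([fit_mk(tree, tips, m, seed=0) for m in ("ER", "SYM", "ARD")])
        with pytest.raises(AllocationError):
            model_averaged_maps(fits, total=2, seed=0)

    def test_pooled_maps_and_root_summary(self):
        tree = random_calibrated_tree(10, seed=21)
        tips, _ = simulate_mk_tips(
            MkSimSpec(tree=tree, Q=_er(0.005), root_state=S3[0], seed=2)
        )
        fits = akaike_weights([fit_mk(tree, tips, m, seed=0) for m in ("ER", "SYM", "ARD")])
        maps, summary = model_averaged_maps(fits, total=60, seed=5)
        assert len(maps) == 60
        root = summary.attrs["root"]
        assert summary.loc[root].sum() == pytest.approx(1.0)
        assert set(summary.columns) == set(S3)
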