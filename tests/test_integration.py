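import math

import numpy as np
import pytest

from fktransfer.errors import ConfigurationError, EvidenceError, UndefinedMIError
from fktransfer.evidence import discretize
from fktransfer.gold import PairGoldStandard
from fktransfer.integration import (
    NaiveBayesModel,
    RegularizedNaiveBayes,
    compute_alpha,
    dataset_mutual_information,
    fit_cpts,
    mutual_information_bits,
    posterior,
)
from fktransfer.network import FunctionalNetwork, integrate_contexts


def levels_dataset(level_map, n_levels, dataset_id="ds", organism="org"):
    """Evidence whose discretized level equals the given integer per pair."""
    edges = tuple(v + 0.5 for v in range(n_levels - 1))
    return discretize(
        {p: float(v) for p, v in level_map.items()},
        edges,
        dataset_id=dataset_id,
        organism=organism,
    )


def pairs(n):
    return [(f"g{i:03d}a", f"g{i:03d}b") for i in range(n)]


def brute_force_mi_bits(joint):
    total = sum(sum(row) for row in joint)
    px = [sum(row) / total for row in joint]
    py = [sum(col) / total for col in zip(*joint)]
    mi = 0.0
    for i, row in enumerate(joint):
        for j, c in enumerate(row):
            if c:
                p = c / total
                mi += p * math.log2(p / (px[i] * py[j]))
    return mi


class TestMutualInformation:
    def test_independent_levels_zero(self):
        assert mutual_information_bits([[25, 25], [25, 25]]) == pytest.approx(0.0, abs=1e-12)

    def test_identical_uniform_binary_one_bit(self):
        ps = pairs(40)
        lv = {p: (i % 2) for i, p in enumerate(ps)}
        a = levels_dataset(lv, 2, "a")
        b = levels_dataset(lv, 2, "b")
        assert dataset_mutual_information(a, b, ps) == pytest.approx(1.0, abs=1e-12)

    def test_printed_toy_joint(self):
        # joint counts ((30,10),(10,30)) over 80 negative pairs
        joint = [[30, 10], [10, 30]]
        mi = mutual_information_bits(joint)
        assert mi == pytest.approx(brute_force_mi_bits(joint), abs=1e-12)
        assert mi == pytest.approx(0.188722, abs=1e-6)

    def test_dataset_route_matches_matrix_route(self):
        ps = pairs(80)
        la, lb = {}, {}
        cells = [(0, 0, 30), (0, 1, 10), (1, 0, 10), (1, 1, 30)]
        it = iter(ps)
        for va, vb, count in cells:
            for _ in range(count):
                p = next(it)
                la[p], lb[p] = va, vb
        a = levels_dataset(la, 2, "a")
        b = levels_dataset(lb, 2, "b")
        assert dataset_mutual_information(a, b, ps) == pytest.approx(0.188722, abs=1e-6)

    def test_empty_joint_support_raises(self):
        a = levels_dataset({("x", "y"): 0}, 2, "a")
        b = levels_dataset({("u", "v"): 0}, 2, "b")
        with pytest.raises(UndefinedMIError):
            dataset_mutual_information(a, b, [("x", "y"), ("u", "v")])


class TestAlpha:
    def test_no_shared_information_alpha_one(self):
        ps = pairs(64)
        rng = np.random.default_rng(0)
        # exactly independent: all 4 combinations equally often
        la = {p: (i // 2) % 2 for i, p in enumerate(ps)}
        lb = {p: i % 2 for i, p in enumerate(ps)}
        a = levels_dataset(la, 2, "a")
        b = levels_dataset(lb, 2, "b")
        assert compute_alpha(a, [a, b], ps) == pytest.approx(1.0, abs=1e-9)

    def test_exact_copy_gives_exp_minus_one(self):
        ps = pairs(40)
        lv = {p: (i % 2) for i, p in enumerate(ps)}
        a = levels_dataset(lv, 2, "a")
        b = levels_dataset(lv, 2, "b")
        assert compute_alpha(a, [a, b], ps) == pytest.approx(math.exp(-1), abs=1e-9)

    def test_alpha_decreasing_in_redundancy(self):
        ps = pairs(200)
        rng = np.random.default_rng(1)
        base = {p: int(rng.integers(2)) for p in ps}
        a = levels_dataset(base, 2, "a")
        alphas = []
        for flip_rate in (0.5, 0.25, 0.05):
            other = {
                p: (v if rng.random() > flip_rate else 1 - v)
                for p, v in base.items()
            }
            b = levels_dataset(other, 2, "b")
            alphas.append(compute_alpha(a, [a, b], ps))
        assert alphas[0] > alphas[1] > alphas[2]  # more redundancy, smaller alpha

    def test_constant_dataset_rejected(self):
        ps = pairs(10)
        a = levels_dataset({p: 0 for p in ps}, 2, "a")
        with pytest.raises(ConfigurationError):
            compute_alpha(a, [a], ps)


class TestCpts:
    def make_gold(self, n_rel=10, n_unrel=10):
        rel = [(f"r{i}a", f"r{i}b") for i in range(n_rel)]
        unrel = [(f"u{i}a", f"u{i}b") for i in range(n_unrel)]
        return rel, unrel, PairGoldStandard(frozenset(rel), frozenset(unrel))

    def test_smoothing_worked_example(self):
        # binary dataset: 8 of 10 related pairs at level 1, n_s = 3
        rel, unrel, gold = self.make_gold()
        lv = {p: (1 if i < 8 else 0) for i, p in enumerate(rel)}
        lv.update({p: 0 for p in unrel})
        model = fit_cpts([levels_dataset(lv, 2)], gold, n_s=3.0)
        assert model.cpts["ds"][1, 1] == pytest.approx((8 + 1.5) / (10 + 3), abs=1e-9)
        assert model.cpts["ds"][1, 1] == pytest.approx(0.730769, abs=1e-6)

    def test_unobserved_levels_get_pure_smoothing_mass(self):
        rel, unrel, gold = self.make_gold()
        lv = {p: 0 for p in rel + unrel}
        model = fit_cpts([levels_dataset(lv, 4)], gold, n_s=3.0)
        # levels 1..3 unobserved: equal smoothing mass (n_s/L)/(N_c + n_s),
        # and with no observations at all the formula reduces to 1/L
        for level in (1, 2, 3):
            assert model.cpts["ds"][level, 1] == pytest.approx(
                (3.0 / 4) / (10 + 3.0), abs=1e-12
            )
        assert (0 + 3.0 / 4) / (0 + 3.0) == pytest.approx(1 / 4)

    def test_no_pseudocount_reproduces_ml_frequencies(self):
        rel, unrel, gold = self.make_gold()
        lv = {p: (i % 2) for i, p in enumerate(rel)}
        lv.update({p: (1 if i < 2 else 0) for i, p in enumerate(unrel)})
        model = fit_cpts([levels_dataset(lv, 2)], gold, n_s=0.0)
        assert model.cpts["ds"][1, 1] == pytest.approx(0.5, abs=1e-12)
        assert model.cpts["ds"][0, 0] == pytest.approx(0.8, abs=1e-12)

    def test_uncovered_dataset_excluded(self):
        rel, unrel, gold = self.make_gold()
        lv = {p: 0 for p in rel + unrel}
        covered = levels_dataset(lv, 2, "covered")
        stray = levels_dataset({("zz1", "zz2"): 0}, 2, "stray")
        model = fit_cpts([covered, stray], gold, n_s=3.0)
        assert "stray" not in model.cpts
        assert "covered" in model.cpts


class TestPosterior:
    def model(self, alpha=1.0):
        cpt = np.array([[0.8, 0.2], [0.2, 0.8]])  # level x class (FR=0, FR=1)
        return NaiveBayesModel(
            prior=0.1,
            pseudocount=3.0,
            cpts={"d1": cpt},
            alphas={"d1": alpha},
            entropies={"d1": 1.0},
            level_counts={"d1": 2},
        )

    def test_no_observations_returns_prior(self):
        assert posterior(self.model(), {}) == pytest.approx(0.1, abs=1e-15)

    def test_closed_form_alpha_one(self):
        # P(v|1)=0.8, P(v|0)=0.2, prior 0.1 -> 0.08 / 0.26
        assert posterior(self.model(1.0), {"d1": 1}) == pytest.approx(
            0.08 / 0.26, abs=1e-12
        )
        assert posterior(self.model(1.0), {"d1": 1}) == pytest.approx(0.307692, abs=1e-6)

    def test_closed_form_alpha_half(self):
        expected = (math.sqrt(0.8) * 0.1) / (
            math.sqrt(0.8) * 0.1 + math.sqrt(0.2) * 0.9
        )
        assert posterior(self.model(0.5), {"d1": 1}) == pytest.approx(expected, abs=1e-12)
        assert posterior(self.model(0.5), {"d1": 1}) == pytest.approx(0.181818, abs=1e-6)

    def test_level_out_of_range(self):
        with pytest.raises(EvidenceError, match="d1"):
            posterior(self.model(), {"d1": 5})

    def test_log_space_matches_direct_product(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n_ds = int(rng.integers(1, 4))
            cpts, alphas, observed = {}, {}, {}
            for d in range(n_ds):
                L = int(rng.integers(2, 5))
                raw = rng.uniform(0.05, 1.0, (L, 2))
                cpts[f"d{d}"] = raw / raw.sum(axis=0)
                alphas[f"d{d}"] = float(rng.uniform(0.1, 1.0))
                observed[f"d{d}"] = int(rng.integers(L))
            prior = float(rng.uniform(0.01, 0.5))
            model = NaiveBayesModel(
                prior=prior, pseudocount=3.0, cpts=cpts, alphas=alphas,
                entropies={k: 1.0 for k in cpts},
                level_counts={k: v.shape[0] for k, v in cpts.items()},
            )
            num = prior * np.prod(
                [cpts[d][observed[d], 1] ** alphas[d] for d in cpts]
            )
            den = num + (1 - prior) * np.prod(
                [cpts[d][observed[d], 0] ** alphas[d] for d in cpts]
            )
            assert posterior(model, observed) == pytest.approx(num / den, abs=1e-12)

    def test_posterior_strictly_inside_unit_interval(self):
        p = posterior(self.model(), {"d1": 1})
        assert 0.0 < p < 1.0


class TestTextbookEquivalence:
    def test_matches_counting_bayes_on_enumerated_binary_worlds(self):
        # alpha=1, n_s=0: posterior equals P(FR=1 | d) computed by direct
        # counting over an exhaustively enumerated two-dataset world
        rel = [(f"r{i}a", f"r{i}b") for i in range(4)]
        unrel = [(f"u{i}a", f"u{i}b") for i in range(4)]
        gold = PairGoldStandard(frozenset(rel), frozenset(unrel))
        la = {rel[0]: 1, rel[1]: 1, rel[2]: 0, rel[3]: 1,
              unrel[0]: 0, unrel[1]: 0, unrel[2]: 1, unrel[3]: 0}
        lb = {rel[0]: 1, rel[1]: 0, rel[2]: 1, rel[3]: 1,
              unrel[0]: 0, unrel[1]: 1, unrel[2]: 0, unrel[3]: 0}
        model = fit_cpts(
            [levels_dataset(la, 2, "a"), levels_dataset(lb, 2, "b")],
            gold, n_s=0.0, prior=0.5, regularize=False,
        )
        for va in (0, 1):
            for vb in (0, 1):
                pa1 = sum(1 for p in rel if la[p] == va) / 4
                pb1 = sum(1 for p in rel if lb[p] == vb) / 4
                pa0 = sum(1 for p in unrel if la[p] == va) / 4
                pb0 = sum(1 for p in unrel if lb[p] == vb) / 4
                expected = (0.5 * pa1 * pb1) / (0.5 * pa1 * pb1 + 0.5 * pa0 * pb0)
                got = posterior(model, {"a": va, "b": vb})
                assert got == pytest.approx(expected, abs=1e-12)


class TestRedundancyDamping:
    def test_duplicated_dataset_damped_toward_single_copy(self):
        rng = np.random.default_rng(5)
        rel = [(f"r{i}a", f"r{i}b") for i in range(60)]
        unrel = [(f"u{i}a", f"u{i}b") for i in range(200)]
        gold = PairGoldStandard(frozenset(rel), frozenset(unrel))
        lv = {p: int(rng.random() < 0.8) for p in rel}
        lv.update({p: int(rng.random() < 0.2) for p in unrel})
        single = fit_cpts([levels_dataset(lv, 2, "a")], gold)
        dup_reg = fit_cpts(
            [levels_dataset(lv, 2, "a"), levels_dataset(lv, 2, "b")],
            gold, regularize=True,
        )
        dup_naive = fit_cpts(
            [levels_dataset(lv, 2, "a"), levels_dataset(lv, 2, "b")],
            gold, regularize=False,
        )
        p1 = posterior(single, {"a": 1})
        p_reg = posterior(dup_reg, {"a": 1, "b": 1})
        p_naive = posterior(dup_naive, {"a": 1, "b": 1})
        assert abs(p_reg - p1) < abs(p_naive - p1)


class TestContexts:
    def test_identical_networks_unchanged(self):
        net = FunctionalNetwork.from_edges("org", {("a", "b"): 0.3, ("b", "c"): 0.7})
        out = integrate_contexts([net, net])
        assert out.edge("a", "b") == pytest.approx(0.3)

    def test_arithmetic_mean(self):
        n1 = FunctionalNetwork.from_edges("org", {("a", "b"): 0.2})
        n2 = FunctionalNetwork.from_edges("org", {("a", "b"): 0.6})
        assert integrate_contexts([n1, n2]).edge("a", "b") == pytest.approx(0.4)

    def test_masked_mean_over_defined_contexts(self):
        n1 = FunctionalNetwork.from_edges("org", {("a", "b"): 0.9, ("b", "c"): 0.1})
        n2 = FunctionalNetwork.from_edges("org", {("b", "c"): 0.5})
        out = integrate_contexts([n1, n2])
        assert out.edge("a", "b") == pytest.approx(0.9)  # defined in one context
        assert out.edge("b", "c") == pytest.approx(0.3)

    def test_bounded_by_inputs(self):
        rng = np.random.default_rng(9)
        nets = [
            FunctionalNetwork.from_edges(
                "org", {("a", "b"): float(rng.uniform()), ("a", "c"): float(rng.uniform())}
            )
            for _ in range(4)
        ]
        out = integrate_contexts(nets)
        for pair in [("a", "b"), ("a", "c")]:
            vals = [n.edge(*pair) for n in nets]
            assert min(vals) - 1e-12 <= out.edge(*pair) <= max(vals) + 1e-12

    def test_empty_list_rejected(self):
        with pytest.raises(ConfigurationError):
            integrate_contexts([])


def test_model_save_load_round_trip(tmp_path):
    cpt = np.array([[0.7, 0.1], [0.3, 0.9]])
    model = NaiveBayesModel(
        prior=0.05, pseudocount=3.0, cpts={"d": cpt}, alphas={"d": 0.87654321},
        entropies={"d": 1.23456789}, level_counts={"d": 2},
        bin_edges={"d": (0.1, 0.9)},
    )
    path = tmp_path / "model.json"
    model.save(path)
    loaded = NaiveBayesModel.load(path)
    assert loaded.prior == model.prior
    assert np.array_equal(loaded.cpts["d"], cpt)
    assert loaded.alphas["d"] == model.alphas["d"]
    assert loaded.bin_edges["d"] == (0.1, 0.9)
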