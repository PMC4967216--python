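import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import regulon2t as r2t
from regulon2t.inference import RegulatoryNetwork, default_n_bins


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------

def brute_force_mi(x, y, n_bins):
    """Independent plug-in MI oracle with Miller–Madow correction."""
    n = len(x)

    def bins(v):
        order = sorted(range(n), key=lambda i: (v[i], i))
        rank = [0] * n
        for pos, i in enumerate(order):
            rank[i] = pos
        return [rank[i] * n_bins // n for i in range(n)]

    xb, yb = bins(list(x)), bins(list(y))
    joint = {}
    for a, b in zip(xb, yb):
        joint[(a, b)] = joint.get((a, b), 0) + 1
    px, py = {}, {}
    for (a, b), c in joint.items():
        px[a] = px.get(a, 0) + c
        py[b] = py.get(b, 0) + c
    mi = 0.0
    for (a, b), c in joint.items():
        mi += (c / n) * np.log(c * n / (px[a] * py[b]))
    mi += (len(px) + len(py) - len(joint) - 1) / (2 * n)
    return max(mi, 0.0)


class TestMutualInformation:
    def test_independent_near_zero(self):
        rng = np.random.default_rng(0)
        mi = r2t.mutual_information(rng.standard_normal(5000),
                                    rng.standard_normal(5000))
        assert mi <= 0.02

    @pytest.mark.parametrize("n_bins", [3, 5, 8])
    def test_identity_matches_brute_force(self, n_bins):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(600)
        mi = r2t.mutual_information(x, x, n_bins=n_bins)
        assert mi == pytest.approx(brute_force_mi(x, x, n_bins), abs=1e-6)
        # log(B) minus the Miller–Madow bias term for a diagonal table
        expected = np.log(n_bins) + (n_bins - 1) / (2 * 600)
        assert mi == pytest.approx(expected, abs=1e-2)

    def test_random_pairs_match_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.standard_normal(200)
            y = rng.standard_normal(200)
            assert r2t.mutual_information(x, y, n_bins=6) == pytest.approx(
                brute_force_mi(x, y, 6), abs=1e-12)

    def test_gaussian_closed_form(self):
        rng = np.random.default_rng(3)
        rho = 0.8
        x = rng.standard_normal(5000)
        y = rho * x + np.sqrt(1 - rho ** 2) * rng.standard_normal(5000)
        expected = -0.5 * np.log(1 - rho ** 2)
        assert abs(r2t.mutual_information(x, y) - expected) <= 0.05

    def test_symmetry_exact(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal(300), rng.standard_normal(300)
        assert r2t.mutual_information(x, y) == r2t.mutual_information(y, x)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal(120), rng.standard_normal(120)
        base = r2t.mutual_information(x, y, n_bins=4)
        assert r2t.mutual_information(np.exp(x), y ** 3, n_bins=4) == base

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            r2t.mutual_information(np.ones(100), np.arange(100.0))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            r2t.mutual_information(np.arange(10.0), np.arange(10.0),
                                   n_bins=5)


# ---------------------------------------------------------------------------
# Network inference
# ---------------------------------------------------------------------------

class TestInferNetwork:
    def test_planted_regulon_recovery(self, planted):
        matrix, truth = planted
        net = r2t.infer_network(matrix, [truth.regulator_id],
                                n_permutations=1000, alpha=0.01,
                                n_bootstraps=25, seed=1)
        called = set(net.edges["target"])
        sens = len(called & truth.targets) / len(truth.targets)
        fpr = len(called & truth.null_genes) / len(truth.null_genes)
        assert sens >= 0.9
        assert fpr <= 0.02

    def test_pure_noise_calibration(self):
        rng = np.random.default_rng(8)
        values = pd.DataFrame(rng.standard_normal((800, 200)),
                              index=[f"G{i:06d}" for i in range(800)],
                              columns=[f"S{j}" for j in range(200)])
        matrix = r2t.ExpressionMatrix(values=values)
        net = r2t.infer_network(matrix, ["G000000"], n_permutations=4000,
                                alpha=0.01, n_bootstraps=0, seed=9)
        frac = net.n_edges / 799
        # binomial 95% band around alpha (wide: shared-null threshold)
        assert 0.0 <= frac <= 0.01 + 2.5 * np.sqrt(0.01 * 0.99 / 799)

    def test_no_bootstrap_support_is_one(self, planted):
        matrix, truth = planted
        net = r2t.infer_network(matrix, [truth.regulator_id],
                                n_bootstraps=0, seed=2)
        assert (net.edges["bootstrap_support"] == 1.0).all()

    def test_p_perm_in_half_open_unit(self, planted):
        matrix, truth = planted
        net = r2t.infer_network(matrix, [truth.regulator_id],
                                n_bootstraps=0, seed=3)
        p = net.edges["p_perm"]
        assert (p > 0).all() and (p <= 1).all()

    def test_absent_regulator_named(self, planted):
        matrix, _ = planted
        with pytest.raises(KeyError, match="NOPE"):
            r2t.infer_network(matrix, ["NOPE"], seed=0)


# ---------------------------------------------------------------------------
# DPI filter
# ---------------------------------------------------------------------------

def brute_force_dpi(network, tolerance):
    """Exhaustive triplet enumeration oracle for the DPI rule."""
    mi_of = {(row.regulator, row.target): row.mi
             for row in network.edges.itertuples()}
    remove = set()
    for r1, r2 in itertools.combinations(network.regulators, 2):
        mi12 = network.regulator_mi.get(frozenset((r1, r2)))
        if mi12 is None:
            continue
        for t in {t for (r, t) in mi_of if r == r1}:
            if (r2, t) not in mi_of:
                continue
            m1, m2 = mi_of[(r1, t)], mi_of[(r2, t)]
            vals = sorted([("e1", m1), ("e2", m2), ("e12", mi12)],
                          key=lambda kv: kv[1])
            name, smallest = vals[0]
            if smallest >= vals[1][1]:  # tie: no strictly weakest edge
                continue
            if name == "e12":
                continue
            if smallest < (1 - tolerance) * min(vals[1][1], vals[2][1]):
                remove.add((r1, t) if name == "e1" else (r2, t))
    kept = [(row.regulator, row.target)
            for row in network.edges.itertuples()
            if (row.regulator, row.target) not in remove]
    return set(kept)


def random_network(rng, n_regs=8, n_targets=42, edge_p=0.4):
    regs = [f"R{i}" for i in range(n_regs)]
    targets = [f"T{i}" for i in range(n_targets)]
    rows = []
    for r in regs:
        for t in targets:
            if rng.random() < edge_p:
                rows.append((r, t, float(rng.random()), 0.001, 1.0))
    edges = pd.DataFrame(rows, columns=["regulator", "target", "mi",
                                        "p_perm", "bootstrap_support"])
    reg_mi = {frozenset(p): float(rng.random())
              for p in itertools.combinations(regs, 2)}
    return RegulatoryNetwork(regulators=tuple(regs), edges=edges,
                             regulator_mi=reg_mi)


class TestDpiFilter:
    def test_weakest_edge_removed(self):
        edges = pd.DataFrame(
            [("r1", "t", 0.2, 0.001, 1.0), ("r2", "t", 0.6, 0.001, 1.0)],
            columns=["regulator", "target", "mi", "p_perm",
                     "bootstrap_support"])
        net = RegulatoryNetwork(regulators=("r1", "r2"), edges=edges,
                                regulator_mi={frozenset(("r1", "r2")): 0.5})
        out = r2t.dpi_filter(net, tolerance=0.0)
        assert set(zip(out.edges["regulator"], out.edges["target"])) \
            == {("r2", "t")}

    def test_tolerance_spares_weak_edge(self):
        edges = pd.DataFrame(
            [("r1", "t", 0.2, 0.001, 1.0), ("r2", "t", 0.6, 0.001, 1.0)],
            columns=["regulator", "target", "mi", "p_perm",
                     "bootstrap_support"])
        net = RegulatoryNetwork(regulators=("r1", "r2"), edges=edges,
                                regulator_mi={frozenset(("r1", "r2")): 0.5})
        out = r2t.dpi_filter(net, tolerance=0.7)  # 0.2 ≥ 0.3·0.5
        assert out.n_edges == 2

    def test_matches_brute_force_on_random_networks(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            net = random_network(rng)
            for tol in (0.0, 0.1, 0.2):
                out = r2t.dpi_filter(net, tol)
                got = set(zip(out.edges["regulator"], out.edges["target"]))
                assert got == brute_force_dpi(net, tol)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_monotone_in_tolerance(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng, n_regs=5, n_targets=15)
        edge_sets = []
        for tol in (0.0, 0.3, 0.8, 1.0):
            out = r2t.dpi_filter(net, tol)
            edge_sets.append(
                set(zip(out.edges["regulator"], out.edges["target"])))
        for a, b in zip(edge_sets, edge_sets[1:]):
            assert a <= b

    def test_invalid_tolerance_rejected(self):
        rng = np.random.default_rng(0)
        net = random_network(rng)
        with pytest.raises(ValueError):
            r2t.dpi_filter(net, -0.1)
        with pytest.raises(ValueError):
            r2t.dpi_filter(net, 1.5)


# ---------------------------------------------------------------------------
# Mode of regulation
# ---------------------------------------------------------------------------

class TestSplitRegulon:
    def _network_for(self, matrix, regulator, targets):
        edges = pd.DataFrame(
            [(regulator, t, 1.0, 0.001, 1.0) for t in targets],
            columns=["regulator", "target", "mi", "p_perm",
                     "bootstrap_support"])
        return RegulatoryNetwork(regulators=(regulator,), edges=edges)

    def test_duplicate_of_regulator_mode_positive(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(50)
        values = pd.DataFrame({"s%d" % i: [x[i], x[i], -x[i]]
                               for i in range(50)},
                              index=["TF", "COPY", "ANTI"])
        matrix = r2t.ExpressionMatrix(values=values)
        net = self._network_for(matrix, "TF", ["COPY", "ANTI"])
        regulon = r2t.split_regulon(matrix, net, "TF")
        assert regulon.table.at["COPY", "mode"] == 1
        assert regulon.table.at["COPY", "r"] == pytest.approx(1.0)
        assert regulon.table.at["ANTI", "mode"] == -1
        assert regulon.table.at["ANTI", "r"] == pytest.approx(-1.0)

    def test_planted_modes_recovered(self, planted):
        matrix, truth = planted
        net = r2t.infer_network(matrix, [truth.regulator_id],
                                n_bootstraps=0, seed=4)
        regulon = r2t.split_regulon(matrix, net, truth.regulator_id)
        recovered_true = [g for g in regulon.table.index
                          if g in truth.targets]
        agree = sum(
            (regulon.table.at[g, "mode"] > 0) == (g in truth.positive_targets)
            for g in recovered_true)
        assert agree / len(recovered_true) >= 0.98

    def test_empty_regulon_rejected(self, planted):
        matrix, truth = planted
        edges = pd.DataFrame(columns=["regulator", "target", "mi", "p_perm",
                                      "bootstrap_support"])
        net = RegulatoryNetwork(regulators=(truth.regulator_id,),
                                edges=edges)
        with pytest.raises(ValueError):
            r2t.split_regulon(matrix, net, truth.regulator_id)
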