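"""Network-inference operations against independent oracles and boundaries."""
from __future__ import annotations

import dataclasses
import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from regmaster.datatypes import EdgeCandidate, InferredNetwork, SignedRegulon
from regmaster.network import (
    apply_dpi,
    assign_modes,
    bootstrap_consensus,
    estimate_mi,
    filter_regulons,
    infer_raw_network,
    permutation_threshold,
)
from regmaster.simulate import SimulationConfig, simulate_network, simulate_reference_cohort


def mi_oracle(x, y, n_bins):
    """Joint-histogram MI computed independently: explicit rank bins + Counter."""
    n = len(x)
    bx = ((rankdata(x, method="ordinal") - 1) * n_bins) // n
    by = ((rankdata(y, method="ordinal") - 1) * n_bins) // n
    joint = Counter(zip(bx.astype(int), by.astype(int)))
    px = Counter(bx.astype(int))
    py = Counter(by.astype(int))
    mi = 0.0
    for (i, j), c in joint.items():
        p = c / n
        mi += p * np.log(p / ((px[i] / n) * (py[j] / n)))
    return mi


class TestEstimateMi:
    def test_two_bin_identity_vectors_give_ln2(self):
        assert estimate_mi([1, 2, 3, 4], [1, 2, 3, 4], 2) == pytest.approx(np.log(2))

    def test_matches_oracle_on_fuzzed_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(20, 80))
            b = int(rng.integers(2, max(3, int(np.sqrt(n)))))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n) + 0.5 * x
            assert estimate_mi(x, y, b) == pytest.approx(mi_oracle(x, y, b), abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=8, max_size=40), st.integers(0, 10**6))
    def test_symmetry(self, xs, seed):
        x = np.asarray(xs)
        y = np.random.default_rng(seed).permutation(x) + 1.0
        assert estimate_mi(x, y, 2) == pytest.approx(estimate_mi(y, x, 2), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.standard_normal(60)
        y = rng.standard_normal(60)
        assert estimate_mi(x, np.exp(y), 4) == estimate_mi(x, y, 4)
        assert estimate_mi(np.tanh(x), y, 4) == estimate_mi(x, y, 4)

    def test_constant_vector_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            assert estimate_mi(np.ones(20), np.arange(20.0), 3) == 0.0


@pytest.fixture(scope="module")
def tiny_cohort():
    cfg = SimulationConfig(n_tf=3, n_genes=20, targets_per_tf=4, n_ref=60,
                           perturbed_mrs={"TF01": "activated"}, seed=21)
    truth = simulate_network(cfg)
    expr = simulate_reference_cohort(truth, 60, cfg.sigma_noise, seed=22)
    return truth, expr


class TestPermutationThreshold:
    def test_p_cutoff_one_returns_null_minimum(self, tiny_cohort):
        truth, expr = tiny_cohort
        thr = permutation_threshold(expr, list(truth.tf_ids), n_perm=200, p_cutoff=1.0, seed=1)
        edges = infer_raw_network(expr, list(truth.tf_ids), thr)
        # every TF-gene pair with MI above the null minimum passes; the null
        # minimum is tiny, so nearly all pairs survive
        assert len(edges) > 0.9 * 3 * 19

    def test_degenerate_null_returns_common_value(self, monkeypatch):
        import regmaster.network as net

        monkeypatch.setattr(net, "_mi_from_bins", lambda *a: 0.7)
        expr = pd.DataFrame(
            np.random.default_rng(0).standard_normal((5, 30)),
            index=[f"g{i}" for i in range(5)],
        )
        thr = net.permutation_threshold(expr, ["g0"], n_perm=150, p_cutoff=0.01, seed=2)
        assert thr == pytest.approx(0.7)

    def test_small_n_perm_warns(self, tiny_cohort):
        truth, expr = tiny_cohort
        with pytest.warns(UserWarning, match="unstable"):
            permutation_threshold(expr, list(truth.tf_ids), n_perm=50, p_cutoff=0.1, seed=3)


class TestRawNetwork:
    def test_infinite_threshold_gives_empty_network(self, tiny_cohort):
        truth, expr = tiny_cohort
        assert infer_raw_network(expr, list(truth.tf_ids), np.inf) == []

    def test_empty_tf_list_is_an_error(self, tiny_cohort):
        _, expr = tiny_cohort
        with pytest.raises(ValueError, match="TF"):
            infer_raw_network(expr, [], 0.1)

    def test_noise_free_single_tf_truth_recovers_exactly_the_targets(self):
        cfg = SimulationConfig(n_tf=1, n_genes=15, targets_per_tf=5, n_ref=60,
                               sigma_noise=0.0, perturbed_mrs={"TF01": "activated"}, seed=30)
        truth = simulate_network(cfg)
        expr = simulate_reference_cohort(truth, 60, 0.0, seed=31)
        thr = permutation_threshold(expr, ["TF01"], n_perm=500, p_cutoff=0.01, seed=32)
        edges = infer_raw_network(expr, ["TF01"], thr)
        assert {e.target for e in edges} == set(truth.targets["TF01"])

    def test_edge_set_matches_brute_force_over_all_pairs(self, tiny_cohort):
        truth, expr = tiny_cohort
        thr = 0.15
        edges = {(e.tf, e.target): e.mi for e in infer_raw_network(expr, list(truth.tf_ids), thr)}
        expected = {}
        for tf in truth.tf_ids:
            for g in expr.index:
                if g == tf:
                    continue
                mi = mi_oracle(expr.loc[tf].to_numpy(), expr.loc[g].to_numpy(), 3)
                if mi >= thr:
                    expected[(tf, g)] = mi
        assert set(edges) == set(expected)
        for k in edges:
            assert edges[k] == pytest.approx(expected[k], abs=1e-12)


class TestBootstrapConsensus:
    def test_consensus_zero_equals_union_and_single_bootstrap_identity(self, tiny_cohort):
        truth, expr = tiny_cohort
        tfs = list(truth.tf_ids)
        union = bootstrap_consensus(expr, tfs, 0.3, n_boot=5, consensus=0.0, seed=7)
        single = bootstrap_consensus(expr, tfs, 0.3, n_boot=1, consensus=1.0, seed=7)
        assert {(e.tf, e.target) for e in single} <= {(e.tf, e.target) for e in union}
        assert all(e.bootstrap_support == 1.0 for e in single)
        assert all(0 < e.bootstrap_support <= 1.0 for e in union)

    def test_strong_edges_have_high_support_null_edges_low(self, scenario, network):
        _, truth, _, _, _ = scenario
        true_edges = {(tf, g) for tf in truth.tf_ids for g in truth.targets[tf]}
        kept = {(r.tf, t) for r in network.regulons.values() for t in r.targets}
        # at the default 0.95 consensus no spurious edge survives and most
        # planted edges do
        assert len(kept - true_edges) <= 0.02 * len(kept)
        assert len(kept & true_edges) >= 0.8 * len(true_edges)


def brute_force_dpi(edges, tfs, tolerance=0.0):
    mi = {(e.tf, e.target): e.mi for e in edges}
    def lookup(a, b):
        return mi.get((a, b), mi.get((b, a)))
    doomed = set()
    for i, j in itertools.permutations(sorted(tfs), 2):
        for (tf, k) in list(mi):
            if tf != i or k in tfs:
                continue
            m_ij = lookup(i, j)
            m_jk = lookup(j, k)
            if m_ij is None or m_jk is None:
                continue
            if mi[(i, k)] < (1 - tolerance) * min(m_ij, m_jk):
                doomed.add((i, k))
    return [e for e in edges if (e.tf, e.target) not in doomed]


class TestDpi:
    def _edges(self, triples):
        return [EdgeCandidate(tf=a, target=b, mi=m) for a, b, m in triples]

    def test_weakest_edge_of_closed_triplet_is_removed(self):
        edges = self._edges([("TF1", "TF2", 0.8), ("TF2", "T", 0.7), ("TF1", "T", 0.3)])
        kept = {(e.tf, e.target) for e in apply_dpi(edges, ["TF1", "TF2"])}
        assert kept == {("TF1", "TF2"), ("TF2", "T")}

    def test_tie_keeps_the_edge(self):
        edges = self._edges([("TF1", "TF2", 0.8), ("TF2", "T", 0.7), ("TF1", "T", 0.7)])
        kept = {(e.tf, e.target) for e in apply_dpi(edges, ["TF1", "TF2"])}
        assert ("TF1", "T") in kept

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        tfs = [f"TF{i}" for i in range(5)]
        targets = [f"g{i}" for i in range(10)]
        for trial in range(25):
            edges = []
            for a, b in itertools.combinations(tfs, 2):
                if rng.random() < 0.5:
                    edges.append(EdgeCandidate(a, b, float(rng.random())))
            for tf in tfs:
                for g in targets:
                    if rng.random() < 0.4:
                        edges.append(EdgeCandidate(tf, g, float(rng.random())))
            got = {(e.tf, e.target) for e in apply_dpi(edges, tfs)}
            want = {(e.tf, e.target) for e in brute_force_dpi(edges, tfs)}
            assert got == want

    def test_output_is_subset_of_input(self, rng):
        edges = [EdgeCandidate("TF1", f"g{i}", float(rng.random())) for i in range(5)]
        assert set(apply_dpi(edges, ["TF1"])) <= set(edges)


class TestAssignModes:
    def test_noise_free_negative_mode_assigned_minus_one(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(40)
        expr = pd.DataFrame(
            {"s%d" % i: [a[i], -a[i], a[i] * 2] for i in range(40)},
            index=["TF1", "gneg", "gpos"],
        )
        regs = assign_modes(expr, [EdgeCandidate("TF1", "gneg", 0.5), EdgeCandidate("TF1", "gpos", 0.5)], ["TF1"])
        assert "gneg" in regs["TF1"].negative
        assert "gpos" in regs["TF1"].positive

    def test_modes_partition_the_regulon_and_tf_tf_edges_drop(self, network, scenario):
        _, truth, _, _, _ = scenario
        for tf, reg in network.regulons.items():
            assert len(reg.positive) + len(reg.negative) == reg.size
            assert not set(reg.targets) & set(truth.tf_ids)

    def test_mode_recovery_on_reference_scenario(self, network, scenario):
        _, truth, _, _, _ = scenario
        ok = tot = 0
        for tf, reg in network.regulons.items():
            for g in reg.targets & truth.regulon_targets(tf):
                tot += 1
                ok += reg.mode_of(g) == truth.mode_of(tf, g)
        assert tot > 0
        assert ok / tot >= 0.95

    def test_zero_variance_gene_is_an_error(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0]], index=["TF1", "flat"]
        )
        with pytest.raises(ValueError, match="flat"):
            assign_modes(expr, [EdgeCandidate("TF1", "flat", 0.2)], ["TF1"])


class TestFilterRegulons:
    @staticmethod
    def _net(sizes):
        regs = {
            tf: SignedRegulon(tf, positive={f"{tf}_g{i}": 0.1 for i in range(k)})
            for tf, k in sizes.items()
        }
        return InferredNetwork(regulons=regs, universe=("x",))

    def test_zero_threshold_is_identity(self):
        net = self._net({"A": 3, "B": 0})
        assert set(filter_regulons(net, 0).regulons) == {"A", "B"}

    def test_analysis_tier_is_inclusive(self):
        net = self._net({"A": 100, "B": 99})
        assert set(filter_regulons(net, 100, inclusive=True).regulons) == {"A"}

    def test_reporting_tier_is_strict(self):
        net = self._net({"A": 25, "B": 26})
        assert set(filter_regulons(net, 25, inclusive=False).regulons) == {"B"}


def test_pipeline_stage_monotonicity(scenario):
    """Raw edges contain the bootstrap consensus, which contains the DPI output."""
    _, truth, ref, _, _ = scenario
    tfs = list(truth.tf_ids)
    thr = permutation_threshold(ref, tfs, n_perm=500, p_cutoff=0.001, seed=40)
    raw = {(e.tf, e.target) for e in infer_raw_network(ref, tfs, thr)}
    boot = bootstrap_consensus(ref, tfs, thr, n_boot=30, consensus=0.95, seed=41,
                               p_cutoff=0.001, n_perm=500)
    boot_keys = {(e.tf, e.target) for e in boot}
    dpi_keys = {(e.tf, e.target) for e in apply_dpi(boot, tfs)}
    assert boot_keys <= raw
    assert dpi_keys <= boot_keys
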