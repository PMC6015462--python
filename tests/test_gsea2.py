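"""Two-tail GSEA: running-sum oracle, antisymmetry, permutation null."""
from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regmaster.datatypes import DifferentialResult, SignedRegulon, TwoTailRecord
from regmaster.gsea2 import (
    RankedPhenotype,
    classify_state,
    enrichment_score,
    permutation_test_des,
    rank_phenotype,
    run_two_tail_gsea,
    two_tail_es,
)


def es_oracle(genes, metric, gene_set, exponent):
    """Brute-force running sum, one explicit step per gene."""
    hits = [g in gene_set for g in genes]
    nh = sum(hits)
    n = len(genes)
    if nh == n:
        return 1.0
    denom = sum(abs(m) ** exponent for g, m in zip(genes, metric) if g in gene_set)
    running, best = 0.0, 0.0
    for g, m, h in zip(genes, metric, hits):
        if h:
            running += (abs(m) ** exponent / denom) if denom > 0 else 1.0 / nh
        else:
            running -= 1.0 / (n - nh)
        if abs(running) > abs(best):
            best = running
    return best


def _de(logfc: dict[str, float], study_id="s1") -> DifferentialResult:
    tbl = pd.DataFrame(
        {"logFC": list(logfc.values()), "t": 0.0, "p": 0.5, "p_adj": 0.5},
        index=pd.Index(list(logfc)),
    )
    return DifferentialResult(table=tbl, study_id=study_id)


class TestRankPhenotype:
    def test_descending_with_lexicographic_ties(self):
        ranked = rank_phenotype(_de({"A": 2.0, "B": -1.0, "C": 0.0}))
        assert ranked.genes == ("A", "C", "B")
        ranked = rank_phenotype(_de({"B": 1.0, "A": 1.0}))
        assert ranked.genes == ("A", "B")

    def test_sign_flip_reverses_order(self):
        vals = {"A": 2.0, "B": -1.0, "C": 0.5, "D": -0.3}
        fwd = rank_phenotype(_de(vals))
        rev = rank_phenotype(_de({g: -v for g, v in vals.items()}))
        assert rev.genes == tuple(reversed(fwd.genes))


class TestEnrichmentScore:
    def test_top_gene_scores_one_unweighted(self):
        ranked = RankedPhenotype(("A", "B", "C", "D"), np.array([3.0, 2.0, 1.0, 0.5]))
        assert enrichment_score(ranked, {"A"}, exponent=0) == pytest.approx(1.0)

    def test_bottom_gene_scores_minus_one_unweighted(self):
        ranked = RankedPhenotype(("A", "B", "C", "D"), np.array([3.0, 2.0, 1.0, 0.5]))
        assert enrichment_score(ranked, {"D"}, exponent=0) == pytest.approx(-1.0)

    def test_full_set_scores_one(self):
        ranked = RankedPhenotype(("A", "B", "C"), np.array([1.0, 0.0, -1.0]))
        assert enrichment_score(ranked, {"A", "B", "C"}) == pytest.approx(1.0)

    def test_disjoint_set_is_an_error(self):
        ranked = RankedPhenotype(("A", "B"), np.array([1.0, -1.0]))
        with pytest.raises(ValueError, match="disjoint"):
            enrichment_score(ranked, {"Z"})

    @settings(max_examples=80, deadline=None)
    @given(
        n=st.integers(2, 10),
        mask=st.integers(1, 2**10 - 1),
        exponent=st.sampled_from([0.0, 1.0]),
        seed=st.integers(0, 10**6),
    )
    def test_matches_brute_force_oracle(self, n, mask, exponent, seed):
        rng = np.random.default_rng(seed)
        metric = np.sort(rng.standard_normal(n))[::-1]
        genes = tuple(f"g{i}" for i in range(n))
        gene_set = {g for i, g in enumerate(genes) if mask & (1 << i)}
        if not gene_set:
            gene_set = {genes[0]}
        ranked = RankedPhenotype(genes, metric)
        got = enrichment_score(ranked, gene_set, exponent)
        want = es_oracle(genes, metric, gene_set, exponent)
        assert got == pytest.approx(want, abs=1e-12)
        assert -1.0 <= got <= 1.0


class TestTwoTailEs:
    def test_separated_modes_give_strong_positive_des(self):
        genes = tuple(f"g{i}" for i in range(10))
        metric = np.linspace(2, -2, 10)
        ranked = RankedPhenotype(genes, metric)
        reg = SignedRegulon("TF", positive={"g0": 1, "g1": 1}, negative={"g8": 1, "g9": 1})
        es_a, es_b, des = two_tail_es(reg, ranked)
        assert es_a > 0 > es_b
        assert des == pytest.approx(es_a - es_b)

    def test_subset_swap_negates_des(self):
        genes = tuple(f"g{i}" for i in range(12))
        rng = np.random.default_rng(5)
        metric = np.sort(rng.standard_normal(12))[::-1]
        ranked = RankedPhenotype(genes, metric)
        reg = SignedRegulon("TF", positive={"g0": 1, "g5": 1}, negative={"g2": 1, "g11": 1})
        swapped = SignedRegulon("TF", positive=dict(reg.negative), negative=dict(reg.positive))
        assert two_tail_es(reg, ranked)[2] == pytest.approx(-two_tail_es(swapped, ranked)[2])

    def test_empty_mode_subset_contributes_zero(self):
        ranked = RankedPhenotype(("A", "B", "C"), np.array([1.0, 0.5, -1.0]))
        reg = SignedRegulon("TF", positive={"A": 1}, negative={})
        es_a, es_b, des = two_tail_es(reg, ranked)
        assert es_b == 0.0
        assert des == es_a


class TestPermutationTest:
    def test_extreme_observation_reaches_the_p_floor(self):
        genes = tuple(f"g{i}" for i in range(40))
        metric = np.linspace(3, -3, 40)
        ranked = RankedPhenotype(genes, metric)
        reg = SignedRegulon(
            "TF",
            positive={f"g{i}": 1 for i in range(6)},
            negative={f"g{i}": 1 for i in range(34, 40)},
        )
        *_, p = permutation_test_des(reg, ranked, n_perm=200, seed=3)
        assert p == pytest.approx(1 / 201)

    def test_agrees_with_exhaustive_enumeration_on_tiny_instance(self):
        genes = tuple(f"g{i}" for i in range(8))
        rng = np.random.default_rng(11)
        metric = np.sort(rng.standard_normal(8))[::-1]
        ranked = RankedPhenotype(genes, metric)
        reg = SignedRegulon("TF", positive={"g0": 1, "g3": 1}, negative={"g5": 1, "g6": 1})

        def des_of(pos_idx, neg_idx):
            p = SignedRegulon(
                "x",
                positive={genes[i]: 1 for i in pos_idx},
                negative={genes[i]: 1 for i in neg_idx},
            )
            return two_tail_es(p, ranked)[2]

        obs = abs(des_of((0, 3), (5, 6)))
        total = hits = 0
        for pos in itertools.combinations(range(8), 2):
            rest = [i for i in range(8) if i not in pos]
            for neg in itertools.combinations(rest, 2):
                total += 1
                if abs(des_of(pos, neg)) >= obs - 1e-12:
                    hits += 1
        exact = hits / total
        n_perm = 10000
        *_, p = permutation_test_des(reg, ranked, n_perm=n_perm, seed=7)
        mc_se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(p - exact) <= 2 * mc_se + 2 / n_perm


class TestClassifyState:
    @staticmethod
    def _rec(des, p_adj):
        return TwoTailRecord(tf="TF", study_id="s", es_pos=des, es_neg=0.0, des=des,
                             p=p_adj, p_adj=p_adj)

    @pytest.mark.parametrize(
        "des,p_adj,state",
        [(1.2, 0.01, "activated"), (-1.2, 0.01, "repressed"), (1.2, 0.2, "ns")],
    )
    def test_rules(self, des, p_adj, state):
        assert classify_state([self._rec(des, p_adj)])[0].state == state

    def test_zero_des_significant_warns_ns(self):
        with pytest.warns(UserWarning, match="dES == 0"):
            out = classify_state([self._rec(0.0, 0.01)])
        assert out[0].state == "ns"


def test_planted_direction_recovery(scenario, analysis_network, de_results):
    """Every planted activated/repressed MR is called with the right sign in >= 3/4 studies."""
    cfg, *_ = scenario
    records = run_two_tail_gsea(
        analysis_network, de_results, tfs=sorted(cfg.perturbed_mrs), seed=12
    )
    for tf, direction in cfg.perturbed_mrs.items():
        calls = [r.state for r in records if r.tf == tf]
        assert sum(c == direction for c in calls) >= 3
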