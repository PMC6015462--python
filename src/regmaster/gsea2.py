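"""Two-tail GSEA: activation-state calling for master-regulator candidates.

A regulon's positive-mode and negative-mode target subsets are enriched
independently in the study's logFC-ranked gene list with the weighted
Kolmogorov-Smirnov running-sum statistic, giving two enrichment scores
EsA (positive-mode) and EsB (negative-mode). Their difference
dES = EsA - EsB summarizes the activation state: a TF whose positive
targets sit at the top of the disease ranking and negative targets at the
bottom (dES strongly positive) is induced/activated in the disease, the
mirror image (dES strongly negative) is repressed. Significance comes
from a gene-label permutation null on dES.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .datatypes import DifferentialResult, InferredNetwork, SignedRegulon, TwoTailRecord, replace
from .diffexp import bh_adjust

log = logging.getLogger(__name__)

__all__ = [
    "RankedPhenotype",
    "rank_phenotype",
    "enrichment_score",
    "two_tail_es",
    "permutation_test_des",
    "classify_state",
    "run_two_tail_gsea",
]


@dataclass(frozen=True)
class RankedPhenotype:
    """Genes ordered by descending logFC with deterministic tie-breaking."""

    genes: tuple[str, ...]
    metric: np.ndarray  # aligned logFC values, descending

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric must align")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranking")

    @property
    def n(self) -> int:
        return len(self.genes)

    def positions_of(self, gene_set: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genes)}
        return np.array(sorted(lookup[g] for g in gene_set if g in lookup), dtype=np.int64)


def rank_phenotype(de: DifferentialResult) -> RankedPhenotype:
    """Rank genes by descending logFC; ties break lexicographically by id."""
    tbl = de.table[["logFC"]].copy()
    tbl["gene"] = tbl.index.astype(str)
    tbl = tbl.sort_values(["logFC", "gene"], ascending=[False, True], kind="mergesort")
    return RankedPhenotype(genes=tuple(tbl["gene"]), metric=tbl["logFC"].to_numpy())


def _es_from_positions(hit_pos: np.ndarray, metric: np.ndarray, exponent: float) -> float:
    """Signed maximum deviation of the weighted KS running sum."""
    n = len(metric)
    nh = len(hit_pos)
    if nh == 0:
        raise ValueError("gene set is disjoint from the ranking")
    if nh == n:
        return 1.0
    weights = np.abs(metric[hit_pos]) ** exponent
    total = weights.sum()
    if total == 0:  # all hit metrics zero: fall back to unweighted steps
        weights = np.full(nh, 1.0)
        total = float(nh)
    running = np.full(n, -1.0 / (n - nh))
    running[hit_pos] = weights / total
    running = np.cumsum(running)
    i = int(np.argmax(np.abs(running)))
    # cumsum rounding can overshoot the exact bounds by ~1 ulp
    return float(np.clip(running[i], -1.0, 1.0))


def enrichment_score(ranked: RankedPhenotype, gene_set: Iterable[str], exponent: float = 1.0) -> float:
    """Weighted KS enrichment score of ``gene_set`` in the ranking, in [-1, 1].

    Hits advance the running sum by |logFC|^exponent (normalized over the
    hits), misses retreat it by 1/(N - set size); the score is the signed
    extremum of the running sum.
    """
    pos = ranked.positions_of(gene_set)
    return _es_from_positions(pos, ranked.metric, exponent)


def two_tail_es(
    regulon: SignedRegulon, ranked: RankedPhenotype, exponent: float = 1.0
) -> tuple[float, float, float]:
    """(EsA, EsB, dES): independent enrichment of the two mode subsets.

    An empty (or out-of-universe) mode subset contributes Es = 0.
    """
    scores = []
    for subset in (regulon.positive, regulon.negative):
        pos = ranked.positions_of(subset)
        if len(pos) == 0:
            log.info("regulon %s: empty mode subset in ranking; Es = 0", regulon.tf)
            scores.append(0.0)
        else:
            scores.append(_es_from_positions(pos, ranked.metric, exponent))
    es_a, es_b = scores
    return es_a, es_b, es_a - es_b


def permutation_test_des(
    regulon: SignedRegulon,
    ranked: RankedPhenotype,
    n_perm: int = 1000,
    exponent: float = 1.0,
    seed: int | None = None,
) -> tuple[float, float, float, float]:
    """Gene-label permutation p-value for dES.

    The null redraws disjoint random subsets matching the two mode-subset
    sizes from the ranked universe and recomputes dES; the two-sided
    p-value is ``(1 + #{|dES_null| >= |dES_obs|}) / (1 + n_perm)``.
    Returns (EsA, EsB, dES, p).
    """
    rng = np.random.default_rng(seed)
    es_a, es_b, des = two_tail_es(regulon, ranked, exponent)
    n_pos = len(ranked.positions_of(regulon.positive))
    n_neg = len(ranked.positions_of(regulon.negative))
    n = ranked.n
    count = 0
    for _ in range(n_perm):
        draw = rng.choice(n, size=n_pos + n_neg, replace=False)
        a = 0.0 if n_pos == 0 else _es_from_positions(np.sort(draw[:n_pos]), ranked.metric, exponent)
        b = 0.0 if n_neg == 0 else _es_from_positions(np.sort(draw[n_pos:]), ranked.metric, exponent)
        if abs(a - b) >= abs(des):
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return es_a, es_b, des, p


def classify_state(records: Sequence[TwoTailRecord], alpha: float = 0.05) -> list[TwoTailRecord]:
    """Call activated / repressed / ns from adjusted p and the sign of dES."""
    out = []
    for r in records:
        if r.p_adj <= alpha:
            if r.des > 0:
                state = "activated"
            elif r.des < 0:
                state = "repressed"
            else:
                warnings.warn(f"{r.tf}: significant but dES == 0; calling ns", stacklevel=2)
                state = "ns"
        else:
            state = "ns"
        out.append(replace(r, state=state))
    return out


def run_two_tail_gsea(
    network: InferredNetwork,
    de_results: Iterable[DifferentialResult],
    tfs: Sequence[str] | None = None,
    n_perm: int = 1000,
    exponent: float = 1.0,
    alpha: float = 0.05,
    seed: int | None = None,
) -> list[TwoTailRecord]:
    """Two-tail GSEA of selected regulons (default: all) across studies.

    Per study: rank by logFC, score each regulon, build the permutation
    null, BH-adjust across TFs, classify states at ``alpha``.
    """
    chosen = list(tfs) if tfs is not None else list(network.regulons)
    missing = [tf for tf in chosen if tf not in network.regulons]
    if missing:
        raise ValueError(f"TFs absent from the network: {missing[:3]}")
    ss = np.random.SeedSequence(seed)
    de_list = list(de_results)
    out: list[TwoTailRecord] = []
    for de, study_ss in zip(de_list, ss.spawn(len(de_list))):
        ranked = rank_phenotype(de)
        tf_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in study_ss.spawn(len(chosen))]
        study_records = []
        for tf, tf_seed in zip(chosen, tf_seeds):
            es_a, es_b, des, p = permutation_test_des(
                network.regulons[tf], ranked, n_perm, exponent, tf_seed
            )
            study_records.append(
                TwoTailRecord(tf=tf, study_id=de.study_id, es_pos=es_a, es_neg=es_b, des=des, p=p)
            )
        adj = bh_adjust([r.p for r in study_records])
        study_records = [replace(r, p_adj=float(q)) for r, q in zip(study_records, adj)]
        out.extend(classify_state(study_records, alpha=alpha))
    return out
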