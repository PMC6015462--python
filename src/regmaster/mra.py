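"""Master regulator analysis: regulon vs differential-expression overlap.

For each study, every regulon's target set is tested for enrichment with
the study's differentially expressed genes using the upper-tail
hypergeometric distribution; p-values are BH-adjusted across TFs within
the study, and a TF is called a master-regulator candidate when its
regulon is significantly enriched in at least ``min_studies`` studies.
"""
from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .datatypes import DifferentialResult, InferredNetwork, MraRecord, replace
from .diffexp import bh_adjust, de_gene_set

log = logging.getLogger(__name__)

__all__ = ["hypergeom_overlap_test", "run_mra", "consensus_mr"]


def hypergeom_overlap_test(
    regulon_targets: set[str],
    de_set: set[str],
    universe: set[str],
    tf: str = "",
    study_id: str = "",
) -> MraRecord:
    """Upper-tail hypergeometric test of the regulon / DE-gene overlap.

    Population N = |universe|, successes K = |regulon ∩ universe|, draws
    n = |DE ∩ universe|, observed k = |regulon ∩ DE ∩ universe|; the
    p-value is P(X >= k).
    """
    if not universe:
        raise ValueError("empty universe")
    reg = set(regulon_targets) & universe
    de = set(de_set) & universe
    outside = (len(regulon_targets) - len(reg)) + (len(de_set) - len(de))
    if outside:
        log.info("dropped %d genes outside the universe", outside)
    N, K, n = len(universe), len(reg), len(de)
    k = len(reg & de)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(1.0, max(0.0, p))
    return MraRecord(
        tf=tf, study_id=study_id, regulon_size=K, de_count=n,
        overlap=k, universe_size=N, p=p,
    )


def run_mra(
    network: InferredNetwork,
    de_results: Iterable[DifferentialResult],
    alpha: float = 0.05,
) -> list[MraRecord]:
    """One hypergeometric test per TF per study, BH-adjusted within study.

    The test universe for a study is the intersection of the network's
    gene space (the reference cohort's genes) with the study's measured
    genes — the most conservative common choice.
    """
    records: list[MraRecord] = []
    net_space = set(network.universe)
    for de in de_results:
        study_genes = set(de.genes)
        universe = net_space & study_genes
        if len(universe) < 0.5 * len(net_space):
            log.warning(
                "study %s shares only %d/%d genes with the network",
                de.study_id, len(universe), len(net_space),
            )
        de_set = de_gene_set(de, alpha=alpha) & universe
        study_records = [
            hypergeom_overlap_test(
                network.regulons[tf].targets, de_set, universe, tf=tf, study_id=de.study_id
            )
            for tf in network.regulons
        ]
        adj = bh_adjust([r.p for r in study_records])
        for rec, q in zip(study_records, adj):
            records.append(replace(rec, p_adj=float(q), significant=bool(q < alpha)))
    return records


def consensus_mr(records: Sequence[MraRecord], min_studies: int = 3) -> pd.DataFrame:
    """Cross-study consensus: candidate iff significant in >= min_studies.

    Returns a frame indexed by TF with one boolean column per study, the
    significant-study count, and the candidate flag.
    """
    if min_studies < 1:
        raise ValueError("min_studies must be >= 1")
    if not records:
        return pd.DataFrame(columns=["n_significant_studies", "is_candidate"])
    flags = pd.DataFrame(
        [(r.tf, r.study_id, r.significant) for r in records],
        columns=["tf", "study_id", "significant"],
    ).pivot_table(index="tf", columns="study_id", values="significant", fill_value=False, aggfunc="any")
    flags = flags.astype(bool)
    out = flags.copy()
    out["n_significant_studies"] = flags.sum(axis=1)
    out["is_candidate"] = out["n_significant_studies"] >= min_studies
    return out
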