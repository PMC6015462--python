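"""Local connectivity-map engine for drug-repositioning scoring.

A query signature (ordered up- and down-regulated tag lists built from the
differentially expressed targets of the strongest master-regulator
candidates) is compared against every treatment instance of a compound
signature database with the Kolmogorov-Smirnov tag statistic. Instances
whose expression response opposes the disease signature score negative
(potential therapeutics); instances that reproduce it score positive
(disease mimetics). Instance scores are scaled to [-1, 1] per study,
summarized per compound with a permutation p-value, and compounds
consistently significant in the same direction across studies form the
consensus lists.
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CompoundSignatureDB,
    ConnectivityRecord,
    DifferentialResult,
    InferredNetwork,
    TagListSignature,
    TwoTailRecord,
)

log = logging.getLogger(__name__)

__all__ = [
    "build_query_signature",
    "ks_tag_score",
    "instance_connectivity",
    "scale_scores",
    "compound_summary",
    "consensus_drugs",
    "run_connectivity",
]

MAX_TAGS = 1000  # per-direction query cap, the classic web-tool input limit


def build_query_signature(
    candidates: Sequence[TwoTailRecord],
    de: DifferentialResult,
    network: InferredNetwork,
    gsea_p_cutoff: float = 0.01,
    de_alpha: float = 0.05,
    max_tags: int = MAX_TAGS,
) -> TagListSignature:
    """Query tags from the DE targets of the strongest MR candidates.

    TFs whose two-tail GSEA p-value (this study) is <= ``gsea_p_cutoff``
    qualify; the union of their regulon targets is intersected with the
    study's DE genes (BH-adjusted p < ``de_alpha``) and split by logFC
    sign into up/down tag lists ordered by |logFC| descending (capped at
    ``max_tags`` per direction).
    """
    qualifying = [r.tf for r in candidates if r.study_id == de.study_id and r.p <= gsea_p_cutoff]
    if not qualifying:
        raise ValueError(f"no query signature: no MR candidate passes p <= {gsea_p_cutoff}")
    targets: set[str] = set()
    for tf in qualifying:
        targets |= set(network.regulons[tf].targets)
    tbl = de.table
    de_genes = tbl.index[(tbl["p_adj"] < de_alpha)]
    chosen = tbl.loc[tbl.index.isin(targets & set(de_genes))]
    def by_abs_logfc(frame: pd.DataFrame) -> pd.DataFrame:
        key = frame["logFC"].abs().sort_values(ascending=False, kind="mergesort")
        return frame.reindex(key.index)

    up = by_abs_logfc(chosen[chosen["logFC"] > 0])
    down = by_abs_logfc(chosen[chosen["logFC"] < 0])
    if len(up) + len(down) == 0:
        raise ValueError("no query signature: no differentially expressed targets")
    return TagListSignature(
        up=tuple(up.index[:max_tags]), down=tuple(down.index[:max_tags])
    )


def ks_tag_score(tags: Sequence[str], instance_ranks: Mapping[str, int] | pd.Series, n: int) -> float:
    """Kolmogorov-Smirnov tag statistic of an ordered tag list vs a rank list.

    With the t tag ranks V(1) <= ... <= V(t) in the instance (rank 1 =
    most up-regulated): a = max_j [ j/t - V(j)/n ], b = max_j [ V(j)/n -
    (j-1)/t ]; the score is ``a`` if a > b else ``-b``. Positive means the
    tags crowd the top of the instance ranking.
    """
    t = len(tags)
    if t < 1:
        raise ValueError("tag list is empty")
    try:
        v = np.sort(np.array([instance_ranks[g] for g in tags], dtype=float))
    except KeyError as exc:
        raise ValueError(f"tag {exc.args[0]!r} absent from the instance universe") from exc
    j = np.arange(1, t + 1)
    a = float(np.max(j / t - v / n))
    b = float(np.max(v / n - (j - 1) / t))
    return a if a > b else -b


def instance_connectivity(query: TagListSignature, instance_ranks, n: int) -> float:
    """Raw connectivity of one instance: ks_up - ks_down, zeroed on agreement.

    When the up- and down-tag statistics share a sign the instance treats
    both halves of the signature the same way and carries no directional
    information: the raw score is 0.
    """
    ks_up = ks_tag_score(query.up, instance_ranks, n) if query.up else 0.0
    ks_down = ks_tag_score(query.down, instance_ranks, n) if query.down else 0.0
    if np.sign(ks_up) == np.sign(ks_down):
        return 0.0
    return ks_up - ks_down


def scale_scores(raw: Sequence[float]) -> np.ndarray:
    """Scale raw instance scores to [-1, 1] per study.

    Positive scores divide by the maximum positive score, negative scores
    by the magnitude of the minimum; zeros stay zero.
    """
    raw = np.asarray(raw, dtype=float)
    out = np.zeros_like(raw)
    pos = raw > 0
    neg = raw < 0
    if pos.any():
        out[pos] = raw[pos] / raw[pos].max()
    if neg.any():
        out[neg] = raw[neg] / (-raw[neg].min())
    return out


def compound_summary(
    scaled: Sequence[float],
    compounds: Sequence[str],
    study_id: str,
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> list[ConnectivityRecord]:
    """Per-compound mean scaled score with an instance-resampling p-value.

    The null draws, ``n_perm`` times, a random instance subset of the same
    size from all of the study's instances and compares |mean|; the
    two-sided p is ``(1 + #{|null mean| >= |observed mean|}) / (1 + n_perm)``.
    """
    scaled = np.asarray(scaled, dtype=float)
    compounds = np.asarray(compounds)
    rng = np.random.default_rng(seed)
    n_inst = len(scaled)
    out: list[ConnectivityRecord] = []

    def null_means(size: int) -> np.ndarray:
        # independent per-compound nulls keep the p-values exchangeable;
        # subsets are drawn without replacement within each draw
        if size * size <= n_inst:
            take = rng.integers(0, n_inst, (n_perm, size))
            bad = np.nonzero((np.sort(take, axis=1)[:, 1:] == np.sort(take, axis=1)[:, :-1]).any(axis=1))[0] if size > 1 else np.array([], dtype=int)
            while bad.size:
                take[bad] = rng.integers(0, n_inst, (bad.size, size))
                srt = np.sort(take[bad], axis=1)
                bad = bad[(srt[:, 1:] == srt[:, :-1]).any(axis=1)]
        else:
            keys = rng.random((n_perm, n_inst))
            take = np.argpartition(keys, size - 1, axis=1)[:, :size]
        return scaled[take].mean(axis=1)

    for compound in sorted(set(compounds)):
        mask = compounds == compound
        mean = float(scaled[mask].mean())
        size = int(mask.sum())
        p = float((1 + np.sum(np.abs(null_means(size)) >= abs(mean))) / (1 + n_perm))
        if p <= alpha and mean < 0:
            direction = "negative"
        elif p <= alpha and mean > 0:
            direction = "positive"
        else:
            direction = "ns"
        out.append(
            ConnectivityRecord(
                compound=compound, study_id=study_id, n_instances=size,
                mean_score=mean, p=p, direction=direction,
            )
        )
    return out


def consensus_drugs(
    records: Sequence[ConnectivityRecord],
    p_cutoff: float = 0.05,
    min_studies: int = 2,
) -> tuple[list[str], list[str]]:
    """Cross-study consensus: (therapeutic, mimetic) compound lists.

    A compound is consensus when it is significant (p <= p_cutoff) with
    the same sign in >= min_studies studies; compounds significant in
    opposite directions across studies are excluded (and logged).
    Negative consensus = therapeutic potential, positive = disease mimetic.
    """
    by_compound: dict[str, dict[str, int]] = {}
    for r in records:
        tally = by_compound.setdefault(r.compound, {"negative": 0, "positive": 0})
        if r.p <= p_cutoff and r.mean_score < 0:
            tally["negative"] += 1
        elif r.p <= p_cutoff and r.mean_score > 0:
            tally["positive"] += 1
    therapeutic, mimetic = [], []
    for compound in sorted(by_compound):
        tally = by_compound[compound]
        if tally["negative"] and tally["positive"]:
            log.warning("compound %s significant in opposite directions; excluded", compound)
            continue
        if tally["negative"] >= min_studies:
            therapeutic.append(compound)
        elif tally["positive"] >= min_studies:
            mimetic.append(compound)
    return therapeutic, mimetic


def run_connectivity(
    gsea_records: Sequence[TwoTailRecord],
    de_results: Iterable[DifferentialResult],
    network: InferredNetwork,
    db: CompoundSignatureDB,
    gsea_p_cutoff: float = 0.01,
    de_alpha: float = 0.05,
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> list[ConnectivityRecord]:
    """Score the signature database against every study's query signature."""
    ss = np.random.SeedSequence(seed)
    de_list = list(de_results)
    records: list[ConnectivityRecord] = []
    n = db.n_genes
    for de, study_ss in zip(de_list, ss.spawn(len(de_list))):
        try:
            query = build_query_signature(gsea_records, de, network, gsea_p_cutoff, de_alpha)
        except ValueError as exc:
            log.warning("study %s skipped: %s", de.study_id, exc)
            continue
        raw = [
            instance_connectivity(query, db.rank_of[inst], n)
            for inst in db.meta["instance_id"]
        ]
        scaled = scale_scores(raw)
        study_seed = int(study_ss.generate_state(1)[0] % (2**31 - 1))
        records.extend(
            compound_summary(
                scaled, db.meta["compound"].to_numpy(), de.study_id,
                n_perm=n_perm, alpha=alpha, seed=study_seed,
            )
        )
    return records
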