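"""Core value types shared by every pipeline stage.

The in-memory lingua franca of the package is a pandas DataFrame of shape
(genes x samples) for expression data; the dataclasses below wrap the
smaller structured objects (regulons, signatures, result records) and
enforce their invariants at construction time.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "validate_expression",
    "validate_phenotype",
    "TagListSignature",
    "SignedRegulon",
    "InferredNetwork",
    "EdgeCandidate",
    "DifferentialResult",
    "CompoundSignatureDB",
    "MraRecord",
    "TwoTailRecord",
    "ConnectivityRecord",
]

CASE = "case"
CONTROL = "control"


def validate_expression(expr: pd.DataFrame, *, min_samples: int = 3) -> pd.DataFrame:
    """Check an expression matrix (genes x samples) and return it unchanged.

    Raises ``ValueError`` on duplicate gene/sample identifiers, missing
    values, or fewer than ``min_samples`` columns.
    """
    if expr.index.duplicated().any():
        dup = expr.index[expr.index.duplicated()][0]
        raise ValueError(f"duplicate gene identifier: {dup!r}")
    if expr.columns.duplicated().any():
        dup = expr.columns[expr.columns.duplicated()][0]
        raise ValueError(f"duplicate sample identifier: {dup!r}")
    if expr.shape[1] < min_samples:
        raise ValueError(
            f"expression matrix needs >= {min_samples} samples, got {expr.shape[1]}"
        )
    if expr.isna().any().any():
        gene = expr.index[expr.isna().any(axis=1)][0]
        raise ValueError(f"missing values in expression matrix (first at gene {gene!r})")
    if not np.issubdtype(np.asarray(expr.values).dtype, np.number):
        raise ValueError("expression matrix contains non-numeric values")
    return expr


def validate_phenotype(pheno: pd.Series, expr: pd.DataFrame | None = None) -> pd.Series:
    """Check a sample -> {case, control} mapping against an expression matrix."""
    bad = set(pheno.unique()) - {CASE, CONTROL}
    if bad:
        raise ValueError(f"phenotype labels must be 'case'/'control', got {sorted(bad)}")
    for grp in (CASE, CONTROL):
        if (pheno == grp).sum() == 0:
            raise ValueError(f"phenotype table has no {grp!r} samples")
    if expr is not None:
        missing = set(pheno.index) - set(expr.columns)
        if missing:
            raise ValueError(f"phenotype samples absent from expression matrix: {sorted(missing)[:3]}")
    return pheno


@dataclass(frozen=True)
class TagListSignature:
    """Ordered up-/down-regulated gene tags forming a connectivity-map query."""

    up: tuple[str, ...]
    down: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValueError(f"up and down tags overlap: {sorted(overlap)[:3]}")
        if len(self.up) + len(self.down) < 2:
            raise ValueError("signature needs at least 2 tags in total")


@dataclass(frozen=True)
class SignedRegulon:
    """One TF's targets split by mode of action, with MI weights.

    ``positive``/``negative`` map target gene id -> mutual information (nats).
    """

    tf: str
    positive: Mapping[str, float] = field(default_factory=dict)
    negative: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.positive) & set(self.negative)
        if overlap:
            raise ValueError(f"regulon {self.tf}: targets in both modes: {sorted(overlap)[:3]}")

    @property
    def size(self) -> int:
        return len(self.positive) + len(self.negative)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(self.positive) | frozenset(self.negative)

    def mode_of(self, target: str) -> int:
        if target in self.positive:
            return 1
        if target in self.negative:
            return -1
        raise KeyError(target)


@dataclass(frozen=True)
class EdgeCandidate:
    """A TF -> target edge candidate during network inference."""

    tf: str
    target: str
    mi: float
    bootstrap_support: float | None = None
    mode: int = 0  # +1 / -1 once assigned, 0 while unset

    def __post_init__(self) -> None:
        if self.mi < 0:
            raise ValueError("mutual information must be nonnegative")
        if self.tf == self.target:
            raise ValueError(f"self edge on {self.tf}")


@dataclass(frozen=True)
class InferredNetwork:
    """TF-centered signed network plus the parameters that produced it."""

    regulons: Mapping[str, SignedRegulon]
    universe: tuple[str, ...]
    provenance: Mapping[str, object] = field(default_factory=dict)

    @property
    def tfs(self) -> tuple[str, ...]:
        return tuple(self.regulons)

    def sizes(self) -> dict[str, int]:
        return {tf: r.size for tf, r in self.regulons.items()}


@dataclass(frozen=True)
class DifferentialResult:
    """Per-gene two-group differential expression for one study.

    ``table`` is indexed by gene id with columns logFC, t, p, p_adj.
    """

    table: pd.DataFrame
    study_id: str

    def __post_init__(self) -> None:
        required = {"logFC", "t", "p", "p_adj"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"differential table missing columns {sorted(missing)}")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate genes in differential table")

    @property
    def genes(self) -> pd.Index:
        return self.table.index


@dataclass(frozen=True)
class CompoundSignatureDB:
    """Rank-ordered compound treatment signatures over a shared gene universe.

    ``meta`` holds one row per instance (instance_id, compound, cell_line);
    ``rank_of`` is a (genes x instances) frame of ranks, 1 = most up-regulated
    under the treatment. Gene order is canonicalized (sorted) so two databases
    with the same content compare equal regardless of input column order.
    """

    meta: pd.DataFrame
    rank_of: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.rank_of.index)
        expected = np.arange(1, n + 1)
        for inst in self.rank_of.columns:
            ranks = np.sort(self.rank_of[inst].to_numpy())
            if not np.array_equal(ranks, expected):
                raise ValueError(f"instance {inst!r}: rank list is not a permutation of the universe")
        if not self.meta["instance_id"].is_unique:
            raise ValueError("duplicate instance ids")
        if set(self.meta["instance_id"]) != set(self.rank_of.columns):
            raise ValueError("meta and rank table disagree on instances")

    @property
    def universe(self) -> tuple[str, ...]:
        return tuple(self.rank_of.index)

    @property
    def n_genes(self) -> int:
        return len(self.rank_of.index)

    @property
    def n_instances(self) -> int:
        return len(self.meta)

    def instances_of(self, compound: str) -> list[str]:
        return list(self.meta.loc[self.meta["compound"] == compound, "instance_id"])


@dataclass(frozen=True)
class MraRecord:
    """One TF x one study hypergeometric overlap test."""

    tf: str
    study_id: str
    regulon_size: int      # K: regulon targets inside the universe
    de_count: int          # n: DE genes inside the universe
    overlap: int           # k
    universe_size: int     # N
    p: float
    p_adj: float = float("nan")
    significant: bool = False

    def __post_init__(self) -> None:
        if self.overlap > min(self.regulon_size, self.de_count):
            raise ValueError("overlap exceeds marginals")
        if max(self.regulon_size, self.de_count) > self.universe_size:
            raise ValueError("marginals exceed universe")


@dataclass(frozen=True)
class TwoTailRecord:
    """Two-tail GSEA result for one TF in one study."""

    tf: str
    study_id: str
    es_pos: float   # enrichment of positive-mode targets
    es_neg: float   # enrichment of negative-mode targets
    des: float      # es_pos - es_neg
    p: float
    p_adj: float = float("nan")
    state: str = "ns"  # activated / repressed / ns

    def __post_init__(self) -> None:
        if abs(self.des - (self.es_pos - self.es_neg)) > 1e-12:
            raise ValueError("dES must equal es_pos - es_neg")


@dataclass(frozen=True)
class ConnectivityRecord:
    """Connectivity summary for one compound in one study."""

    compound: str
    study_id: str
    n_instances: int
    mean_score: float
    p: float
    direction: str = "ns"  # negative / positive / ns


def replace(obj, **changes):
    """dataclasses.replace passthrough (kept for a stable public name)."""
    return dataclasses.replace(obj, **changes)


def as_frame(records: Iterable) -> pd.DataFrame:
    """Flatten an iterable of result dataclasses into a DataFrame."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records])
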