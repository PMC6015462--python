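"""Synthetic ground-truth networks, expression cohorts and drug databases.

The generator plants a signed TF -> target network and drives expression
through a linear-Gaussian model: per sample, each TF has a latent activity
``a ~ N(0, 1)``; the TF's own expression is a noisy readout ``a + sigma*eps``;
each target's expression is ``sum_t beta * mode(t, g) * a_t + sigma*eps``
over the TFs regulating it, and unregulated genes are pure noise. Disease
cohorts shift the latent activity of selected TFs by ``+delta`` (activated)
or ``-delta`` (repressed), so a repressed TF's positive-mode targets drop
and its negative-mode targets rise — exactly the consequence the master
regulator and two-tail enrichment stages are built to detect.

Compound signature databases are generated against a planted disease
signature: "therapeutic" drugs produce rank lists that reverse the
signature (disease-up genes near the bottom), "mimetic" drugs reproduce
it, and "neutral" drugs are uniformly random permutations.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import (
    CASE,
    CONTROL,
    CompoundSignatureDB,
    TagListSignature,
    validate_expression,
)

__all__ = [
    "GroundTruthNetwork",
    "SimulationConfig",
    "SyntheticStudy",
    "simulate_network",
    "simulate_reference_cohort",
    "simulate_case_control",
    "expected_logfc",
    "planted_signature",
    "simulate_signature_db",
    "reference_scenario",
]

ACTIVATED = "activated"
REPRESSED = "repressed"


@dataclass(frozen=True)
class GroundTruthNetwork:
    """Planted signed regulatory network.

    ``targets`` maps TF -> {target gene -> (mode, beta)} with mode in {+1, -1}.
    """

    tf_ids: tuple[str, ...]
    targets: Mapping[str, Mapping[str, tuple[int, float]]]
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        for tf, tgts in self.targets.items():
            if len(tgts) == 0:
                raise ValueError(f"TF {tf} has no targets")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def mode_of(self, tf: str, target: str) -> int:
        return self.targets[tf][target][0]

    def regulon_targets(self, tf: str) -> frozenset[str]:
        return frozenset(self.targets[tf])


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the reference-scenario defaults.

    The default scenario: 10 TFs among 500 genes, 30 targets each with
    effect size beta=1 and residual noise sigma=0.25; a 200-sample reference
    cohort; four 50 vs 50 case-control studies in which two TFs are
    activated and two repressed with activity shift delta=2; a drug
    database of 3 therapeutic, 3 mimetic and 44 neutral compounds.
    """

    n_tf: int = 10
    n_genes: int = 500
    targets_per_tf: int = 30
    beta: float = 1.0
    sigma_noise: float = 0.25
    mode_pos_prob: float = 0.7
    n_ref: int = 200
    n_case: int = 50
    n_control: int = 50
    n_studies: int = 4
    perturbed_mrs: Mapping[str, str] = field(
        default_factory=lambda: {
            "TF01": ACTIVATED,
            "TF02": ACTIVATED,
            "TF03": REPRESSED,
            "TF04": REPRESSED,
        }
    )
    delta: float = 2.0
    n_instances_per_drug: int = 5
    drug_truth: Mapping[str, str] = field(
        default_factory=lambda: {
            **{f"thx_{i:02d}": "therapeutic" for i in range(1, 4)},
            **{f"mim_{i:02d}": "mimetic" for i in range(1, 4)},
            **{f"ntr_{i:02d}": "neutral" for i in range(1, 45)},
        }
    )
    drug_rank_noise: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_tf, self.n_genes, self.targets_per_tf,
            self.n_ref, self.n_case, self.n_control, self.n_studies,
            self.n_instances_per_drug,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.delta <= 0:
            raise ValueError("activity shift delta must be > 0")
        if not 0.0 <= self.mode_pos_prob <= 1.0:
            raise ValueError("mode_pos_prob must be in [0, 1]")

    def gene_names(self) -> tuple[str, ...]:
        tfs = tuple(f"TF{i:02d}" for i in range(1, self.n_tf + 1))
        others = tuple(f"G{i:04d}" for i in range(1, self.n_genes - self.n_tf + 1))
        return tfs + others


@dataclass(frozen=True)
class SyntheticStudy:
    """One simulated case-control study plus its generating truth."""

    expression: pd.DataFrame
    phenotype: pd.Series
    truth: GroundTruthNetwork
    perturbed_mrs: Mapping[str, str]
    study_id: str = "synthetic"

    def __post_init__(self) -> None:
        if set(self.phenotype.index) != set(self.expression.columns):
            raise ValueError("phenotype must cover exactly the study samples")


def simulate_network(config: SimulationConfig) -> GroundTruthNetwork:
    """Plant a signed TF -> target network (deterministic under config.seed)."""
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    tfs = genes[: config.n_tf]
    pool = np.array(genes[config.n_tf:])
    if config.targets_per_tf > len(pool):
        raise ValueError(
            f"targets_per_tf={config.targets_per_tf} exceeds the {len(pool)} available non-TF genes"
        )
    bad = set(config.perturbed_mrs) - set(tfs)
    if bad:
        raise ValueError(f"perturbed TFs absent from the network: {sorted(bad)}")
    targets: dict[str, dict[str, tuple[int, float]]] = {}
    for tf in tfs:
        chosen = rng.choice(pool, size=config.targets_per_tf, replace=False)
        modes = np.where(rng.random(config.targets_per_tf) < config.mode_pos_prob, 1, -1)
        targets[tf] = {g: (int(m), config.beta) for g, m in zip(chosen, modes)}
    return GroundTruthNetwork(tf_ids=tfs, targets=targets, gene_ids=genes)


def _draw_cohort(
    truth: GroundTruthNetwork,
    n: int,
    sigma: float,
    rng: np.random.Generator,
    shift: Mapping[str, float] | None = None,
    sample_prefix: str = "S",
) -> pd.DataFrame:
    genes = list(truth.gene_ids)
    gidx = {g: i for i, g in enumerate(genes)}
    activity = rng.standard_normal((len(truth.tf_ids), n))
    if shift:
        for tf, d in shift.items():
            activity[list(truth.tf_ids).index(tf)] += d
    x = sigma * rng.standard_normal((len(genes), n))
    for t, tf in enumerate(truth.tf_ids):
        x[gidx[tf]] += activity[t]
        for g, (mode, beta) in truth.targets[tf].items():
            x[gidx[g]] += beta * mode * activity[t]
    samples = [f"{sample_prefix}{i:03d}" for i in range(1, n + 1)]
    return pd.DataFrame(x, index=pd.Index(genes, name="gene_id"), columns=samples)


def simulate_reference_cohort(
    truth: GroundTruthNetwork,
    n_ref: int,
    sigma_noise: float,
    seed: int,
) -> pd.DataFrame:
    """Healthy reference cohort under the linear-Gaussian model."""
    if n_ref < 10:
        raise ValueError("reference cohort needs n_ref >= 10")
    rng = np.random.default_rng(seed)
    expr = _draw_cohort(truth, n_ref, sigma_noise, rng, sample_prefix="REF")
    return validate_expression(expr)


def simulate_case_control(
    truth: GroundTruthNetwork,
    perturbed_mrs: Mapping[str, str],
    delta: float,
    n_case: int,
    n_control: int,
    sigma_noise: float,
    seed: int,
    study_id: str = "synthetic",
) -> SyntheticStudy:
    """Case-control study: cases shift perturbed TF activities by +/- delta."""
    if not perturbed_mrs:
        raise ValueError("perturbed_mrs must be non-empty")
    bad = set(perturbed_mrs) - set(truth.tf_ids)
    if bad:
        raise ValueError(f"perturbed TFs absent from truth: {sorted(bad)}")
    for tf, direction in perturbed_mrs.items():
        if direction not in (ACTIVATED, REPRESSED):
            raise ValueError(f"direction for {tf} must be activated/repressed, got {direction!r}")
    rng = np.random.default_rng(seed)
    shift = {tf: (delta if d == ACTIVATED else -delta) for tf, d in perturbed_mrs.items()}
    controls = _draw_cohort(truth, n_control, sigma_noise, rng, sample_prefix="CTL")
    cases = _draw_cohort(truth, n_case, sigma_noise, rng, shift=shift, sample_prefix="CASE")
    expr = pd.concat([cases, controls], axis=1)
    pheno = pd.Series(
        [CASE] * n_case + [CONTROL] * n_control,
        index=expr.columns, name="group",
    )
    pheno.index.name = "sample_id"
    validate_expression(expr)
    return SyntheticStudy(
        expression=expr, phenotype=pheno, truth=truth,
        perturbed_mrs=dict(perturbed_mrs), study_id=study_id,
    )


def expected_logfc(truth: GroundTruthNetwork, perturbed_mrs: Mapping[str, str], delta: float) -> pd.Series:
    """Closed-form expected case-minus-control logFC per gene.

    A gene regulated by perturbed TFs accumulates ``beta * mode * (+/-)delta``
    per regulator; a perturbed TF's own expression shifts by ``+/-delta``.
    """
    lfc = pd.Series(0.0, index=pd.Index(truth.gene_ids, name="gene_id"))
    for tf, direction in perturbed_mrs.items():
        sign = 1.0 if direction == ACTIVATED else -1.0
        lfc[tf] += sign * delta
        for g, (mode, beta) in truth.targets[tf].items():
            lfc[g] += sign * delta * beta * mode
    return lfc


def planted_signature(
    truth: GroundTruthNetwork, perturbed_mrs: Mapping[str, str], delta: float
) -> TagListSignature:
    """Disease signature implied by the planted perturbation (by |logFC| desc)."""
    lfc = expected_logfc(truth, perturbed_mrs, delta)
    up = lfc[lfc > 0].sort_values(ascending=False, kind="mergesort")
    down = lfc[lfc < 0].sort_values(kind="mergesort")
    return TagListSignature(up=tuple(up.index), down=tuple(down.index))


def simulate_signature_db(
    disease_signature: TagListSignature,
    drug_truth: Mapping[str, str],
    n_instances_per_drug: int,
    noise: float,
    seed: int,
    universe: tuple[str, ...],
) -> CompoundSignatureDB:
    """Generate per-instance rank lists against a planted disease signature.

    Each tagged gene carries a graded signal (a linear ramp down the tag
    list); a therapeutic instance scores genes as ``-signal + noise*eps``
    (reversal), a mimetic one as ``+signal + noise*eps``, and neutral
    instances are uniformly random permutations. Rank 1 = highest score.
    """
    if len(disease_signature.up) + len(disease_signature.down) == 0:
        raise ValueError("disease signature is empty")
    rng = np.random.default_rng(seed)
    genes = np.asarray(universe)
    gidx = {g: i for i, g in enumerate(genes)}
    signal = np.zeros(len(genes))
    n_up = len(disease_signature.up)
    for i, g in enumerate(disease_signature.up):
        signal[gidx[g]] = (n_up - i) / n_up
    n_dn = len(disease_signature.down)
    for i, g in enumerate(disease_signature.down):
        signal[gidx[g]] = -(n_dn - i) / n_dn

    cell_lines = ("MCF7", "PC3", "HL60")
    meta_rows = []
    ranks: dict[str, np.ndarray] = {}
    k = 0
    for compound, kind in drug_truth.items():
        if kind not in ("therapeutic", "mimetic", "neutral"):
            raise ValueError(f"unknown drug class {kind!r} for {compound}")
        for j in range(n_instances_per_drug):
            inst = f"{compound}.{j + 1}"
            if kind == "neutral":
                order = rng.permutation(len(genes))
                rank = np.empty(len(genes), dtype=np.int64)
                rank[order] = np.arange(1, len(genes) + 1)
            else:
                sgn = -1.0 if kind == "therapeutic" else 1.0
                score = sgn * signal + noise * rng.standard_normal(len(genes))
                # infinitesimal jitter keeps untagged ties random yet seeded
                score += 1e-9 * rng.random(len(genes))
                order = np.argsort(-score, kind="mergesort")
                rank = np.empty(len(genes), dtype=np.int64)
                rank[order] = np.arange(1, len(genes) + 1)
            meta_rows.append((inst, compound, cell_lines[k % len(cell_lines)]))
            ranks[inst] = rank
            k += 1
    meta = pd.DataFrame(meta_rows, columns=["instance_id", "compound", "cell_line"])
    uni_sorted = sorted(genes)
    reorder = [gidx[g] for g in uni_sorted]
    rank_of = pd.DataFrame({i: r[reorder] for i, r in ranks.items()}, index=pd.Index(uni_sorted))
    return CompoundSignatureDB(meta=meta, rank_of=rank_of)


def reference_scenario(seed: int, config: SimulationConfig | None = None):
    """Build the full default scenario: truth, reference cohort, studies, drug DB.

    Returns ``(config, truth, reference_expr, studies, signature_db)`` where
    ``studies`` is a list of SyntheticStudy. All randomness derives from
    ``seed`` via independent spawned streams, so the scenario is fully
    reproducible and the stages are decoupled.
    """
    config = replace(config or SimulationConfig(), seed=seed)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(config.n_studies + 3)]
    truth = simulate_network(replace(config, seed=seeds[0]))
    reference = simulate_reference_cohort(truth, config.n_ref, config.sigma_noise, seeds[1])
    studies = [
        simulate_case_control(
            truth, config.perturbed_mrs, config.delta,
            config.n_case, config.n_control, config.sigma_noise,
            seeds[2 + i], study_id=f"study_{i + 1}",
        )
        for i in range(config.n_studies)
    ]
    signature = planted_signature(truth, config.perturbed_mrs, config.delta)
    db = simulate_signature_db(
        signature, config.drug_truth, config.n_instances_per_drug,
        config.drug_rank_noise, seeds[config.n_studies + 2], tuple(truth.gene_ids),
    )
    return config, truth, reference, studies, db
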