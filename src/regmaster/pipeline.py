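"""End-to-end orchestration: simulate -> infer -> DE -> MRA -> GSEA -> drugs.

A single YAML-serializable config drives every stage; one global seed
deterministically derives independent per-stage seeds, so a rerun with
the same config reproduces every artifact byte for byte. Each run writes
a manifest of output files with SHA-256 content hashes.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import connectivity as cmap
from . import io as rio
from . import mra as mra_mod
from . import simulate as sim
from .datatypes import as_frame
from .diffexp import moderated_t_test
from .gsea2 import run_two_tail_gsea
from .network import filter_regulons, infer_network
from .report import build_mr_subnetwork

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters for every stage of the synthetic end-to-end run."""

    outdir: str = "regmaster_run"
    seed: int = 0
    simulation: Mapping[str, object] = field(default_factory=dict)
    # network inference
    n_perm: int = 1000
    p_cutoff: float = 0.001
    n_boot: int = 100
    consensus: float = 0.95
    dpi_tolerance: float = 0.0
    mra_min_targets: int = 100
    # downstream thresholds
    de_alpha: float = 0.05
    mra_alpha: float = 0.05
    min_studies: int = 3
    gsea_n_perm: int = 1000
    gsea_alpha: float = 0.05
    gsea_exponent: float = 1.0
    # connectivity
    run_cmap: bool = True
    cmap_gsea_p_cutoff: float = 0.01
    cmap_n_perm: int = 10000
    cmap_p_cutoff: float = 0.05
    cmap_min_studies: int = 2


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def _write_frame(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n", float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order; return the artifact manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=True))
    seeds = _stage_seeds(config.seed, 4)

    # --- simulate -------------------------------------------------------
    sim_cfg = sim.SimulationConfig(**dict(config.simulation))
    sim_cfg, truth, reference, studies, db = sim.reference_scenario(seeds[0], sim_cfg)
    rio.write_expression_matrix(reference, outdir / "reference_expr.tsv")
    for study in studies:
        rio.write_expression_matrix(study.expression, outdir / f"{study.study_id}_expr.tsv")
        rio.write_phenotype_table(study.phenotype, outdir / f"{study.study_id}_pheno.tsv")
    rio.write_signature_db(db, outdir / "signature_db.tsv")
    truth_json = {
        "tfs": list(truth.tf_ids),
        "targets": {tf: {g: [m, b] for g, (m, b) in truth.targets[tf].items()} for tf in truth.tf_ids},
        "perturbed_mrs": dict(sim_cfg.perturbed_mrs),
        "drug_truth": dict(sim_cfg.drug_truth),
    }
    (outdir / "truth.json").write_text(json.dumps(truth_json, indent=1, sort_keys=True) + "\n")

    # --- network inference ----------------------------------------------
    network = infer_network(
        reference, list(truth.tf_ids),
        n_perm=config.n_perm, p_cutoff=config.p_cutoff,
        n_boot=config.n_boot, consensus=config.consensus,
        dpi_tolerance=config.dpi_tolerance, seed=seeds[1],
    )
    mra_network = filter_regulons(network, config.mra_min_targets, inclusive=True)
    rio.write_regulon_gmt(dict(network.regulons), outdir / "network.gmt")
    if not mra_network.regulons:
        raise RuntimeError(
            f"no regulon reaches the analysis tier of {config.mra_min_targets} targets"
        )

    # --- differential expression ----------------------------------------
    de_results = []
    for study in studies:
        de = moderated_t_test(study.expression, study.phenotype, study_id=study.study_id)
        _write_frame(de.table.rename_axis("gene"), outdir / f"{study.study_id}_de.tsv")
        de_results.append(de)

    # --- MRA -------------------------------------------------------------
    mra_records = mra_mod.run_mra(mra_network, de_results, alpha=config.mra_alpha)
    _write_frame(as_frame(mra_records), outdir / "mra.tsv", index=False)
    candidates = mra_mod.consensus_mr(mra_records, min_studies=config.min_studies)
    _write_frame(candidates.rename_axis("tf"), outdir / "mr_candidates.tsv")
    candidate_tfs = list(candidates.index[candidates["is_candidate"]])

    # --- two-tail GSEA ----------------------------------------------------
    gsea_records = run_two_tail_gsea(
        mra_network, de_results, tfs=candidate_tfs or None,
        n_perm=config.gsea_n_perm, exponent=config.gsea_exponent,
        alpha=config.gsea_alpha, seed=seeds[2],
    ) if candidate_tfs else []
    _write_frame(as_frame(gsea_records), outdir / "gsea2.tsv", index=False)

    # consensus state per TF: the majority significant call across studies
    states: dict[str, str] = {}
    for tf in candidate_tfs:
        calls = [r.state for r in gsea_records if r.tf == tf and r.state != "ns"]
        if calls:
            states[tf] = max(sorted(set(calls)), key=calls.count)

    # --- connectivity map -------------------------------------------------
    therapeutic: list[str] = []
    mimetic: list[str] = []
    if config.run_cmap:
        if db.n_instances == 0:
            raise RuntimeError("connectivity stage enabled but the signature DB is empty")
        cmap_records = cmap.run_connectivity(
            gsea_records, de_results, mra_network, db,
            gsea_p_cutoff=config.cmap_gsea_p_cutoff, de_alpha=config.de_alpha,
            n_perm=config.cmap_n_perm, alpha=config.cmap_p_cutoff, seed=seeds[3],
        )
        _write_frame(as_frame(cmap_records), outdir / "connectivity.tsv", index=False)
        therapeutic, mimetic = cmap.consensus_drugs(
            cmap_records, p_cutoff=config.cmap_p_cutoff, min_studies=config.cmap_min_studies
        )
        (outdir / "consensus_drugs.json").write_text(
            json.dumps({"therapeutic": therapeutic, "mimetic": mimetic}, indent=1) + "\n"
        )

    # --- report -----------------------------------------------------------
    state_tfs = {tf: s for tf, s in states.items()}
    if len(state_tfs) >= 2:
        sub = build_mr_subnetwork(
            {tf: mra_network.regulons[tf] for tf in state_tfs}, state_tfs
        )
        _write_frame(sub.nodes, outdir / "subnetwork_nodes.tsv")
        _write_frame(sub.edges, outdir / "subnetwork_edges.tsv", index=False)
        degree_stats = {"mean_degree": sub.mean_degree, "sd_degree": sub.sd_degree}
    else:
        degree_stats = {"mean_degree": None, "sd_degree": None}
    summary = {
        "n_tfs": len(truth.tf_ids),
        "n_regulons_inferred": len(network.regulons),
        "n_regulons_analysis_tier": len(mra_network.regulons),
        "n_mr_candidates": len(candidate_tfs),
        "n_state_significant": len(state_tfs),
        "states": state_tfs,
        "n_therapeutic": len(therapeutic),
        "n_mimetic": len(mimetic),
        **degree_stats,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")

    manifest = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
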