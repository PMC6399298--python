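"""End-to-end desk-scale experiments: simulate, scan, featurize, train, call, evaluate.

The reference experiment recovers planted somatic mutations from a
simulated 200 kb tumor/normal pair (50x each, pure tumor, 300 somatic
SNVs + 100 INDELs at target AF >= 0.25).  Genomic regions are split
50/50 into train/test; the network trains on candidates from the training
regions only and is evaluated on the held-out regions (SNVs matched on
position + allele; INDELs in position-only mode).  A companion run
regenerates the tumor at 25% purity with the same truth to measure the
recall cost of purity dilution.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np

from . import bench, call as call_mod
from .featurize import MatrixDataset, featurize_candidates
from .network import NetConfig, SomaticNet
from .scan import FilterConfig, filter_candidates, scan_region
from .simulate import SimConfig, SimOutput, resimulate_tumor, simulate
from .train import (LabeledDataset, TrainConfig, fit, in_regions, label_candidates,
                    split_regions)
from .variants import DEL, INS, SNV


@dataclass
class PipelineResult:
    sim: SimOutput
    candidates: list
    dataset: MatrixDataset
    labeled: LabeledDataset
    model: SomaticNet
    metrics: list
    calls: list
    summary: dict


def candidate_recall(candidates, truth_somatic, min_af: float = 0.0) -> float:
    """Fraction of somatic truth sites (target AF >= min_af) present among
    the filtered candidates, matched on position + type."""
    keys = {(c.chrom, c.pos, c.kind) for c in candidates}
    eligible = [v for v in truth_somatic if v.target_af >= min_af]
    if not eligible:
        return float("nan")
    hit = sum(1 for v in eligible if (v.chrom, v.pos, v.kind) in keys)
    return hit / len(eligible)


def scan_and_featurize(tumor_bam: str, normal_bam: str, reference_fasta: str,
                       preset: str = "wgs") -> tuple[list, MatrixDataset]:
    stats = scan_region(tumor_bam, reference_fasta)
    candidates = filter_candidates(stats, FilterConfig.preset(preset))
    dataset = featurize_candidates(candidates, tumor_bam, normal_bam, reference_fasta)
    return candidates, dataset


def _evaluate_split(calls, truth_somatic, regions) -> dict:
    cfg_exact = bench.EvalConfig(regions=tuple(regions))
    cfg_pos = bench.EvalConfig(indel_match_mode="position_only", regions=tuple(regions))
    out = {}
    snv_calls = [c for c in calls if c.kind == SNV]
    indel_calls = [c for c in calls if c.kind in (INS, DEL)]
    snv_truth = [t for t in truth_somatic if t.kind == SNV]
    indel_truth = [t for t in truth_somatic if t.kind in (INS, DEL)]
    _, best_snv = bench.pr_curve(snv_calls, snv_truth, cfg_exact)
    _, best_indel = bench.pr_curve(indel_calls, indel_truth, cfg_pos)
    _, best_indel_exact = bench.pr_curve(indel_calls, indel_truth, cfg_exact)
    out["snv"] = best_snv
    out["indel"] = best_indel
    out["indel_exact"] = best_indel_exact
    return out


def run_recovery_experiment(outdir: str, seed: int = 1,
                            sim_config: SimConfig | None = None,
                            epochs: int = 100,
                            include_purity_arm: bool = True) -> PipelineResult:
    """The package's reference experiment; see module docstring."""
    os.makedirs(outdir, exist_ok=True)
    cfg = sim_config or SimConfig()
    cfg = replace(cfg, seed=seed % (2 ** 28))
    sim = simulate(cfg, outdir)
    candidates, dataset = scan_and_featurize(sim.tumor_bam, sim.normal_bam,
                                             sim.reference_fasta)
    labeled = label_candidates(dataset, sim.truth)

    train_regions, test_regions = split_regions(cfg.ref_length, chunk=10_000,
                                                seed=cfg.seed + 101)
    pos = np.array([c.pos for c in dataset.candidates])
    train_idx = np.array([i for i, p in enumerate(pos) if in_regions(p, train_regions)],
                         dtype=np.int64)
    test_idx = np.array([i for i, p in enumerate(pos) if in_regions(p, test_regions)],
                        dtype=np.int64)
    train_set = labeled.subset(train_idx)
    test_set = labeled.subset(test_idx)

    model = SomaticNet(NetConfig(in_channels=len(dataset.registry)),
                       seed=cfg.seed + 7, registry_hash=dataset.registry.hash)
    # small batches: at desk scale each epoch must still provide several
    # optimizer steps for SGD to converge within the epoch budget
    tc = TrainConfig(epochs=epochs, seed=cfg.seed + 23, batch_size=32)
    result = fit(model, train_set, tc)

    predictions = call_mod.predict(model, test_set.data)
    calls = call_mod.make_calls(predictions, test_set.data, sim.tumor_bam,
                                sim.reference_fasta, preset="wgs")
    test_truth = [v for v in sim.truth.somatic if in_regions(v.pos, test_regions)]
    evals = _evaluate_split(calls, test_truth, test_regions)

    summary = {
        "n_candidates": len(candidates),
        "n_train": int(train_idx.size),
        "n_test": int(test_idx.size),
        "n_truth_test_snv": sum(1 for t in test_truth if t.kind == SNV),
        "n_truth_test_indel": sum(1 for t in test_truth if t.kind != SNV),
        "snv_best_f1": evals["snv"].f1,
        "snv_precision": evals["snv"].precision,
        "snv_recall": evals["snv"].recall,
        "indel_best_f1": evals["indel"].f1,
        "indel_precision": evals["indel"].precision,
        "indel_recall": evals["indel"].recall,
        "indel_exact_best_f1": evals["indel_exact"].f1,
        "candidate_recall_af20": candidate_recall(candidates, sim.truth.somatic, 0.2),
        "final_train_loss": result.metrics[-1]["loss"],
        "recall_purity_100": evals["snv"].recall,  # refined below to all-kinds
    }
    pairs, _, _ = bench.match_calls(
        calls, test_truth, bench.EvalConfig(indel_match_mode="position_only",
                                            regions=tuple(test_regions)))
    summary["recall_purity_100"] = len(pairs) / max(len(test_truth), 1)

    if include_purity_arm:
        low_bam = resimulate_tumor(sim, tumor_purity=0.25)
        low_cands, low_ds = scan_and_featurize(low_bam, sim.normal_bam,
                                               sim.reference_fasta)
        lpos = np.array([c.pos for c in low_ds.candidates])
        lsel = np.array([i for i, p in enumerate(lpos) if in_regions(p, test_regions)],
                        dtype=np.int64)
        low_test = MatrixDataset(low_ds.values[lsel],
                                 [low_ds.candidates[i] for i in lsel],
                                 low_ds.candidate_columns[lsel], low_ds.registry)
        low_pred = call_mod.predict(model, low_test)
        low_calls = call_mod.make_calls(low_pred, low_test, low_bam,
                                        sim.reference_fasta, preset="wgs")
        lpairs, _, _ = bench.match_calls(
            low_calls, test_truth, bench.EvalConfig(indel_match_mode="position_only",
                                                    regions=tuple(test_regions)))
        summary["recall_purity_25"] = len(lpairs) / max(len(test_truth), 1)

    return PipelineResult(sim, candidates, dataset, labeled, model,
                          result.metrics, calls, summary)
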