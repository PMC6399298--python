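"""Training loop: truth labeling, class-balanced epoch sampling, SGD schedule.

Each epoch uses every somatic training record plus a fresh uniform draw of
non-somatic candidates at twice their number (ratio configurable), so the
expected somatic fraction per epoch is 1/(1+ratio) by construction.  The
optimizer is SGD (batch size 1000, learning rate 0.01, momentum 0.9) with
the learning rate multiplied by 0.1 every 400 epochs.  Softmax losses can
be class-weighted; defaults are uniform.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .featurize import MatrixDataset
from .network import SGD, SomaticNet, multitask_loss, POSITION_SCALE
from .simulate import TruthSet, Variant, read_truth_vcf
from .variants import DEL, INS, SNV

TYPE_CLASS = {"non-somatic": 0, SNV: 1, INS: 2, DEL: 3}


@dataclass
class TrainConfig:
    batch_size: int = 1000
    lr: float = 0.01
    momentum: float = 0.9
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 400
    nonsomatic_ratio: float = 2.0
    epochs: int = 100
    seed: int = 0
    class_weights_type: tuple = (1.0, 1.0, 1.0, 1.0)
    class_weights_length: tuple = (1.0, 1.0, 1.0, 1.0)
    # Relabel the four base rows by a random permutation per record per
    # epoch (consistently across channels).  Base identity is arbitrary to
    # the somatic/germline decision, so this enlarges small training sets
    # 24-fold without changing the task; disable to train on raw matrices.
    augment_base_permutation: bool = True

    def validate(self) -> None:
        if min(self.batch_size, self.lr, self.momentum + 1e-12, self.lr_decay_factor,
               self.lr_decay_every, self.epochs) <= 0:
            raise ValueError("all TrainConfig scalars must be positive")
        if self.nonsomatic_ratio < 0:
            raise ValueError("nonsomatic_ratio must be >= 0")


def length_class(kind: str, length: int) -> int:
    """The 4-way size label: 0 non-somatic; SNVs and 1-base INDELs 1;
    2-base INDELs 2; longer INDELs 3."""
    if kind == "non-somatic":
        return 0
    if kind == SNV:
        return 1
    return min(length, 3)


@dataclass
class LabeledDataset:
    """A featurized candidate set with per-record training targets."""

    data: MatrixDataset
    type_y: np.ndarray      # (n,) int in {0..3}
    length_y: np.ndarray    # (n,) int in {0..3}
    column_y: np.ndarray    # (n,) float in [0,1]: candidate column / 32
    missed_truth: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def is_somatic(self) -> np.ndarray:
        return self.type_y > 0

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        sub = MatrixDataset(self.data.values[idx],
                            [self.data.candidates[i] for i in idx],
                            self.data.candidate_columns[idx], self.data.registry)
        return LabeledDataset(sub, self.type_y[idx], self.length_y[idx],
                              self.column_y[idx], [])


def label_candidates(dataset: MatrixDataset, truth: TruthSet | str | Sequence[Variant]
                     ) -> LabeledDataset:
    """Assign type/length/column labels by matching candidates to somatic
    truth (position + type; allele for SNVs).  Unmatched candidates are
    non-somatic.  Truth records with no candidate are collected in
    ``missed_truth`` (they cap achievable recall but are not an error)."""
    if isinstance(truth, str):
        somatic = [v for v in read_truth_vcf(truth) if v.somatic]
    elif isinstance(truth, TruthSet):
        somatic = truth.somatic
    else:
        somatic = list(truth)
    by_key = {}
    for v in somatic:
        by_key[(v.chrom, v.pos, v.kind)] = v
    n = len(dataset)
    type_y = np.zeros(n, dtype=np.int64)
    length_y = np.zeros(n, dtype=np.int64)
    column_y = dataset.candidate_columns.astype(np.float64) / POSITION_SCALE
    matched = set()
    for i, cand in enumerate(dataset.candidates):
        v = by_key.get((cand.chrom, cand.pos, cand.kind))
        if v is None:
            continue
        if v.kind == SNV and v.alt != cand.alt:
            continue
        type_y[i] = TYPE_CLASS[v.kind]
        length_y[i] = length_class(v.kind, v.length)
        matched.add((v.chrom, v.pos, v.kind))
    missed = [v for v in somatic if (v.chrom, v.pos, v.kind) not in matched]
    return LabeledDataset(dataset, type_y, length_y, column_y, missed)


def epoch_sample(is_somatic: np.ndarray, nonsomatic_ratio: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Epoch index list: all somatic records plus floor(ratio * n_somatic)
    non-somatic records drawn uniformly (without replacement when enough
    are available), shuffled."""
    if is_somatic.size == 0:
        raise ValueError("empty dataset")
    som = np.flatnonzero(is_somatic)
    non = np.flatnonzero(~is_somatic)
    if som.size == 0:
        raise ValueError("dataset contains no somatic records")
    n_non = int(math.floor(nonsomatic_ratio * som.size))
    if n_non > 0 and non.size > 0:
        draw = rng.choice(non, size=n_non, replace=non.size < n_non)
    else:
        draw = np.empty(0, dtype=np.int64)
    idx = np.concatenate([som, draw])
    rng.shuffle(idx)
    return idx


def lr_at(epoch: int, config: TrainConfig) -> float:
    return config.lr * config.lr_decay_factor ** (epoch // config.lr_decay_every)


_BASE_ROW_PERMS = np.array(
    [list(p) + [4] for p in __import__("itertools").permutations(range(4))],
    dtype=np.int64)


def permute_base_rows(x: np.ndarray, perm_idx: np.ndarray) -> np.ndarray:
    """Apply per-record base-row relabelings (gap row fixed) to a batch of
    (n, k, 5, 32) matrices; ``perm_idx`` indexes the 24 permutations."""
    perm = _BASE_ROW_PERMS[perm_idx]  # (n, 5)
    return np.take_along_axis(x, perm[:, None, :, None], axis=2)


@dataclass
class FitResult:
    model: SomaticNet
    metrics: list            # per-epoch dicts
    best_state: dict         # parameters at the lowest epoch loss
    best_epoch: int

    def write_metrics_tsv(self, path: str) -> None:
        import pandas as pd
        pd.DataFrame(self.metrics).to_csv(path, sep="\t", index=False)


def fit(model: SomaticNet, dataset: LabeledDataset, config: TrainConfig) -> FitResult:
    """Optimize the network on the labeled dataset; reproducible per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    opt = SGD(model.parameters(), momentum=config.momentum)
    values = dataset.data.values
    metrics = []
    best_loss = np.inf
    best_state = None
    best_epoch = -1
    for epoch in range(config.epochs):
        lr = lr_at(epoch, config)
        idx = epoch_sample(dataset.is_somatic, config.nonsomatic_ratio, rng)
        total_loss = 0.0
        n_correct_t = n_correct_l = n_seen = 0
        for lo in range(0, idx.size, config.batch_size):
            b = idx[lo: lo + config.batch_size]
            x = values[b]
            if config.augment_base_permutation:
                x = permute_base_rows(x, rng.integers(0, 24, size=b.size))
            ty, ly, cy = dataset.type_y[b], dataset.length_y[b], dataset.column_y[b]
            model.zero_grad()
            out = model.forward(x, training=True)
            loss, dt, dl, dp = multitask_loss(
                out, ty, ly, cy, config.class_weights_type, config.class_weights_length)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch} "
                    f"(lr={lr}); reduce the learning rate")
            model.backward(dt, dl, dp)
            opt.step(lr)
            total_loss += loss * b.size
            n_correct_t += int((out.type_logits.argmax(axis=1) == ty).sum())
            n_correct_l += int((out.length_logits.argmax(axis=1) == ly).sum())
            n_seen += b.size
        epoch_loss = total_loss / max(n_seen, 1)
        metrics.append({
            "epoch": epoch, "lr": lr, "loss": epoch_loss,
            "type_acc": n_correct_t / max(n_seen, 1),
            "length_acc": n_correct_l / max(n_seen, 1),
            "n_records": n_seen,
        })
        if epoch_loss < best_loss:
            best_loss = epoch_loss
            best_state = model.state_dict()
            best_epoch = epoch
    if best_state is not None:
        model.load_state_dict(best_state)
    return FitResult(model, metrics, best_state or model.state_dict(), best_epoch)


def split_regions(length: int, chunk: int = 10_000, seed: int = 0,
                  train_fraction: float = 0.5) -> tuple[list, list]:
    """Random split of the genome into train/test interval lists (0-based
    half-open), split by region rather than by candidate.  Chunks are
    permuted and assigned so the train side holds exactly
    ``train_fraction`` of them (not an independent coin flip per chunk,
    which at desk scale can starve one side of training events)."""
    rng = np.random.default_rng(seed)
    starts = np.arange(0, length, chunk)
    order = rng.permutation(starts.size)
    n_train = int(round(train_fraction * starts.size))
    train_set = set(order[:n_train].tolist())
    train = [(int(s), int(min(s + chunk, length)))
             for i, s in enumerate(starts) if i in train_set]
    test = [(int(s), int(min(s + chunk, length)))
            for i, s in enumerate(starts) if i not in train_set]
    return train, test


def in_regions(pos: int, regions: Sequence[tuple]) -> bool:
    return any(lo <= pos < hi for lo, hi in regions)
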