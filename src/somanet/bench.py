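"""Benchmarking calls against truth: matching, PR curves, stratification.

Calls and truth are compared on left-normalized, anchored representations.
SNVs always match on position + alternate allele.  INDELs match either
exactly (position, REF, ALT) or in position-only mode (position + type,
ignoring the allele sequence), the relaxed criterion that separates
localization accuracy from allele-resolution accuracy.  Matching is
one-to-one: each truth record can absorb at most one call, claimed in
descending score order.  PR curves sweep thresholds over the distinct call
scores (ties included together; threshold is >=), and the best F1 over the
sweep is the headline number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .call import SomaticCall, read_calls_vcf
from .simulate import Variant, read_truth_vcf
from .variants import DEL, INS, SNV


@dataclass(frozen=True)
class EvalConfig:
    indel_match_mode: str = "exact"  # exact | position_only
    regions: tuple | None = None     # optional ((lo, hi), ...) restriction

    def __post_init__(self):
        if self.indel_match_mode not in ("exact", "position_only"):
            raise ValueError(f"unknown indel_match_mode {self.indel_match_mode!r}")


@dataclass
class EvalPoint:
    threshold: float
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 1.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def _truth_internal(v: Variant) -> tuple:
    # (pos, kind, allele-key)
    return (v.pos, v.kind, str(v.alt))


def _call_internal(c: SomaticCall) -> tuple:
    if c.kind == SNV:
        return (c.pos1 - 1, SNV, c.alt)
    if c.kind == INS:
        return (c.pos1 - 1, INS, c.alt[len(c.ref):])
    return (c.pos1, DEL, str(len(c.ref) - len(c.alt)))  # pos1 == 0-based first deleted


def _match_key(pos: int, kind: str, allele: str, mode: str) -> tuple:
    if kind == SNV:
        return (pos, SNV, allele)
    if mode == "position_only":
        return (pos, kind)
    return (pos, kind, allele)


def _in_regions(pos: int, regions) -> bool:
    return regions is None or any(lo <= pos < hi for lo, hi in regions)


def match_calls(calls: Sequence[SomaticCall], truth: Sequence[Variant],
                config: EvalConfig = EvalConfig()
                ) -> tuple[list, list, list]:
    """One-to-one assignment.  Returns (matched call/truth index pairs,
    unmatched call indices, unmatched truth indices)."""
    truth = [t for t in truth if _in_regions(t.pos, config.regions)]
    mode = config.indel_match_mode
    truth_by_key: dict[tuple, list[int]] = {}
    for j, t in enumerate(truth):
        pos, kind, allele = _truth_internal(t)
        truth_by_key.setdefault(_match_key(pos, kind, allele, mode), []).append(j)
    order = sorted(range(len(calls)), key=lambda i: -calls[i].score)
    matched_truth: set[int] = set()
    pairs, fp = [], []
    for i in order:
        c = calls[i]
        pos, kind, allele = _call_internal(c)
        if not _in_regions(pos, config.regions):
            continue
        found = None
        for j in truth_by_key.get(_match_key(pos, kind, allele, mode), []):
            if j not in matched_truth:
                found = j
                break
        if found is None:
            fp.append(i)
        else:
            matched_truth.add(found)
            pairs.append((i, found))
    fn = [j for j in range(len(truth)) if j not in matched_truth]
    return pairs, fp, fn


def pr_curve(calls: Sequence[SomaticCall], truth: Sequence[Variant],
             config: EvalConfig = EvalConfig()
             ) -> tuple[list[EvalPoint], EvalPoint]:
    """Quality-sorted precision-recall sweep plus the best-F1 point."""
    for c in calls:
        if c.score is None or c.score != c.score:
            raise ValueError(f"unscored call at {c.chrom}:{c.pos1}")
    truth_n = sum(1 for t in truth if _in_regions(t.pos, config.regions))
    pairs, fp_idx, _ = match_calls(calls, truth, config)
    matched = {i for i, _ in pairs}
    in_reg = [i for i in range(len(calls))
              if _in_regions(_call_internal(calls[i])[0], config.regions)]
    if not in_reg:
        pt = EvalPoint(0.0, 0, 0, truth_n)
        return [pt], pt
    scores = np.array([calls[i].score for i in in_reg])
    is_tp = np.array([i in matched for i in in_reg])
    order = np.argsort(-scores, kind="stable")
    scores, is_tp = scores[order], is_tp[order]
    points = []
    thresholds = np.unique(scores)[::-1]
    for thr in thresholds:
        sel = scores >= thr
        tp = int(is_tp[sel].sum())
        fp = int(sel.sum()) - tp
        points.append(EvalPoint(float(thr), tp, fp, truth_n - tp))
    best = max(points, key=lambda p: (p.f1, p.threshold))
    return points, best


def stratify(calls: Sequence[SomaticCall], truth: Sequence[Variant],
             key: str, bins: Sequence | None = None,
             config: EvalConfig = EvalConfig()) -> dict:
    """Per-stratum evaluation at the all-calls operating point.

    ``key='indel_size'`` buckets INDEL truth/calls by length (bins are
    upper-inclusive edges; default [1, 2, 3+]); FP calls are assigned to
    strata by their own resolved length, so precision is meaningful.
    ``key='af'`` buckets truth by target AF (default edges 0.1..1.0);
    AF is unknown for false-positive calls, so AF strata report recall
    (FP fixed at 0).  Strata without truth are reported as None.
    """
    if key == "indel_size":
        edges = list(bins) if bins is not None else [1, 2, 3]
        def truth_stratum(t):
            if t.kind == SNV:
                return None
            return _bucket(t.length, edges)
        def call_stratum(c):
            if c.kind == SNV:
                return None
            return _bucket(c.length, edges)
    elif key == "af":
        edges = list(bins) if bins is not None else [0.1, 0.2, 0.3, 0.5, 1.0]
        def truth_stratum(t):
            return _bucket(t.target_af, edges)
        def call_stratum(c):
            return None
    else:
        raise ValueError(f"unknown stratum key {key!r}")

    pairs, fp_idx, fn_idx = match_calls(calls, truth, config)
    truth_in = [t for t in truth if _in_regions(t.pos, config.regions)]
    strata = {}
    for s in [_fmt_bucket(e, edges) for e in range(len(edges))]:
        strata[s] = {"tp": 0, "fp": 0, "fn": 0, "n_truth": 0}
    for t in truth_in:
        s = truth_stratum(t)
        if s is not None:
            strata[s]["n_truth"] += 1
    for i, j in pairs:
        s = truth_stratum(truth_in[j])
        if s is not None:
            strata[s]["tp"] += 1
    for j in fn_idx:
        s = truth_stratum(truth_in[j])
        if s is not None:
            strata[s]["fn"] += 1
    if key == "indel_size":
        for i in fp_idx:
            s = call_stratum(calls[i])
            if s is not None:
                strata[s]["fp"] += 1
    out = {}
    for s, d in strata.items():
        if d["n_truth"] == 0:
            out[s] = None
        else:
            out[s] = EvalPoint(0.0, d["tp"], d["fp"], d["fn"])
    return out


def _bucket(value, edges) -> str:
    for i, e in enumerate(edges):
        if value <= e:
            return _fmt_bucket(i, edges)
    return _fmt_bucket(len(edges) - 1, edges)


def _fmt_bucket(i: int, edges) -> str:
    lo = edges[i - 1] if i > 0 else 0
    if i == len(edges) - 1:
        return f">{lo}"
    return f"({lo},{edges[i]}]"


def evaluate_vcfs(calls_vcf: str, truth_vcf: str,
                  config: EvalConfig = EvalConfig()) -> dict:
    """File-level convenience: best-F1 PR summary for SNVs and INDELs."""
    calls = read_calls_vcf(calls_vcf)
    truth = [t for t in read_truth_vcf(truth_vcf)]
    out = {}
    for label, kinds in (("snv", {SNV}), ("indel", {INS, DEL})):
        sub_calls = [c for c in calls if c.kind in kinds]
        sub_truth = [t for t in truth if t.kind in kinds]
        pts, best = pr_curve(sub_calls, sub_truth, config)
        out[label] = {"best_f1": best.f1, "precision": best.precision,
                      "recall": best.recall, "threshold": best.threshold,
                      "n_truth": len(sub_truth), "n_calls": len(sub_calls)}
    return out
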