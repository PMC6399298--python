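"""Inference, INDEL allele resolution and VCF emission.

The network's type head decides whether a candidate is called; the somatic
probability is p = 1 - P(non-somatic) and the VCF QUAL is the
Phred-scaled -10 log10(1 - p), capped at 99.  INDEL alleles are resolved
by consensus over the CIGAR events of reads overlapping the call: for
predicted lengths 1 and 2 the majority event of that exact length, for
length class >=3 the most frequent event sequence/span, ties broken
lexicographically.  Calls whose predicted matrix column disagrees with the
candidate column by more than 2 are demoted to LowScore, as are calls
below the preset probability threshold (0.97 genome-wide, 0.6 for
exome/panel enrichment).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pysam

from .featurize import MatrixDataset
from .network import NetworkOutput, POSITION_SCALE, SomaticNet
from .scan import CandidateSite
from .variants import DEL, INS, SNV, left_align_deletion, left_align_insertion, vcf_alleles

SCORE_THRESHOLDS = {"wgs": 0.97, "wes": 0.6, "panel": 0.6, "pacbio": 0.97}
POSITION_TOLERANCE = 2.0  # matrix columns
QUAL_CAP = 99.0


@dataclass
class SomaticCall:
    chrom: str
    pos1: int          # 1-based VCF position
    ref: str
    alt: str
    kind: str          # SNV | INS | DEL
    length: int
    score: float       # somatic probability p
    qual: float        # -10 log10(1-p), capped
    filter: str = "PASS"

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos1, self.ref, self.alt)


def phred_quality(p: float) -> float:
    return min(QUAL_CAP, -10.0 * math.log10(max(1.0 - p, 1e-10)))


def predict(model: SomaticNet, dataset: MatrixDataset, batch_size: int = 1000
            ) -> NetworkOutput:
    """Run inference (stored batch-norm statistics) over all candidates."""
    if model.registry_hash and model.registry_hash != dataset.registry.hash:
        raise ValueError(
            f"channel registry mismatch: checkpoint {model.registry_hash!r} "
            f"vs dataset {dataset.registry.hash!r}")
    t_parts, l_parts, p_parts = [], [], []
    for lo in range(0, len(dataset), batch_size):
        out = model.forward(dataset.values[lo: lo + batch_size], training=False)
        t_parts.append(out.type_logits)
        l_parts.append(out.length_logits)
        p_parts.append(out.position)
    if not t_parts:
        z = np.zeros((0, 4))
        return NetworkOutput(z, z.copy(), np.zeros(0))
    return NetworkOutput(np.concatenate(t_parts), np.concatenate(l_parts),
                         np.concatenate(p_parts))


def _cigar_events(bam: pysam.AlignmentFile, ref: str, chrom: str, pos: int,
                  kind: str) -> Counter:
    """Insertion sequences or deletion lengths whose left-aligned anchor is
    ``pos`` among reads overlapping it."""
    events: Counter = Counter()
    lo = max(0, pos - 1)
    for read in bam.fetch(chrom, lo, pos + 1):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        rp, qp = read.reference_start, 0
        seq = read.query_sequence
        for op, ln in read.cigartuples:
            if op in (0, 7, 8):
                rp += ln
                qp += ln
            elif op == 1:
                if kind == INS and rp >= 1:
                    anchor, s = left_align_insertion(ref, rp - 1, seq[qp:qp + ln])
                    if anchor == pos:
                        events[s] += 1
                qp += ln
            elif op == 2:
                if kind == DEL and left_align_deletion(ref, rp, ln) == pos:
                    events[ln] += 1
                rp += ln
            elif op == 3:
                rp += ln
            elif op == 4:
                qp += ln
    return events


def _majority(counter: Counter):
    """Most frequent key; ties broken by lexicographic/numeric order."""
    if not counter:
        return None
    best = max(counter.items(), key=lambda kv: (kv[1], ))
    top = best[1]
    return sorted(k for k, c in counter.items() if c == top)[0]


def resolve_allele(candidate: CandidateSite, kind: str, length_cls: int,
                   tumor_bam: pysam.AlignmentFile, ref: str
                   ) -> tuple[int, str, str, int] | None:
    """(pos1, REF, ALT, length) for a somatic prediction, or None when no
    supporting read remains at call time."""
    chrom, pos = candidate.chrom, candidate.pos
    if kind == SNV:
        counts: Counter = Counter()
        for col in tumor_bam.pileup(chrom, pos, pos + 1, truncate=True,
                                    min_base_quality=0):
            for pr in col.pileups:
                if pr.is_del or pr.is_refskip or pr.query_position is None:
                    continue
                b = pr.alignment.query_sequence[pr.query_position]
                if b != ref[pos] and b in "ACGT":
                    counts[b] += 1
        alt = _majority(counts)
        if alt is None:
            return None
        return pos + 1, ref[pos], alt, 1

    events = _cigar_events(tumor_bam, ref, chrom, pos, kind)
    if length_cls in (1, 2):
        events = Counter({k: c for k, c in events.items()
                          if (len(k) if kind == INS else k) == length_cls})
    else:  # >=3: consensus among long events
        events = Counter({k: c for k, c in events.items()
                          if (len(k) if kind == INS else k) >= 3})
    choice = _majority(events)
    if choice is None:
        return None
    if kind == INS:
        pos1, r, a = vcf_alleles(ref, pos, INS, choice)
        return pos1, r, a, len(choice)
    pos1, r, a = vcf_alleles(ref, pos, DEL, int(choice))
    return pos1, r, a, int(choice)


def make_calls(predictions: NetworkOutput, dataset: MatrixDataset,
               tumor_bam: str, reference_fasta: str,
               preset: str = "wgs") -> list[SomaticCall]:
    """Turn network outputs into VCF-ready calls (all somatic-typed
    candidates retained; FILTER distinguishes PASS from LowScore)."""
    if preset not in SCORE_THRESHOLDS:
        raise ValueError(f"unknown preset {preset!r}; expected one of "
                         f"{sorted(SCORE_THRESHOLDS)}")
    type_probs = predictions.type_probs
    length_probs = predictions.length_probs
    p_somatic = predictions.somatic_prob
    fasta = pysam.FastaFile(reference_fasta)
    ref_cache: dict[str, str] = {}
    kind_of = {1: SNV, 2: INS, 3: DEL}
    calls: list[SomaticCall] = []
    dropped = 0
    with pysam.AlignmentFile(tumor_bam) as bam:
        for i, cand in enumerate(dataset.candidates):
            t = int(type_probs[i].argmax())
            if t == 0:
                continue
            kind = kind_of[t]
            lcls = int(length_probs[i].argmax())
            if kind == SNV:
                lcls = 1  # type head wins; SNV length is 1 by definition
            elif lcls == 0:
                lcls = 1 + int(length_probs[i, 1:].argmax())
            if cand.chrom not in ref_cache:
                ref_cache[cand.chrom] = fasta.fetch(cand.chrom)
            ref = ref_cache[cand.chrom]
            resolved = resolve_allele(cand, kind, lcls, bam, ref)
            if resolved is None:
                dropped += 1
                continue
            pos1, r, a, length = resolved
            p = float(p_somatic[i])
            call = SomaticCall(cand.chrom, pos1, r, a, kind, length, p,
                               phred_quality(p))
            col_err = abs(float(predictions.position[i]) * POSITION_SCALE
                          - float(dataset.candidate_columns[i]))
            if p < SCORE_THRESHOLDS[preset] or col_err > POSITION_TOLERANCE:
                call.filter = "LowScore"
            calls.append(call)
    calls.sort(key=lambda c: (c.chrom, c.pos1, c.ref, c.alt))
    return calls


def score_and_filter(calls: list[SomaticCall], preset: str = "wgs"
                     ) -> list[SomaticCall]:
    """(Re)assign FILTER against the preset threshold; calls are kept."""
    if preset not in SCORE_THRESHOLDS:
        raise ValueError(f"unknown preset {preset!r}; expected one of "
                         f"{sorted(SCORE_THRESHOLDS)}")
    thr = SCORE_THRESHOLDS[preset]
    for c in calls:
        c.filter = "PASS" if c.score >= thr else "LowScore"
    return calls


def write_vcf(calls: list[SomaticCall], out_path: str, reference_fasta: str,
              checkpoint_hash: str = "", preset: str = "wgs") -> None:
    """Write calls as VCF v4.2 with INFO TYPE/LEN/SCORE; input must be
    coordinate-sorted."""
    for a, b in zip(calls, calls[1:]):
        if (a.chrom, a.pos1) > (b.chrom, b.pos1):
            raise ValueError("calls must be sorted by (chrom, pos)")
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    fasta = pysam.FastaFile(reference_fasta)
    for chrom, ln in zip(fasta.references, fasta.lengths):
        header.contigs.add(chrom, length=ln)
    header.filters.add("LowScore", None, None, "Somatic probability below preset threshold")
    header.info.add("TYPE", 1, "String", "Somatic variant type: SNV, INS or DEL")
    header.info.add("LEN", 1, "Integer", "Variant length")
    header.info.add("SCORE", 1, "Float", "Somatic probability from the classifier")
    header.add_line(f"##somanet_checkpoint={checkpoint_hash or 'unspecified'}")
    header.add_line(f"##somanet_preset={preset}")
    with pysam.VariantFile(out_path, "w", header=header) as vcf:
        for c in calls:
            rec = vcf.new_record(contig=c.chrom, start=c.pos1 - 1,
                                 alleles=(c.ref, c.alt), qual=round(c.qual, 2),
                                 filter=c.filter)
            rec.info["TYPE"] = c.kind
            rec.info["LEN"] = c.length
            rec.info["SCORE"] = c.score
            vcf.write(rec)


def read_calls_vcf(path: str) -> list[SomaticCall]:
    from .variants import read_vcf
    out = []
    for rec in read_vcf(path):
        _, pos, kind, alt = rec.key()
        length = 1 if kind == SNV else (len(alt) if kind == INS else int(alt))
        score = float(rec.info.get("SCORE", 1.0))
        out.append(SomaticCall(rec.chrom, rec.pos1, rec.ref, rec.alt,
                               rec.info.get("TYPE", kind), length, score,
                               rec.qual if rec.qual is not None else 0.0,
                               rec.filter))
    return out
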