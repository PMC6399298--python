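"""Candidate somatic locus scanning and liberal filtering.

The tumor alignment is scanned once; every locus with at least one
non-reference observation (mismatch, insertion or deletion) yields a
:class:`SiteStats`.  Liberal filters then reduce these to
:class:`CandidateSite` records for the network to classify:

* SNV kept iff (AF >= 0.03 OR alt support >= 3 reads) AND mean alt base
  quality > 19 (Phred); the WES preset relaxes the quality bound to > 14.
* 1-base INDEL kept iff AF >= 0.02 OR support >= 2 reads.
* Longer INDEL kept iff AF >= 0.03.
* PacBio preset: AF >= 0.1 for SNVs and multi-base INDELs, >= 0.15 for
  1-base INDELs.

INDEL evidence is left-aligned against the reference before keying so the
scan, truth VCFs and external-caller VCFs share a canonical representation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam

from .variants import BASES, DEL, INS, SNV, left_align_deletion, left_align_insertion, read_vcf


@dataclass
class SiteStats:
    """Per-locus pileup summary (0-based position).

    ``depth`` counts reads whose alignment spans the position (including
    deleted bases), which is the AF denominator for every allele class.
    """

    chrom: str
    pos: int
    ref_base: str
    depth: int
    base_counts: dict = field(default_factory=dict)   # base -> read count (incl. ref)
    base_bq: dict = field(default_factory=dict)       # base -> mean Phred of those reads
    ins_counts: dict = field(default_factory=dict)    # inserted seq -> read count
    ins_bq: dict = field(default_factory=dict)        # inserted seq -> mean Phred
    del_counts: dict = field(default_factory=dict)    # deletion length -> read count


@dataclass
class CandidateSite:
    chrom: str
    pos: int          # 0-based; SNV: base, INS: anchor, DEL: first deleted base
    kind: str         # SNV | INS | DEL
    alt: object       # SNV: base; INS: inserted seq; DEL: length (int)
    af: float
    support: int
    mean_bq: float
    source: str = "scan"

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.kind, self.alt)


@dataclass(frozen=True)
class FilterConfig:
    snv_min_af: float = 0.03
    snv_alt_support_floor: int = 3     # "more than two reads"
    snv_min_bq: float = 19.0           # strict: mean alt BQ must exceed this
    indel1_min_af: float = 0.02
    indel1_support_floor: int = 2      # "more than one read"
    indelN_min_af: float = 0.03

    @classmethod
    def preset(cls, name: str) -> "FilterConfig":
        presets = {
            "wgs": cls(),
            "wes": cls(snv_min_bq=14.0),
            "panel": cls(snv_min_bq=14.0),
            # high-error long reads: AF-only thresholds; low read-count
            # support is not evidence there, so the support branches are off
            "pacbio": cls(snv_min_af=0.1, indelN_min_af=0.1, indel1_min_af=0.15,
                          snv_alt_support_floor=10 ** 9,
                          indel1_support_floor=10 ** 9),
        }
        try:
            return presets[name]
        except KeyError:
            raise ValueError(f"unknown preset {name!r}; expected one of {sorted(presets)}") from None


def scan_region(tumor_bam: str, reference_fasta: str, region: tuple | None = None
                ) -> Iterator[SiteStats]:
    """Scan the tumor BAM, yielding SiteStats for each locus with >=1
    non-reference observation, in genomic order.

    ``region`` is ``(chrom, start, end)`` with 0-based half-open
    coordinates, or None for the whole first contig of the BAM.
    """
    if not (os.path.exists(tumor_bam + ".bai") or os.path.exists(tumor_bam + ".csi")
            or os.path.exists(os.path.splitext(tumor_bam)[0] + ".bai")):
        raise IOError(f"BAM index not found for {tumor_bam}")
    bam = pysam.AlignmentFile(tumor_bam)
    fasta = pysam.FastaFile(reference_fasta)
    if region is None:
        chrom = bam.references[0]
        start, end = 0, bam.get_reference_length(chrom)
    else:
        chrom, start, end = region
    if chrom not in fasta.references:
        raise ValueError(f"chromosome {chrom!r} present in BAM but not in FASTA "
                         f"({list(fasta.references)})")
    ref = fasta.fetch(chrom)
    ref_bytes = np.frombuffer(ref.encode(), dtype=np.uint8)
    L = len(ref)

    span_diff = np.zeros(L + 1, dtype=np.int32)
    base_diff = np.zeros(L + 1, dtype=np.int32)
    mism_pos: list[np.ndarray] = []
    mism_base: list[np.ndarray] = []
    mism_qual: list[np.ndarray] = []
    ins_events: dict[int, dict[str, list]] = {}
    del_events: dict[int, dict[int, int]] = {}

    for read in bam.fetch(chrom, start, end):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        seq = read.query_sequence
        if seq is None:
            continue
        quals = read.query_qualities
        seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        rp, qp = read.reference_start, 0
        span_diff[rp] += 1
        span_diff[read.reference_end] -= 1
        for op, ln in read.cigartuples:
            if op in (0, 7, 8):  # M/=/X
                diff = np.nonzero(seq_arr[qp:qp + ln] != ref_bytes[rp:rp + ln])[0]
                if diff.size:
                    mism_pos.append(rp + diff)
                    mism_base.append(seq_arr[qp + diff])
                    if quals is not None:
                        mism_qual.append(np.asarray(quals, dtype=np.int16)[qp + diff])
                    else:
                        mism_qual.append(np.full(diff.size, 30, dtype=np.int16))
                base_diff[rp] += 1
                base_diff[rp + ln] -= 1
                rp += ln
                qp += ln
            elif op == 1:  # I
                ins_seq = seq[qp:qp + ln]
                anchor = rp - 1
                if anchor >= 0:
                    anchor, ins_seq = left_align_insertion(ref, anchor, ins_seq)
                    bq = float(np.mean(quals[qp:qp + ln])) if quals is not None else 30.0
                    slot = ins_events.setdefault(anchor, {}).setdefault(ins_seq, [0, 0.0])
                    slot[0] += 1
                    slot[1] += bq
                qp += ln
            elif op == 2:  # D
                d = left_align_deletion(ref, rp, ln)
                del_events.setdefault(d, {}).setdefault(ln, 0)
                del_events[d][ln] += 1
                rp += ln
            elif op == 4:  # S
                qp += ln
            elif op == 3:  # N
                rp += ln
            elif op == 5 or op == 6:  # H/P
                pass
            else:
                raise ValueError(f"read {read.query_name}: unsupported CIGAR op {op}")

    span = np.cumsum(span_diff[:-1])
    basecov = np.cumsum(base_diff[:-1])

    if mism_pos:
        mp = np.concatenate(mism_pos)
        mb = np.concatenate(mism_base)
        mq = np.concatenate(mism_qual).astype(np.float64)
        code = np.frombuffer(BASES.encode(), dtype=np.uint8)
        base_idx = np.searchsorted(code, mb)  # A<C<G<T ascii-ordered
        valid = (base_idx < 4) & (code[np.clip(base_idx, 0, 3)] == mb)
        mp, base_idx, mq = mp[valid], base_idx[valid], mq[valid]
        key = mp * 4 + base_idx
        order = np.argsort(key, kind="stable")
        key, mq = key[order], mq[order]
        uniq, idx_start = np.unique(key, return_index=True)
        counts = np.diff(np.append(idx_start, key.size))
        qsums = np.add.reduceat(mq, idx_start) if key.size else np.array([])
        snv_map: dict[int, list] = {}
        for k, c, qs in zip(uniq, counts, qsums):
            p, b = int(k // 4), int(k % 4)
            snv_map.setdefault(p, []).append((BASES[b], int(c), qs / c))
    else:
        snv_map = {}

    loci = sorted(set(snv_map) | set(ins_events) | set(del_events))
    for pos in loci:
        if not (start <= pos < end):
            continue
        depth = int(span[pos])
        ref_b = ref[pos]
        stats = SiteStats(chrom, pos, ref_b, depth)
        alt_total = 0
        for base, c, bq in snv_map.get(pos, []):
            if base == ref_b:
                continue
            stats.base_counts[base] = c
            stats.base_bq[base] = bq
            alt_total += c
        stats.base_counts[ref_b] = max(int(basecov[pos]) - alt_total, 0)
        for s, (c, bqsum) in ins_events.get(pos, {}).items():
            stats.ins_counts[s] = c
            stats.ins_bq[s] = bqsum / c
        for ln, c in del_events.get(pos, {}).items():
            stats.del_counts[ln] = c
        if stats.base_bq or stats.ins_counts or stats.del_counts:
            yield stats


def filter_candidates(stats_stream: Iterable[SiteStats],
                      config: FilterConfig | None = None) -> list[CandidateSite]:
    """Apply the liberal candidate filters; one candidate per
    (pos, type, alt) with evidence passing the corresponding rule."""
    fc = config or FilterConfig()
    out: list[CandidateSite] = []
    for st in stats_stream:
        depth = max(st.depth, 1)
        for base, c in sorted(st.base_counts.items()):
            if base == st.ref_base or c == 0:
                continue
            af = c / depth
            bq = st.base_bq.get(base, 0.0)
            if (af >= fc.snv_min_af or c >= fc.snv_alt_support_floor) and bq > fc.snv_min_bq:
                out.append(CandidateSite(st.chrom, st.pos, SNV, base, min(af, 1.0), c, bq))
        for seq, c in sorted(st.ins_counts.items()):
            af = c / depth
            bq = st.ins_bq.get(seq, 0.0)
            if len(seq) == 1:
                keep = af >= fc.indel1_min_af or c >= fc.indel1_support_floor
            else:
                keep = af >= fc.indelN_min_af
            if keep:
                out.append(CandidateSite(st.chrom, st.pos, INS, seq, min(af, 1.0), c, bq))
        for ln, c in sorted(st.del_counts.items()):
            af = c / depth
            if ln == 1:
                keep = af >= fc.indel1_min_af or c >= fc.indel1_support_floor
            else:
                keep = af >= fc.indelN_min_af
            if keep:
                out.append(CandidateSite(st.chrom, st.pos, DEL, int(ln), min(af, 1.0), c, 0.0))
    out.sort(key=lambda c: (c.chrom, c.pos, c.kind, str(c.alt)))
    return out


def exclude_dbsnp(candidates: Sequence[CandidateSite], dbsnp_vcf: str,
                  allele_aware: bool = True,
                  reference: str | None = None) -> list[CandidateSite]:
    """Drop candidates present in a dbSNP-style VCF.

    ``allele_aware=True`` matches on (chrom, pos, type, alt); otherwise on
    position alone.
    """
    keys = set()
    positions = set()
    for rec in read_vcf(dbsnp_vcf):
        chrom, pos, kind, alt = rec.key(reference)
        keys.add((chrom, pos, kind, alt))
        positions.add((chrom, pos))
    if allele_aware:
        return [c for c in candidates if c.key not in keys]
    return [c for c in candidates if (c.chrom, c.pos) not in positions]


def merge_external(candidates: Sequence[CandidateSite], external_vcfs: Sequence[str],
                   reference: str | None = None) -> list[CandidateSite]:
    """Union scanned candidates with external-caller calls, keyed by
    (chrom, pos, type, alt); external-only sites get ``source='external'``."""
    seen = {c.key: c for c in candidates}
    merged = list(candidates)
    for path in external_vcfs:
        for rec in read_vcf(path):
            chrom, pos, kind, alt = rec.key(reference)
            if kind == "COMPLEX":
                continue
            key = (chrom, pos, kind, alt)
            if key in seen:
                continue
            af = float(rec.info["AF"]) if "AF" in rec.info else float("nan")
            cand = CandidateSite(chrom, pos, kind, alt, af, 0, 0.0, source="external")
            seen[key] = cand
            merged.append(cand)
    merged.sort(key=lambda c: (c.chrom, c.pos, c.kind, str(c.alt)))
    return merged


_TSV_COLUMNS = ["chrom", "pos0", "pos1", "type", "alt", "af", "support", "bq", "source"]


def write_candidates_tsv(candidates: Sequence[CandidateSite], path: str) -> None:
    rows = []
    for c in candidates:
        pos1 = c.pos + (int(c.alt) if c.kind == DEL else 1)
        rows.append((c.chrom, c.pos, pos1, c.kind, str(c.alt), c.af, c.support,
                     round(c.mean_bq, 2), c.source))
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_candidates_tsv(path: str) -> list[CandidateSite]:
    df = pd.read_csv(path, sep="\t", dtype={"alt": str})
    out = []
    for row in df.itertuples(index=False):
        alt = int(row.alt) if row.type == DEL else row.alt
        out.append(CandidateSite(row.chrom, int(row.pos0), row.type, alt,
                                 float(row.af), int(row.support), float(row.bq), row.source))
    return out
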