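"""Candidate featurization: the k x 5 x 32 input matrix.

For each candidate a window of seven reference bases (candidate +/- 3) is
taken and the reference is augmented with gap columns wherever any
overlapping read carries an insertion, turning the BAM alignments into a
multiple sequence alignment without realignment.  Distinct insertions at
the same anchor share the same left-aligned slot columns.  32 matrix
columns are reserved; if insertions overflow them, insertion columns
farthest from the candidate are truncated first, so at least the three
flanking reference bases on each side always survive.

Rows are (A, C, G, T, gap).  The stand-alone layout has 26 channels:
reference one-hot, tumor base frequencies, normal base frequencies,
candidate-position one-hot, then 11 alignment-feature channels per sample
(depth, base quality, mapping quality, forward/reverse strand fractions,
soft-/any-clip fractions, edit distance, alignment score, properly-paired
and mate-unmapped fractions).  Ensemble mode appends 93 opaque slots for
external-caller features (119 total).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pysam

from .scan import CandidateSite
from .variants import BASES, DEL, INS, SNV, left_align_insertion

WINDOW_FLANK = 3
N_COLS = 32
N_ROWS = 5
GAP_ROW = 4
ROW_OF = {b: i for i, b in enumerate(BASES)}
ROW_OF["-"] = GAP_ROW

BQ_CAP = 41.0
MQ_CAP = 70.0
DEPTH_NORM = 100.0

N_EXTERNAL_SLOTS = 93

_PER_SAMPLE_FEATURES = [
    "depth", "bq", "mq", "fwd_frac", "rev_frac", "softclip_frac",
    "anyclip_frac", "edit_dist", "aln_score", "paired_frac", "mate_unmapped_frac",
]


@dataclass(frozen=True)
class ChannelRegistry:
    names: tuple

    @classmethod
    def build(cls, mode: str = "standalone") -> "ChannelRegistry":
        names = ["reference", "tumor_freq", "normal_freq", "position"]
        for sample in ("tumor", "normal"):
            names += [f"{sample}_{f}" for f in _PER_SAMPLE_FEATURES]
        if mode == "ensemble":
            names += [f"ext_{i:02d}" for i in range(N_EXTERNAL_SLOTS)]
        elif mode != "standalone":
            raise ValueError(f"unknown mode {mode!r}")
        if len(set(names)) != len(names):
            raise AssertionError("channel names must be unique")
        return cls(tuple(names))

    def __len__(self) -> int:
        return len(self.names)

    @property
    def hash(self) -> str:
        return hashlib.sha256(",".join(self.names).encode()).hexdigest()[:16]


@dataclass
class ColumnMap:
    """Mapping from reference positions / insertion slots to matrix columns.

    ``columns`` holds descriptors ``("ref", rpos)`` or
    ``("ins", anchor_rpos, offset)``; ins-slot columns immediately follow
    their anchor's reference column.
    """

    chrom: str
    columns: list
    candidate_column: int
    window: tuple  # (first_rpos, last_rpos) inclusive

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def ref_col(self, rpos: int) -> int | None:
        for i, d in enumerate(self.columns):
            if d[0] == "ref" and d[1] == rpos:
                return i
        return None


@dataclass
class InputMatrix:
    values: np.ndarray  # (k, 5, 32) float32 in [0, 1]
    registry: ChannelRegistry
    colmap: ColumnMap
    candidate: CandidateSite

    @property
    def candidate_id(self) -> str:
        c = self.candidate
        return f"{c.chrom}:{c.pos}:{c.kind}:{c.alt}"


def _read_insertions(read: pysam.AlignedSegment, ref: str) -> list[tuple[int, str]]:
    """(left-aligned anchor, inserted seq) events of one read."""
    out = []
    rp, qp = read.reference_start, 0
    seq = read.query_sequence
    for op, ln in read.cigartuples:
        if op in (0, 7, 8):
            rp += ln
            qp += ln
        elif op == 1:
            if rp >= 1:
                anchor, s = left_align_insertion(ref, rp - 1, seq[qp:qp + ln])
                out.append((anchor, s))
            qp += ln
        elif op == 2 or op == 3:
            rp += ln
        elif op == 4:
            qp += ln
    return out


def build_column_map(tumor_reads: Sequence[pysam.AlignedSegment],
                     normal_reads: Sequence[pysam.AlignedSegment],
                     reference: str, candidate: CandidateSite) -> ColumnMap:
    """Allocate the up-to-32 matrix columns for one candidate window."""
    pos = candidate.pos
    if pos - WINDOW_FLANK < 0 or pos + WINDOW_FLANK >= len(reference):
        raise ValueError(
            f"candidate at {candidate.chrom}:{pos} too close to the contig edge "
            f"for a +/-{WINDOW_FLANK} base window")
    window_lo, window_hi = pos - WINDOW_FLANK, pos + WINDOW_FLANK

    max_ins: dict[int, int] = {}
    for read in list(tumor_reads) + list(normal_reads):
        for anchor, s in _read_insertions(read, reference):
            if window_lo <= anchor <= window_hi:
                max_ins[anchor] = max(max_ins.get(anchor, 0), len(s))
    if candidate.kind == INS and window_lo <= pos <= window_hi:
        max_ins[pos] = max(max_ins.get(pos, 0), 1)

    budget = N_COLS - (2 * WINDOW_FLANK + 1)
    # truncate insertion slots farthest from the candidate first
    while sum(max_ins.values()) > budget:
        far = max(max_ins, key=lambda a: (abs(a - pos), a))
        if far == pos:  # only the candidate's own anchor left: cap it
            max_ins[far] = budget
            break
        max_ins[far] -= 1
        if max_ins[far] == 0:
            del max_ins[far]

    columns: list = []
    candidate_column = None
    for rpos in range(window_lo, window_hi + 1):
        columns.append(("ref", rpos))
        if rpos == pos and candidate.kind in (SNV, DEL):
            candidate_column = len(columns) - 1
        for off in range(max_ins.get(rpos, 0)):
            columns.append(("ins", rpos, off))
            if rpos == pos and off == 0 and candidate.kind == INS:
                candidate_column = len(columns) - 1
    if candidate_column is None:
        candidate_column = WINDOW_FLANK
    return ColumnMap(candidate.chrom, columns, candidate_column, (window_lo, window_hi))


def project_read(read: pysam.AlignedSegment, colmap: ColumnMap, reference: str
                 ) -> tuple[list, list]:
    """Per-column (symbol, base quality) for one read.

    Symbols are 'A'/'C'/'G'/'T'/'-' or None for columns outside the read's
    aligned span.  Gap symbols carry quality None.
    """
    n = colmap.n_columns
    syms: list = [None] * n
    quals: list = [None] * n
    ref_col = {}
    ins_cols: dict[int, list[int]] = {}
    for i, d in enumerate(colmap.columns):
        if d[0] == "ref":
            ref_col[d[1]] = i
        else:
            ins_cols.setdefault(d[1], []).append(i)
    lo, hi = colmap.window

    seq = read.query_sequence
    rquals = read.query_qualities
    if seq is None or read.cigartuples is None:
        raise ValueError(f"read {read.query_name}: missing sequence or CIGAR")
    qlen = sum(ln for op, ln in read.cigartuples if op in (0, 1, 4, 7, 8))
    if qlen != len(seq):
        raise ValueError(f"read {read.query_name}: CIGAR/sequence length mismatch")

    rp, qp = read.reference_start, 0
    for op, ln in read.cigartuples:
        if op in (0, 7, 8):  # aligned bases
            for j in range(ln):
                r = rp + j
                if lo <= r <= hi:
                    c = ref_col[r]
                    syms[c] = seq[qp + j]
                    quals[c] = rquals[qp + j] if rquals is not None else None
            rp += ln
            qp += ln
        elif op == 1:  # insertion: fill slots left-aligned
            if rp >= 1:
                anchor, s = left_align_insertion(reference, rp - 1, seq[qp:qp + ln])
                if anchor in ins_cols:
                    for off, col in enumerate(ins_cols[anchor]):
                        if off < len(s):
                            syms[col] = s[off]
                            quals[col] = rquals[qp + min(off, ln - 1)] if rquals is not None else None
            qp += ln
        elif op == 2:  # deletion: gap in deleted reference columns
            for j in range(ln):
                r = rp + j
                if lo <= r <= hi:
                    syms[ref_col[r]] = "-"
            rp += ln
        elif op == 3:
            rp += ln
        elif op == 4:
            qp += ln

    # a read aligned across an anchor but without (enough) inserted bases
    # shows gaps in the remaining slot columns
    for anchor, cols in ins_cols.items():
        if anchor in ref_col and syms[ref_col[anchor]] is not None:
            for col in cols:
                if syms[col] is None:
                    syms[col] = "-"
    return syms, quals


def _fetch_window(bam: pysam.AlignmentFile, chrom: str, pos: int) -> list:
    lo = max(0, pos - WINDOW_FLANK)
    hi = pos + WINDOW_FLANK + 1
    return [r for r in bam.fetch(chrom, lo, hi)
            if not (r.is_unmapped or r.is_secondary or r.is_supplementary)]


def _sample_channels(reads: Sequence[pysam.AlignedSegment], colmap: ColumnMap,
                     reference: str, depth_norm: float) -> dict[str, np.ndarray]:
    """The 1 frequency channel + 11 feature channels for one sample."""
    n = colmap.n_columns
    counts = np.zeros((N_ROWS, n))
    bq_sum = np.zeros((N_ROWS, n))
    bq_n = np.zeros((N_ROWS, n))
    mq_sum = np.zeros((N_ROWS, n))
    fwd = np.zeros((N_ROWS, n))
    softclip = np.zeros((N_ROWS, n))
    anyclip = np.zeros((N_ROWS, n))
    edit = np.zeros((N_ROWS, n))
    score = np.zeros((N_ROWS, n))
    paired = np.zeros((N_ROWS, n))
    mate_unmapped = np.zeros((N_ROWS, n))

    for read in reads:
        syms, quals = project_read(read, colmap, reference)
        has_soft = any(op == 4 for op, _ in read.cigartuples)
        has_clip = any(op in (4, 5) for op, _ in read.cigartuples)
        rlen = read.query_length or 1
        nm = float(read.get_tag("NM")) if read.has_tag("NM") else 0.0
        a_s = float(read.get_tag("AS")) if read.has_tag("AS") else 0.0
        for col, sym in enumerate(syms):
            if sym is None:
                continue
            row = ROW_OF[sym]
            counts[row, col] += 1
            if quals[col] is not None:
                bq_sum[row, col] += quals[col]
                bq_n[row, col] += 1
            mq_sum[row, col] += read.mapping_quality
            if not read.is_reverse:
                fwd[row, col] += 1
            if has_soft:
                softclip[row, col] += 1
            if has_clip:
                anyclip[row, col] += 1
            edit[row, col] += nm / rlen
            score[row, col] += a_s / rlen
            if read.is_paired:
                paired[row, col] += 1
                if read.mate_is_unmapped:
                    mate_unmapped[row, col] += 1

    cover = counts.sum(axis=0)
    safe = np.maximum(counts, 1)
    safe_cover = np.maximum(cover, 1)
    out = {
        "freq": counts / safe_cover,
        "counts": counts,
        "depth": np.broadcast_to(np.clip(cover / depth_norm, 0, 1), (N_ROWS, n)).copy(),
        "bq": np.clip(bq_sum / np.maximum(bq_n, 1) / BQ_CAP, 0, 1),
        "mq": np.clip(mq_sum / safe / MQ_CAP, 0, 1),
        "fwd_frac": fwd / safe,
        "rev_frac": (counts - fwd) / safe,
        "softclip_frac": softclip / safe,
        "anyclip_frac": anyclip / safe,
        "edit_dist": np.clip(edit / safe, 0, 1),
        "aln_score": np.clip(score / safe, 0, 1),
        "paired_frac": paired / safe,
        "mate_unmapped_frac": mate_unmapped / safe,
    }
    return out


def build_matrix(tumor_reads: Sequence[pysam.AlignedSegment],
                 normal_reads: Sequence[pysam.AlignedSegment],
                 reference: str, candidate: CandidateSite,
                 mode: str = "standalone", depth_norm: float = DEPTH_NORM
                 ) -> InputMatrix:
    """Assemble the k x 5 x 32 matrix for one candidate."""
    registry = ChannelRegistry.build(mode)
    colmap = build_column_map(tumor_reads, normal_reads, reference, candidate)
    k = len(registry)
    M = np.zeros((k, N_ROWS, N_COLS), dtype=np.float32)
    n = colmap.n_columns

    for i, d in enumerate(colmap.columns):
        row = ROW_OF[reference[d[1]]] if d[0] == "ref" else GAP_ROW
        M[0, row, i] = 1.0
    M[3, :, colmap.candidate_column] = 1.0

    name_idx = {nm: i for i, nm in enumerate(registry.names)}
    for sample, reads in (("tumor", tumor_reads), ("normal", normal_reads)):
        ch = _sample_channels(reads, colmap, reference, depth_norm)
        M[name_idx[f"{sample}_freq"], :, :n] = ch["freq"]
        for f in _PER_SAMPLE_FEATURES:
            M[name_idx[f"{sample}_{f}"], :, :n] = ch[f]
    return InputMatrix(M, registry, colmap, candidate)


def attach_external_features(matrix: InputMatrix, features: Sequence[float]) -> InputMatrix:
    """Broadcast per-caller feature values into the ensemble slots at the
    candidate column."""
    if "ext_00" not in matrix.registry.names:
        raise ValueError("external features require an ensemble-mode matrix")
    if len(features) > N_EXTERNAL_SLOTS:
        raise ValueError(f"{len(features)} external features exceed the "
                         f"{N_EXTERNAL_SLOTS} reserved slots")
    base = matrix.registry.names.index("ext_00")
    for i, v in enumerate(features):
        matrix.values[base + i, :, matrix.colmap.candidate_column] = float(v)
    return matrix


def featurize_candidates(candidates: Sequence[CandidateSite], tumor_bam: str,
                         normal_bam: str, reference_fasta: str,
                         mode: str = "standalone",
                         depth_norm: float = DEPTH_NORM) -> "MatrixDataset":
    """Build matrices for a list of candidates by fetching reads per window."""
    registry = ChannelRegistry.build(mode)
    fasta = pysam.FastaFile(reference_fasta)
    ref_cache: dict[str, str] = {}
    matrices = []
    kept = []
    with pysam.AlignmentFile(tumor_bam) as tb, pysam.AlignmentFile(normal_bam) as nb:
        for cand in candidates:
            if cand.chrom not in ref_cache:
                ref_cache[cand.chrom] = fasta.fetch(cand.chrom)
            ref = ref_cache[cand.chrom]
            treads = _fetch_window(tb, cand.chrom, cand.pos)
            nreads = _fetch_window(nb, cand.chrom, cand.pos)
            m = build_matrix(treads, nreads, ref, cand, mode=mode, depth_norm=depth_norm)
            matrices.append(m)
            kept.append(cand)
    values = np.stack([m.values for m in matrices]) if matrices else \
        np.zeros((0, len(registry), N_ROWS, N_COLS), dtype=np.float32)
    cand_cols = np.array([m.colmap.candidate_column for m in matrices], dtype=np.int64)
    return MatrixDataset(values, kept, cand_cols, registry)


@dataclass
class MatrixDataset:
    """Featurized candidates ready for the network: values (n, k, 5, 32)."""

    values: np.ndarray
    candidates: list
    candidate_columns: np.ndarray
    registry: ChannelRegistry

    def __len__(self) -> int:
        return len(self.candidates)

    def save(self, path: str) -> None:
        meta = [{"chrom": c.chrom, "pos": c.pos, "kind": c.kind, "alt": str(c.alt),
                 "af": None if c.af != c.af else c.af, "support": c.support,
                 "bq": c.mean_bq, "source": c.source} for c in self.candidates]
        np.savez_compressed(
            path, values=self.values, candidate_columns=self.candidate_columns,
            meta=np.array(json.dumps(meta)), registry=np.array(json.dumps(list(self.registry.names))))

    @classmethod
    def load(cls, path: str) -> "MatrixDataset":
        with np.load(path, allow_pickle=False) as z:
            values = z["values"]
            cand_cols = z["candidate_columns"]
            meta = json.loads(str(z["meta"]))
            names = tuple(json.loads(str(z["registry"])))
        cands = []
        for m in meta:
            alt = int(m["alt"]) if m["kind"] == DEL else m["alt"]
            af = float("nan") if m["af"] is None else m["af"]
            cands.append(CandidateSite(m["chrom"], m["pos"], m["kind"], alt, af,
                                       m["support"], m["bq"], m["source"]))
        return cls(values, cands, cand_cols, ChannelRegistry(names))
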