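"""Synthetic paired tumor/normal read simulator with known somatic truth.

Generates a random reference contig, plants germline variants plus somatic
SNVs/INDELs at controlled target allele fractions, and emits pre-aligned,
coordinate-sorted, indexed BAMs for a tumor and a matched normal sample.
Reads are generated directly with a CIGAR constructed from the known
variant placement, so no external aligner is involved; a read drawn from
the tumor genome carries each somatic allele with probability equal to the
variant's target allele fraction, so the expected somatic AF observed in
the tumor BAM is ``tumor_purity * target_af`` (mirroring purity-mixture
construction, where mixing pure samples dilutes the somatic AF).  Setting
the per-variant target AF to a binomial-spike mean reproduces
``Binomial(depth, mean)`` alt counts per site.

Sequencing errors are uniform substitutions; the INDEL error rate defaults
to zero so truth AFs stay clean.  Reads are single-end, unpaired.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pysam

from .variants import BASES, DEL, INS, SNV, left_align_deletion, left_align_insertion, read_vcf, vcf_alleles

CHROM = "chrS"

_CODE = {b: i for i, b in enumerate(BASES)}


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for one synthetic tumor/normal pair.

    Defaults describe the package's reference desk-scale experiment: a
    200 kb contig at 50x tumor / 50x normal coverage with a pure tumor and
    a pure normal, 300 somatic SNVs and 100 somatic INDELs at target AFs
    of at least 0.25, and ~1.5 germline het/hom variants per kb.
    """

    ref_length: int = 200_000
    read_length: int = 100
    coverage_normal: float = 50.0
    coverage_tumor: float = 50.0
    tumor_purity: float = 1.0
    normal_purity: float = 1.0
    somatic_af_means: Sequence[float] = (0.25, 0.5, 1.0)
    n_germline: int = 300
    n_somatic_snv: int = 300
    n_somatic_indel: int = 100
    base_error_rate: float = 0.002
    indel_error_rate: float = 0.0
    min_spacing: int = 20
    indel_length_max: int = 10
    germline_indel_fraction: float = 0.2
    seed: int = 0
    chrom: str = CHROM

    def validate(self) -> None:
        if not (0.0 <= self.tumor_purity <= 1.0 and 0.0 <= self.normal_purity <= 1.0):
            raise SimulationError("purities must lie in [0, 1]")
        if min(self.n_germline, self.n_somatic_snv, self.n_somatic_indel) < 0:
            raise SimulationError("variant counts must be >= 0")
        if not all(0.0 < a <= 1.0 for a in self.somatic_af_means):
            raise SimulationError("somatic_af_means must lie in (0, 1]")
        if self.ref_length < 1000:
            raise SimulationError("ref_length must be >= 1000")
        n_total = self.n_germline + self.n_somatic_snv + self.n_somatic_indel
        usable = self.ref_length - 2 * self.read_length
        if n_total * max(self.min_spacing, 1) > usable:
            raise SimulationError(
                f"reference of {self.ref_length} bp cannot hold {n_total} variants "
                f"at min_spacing={self.min_spacing} (usable span {usable} bp)"
            )


@dataclass(frozen=True)
class Variant:
    """One truth variant in internal coordinates (see :mod:`somanet.variants`)."""

    chrom: str
    pos: int
    kind: str  # SNV | INS | DEL
    alt: object  # SNV: base; INS: inserted seq; DEL: length (int)
    target_af: float  # within-genome allele fraction (germline: 0.5 het / 1.0 hom)
    somatic: bool
    zygosity: str | None = None  # germline only: het | hom

    @property
    def length(self) -> int:
        if self.kind == SNV:
            return 1
        return len(self.alt) if self.kind == INS else int(self.alt)


@dataclass
class TruthSet:
    germline: list[Variant] = field(default_factory=list)
    somatic: list[Variant] = field(default_factory=list)

    @property
    def all_variants(self) -> list[Variant]:
        return sorted(self.germline + self.somatic, key=lambda v: v.pos)


@dataclass
class SimOutput:
    reference_fasta: str
    reference: str
    tumor_bam: str
    normal_bam: str
    truth_vcf: str
    germline_vcf: str
    truth: TruthSet
    config: SimConfig


def generate_reference(length: int, seed: int, fasta_path: str | None = None,
                       chrom: str = CHROM) -> str:
    """Uniform-random A/C/G/T contig; deterministic per seed.  If
    ``fasta_path`` is given the sequence is written and faidx-indexed."""
    if length < 1000:
        raise SimulationError("reference length must be >= 1000")
    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            fh.write(f">{chrom}\n")
            for i in range(0, length, 70):
                fh.write(seq[i:i + 70] + "\n")
        pysam.faidx(fasta_path)
    return seq


def _draw_positions(rng, config: SimConfig, n: int) -> np.ndarray:
    """n variant positions with pairwise spacing >= min_spacing, away from
    the contig edges so reads fully cover every variant."""
    lo = config.read_length
    hi = config.ref_length - config.read_length - config.indel_length_max - 1
    # extra margin absorbs the (small) leftward shift of indel normalization
    spacing = max(config.min_spacing, 1) + 8
    for _ in range(20):
        cand = np.sort(rng.integers(lo, hi, size=4 * n + 16))
        keep = []
        last = -10 ** 9
        for p in cand:
            if p - last >= spacing:
                keep.append(int(p))
                last = p
            if len(keep) == n:
                break
        if len(keep) == n:
            pos = np.array(keep)
            return pos[rng.permutation(n)]
    raise SimulationError(
        f"cannot place {n} variants with min_spacing={config.min_spacing} "
        f"in [{lo}, {hi})"
    )


def _random_indel(rng, ref: str, pos: int, length: int) -> tuple[int, str, object]:
    """A left-normalized insertion or deletion of ``length`` anchored near
    ``pos``.  Variants are stored left-aligned so the scanner, the truth
    VCF and external representations all share one canonical key."""
    if rng.random() < 0.5:
        seq = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
        a, s = left_align_insertion(ref, pos, seq)
        return a, INS, s
    start = left_align_deletion(ref, pos + 1, length)
    return start, DEL, length


def plant_truth(reference: str, config: SimConfig, rng: np.random.Generator | None = None) -> TruthSet:
    """Place germline and somatic variants on the reference.

    Somatic INDEL lengths are drawn from ``{1..indel_length_max}`` with the
    first three forced to 1, 2 and 3 so every length class is represented
    whenever at least three INDELs are requested.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n_total = config.n_germline + config.n_somatic_snv + config.n_somatic_indel
    positions = _draw_positions(rng, config, n_total)
    truth = TruthSet()
    idx = 0

    def next_pos() -> int:
        nonlocal idx
        p = int(positions[idx])
        idx += 1
        return p

    for _ in range(config.n_germline):
        pos = next_pos()
        zyg = "het" if rng.random() < 0.5 else "hom"
        af = 0.5 if zyg == "het" else 1.0
        if rng.random() < config.germline_indel_fraction:
            pos2, kind, alt = _random_indel(rng, reference, pos, int(rng.integers(1, 6)))
            truth.germline.append(Variant(config.chrom, pos2, kind, alt, af, False, zyg))
        else:
            ref_b = reference[pos]
            alt_b = rng.choice([b for b in BASES if b != ref_b])
            truth.germline.append(Variant(config.chrom, pos, SNV, str(alt_b), af, False, zyg))

    for _ in range(config.n_somatic_snv):
        pos = next_pos()
        ref_b = reference[pos]
        alt_b = rng.choice([b for b in BASES if b != ref_b])
        af = float(rng.choice(np.asarray(config.somatic_af_means)))
        truth.somatic.append(Variant(config.chrom, pos, SNV, str(alt_b), af, True))

    n_ind = config.n_somatic_indel
    lengths = list(range(1, min(3, n_ind) + 1))
    if n_ind > 3:
        lengths += list(rng.integers(1, config.indel_length_max + 1, size=n_ind - 3))
    lengths = [int(lengths[i]) for i in rng.permutation(len(lengths))]
    for length in lengths:
        pos = next_pos()
        pos2, kind, alt = _random_indel(rng, reference, pos, length)
        af = float(rng.choice(np.asarray(config.somatic_af_means)))
        truth.somatic.append(Variant(config.chrom, pos2, kind, alt, af, True))

    truth.germline.sort(key=lambda v: v.pos)
    truth.somatic.sort(key=lambda v: v.pos)
    return truth


def _build_read(ref: str, start: int, read_len: int, events: list[Variant],
                carry: list[bool]) -> tuple[str, list[tuple[int, int]]]:
    """Construct read sequence + CIGAR from ``start`` over the reference,
    applying the carried variants.  CIGAR ops use BAM codes (0=M, 1=I, 2=D)."""
    seq: list[str] = []
    cig: list[tuple[int, int]] = []

    def emit(op: int, ln: int) -> None:
        if ln <= 0:
            return
        if cig and cig[-1][0] == op:
            cig[-1] = (op, cig[-1][1] + ln)
        else:
            cig.append((op, ln))

    rp = start
    qlen = 0
    ev = [(v, c) for v, c in zip(events, carry) if c and v.pos >= start]
    ev.sort(key=lambda vc: vc[0].pos)
    qi = 0
    L = len(ref)
    while qlen < read_len and rp < L:
        nxt = ev[qi][0].pos if qi < len(ev) else L
        if nxt > rp:
            take = min(nxt - rp, read_len - qlen)
            seq.append(ref[rp:rp + take])
            emit(0, take)
            rp += take
            qlen += take
            continue
        v = ev[qi][0]
        qi += 1
        if v.kind == SNV:
            seq.append(v.alt)
            emit(0, 1)
            rp += 1
            qlen += 1
        elif v.kind == INS:
            seq.append(ref[rp])
            emit(0, 1)
            rp += 1
            qlen += 1
            ins = v.alt[: read_len - qlen]
            if ins:
                seq.append(ins)
                emit(1, len(ins))
                qlen += len(ins)
        else:  # DEL: pos is the first deleted base
            if rp == start:
                continue  # cannot start an alignment with a deletion
            emit(2, int(v.alt))
            rp += int(v.alt)
    while cig and cig[-1][0] == 2:
        cig.pop()  # trailing deletion carries no evidence
    return "".join(seq), cig


def _make_header(config: SimConfig) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": config.chrom, "LN": config.ref_length}],
    })


def _write_sample_bam(path: str, ref: str, truth: TruthSet, config: SimConfig,
                      coverage: float, tumor_fraction: float, rng: np.random.Generator) -> None:
    """Write one coordinate-sorted, indexed BAM.

    ``tumor_fraction`` is the probability a read is drawn from the tumor
    genome (carrying somatic alleles); the remainder come from the normal
    genome (germline only).
    """
    read_len = config.read_length
    n_reads = int(round(config.ref_length * coverage / read_len))
    if n_reads <= 0:
        raise SimulationError("configured coverage yields zero reads")
    starts = np.sort(rng.integers(0, config.ref_length - read_len + 1, size=n_reads))
    variants = truth.all_variants
    vpos = np.array([v.pos for v in variants], dtype=np.int64)
    from_tumor = rng.random(n_reads) < tumor_fraction
    is_rev = rng.random(n_reads) < 0.5
    ref_bytes = np.frombuffer(ref.encode(), dtype=np.uint8)

    with pysam.AlignmentFile(path, "wb", header=_make_header(config)) as bam:
        for i in range(n_reads):
            start = int(starts[i])
            lo = np.searchsorted(vpos, start)
            hi = np.searchsorted(vpos, start + read_len + config.indel_length_max + 1)
            window_vars = [variants[j] for j in range(lo, hi)]
            carry = []
            for v in window_vars:
                if v.somatic and not from_tumor[i]:
                    carry.append(False)
                else:
                    carry.append(bool(rng.random() < v.target_af))
            seq, cig = _build_read(ref, start, read_len, window_vars, carry)
            if not seq or not cig:
                continue
            seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            n_err = rng.binomial(len(seq_arr), config.base_error_rate)
            if n_err:
                err_pos = rng.integers(0, len(seq_arr), size=n_err)
                for p in err_pos:
                    old = chr(seq_arr[p])
                    choices = [b for b in BASES if b != old]
                    seq_arr[p] = ord(choices[int(rng.integers(0, len(choices)))])
            final_seq = seq_arr.tobytes().decode()
            # edit distance vs reference along the alignment
            nm = 0
            rp, qp = start, 0
            for op, ln in cig:
                if op == 0:
                    nm += int(np.count_nonzero(seq_arr[qp:qp + ln] != ref_bytes[rp:rp + ln]))
                    rp += ln
                    qp += ln
                elif op == 1:
                    nm += ln
                    qp += ln
                else:
                    nm += ln
                    rp += ln
            a = pysam.AlignedSegment(header=bam.header)
            a.query_name = f"r{i:07d}"
            a.query_sequence = final_seq
            a.flag = 16 if is_rev[i] else 0
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = 60
            a.cigartuples = cig
            a.query_qualities = rng.integers(25, 41, size=len(final_seq)).tolist()
            a.set_tag("NM", int(nm))
            a.set_tag("AS", int(max(0, len(final_seq) - 5 * nm)))
            bam.write(a)
    pysam.index(path)


def write_truth_vcf(path: str, ref: str, variants: list[Variant], config: SimConfig,
                    germline: bool = False) -> None:
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    header.contigs.add(config.chrom, length=config.ref_length)
    header.info.add("TYPE", 1, "String", "Variant type: SNV, INS or DEL")
    header.info.add("TAF", 1, "Float", "Target (within-genome) allele fraction")
    if germline:
        header.info.add("ZYG", 1, "String", "Germline zygosity")
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for v in sorted(variants, key=lambda x: (x.pos, x.kind)):
            pos1, ref_a, alt_a = vcf_alleles(ref, v.pos, v.kind, v.alt)
            rec = vcf.new_record(contig=config.chrom, start=pos1 - 1,
                                 alleles=(ref_a, alt_a))
            rec.info["TYPE"] = v.kind
            rec.info["TAF"] = float(v.target_af)
            if germline and v.zygosity:
                rec.info["ZYG"] = v.zygosity
            vcf.write(rec)


def read_truth_vcf(path: str) -> list[Variant]:
    """Parse a truth VCF back into internal-convention variants."""
    out = []
    for rec in read_vcf(path):
        chrom, pos, kind, alt = rec.key()
        taf = float(rec.info.get("TAF", 0.5))
        zyg = rec.info.get("ZYG")
        out.append(Variant(chrom, pos, kind, alt, taf, zyg is None, zyg))
    return out


def simulate_pair(reference: str, truth: TruthSet, config: SimConfig, outdir: str,
                  write_reference: bool = True, tumor_name: str = "tumor",
                  normal_name: str = "normal") -> SimOutput:
    """Simulate the tumor and normal BAMs plus truth VCFs into ``outdir``."""
    config.validate()
    if config.coverage_tumor <= 0 or config.coverage_normal <= 0:
        raise SimulationError("coverage must be positive")
    os.makedirs(outdir, exist_ok=True)
    fasta = os.path.join(outdir, "reference.fa")
    if write_reference or not os.path.exists(fasta):
        with open(fasta, "w") as fh:
            fh.write(f">{config.chrom}\n")
            for i in range(0, len(reference), 70):
                fh.write(reference[i:i + 70] + "\n")
        pysam.faidx(fasta)
    tumor_bam = os.path.join(outdir, f"{tumor_name}.bam")
    normal_bam = os.path.join(outdir, f"{normal_name}.bam")
    rng_t = np.random.default_rng(config.seed + 11)
    rng_n = np.random.default_rng(config.seed + 13)
    _write_sample_bam(tumor_bam, reference, truth, config, config.coverage_tumor,
                      config.tumor_purity, rng_t)
    _write_sample_bam(normal_bam, reference, truth, config, config.coverage_normal,
                      1.0 - config.normal_purity, rng_n)
    truth_vcf = os.path.join(outdir, "truth_somatic.vcf")
    germline_vcf = os.path.join(outdir, "truth_germline.vcf")
    write_truth_vcf(truth_vcf, reference, truth.somatic, config)
    write_truth_vcf(germline_vcf, reference, truth.germline, config, germline=True)
    return SimOutput(fasta, reference, tumor_bam, normal_bam, truth_vcf,
                     germline_vcf, truth, config)


def simulate(config: SimConfig, outdir: str) -> SimOutput:
    """End-to-end convenience: reference -> truth -> BAM pair."""
    reference = generate_reference(config.ref_length, config.seed, chrom=config.chrom)
    truth = plant_truth(reference, config)
    return simulate_pair(reference, truth, config, outdir)


def resimulate_tumor(sim: SimOutput, tumor_purity: float, name: str = "tumor_lowpurity") -> str:
    """Regenerate only the tumor BAM at a different purity, same truth."""
    config = replace(sim.config, tumor_purity=tumor_purity)
    outdir = os.path.dirname(sim.tumor_bam)
    path = os.path.join(outdir, f"{name}.bam")
    rng = np.random.default_rng(config.seed + 17)
    _write_sample_bam(path, sim.reference, sim.truth, config, config.coverage_tumor,
                      tumor_purity, rng)
    return path
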