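"""Shared variant primitives: coordinate conventions, normalization, VCF text parsing.

Coordinate conventions used throughout the package (0-based internally):

* SNV  -- ``pos`` is the substituted base.
* INS  -- ``pos`` is the anchor base; the insertion occurs between ``pos``
  and ``pos + 1``.  ``alt`` is the inserted sequence (without the anchor).
* DEL  -- ``pos`` is the first deleted base.  ``alt`` is the deletion
  length (int).

VCF records are 1-based and anchored: an insertion at anchor ``a`` is
written at POS ``a + 1`` with REF the anchor base; a deletion of
``[d, d + L)`` is written at POS ``d`` (the 1-based coordinate of the base
before the run) with REF covering the anchor plus the deleted bases.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterator

SNV = "SNV"
INS = "INS"
DEL = "DEL"

BASES = "ACGT"


class VcfParseError(ValueError):
    """Malformed VCF content; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def left_align_insertion(ref: str, anchor: int, seq: str) -> tuple[int, str]:
    """Shift an insertion (after 0-based ``anchor``) to its leftmost
    equivalent placement against ``ref``."""
    while anchor > 0 and seq[-1] == ref[anchor]:
        seq = ref[anchor] + seq[:-1]
        anchor -= 1
    return anchor, seq


def left_align_deletion(ref: str, start: int, length: int) -> int:
    """Shift a deletion of ``ref[start:start+length]`` to its leftmost
    equivalent start position."""
    while start > 1 and ref[start - 1] == ref[start + length - 1]:
        start -= 1
    return start


@dataclass(frozen=True)
class VcfRecord:
    """One data line of a VCF file (single ALT)."""

    chrom: str
    pos1: int  # 1-based, as printed
    ref: str
    alt: str
    qual: float | None = None
    filter: str = "."
    info: dict = field(default_factory=dict)

    @property
    def kind(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return SNV
        if len(self.alt) > len(self.ref) and self.alt.startswith(self.ref):
            return INS
        if len(self.ref) > len(self.alt) and self.ref.startswith(self.alt):
            return DEL
        return "COMPLEX"

    def key(self, ref_seq: str | None = None) -> tuple:
        """Internal-convention key ``(chrom, pos0, type, alt)``.

        If ``ref_seq`` is given, INDELs are left-aligned against it first so
        that differently represented but equivalent records unify.
        """
        kind = self.kind
        if kind == SNV:
            return (self.chrom, self.pos1 - 1, SNV, self.alt)
        if kind == INS:
            anchor = self.pos1 - 1 + len(self.ref) - 1
            seq = self.alt[len(self.ref):]
            if ref_seq is not None:
                anchor, seq = left_align_insertion(ref_seq, anchor, seq)
            return (self.chrom, anchor, INS, seq)
        if kind == DEL:
            start = self.pos1 - 1 + len(self.alt)
            length = len(self.ref) - len(self.alt)
            if ref_seq is not None:
                start = left_align_deletion(ref_seq, start, length)
            return (self.chrom, start, DEL, length)
        return (self.chrom, self.pos1 - 1, "COMPLEX", self.alt)


def read_vcf(path: str) -> Iterator[VcfRecord]:
    """Parse a (possibly gzipped) VCF file, yielding one record per ALT
    allele.  Raises :class:`VcfParseError` with the offending line number."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise VcfParseError(
                    f"expected >=8 tab-separated fields, got {len(fields)}", lineno
                )
            chrom, pos_s, _id, ref, alts, qual_s, filt, info_s = fields[:8]
            try:
                pos1 = int(pos_s)
            except ValueError:
                raise VcfParseError(f"non-integer POS {pos_s!r}", lineno) from None
            if pos1 < 1:
                raise VcfParseError(f"POS must be >=1, got {pos1}", lineno)
            if not ref or any(b not in "ACGTN" for b in ref.upper()):
                raise VcfParseError(f"invalid REF allele {ref!r}", lineno)
            qual = None if qual_s in (".", "") else float(qual_s)
            info: dict = {}
            if info_s not in (".", ""):
                for item in info_s.split(";"):
                    if "=" in item:
                        k, v = item.split("=", 1)
                        info[k] = v
                    else:
                        info[item] = True
            for alt in alts.split(","):
                if alt in (".", "*", "<NON_REF>"):
                    continue
                yield VcfRecord(chrom, pos1, ref.upper(), alt.upper(), qual, filt, info)


def vcf_alleles(ref_seq: str, pos: int, kind: str, alt) -> tuple[int, str, str]:
    """Convert an internal-convention variant to VCF ``(pos1, REF, ALT)``."""
    if kind == SNV:
        return pos + 1, ref_seq[pos], alt
    if kind == INS:
        anchor = ref_seq[pos]
        return pos + 1, anchor, anchor + alt
    if kind == DEL:
        length = int(alt)
        if pos < 1:
            raise ValueError("deletion at contig start cannot be anchored")
        return pos, ref_seq[pos - 1: pos + length], ref_seq[pos - 1]
    raise ValueError(f"unknown variant kind {kind!r}")
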