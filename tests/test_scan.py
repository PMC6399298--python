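"""Scanner: pileup statistics, liberal filters, dbSNP exclusion, merging."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings, strategies as st

from somanet.scan import (CandidateSite, FilterConfig, SiteStats, exclude_dbsnp,
                          filter_candidates, merge_external, read_candidates_tsv,
                          scan_region, write_candidates_tsv)
from somanet.variants import DEL, INS, SNV


def make_stats(ref_base="C", depth=10, alts=None, ins=None, dels=None):
    st_ = SiteStats("chrS", 100, ref_base, depth)
    for base, count, bq in (alts or []):
        st_.base_counts[base] = count
        st_.base_bq[base] = bq
    st_.base_counts[ref_base] = depth - sum(c for _, c, _ in (alts or []))
    for seq, count in (ins or []):
        st_.ins_counts[seq] = count
        st_.ins_bq[seq] = 30.0
    for ln, count in (dels or []):
        st_.del_counts[ln] = count
    return st_


class TestFilterRules:
    """The six worked filter examples, as printed rules."""

    def test_snv_kept_on_af_branch(self):
        # AF = 0.03 with single read support but good quality -> kept
        out = filter_candidates([make_stats(depth=100, alts=[("T", 3, 30.0)])])
        assert len(out) == 1 and out[0].kind == SNV

    def test_snv_kept_on_support_branch(self):
        # AF 0.02 < 0.03 but 3 supporting reads ("more than two") -> kept
        out = filter_candidates([make_stats(depth=150, alts=[("T", 3, 25.0)])])
        assert len(out) == 1

    def test_snv_dropped_on_low_quality(self):
        # same support but mean BQ 15 <= 19 -> dropped
        out = filter_candidates([make_stats(depth=150, alts=[("T", 3, 15.0)])])
        assert out == []

    def test_one_base_insertion_kept_on_support(self):
        # AF 0.015 but 2 reads ("more than one") -> kept
        out = filter_candidates([make_stats(depth=140, ins=[("A", 2)])])
        assert len(out) == 1 and out[0].kind == INS

    def test_long_deletion_needs_higher_af(self):
        # 3-base deletion at AF 0.02 -> dropped (needs AF >= 0.03)
        out = filter_candidates([make_stats(depth=100, dels=[(3, 2)])])
        assert out == []

    def test_long_deletion_kept_at_af(self):
        out = filter_candidates([make_stats(depth=100, dels=[(3, 3)])])
        assert len(out) == 1 and out[0].kind == DEL

    def test_wes_preset_relaxes_bq(self):
        stats = [make_stats(depth=100, alts=[("T", 5, 16.0)])]
        assert filter_candidates(stats, FilterConfig.preset("wgs")) == []
        assert len(filter_candidates(stats, FilterConfig.preset("wes"))) == 1

    def test_pacbio_preset_raises_af(self):
        stats = [make_stats(depth=100, alts=[("T", 8, 30.0)], ins=[("A", 12)])]
        out = filter_candidates(stats, FilterConfig.preset("pacbio"))
        # SNV AF 0.08 < 0.1 dropped; 1-base ins AF 0.12 < 0.15 dropped
        assert out == []

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            FilterConfig.preset("nanopore")

    def test_multiallelic_yields_one_candidate_per_alt(self):
        out = filter_candidates([make_stats(depth=10, alts=[("T", 3, 30.0),
                                                            ("G", 3, 30.0)])])
        assert {c.alt for c in out} == {"T", "G"}

    @given(af1=st.floats(0.0, 0.5), af2=st.floats(0.0, 0.5))
    @settings(max_examples=100, deadline=None)
    def test_af_threshold_monotonicity(self, af1, af2):
        """Raising any AF threshold never increases the candidate count."""
        lo, hi = sorted([af1, af2])
        stats = [make_stats(depth=100, alts=[("T", k, 30.0)], ins=[("AG", k)],
                            dels=[(1, k)]) for k in (1, 2, 3, 5, 9, 30)]
        def count(cfg):
            return len(filter_candidates(stats, cfg))
        base = FilterConfig(snv_alt_support_floor=10**9, indel1_support_floor=10**9)
        import dataclasses
        for field in ("snv_min_af", "indel1_min_af", "indelN_min_af"):
            c_lo = dataclasses.replace(base, **{field: lo})
            c_hi = dataclasses.replace(base, **{field: hi})
            assert count(c_hi) <= count(c_lo)

    def test_decision_pure_function_of_stats(self):
        stats = make_stats(depth=50, alts=[("A", 4, 22.0)], ins=[("AT", 3)])
        a = filter_candidates([stats])
        b = filter_candidates([stats])
        assert [(c.key, c.af, c.support) for c in a] == \
               [(c.key, c.af, c.support) for c in b]


class TestScanRegion:
    def test_pileup_counts_match_bruteforce(self, small_sim):
        """Scanner allele counts equal a per-read brute-force recount (via
        pysam pileup) at 100 random scanned loci."""
        stats = {s.pos: s for s in scan_region(small_sim.tumor_bam,
                                               small_sim.reference_fasta)}
        rng = np.random.default_rng(5)
        positions = rng.choice(sorted(stats), size=100, replace=False)
        bam = pysam.AlignmentFile(small_sim.tumor_bam)
        ref = small_sim.reference
        for pos in positions:
            s = stats[pos]
            counts = {b: 0 for b in "ACGT"}
            span = 0
            for col in bam.pileup("chrS", pos, pos + 1, truncate=True,
                                  min_base_quality=0, max_depth=100000):
                for pr in col.pileups:
                    span += 1
                    if pr.is_del or pr.query_position is None:
                        continue
                    counts[pr.alignment.query_sequence[pr.query_position]] += 1
            for b in "ACGT":
                assert s.base_counts.get(b, 0) == counts[b], (pos, b)
            assert s.depth == span

    def test_insertion_evidence_at_anchor(self, small_sim):
        ins_truth = [v for v in small_sim.truth.somatic if v.kind == INS]
        stats = {(s.pos): s for s in scan_region(small_sim.tumor_bam,
                                                 small_sim.reference_fasta)}
        found = sum(1 for v in ins_truth
                    if v.pos in stats and str(v.alt) in stats[v.pos].ins_counts)
        assert found == len(ins_truth)

    def test_deletion_evidence_at_first_deleted_base(self, small_sim):
        del_truth = [v for v in small_sim.truth.somatic if v.kind == DEL]
        stats = {(s.pos): s for s in scan_region(small_sim.tumor_bam,
                                                 small_sim.reference_fasta)}
        found = sum(1 for v in del_truth
                    if v.pos in stats and int(v.alt) in stats[v.pos].del_counts)
        assert found == len(del_truth)

    def test_missing_index_rejected(self, small_sim, tmp_path):
        import shutil
        orphan = tmp_path / "noindex.bam"
        shutil.copy(small_sim.tumor_bam, orphan)
        with pytest.raises(IOError, match="index"):
            list(scan_region(str(orphan), small_sim.reference_fasta))

    def test_chromosome_mismatch_rejected(self, small_sim, tmp_path):
        import pysam as ps
        alt_fa = tmp_path / "other.fa"
        alt_fa.write_text(">chrOther\n" + "ACGT" * 300 + "\n")
        ps.faidx(str(alt_fa))
        with pytest.raises(ValueError, match="chrS"):
            list(scan_region(small_sim.tumor_bam, str(alt_fa)))

    def test_candidate_recall_on_liberal_filters(self, small_sim):
        """On pure tumor with AF targets >= 0.2, >=99% of truth sites
        survive the liberal filters."""
        cands = filter_candidates(scan_region(small_sim.tumor_bam,
                                              small_sim.reference_fasta))
        keys = {(c.pos, c.kind) for c in cands}
        truth = [v for v in small_sim.truth.somatic if v.target_af >= 0.2]
        hit = sum(1 for v in truth if (v.pos, v.kind) in keys)
        assert hit / len(truth) >= 0.99


def _write_vcf(path, records):
    """records: list of (chrom,pos1,ref,alt) or with info dict appended."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            chrom, pos1, ref, alt = r[:4]
            info = r[4] if len(r) > 4 else "."
            fh.write(f"{chrom}\t{pos1}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")


class TestDbsnpExclusion:
    CANDS = [CandidateSite("chrS", 99, SNV, "T", 0.2, 5, 30.0),
             CandidateSite("chrS", 199, INS, "AG", 0.2, 5, 30.0)]

    def test_same_alt_removed(self, tmp_path):
        p = str(tmp_path / "db.vcf")
        _write_vcf(p, [("chrS", 100, "C", "T")])
        out = exclude_dbsnp(self.CANDS, p)
        assert [c.pos for c in out] == [199]

    def test_empty_dbsnp_is_identity(self, tmp_path):
        p = str(tmp_path / "db.vcf")
        _write_vcf(p, [])
        assert exclude_dbsnp(self.CANDS, p) == self.CANDS

    def test_different_alt_kept_in_allele_aware_mode(self, tmp_path):
        p = str(tmp_path / "db.vcf")
        _write_vcf(p, [("chrS", 100, "C", "G")])
        assert len(exclude_dbsnp(self.CANDS, p, allele_aware=True)) == 2
        assert len(exclude_dbsnp(self.CANDS, p, allele_aware=False)) == 1


class TestMergeExternal:
    def test_external_only_site_marked(self, tmp_path):
        p = str(tmp_path / "ext.vcf")
        _write_vcf(p, [("chrS", 300, "A", "G")])
        merged = merge_external(self.base_cands(), [p])
        ext = [c for c in merged if c.source == "external"]
        assert len(ext) == 1 and ext[0].pos == 299 and ext[0].kind == SNV

    def test_duplicate_collapsed(self, tmp_path):
        p = str(tmp_path / "ext.vcf")
        _write_vcf(p, [("chrS", 100, "C", "T")])
        merged = merge_external(self.base_cands(), [p])
        assert len(merged) == len(self.base_cands())
        assert all(c.source == "scan" for c in merged)

    def test_no_externals_is_identity(self):
        assert merge_external(self.base_cands(), []) == self.base_cands()

    @staticmethod
    def base_cands():
        return [CandidateSite("chrS", 99, SNV, "T", 0.2, 5, 30.0)]


def test_candidates_tsv_round_trip(tmp_path):
    cands = [CandidateSite("chrS", 10, SNV, "T", 0.25, 5, 31.5),
             CandidateSite("chrS", 20, INS, "ACG", 0.1, 3, 28.0),
             CandidateSite("chrS", 30, DEL, 2, 0.5, 9, 0.0, source="external")]
    path = str(tmp_path / "c.tsv")
    write_candidates_tsv(cands, path)
    back = read_candidates_tsv(path)
    assert [(c.key, c.support, c.source) for c in back] == \
           [(c.key, c.support, c.source) for c in cands]
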