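"""Featurizer: column maps, read projection, matrix invariants, oracle checks."""

import numpy as np
import pysam
import pytest

from somanet.featurize import (ChannelRegistry, MatrixDataset, attach_external_features,
                               build_column_map, build_matrix, featurize_candidates,
                               project_read, N_COLS)
from somanet.scan import CandidateSite, filter_candidates, scan_region
from somanet.variants import INS, SNV

CHROM = "chrS"


def make_read(start, cigar, seq, header=None, name="r1", qual=30):
    header = header or pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": CHROM, "LN": 10000}]})
    a = pysam.AlignedSegment(header=header)
    a.query_name = name
    a.query_sequence = seq
    a.reference_id = 0
    a.reference_start = start
    a.mapping_quality = 60
    a.cigarstring = cigar
    a.query_qualities = [qual] * len(seq)
    a.set_tag("NM", 0)
    a.set_tag("AS", len(seq))
    return a


REF = "GGATCGTACGATCGGATTACGGCA" + "ACGT" * 200  # candidate windows live < 24


class TestColumnMap:
    def cand(self, pos=10, kind=SNV, alt="T"):
        return CandidateSite(CHROM, pos, kind, alt, 0.5, 5, 30.0)

    def test_no_insertions_gives_seven_ref_columns(self):
        reads = [make_read(5, "12M", REF[5:17])]
        cm = build_column_map(reads, [], REF, self.cand())
        assert [d[0] for d in cm.columns] == ["ref"] * 7
        assert [d[1] for d in cm.columns] == list(range(7, 14))
        assert cm.candidate_column == 3

    def test_distinct_insertions_share_slots(self):
        # reads inserting A and C after the same anchor share one column
        # (anchor base G, so neither insertion left-shifts)
        r1 = make_read(5, "5M1I7M", REF[5:10] + "A" + REF[10:17])
        r2 = make_read(5, "5M1I7M", REF[5:10] + "C" + REF[10:17])
        cm = build_column_map([r1, r2], [], REF, self.cand())
        ins_cols = [d for d in cm.columns if d[0] == "ins"]
        assert len(ins_cols) == 1
        assert ins_cols[0][1] == 9  # anchored at the base before the insertion

    def test_slots_sized_by_longest_insertion(self):
        r1 = make_read(5, "4M1I8M", REF[5:9] + "A" + REF[9:17])
        r2 = make_read(5, "4M3I8M", REF[5:9] + "ATT" + REF[9:17])
        cm = build_column_map([r1, r2], [], REF, self.cand())
        assert sum(1 for d in cm.columns if d[0] == "ins") == 3

    def test_huge_insertion_truncated_to_budget(self):
        ins = "A" * 40
        r = make_read(7, "4M40I8M", REF[7:11] + ins + REF[11:19])
        cm = build_column_map([r], [], REF, self.cand())
        assert cm.n_columns <= N_COLS
        assert sum(1 for d in cm.columns if d[0] == "ref") == 7  # flanks kept

    def test_far_insertions_truncated_first(self):
        near = make_read(5, "6M20I8M", REF[5:11] + "G" * 20 + REF[11:19])  # anchor 10
        far = make_read(5, "3M20I8M", REF[5:8] + "G" * 20 + REF[8:19])     # anchor 7
        cm = build_column_map([near, far], [], REF, self.cand())
        n_near = sum(1 for d in cm.columns if d[0] == "ins" and d[1] == 10)
        n_far = sum(1 for d in cm.columns if d[0] == "ins" and d[1] == 7)
        assert cm.n_columns <= N_COLS and n_near > n_far

    def test_insertion_candidate_column_is_first_slot(self):
        r = make_read(5, "6M2I8M", REF[5:11] + "CA" + REF[11:19])
        cm = build_column_map([r], [], REF, self.cand(pos=10, kind=INS, alt="CA"))
        d = cm.columns[cm.candidate_column]
        assert d == ("ins", 10, 0)

    def test_candidate_near_edge_rejected(self):
        with pytest.raises(ValueError, match="edge"):
            build_column_map([], [], REF, self.cand(pos=1))


class TestProjectRead:
    def cand(self, pos=10):
        return CandidateSite(CHROM, pos, SNV, "T", 0.5, 5, 30.0)

    def test_full_match_projects_reference(self):
        reads = [make_read(5, "12M", REF[5:17])]
        cm = build_column_map(reads, [], REF, self.cand())
        syms, _ = project_read(reads[0], cm, REF)
        assert "".join(syms) == REF[7:14]

    def test_insertion_and_gap_for_non_inserting_read(self):
        r_ins = make_read(5, "4M1I8M", REF[5:9] + "A" + REF[9:17])
        r_ref = make_read(5, "12M", REF[5:17])
        cm = build_column_map([r_ins, r_ref], [], REF, self.cand())
        ins_col = next(i for i, d in enumerate(cm.columns) if d[0] == "ins")
        syms_ins, _ = project_read(r_ins, cm, REF)
        syms_ref, _ = project_read(r_ref, cm, REF)
        assert syms_ins[ins_col] == "A"
        assert syms_ref[ins_col] == "-"

    def test_deletion_projects_gap(self):
        r = make_read(5, "5M2D7M", REF[5:10] + REF[12:19])
        cm = build_column_map([r], [], REF, self.cand())
        syms, _ = project_read(r, cm, REF)
        assert syms[cm.ref_col(10)] == "-" and syms[cm.ref_col(11)] == "-"
        assert syms[cm.ref_col(12)] == REF[12]

    def test_columns_outside_span_absent(self):
        r = make_read(9, "6M", REF[9:15])
        cm = build_column_map([r], [], REF, self.cand())
        syms, _ = project_read(r, cm, REF)
        assert syms[cm.ref_col(7)] is None and syms[cm.ref_col(8)] is None
        assert syms[cm.ref_col(9)] == REF[9]

    def test_malformed_read_rejected(self):
        r = make_read(5, "12M", REF[5:17])
        r.cigarstring = "13M"
        cm = build_column_map([], [], REF, self.cand())
        with pytest.raises(ValueError, match="mismatch"):
            project_read(r, cm, REF)


def naive_msa_counts(reads, colmap, reference):
    """Independent oracle: materialize each read's gapped window string via
    pysam aligned pairs, then count symbols per column."""
    counts = np.zeros((5, colmap.n_columns))
    row = {b: i for i, b in enumerate("ACGT")}
    row["-"] = 4
    lo, hi = colmap.window
    col_of_ref = {d[1]: i for i, d in enumerate(colmap.columns) if d[0] == "ref"}
    ins_cols = {}
    for i, d in enumerate(colmap.columns):
        if d[0] == "ins":
            ins_cols.setdefault(d[1], []).append(i)
    from somanet.variants import left_align_insertion
    for read in reads:
        sym = {}
        pairs = read.get_aligned_pairs()
        # base/deletion symbols from aligned pairs
        for q, r in pairs:
            if r is None or not (lo <= r <= hi):
                continue
            sym[col_of_ref[r]] = "-" if q is None else read.query_sequence[q]
        # insertions: consecutive q with r None, anchored at previous r
        k = 0
        while k < len(pairs):
            q, r = pairs[k]
            if q is not None and r is None and k > 0 and pairs[k - 1][1] is not None:
                anchor = pairs[k - 1][1]
                run = []
                while k < len(pairs) and pairs[k][1] is None and pairs[k][0] is not None:
                    run.append(read.query_sequence[pairs[k][0]])
                    k += 1
                a, s = left_align_insertion(reference, anchor, "".join(run))
                for off, col in enumerate(ins_cols.get(a, [])):
                    if off < len(s):
                        sym[col] = s[off]
            else:
                k += 1
        for anchor, cols in ins_cols.items():
            if col_of_ref.get(anchor) in sym:
                for col in cols:
                    sym.setdefault(col, "-")
        for col, s in sym.items():
            counts[row[s], col] += 1
    return counts


class TestMatrix:
    def test_frequency_normalization_example(self):
        # 3 A, 2 T, 1 gap among six covering reads -> (0.5, 0, 0, 1/3, 1/6)
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"}, "SQ": [{"SN": CHROM, "LN": 10000}]})
        reads = []
        base_at_10 = {"A": 3, "T": 2}
        i = 0
        for b, n in base_at_10.items():
            for _ in range(n):
                seq = REF[5:10] + b + REF[11:17]
                reads.append(make_read(5, "12M", seq, header, name=f"r{i}"))
                i += 1
        reads.append(make_read(5, "5M1D7M", REF[5:10] + REF[11:19][:7], header,
                               name="rdel"))
        cand = CandidateSite(CHROM, 10, SNV, "A", 0.5, 3, 30.0)
        m = build_matrix(reads, [], REF, cand)
        col = m.colmap.candidate_column
        np.testing.assert_allclose(m.values[1, :, col],
                                   [0.5, 0.0, 0.0, 2 / 6, 1 / 6], atol=1e-6)

    def test_channel_counts(self):
        assert len(ChannelRegistry.build("standalone")) == 26
        assert len(ChannelRegistry.build("ensemble")) == 119

    def test_registry_names_unique_and_hashing(self):
        r1 = ChannelRegistry.build("standalone")
        r2 = ChannelRegistry.build("ensemble")
        assert len(set(r1.names)) == 26
        assert r1.hash != r2.hash

    def test_empty_window_emits_zero_matrix(self):
        cand = CandidateSite(CHROM, 10, SNV, "T", 0.5, 5, 30.0)
        m = build_matrix([], [], REF, cand)
        assert m.values.shape == (26, 5, 32)
        assert m.values[1].sum() == 0 and m.values[2].sum() == 0
        assert m.values[0].sum() == 7  # reference one-hot intact

    def test_reference_channel_one_hot(self):
        r = make_read(5, "4M2I8M", REF[5:9] + "AA" + REF[9:17])
        cand = CandidateSite(CHROM, 10, SNV, "T", 0.5, 5, 30.0)
        m = build_matrix([r], [], REF, cand)
        n = m.colmap.n_columns
        assert np.all(m.values[0, :, :n].sum(axis=0) == 1)
        for i, d in enumerate(m.colmap.columns):
            if d[0] == "ins":
                assert m.values[0, 4, i] == 1  # gap row for ins slots

    def test_position_channel_marks_candidate_column(self):
        cand = CandidateSite(CHROM, 10, SNV, "T", 0.5, 5, 30.0)
        m = build_matrix([], [], REF, cand)
        assert np.all(m.values[3, :, m.colmap.candidate_column] == 1)
        assert m.values[3].sum() == 5

    def test_matrix_values_bounded(self, small_sim):
        cands = filter_candidates(scan_region(small_sim.tumor_bam,
                                              small_sim.reference_fasta))[:40]
        ds = featurize_candidates(cands, small_sim.tumor_bam, small_sim.normal_bam,
                                  small_sim.reference_fasta)
        assert ds.values.min() >= 0 and ds.values.max() <= 1 + 1e-6

    def test_frequency_channels_match_naive_msa(self, small_sim):
        """Implementation vs naive-MSA oracle on 200 random candidates:
        integer counts must agree exactly before normalization."""
        rng = np.random.default_rng(8)
        positions = rng.integers(200, small_sim.config.ref_length - 200, size=200)
        bam_t = pysam.AlignmentFile(small_sim.tumor_bam)
        ref = small_sim.reference
        from somanet.featurize import _fetch_window, _sample_channels
        for pos in positions:
            cand = CandidateSite(CHROM, int(pos), SNV, "A", 0.5, 3, 30.0)
            reads = _fetch_window(bam_t, CHROM, int(pos))
            cm = build_column_map(reads, [], ref, cand)
            impl = _sample_channels(reads, cm, ref, 100.0)["counts"]
            oracle = naive_msa_counts(reads, cm, ref)
            np.testing.assert_array_equal(impl, oracle)

    def test_determinism(self, small_sim):
        cands = filter_candidates(scan_region(small_sim.tumor_bam,
                                              small_sim.reference_fasta))[:10]
        a = featurize_candidates(cands, small_sim.tumor_bam, small_sim.normal_bam,
                                 small_sim.reference_fasta)
        b = featurize_candidates(cands, small_sim.tumor_bam, small_sim.normal_bam,
                                 small_sim.reference_fasta)
        np.testing.assert_array_equal(a.values, b.values)


class TestExternalFeatures:
    def cand_matrix(self, mode):
        cand = CandidateSite(CHROM, 10, SNV, "T", 0.5, 5, 30.0)
        return build_matrix([], [], REF, cand, mode=mode)

    def test_empty_table_leaves_slots_zero(self):
        m = self.cand_matrix("ensemble")
        attach_external_features(m, [])
        assert m.values[26:].sum() == 0

    def test_broadcast_to_candidate_column(self):
        m = self.cand_matrix("ensemble")
        attach_external_features(m, [0.8])
        col = m.colmap.candidate_column
        assert np.all(m.values[26, :, col] == np.float32(0.8))
        assert m.values[26].sum() == pytest.approx(5 * 0.8, rel=1e-6)

    def test_overflow_rejected(self):
        m = self.cand_matrix("ensemble")
        with pytest.raises(ValueError, match="93"):
            attach_external_features(m, [0.1] * 94)

    def test_standalone_matrix_rejected(self):
        m = self.cand_matrix("standalone")
        with pytest.raises(ValueError, match="ensemble"):
            attach_external_features(m, [0.5])


def test_dataset_save_load_round_trip(small_sim, tmp_path):
    cands = filter_candidates(scan_region(small_sim.tumor_bam,
                                          small_sim.reference_fasta))[:15]
    ds = featurize_candidates(cands, small_sim.tumor_bam, small_sim.normal_bam,
                              small_sim.reference_fasta)
    path = str(tmp_path / "data.npz")
    ds.save(path)
    back = MatrixDataset.load(path)
    np.testing.assert_array_equal(ds.values, back.values)
    assert [c.key for c in ds.candidates] == [c.key for c in back.candidates]
    assert ds.registry.hash == back.registry.hash
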