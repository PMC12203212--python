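import numpy as np
import pytest

from conftest import mutate, random_record
from structcore.iodb import ProteinRecord, build_database
from structcore.msta import (
    Msta,
    align_core_gene,
    concatenate,
    filter_gappy_columns,
    guide_tree,
    progressive_align,
    project_to_aa,
    write_supermatrix,
)
from structcore.synthgen import SynthConfig, simulated_database


def degap(s):
    return s.replace("-", "")


class TestGuideTree:
    def test_two_members(self, model, rng):
        members = [random_record(rng, pid=f"p{i}", length=60)
                   for i in range(2)]
        assert guide_tree(members, model) == (0, 1)

    def test_identical_members_deterministic(self, model, rng):
        base = random_record(rng, length=80)
        members = [ProteinRecord(f"s{i}", f"p{i}", base.aa, base.tdi)
                   for i in range(3)]
        assert guide_tree(members, model) == guide_tree(members, model)

    def test_planted_subfamilies_join_first(self, model, rng):
        famA = random_record(rng, pid="a0", length=100)
        famB = random_record(rng, pid="b0", length=100)
        r2 = np.random.default_rng(0)
        members = [
            famA,
            ProteinRecord("s1", "a1", mutate(famA.aa, r2, 0.1),
                          mutate(famA.tdi, r2, 0.05)),
            famB,
            ProteinRecord("s3", "b1", mutate(famB.aa, r2, 0.1),
                          mutate(famB.tdi, r2, 0.05)),
        ]
        order = guide_tree(members, model)
        assert set(map(frozenset, order)) == {frozenset({0, 1}),
                                              frozenset({2, 3})}


class TestProgressiveAlign:
    def test_identical_sequences_no_gaps(self, model, rng):
        base = random_record(rng, length=60)
        members = [ProteinRecord(f"s{i}", f"p{i}", base.aa, base.tdi)
                   for i in range(4)]
        msa = progressive_align(members, guide_tree(members, model), model)
        assert all("-" not in row for _, _, row in msa.rows)
        assert msa.n_cols == 60

    def test_length_difference_inserts_gap(self, model):
        a = ProteinRecord("s1", "a", "MKVA", "DDVV")
        b = ProteinRecord("s2", "b", "MKV", "DDV")
        msa = progressive_align([a, b], (0, 1), model)
        assert msa.n_cols == 4
        rows = {pid: row for _, pid, row in msa.rows}
        assert rows["a"] == "DDVV"
        assert rows["b"].count("-") == 1

    def test_rows_reproduce_members(self, model, rng):
        members = [random_record(rng, pid=f"p{i}", length=50 + 10 * i)
                   for i in range(3)]
        msa = progressive_align(members, guide_tree(members, model), model)
        for (_, pid, row), member in zip(msa.rows, members):
            assert pid == member.protein_id
            assert degap(row) == member.tdi

    def test_conserved_columns_recovered(self, model):
        # equal-length family evolved without indels: the true alignment is
        # the identity map, so the aligner should produce gap-free rows
        db, truth = simulated_database(SynthConfig(
            n_species=8, n_core_families=1, n_accessory_families=0,
            loss_prob=0.0, dup_prob=0.0, rate_aa=0.3, rate_3di=0.1,
            seq_len_range=(120, 120), seed=31))
        members = sorted(db.records, key=lambda r: r.protein_id)
        msa = progressive_align(members, guide_tree(members, model), model)
        n_pairs = 0
        n_correct = 0
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                row_i, row_j = msa.rows[i][2], msa.rows[j][2]
                pos_i = pos_j = 0
                for a, b in zip(row_i, row_j):
                    if a != "-" and b != "-":
                        n_pairs += 1
                        n_correct += pos_i == pos_j
                    pos_i += a != "-"
                    pos_j += b != "-"
        assert n_correct / n_pairs >= 0.9


class TestFilterGappyColumns:
    def toy(self):
        return Msta("g", [
            ("s1", "p1", "DDVK-"),
            ("s2", "p2", "DD-K-"),
            ("s3", "p3", "D-VKC"),
            ("s4", "p4", "D--KC"),
        ])

    def test_half_gap_column_removed(self):
        filtered, kept = filter_gappy_columns(self.toy(), 0.5)
        # col1 has 2/4 gaps (removed), col2 has 2/4 (removed),
        # col4 has 2/4 (removed); cols 0 and 3 kept
        assert kept == [0, 3]
        assert [r[2] for r in filtered.rows] == ["DK", "DK", "DK", "DK"]

    def test_quarter_gap_column_kept(self):
        msa = Msta("g", [("s1", "p1", "DV"), ("s2", "p2", "DV"),
                         ("s3", "p3", "DV"), ("s4", "p4", "D-")])
        filtered, kept = filter_gappy_columns(msa, 0.5)
        assert kept == [0, 1]

    def test_all_gap_column_removed(self):
        msa = Msta("g", [("s1", "p1", "D-"), ("s2", "p2", "V-")])
        filtered, kept = filter_gappy_columns(msa, 0.5)
        assert kept == [0]

    def test_idempotent(self):
        once, kept1 = filter_gappy_columns(self.toy(), 0.5)
        twice, kept2 = filter_gappy_columns(once, 0.5)
        assert [r[2] for r in once.rows] == [r[2] for r in twice.rows]
        assert kept2 == list(range(len(kept1)))

    def test_column_conservation(self):
        msa = self.toy()
        filtered, kept = filter_gappy_columns(msa, 0.5)
        assert len(kept) + (msa.n_cols - len(kept)) == msa.n_cols
        assert filtered.n_cols == len(kept)

    def test_all_columns_removed_is_error(self):
        msa = Msta("gene7", [("s1", "p1", "D-"), ("s2", "p2", "-V")])
        with pytest.raises(ValueError, match="gene7"):
            filter_gappy_columns(msa, 0.5)

    def test_x_counts_as_residue(self):
        msa = Msta("g", [("s1", "p1", "X"), ("s2", "p2", "-")])
        filtered, kept = filter_gappy_columns(msa, 0.6)
        assert kept == [0]


class TestProjectToAa:
    def db(self):
        return build_database({
            "s1": [ProteinRecord("s1", "p1", "MLKR", "DDVK")],
            "s2": [ProteinRecord("s2", "p2", "MLK", "DDV")],
        })

    def test_positional_mapping(self):
        msa = Msta("g", [("s1", "s1|p1", "DD-VK"), ("s2", "s2|p2", "DDV--")])
        proj = project_to_aa(msa, self.db())
        assert proj.rows == [("s1", "ML-KR"), ("s2", "MLK--")]

    def test_gap_free_row_equals_record(self):
        msa = Msta("g", [("s1", "s1|p1", "DDVK"),
                         ("s2", "s2|p2", "DDV-")])
        proj = project_to_aa(msa, self.db())
        assert proj.rows[0][1] == "MLKR"

    def test_filtered_rows_project_residues_at_kept_positions(self):
        msa = Msta("g", [("s1", "s1|p1", "DD-VK"), ("s2", "s2|p2", "DDV--")])
        filtered, kept = filter_gappy_columns(msa, 0.5)
        proj = project_to_aa(filtered, self.db())
        # kept columns: 0,1 plus any column with <50% gaps
        by_sp = dict(proj.rows)
        assert degap(by_sp["s1"]) == "".join(
            "MLKR"[k] for k in range(4) if k in (0, 1, 2, 3)
        )[: len(degap(by_sp["s1"]))]
        # gap masks identical between 3Di and AA projection
        for (_, _, trow), (_, arow) in zip(filtered.rows, proj.rows):
            assert [c == "-" for c in trow] == [c == "-" for c in arow]

    def test_mismatching_row_is_hard_error(self):
        msa = Msta("g", [("s1", "s1|p1", "DDKK")])  # K at pos 2 mismatches
        with pytest.raises(ValueError, match="does not match"):
            project_to_aa(msa, self.db())

    def test_gap_mask_roundtrip_on_simulated_gene(self, model):
        db, _ = simulated_database(SynthConfig(
            n_species=5, n_core_families=1, n_accessory_families=0,
            loss_prob=0.0, dup_prob=0.0, seq_len_range=(60, 60), seed=37))
        members = sorted(db.records, key=lambda r: r.protein_id)
        filtered, proj, kept = align_core_gene(members, model, db, "g")
        for (_, _, trow), (_, arow) in zip(filtered.rows, proj.rows):
            assert [c == "-" for c in trow] == [c == "-" for c in arow]


class TestConcatenate:
    def test_partition_arithmetic(self):
        from structcore.msta import ProjectedMsa
        g1 = ProjectedMsa("g1", [("s1", "A" * 10), ("s2", "C" * 10)])
        g2 = ProjectedMsa("g2", [("s1", "D" * 15), ("s2", "E" * 15)])
        sm = concatenate([g1, g2], ["s1", "s2"])
        assert sm.n_cols == 25
        assert sm.partitions == [("g1", 1, 10), ("g2", 11, 25)]

    def test_missing_species_gets_gap_block(self):
        from structcore.msta import ProjectedMsa
        g1 = ProjectedMsa("g1", [("s1", "AAAA"), ("s2", "CCCC")])
        g2 = ProjectedMsa("g2", [("s1", "DDD")])
        sm = concatenate([g1, g2], ["s1", "s2"])
        assert sm.rows["s2"] == "CCCC---"

    def test_single_gene_identity(self):
        from structcore.msta import ProjectedMsa
        g1 = ProjectedMsa("g1", [("s1", "AAAA"), ("s2", "CCCC")])
        sm = concatenate([g1], ["s1", "s2"])
        assert sm.rows == {"s1": "AAAA", "s2": "CCCC"}
        assert sm.partitions == [("g1", 1, 4)]

    def test_duplicate_species_is_error(self):
        from structcore.msta import ProjectedMsa
        g1 = ProjectedMsa("g1", [("s1", "AA"), ("s1", "CC")])
        with pytest.raises(ValueError, match="twice"):
            concatenate([g1], ["s1"])

    def test_partition_file_format(self, tmp_path):
        from structcore.msta import ProjectedMsa
        g1 = ProjectedMsa("g1", [("s1", "AAAA"), ("s2", "CCCC")])
        g2 = ProjectedMsa("g2", [("s1", "DDD"), ("s2", "EEE")])
        sm = concatenate([g1, g2], ["s1", "s2"])
        write_supermatrix(sm, tmp_path / "sm.fasta", tmp_path / "parts.txt")
        lines = (tmp_path / "parts.txt").read_text().splitlines()
        assert lines == ["JTT+F+I+G, g1 = 1-4", "JTT+F+I+G, g2 = 5-7"]
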