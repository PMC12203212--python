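import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import cluster_labels, mutate, random_record
from structcore.iodb import ProteinRecord
from structcore.structcluster import (
    ClusterParams,
    brute_force_cluster,
    cascade_cluster,
    default_max_seqs,
    greedy_cluster_round,
    pair_align,
    reassign_members,
    select_kmers,
)
from structcore.synthgen import SynthConfig, simulated_database


class TestSelectKmers:
    def test_too_short_yields_empty(self, rng):
        rec = random_record(rng, length=5)
        assert select_kmers(rec, kmer_len=6) == set()

    def test_identical_strings_identical_sets(self, rng):
        rec = random_record(rng, length=100)
        twin = ProteinRecord("other", "q", rec.aa, rec.tdi)
        assert {k for k, _ in select_kmers(rec)} == \
               {k for k, _ in select_kmers(twin)}

    def test_count_contract(self, rng):
        rec = random_record(rng, length=100)
        assert len(select_kmers(rec, 6, 21)) == min(21, 95)
        short = random_record(rng, pid="s", length=10)
        assert len(select_kmers(short, 6, 21)) == 5

    def test_seed_changes_selection_deterministically(self, rng):
        rec = random_record(rng, length=200)
        a1 = select_kmers(rec, seed=1)
        a2 = select_kmers(rec, seed=1)
        b = select_kmers(rec, seed=2)
        assert a1 == a2
        assert a1 != b


class TestPairAlign:
    def test_self_alignment(self, model, rng):
        rec = random_record(rng, length=80)
        hit = pair_align(rec, rec, model)
        assert hit.qcov == 1.0 and hit.tcov == 1.0
        assert hit.seq_identity == 1.0
        assert hit.evalue < 1e-10

    def test_structure_channel_raises_score_for_twilight_pair(self, model, aa_model, rng):
        # identical 3Di, 75% AA divergence: combined must outscore AA-only
        rec = random_record(rng, length=120)
        other = ProteinRecord("s2", "q", mutate(rec.aa, rng, 0.75), rec.tdi)
        combined = pair_align(rec, other, model)
        aa_only = pair_align(rec, other, aa_model)
        assert combined.raw_score > aa_only.raw_score
        assert combined.seq_identity < 0.4

    def test_evalue_uses_search_space(self, model, rng):
        rec = random_record(rng, length=80)
        h_small = pair_align(rec, rec, model, n_db=1000)
        h_large = pair_align(rec, rec, model, n_db=100000)
        assert h_large.evalue == pytest.approx(100 * h_small.evalue)


class TestGreedyRound:
    def test_unrelated_records_stay_singletons(self, model, rng):
        records = [random_record(rng, pid=f"p{i}", length=100)
                   for i in range(12)]
        clusters = greedy_cluster_round(records, ClusterParams(), model)
        assert len(clusters) == 12
        assert all(len(c) == 1 for c in clusters)

    def test_identical_records_form_one_cluster(self, model, rng):
        base = random_record(rng, length=100)
        records = [ProteinRecord(f"s{i}", f"p{i}", base.aa, base.tdi)
                   for i in range(5)]
        clusters = greedy_cluster_round(records, ClusterParams(), model)
        assert len(clusters) == 1 and len(clusters[0]) == 5

    def test_low_target_coverage_rejected(self, model, rng):
        # 100-residue query embedded in a 200-residue target: tcov 0.5 < 0.8
        short = random_record(rng, pid="short", length=100)
        pad = random_record(rng, pid="pad", length=100)
        long = ProteinRecord("s2", "long", short.aa + pad.aa,
                             short.tdi + pad.tdi)
        hit = pair_align(short, long, model)
        assert hit.evalue < 1e-3 and hit.tcov <= 0.55
        clusters = greedy_cluster_round([short, long], ClusterParams(), model)
        assert len(clusters) == 2

    def test_partition_property(self, model):
        db, _ = simulated_database(SynthConfig(
            n_species=6, n_core_families=5, n_accessory_families=3,
            seq_len_range=(60, 120), seed=5))
        clusters = greedy_cluster_round(db.records, ClusterParams(), model)
        members = [m for c in clusters for m in c.member_ids]
        assert len(members) == len(db)
        assert set(members) == set(db.index)


class TestCascade:
    def test_single_round_equals_greedy(self, model):
        db, _ = simulated_database(SynthConfig(
            n_species=5, n_core_families=4, n_accessory_families=0,
            seq_len_range=(60, 100), seed=7))
        params = ClusterParams(cascade_rounds=1, reassign=False)
        one = cascade_cluster(db, params, model, seed=3)
        direct = greedy_cluster_round(db.records, params, model, seed=3)
        assert {frozenset(c.member_ids) for c in one} == \
               {frozenset(c.member_ids) for c in direct}

    def test_chain_merges_through_shared_representative(self, model, rng):
        # A matches B's head, C matches B's tail; A-C overlap is too short
        # to pass coverage, but both pass against B, so cascading with B as
        # representative unites all three.
        b = random_record(rng, pid="b", length=200)
        a = ProteinRecord("s1", "a", b.aa[:160], b.tdi[:160])
        c = ProteinRecord("s3", "c", b.aa[40:], b.tdi[40:])
        params = ClusterParams(reassign=False)
        ab = pair_align(a, b, model)
        cb = pair_align(c, b, model)
        ac = pair_align(a, c, model)
        assert min(ab.qcov, ab.tcov) >= 0.8 and ab.evalue <= 1e-3
        assert min(cb.qcov, cb.tcov) >= 0.8 and cb.evalue <= 1e-3
        assert min(ac.qcov, ac.tcov) < 0.8
        clusters = cascade_cluster([a, b, c], params, model)
        assert len(clusters) == 1
        assert clusters[0].rep_id == "b"

    def test_disjoint_families_never_merge(self, model, rng):
        fam1 = random_record(rng, pid="f1", length=100)
        fam2 = random_record(rng, pid="f2", length=100)
        records = []
        for i in range(4):
            r2 = np.random.default_rng(100 + i)
            records.append(ProteinRecord(
                f"s{i}", f"f1_{i}", mutate(fam1.aa, r2, 0.1),
                mutate(fam1.tdi, r2, 0.05)))
            records.append(ProteinRecord(
                f"s{i}", f"f2_{i}", mutate(fam2.aa, r2, 0.1),
                mutate(fam2.tdi, r2, 0.05)))
        clusters = cascade_cluster(records, ClusterParams(), model)
        for c in clusters:
            fams = {m.split("_")[0] for m in c.member_ids}
            assert len(fams) == 1

    def test_deterministic_under_seed(self, model):
        db, _ = simulated_database(SynthConfig(
            n_species=6, n_core_families=5, n_accessory_families=2,
            seq_len_range=(60, 120), seed=11))
        c1 = cascade_cluster(db, ClusterParams(), model, seed=9)
        c2 = cascade_cluster(db, ClusterParams(), model, seed=9)
        assert [(c.rep_id, sorted(c.member_ids)) for c in c1] == \
               [(c.rep_id, sorted(c.member_ids)) for c in c2]


class TestReassign:
    def test_fixed_point_when_already_best(self, model, rng):
        base = random_record(rng, length=100)
        members = [ProteinRecord(f"s{i}", f"p{i}", base.aa, base.tdi)
                   for i in range(4)]
        clusters = cascade_cluster(members, ClusterParams(reassign=False),
                                   model)
        again = reassign_members(clusters, members, ClusterParams(), model)
        assert {frozenset(c.member_ids) for c in clusters} == \
               {frozenset(c.member_ids) for c in again}

    def test_member_moved_to_higher_scoring_representative(self, model, rng):
        famA = random_record(rng, pid="repA", length=120)
        famB = random_record(rng, pid="repB", length=120)
        r2 = np.random.default_rng(42)
        near_a = ProteinRecord("s9", "member",
                               mutate(famA.aa, r2, 0.05),
                               mutate(famA.tdi, r2, 0.02))
        from structcore.structcluster import Cluster
        wrong = [Cluster("repA"), Cluster("repB", {"repB", "member"})]
        fixed = reassign_members(wrong, [famA, famB, near_a],
                                 ClusterParams(), model)
        by_rep = {c.rep_id: c.member_ids for c in fixed}
        assert "member" in by_rep["repA"]

    def test_failing_member_split_to_singleton(self, model, rng):
        rep = random_record(rng, pid="rep", length=100)
        stranger = random_record(rng, pid="stranger", length=100)
        from structcore.structcluster import Cluster
        clusters = [Cluster("rep", {"rep", "stranger"})]
        fixed = reassign_members(clusters, [rep, stranger],
                                 ClusterParams(), model)
        assert {c.rep_id for c in fixed} == {"rep", "stranger"}
        assert all(len(c) == 1 for c in fixed)


class TestBruteForce:
    def test_single_and_identical_records(self, model, rng):
        one = [random_record(rng, pid="only", length=80)]
        clusters = brute_force_cluster(one, ClusterParams(), model)
        assert len(clusters) == 1 and len(clusters[0]) == 1
        twin = ProteinRecord("s2", "twin", one[0].aa, one[0].tdi)
        clusters = brute_force_cluster(one + [twin], ClusterParams(), model)
        assert len(clusters) == 1 and len(clusters[0]) == 2

    def test_order_invariance(self, model):
        db, _ = simulated_database(SynthConfig(
            n_species=5, n_core_families=4, n_accessory_families=2,
            seq_len_range=(60, 100), seed=13))
        params = ClusterParams()
        fwd = brute_force_cluster(db.records, params, model)
        rev = brute_force_cluster(db.records[::-1], params, model)
        assert [(c.rep_id, sorted(c.member_ids)) for c in fwd] == \
               [(c.rep_id, sorted(c.member_ids)) for c in rev]

    def test_threshold_monotonicity(self, model):
        db, _ = simulated_database(SynthConfig(
            n_species=6, n_core_families=5, n_accessory_families=3,
            seq_len_range=(60, 120), rate_aa=0.8, rate_3di=0.3, seed=17))
        n_clusters = []
        for max_e, min_cov in ((1e-6, 0.9), (1e-3, 0.8), (1e-1, 0.6)):
            params = ClusterParams(min_cov=min_cov, max_evalue=max_e)
            n_clusters.append(len(brute_force_cluster(db, params, model)))
        assert n_clusters[0] >= n_clusters[1] >= n_clusters[2]

    def test_agrees_with_cascade_on_families(self, model):
        db, _ = simulated_database(SynthConfig(
            n_species=8, n_core_families=8, n_accessory_families=4,
            seq_len_range=(60, 120), seed=19))
        params = ClusterParams()
        greedy = cascade_cluster(db, params, model, seed=1)
        brute = brute_force_cluster(db, params, model)
        ari = adjusted_rand_score(cluster_labels(greedy),
                                  cluster_labels(brute))
        assert ari >= 0.95


def test_default_max_seqs_rule():
    assert default_max_seqs(30) == 1000
    assert default_max_seqs(50) == 1000
    assert default_max_seqs(100) == 2000
    with pytest.raises(ValueError):
        default_max_seqs(0)


def test_cluster_params_validation():
    with pytest.raises(ValueError):
        ClusterParams(min_cov=0.0)
    with pytest.raises(ValueError):
        ClusterParams(max_evalue=-1)
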