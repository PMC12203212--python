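"""Quasilinear greedy clustering of proteins on combined 3Di+AA similarity.

The prefilter is Linclust-style minimizer hashing over 3Di k-mers: each
sequence contributes its ``kmers_per_seq`` lowest-hashing k-mers; sequences
sharing a selected k-mer become alignment candidates, the longest sequence in
each k-mer group acting as centroid. Candidates are verified by gapped local
alignment under the combined scoring model; a member joins a centroid only if
the alignment passes the E-value and bidirectional-coverage thresholds.
Cascaded rounds recluster the representatives to merge families split by the
prefilter, and an optional reassignment pass re-attaches every member to its
best-scoring representative.

A brute-force all-vs-all clusterer is provided as the test oracle.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

from ._kernels import local_align_stats, local_align_traceback
from .iodb import PairedDatabase, ProteinRecord
from .substitution import SubstitutionModel, encode

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentHit:
    """One verified pairwise alignment."""

    query_id: str
    target_id: str
    raw_score: int
    bit_score: float
    evalue: float
    qcov: float
    tcov: float
    seq_identity: float | None = None  # AA identity over aligned columns


@dataclass
class Cluster:
    """A representative and its members (the representative included)."""

    rep_id: str
    member_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.member_ids = set(self.member_ids)
        self.member_ids.add(self.rep_id)

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass
class ClusterParams:
    """Thresholds and knobs for greedy clustering.

    min_cov applies to both query and target coverage (the 80% rule);
    max_evalue is the acceptance E-value (1e-3); max_seqs caps the number of
    prefilter candidates per sequence and defaults to the species-count rule
    of :func:`default_max_seqs` when left at 0.
    """

    min_cov: float = 0.8
    max_evalue: float = 1e-3
    kmer_len: int = 6
    kmers_per_seq: int = 21
    cascade_rounds: int = 2
    reassign: bool = True
    max_seqs: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_cov <= 1:
            raise ValueError("min_cov must be in (0, 1]")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")


def default_max_seqs(n_species: int) -> int:
    """Prefilter candidate cap: the larger of 1,000 or 20x the species count."""
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    return max(1000, 20 * n_species)


def select_kmers(
    record: ProteinRecord,
    kmer_len: int = 6,
    kmers_per_seq: int = 21,
    seed: int = 0,
) -> set[tuple[str, int]]:
    """Pick the ``kmers_per_seq`` lowest-hashing 3Di k-mers of a record.

    The hash is a keyed blake2b over the k-mer string, so selection is
    deterministic for a fixed seed and identical strings always select
    identical k-mer sets. Sequences shorter than ``kmer_len`` yield the
    empty set. Returns a set of ``(kmer, position)`` pairs.
    """
    tdi = record.tdi
    if tdi is None or len(tdi) < kmer_len:
        return set()
    key = int(seed).to_bytes(8, "little", signed=True)
    scored = []
    for pos in range(len(tdi) - kmer_len + 1):
        kmer = tdi[pos:pos + kmer_len]
        h = hashlib.blake2b(kmer.encode(), digest_size=8, key=key).digest()
        scored.append((h, pos, kmer))
    scored.sort()
    return {(kmer, pos) for _, pos, kmer in scored[:kmers_per_seq]}


def _encoded(record: ProteinRecord):
    return encode(record.tdi), encode(record.aa)


def _align_stats(a: ProteinRecord, b: ProteinRecord, model: SubstitutionModel):
    """Raw score and coverage of the optimal local alignment (no traceback)."""
    ta, aaa = _encoded(a)
    tb, aab = _encoded(b)
    S = model.score_pair_matrix(ta, tb, aaa, aab)
    raw, qs, qe, ts, te = local_align_stats(S, model.gap_open, model.gap_extend)
    if raw <= 0:
        return 0, 0.0, 0.0
    qcov = (qe - qs + 1) / len(a)
    tcov = (te - ts + 1) / len(b)
    return int(raw), qcov, tcov


def pair_align(
    a: ProteinRecord,
    b: ProteinRecord,
    model: SubstitutionModel,
    n_db: int | None = None,
) -> AlignmentHit:
    """Optimal gapped local alignment of two records under combined scoring.

    Each aligned column scores ``round(w3di*S3di + waa*Saa)`` with affine
    gaps. ``n_db`` is the search-space residue count for the E-value
    (defaults to the target length). Sequence identity is the AA identity
    over aligned residue-residue columns.
    """
    ta, aaa = _encoded(a)
    tb, aab = _encoded(b)
    S = model.score_pair_matrix(ta, tb, aaa, aab)
    raw, qa, tb_path = local_align_traceback(S, model.gap_open, model.gap_extend)
    if n_db is None:
        n_db = len(b)
    if raw <= 0:
        return AlignmentHit(a.protein_id, b.protein_id, 0, model.bit_score(0),
                            model.evalue(0, len(a), n_db), 0.0, 0.0, 0.0)
    qpos = qa[qa >= 0]
    tpos = tb_path[tb_path >= 0]
    qcov = (qpos.max() - qpos.min() + 1) / len(a)
    tcov = (tpos.max() - tpos.min() + 1) / len(b)
    both = (qa >= 0) & (tb_path >= 0)
    n_cols = int(both.sum())
    matches = int((aaa[qa[both]] == aab[tb_path[both]]).sum()) if n_cols else 0
    ident = matches / n_cols if n_cols else 0.0
    return AlignmentHit(
        a.protein_id, b.protein_id, int(raw), model.bit_score(raw),
        model.evalue(raw, len(a), n_db), qcov, tcov, ident,
    )


def _passes(raw, qcov, tcov, qlen, n_db, params, model) -> tuple[bool, float]:
    """Threshold check on a stats-kernel result; returns (ok, bit_score)."""
    if qcov < params.min_cov or tcov < params.min_cov:
        return False, 0.0
    bit = model.bit_score(raw)
    ev = model.evalue(raw, qlen, n_db)
    return ev <= params.max_evalue, bit


def _coverage_possible(la: int, lb: int, min_cov: float) -> bool:
    # the aligned span cannot exceed the shorter sequence
    return min(la, lb) / max(la, lb) >= min_cov


def greedy_cluster_round(
    records: list[ProteinRecord],
    params: ClusterParams,
    model: SubstitutionModel,
    n_db: int | None = None,
    seed: int = 0,
) -> list[Cluster]:
    """One Linclust-style greedy round over ``records``.

    K-mer groups nominate their longest sequence as centroid; every other
    sequence is aligned against the centroids it shares k-mers with (ordered
    by shared-k-mer count, capped at ``max_seqs``) and joins the best-scoring
    centroid that passes the E-value and coverage thresholds. Unassigned
    sequences become singletons.
    """
    model.ensure_calibrated()
    if n_db is None:
        n_db = sum(len(r) for r in records)
    max_seqs = params.max_seqs or default_max_seqs(
        len({r.species_id for r in records}) or 1
    )
    by_id = {r.protein_id: r for r in records}

    kmer_sets = {
        r.protein_id: select_kmers(r, params.kmer_len, params.kmers_per_seq, seed)
        for r in records
    }
    buckets: dict[str, list[str]] = {}
    for r in records:
        for kmer, _pos in kmer_sets[r.protein_id]:
            buckets.setdefault(kmer, []).append(r.protein_id)

    # longest-first incremental assignment: the longest unassigned sequence
    # of each candidate group becomes the centroid and absorbs the passing
    # members of its k-mer neighbourhood
    order = sorted(by_id, key=lambda p: (-len(by_id[p]), p))
    assigned: dict[str, str] = {}
    clusters: dict[str, Cluster] = {}
    for pid in order:
        if pid in assigned:
            continue
        assigned[pid] = pid
        clusters[pid] = Cluster(pid)
        crec = by_id[pid]
        counts: dict[str, int] = {}
        for kmer, _pos in kmer_sets[pid]:
            for other in buckets.get(kmer, ()):  # k-mer co-occurrence
                if other != pid and other not in assigned:
                    counts[other] = counts.get(other, 0) + 1
        candidates = sorted(counts, key=lambda c: (-counts[c], c))[:max_seqs]
        for cand in candidates:
            mrec = by_id[cand]
            if not _coverage_possible(len(mrec), len(crec), params.min_cov):
                continue
            raw, qcov, tcov = _align_stats(mrec, crec, model)
            ok, _bit = _passes(raw, qcov, tcov, len(mrec), n_db,
                               params, model)
            if ok:
                assigned[cand] = pid
                clusters[pid].member_ids.add(cand)
    return [clusters[k] for k in sorted(clusters)]


def cascade_cluster(
    db: PairedDatabase | list[ProteinRecord],
    params: ClusterParams,
    model: SubstitutionModel,
    seed: int = 0,
) -> list[Cluster]:
    """Cascaded greedy clustering (+ optional member reassignment).

    Round 1 clusters all records; each subsequent round clusters only the
    previous round's representatives with the same thresholds, and clusters
    whose representatives merge union their members. When
    ``params.reassign`` is set, a final pass re-attaches every member to its
    best representative (see :func:`reassign_members`).
    """
    records = db.records if isinstance(db, PairedDatabase) else list(db)
    by_id = {r.protein_id: r for r in records}
    n_db_full = sum(len(r) for r in records)
    clusters = greedy_cluster_round(records, params, model,
                                    n_db=n_db_full, seed=seed)
    for rnd in range(1, params.cascade_rounds):
        reps = [by_id[c.rep_id] for c in clusters]
        if len(reps) <= 1:
            break
        n_db = sum(len(r) for r in reps)
        merged = greedy_cluster_round(reps, params, model,
                                      n_db=n_db, seed=seed + rnd)
        members_of = {c.rep_id: c.member_ids for c in clusters}
        clusters = [
            Cluster(mc.rep_id,
                    set().union(*(members_of[r] for r in mc.member_ids)))
            for mc in merged
        ]
    clusters.sort(key=lambda c: c.rep_id)
    if params.reassign:
        dbx = db if isinstance(db, PairedDatabase) else None
        clusters = reassign_members(
            clusters, dbx if dbx is not None else records, params, model
        )
    return clusters


def reassign_members(
    clusters: list[Cluster],
    db: PairedDatabase | list[ProteinRecord],
    params: ClusterParams,
    model: SubstitutionModel,
) -> list[Cluster]:
    """Re-attach every non-representative member to its best representative.

    Each member is aligned to all current representatives and moves to the
    one with the best bit score among those passing the thresholds; members
    passing none become singletons. The result is still a partition.
    """
    records = db.records if isinstance(db, PairedDatabase) else list(db)
    by_id = {r.protein_id: r for r in records}
    n_db = sum(len(r) for r in records)
    rep_ids = sorted(c.rep_id for c in clusters)
    out: dict[str, Cluster] = {rid: Cluster(rid) for rid in rep_ids}
    singletons: list[str] = []
    for cluster in clusters:
        for pid in sorted(cluster.member_ids):
            if pid == cluster.rep_id:
                continue
            rec = by_id[pid]
            best: tuple[float, str] | None = None
            for rid in rep_ids:
                rrec = by_id[rid]
                if not _coverage_possible(len(rec), len(rrec), params.min_cov):
                    continue
                raw, qcov, tcov = _align_stats(rec, rrec, model)
                ok, bit = _passes(raw, qcov, tcov, len(rec), n_db,
                                  params, model)
                if ok and (best is None or (-bit, rid) < (-best[0], best[1])):
                    best = (bit, rid)
            if best is None:
                singletons.append(pid)
            else:
                out[best[1]].member_ids.add(pid)
    for pid in singletons:
        out[pid] = Cluster(pid)
    return [out[k] for k in sorted(out)]


def brute_force_cluster(
    db: PairedDatabase | list[ProteinRecord],
    params: ClusterParams,
    model: SubstitutionModel,
) -> list[Cluster]:
    """All-vs-all greedy set-cover clustering (test oracle).

    Every pair is aligned; a pair is a "passing" edge when it meets the
    E-value and bidirectional coverage thresholds. Repeatedly the unclustered
    sequence with the most unclustered passing neighbours (ties by id)
    becomes a representative and absorbs those neighbours. Deterministic and
    input-order invariant.
    """
    model.ensure_calibrated()
    records = db.records if isinstance(db, PairedDatabase) else list(db)
    records = sorted(records, key=lambda r: r.protein_id)
    n = len(records)
    n_db = sum(len(r) for r in records)
    neighbors: dict[str, set[str]] = {r.protein_id: set() for r in records}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = records[i], records[j]
            if not _coverage_possible(len(a), len(b), params.min_cov):
                continue
            raw, qcov, tcov = _align_stats(a, b, model)
            ok, _ = _passes(raw, qcov, tcov, len(a), n_db, params, model)
            if ok:
                neighbors[a.protein_id].add(b.protein_id)
                neighbors[b.protein_id].add(a.protein_id)
    unclustered = {r.protein_id for r in records}
    clusters: list[Cluster] = []
    while unclustered:
        rep = min(
            unclustered,
            key=lambda p: (-len(neighbors[p] & unclustered), p),
        )
        members = (neighbors[rep] & unclustered) | {rep}
        clusters.append(Cluster(rep, members))
        unclustered -= members
    clusters.sort(key=lambda c: c.rep_id)
    return clusters


def write_cluster_tsv(clusters: list[Cluster], path) -> None:
    """MMseqs/Foldseek-style TSV: rep_id <TAB> member_id per line."""
    with open(path, "w") as fh:
        for c in sorted(clusters, key=lambda c: c.rep_id):
            for m in sorted(c.member_ids):
                fh.write(f"{c.rep_id}\t{m}\n")


def read_cluster_tsv(path) -> list[Cluster]:
    by_rep: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            rep, member = line.split("\t")
            by_rep.setdefault(rep, set()).add(member)
    return [Cluster(rep, members) for rep, members in sorted(by_rep.items())]
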