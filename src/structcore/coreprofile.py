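"""Single-copy coverage profiling and structural core-gene selection.

The single-copy coverage of a cluster is the fraction of *all* input species
that have exactly one member in it; clusters at or above the coverage
threshold (default 0.8) are the structural core genes. Also provides the
diagnostics used to compare against sequence-based gene sets: mapping an
external gene to a cluster by 80% member sharing, and detecting genes
fragmented across two clusters via a significant low-coverage alignment of
the cluster representatives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from .iodb import PairedDatabase
from .structcluster import Cluster, pair_align
from .substitution import SubstitutionModel

logger = logging.getLogger(__name__)


@dataclass
class ClusterProfile:
    """Per-species copy counts and coverages of one cluster."""

    cluster_id: str
    copy_count: dict[str, int]
    single_copy_coverage: float
    any_copy_coverage: float


@dataclass
class CoreGeneSet:
    """Selected core clusters plus per-species representation bookkeeping."""

    threshold: float
    core_cluster_ids: list[str]
    species_core_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[tuple[str, int, int]] = field(default_factory=list)


def profile_clusters(
    clusters: list[Cluster], db: PairedDatabase
) -> list[ClusterProfile]:
    """Compute copy counts and coverages against all species in the database."""
    n_species = db.n_species
    if n_species == 0:
        raise ValueError("database has no species")
    profiles = []
    for cluster in sorted(clusters, key=lambda c: c.rep_id):
        counts: dict[str, int] = {}
        for pid in cluster.member_ids:
            sp = db.index[pid].species_id
            counts[sp] = counts.get(sp, 0) + 1
        single = sum(1 for v in counts.values() if v == 1)
        profiles.append(
            ClusterProfile(
                cluster_id=cluster.rep_id,
                copy_count=counts,
                single_copy_coverage=single / n_species,
                any_copy_coverage=len(counts) / n_species,
            )
        )
    return profiles


def select_core(
    profiles: list[ClusterProfile], threshold: float = 0.8
) -> CoreGeneSet:
    """Select clusters with single-copy coverage >= threshold (inclusive).

    Ordered by descending coverage, then cluster id. The comparison is
    inclusive ("at least"), so a coverage of exactly 0.90 is selected at
    threshold 0.9.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    eps = 1e-12  # guard float representation of exact fractions
    core = [p for p in profiles if p.single_copy_coverage >= threshold - eps]
    core.sort(key=lambda p: (-p.single_copy_coverage, p.cluster_id))
    return CoreGeneSet(threshold, [p.cluster_id for p in core])


def species_representation_warnings(
    core_set: CoreGeneSet,
    profiles: list[ClusterProfile],
    species_ids: list[str] | None = None,
) -> list[tuple[str, int, int]]:
    """Warn for species present single-copy in fewer than a strict majority
    of the core genes.

    Returns ``(species_id, n_core_present, n_core_total)`` tuples; also
    stored on ``core_set``. With an empty core set an empty list is returned
    (logged at warning level).
    """
    n_core = len(core_set.core_cluster_ids)
    if n_core == 0:
        logger.warning("empty core gene set; no representation check possible")
        return []
    by_id = {p.cluster_id: p for p in profiles}
    if species_ids is None:
        species_ids = sorted(
            {sp for p in profiles for sp in p.copy_count}
        )
    majority = math.ceil((n_core + 1) / 2)
    warnings = []
    for sp in species_ids:
        present = sum(
            1
            for cid in core_set.core_cluster_ids
            if by_id[cid].copy_count.get(sp, 0) == 1
        )
        core_set.species_core_counts[sp] = present
        if present < majority:
            logger.warning(
                "proteome %s represents only %d of %d core genes",
                sp, present, n_core,
            )
            warnings.append((sp, present, n_core))
    core_set.warnings = warnings
    return warnings


def map_gene_to_cluster(
    external_gene_members: set[str], clusters: list[Cluster]
) -> str | None:
    """Map an external gene to the cluster sharing >= 80% of its members.

    Returns the id of the cluster maximising ``|gene & cluster| / |gene|``
    when that fraction reaches 0.8, else None. Ties broken by larger
    intersection, then cluster id.
    """
    gene = set(external_gene_members)
    if not gene:
        raise ValueError("empty gene member set")
    best: tuple[int, str] | None = None
    for cluster in clusters:
        inter = len(gene & cluster.member_ids)
        if inter == 0:
            continue
        if best is None or (-inter, cluster.rep_id) < (-best[0], best[1]):
            best = (inter, cluster.rep_id)
    if best is None or best[0] / len(gene) < 0.8 - 1e-12:
        return None
    return best[1]


def detect_fragmentation(
    external_gene_members: set[str],
    clusters: list[Cluster],
    db: PairedDatabase,
    model: SubstitutionModel,
) -> bool:
    """Did an unmapped gene fragment across two clusters?

    The representatives of the two clusters sharing the most members with
    the gene are aligned; the gene counts as fragmented when the alignment
    is significant (E-value < 1e-3) but with coverage below 0.8 on at least
    one side — i.e. the pieces are homologous but fail the clustering
    coverage rule. With fewer than two overlapping clusters: False.
    """
    gene = set(external_gene_members)
    overlaps = sorted(
        (
            (len(gene & c.member_ids), c)
            for c in clusters
            if gene & c.member_ids
        ),
        key=lambda t: (-t[0], t[1].rep_id),
    )
    if len(overlaps) < 2:
        return False
    rep_a = db.index[overlaps[0][1].rep_id]
    rep_b = db.index[overlaps[1][1].rep_id]
    hit = pair_align(rep_a, rep_b, model, n_db=db.total_residues())
    return bool(hit.evalue < 1e-3 and min(hit.qcov, hit.tcov) < 0.8)


def write_profiles_tsv(
    profiles: list[ClusterProfile], db: PairedDatabase, path: str | Path
) -> None:
    species = list(db.species_ids)
    with open(path, "w") as fh:
        fh.write(
            "cluster_id\tsingle_copy_coverage\tany_copy_coverage\t"
            + "\t".join(species) + "\n"
        )
        for p in profiles:
            counts = "\t".join(str(p.copy_count.get(sp, 0)) for sp in species)
            fh.write(
                f"{p.cluster_id}\t{p.single_copy_coverage:.6f}\t"
                f"{p.any_copy_coverage:.6f}\t{counts}\n"
            )


def write_core_genes_tsv(
    core_set: CoreGeneSet, profiles: list[ClusterProfile], path: str | Path
) -> None:
    by_id = {p.cluster_id: p for p in profiles}
    with open(path, "w") as fh:
        fh.write("cluster_id\tsingle_copy_coverage\n")
        for cid in core_set.core_cluster_ids:
            fh.write(f"{cid}\t{by_id[cid].single_copy_coverage:.6f}\n")


def write_warnings_tsv(warnings, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species_id\tn_core_present\tn_core_total\n")
        for sp, present, total in warnings:
            fh.write(f"{sp}\t{present}\t{total}\n")
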