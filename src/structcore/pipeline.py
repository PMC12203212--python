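"""End-to-end orchestration: createdb -> cluster -> profile -> align -> tree.

:func:`easy_core` runs the whole pipeline on a paired database (or raw
FASTA inputs), writing every intermediate artifact plus a manifest of
parameters and seed, so that a run is reproducible and each stage's output
is a valid standalone input to the next stage's subcommand.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import coreprofile, msta, phylo, structcluster
from .iodb import (
    LookupTable,
    PairedDatabase,
    build_database,
    read_proteome,
    resolve_3di,
    write_database,
)
from .structcluster import ClusterParams
from .substitution import SubstitutionModel

logger = logging.getLogger(__name__)


@dataclass
class EasyCoreResult:
    out_dir: Path
    db: PairedDatabase
    clusters: list
    profiles: list
    core_set: coreprofile.CoreGeneSet
    supermatrix: msta.Supermatrix | None
    species_tree: object | None
    rooted_tree: object | None
    gene_trees: dict[str, object] = field(default_factory=dict)


def createdb(
    aa_fastas: list[str | Path],
    tdi_dir: str | Path | None = None,
    lookup_tsv: str | Path | None = None,
    converter=None,
    max_len: int = 4000,
) -> PairedDatabase:
    """Assemble a paired database from per-species FASTA files.

    For each AA FASTA, a 3Di FASTA named ``<species>.3di.fasta`` is searched
    next to it (or under ``tdi_dir``); records without one are resolved via
    the lookup table and/or converter, and dropped with a warning otherwise.
    """
    lookup = LookupTable.from_tsv(lookup_tsv) if lookup_tsv else None
    per_species = {}
    for aa_path in aa_fastas:
        aa_path = Path(aa_path)
        # 3Di companion files swept up by a glob are not species proteomes
        if ".3di." in aa_path.name:
            continue
        species = aa_path.name
        for suf in (".gz", ".fasta", ".fa", ".faa"):
            if species.endswith(suf):
                species = species[: -len(suf)]
        base = Path(tdi_dir) if tdi_dir else aa_path.parent
        tdi_path = None
        for cand in (base / f"{species}.3di.fasta", base / f"{species}.3di.fa"):
            if cand.exists():
                tdi_path = cand
                break
        records, unresolved = read_proteome(aa_path, tdi_path, species)
        if unresolved:
            resolved, unresolved = resolve_3di(unresolved, lookup, converter)
            records.extend(resolved)
        if unresolved:
            logger.warning(
                "%s: %d records lack a 3Di source and are dropped",
                species, len(unresolved),
            )
        per_species[species] = records
    return build_database(per_species, max_len=max_len)


def easy_core(
    db: PairedDatabase | None = None,
    aa_fastas: list | None = None,
    tdi_dir=None,
    lookup_tsv=None,
    out_dir: str | Path = "structcore_out",
    threshold: float = 0.8,
    gap_frac: float = 0.5,
    cluster_params: ClusterParams | None = None,
    model: SubstitutionModel | None = None,
    seed: int = 42,
    bootstrap_reps: int = 100,
    max_len: int = 4000,
    tree_options: str | None = None,
) -> EasyCoreResult:
    """Run the full pipeline and write all artifacts under ``out_dir``.

    Stages run in order (createdb, cluster, profile, align, tree); a stage
    failure raises with the stage name and leaves a FAILED marker naming it.
    ``tree_options`` is stored in the manifest and forwarded only when an
    external tree builder is requested explicitly; the built-in builder is
    neighbor joining with ``bootstrap_reps`` replicates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = model or SubstitutionModel()
    params = cluster_params or ClusterParams()
    manifest = {
        "seed": seed,
        "threshold": threshold,
        "gap_frac": gap_frac,
        "max_len": max_len,
        "bootstrap_reps": bootstrap_reps,
        "cluster_params": asdict(params),
        "tree_options": tree_options,
        "stages": [],
    }

    stage = "createdb"
    try:
        if db is None:
            if not aa_fastas:
                raise ValueError("need either a database or FASTA inputs")
            db = createdb(aa_fastas, tdi_dir, lookup_tsv, max_len=max_len)
        if not params.max_seqs:
            params.max_seqs = structcluster.default_max_seqs(db.n_species)
        write_database(db, out / "db")
        manifest["stages"].append(stage)
        manifest["n_species"] = db.n_species
        manifest["n_records"] = len(db)
        manifest["max_seqs"] = params.max_seqs

        stage = "cluster"
        clusters = structcluster.cascade_cluster(db, params, model, seed=seed)
        structcluster.write_cluster_tsv(clusters, out / "clusters.tsv")
        manifest["stages"].append(stage)

        stage = "profile"
        profiles = coreprofile.profile_clusters(clusters, db)
        core_set = coreprofile.select_core(profiles, threshold)
        warnings = coreprofile.species_representation_warnings(
            core_set, profiles, db.species_ids
        )
        coreprofile.write_profiles_tsv(profiles, db, out / "profiles.tsv")
        coreprofile.write_core_genes_tsv(
            core_set, profiles, out / "core_genes.tsv"
        )
        coreprofile.write_warnings_tsv(warnings, out / "warnings.tsv")
        manifest["stages"].append(stage)
        manifest["n_core_genes"] = len(core_set.core_cluster_ids)

        stage = "align"
        aln_dir = out / "alignments"
        aln_dir.mkdir(exist_ok=True)
        by_id = {c.rep_id: c for c in clusters}
        prof_by_id = {p.cluster_id: p for p in profiles}
        projected: list[msta.ProjectedMsa] = []
        for cid in core_set.core_cluster_ids:
            prof = prof_by_id[cid]
            single_species = {
                sp for sp, n in prof.copy_count.items() if n == 1
            }
            members = sorted(
                (
                    db.index[m] for m in by_id[cid].member_ids
                    if db.index[m].species_id in single_species
                ),
                key=lambda r: r.protein_id,
            )
            if len(members) < 2:
                logger.warning("core gene %s: fewer than 2 single-copy "
                               "members; skipped", cid)
                continue
            gene_id = cid.replace("|", "_")
            filtered, proj, _kept = msta.align_core_gene(
                members, model, db, gene_id=gene_id, max_gap_frac=gap_frac
            )
            msta.write_alignment_fasta(
                [(pid, row) for _, pid, row in filtered.rows],
                aln_dir / f"{gene_id}.3di.fasta",
            )
            msta.write_alignment_fasta(
                [(sp, row) for sp, row in proj.rows],
                aln_dir / f"{gene_id}.aa.fasta",
            )
            projected.append(proj)
        supermatrix = None
        if projected:
            supermatrix = msta.concatenate(projected, db.species_ids)
            msta.write_supermatrix(
                supermatrix, out / "supermatrix.fasta", out / "partitions.txt"
            )
        manifest["stages"].append(stage)

        stage = "tree"
        species_tree = rooted = None
        gene_trees = {}
        if supermatrix is not None and db.n_species >= 3:
            species_tree = phylo.bootstrap_support(
                supermatrix.to_dict(), n_reps=bootstrap_reps, seed=seed
            )
            phylo.write_newick(species_tree, out / "species_tree.nwk")
            rooted = phylo.mad_root(species_tree)
            phylo.write_newick(rooted, out / "species_tree.rooted.nwk")
            gt_dir = out / "gene_trees"
            gt_dir.mkdir(exist_ok=True)
            for proj in projected:
                rows = proj.to_dict()
                if len(rows) < 3:
                    continue
                try:
                    gtree = phylo.nj_tree(phylo.pairwise_distance(rows))
                except ValueError as exc:
                    logger.warning("gene tree %s skipped: %s",
                                   proj.gene_id, exc)
                    continue
                gene_trees[proj.gene_id] = gtree
                phylo.write_newick(gtree, gt_dir / f"{proj.gene_id}.nwk")
                phylo.write_newick(
                    phylo.mad_root(gtree),
                    gt_dir / f"{proj.gene_id}.rooted.nwk",
                )
        manifest["stages"].append(stage)
    except Exception:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        logger.error("easy-core failed at stage %r", stage)
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return EasyCoreResult(
        out_dir=out,
        db=db,
        clusters=clusters,
        profiles=profiles,
        core_set=core_set,
        supermatrix=supermatrix,
        species_tree=species_tree,
        rooted_tree=rooted,
        gene_trees=gene_trees,
    )
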