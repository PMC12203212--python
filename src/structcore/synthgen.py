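"""Synthetic multi-species proteomes with planted gene families.

Species are related by a random ultrametric tree of known height. Each gene
family starts from random root AA and 3Di strings that evolve down the tree
under independent uniform (Jukes-Cantor-like) substitution processes — AA
typically faster than 3Di, which is what makes the "twilight zone" regime
(AA identity below 30% while 3Di stays conserved) reproducible on demand.
No indels are simulated, so the true alignment of a family is the identity
column map.

Core families are planted to be single-copy in at least a configured
fraction of species (loss/duplication draws are rejection-sampled to keep
the planted label unambiguous); accessory families are present in a minority
subset of species. Everything is reproducible from a single seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .iodb import PairedDatabase, ProteinRecord, build_database
from .substitution import ALPHABET

logger = logging.getLogger(__name__)


@dataclass
class SynthConfig:
    """Study conditions for one simulated dataset.

    Rates are expected substitutions per site per unit of tree height. The
    defaults (20 species, 50 core + 50 accessory families, lengths 120-400,
    10% loss, 5% duplication) describe a detectable-homology regime;
    :meth:`twilight` switches to rates where AA identity decays below 30%
    while 3Di identity stays above 80%.
    """

    n_species: int = 20
    n_core_families: int = 50
    n_accessory_families: int = 50
    seq_len_range: tuple[int, int] = (120, 400)
    species_tree_height: float = 0.5
    rate_aa: float = 0.5
    rate_3di: float = 0.15
    loss_prob: float = 0.1
    dup_prob: float = 0.05
    core_coverage_floor: float = 0.8
    accessory_presence: tuple[float, float] = (0.2, 0.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.rate_aa >= self.rate_3di >= 0):
            raise ValueError("rates must satisfy rate_aa >= rate_3di >= 0")
        for p in (self.loss_prob, self.dup_prob, self.core_coverage_floor):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")

    @classmethod
    def twilight(cls, **overrides) -> "SynthConfig":
        """Twilight-zone regime: AA past the twilight zone, 3Di conserved."""
        base = dict(rate_aa=2.5, rate_3di=0.08, species_tree_height=0.5)
        base.update(overrides)
        return cls(**base)


@dataclass
class FamilyTruth:
    family_id: str
    status: str  # "core" or "accessory"
    length: int  # true column map is the identity over this many columns


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline must rediscover."""

    species_tree: dendropy.Tree
    family_assignments: dict[str, str] = field(default_factory=dict)
    families: dict[str, FamilyTruth] = field(default_factory=dict)
    per_species: dict[str, list[ProteinRecord]] = field(default_factory=dict)

    def members_of(self, family_id: str) -> set[str]:
        return {
            pid for pid, fam in self.family_assignments.items()
            if fam == family_id
        }

    def true_single_copy_coverage(self, family_id: str) -> float:
        counts: dict[str, int] = {}
        for pid, fam in self.family_assignments.items():
            if fam == family_id:
                sp = pid.split("|", 1)[0]
                counts[sp] = counts.get(sp, 0) + 1
        n_species = len(self.per_species)
        return sum(1 for v in counts.values() if v == 1) / n_species


# ---------------------------------------------------------------------------
# species tree


def _random_ultrametric_tree(
    species: list[str], height: float, rng: np.random.Generator
) -> dendropy.Tree:
    """Random coalescent-style ultrametric tree scaled to ``height``."""
    n = len(species)
    taxa = dendropy.TaxonNamespace(species)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for sp in species:
        node = dendropy.Node(taxon=taxa.get_taxon(sp))
        node.age_ = 0.0
        nodes.append(node)
    waits = rng.exponential(1.0, size=n - 1)
    ages = np.cumsum(waits)
    ages = ages / ages[-1] * height if n > 1 else ages
    active = nodes[:]
    for age in ages:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        parent = dendropy.Node()
        parent.age_ = float(age)
        for child in (active[i], active[j]):
            parent.add_child(child)
            child.edge.length = parent.age_ - child.age_
        active = [nd for k, nd in enumerate(active) if k not in (i, j)]
        active.append(parent)
    tree.seed_node = active[0]
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# sequence evolution


def _evolve(seq: np.ndarray, rate: float, t: float,
            rng: np.random.Generator) -> np.ndarray:
    """Uniform 20-state substitution: with probability ``1 - exp(-a*r*t)``
    a site is resampled uniformly from all 20 letters (a = 20/19 normalises
    ``rate`` to expected substitutions per site)."""
    if t <= 0 or rate <= 0:
        return seq.copy()
    p_event = 1.0 - np.exp(-(20.0 / 19.0) * rate * t)
    hit = rng.random(seq.size) < p_event
    out = seq.copy()
    out[hit] = rng.integers(0, 20, size=int(hit.sum()))
    return out


def _evolve_down(
    tree: dendropy.Tree,
    root_seq: np.ndarray,
    rate: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Evolve one sequence down the species tree; returns per-leaf arrays."""
    out: dict[str, np.ndarray] = {}
    stack = [(tree.seed_node, root_seq)]
    while stack:
        node, seq = stack.pop()
        if node.is_leaf():
            out[node.taxon.label] = seq
            continue
        for child in node.child_nodes():
            stack.append(
                (child, _evolve(seq, rate, child.edge.length or 0.0, rng))
            )
    return out


def _to_str(arr: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in arr)


# ---------------------------------------------------------------------------
# simulation


def simulate(config: SynthConfig) -> tuple[dict[str, list[ProteinRecord]], GroundTruth]:
    """Draw one dataset: per-species record lists plus the ground truth.

    Per core family each species is lost with ``loss_prob`` or duplicated
    with ``dup_prob`` (the duplicate re-diverged by an extra 10% of the tree
    height); draws are redone until the family's realized single-copy
    coverage reaches ``core_coverage_floor``, keeping the planted core label
    exact. Accessory families are planted in a random minority of species
    (presence fraction drawn from ``accessory_presence``, capped below the
    floor). Byte-identical outputs for identical configs.
    """
    rng = np.random.default_rng(config.seed)
    species = [f"s{i:03d}" for i in range(config.n_species)]
    tree = _random_ultrametric_tree(
        species, config.species_tree_height, rng
    )
    truth = GroundTruth(species_tree=tree)
    per_species: dict[str, list[ProteinRecord]] = {sp: [] for sp in species}

    lo, hi = config.seq_len_range
    dup_t = 0.1 * config.species_tree_height
    n_total = config.n_core_families + config.n_accessory_families
    floor_count = int(np.ceil(config.core_coverage_floor * config.n_species))

    for fam_idx in range(n_total):
        is_core = fam_idx < config.n_core_families
        fam_id = (
            f"core{fam_idx:03d}" if is_core
            else f"acc{fam_idx - config.n_core_families:03d}"
        )
        length = int(rng.integers(lo, hi + 1))
        root_aa = rng.integers(0, 20, size=length)
        root_tdi = rng.integers(0, 20, size=length)
        leaf_aa = _evolve_down(tree, root_aa, config.rate_aa, rng)
        leaf_tdi = _evolve_down(tree, root_tdi, config.rate_3di, rng)

        if is_core:
            # reject loss/dup draws that would sink the planted family
            # below the single-copy coverage floor
            while True:
                lost = rng.random(config.n_species) < config.loss_prob
                dup = rng.random(config.n_species) < config.dup_prob
                single = int((~lost & ~dup).sum())
                if single >= floor_count:
                    break
            present = ~lost
        else:
            frac = rng.uniform(*config.accessory_presence)
            n_present = max(2, int(round(frac * config.n_species)))
            n_present = min(n_present, floor_count - 1)
            chosen = rng.choice(config.n_species, size=n_present,
                                replace=False)
            present = np.zeros(config.n_species, dtype=bool)
            present[chosen] = True
            dup = (rng.random(config.n_species) < config.dup_prob) & present

        truth.families[fam_id] = FamilyTruth(
            fam_id, "core" if is_core else "accessory", length
        )
        for si, sp in enumerate(species):
            if not present[si]:
                continue
            copies = [(fam_id, leaf_aa[sp], leaf_tdi[sp])]
            if dup[si]:
                copies.append((
                    f"{fam_id}.d1",
                    _evolve(leaf_aa[sp], config.rate_aa, dup_t, rng),
                    _evolve(leaf_tdi[sp], config.rate_3di, dup_t, rng),
                ))
            for pid, aa, tdi in copies:
                rec = ProteinRecord(sp, pid, _to_str(aa), _to_str(tdi))
                per_species[sp].append(rec)
                truth.family_assignments[f"{sp}|{pid}"] = fam_id

    truth.per_species = per_species
    return per_species, truth


def simulated_database(config: SynthConfig) -> tuple[PairedDatabase, GroundTruth]:
    """Convenience: simulate and assemble the paired database directly."""
    per_species, truth = simulate(config)
    return build_database(per_species), truth


def write_simulation(
    per_species: dict[str, list[ProteinRecord]],
    truth: GroundTruth,
    out_dir: str | Path,
) -> None:
    """Write per-species FASTA pairs plus a truth/ directory."""
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    for sp, recs in per_species.items():
        with open(out / f"{sp}.fasta", "w") as fa, \
                open(out / f"{sp}.3di.fasta", "w") as ft:
            for rec in recs:
                fa.write(f">{rec.protein_id}\n{rec.aa}\n")
                ft.write(f">{rec.protein_id}\n{rec.tdi}\n")
    truth.species_tree.write(
        path=str(out / "truth" / "species_tree.nwk"), schema="newick",
        suppress_rooting=True,
    )
    with open(out / "truth" / "family_assignments.tsv", "w") as fh:
        fh.write("protein_id\tfamily_id\tstatus\n")
        for pid, fam in sorted(truth.family_assignments.items()):
            fh.write(f"{pid}\t{fam}\t{truth.families[fam].status}\n")


# ---------------------------------------------------------------------------
# evaluation against the truth


def truth_metrics(
    truth: GroundTruth,
    clusters=None,
    core_cluster_ids: list[str] | None = None,
    inferred_tree: dendropy.Tree | None = None,
) -> dict[str, float]:
    """Score pipeline outputs against the planted truth.

    Returns whichever of these the inputs allow: adjusted Rand index of the
    clustering vs the planted families; precision/recall/F1 of core-gene
    recovery (a planted core family is recovered iff some selected core
    cluster shares >= 80% of its members with it); and quartet similarity of
    the inferred species tree to the true one.
    """
    out: dict[str, float] = {}
    if clusters is not None:
        from sklearn.metrics import adjusted_rand_score

        pids = sorted(truth.family_assignments)
        true_labels = [truth.family_assignments[p] for p in pids]
        label_of = {}
        for c in clusters:
            for m in c.member_ids:
                label_of[m] = c.rep_id
        pred_labels = [label_of.get(p, f"unassigned:{p}") for p in pids]
        out["ari"] = float(adjusted_rand_score(true_labels, pred_labels))

    if core_cluster_ids is not None and clusters is not None:
        by_id = {c.rep_id: c for c in clusters}
        core_families = {
            f for f, t in truth.families.items() if t.status == "core"
        }
        recovered: set[str] = set()
        n_good_clusters = 0
        for cid in core_cluster_ids:
            members = by_id[cid].member_ids
            fams: dict[str, int] = {}
            for m in members:
                fam = truth.family_assignments.get(m)
                if fam is not None:
                    fams[fam] = fams.get(fam, 0) + 1
            best_fam, best_n = max(
                fams.items(), key=lambda t: (t[1], t[0]), default=(None, 0)
            )
            if best_fam is not None and best_n / len(members) >= 0.8:
                if best_fam in core_families:
                    n_good_clusters += 1
                    recovered.add(best_fam)
        precision = n_good_clusters / len(core_cluster_ids) \
            if core_cluster_ids else 0.0
        recall = len(recovered) / len(core_families) if core_families else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0 else 0.0
        )
        out["core_precision"] = precision
        out["core_recall"] = recall
        out["core_f1"] = f1

    if inferred_tree is not None:
        from .treemetrics import quartet_similarity

        out["quartet_similarity"] = quartet_similarity(
            inferred_tree, truth.species_tree
        ).similarity
    return out


def mean_family_identity(
    truth: GroundTruth, channel: str = "aa", max_families: int | None = None
) -> float:
    """Mean pairwise identity within families (sequences are unaligned but
    equal-length within a family, so identity is positional)."""
    idents = []
    fam_ids = sorted(truth.families)
    if max_families:
        fam_ids = fam_ids[:max_families]
    members_by_fam: dict[str, list[ProteinRecord]] = {f: [] for f in fam_ids}
    for sp, recs in truth.per_species.items():
        for rec in recs:
            fam = truth.family_assignments[f"{sp}|{rec.protein_id}"]
            if fam in members_by_fam:
                members_by_fam[fam].append(rec)
    for fam, members in members_by_fam.items():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a = members[i].aa if channel == "aa" else members[i].tdi
                b = members[j].aa if channel == "aa" else members[j].tdi
                idents.append(
                    sum(x == y for x, y in zip(a, b)) / len(a)
                )
    return float(np.mean(idents)) if idents else float("nan")
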