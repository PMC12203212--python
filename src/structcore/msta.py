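"""Progressive multiple structural alignment and amino-acid projection.

Each core gene's single-copy members are aligned progressively in 3Di space
along a neighbor-joining guide tree, profile against profile, columns scored
by the mean pairwise combined 3Di+AA score. Gappy columns (gap fraction >=
50%) are removed, the surviving columns are projected back to amino acids by
positional mapping, and the per-gene amino-acid alignments are concatenated
into a partitioned supermatrix for tree inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._kernels import global_align_profile
from .iodb import PairedDatabase, ProteinRecord
from .structcluster import _align_stats
from .substitution import ALPHABET_X, SubstitutionModel, encode

logger = logging.getLogger(__name__)

GAP = "-"
#: Partition model string written to the RAxML-style partition file.
PARTITION_MODEL = "JTT+F+I+G"


@dataclass
class Msta:
    """Gapped 3Di alignment of one core gene.

    ``residue_idx`` optionally maps every aligned cell to the 0-based residue
    index in the member's original sequence (-1 for gaps); it is produced by
    the aligner and carried through column filtering so that the amino-acid
    projection stays exact even after columns are dropped. For an unfiltered
    alignment it is simply the running non-gap count per row.
    """

    gene_id: str
    rows: list[tuple[str, str, str]]  # (species_id, protein_id, aligned_tdi)
    residue_idx: list[np.ndarray] | None = None

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][2]) if self.rows else 0

    def __post_init__(self) -> None:
        lens = {len(r[2]) for r in self.rows}
        if len(lens) > 1:
            raise ValueError(f"{self.gene_id}: ragged alignment rows")
        if self.residue_idx is None and self.rows:
            # unfiltered contract: k-th non-gap letter is the k-th residue
            idx = []
            for _, _, row in self.rows:
                arr = np.full(len(row), -1, dtype=np.int64)
                k = 0
                for c, ch in enumerate(row):
                    if ch != GAP:
                        arr[c] = k
                        k += 1
                idx.append(arr)
            self.residue_idx = idx


@dataclass
class ProjectedMsa:
    """Amino-acid projection of a (filtered) 3Di alignment."""

    gene_id: str
    rows: list[tuple[str, str]]  # (species_id, aligned_aa)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def to_dict(self) -> dict[str, str]:
        return {sp: row for sp, row in self.rows}


@dataclass
class Supermatrix:
    """Concatenated projected alignments with 1-based partition ranges."""

    rows: dict[str, str]
    partitions: list[tuple[str, int, int]]  # (gene_id, start, end) inclusive

    @property
    def n_cols(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def to_dict(self) -> dict[str, str]:
        return dict(self.rows)


# ---------------------------------------------------------------------------
# guide tree


def _pairwise_guide_distances(
    members: list[ProteinRecord], model: SubstitutionModel
) -> np.ndarray:
    """d(a, b) = 1 - raw(a, b) / min(raw(a, a), raw(b, b)), clamped to [0, 1]."""
    n = len(members)
    self_raw = np.array(
        [_align_stats(m, m, model)[0] for m in members], dtype=float
    )
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            raw, _, _ = _align_stats(members[i], members[j], model)
            norm = min(self_raw[i], self_raw[j])
            sim = raw / norm if norm > 0 else 0.0
            D[i, j] = D[j, i] = min(1.0, max(0.0, 1.0 - sim))
    return D


def guide_tree(
    members: list[ProteinRecord], model: SubstitutionModel
):
    """Neighbor-joining join order for progressive alignment.

    Returns a nested tuple of member indices (a rooted merge order derived
    from NJ agglomeration on alignment-score distances). Deterministic: ties
    are broken by member index.
    """
    n = len(members)
    if n == 0:
        raise ValueError("no members")
    if n == 1:
        return 0
    if n == 2:
        return (0, 1)
    D = _pairwise_guide_distances(members, model)
    nodes: list[object] = list(range(n))
    active = list(range(n))
    Dw = D.copy()
    while len(active) > 2:
        na = len(active)
        r = {i: sum(Dw[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(na):
            for aj in range(ai + 1, na):
                i, j = active[ai], active[aj]
                q = (na - 2) * Dw[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        new = len(nodes)
        nodes.append((nodes[i], nodes[j]))
        Dw = np.pad(Dw, ((0, 1), (0, 1)))
        for k in active:
            if k not in (i, j):
                Dw[new, k] = Dw[k, new] = (Dw[i, k] + Dw[j, k] - Dw[i, j]) / 2
        active = [k for k in active if k not in (i, j)] + [new]
    a, b = active
    return (nodes[a], nodes[b])


# ---------------------------------------------------------------------------
# progressive profile alignment

_N_SYMBOLS = 21  # 20 letters + X; gaps are encoded as -1 in profiles


class _Profile:
    """Aligned block: (rows x cols) int arrays for 3Di and AA, -1 = gap."""

    def __init__(self, member_idx: list[int], tdi: np.ndarray, aa: np.ndarray):
        self.member_idx = member_idx
        self.tdi = tdi
        self.aa = aa

    @classmethod
    def leaf(cls, idx: int, rec: ProteinRecord) -> "_Profile":
        return cls([idx], encode(rec.tdi)[None, :].astype(np.int16),
                   encode(rec.aa)[None, :].astype(np.int16))

    def counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-column symbol counts (cols x 21) and non-gap counts."""
        n_cols = self.tdi.shape[1]
        c3 = np.zeros((n_cols, _N_SYMBOLS))
        ca = np.zeros((n_cols, _N_SYMBOLS))
        for row3, rowa in zip(self.tdi, self.aa):
            mask = row3 >= 0
            cols = np.nonzero(mask)[0]
            np.add.at(c3, (cols, row3[mask]), 1)
            np.add.at(ca, (cols, rowa[mask]), 1)
        nongap = c3.sum(axis=1)
        return c3, ca, nongap


def _column_scores(
    pa: _Profile, pb: _Profile, model: SubstitutionModel
) -> np.ndarray:
    """Mean pairwise combined score between every column pair."""
    c3a, caa, ga = pa.counts()
    c3b, cab, gb = pb.counts()
    num = model.w3di * (c3a @ model.mat3di @ c3b.T) \
        + model.waa * (caa @ model.mataa @ cab.T)
    denom = np.outer(ga, gb)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(denom > 0, num / np.maximum(denom, 1), 0.0)
    return S


def _merge(pa: _Profile, pb: _Profile, model: SubstitutionModel) -> _Profile:
    S = _column_scores(pa, pb, model)
    _, qa, ta = global_align_profile(S, float(model.gap_open),
                                     float(model.gap_extend))
    n_cols = len(qa)

    def expand(block: np.ndarray, path: np.ndarray) -> np.ndarray:
        out = np.full((block.shape[0], n_cols), -1, dtype=np.int16)
        sel = path >= 0
        out[:, np.nonzero(sel)[0]] = block[:, path[sel]]
        return out

    return _Profile(
        pa.member_idx + pb.member_idx,
        np.vstack([expand(pa.tdi, qa), expand(pb.tdi, ta)]),
        np.vstack([expand(pa.aa, qa), expand(pb.aa, ta)]),
    )


def progressive_align(
    members: list[ProteinRecord],
    join_order,
    model: SubstitutionModel,
    gene_id: str = "gene",
) -> Msta:
    """Align members progressively along ``join_order`` (from guide_tree).

    Row order follows the input member order; removing the gaps from any row
    reproduces that member's 3Di string exactly.
    """
    if not members:
        raise ValueError("no members to align")

    def build(node) -> _Profile:
        if isinstance(node, int):
            return _Profile.leaf(node, members[node])
        left, right = node
        return _merge(build(left), build(right), model)

    prof = build(join_order)
    order = np.argsort(prof.member_idx)
    rows = []
    sym = ALPHABET_X + GAP  # index -1 -> '-'
    for k in order:
        rec = members[prof.member_idx[k]]
        aligned = "".join(sym[v] for v in prof.tdi[k])
        rows.append((rec.species_id, rec.protein_id, aligned))
    return Msta(gene_id, rows)


# ---------------------------------------------------------------------------
# filtering, projection, concatenation


def filter_gappy_columns(
    msa: Msta, max_gap_frac: float = 0.5
) -> tuple[Msta, list[int]]:
    """Remove columns whose gap fraction is >= ``max_gap_frac``.

    Only ``-`` counts as a gap ('X' is a residue). Returns the filtered
    alignment and the list of retained original column indices. Removing
    every column is an error.
    """
    n_rows = len(msa.rows)
    kept = []
    for col in range(msa.n_cols):
        gaps = sum(1 for _, _, row in msa.rows if row[col] == GAP)
        if gaps / n_rows < max_gap_frac - 1e-12:
            kept.append(col)
    if not kept:
        raise ValueError(f"{msa.gene_id}: all columns removed by gap filter")
    rows = [
        (sp, pid, "".join(row[c] for c in kept)) for sp, pid, row in msa.rows
    ]
    kept_arr = np.asarray(kept)
    residue_idx = [arr[kept_arr] for arr in msa.residue_idx]
    return Msta(msa.gene_id, rows, residue_idx), kept


def project_to_aa(msta: Msta, db: PairedDatabase) -> ProjectedMsa:
    """Map each aligned 3Di letter back to its residue, gaps to gaps.

    The k-th non-gap position of a row corresponds to the k-th residue of
    the member's sequence — valid also after column filtering, where the
    surviving 3Di letters select exactly the residues at kept positions.
    A row whose gap-free 3Di does not occur in-order in the database record
    is a hard error.
    """
    rows = []
    for (sp, pid, aligned), idx in zip(msta.rows, msta.residue_idx):
        rec = db.index.get(pid)
        if rec is None:
            raise ValueError(f"{msta.gene_id}: unknown record {pid!r}")
        out = []
        for ch, k in zip(aligned, idx):
            if ch == GAP:
                if k != -1:
                    raise ValueError(
                        f"{msta.gene_id}: row {pid!r} has an inconsistent "
                        "residue map"
                    )
                out.append(GAP)
                continue
            if k < 0 or k >= len(rec.tdi) or rec.tdi[k] != ch:
                raise ValueError(
                    f"{msta.gene_id}: row {pid!r} does not match the "
                    "database 3Di string"
                )
            out.append(rec.aa[k])
        rows.append((sp, "".join(out)))
    return ProjectedMsa(msta.gene_id, rows)


def concatenate(
    projected_msas: list[ProjectedMsa], all_species: list[str]
) -> Supermatrix:
    """Concatenate per-gene alignments into a partitioned supermatrix.

    Species missing from a gene receive an all-gap block of that gene's
    width; a species appearing twice in one gene is a hard error.
    Partition coordinates are 1-based inclusive, in input gene order.
    """
    rows = {sp: [] for sp in all_species}
    partitions = []
    pos = 1
    for msa in projected_msas:
        width = msa.n_cols
        seen: dict[str, str] = {}
        for sp, row in msa.rows:
            if sp in seen:
                raise ValueError(
                    f"{msa.gene_id}: species {sp!r} appears twice"
                )
            seen[sp] = row
        for sp in all_species:
            rows[sp].append(seen.get(sp, GAP * width))
        partitions.append((msa.gene_id, pos, pos + width - 1))
        pos += width
    return Supermatrix({sp: "".join(parts) for sp, parts in rows.items()},
                       partitions)


def align_core_gene(
    members: list[ProteinRecord],
    model: SubstitutionModel,
    db: PairedDatabase,
    gene_id: str = "gene",
    max_gap_frac: float = 0.5,
) -> tuple[Msta, ProjectedMsa, list[int]]:
    """Guide tree -> progressive 3Di alignment -> gap filter -> AA projection."""
    order = guide_tree(members, model)
    msta = progressive_align(members, order, model, gene_id=gene_id)
    filtered, kept = filter_gappy_columns(msta, max_gap_frac)
    projected = project_to_aa(filtered, db)
    return filtered, projected, kept


# ---------------------------------------------------------------------------
# on-disk formats


def write_alignment_fasta(rows: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in rows:
            fh.write(f">{name}\n{seq}\n")


def write_supermatrix(
    sm: Supermatrix, fasta_path: str | Path, partition_path: str | Path
) -> None:
    """FASTA plus RAxML-style partition lines ``MODEL, gene = start-end``."""
    write_alignment_fasta(sorted(sm.rows.items()), fasta_path)
    with open(partition_path, "w") as fh:
        for gene_id, start, end in sm.partitions:
            fh.write(f"{PARTITION_MODEL}, {gene_id} = {start}-{end}\n")
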