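"""Paired amino-acid / 3Di proteome database.

Each protein carries two equal-length strings: its amino-acid sequence and
its 3Di string (one structural state per residue, written in the same 20
uppercase letters — the Foldseek convention). Proteomes arrive as one FASTA
per species for each alphabet, paired record-by-record via identical FASTA
headers. Proteins whose 3Di string is missing can be resolved later from an
exact-sequence lookup table or a pluggable converter (e.g. a ProstT5
adapter running out of process).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO

from .substitution import ALPHABET_X

logger = logging.getLogger(__name__)

_VALID = set(ALPHABET_X)


def _clean(seq: str, header: str, kind: str) -> str:
    """Uppercase and map out-of-alphabet letters to 'X' (with a warning)."""
    seq = seq.upper()
    if set(seq) <= _VALID:
        return seq
    bad = sorted(set(seq) - _VALID)
    logger.warning("%s %s: residues %s outside alphabet mapped to X",
                   kind, header, "".join(bad))
    return "".join(c if c in _VALID else "X" for c in seq)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: paired AA and 3Di strings of equal length.

    ``tdi`` may be None for a not-yet-resolved record; once set it must have
    exactly one 3Di letter per residue.
    """

    species_id: str
    protein_id: str
    aa: str
    tdi: str | None = None

    def __post_init__(self) -> None:
        if len(self.aa) < 1:
            raise ValueError(f"{self.protein_id}: empty amino-acid sequence")
        if "-" in self.aa or (self.tdi and "-" in self.tdi):
            raise ValueError(f"{self.protein_id}: gap characters not allowed")
        if self.tdi is not None and len(self.tdi) != len(self.aa):
            raise ValueError(
                f"length mismatch for {self.protein_id}: "
                f"aa={len(self.aa)} 3di={len(self.tdi)}"
            )

    @property
    def resolved(self) -> bool:
        return self.tdi is not None

    def __len__(self) -> int:
        return len(self.aa)


class LookupTable:
    """Exact amino-acid-sequence → 3Di-string lookup (AFDB-style shortcut)."""

    def __init__(self, entries: dict[str, str] | None = None):
        self.entries: dict[str, str] = {}
        for aa, tdi in (entries or {}).items():
            self.add(aa, tdi)

    def add(self, aa: str, tdi: str) -> None:
        aa, tdi = aa.upper(), tdi.upper()
        if len(aa) != len(tdi):
            raise ValueError("lookup entry with mismatched AA/3Di lengths")
        self.entries[aa] = tdi

    def get(self, aa: str) -> str | None:
        return self.entries.get(aa.upper())

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LookupTable":
        """Read a 2-column TSV (aa_sequence, tdi_sequence)."""
        table = cls()
        with _open_text(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{ln}: expected 2 columns")
                table.add(parts[0], parts[1])
        return table

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for aa, tdi in self.entries.items():
                fh.write(f"{aa}\t{tdi}\n")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate header {rec.id!r} in {path}")
            seqs[rec.id] = str(rec.seq)
    return seqs


def read_proteome(
    aa_fasta_path: str | Path,
    tdi_fasta_path: str | Path | None = None,
    species_id: str | None = None,
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Read one species' proteome, pairing AA and 3Di records by header.

    Returns ``(records, unresolved)``: fully paired records, and records for
    which no 3Di source was available (``tdi is None``). A 3Di sequence whose
    length differs from its amino-acid partner is a hard error.
    """
    aa_path = Path(aa_fasta_path)
    if species_id is None:
        species_id = aa_path.name
        for suf in (".gz", ".fasta", ".fa", ".faa"):
            if species_id.endswith(suf):
                species_id = species_id[: -len(suf)]
    aa_seqs = _read_fasta(aa_path)
    tdi_seqs = _read_fasta(tdi_fasta_path) if tdi_fasta_path else {}

    records: list[ProteinRecord] = []
    unresolved: list[ProteinRecord] = []
    for header, aa in aa_seqs.items():
        aa = _clean(aa, header, "AA")
        tdi = tdi_seqs.get(header)
        if tdi is not None:
            tdi = _clean(tdi, header, "3Di")
            if len(tdi) != len(aa):
                raise ValueError(
                    f"length mismatch for {header!r}: aa={len(aa)} "
                    f"3di={len(tdi)}"
                )
            records.append(ProteinRecord(species_id, header, aa, tdi))
        else:
            unresolved.append(ProteinRecord(species_id, header, aa, None))
    return records, unresolved


def resolve_3di(
    unresolved_records: list[ProteinRecord],
    lookup: LookupTable | None = None,
    converter=None,
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Resolve missing 3Di strings: exact lookup first, then the converter.

    The converter is a callable ``aa_string -> tdi_string`` (the ProstT5
    process-boundary adapter); returning a string of the wrong length is a
    hard error. Already-resolved records pass through untouched, so the
    operation is idempotent.
    """
    resolved: list[ProteinRecord] = []
    still: list[ProteinRecord] = []
    for rec in unresolved_records:
        if rec.resolved:
            resolved.append(rec)
            continue
        tdi = lookup.get(rec.aa) if lookup is not None else None
        if tdi is None and converter is not None:
            tdi = converter(rec.aa)
        if tdi is None:
            still.append(rec)
            continue
        tdi = tdi.upper()
        if len(tdi) != len(rec.aa):
            raise ValueError(
                f"converter returned 3Di of length {len(tdi)} for "
                f"{rec.protein_id!r} (expected {len(rec.aa)})"
            )
        resolved.append(replace(rec, tdi=_clean(tdi, rec.protein_id, "3Di")))
    return resolved, still


@dataclass
class PairedDatabase:
    """All species' resolved records, indexed by namespaced protein id.

    Record ids are always namespaced as ``species_id|protein_id`` so ids are
    globally unique regardless of per-species naming.
    """

    records: list[ProteinRecord] = field(default_factory=list)
    species_ids: list[str] = field(default_factory=list)
    index: dict[str, ProteinRecord] = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def __len__(self) -> int:
        return len(self.records)

    def total_residues(self) -> int:
        return sum(len(r) for r in self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PairedDatabase):
            return NotImplemented
        return (
            self.records == other.records
            and self.species_ids == other.species_ids
        )


def build_database(
    per_species_records: dict[str, list[ProteinRecord]] | list[list[ProteinRecord]],
    max_len: int = 4000,
) -> PairedDatabase:
    """Assemble the paired database, excluding over-length records.

    Records longer than ``max_len`` (default 4000 residues) are dropped and
    the count logged. Unresolved records (no 3Di) are dropped with a warning.
    Requires at least 2 species.
    """
    if isinstance(per_species_records, dict):
        groups = list(per_species_records.items())
    else:
        groups = [(recs[0].species_id if recs else "?", recs)
                  for recs in per_species_records]
    if len(groups) < 2:
        raise ValueError("a paired database needs at least 2 species")
    db = PairedDatabase()
    n_excluded = n_unresolved = 0
    for species_id, recs in groups:
        db.species_ids.append(species_id)
        for rec in recs:
            if not rec.resolved:
                n_unresolved += 1
                continue
            if len(rec) > max_len:
                n_excluded += 1
                continue
            full_id = f"{species_id}|{rec.protein_id}"
            if full_id in db.index:
                raise ValueError(f"duplicate protein id {full_id!r}")
            stored = ProteinRecord(species_id, full_id, rec.aa, rec.tdi)
            db.records.append(stored)
            db.index[full_id] = stored
    if n_excluded:
        logger.info("excluded %d records longer than %d residues",
                    n_excluded, max_len)
    if n_unresolved:
        logger.warning("dropped %d records without a 3Di string", n_unresolved)
    return db


def write_database(db: PairedDatabase, path: str | Path) -> None:
    """Write the on-disk layout: db.aa.fasta, db.3di.fasta, db.meta.tsv."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "db.aa.fasta", "w") as fa, \
            open(path / "db.3di.fasta", "w") as ft:
        for rec in db.records:
            fa.write(f">{rec.protein_id}\n{rec.aa}\n")
            ft.write(f">{rec.protein_id}\n{rec.tdi}\n")
    with open(path / "db.meta.tsv", "w") as fm:
        fm.write("protein_id\tspecies_id\tlength\n")
        # species manifest first (preserves species order, even for species
        # that contributed no record), then one row per record
        for sp in db.species_ids:
            fm.write(f"-\t{sp}\t0\n")
        for rec in db.records:
            fm.write(f"{rec.protein_id}\t{rec.species_id}\t{len(rec)}\n")


def load_database(path: str | Path) -> PairedDatabase:
    """Load a database directory written by :func:`write_database`."""
    path = Path(path)
    meta = path / "db.meta.tsv"
    if not meta.exists():
        raise FileNotFoundError(f"{path} is not a database directory "
                                "(missing db.meta.tsv)")
    aa = _read_fasta(path / "db.aa.fasta")
    tdi = _read_fasta(path / "db.3di.fasta")
    species_of: dict[str, str] = {}
    species_order: list[str] = []
    order: list[str] = []
    with open(meta) as fh:
        header = fh.readline()
        if not header.startswith("protein_id"):
            raise ValueError(f"{meta}: unexpected header at offset 0")
        for ln, line in enumerate(fh, 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{meta}: parse error at line {ln}")
            pid, sp = parts[0], parts[1]
            if sp not in species_order:
                species_order.append(sp)
            if pid != "-":
                species_of[pid] = sp
                order.append(pid)
    db = PairedDatabase(species_ids=species_order)
    for pid in order:
        if pid not in aa or pid not in tdi:
            raise ValueError(f"{path}: record {pid!r} missing from FASTA")
        rec = ProteinRecord(species_of[pid], pid, aa[pid], tdi[pid])
        db.records.append(rec)
        db.index[pid] = rec
    return db
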