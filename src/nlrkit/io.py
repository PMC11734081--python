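"""Readers and writers for every on-disk format the pipeline touches.

Formats handled: InterProScan tab-separated output (11-15 columns),
multi-FASTA protein sequences, BED-like 4-column gene coordinate tables,
and TSV/JSON result tables.

Conventions: genomic coordinates are stored 0-based half-open internally;
domain-hit residue coordinates stay 1-based inclusive as emitted by
InterProScan and are never mixed with genomic coordinates.  Species
strings are normalized to single-space "Genus species" form and used as
grouping keys everywhere.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ValidationError
from .roles import IPR_PATTERN

logger = logging.getLogger(__name__)

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


def normalize_species(name: str) -> str:
    """Collapse whitespace to single spaces: 'Genus  species ' -> 'Genus species'."""
    return " ".join(str(name).split())


@dataclass(frozen=True)
class DomainHit:
    """One InterPro signature match on one protein.

    ``interpro_id`` is empty for member-database hits that InterProScan
    did not integrate into an InterPro entry; residue coordinates are
    1-based inclusive.
    """

    protein_id: str
    interpro_id: str
    signature_id: str
    start: int
    end: int
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"hit on {self.protein_id}: invalid span {self.start}..{self.end}"
            )
        if self.interpro_id and not IPR_PATTERN.match(self.interpro_id):
            raise ValidationError(
                f"hit on {self.protein_id}: bad InterPro accession {self.interpro_id!r}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    species: str
    gene_id: str = ""
    transcript_id: Optional[str] = None
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sequence is not None:
            bad = set(self.sequence) - _VALID_RESIDUES
            if bad:
                raise ValidationError(
                    f"{self.protein_id}: non-standard residues {sorted(bad)}"
                )


class AnnotationTable:
    """Proteins plus their domain hits, keyed by protein id.

    Every hit's protein_id resolves to a registered ProteinRecord.
    """

    def __init__(self) -> None:
        self.proteins: Dict[str, ProteinRecord] = {}
        self._hits: Dict[str, List[DomainHit]] = {}

    # -- construction -------------------------------------------------

    def add_protein(self, record: ProteinRecord, replace_existing: bool = False) -> None:
        if record.protein_id in self.proteins and not replace_existing:
            existing = self.proteins[record.protein_id]
            # merging a sequence into an annotation-only record is allowed
            merged = existing
            if record.sequence is not None and existing.sequence is None:
                merged = replace(existing, sequence=record.sequence)
            if record.gene_id and not existing.gene_id:
                merged = replace(merged, gene_id=record.gene_id)
            self.proteins[record.protein_id] = merged
            return
        self.proteins[record.protein_id] = record
        self._hits.setdefault(record.protein_id, [])

    def add_hit(self, hit: DomainHit) -> None:
        if hit.protein_id not in self.proteins:
            raise ValidationError(f"hit references unknown protein {hit.protein_id}")
        self._hits.setdefault(hit.protein_id, []).append(hit)

    def merge(self, other: "AnnotationTable") -> "AnnotationTable":
        out = AnnotationTable()
        for tab in (self, other):
            for rec in tab.proteins.values():
                out.add_protein(rec)
            for hit in tab.iter_hits():
                out.add_hit(hit)
        return out

    def subset(self, protein_ids: Iterable[str]) -> "AnnotationTable":
        keep = set(protein_ids)
        out = AnnotationTable()
        for pid in sorted(keep):
            out.add_protein(self.proteins[pid])
            for hit in self._hits.get(pid, ()):
                out.add_hit(hit)
        return out

    # -- access -------------------------------------------------------

    def hits_for(self, protein_id: str) -> Tuple[DomainHit, ...]:
        return tuple(self._hits.get(protein_id, ()))

    def iter_hits(self):
        for pid in self._hits:
            yield from self._hits[pid]

    def interpro_ids_for(self, protein_id: str) -> frozenset:
        return frozenset(
            h.interpro_id for h in self._hits.get(protein_id, ()) if h.interpro_id
        )

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_hits(self) -> int:
        return sum(len(v) for v in self._hits.values())

    def species_of(self) -> List[str]:
        return sorted({p.species for p in self.proteins.values()})

    def proteins_frame(self) -> pd.DataFrame:
        rows = [
            {
                "protein_id": p.protein_id,
                "species": p.species,
                "gene_id": p.gene_id,
                "transcript_id": p.transcript_id or "",
                "has_sequence": p.sequence is not None,
            }
            for p in self.proteins.values()
        ]
        frame = pd.DataFrame(
            rows,
            columns=["protein_id", "species", "gene_id", "transcript_id", "has_sequence"],
        )
        return frame.sort_values("protein_id", ignore_index=True)

    def hits_frame(self) -> pd.DataFrame:
        rows = [
            {
                "protein_id": h.protein_id,
                "interpro_id": h.interpro_id,
                "signature_id": h.signature_id,
                "start": h.start,
                "end": h.end,
                "score": h.score,
            }
            for h in self.iter_hits()
        ]
        frame = pd.DataFrame(
            rows,
            columns=["protein_id", "interpro_id", "signature_id", "start", "end", "score"],
        )
        return frame.sort_values(
            ["protein_id", "start", "interpro_id", "signature_id"], ignore_index=True
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        return self.proteins == other.proteins and {
            k: sorted(v, key=lambda h: (h.start, h.end, h.signature_id))
            for k, v in self._hits.items()
        } == {
            k: sorted(v, key=lambda h: (h.start, h.end, h.signature_id))
            for k, v in other._hits.items()
        }


@dataclass
class GeneCoordinateTable:
    """Gene coordinates, 0-based half-open, sorted by (species, chromosome, start)."""

    frame: pd.DataFrame

    COLUMNS = ["gene_id", "chromosome", "start", "end", "species"]

    def __post_init__(self) -> None:
        frame = self.frame.copy()
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"gene coordinate table missing columns {missing}")
        frame = frame[self.COLUMNS]
        bad = frame.index[frame["start"] >= frame["end"]].tolist()
        if bad:
            raise ValidationError(f"start >= end at row(s) {bad}")
        self.frame = frame.sort_values(
            ["species", "chromosome", "start", "gene_id"], ignore_index=True
        )

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneCoordinateTable):
            return NotImplemented
        return self.frame.equals(other.frame)


@dataclass
class ReferenceRGeneTable:
    """Reference R genes with their database-asserted classes."""

    frame: pd.DataFrame

    #: Closed vocabulary of reference classes (curated R-gene database export).
    CLASSES = (
        "CN", "CNL", "LECRK", "LYK", "LYP", "N",
        "NL", "Other", "RLK", "RLP", "T", "TNL",
    )
    COLUMNS = ["gene_name", "accession", "asserted_class", "species"]

    def __post_init__(self) -> None:
        frame = self.frame.copy()
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"reference table missing columns {missing}")
        unknown = set(frame["asserted_class"]) - set(self.CLASSES)
        if unknown:
            raise ValidationError(f"unknown reference classes {sorted(unknown)}")
        self.frame = frame[self.COLUMNS].sort_values("accession", ignore_index=True)

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------

def read_interproscan_tsv(path, species: str) -> AnnotationTable:
    """Parse InterProScan tab-separated output into an AnnotationTable.

    Accepts the 11-15 column layout (protein accession, MD5, length,
    analysis, signature accession/description, start, stop, score,
    status, date, then optional InterPro accession/description, GO and
    pathway columns); "-" marks a missing field.  Every row is retained
    as a hit; rows whose InterPro column is missing stay signature-level
    hits with an empty ``interpro_id``.
    """
    species = normalize_species(species)
    table = AnnotationTable()
    n_rows = n_kept = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if not 11 <= len(fields) <= 15:
                raise FormatError(
                    f"{path}: line {lineno}: expected 11-15 tab-separated "
                    f"columns, got {len(fields)}"
                )
            n_rows += 1
            pid = fields[0]
            signature = fields[4]
            try:
                start, end = int(fields[6]), int(fields[7])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            score: Optional[float] = None
            if fields[8] not in ("-", ""):
                try:
                    score = float(fields[8])
                except ValueError:
                    score = None
            ipr = fields[11] if len(fields) > 11 else ""
            if ipr in ("-", ""):
                ipr = ""
            table.add_protein(ProteinRecord(pid, species))
            table.add_hit(DomainHit(pid, ipr, signature, start, end, score))
            n_kept += 1
    logger.info(
        "read_interproscan_tsv(%s): %d rows in, %d hits retained, %d proteins",
        path, n_rows, n_kept, table.n_proteins,
    )
    return table


def read_fasta(path, species: str) -> AnnotationTable:
    """Read a multi-FASTA of protein sequences; header first token is the id."""
    species = normalize_species(species)
    table = AnnotationTable()
    seen: Dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        seen[pid] = seen.get(pid, 0) + 1
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for {pid}")
        table.add_protein(
            ProteinRecord(pid, species, sequence=seq), replace_existing=True
        )
    dups = sorted(p for p, n in seen.items() if n > 1)
    if dups:
        raise FormatError(f"{path}: duplicate sequence ids: {dups}")
    return table


def write_fasta(table: AnnotationTable, path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(table.proteins):
            rec = table.proteins[pid]
            if rec.sequence is None:
                continue
            fh.write(f">{pid}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def write_interproscan_tsv(table: AnnotationTable, path) -> None:
    """Write hits in the 13-column InterProScan TSV layout ("-" for missing).

    Inverse of :func:`read_interproscan_tsv` for the columns that reader
    consumes (protein id, signature, span, score, InterPro accession).
    """
    with open(path, "w") as fh:
        for pid in sorted(table.proteins):
            rec = table.proteins[pid]
            seq_len = len(rec.sequence) if rec.sequence else 0
            for hit in sorted(
                table.hits_for(pid), key=lambda h: (h.start, h.end, h.signature_id)
            ):
                score = "-" if hit.score is None else repr(hit.score)
                fields = [
                    pid, "-", str(seq_len), "SYNTH", hit.signature_id, "-",
                    str(hit.start), str(hit.end), score, "T", "-",
                    hit.interpro_id or "-", "-",
                ]
                fh.write("\t".join(fields) + "\n")


def read_gene_coordinates(path, species: str, one_based: bool = False) -> GeneCoordinateTable:
    """Read a BED-like 4-column TSV (chrom, start, end, gene_id).

    The default dialect is 0-based half-open; pass ``one_based=True``
    for 1-based fully-closed input, which is shifted on read.
    """
    species = normalize_species(species)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = re.split(r"\s+", line.strip())
            if len(fields) < 4:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=4 columns, got {len(fields)}"
                )
            chrom, start_s, end_s, gene_id = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if one_based:
                start -= 1
            if start >= end:
                raise ValidationError(
                    f"{path}: line {lineno}: start >= end after normalization"
                )
            rows.append(
                {"gene_id": gene_id, "chromosome": chrom, "start": start,
                 "end": end, "species": species}
            )
    frame = pd.DataFrame(rows, columns=GeneCoordinateTable.COLUMNS)
    return GeneCoordinateTable(frame)


def write_gene_coordinates(table: GeneCoordinateTable, path) -> None:
    """Write BED-like 0-based half-open 4-column TSV (per species file)."""
    with open(path, "w") as fh:
        for row in table.frame.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.start}\t{row.end}\t{row.gene_id}\n")


def read_gene_map(table: AnnotationTable, path) -> AnnotationTable:
    """Attach gene/transcript linkage from a TSV (protein_id, gene_id[, transcript_id]).

    InterProScan output carries no gene column, so gene linkage arrives
    as a companion table (as it does from an annotation-database export).
    Unknown protein ids are ignored.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("protein_id", "gene_id"):
        if col not in frame.columns:
            raise FormatError(f"{path}: gene map missing column {col}")
    out = AnnotationTable()
    linkage = frame.set_index("protein_id")
    for pid in table.proteins:
        rec = table.proteins[pid]
        if pid in linkage.index:
            row = linkage.loc[pid]
            rec = replace(
                rec,
                gene_id=row["gene_id"],
                transcript_id=row.get("transcript_id", rec.transcript_id),
            )
        out.add_protein(rec, replace_existing=True)
    for hit in table.iter_hits():
        out.add_hit(hit)
    return out


def write_gene_map(table: AnnotationTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tgene_id\ttranscript_id\n")
        for pid in sorted(table.proteins):
            rec = table.proteins[pid]
            fh.write(f"{pid}\t{rec.gene_id}\t{rec.transcript_id or ''}\n")


def read_reference_rgenes(path) -> ReferenceRGeneTable:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return ReferenceRGeneTable(frame)


# ---------------------------------------------------------------------
# generic result-table output
# ---------------------------------------------------------------------

def write_table(table, path, format: str = "tsv") -> None:
    """Write a tabular result byte-stably (fixed column order, sorted rows).

    Accepts a pandas DataFrame or any of the package's table wrappers
    exposing a ``frame`` attribute.
    """
    frame = getattr(table, "frame", table)
    if not isinstance(frame, pd.DataFrame):
        raise ValidationError(f"cannot write object of type {type(table).__name__}")
    frame = frame.sort_values(list(frame.columns), ignore_index=True)
    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
    elif format == "json":
        payload = frame.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise ValidationError(f"unknown output format {format!r}")


def read_table(path, format: str = "tsv") -> pd.DataFrame:
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        with open(path) as fh:
            return pd.DataFrame(json.load(fh))
    raise ValidationError(f"unknown input format {format!r}")
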