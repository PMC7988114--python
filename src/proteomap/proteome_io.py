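"""Reading proteome FASTA files and sanitizing sequences.

NCBI-style annotated proteomes use the extended one-letter alphabet: besides
the 20 canonical residues they may contain the ambiguity codes B (Asn/Asp),
J (Leu/Ile), Z (Gln/Glu), the unknown-residue code X ("Xaa"), the rare
proteinogenic residues U (selenocysteine) and O (pyrrolysine), and stop
symbols '*'.  Sanitization translates B→N, J→L, Z→Q, strips stops anywhere in
the sequence, uppercases, and keeps X/U/O while counting every special code.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The ten fungal groups used for per-phylum grouping.
PHYLA = (
    "Ascomycota", "Basidiomycota", "Blastocladiomycota", "Chytridiomycota",
    "Glomeromycota", "Microsporidia", "Mucoromycota", "Neocallimastigomycota",
    "Opisthokonta", "Zoopagomycota",
)

#: Ambiguity translation rules: B is Asn or Asp and translates to Asn,
#: J is Leu or Ile and translates to Leu, Z is Gln or Glu and translates to Gln.
AMBIGUITY_TRANSLATION = {"B": "N", "J": "L", "Z": "Q"}

SPECIAL_CODES = ("B", "J", "Z", "X", "U", "O", "*")


class FastaFormatError(ValueError):
    """Raised for files that are not syntactically valid FASTA."""


@dataclass
class ProteinRecord:
    """One protein sequence with its provenance and sanitization bookkeeping."""

    accession: str
    description: str = ""
    raw_sequence: str = ""
    clean_sequence: str = ""
    species_label: str = ""
    ambiguity_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class SpeciesMetadata:
    species: str
    phylum: str
    genome_size_mb: float | None = None
    fasta_path: str | None = None

    def __post_init__(self) -> None:
        if self.phylum not in PHYLA:
            raise ValueError(
                f"phylum {self.phylum!r} not in the ten-group vocabulary {PHYLA}")
        if self.genome_size_mb is not None and self.genome_size_mb <= 0:
            raise ValueError("genome_size_mb must be positive")


# ---------------------------------------------------------------------------
# FASTA reading / writing
# ---------------------------------------------------------------------------

def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path, species_label: str = "") -> list[ProteinRecord]:
    """Parse a (plain or gzipped) multi-FASTA protein file.

    Wrapped sequence lines are concatenated, whitespace removed and letters
    uppercased; record order is preserved.  A file with no FASTA header is a
    format error, as is a header with an empty id.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, "fasta"):
                if not rec.id:
                    raise FastaFormatError(f"{path}: header with empty id")
                desc = rec.description
                if desc.startswith(rec.id):
                    desc = desc[len(rec.id):].strip()
                records.append(ProteinRecord(
                    accession=rec.id,
                    description=desc,
                    raw_sequence=str(rec.seq).upper().replace(" ", ""),
                    species_label=species_label,
                ))
        except FastaFormatError:
            raise
        except ValueError as exc:
            raise FastaFormatError(f"{path}: {exc}") from exc
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                use_clean: bool = True, width: int = 60) -> None:
    """Write records to FASTA, wrapping sequences at ``width`` columns."""
    path = Path(path)
    with open(path, "wt") as out:
        for rec in records:
            seq = rec.clean_sequence if use_clean else rec.raw_sequence
            header = rec.accession
            if rec.description:
                header += " " + rec.description
            out.write(f">{header}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Sanitization
# ---------------------------------------------------------------------------

_SANITIZE_TABLE = str.maketrans(AMBIGUITY_TRANSLATION)


def sanitize(record: ProteinRecord) -> ProteinRecord:
    """Apply the residue-translation rules and populate ambiguity counts.

    B→N, J→L, Z→Q; '*' stripped anywhere in the sequence; X kept and counted;
    U/O kept in the clean sequence but counted and flagged so downstream mass
    and charge terms can exclude them.  Idempotent.  Returns a new record;
    raises ``ValueError`` if nothing remains after stop-stripping.
    """
    raw = record.raw_sequence.upper().replace(" ", "")
    counts = {c: raw.count(c) for c in SPECIAL_CODES if raw.count(c)}
    clean = raw.translate(_SANITIZE_TABLE).replace("*", "")
    if not clean:
        raise ValueError(f"{record.accession}: sequence empty after sanitization")
    if counts.get("U") or counts.get("O"):
        logger.warning("%s contains Sec/Pyl residues (U=%d, O=%d); they carry "
                       "no mass or charge downstream", record.accession,
                       counts.get("U", 0), counts.get("O", 0))
    return replace(record, raw_sequence=raw, clean_sequence=clean,
                   ambiguity_counts=counts)


def sanitize_all(records: Iterable[ProteinRecord]) -> tuple[list[ProteinRecord], list[str]]:
    """Sanitize a batch; records emptied by sanitization are dropped and logged."""
    kept: list[ProteinRecord] = []
    dropped: list[str] = []
    for rec in records:
        try:
            kept.append(sanitize(rec))
        except ValueError as exc:
            logger.warning("dropping record: %s", exc)
            dropped.append(rec.accession)
    return kept, dropped


# ---------------------------------------------------------------------------
# Scans
# ---------------------------------------------------------------------------

def scan_descriptions(records: Iterable[ProteinRecord],
                      keyword: str) -> list[tuple[str, str]]:
    """Case-insensitive substring search over record descriptions.

    This is the annotation-keyword scan used to audit claims such as proteins
    annotated "selenocysteine" that contain no Sec residue.
    """
    if not keyword:
        raise ValueError("keyword must be non-empty")
    needle = keyword.lower()
    return [(r.accession, r.description) for r in records
            if needle in r.description.lower()]


def count_special_residues(records: Iterable[ProteinRecord]) -> pd.DataFrame:
    """Per-species totals of the special residue codes U, O, X, B, J, Z.

    A proteome free of selenocysteine and pyrrolysine shows U = O = 0 here.
    """
    codes = ("U", "O", "X", "B", "J", "Z")
    totals: dict[str, dict[str, int]] = {}
    for rec in records:
        row = totals.setdefault(rec.species_label or "", dict.fromkeys(codes, 0))
        for c in codes:
            row[c] += rec.ambiguity_counts.get(c, 0)
    frame = pd.DataFrame.from_dict(totals, orient="index", columns=list(codes))
    frame.index.name = "species"
    return frame.sort_index()


# ---------------------------------------------------------------------------
# Metadata and reports
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> list[SpeciesMetadata]:
    """Read the species-metadata TSV (species, phylum, genome_size_mb, fasta_path)."""
    frame = pd.read_csv(path, sep="\t")
    required = {"species", "phylum"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"metadata missing columns {sorted(missing)}")
    out = []
    for row in frame.itertuples(index=False):
        out.append(SpeciesMetadata(
            species=str(row.species),
            phylum=str(row.phylum),
            genome_size_mb=float(row.genome_size_mb)
            if "genome_size_mb" in frame.columns and pd.notna(row.genome_size_mb)
            else None,
            fasta_path=str(row.fasta_path) if "fasta_path" in frame.columns else None,
        ))
    return out


def sanitization_report(species: str, n_records: int, n_dropped: int,
                        records: Sequence[ProteinRecord]) -> pd.DataFrame:
    """One-row report frame: species, record counts and per-code totals."""
    codes = ("B", "J", "Z", "X", "U", "O", "*")
    row = {"species": species, "n_records": n_records, "n_dropped": n_dropped}
    for c in codes:
        key = "stop" if c == "*" else c
        row[key] = sum(r.ambiguity_counts.get(c, 0) for r in records)
    return pd.DataFrame([row])
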