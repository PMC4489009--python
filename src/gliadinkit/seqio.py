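"""Readers and writers for the formats the pipeline touches.

FASTA goes through Biopython; the tabular gene-catalogue and 2-DE spot
schemas are plain TSV with a header; protein-space annotations are emitted
as GFF3 with 1-based inclusive coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

NT_ALPHABET = set("ACGTN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}

#: literal marker used in the catalogue for genes without a full ORF
PSEUDO_FLAG = "pseudo"


@dataclass
class SequenceRecord:
    """One FASTA entry; sequence is always stored uppercase."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.id:
            raise ValueError("sequence record with empty id")
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneTableRow:
    """One row of the gene catalogue (published Table-1 schema).

    ``predicted_aa_length`` is None for pseudogene rows, in which case
    ``is_pseudo`` is set.  For full-ORF rows the cloned fragment holds
    exactly 3 bp per residue (terminal stop excluded).
    """

    gene_name: str
    genbank_id: str
    cdna_evidence: bool
    genome_id: str | None
    fragment_length: int
    predicted_aa_length: int | None
    cysteine_count: int

    @property
    def is_pseudo(self) -> bool:
        return self.predicted_aa_length is None

    @property
    def length_consistent(self) -> bool:
        """3 bp per residue for full-ORF rows (vacuously true for pseudo).

        Published catalogues occasionally violate this (the PI428198 table
        prints one full-ORF row, Gli-α-13, as 864 bp / 287 aa), so the
        check flags rather than rejects.
        """
        if self.predicted_aa_length is None:
            return True
        return self.fragment_length == 3 * self.predicted_aa_length

    def __post_init__(self) -> None:
        if self.fragment_length <= 0:
            raise ValueError(f"{self.gene_name}: fragment_length must be > 0")
        if self.cysteine_count < 0:
            raise ValueError(f"{self.gene_name}: cysteine_count must be >= 0")
        if not self.length_consistent:
            warnings.warn(
                f"{self.gene_name}: fragment_length {self.fragment_length} "
                f"!= 3 x {self.predicted_aa_length} aa",
                stacklevel=2,
            )


@dataclass
class SpotTableRow:
    """One (spot, candidate gene) line of a 2-DE spot table.

    Lines sharing a spot id describe one gel spot matched by several
    near-identical proteins; ``percent_volume`` is repeated on each line.
    """

    spot_id: int
    percent_volume: float
    mw_kd: float
    pi: float
    assigned_gene: str | None = None
    peptides: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.percent_volume <= 100:
            raise ValueError(f"spot {self.spot_id}: %Vol out of (0, 100]")
        if self.mw_kd <= 0:
            raise ValueError(f"spot {self.spot_id}: MW must be positive")
        if not 0 < self.pi < 14:
            raise ValueError(f"spot {self.spot_id}: pI out of (0, 14)")


def _check_alphabet(records: Sequence[SequenceRecord], alphabet: str | None) -> None:
    if alphabet is None:
        return
    allowed = NT_ALPHABET if alphabet == "nt" else AA_ALPHABET
    for rec in records:
        bad = set(rec.sequence) - allowed
        if bad:
            raise ValueError(
                f"{rec.id}: illegal characters for {alphabet} alphabet: {sorted(bad)}"
            )


def read_fasta(path: str | Path, alphabet: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Order is preserved and sequences are uppercased.  Raises on a missing
    or empty file, duplicate ids, or characters outside the declared
    alphabet (``"nt"`` or ``"aa"``; ``None`` skips the check).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = [
        SequenceRecord(id=r.id, sequence=str(r.seq), description=r.description)
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate record ids: {dupes}")
    _check_alphabet(records, alphabet)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_gene_table(path: str | Path) -> list[GeneTableRow]:
    """Parse a gene-catalogue TSV with the seven published columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {
        "gene", "genbank_id", "cdna", "genome_id",
        "fragment_length", "predicted_aa_length", "n_cysteines",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    rows = []
    for _, r in df.iterrows():
        aa = r["predicted_aa_length"]
        if isinstance(aa, str) and aa.strip().lower() == PSEUDO_FLAG:
            aa_len = None
        else:
            aa_len = int(aa)
        genome_id = r["genome_id"]
        if pd.isna(genome_id) or genome_id == "NA":
            genome_id = None
        rows.append(
            GeneTableRow(
                gene_name=r["gene"],
                genbank_id=r["genbank_id"],
                cdna_evidence=r["cdna"].strip().upper() == "Y",
                genome_id=genome_id,
                fragment_length=int(r["fragment_length"]),
                predicted_aa_length=aa_len,
                cysteine_count=int(r["n_cysteines"]),
            )
        )
    return rows


def write_gene_table(rows: Iterable[GeneTableRow], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene": [r.gene_name for r in rows],
            "genbank_id": [r.genbank_id for r in rows],
            "cdna": ["Y" if r.cdna_evidence else "N" for r in rows],
            "genome_id": [r.genome_id or "NA" for r in rows],
            "fragment_length": [r.fragment_length for r in rows],
            "predicted_aa_length": [
                PSEUDO_FLAG if r.is_pseudo else r.predicted_aa_length for r in rows
            ],
            "n_cysteines": [r.cysteine_count for r in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_spot_table(path: str | Path) -> list[SpotTableRow]:
    """Parse a spot-table TSV; the ``gene`` and ``peptides`` columns are optional.

    Peptides are semicolon-separated on their line.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"spot", "percent_volume", "mw_kd", "pi"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    rows = []
    for _, r in df.iterrows():
        gene = r.get("gene")
        if isinstance(gene, float) or gene in (None, "", "NA"):
            gene = None
        pep_field = r.get("peptides")
        peptides: list[str] = []
        if isinstance(pep_field, str) and pep_field.strip():
            peptides = [p for p in pep_field.split(";") if p]
        rows.append(
            SpotTableRow(
                spot_id=int(r["spot"]),
                percent_volume=float(r["percent_volume"]),
                mw_kd=float(r["mw_kd"]),
                pi=float(r["pi"]),
                assigned_gene=gene,
                peptides=peptides,
            )
        )
    return rows


def write_spot_table(rows: Iterable[SpotTableRow], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "spot": [r.spot_id for r in rows],
            "percent_volume": [r.percent_volume for r in rows],
            "gene": [r.assigned_gene or "" for r in rows],
            "mw_kd": [r.mw_kd for r in rows],
            "pi": [r.pi for r in rows],
            "peptides": [";".join(r.peptides) for r in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3 in protein coordinates


def write_domain_gff(annotations, path: str | Path) -> None:
    """Write domain segmentations as GFF3 (protein space, 1-based inclusive).

    One ``domain`` feature per non-empty segment; empty segments are
    dropped from the file.  Raises if a protein's segments overlap.
    """
    lines = ["##gff-version 3"]
    for ann in annotations:
        occupied: list[tuple[int, int]] = []
        for label, start, end in ann.domains:
            if end < start:  # empty domain
                continue
            for s0, e0 in occupied:
                if start <= e0 and s0 <= end:
                    raise ValueError(
                        f"{ann.gene_id}: overlapping domains at {start}-{end}"
                    )
            occupied.append((start, end))
            lines.append(
                "\t".join(
                    [
                        ann.gene_id, "gliadinkit", "domain",
                        str(start), str(end), ".", ".", ".",
                        f"ID={ann.gene_id}:{label};Name={label}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_domain_gff(path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """Parse a GFF3 written by :func:`write_domain_gff` back into
    ``{protein id: [(label, start, end), ...]}`` in file order."""
    out: dict[str, list[tuple[str, int, int]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"malformed GFF line: {line!r}")
        attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
        out.setdefault(cols[0], []).append(
            (attrs.get("Name", cols[2]), int(cols[3]), int(cols[4]))
        )
    return out


# ---------------------------------------------------------------------------
# bundled reference tables


def load_reference_catalogue() -> list[GeneTableRow]:
    """The transcribed gene catalogue of the T. urartu PI428198 family."""
    return read_gene_table(files("gliadinkit.data") / "gene_catalogue_pi428198.tsv")


def load_reference_spot_table() -> list[SpotTableRow]:
    """The transcribed 2-DE spot table for PI428198 gliadins."""
    return read_spot_table(files("gliadinkit.data") / "spot_table_pi428198.tsv")
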