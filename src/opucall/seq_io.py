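"""Readers and writers for sequences, trees, tables, and the sample manifest.

Every downstream stage consumes only the types defined here: :class:`SeqRecord`
for reads and references, :class:`SampleManifest` for the sample sheet,
:class:`ReferenceDB` for the type-strain database, and scikit-bio ``TreeNode``
objects for phylogenies.  Formats are deliberately plain: FASTA/FASTQ
(Phred+33), Newick, and tab-separated tables with a header row.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

IUPAC_DNA = set("ACGTRYSWKMBDHVN")

AGE_GROUPS = ("children", "youth", "middle", "elderly")
EYE_SIDES = ("L", "R", "NA")
MANIFEST_COLUMNS = (
    "sample_id",
    "subject_id",
    "eye_side",
    "age_group",
    "reads_path",
    "is_control",
)

RANKS = ("genus", "family", "order", "class", "phylum")


class ParseError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class SeqRecord:
    """A read or reference sequence with an abundance.

    ``count`` carries read multiplicity through dereplication and clustering;
    a freshly parsed read has count 1.
    """

    id: str
    seq: str
    description: str = ""
    count: int = 1

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        if not self.seq:
            raise ValueError(f"SeqRecord {self.id!r}: empty sequence")
        if self.count < 1:
            raise ValueError(f"SeqRecord {self.id!r}: count must be >= 1")
        bad = set(self.seq) - IUPAC_DNA
        if bad:
            raise ValueError(
                f"SeqRecord {self.id!r}: non-IUPAC characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def with_seq(self, seq: str) -> "SeqRecord":
        return replace(self, seq=seq)

    def with_count(self, count: int) -> "SeqRecord":
        return replace(self, count=count)


_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-"
)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_unique_ids(records: Sequence[SeqRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ParseError(f"duplicate sequence id {r.id!r}")
        seen.add(r.id)


def read_sequences(
    path: str | os.PathLike,
    format: str = "fasta",
    min_mean_quality: float | None = None,
) -> list[SeqRecord]:
    """Read FASTA or FASTQ into :class:`SeqRecord` objects.

    Sequences are uppercased; FASTQ qualities are discarded after the optional
    mean-quality filter (records with mean Phred below ``min_mean_quality`` are
    dropped).  An empty file yields an empty list.  Duplicate ids raise
    :class:`ParseError` naming the id.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    records: list[SeqRecord] = []
    try:
        for rec in SeqIO.parse(str(path), format):
            if format == "fastq" and min_mean_quality is not None:
                quals = rec.letter_annotations.get("phred_quality", [])
                if quals and float(np.mean(quals)) < min_mean_quality:
                    continue
            records.append(
                SeqRecord(
                    id=rec.id,
                    seq=str(rec.seq).upper(),
                    description=rec.description[len(rec.id):].strip(),
                )
            )
    except ValueError as exc:  # biopython reports the offending entry
        raise ParseError(f"{path}: {exc}") from exc
    _check_unique_ids(records)
    return records


def write_sequences(
    records: Iterable[SeqRecord], path: str | os.PathLike, format: str = "fasta"
) -> None:
    """Write records as FASTA (or FASTQ with flat Q40 qualities)."""
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    with open(path, "w") as fh:
        for r in records:
            header = f"{r.id} {r.description}".rstrip()
            if format == "fasta":
                fh.write(f">{header}\n{r.seq}\n")
            else:
                fh.write(f"@{header}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


# ---------------------------------------------------------------------------
# Newick trees

def read_newick(source: str | os.PathLike) -> TreeNode:
    """Read a Newick tree; duplicate leaf labels are rejected."""
    tree = TreeNode.read(str(source), format="newick", convert_underscores=False)
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise ParseError("duplicate leaf labels in Newick tree")
    return tree


def _newick_string(node: TreeNode) -> str:
    if node.is_tip():
        label = node.name or ""
    else:
        label = (
            "(" + ",".join(_newick_string(c) for c in node.children) + ")"
            + (node.name or "")
        )
    if node.length is not None:
        label += f":{node.length:.6f}"
    return label


def write_newick(tree: TreeNode, path: str | os.PathLike) -> None:
    """Serialize with branch lengths printed to 6 decimals."""
    with open(path, "w") as fh:
        fh.write(_newick_string(tree) + ";\n")


def newick_str(tree: TreeNode) -> str:
    return _newick_string(tree) + ";"


# ---------------------------------------------------------------------------
# Manifest and tables

@dataclass(frozen=True)
class ManifestRow:
    sample_id: str
    subject_id: str
    eye_side: str
    age_group: str
    reads_path: str
    is_control: bool


@dataclass
class SampleManifest:
    """Sample sheet: sample <-> subject, eye side, age group, control flag."""

    rows: list[ManifestRow]

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.rows]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ParseError(f"duplicate sample_id: {sorted(dup)}")
        keys: set[tuple[str, str]] = set()
        for r in self.rows:
            if r.eye_side not in EYE_SIDES:
                raise ParseError(
                    f"sample {r.sample_id}: eye_side {r.eye_side!r} not in {EYE_SIDES}"
                )
            if not r.is_control:
                if r.age_group not in AGE_GROUPS:
                    raise ParseError(
                        f"sample {r.sample_id}: age_group {r.age_group!r}; "
                        f"allowed: {AGE_GROUPS}"
                    )
                key = (r.subject_id, r.eye_side)
                if key in keys:
                    raise ParseError(f"duplicate (subject_id, eye_side) {key}")
                keys.add(key)

    @property
    def samples(self) -> list[ManifestRow]:
        return [r for r in self.rows if not r.is_control]

    @property
    def controls(self) -> list[ManifestRow]:
        return [r for r in self.rows if r.is_control]

    def __len__(self) -> int:
        return len(self.rows)


def read_manifest(path: str | os.PathLike) -> SampleManifest:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"manifest missing columns: {sorted(missing)}")
    rows = [
        ManifestRow(
            sample_id=r.sample_id,
            subject_id=r.subject_id,
            eye_side=r.eye_side or "NA",
            age_group=r.age_group,
            reads_path=r.reads_path,
            is_control=str(r.is_control).strip().lower() in ("1", "true", "yes"),
        )
        for r in df.itertuples()
    ]
    return SampleManifest(rows)


def write_manifest(manifest: SampleManifest, path: str | os.PathLike) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "subject_id": r.subject_id,
                "eye_side": r.eye_side,
                "age_group": r.age_group,
                "reads_path": r.reads_path,
                "is_control": int(r.is_control),
            }
            for r in manifest.rows
        ]
    ).to_csv(path, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Labeled numeric matrix from TSV (first column = row labels)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(matrix: pd.DataFrame, path: str | os.PathLike) -> None:
    matrix.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Reference database

@dataclass(frozen=True)
class Lineage:
    genus: str
    family: str
    order: str
    class_: str
    phylum: str

    def __post_init__(self) -> None:
        for rank in RANKS:
            if not getattr(self, "class_" if rank == "class" else rank):
                raise ValueError(f"lineage rank {rank!r} is empty")

    def at(self, rank: str) -> str:
        return getattr(self, "class_" if rank == "class" else rank)


@dataclass(frozen=True)
class RefEntry:
    accession: str
    species_name: str
    lineage: Lineage
    seq: str
    aligned_seq: str | None = None


@dataclass
class ReferenceDB:
    """Type strains with full taxonomy and optional template-aligned rows."""

    entries: list[RefEntry]

    def __post_init__(self) -> None:
        names = [e.species_name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("species_name not unique in ReferenceDB")
        lens = {len(e.aligned_seq) for e in self.entries if e.aligned_seq}
        if len(lens) > 1:
            raise ValueError("aligned_seq lengths differ across entries")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_accession(self, accession: str) -> RefEntry:
        for e in self.entries:
            if e.accession == accession:
                return e
        raise KeyError(accession)

    @property
    def alignment_length(self) -> int | None:
        for e in self.entries:
            if e.aligned_seq:
                return len(e.aligned_seq)
        return None


def read_reference_db(
    fasta_path: str | os.PathLike,
    taxonomy_path: str | os.PathLike,
    aligned_fasta_path: str | os.PathLike | None = None,
) -> ReferenceDB:
    """Assemble a ReferenceDB from a FASTA, a taxonomy TSV, and optionally a
    pre-aligned FASTA on a shared template.

    Taxonomy columns: accession, species, genus, family, order, class, phylum.
    """
    seqs = {r.id: r.seq for r in read_sequences(fasta_path)}
    aligned: dict[str, str] = {}
    if aligned_fasta_path is not None:
        # gapped rows bypass SeqRecord (which forbids gap characters)
        aligned = {
            r.id: str(r.seq).upper()
            for r in SeqIO.parse(str(aligned_fasta_path), "fasta")
        }
    tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str)
    required = {"accession", "species", "genus", "family", "order", "class", "phylum"}
    missing = required - set(tax.columns)
    if missing:
        raise ParseError(f"taxonomy missing columns: {sorted(missing)}")
    entries = []
    for row in tax.itertuples():
        if row.accession not in seqs:
            raise ParseError(f"taxonomy accession {row.accession} not in FASTA")
        entries.append(
            RefEntry(
                accession=row.accession,
                species_name=row.species,
                lineage=Lineage(
                    genus=row.genus,
                    family=row.family,
                    order=row.order,
                    class_=getattr(row, "_6"),  # 'class' is a keyword
                    phylum=row.phylum,
                ),
                seq=seqs[row.accession],
                aligned_seq=aligned.get(row.accession),
            )
        )
    return ReferenceDB(entries)


def write_reference_db(
    refdb: ReferenceDB,
    fasta_path: str | os.PathLike,
    taxonomy_path: str | os.PathLike,
    aligned_fasta_path: str | os.PathLike | None = None,
) -> None:
    write_sequences(
        [SeqRecord(e.accession, e.seq, e.species_name) for e in refdb], fasta_path
    )
    pd.DataFrame(
        [
            {
                "accession": e.accession,
                "species": e.species_name,
                "genus": e.lineage.genus,
                "family": e.lineage.family,
                "order": e.lineage.order,
                "class": e.lineage.class_,
                "phylum": e.lineage.phylum,
            }
            for e in refdb
        ]
    ).to_csv(taxonomy_path, sep="\t", index=False)
    if aligned_fasta_path is not None:
        # gapped rows are written directly: SeqRecord forbids gap characters
        with open(aligned_fasta_path, "w") as fh:
            for e in refdb:
                if e.aligned_seq:
                    fh.write(f">{e.accession}\n{e.aligned_seq}\n")
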