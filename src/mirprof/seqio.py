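"""Sequence and fixture I/O.

Readers and writers for FASTA/FASTQ (Sanger Phred+33), the packaged
conserved/novel miRNA reference tables, and sequence-alphabet helpers.
All homology comparisons in the pipeline run in canonical uppercase DNA
space (U mapped to T); raw reads keep their original alphabet and case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


class ParseError(ValueError):
    """Raised when a sequence file cannot be parsed."""


class FixtureIntegrityError(ValueError):
    """Raised when a packaged fixture violates its documented invariants."""


@dataclass
class SmallRNARead:
    """One raw small-RNA read.

    ``quality`` holds per-base Phred scores (Sanger scale) when the read
    came from FASTQ, ``None`` for FASTA input.
    """

    read_id: str
    sequence: str
    quality: Optional[list[int]] = None

    def __post_init__(self) -> None:
        # Raw parsed reads are non-empty (enforced in read_sequences);
        # adapter trimming may legitimately leave an empty sequence that the
        # length filter later removes.
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReferenceMatureRecord:
    """A mature miRNA reference entry (miRBase-style)."""

    ref_id: str
    family: Optional[str]
    sequence: str

    def __post_init__(self) -> None:
        if not (18 <= len(self.sequence) <= 26):
            raise ValueError(
                f"reference {self.ref_id}: mature length {len(self.sequence)} "
                "outside 18-26 nt"
            )


def canonical(sequence: str) -> str:
    """Map a sequence to canonical comparison space: uppercase DNA, U -> T."""
    return sequence.upper().replace("U", "T")


def reverse_complement(sequence: str) -> str:
    """Reverse complement in DNA space (handles U and lowercase on input)."""
    return canonical(sequence).translate(_COMPLEMENT)[::-1]


def read_sequences(path: str | Path, format: Optional[str] = None) -> list[SmallRNARead]:
    """Read a FASTA or FASTQ file into :class:`SmallRNARead` records.

    The format is inferred from the extension when not given. Raw sequence
    text (case, U vs T) is preserved; order follows the file. An empty file
    yields an empty list with a warning.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "fastq" if suffix in {".fastq", ".fq"} else "fasta"
    if format not in {"fasta", "fastq"}:
        raise ValueError(f"unsupported format {format!r}")
    reads: list[SmallRNARead] = []
    try:
        for rec in SeqIO.parse(str(path), format):
            if len(rec.seq) == 0:
                raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
            qual = rec.letter_annotations.get("phred_quality")
            reads.append(
                SmallRNARead(
                    read_id=rec.id,
                    sequence=str(rec.seq),
                    quality=list(qual) if qual is not None else None,
                )
            )
    except ValueError as exc:  # biopython signals malformed records this way
        raise ParseError(f"{path}: malformed {format} record: {exc}") from exc
    if not reads:
        warnings.warn(f"{path}: no sequences found", stacklevel=2)
    return reads


def write_sequences(
    reads: Iterable[SmallRNARead], path: str | Path, format: Optional[str] = None
) -> None:
    """Write reads as FASTA or FASTQ (Phred+33). Inverse of :func:`read_sequences`."""
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "fastq" if suffix in {".fastq", ".fq"} else "fasta"
    with open(path, "w") as fh:
        for read in reads:
            if format == "fastq":
                if read.quality is None:
                    raise ValueError(f"read {read.read_id}: FASTQ output needs quality")
                qline = "".join(chr(q + 33) for q in read.quality)
                fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qline}\n")
            else:
                fh.write(f">{read.read_id}\n{read.sequence}\n")


def read_fasta_genome(path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into {contig: canonical sequence}.

    Duplicate contig names are an input error (they would make hit
    coordinates ambiguous).
    """
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"{path}: duplicate contig name {rec.id!r}")
        genome[rec.id] = canonical(str(rec.seq))
    return genome


def write_fasta_genome(genome: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_reference_set(path: str | Path) -> list[ReferenceMatureRecord]:
    """Read a mature reference set.

    FASTA headers may carry a family after ``|`` (``ref_id|FAMILY``); TSV
    input needs columns ``ref_id``, ``family``, ``sequence``. ``NA`` (or a
    missing field) means no family assignment.
    """
    path = Path(path)
    records: list[ReferenceMatureRecord] = []
    if path.suffix.lower() in {".tsv", ".txt"}:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for _, row in df.iterrows():
            fam = row.get("family", "NA")
            records.append(
                ReferenceMatureRecord(
                    ref_id=row["ref_id"],
                    family=None if fam in ("", "NA") else fam,
                    sequence=canonical(row["sequence"]),
                )
            )
    else:
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.description.split()[0].split("|")
            fam = parts[1] if len(parts) > 1 and parts[1] not in ("", "NA") else None
            records.append(
                ReferenceMatureRecord(
                    ref_id=parts[0], family=fam, sequence=canonical(str(rec.seq))
                )
            )
    seen: set[str] = set()
    for rec in records:
        if rec.ref_id in seen:
            raise ValueError(f"{path}: duplicate ref_id {rec.ref_id!r}")
        seen.add(rec.ref_id)
    return records


def write_reference_set(records: Iterable[ReferenceMatureRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fam = rec.family if rec.family is not None else "NA"
            fh.write(f">{rec.ref_id}|{fam}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# Packaged fixtures: curated conserved / novel miRNA tables for M. koenigii
# ---------------------------------------------------------------------------

def _fixture_path(name: str):
    return resources.files("mirprof.data").joinpath(name)


def load_table2_fixture() -> pd.DataFrame:
    """Load the conserved-miRNA reference table (142 M. koenigii miRNAs).

    Columns: family (literal ``NA`` for unassigned), name, sequence,
    length_nt, reference_mirna, mismatches, read_count, e_value (opaque
    metadata, never recomputed), plus a derived boolean
    ``length_discrepancy`` flagging rows whose printed length differs from
    the character length of the printed sequence (both values are kept
    verbatim; no correction is guessed).
    """
    with resources.as_file(_fixture_path("conserved_mirnas.tsv")) as p:
        df = pd.read_csv(
            p,
            sep="\t",
            dtype={
                "family": str,
                "name": str,
                "sequence": str,
                "length_nt": int,
                "reference_mirna": str,
                "mismatches": int,
                "read_count": int,
                "e_value": float,
            },
            keep_default_na=False,
            na_values=[],
        )
    if len(df) != 142:
        raise FixtureIntegrityError(f"conserved fixture has {len(df)} rows, expected 142")
    bad = df[~df["mismatches"].isin([0, 1])]
    if len(bad):
        raise FixtureIntegrityError(f"mismatches outside {{0,1}} at row(s) {bad.index.tolist()}")
    bad = df[df["read_count"] < 1]
    if len(bad):
        raise FixtureIntegrityError(f"read_count < 1 at row(s) {bad.index.tolist()}")
    n_fam = df.loc[df["family"] != "NA", "family"].nunique()
    if n_fam != 34:
        raise FixtureIntegrityError(f"{n_fam} non-NA families, expected 34")
    df["length_discrepancy"] = df["sequence"].str.len() != df["length_nt"]
    return df


def load_table3_fixture() -> pd.DataFrame:
    """Load the novel-miRNA candidate table (7 M. koenigii candidates).

    Columns: name, sequence (RNA alphabet, 5'->3'), length_nt, read_count,
    strand (+/-), mfei (precursor MFEI).
    """
    with resources.as_file(_fixture_path("novel_mirnas.tsv")) as p:
        df = pd.read_csv(
            p,
            sep="\t",
            dtype={
                "name": str,
                "sequence": str,
                "length_nt": int,
                "read_count": int,
                "strand": str,
                "mfei": float,
            },
        )
    if len(df) != 7:
        raise FixtureIntegrityError(f"novel fixture has {len(df)} rows, expected 7")
    for idx, row in df.iterrows():
        if len(row["sequence"]) != row["length_nt"]:
            raise FixtureIntegrityError(f"row {row['name']}: sequence length != length_nt")
        if row["mfei"] < 0.70:
            raise FixtureIntegrityError(f"row {row['name']}: MFEI {row['mfei']} < 0.70")
        if row["read_count"] < 5:
            raise FixtureIntegrityError(f"row {row['name']}: read_count {row['read_count']} < 5")
        if row["strand"] not in ("+", "-"):
            raise FixtureIntegrityError(f"row {row['name']}: bad strand {row['strand']!r}")
    return df
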