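"""Data model and file formats shared by all pipeline stages.

Coordinates are 1-based inclusive everywhere inside the package, matching
the "m.8993"-style numbering used for mitochondrial variants.  BED input
(0-based, half-open) is converted on read.

Allele-count tables are the pileup-level representation this toolkit starts
from: one row per reference position with the depth and the A/C/G/T base
call counts, plus counts of reads supporting an insertion immediately after
the position (``ins``) and reads reporting the position deleted (``del``).
Deletion-supporting reads are *not* part of ``depth``; insertion-supporting
reads are (they carry a base call at the anchor position).  This keeps the
substitution denominator purely base-call based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("mitomut")

VALID_BASES = frozenset("ACGT")
REGION_CLASSES = ("protein", "tRNA", "rRNA", "dloop", "other")
POLG_GENOTYPES = ("+/+", "+/mut", "mut/mut")


class MitomutError(Exception):
    """Base class for all typed errors raised by this package."""


class FormatError(MitomutError):
    """Malformed or invariant-violating input file."""


class CoordinateError(MitomutError):
    """Position or interval outside the genome."""


@dataclass(frozen=True)
class MtGenome:
    """A circular mitochondrial reference sequence."""

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError("empty genome sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise FormatError(
                f"genome {self.name!r} contains non-ACGT characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Reference base at 1-based position ``pos``."""
        if not 1 <= pos <= self.length:
            raise CoordinateError(f"position {pos} outside genome of length {self.length}")
        return self.sequence[pos - 1]


@dataclass(frozen=True)
class GeneRecord:
    """One annotated feature in reference-strand 1-based inclusive coordinates.

    Minus-strand protein genes store reference-strand coordinates; the
    reverse complement is taken only at translation time.
    """

    gene_name: str
    region_class: str
    start: int
    end: int
    strand: str = "+"
    incomplete: bool = False

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise FormatError(f"unknown region class {self.region_class!r}")
        if self.strand not in ("+", "-"):
            raise FormatError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 1 <= self.start <= self.end:
            raise CoordinateError(
                f"invalid interval {self.start}-{self.end} for {self.gene_name}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneAnnotation:
    """Ordered collection of gene/region records for one genome."""

    records: list[GeneRecord]
    genome_length: int

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.end > self.genome_length:
                raise CoordinateError(
                    f"{rec.gene_name}: end {rec.end} exceeds genome length "
                    f"{self.genome_length}"
                )

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def records_at(self, pos: int) -> list[GeneRecord]:
        """All records containing ``pos``, in file order."""
        return [r for r in self.records if r.start <= pos <= r.end]

    def region_of(self, pos: int) -> tuple[str, str]:
        """(region_class, gene_name) at ``pos``; ('other', '.') if unannotated.

        Overlapping records resolve to the first in file order.
        """
        hits = self.records_at(pos)
        if not hits:
            return "other", "."
        if len(hits) > 1:
            logger.debug(
                "position %d in %d overlapping records; using %s",
                pos, len(hits), hits[0].gene_name,
            )
        return hits[0].region_class, hits[0].gene_name

    def class_array(self) -> np.ndarray:
        """Region class per position (object array, index 0 = position 1)."""
        arr = np.full(self.genome_length, "other", dtype=object)
        for rec in reversed(self.records):  # earlier records win on overlap
            arr[rec.start - 1: rec.end] = rec.region_class
        return arr

    def gene_array(self) -> np.ndarray:
        arr = np.full(self.genome_length, ".", dtype=object)
        for rec in reversed(self.records):
            arr[rec.start - 1: rec.end] = rec.gene_name
        return arr


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one sequenced organ sample."""

    mouse_id: str
    organ: str
    polg_genotype: str
    generation: str

    def __post_init__(self) -> None:
        if self.polg_genotype not in POLG_GENOTYPES:
            raise FormatError(
                f"polg_genotype must be one of {POLG_GENOTYPES}, "
                f"got {self.polg_genotype!r}"
            )


COUNT_COLUMNS = ["pos", "depth", "A", "C", "G", "T", "ins", "del"]


@dataclass
class AlleleCountTable:
    """Per-site allele counts for one sample over an entire mtDNA genome.

    ``table`` has one row per position 1..L with columns
    pos, depth, A, C, G, T, ins, del.  Invariant: A+C+G+T == depth per row.
    """

    meta: SampleMeta
    table: pd.DataFrame
    genome_name: str = "chrM"

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"count table missing columns: {missing}")
        if (df[COUNT_COLUMNS] < 0).any().any():
            raise FormatError("negative counts in allele-count table")
        sums = df[["A", "C", "G", "T"]].sum(axis=1)
        bad = df.index[sums.to_numpy() != df["depth"].to_numpy()]
        if len(bad):
            pos = int(df.loc[bad[0], "pos"])
            raise FormatError(
                f"depth != A+C+G+T at position {pos} "
                f"({int(df.loc[bad[0], 'depth'])} vs {int(sums.loc[bad[0]])})"
            )
        expected = np.arange(1, len(df) + 1)
        if not np.array_equal(df["pos"].to_numpy(), expected):
            raise FormatError("count table must cover positions 1..L exactly, in order")

    @property
    def length(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> MtGenome:
    """Read a single-record FASTA into an :class:`MtGenome`.

    The sequence is uppercased; ambiguity codes are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise FormatError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise FormatError(f"{path}: expected a single record, found {len(records)}")
    rec = records[0]
    return MtGenome(name=rec.id, sequence=str(rec.seq).upper())


def read_annotation(path: str | Path, genome: MtGenome) -> GeneAnnotation:
    """Read a BED 6+1 annotation (chrom start end name score strand class).

    BED coordinates (0-based half-open) are converted to 1-based inclusive.
    A protein record whose length is not divisible by 3 is flagged
    ``incomplete`` with a warning rather than rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                # allow whitespace-separated toy files
                fields = line.split()
            if len(fields) < 7:
                raise FormatError(
                    f"{path}:{lineno}: expected 7 columns "
                    "(chrom start end name score strand class)"
                )
            _, start0, end0, name, _score, strand, cls = fields[:7]
            start = int(start0) + 1
            end = int(end0)
            if end > genome.length:
                raise CoordinateError(
                    f"{path}:{lineno}: end {end} exceeds genome length {genome.length}"
                )
            incomplete = False
            if cls == "protein" and (end - start + 1) % 3 != 0:
                logger.warning(
                    "%s: protein record %s has length %d not divisible by 3; "
                    "flagging incomplete", path, name, end - start + 1,
                )
                incomplete = True
            records.append(
                GeneRecord(
                    gene_name=name, region_class=cls, start=start, end=end,
                    strand=strand, incomplete=incomplete,
                )
            )
    return GeneAnnotation(records=records, genome_length=genome.length)


def read_counts(path: str | Path, genome: MtGenome, meta: SampleMeta) -> AlleleCountTable:
    """Read a TSV allele-count table; absent positions are filled with zeros."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df[COUNT_COLUMNS].astype(np.int64)
    if df["pos"].duplicated().any():
        dup = int(df.loc[df["pos"].duplicated(), "pos"].iloc[0])
        raise FormatError(f"{path}: duplicate position {dup}")
    if ((df["pos"] < 1) | (df["pos"] > genome.length)).any():
        bad = df.loc[(df["pos"] < 1) | (df["pos"] > genome.length), "pos"].iloc[0]
        raise CoordinateError(f"{path}: position {int(bad)} outside 1..{genome.length}")
    full = pd.DataFrame({"pos": np.arange(1, genome.length + 1, dtype=np.int64)})
    full = full.merge(df, on="pos", how="left").fillna(0).astype(np.int64)
    return AlleleCountTable(meta=meta, table=full, genome_name=genome.name)


def write_counts(acount: AlleleCountTable, path: str | Path) -> None:
    """Write an allele-count table as a TSV (inverse of :func:`read_counts`)."""
    acount.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# variant / summary serialization
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = [
    "pos", "ref", "alt", "depth", "alt_count", "frequency_percent",
    "region", "gene", "effect", "pathogenic_human_pos",
]


def write_variants(variants: Iterable, path: str | Path) -> None:
    """Write SiteVariants as a VCF-like TSV with a fixed column order.

    Frequencies are serialized with 6 significant digits so round-trips
    preserve them at working precision.
    """
    rows = []
    for v in variants:
        rows.append({
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "depth": v.depth,
            "alt_count": v.alt_count,
            "frequency_percent": f"{v.frequency:.6g}",
            "region": v.region_class,
            "gene": v.gene_name,
            "effect": v.effect if v.effect is not None else ".",
            "pathogenic_human_pos": (
                v.pathogenic_human_pos if v.pathogenic_human_pos is not None else "."
            ),
        })
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_variants(path: str | Path) -> list:
    """Read back a variant TSV written by :func:`write_variants`."""
    from .mutfreq import SiteVariant  # local import: avoid cycle at import time

    df = pd.read_csv(path, sep="\t", dtype={"effect": str, "pathogenic_human_pos": str})
    out = []
    for row in df.itertuples(index=False):
        patho = None if str(row.pathogenic_human_pos) in (".", "nan") else int(
            float(row.pathogenic_human_pos)
        )
        effect = None if str(row.effect) in (".", "nan") else str(row.effect)
        out.append(
            SiteVariant(
                pos=int(row.pos), ref=str(row.ref), alt=str(row.alt),
                depth=int(row.depth), alt_count=int(row.alt_count),
                region_class=str(row.region), gene_name=str(row.gene),
                effect=effect, pathogenic_human_pos=patho,
            )
        )
    return out


def write_summary(summary, path: str | Path) -> None:
    """Write a SampleSummary as a one-row TSV (region columns prefixed)."""
    row = {
        "mouse_id": summary.meta.mouse_id,
        "organ": summary.meta.organ,
        "polg_genotype": summary.meta.polg_genotype,
        "generation": summary.meta.generation,
        "total_mut_freq": f"{summary.total_mut_freq:.6g}",
        "insertion_freq": f"{summary.insertion_freq:.6g}",
        "deletion_freq": f"{summary.deletion_freq:.6g}",
        "n_nonsyn_gt1": summary.n_nonsyn_gt1,
        "n_pathogenic_gt1": summary.n_pathogenic_gt1,
        "total_bases": summary.qc.total_bases,
        "average_depth": f"{summary.qc.average_depth:.6g}",
        "coverage_rate": f"{summary.qc.coverage_rate:.6g}",
    }
    for name, freq in summary.region_mut_freq.items():
        row[f"freq:{name}"] = f"{freq:.6g}"
    pd.DataFrame([row]).to_csv(path, sep="\t", index=False)


def read_summary(path: str | Path):
    """Read back a one-row summary TSV written by :func:`write_summary`."""
    from .mutfreq import QCMetrics, SampleSummary

    df = pd.read_csv(path, sep="\t")
    if len(df) != 1:
        raise FormatError(f"{path}: expected exactly one summary row, got {len(df)}")
    row = df.iloc[0]
    meta = SampleMeta(
        mouse_id=str(row["mouse_id"]), organ=str(row["organ"]),
        polg_genotype=str(row["polg_genotype"]), generation=str(row["generation"]),
    )
    region = {
        c[len("freq:"):]: float(row[c]) for c in df.columns if c.startswith("freq:")
    }
    return SampleSummary(
        meta=meta,
        total_mut_freq=float(row["total_mut_freq"]),
        region_mut_freq=region,
        insertion_freq=float(row["insertion_freq"]),
        deletion_freq=float(row["deletion_freq"]),
        n_nonsyn_gt1=int(row["n_nonsyn_gt1"]),
        n_pathogenic_gt1=int(row["n_pathogenic_gt1"]),
        qc=QCMetrics(
            total_bases=int(row["total_bases"]),
            average_depth=float(row["average_depth"]),
            coverage_rate=float(row["coverage_rate"]),
        ),
    )


def write_fasta(genome: MtGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.name}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.sequence[i:i + width] + "\n")


def write_annotation(annot: GeneAnnotation, path: str | Path,
                     chrom: str = "chrM") -> None:
    """Write an annotation as BED 6+1 (inverse of :func:`read_annotation`)."""
    with open(path, "w") as fh:
        for rec in annot:
            fh.write(
                f"{chrom}\t{rec.start - 1}\t{rec.end}\t{rec.gene_name}\t0\t"
                f"{rec.strand}\t{rec.region_class}\n"
            )
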