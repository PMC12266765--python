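"""Per-base mtDNA mutation-frequency statistics from allele-count tables.

The central statistic is

    mutation frequency (%) = non-reference base calls x 100 / sequenced bases

summed over sites.  Sites with zero depth contribute to neither numerator
nor denominator (coverage is reported separately in the QC metrics).  The
numerator sums *all* non-reference base calls at a site, so a tri-allelic
site contributes every mismatching read.  Indel-supporting reads are
excluded from the substitution statistic and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import AlleleCountTable, GeneAnnotation, MtGenome, MitomutError, SampleMeta

BASES = ("A", "C", "G", "T")
AGGREGATE_CLASSES = ("protein", "tRNA", "rRNA", "dloop", "other")


class EmptyTableError(MitomutError):
    """Statistic undefined: no sequenced bases."""


@dataclass
class SiteVariant:
    """One alternative allele observed at one site."""

    pos: int
    ref: str
    alt: str
    depth: int
    alt_count: int
    region_class: str = "other"
    gene_name: str = "."
    effect: Optional[str] = None
    pathogenic_human_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError(f"alt equals ref at position {self.pos}")
        if not 0 < self.alt_count <= self.depth:
            raise ValueError(
                f"alt_count {self.alt_count} not in (0, depth={self.depth}] "
                f"at position {self.pos}"
            )

    @property
    def frequency(self) -> float:
        """Alt-allele frequency in percent."""
        return 100.0 * self.alt_count / self.depth


@dataclass(frozen=True)
class QCMetrics:
    """Sequencing QC readout: total bases, mean depth, coverage."""

    total_bases: int
    average_depth: float
    coverage_rate: float  # percent of positions with depth >= 1


@dataclass
class SampleSummary:
    """Per-sample readout of the whole pipeline."""

    meta: SampleMeta
    total_mut_freq: float
    region_mut_freq: dict[str, float]
    insertion_freq: float
    deletion_freq: float
    n_nonsyn_gt1: int
    n_pathogenic_gt1: int
    qc: QCMetrics


def _check_lengths(table: AlleleCountTable, genome: MtGenome) -> None:
    if table.length != genome.length:
        raise MitomutError(
            f"count table covers {table.length} positions but genome "
            f"{genome.name} has {genome.length}"
        )


def _ref_indices(genome: MtGenome) -> np.ndarray:
    """Index (0=A,1=C,2=G,3=T) of the reference base at each position."""
    lut = np.zeros(128, dtype=np.int8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    return lut[np.frombuffer(genome.sequence.encode(), dtype=np.uint8)]


def mismatch_counts(table: AlleleCountTable, genome: MtGenome) -> np.ndarray:
    """Per-position count of base calls differing from the reference."""
    _check_lengths(table, genome)
    counts = table.table[list(BASES)].to_numpy()
    ref_idx = _ref_indices(genome)
    ref_calls = counts[np.arange(len(counts)), ref_idx]
    return counts.sum(axis=1) - ref_calls


def total_mutation_frequency(table: AlleleCountTable, genome: MtGenome) -> float:
    """Genome-wide mutation frequency in percent."""
    _check_lengths(table, genome)
    depth = table.table["depth"].to_numpy()
    total = int(depth.sum())
    if total == 0:
        raise EmptyTableError("all positions have zero depth; frequency undefined")
    return 100.0 * mismatch_counts(table, genome).sum() / total


def region_mutation_frequency(
    table: AlleleCountTable,
    genome: MtGenome,
    annotation: GeneAnnotation,
) -> dict[str, float]:
    """Mutation frequency restricted to each gene and aggregate region class.

    Keys are individual gene names plus the aggregates ``protein``, ``tRNA``,
    ``rRNA``, ``dloop`` and ``other`` (unannotated positions).  Regions with
    zero sequenced bases report 0.0.
    """
    _check_lengths(table, genome)
    mism = mismatch_counts(table, genome)
    depth = table.table["depth"].to_numpy()

    out: dict[str, float] = {}

    cls_arr = annotation.class_array()
    for cls in AGGREGATE_CLASSES:
        mask = cls_arr == cls
        d = depth[mask].sum()
        out[cls] = 100.0 * mism[mask].sum() / d if d > 0 else 0.0

    gene_arr = annotation.gene_array()
    for rec in annotation:
        mask = gene_arr == rec.gene_name
        d = depth[mask].sum()
        out[rec.gene_name] = 100.0 * mism[mask].sum() / d if d > 0 else 0.0
    return out


def indel_frequency(table: AlleleCountTable) -> tuple[float, float]:
    """(insertion %, deletion %) over the whole table.

    Insertions: supporting reads / base-call depth.  Deletions: supporting
    reads / (depth + deletion reads), since deletion-supporting reads carry
    no base call at the site.
    """
    df = table.table
    depth_sum = int(df["depth"].sum())
    del_sum = int(df["del"].sum())
    if depth_sum == 0:
        raise EmptyTableError("all positions have zero depth; frequency undefined")
    ins_freq = 100.0 * df["ins"].sum() / depth_sum
    del_freq = 100.0 * del_sum / (depth_sum + del_sum)
    return float(ins_freq), float(del_freq)


def qc_metrics(table: AlleleCountTable) -> QCMetrics:
    depth = table.table["depth"].to_numpy()
    total = int(depth.sum())
    L = len(depth)
    return QCMetrics(
        total_bases=total,
        average_depth=total / L if L else 0.0,
        coverage_rate=100.0 * (depth > 0).sum() / L if L else 0.0,
    )


def site_variants(
    table: AlleleCountTable,
    genome: MtGenome,
    annotation: Optional[GeneAnnotation] = None,
    min_depth: int = 0,
) -> list[SiteVariant]:
    """All (position, alt base) pairs with at least one supporting read.

    Up to three variants per site.  Positions with depth 0 (or below
    ``min_depth``) emit nothing.
    """
    _check_lengths(table, genome)
    counts = table.table[list(BASES)].to_numpy()
    depth = table.table["depth"].to_numpy()
    ref_idx = _ref_indices(genome)

    out: list[SiteVariant] = []
    rows, cols = np.nonzero(counts)
    keep = (cols != ref_idx[rows]) & (depth[rows] >= max(min_depth, 1))
    for r, c in zip(rows[keep], cols[keep]):
        pos = int(r) + 1
        region_class, gene_name = (
            annotation.region_of(pos) if annotation is not None else ("other", ".")
        )
        out.append(
            SiteVariant(
                pos=pos, ref=BASES[ref_idx[r]], alt=BASES[c],
                depth=int(depth[r]), alt_count=int(counts[r, c]),
                region_class=region_class, gene_name=gene_name,
            )
        )
    return out


def summarize_sample(
    table: AlleleCountTable,
    genome: MtGenome,
    annotation: GeneAnnotation,
    min_depth: int = 0,
    threshold: float = 1.0,
    pathogenic_counter=None,
) -> SampleSummary:
    """Assemble the full per-sample summary.

    ``pathogenic_counter``, if given, is called with the (annotated) variant
    list and must return the count of pathogenic-homologous variants above
    threshold; without it the count is 0.
    """
    from .effects import annotate_variants, count_nonsynonymous

    variants = site_variants(table, genome, annotation, min_depth=min_depth)
    annotate_variants(variants, genome, annotation)
    ins_freq, del_freq = indel_frequency(table)
    n_patho = pathogenic_counter(variants) if pathogenic_counter is not None else 0
    return SampleSummary(
        meta=table.meta,
        total_mut_freq=total_mutation_frequency(table, genome),
        region_mut_freq=region_mutation_frequency(table, genome, annotation),
        insertion_freq=ins_freq,
        deletion_freq=del_freq,
        n_nonsyn_gt1=count_nonsynonymous(variants, genome, annotation, threshold),
        n_pathogenic_gt1=n_patho,
        qc=qc_metrics(table),
    )
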