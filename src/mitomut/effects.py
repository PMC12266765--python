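"""Synonymous / non-synonymous classification of mtDNA substitutions.

Protein-coding variants are translated under the vertebrate mitochondrial
genetic code (NCBI translation table 2: ATA=Met, TGA=Trp, AGA/AGG=stop).
Minus-strand genes are read on the reverse complement; coordinates stay in
reference-strand numbering throughout.  Stop gains and losses count as
non-synonymous — the readout is binary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Data import CodonTable

from .io import CoordinateError, GeneAnnotation, GeneRecord, MtGenome

logger = logging.getLogger("mitomut")

_TABLE2 = CodonTable.unambiguous_dna_by_id[2]

COMPLEMENT = str.maketrans("ACGT", "TGCA")

NONCODING_EFFECT = {
    "tRNA": "noncoding_tRNA",
    "rRNA": "noncoding_rRNA",
    "dloop": "noncoding_dloop",
    "other": "noncoding_other",
}


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Amino acid (single letter, '*' for stop) under translation table 2."""
    codon = codon.upper()
    if codon in _TABLE2.stop_codons:
        return "*"
    return _TABLE2.forward_table[codon]


@dataclass
class EffectCall:
    """Classification of one substitution."""

    pos: int
    ref: str
    alt: str
    effect: str
    gene_name: str = "."
    codon_index: int | None = None  # 1-based codon number within the gene
    ref_codon: str | None = None    # on the coding strand
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    partial_codon: bool = False     # trailing incomplete codon of a flagged record


_warned_overlaps: set[tuple[str, ...]] = set()


def _warn_overlap_once(genes: tuple[str, ...]) -> None:
    if genes not in _warned_overlaps:
        _warned_overlaps.add(genes)
        logger.warning(
            "overlapping records %s: variants classified within %s "
            "(first in file order)", "/".join(genes), genes[0],
        )


def _coding_offset(rec: GeneRecord, pos: int) -> int:
    """0-based offset of ``pos`` along the coding strand of ``rec``."""
    return pos - rec.start if rec.strand == "+" else rec.end - pos


def classify_substitution(
    genome: MtGenome,
    annotation: GeneAnnotation,
    pos: int,
    alt_base: str,
) -> EffectCall:
    """Classify the substitution ref→``alt_base`` at 1-based ``pos``.

    Variants in overlapping records take the first record in file order.
    A variant in the trailing partial codon of an incomplete protein record
    is classified ``noncoding_other`` with ``partial_codon=True`` and a
    warning, since no full codon exists to translate.
    """
    ref = genome.base(pos)  # raises CoordinateError if out of range
    if alt_base == ref:
        raise ValueError(f"alt base {alt_base} equals reference at {pos}")
    hits = annotation.records_at(pos)
    if not hits:
        return EffectCall(pos=pos, ref=ref, alt=alt_base, effect="noncoding_other")
    if len(hits) > 1:
        _warn_overlap_once(tuple(r.gene_name for r in hits))
    rec = hits[0]
    if rec.region_class != "protein":
        return EffectCall(
            pos=pos, ref=ref, alt=alt_base,
            effect=NONCODING_EFFECT[rec.region_class], gene_name=rec.gene_name,
        )

    offset = _coding_offset(rec, pos)
    codon_idx = offset // 3
    within = offset % 3
    n_full_codons = rec.length // 3
    if codon_idx >= n_full_codons:
        logger.warning(
            "position %d falls in the trailing partial codon of incomplete "
            "record %s; cannot translate", pos, rec.gene_name,
        )
        return EffectCall(
            pos=pos, ref=ref, alt=alt_base, effect="noncoding_other",
            gene_name=rec.gene_name, partial_codon=True,
        )

    # reference-strand coordinates of the codon, 5'->3' on the coding strand
    if rec.strand == "+":
        codon_start = rec.start + 3 * codon_idx
        ref_codon = genome.sequence[codon_start - 1: codon_start + 2]
        alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1:]
    else:
        codon_end = rec.end - 3 * codon_idx  # reference-strand coordinate
        plus_codon = genome.sequence[codon_end - 3: codon_end]
        ref_codon = revcomp(plus_codon)
        alt_plus = alt_base
        plus_within = 2 - within  # position within the plus-strand triplet
        mutated_plus = (
            plus_codon[:plus_within] + alt_plus + plus_codon[plus_within + 1:]
        )
        alt_codon = revcomp(mutated_plus)

    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    effect = "synonymous" if ref_aa == alt_aa else "nonsynonymous"
    return EffectCall(
        pos=pos, ref=ref, alt=alt_base, effect=effect, gene_name=rec.gene_name,
        codon_index=codon_idx + 1, ref_codon=ref_codon, alt_codon=alt_codon,
        ref_aa=ref_aa, alt_aa=alt_aa,
    )


def annotate_variants(variants, genome: MtGenome, annotation: GeneAnnotation):
    """Fill ``effect`` on each SiteVariant in place; returns the list."""
    for v in variants:
        call = classify_substitution(genome, annotation, v.pos, v.alt)
        v.effect = call.effect
    return variants


def count_nonsynonymous(
    variants,
    genome: MtGenome,
    annotation: GeneAnnotation,
    threshold: float = 1.0,
) -> int:
    """Number of distinct (pos, alt) non-synonymous variants with frequency
    strictly above ``threshold`` percent."""
    seen: set[tuple[int, str]] = set()
    n = 0
    for v in variants:
        if v.frequency <= threshold:
            continue
        key = (v.pos, v.alt)
        if key in seen:
            continue
        seen.add(key)
        effect = v.effect
        if effect is None:
            effect = classify_substitution(genome, annotation, v.pos, v.alt).effect
        if effect == "nonsynonymous":
            n += 1
    return n


HISTOGRAM_EDGES = [1.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0]


@dataclass
class FrequencyHistogram:
    """Decile histogram of variant frequencies above the 1% threshold.

    Bins are (1,10], (10,20], ..., (90,100] percent.
    """

    bin_edges: list[float]
    counts: list[int]
    variant_class: str

    @property
    def total(self) -> int:
        return sum(self.counts)

    def counts_above(self, edge: float) -> int:
        """Total count in bins whose lower edge is >= ``edge``."""
        return sum(
            c for lo, c in zip(self.bin_edges[:-1], self.counts) if lo >= edge
        )


def frequency_histogram(variants, variant_class: str) -> FrequencyHistogram:
    """Bin variant frequencies (percent) into the decile histogram.

    Only variants with frequency strictly above the first edge (1%) are
    counted, matching the quantification threshold.
    """
    edges = HISTOGRAM_EDGES
    counts = [0] * (len(edges) - 1)
    for v in variants:
        f = v.frequency
        if f <= edges[0]:
            continue
        for i in range(len(edges) - 1):
            if edges[i] < f <= edges[i + 1]:
                counts[i] += 1
                break
    return FrequencyHistogram(bin_edges=list(edges), counts=counts,
                              variant_class=variant_class)
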