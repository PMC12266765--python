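"""Synthetic mtDNA reference sequences and annotations for simulation and tests.

The sequences generated here are random — they are NOT the real mouse or
human mitochondrial genomes.  What is preserved is the *structure* a real
analysis sees: genome lengths (16299 bp mouse-like, 16569 bp human-like),
the mitochondrial gene order, gene lengths and genomic coordinates close to
the real annotations (ATP6 exactly at its real coordinates in both layouts:
mouse 7927-8607, human 8527-9207), the ATP8/ATP6 overlap, one minus-strand
protein gene (ND6), two rRNAs and a control region.

:func:`ortholog_pair` derives the human-like genome from the mouse-like one
gene by gene (point mutations plus a length-adjusting indel where the gene
lengths differ), so per-gene alignments behave like real mouse/human
orthologs at ~85-90% identity.  Because both ATP6 genes are 681 bp and
colinear, lifting human position 8993 through the alignment lands on mouse
position 8393 — the classic MT-ATP6 m.8993 homology.
"""

from __future__ import annotations

import numpy as np

from .io import GeneAnnotation, GeneRecord, MtGenome

MOUSE_LIKE_LENGTH = 16299
HUMAN_LIKE_LENGTH = 16569

# (name, class, start, end, strand) -- 1-based inclusive, reference strand.
# Protein-gene lengths are all multiples of 3 (complete CDSs).
MOUSE_LIKE_GENES = [
    ("tRNA-F", "tRNA", 1, 68, "+"),
    ("rRNA-12S", "rRNA", 70, 1024, "+"),
    ("tRNA-V", "tRNA", 1025, 1093, "+"),
    ("rRNA-16S", "rRNA", 1094, 2675, "+"),
    ("ND1", "protein", 2751, 3707, "+"),
    ("ND2", "protein", 3914, 4951, "+"),
    ("COX1", "protein", 5328, 6872, "+"),
    ("COX2", "protein", 7013, 7696, "+"),
    ("ATP8", "protein", 7766, 7969, "+"),
    ("ATP6", "protein", 7927, 8607, "+"),
    ("COX3", "protein", 8610, 9392, "+"),
    ("ND3", "protein", 9459, 9806, "+"),
    ("ND4L", "protein", 9877, 10173, "+"),
    ("ND4", "protein", 10174, 11544, "+"),
    ("ND5", "protein", 11742, 13565, "+"),
    ("ND6", "protein", 13570, 14070, "-"),
    ("CYTB", "protein", 14146, 15288, "+"),
    ("dloop", "dloop", 15423, 16299, "+"),
]

HUMAN_LIKE_GENES = [
    ("tRNA-F", "tRNA", 577, 647, "+"),
    ("rRNA-12S", "rRNA", 648, 1601, "+"),
    ("tRNA-V", "tRNA", 1602, 1670, "+"),
    ("rRNA-16S", "rRNA", 1671, 3229, "+"),
    ("ND1", "protein", 3307, 4260, "+"),
    ("ND2", "protein", 4470, 5510, "+"),
    ("COX1", "protein", 5904, 7445, "+"),
    ("COX2", "protein", 7586, 8269, "+"),
    ("ATP8", "protein", 8366, 8569, "+"),
    ("ATP6", "protein", 8527, 9207, "+"),
    ("COX3", "protein", 9208, 9990, "+"),
    ("ND3", "protein", 10059, 10406, "+"),
    ("ND4L", "protein", 10470, 10766, "+"),
    ("ND4", "protein", 10767, 12137, "+"),
    ("ND5", "protein", 12337, 14148, "+"),
    ("ND6", "protein", 14149, 14673, "-"),
    ("CYTB", "protein", 14747, 15886, "+"),
    ("dloop", "dloop", 16024, 16569, "+"),
]

_BASES = np.array(list("ACGT"))

# mouse ATP6 offset of the m.8993-homologous site: 8393 - 7927 = 466
_ATP6_ANCHOR_OFFSET = 466


def _annotation(table, length: int) -> GeneAnnotation:
    records = [
        GeneRecord(gene_name=n, region_class=c, start=s, end=e, strand=st)
        for n, c, s, e, st in table
    ]
    return GeneAnnotation(records=records, genome_length=length)


def mouse_like_annotation() -> GeneAnnotation:
    return _annotation(MOUSE_LIKE_GENES, MOUSE_LIKE_LENGTH)


def human_like_annotation() -> GeneAnnotation:
    return _annotation(HUMAN_LIKE_GENES, HUMAN_LIKE_LENGTH)


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def mouse_like_genome(seed: int = 0) -> MtGenome:
    """Random 16299-bp genome with the mouse-like annotation layout.

    The base at position 8393 (ATP6 offset 466) is pinned to T so the
    m.8993-homologous site carries the same reference base as in the real
    genomes (the T8993C / T8393C pairing).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6D6F7573]))
    seq = list(_random_sequence(rng, MOUSE_LIKE_LENGTH))
    seq[8393 - 1] = "T"
    return MtGenome(name="mouse_like_chrM", sequence="".join(seq))


def ortholog_pair(
    seed: int = 0,
    divergence: float = 0.10,
) -> tuple[MtGenome, GeneAnnotation, MtGenome, GeneAnnotation]:
    """(mouse_genome, mouse_annot, human_genome, human_annot) ortholog fixture.

    Each human-like gene is the mouse-like gene's coding-strand sequence
    with point substitutions at rate ``divergence`` and, where the species'
    gene lengths differ by d bases, one d-bp insertion or deletion placed
    mid-gene.  ATP6 (identical lengths) stays indel-free and its anchor
    site (mouse 8393 / human 8993) is never substituted, so the homology of
    the m.8993 site is preserved by construction *of the sequences*; the
    mapping itself must still be recovered by alignment.
    """
    mouse = mouse_like_genome(seed)
    mouse_annot = mouse_like_annotation()
    human_annot = human_like_annotation()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x68756D61]))

    human_seq = list(_random_sequence(rng, HUMAN_LIKE_LENGTH))
    mouse_by_name = {r.gene_name: r for r in mouse_annot}
    for hrec in human_annot:
        mrec = mouse_by_name[hrec.gene_name]
        gene = list(mouse.sequence[mrec.start - 1: mrec.end])  # plus strand
        anchor = _ATP6_ANCHOR_OFFSET if hrec.gene_name == "ATP6" else None
        for i in range(len(gene)):
            if i == anchor:
                continue
            if rng.random() < divergence:
                alt = [b for b in "ACGT" if b != gene[i]]
                gene[i] = alt[rng.integers(0, 3)]
        d = hrec.length - len(gene)
        mid = len(gene) // 2
        if d > 0:
            gene[mid:mid] = list(_random_sequence(rng, d))
        elif d < 0:
            del gene[mid:mid - d]
        human_seq[hrec.start - 1: hrec.end] = gene
    human = MtGenome(name="human_like_chrM", sequence="".join(human_seq))
    return mouse, mouse_annot, human, human_annot
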