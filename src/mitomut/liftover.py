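"""Cross-species mapping of pathogenic mtDNA mutations via per-gene alignment.

Human pathogenic variants (a MITOMAP-style catalog) are projected onto the
mouse genome by aligning each annotated gene/region pair with a
deterministic global Needleman-Wunsch alignment (affine gaps, Gotoh
recursion).  Default scoring: match +2, mismatch -1, gap open -5 (first
gap base), gap extend -1; traceback ties break diagonal > up > left.
Minus-strand regions are aligned as reverse complements and the mapped
coordinates converted back to reference-strand numbering, so the homology
map always pairs reference-strand positions.

At the high sequence identities of mammalian mtDNA orthologs the mapping
is insensitive to the exact gap penalties; inter-genic positions are
deliberately left unmapped.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

import numpy as np

from .effects import revcomp, translate_codon
from .io import GeneAnnotation, MtGenome, MitomutError

NEG_INF = float("-inf")


class AlignmentError(MitomutError):
    pass


class CatalogError(MitomutError):
    pass


@dataclass
class AlignedRegion:
    """Alignment of one region pair as ordered (pos_a, pos_b) columns.

    Either side of a column may be None (gap).  Positions are 1-based
    reference-strand coordinates in their respective genomes.
    """

    region_name: str
    pairs: list[tuple[Optional[int], Optional[int]]]
    identity: float  # percent of alignment columns that are matches
    score: float

    def a_to_b(self) -> dict[int, int]:
        return {a: b for a, b in self.pairs if a is not None and b is not None}

    def b_to_a(self) -> dict[int, int]:
        return {b: a for a, b in self.pairs if a is not None and b is not None}


@dataclass
class HomologyMap:
    """Per-region alignment-derived coordinate mapping between two genomes."""

    regions: list[AlignedRegion]

    def lift(self, pos: int, source: Literal["a", "b"] = "b") -> Optional[int]:
        """Image of ``pos`` in the other genome, or None if unmapped
        (gap-aligned or inter-genic)."""
        for region in self.regions:
            table = region.b_to_a() if source == "b" else region.a_to_b()
            if pos in table:
                return table[pos]
        return None


def _score_matrix(a: str, b: str, match: float, mismatch: float,
                  gap_open: float, gap_extend: float):
    """Gotoh DP. Returns (M, X, Y) score matrices and traceback pointers."""
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)  # a[i] against gap ("up")
    Y = np.full((n + 1, m + 1), NEG_INF)  # b[j] against gap ("left")
    # pointer codes: which predecessor state (0=M, 1=X, 2=Y)
    ptr_M = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_X = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_Y = np.zeros((n + 1, m + 1), dtype=np.int8)

    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
        ptr_X[i, 0] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
        ptr_Y[0, j] = 2 if j > 1 else 0

    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        pM, pX, pY = ptr_M[i], ptr_X[i], ptr_Y[i]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            # diagonal into M: tie order M > X > Y
            best, arg = Mi1[j - 1], 0
            if Xi1[j - 1] > best:
                best, arg = Xi1[j - 1], 1
            if Yi1[j - 1] > best:
                best, arg = Yi1[j - 1], 2
            Mi[j] = best + s
            pM[j] = arg
            # up into X (gap in b): open from M/Y, extend from X
            o, e = Mi1[j] + gap_open, Xi1[j] + gap_extend
            oy = Yi1[j] + gap_open
            best, arg = o, 0
            if e > best:
                best, arg = e, 1
            if oy > best:
                best, arg = oy, 2
            Xi[j] = best
            pX[j] = arg
            # left into Y (gap in a)
            o, e = Mi[j - 1] + gap_open, Yi[j - 1] + gap_extend
            ox = Xi[j - 1] + gap_open
            best, arg = o, 0
            if ox > best:
                best, arg = ox, 1
            if e > best:
                best, arg = e, 2
            Yi[j] = best
            pY[j] = arg
    return M, X, Y, ptr_M, ptr_X, ptr_Y


def align_sequences(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> tuple[list[tuple[Optional[int], Optional[int]]], float, float]:
    """Global affine-gap alignment of two sequences.

    Returns (columns, identity_percent, score) where columns are 1-based
    index pairs into ``a`` and ``b`` with None marking a gap.  Traceback is
    deterministic with tie order diagonal > up > left.
    """
    if not a or not b:
        raise AlignmentError("cannot align an empty sequence")
    n, m = len(a), len(b)
    M, X, Y, pM, pX, pY = _score_matrix(a, b, match, mismatch, gap_open,
                                        gap_extend)
    # final state: tie order M > X > Y
    state = 0
    best = M[n, m]
    if X[n, m] > best:
        best, state = X[n, m], 1
    if Y[n, m] > best:
        best, state = Y[n, m], 2
    score = float(best)

    cols: list[tuple[Optional[int], Optional[int]]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            prev = pM[i, j]
            cols.append((i, j))
            i, j = i - 1, j - 1
            state = prev
        elif state == 1:
            prev = pX[i, j]
            cols.append((i, None))
            i -= 1
            state = prev
        else:
            prev = pY[i, j]
            cols.append((None, j))
            j -= 1
            state = prev
    cols.reverse()
    matches = sum(
        1 for ia, ib in cols
        if ia is not None and ib is not None and a[ia - 1] == b[ib - 1]
    )
    identity = 100.0 * matches / len(cols)
    return cols, identity, score


def align_region(
    seq_a: str,
    seq_b: str,
    region_name: str = "region",
    **scoring,
) -> AlignedRegion:
    """Align two same-orientation region sequences into an AlignedRegion
    whose positions are 1-based offsets within each sequence."""
    cols, identity, score = align_sequences(seq_a.upper(), seq_b.upper(),
                                            **scoring)
    return AlignedRegion(region_name=region_name, pairs=cols,
                         identity=identity, score=score)


def _region_positions(rec) -> list[int]:
    """Reference-strand positions of a record along its coding strand."""
    if rec.strand == "+":
        return list(range(rec.start, rec.end + 1))
    return list(range(rec.end, rec.start - 1, -1))


def _region_sequence(genome: MtGenome, rec) -> str:
    seq = genome.sequence[rec.start - 1: rec.end]
    return revcomp(seq) if rec.strand == "-" else seq


def build_homology_map(
    genome_a: MtGenome,
    annot_a: GeneAnnotation,
    genome_b: MtGenome,
    annot_b: GeneAnnotation,
    region_names: Optional[Iterable[str]] = None,
    **scoring,
) -> HomologyMap:
    """Per-region homology map between two annotated genomes.

    Regions are paired by name; ``region_names`` restricts the map to a
    subset (all shared names by default).  Raises on names present in only
    one annotation when requested explicitly.
    """
    by_a = {r.gene_name: r for r in annot_a}
    by_b = {r.gene_name: r for r in annot_b}
    if region_names is None:
        names = [r.gene_name for r in annot_a if r.gene_name in by_b]
    else:
        names = list(region_names)
        missing = [n for n in names if n not in by_a or n not in by_b]
        if missing:
            raise AlignmentError(f"regions not present in both annotations: {missing}")

    regions: list[AlignedRegion] = []
    for name in names:
        ra, rb = by_a[name], by_b[name]
        frag = align_region(_region_sequence(genome_a, ra),
                            _region_sequence(genome_b, rb),
                            region_name=name, **scoring)
        pos_a = _region_positions(ra)
        pos_b = _region_positions(rb)
        pairs = [
            (pos_a[ia - 1] if ia is not None else None,
             pos_b[ib - 1] if ib is not None else None)
            for ia, ib in frag.pairs
        ]
        regions.append(AlignedRegion(region_name=name, pairs=pairs,
                                     identity=frag.identity, score=frag.score))
    return HomologyMap(regions=regions)


def lift_position(hmap: HomologyMap, pos: int,
                  source: Literal["a", "b"] = "b") -> Optional[int]:
    """Image of ``pos`` under the map; None for gap-aligned or inter-genic
    positions (the "unmapped" sentinel)."""
    return hmap.lift(pos, source=source)


# ---------------------------------------------------------------------------
# pathogenic catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathogenicCatalogEntry:
    human_pos: int
    human_ref: str
    human_alt: str
    locus_name: str
    status: str

    def __post_init__(self) -> None:
        if self.human_ref == self.human_alt:
            raise CatalogError(f"ref equals alt at m.{self.human_pos}")


_ALLELE_COMPACT = re.compile(r"^([ACGTU])(\d+)([ACGTU])$", re.IGNORECASE)
_ALLELE_HGVS = re.compile(r"^m\.(\d+)([ACGTU])>([ACGTU])$", re.IGNORECASE)


def parse_allele(text: str) -> tuple[int, str, str]:
    """Parse 'T8993G' or 'm.8993T>G' into (position, ref, alt); U -> T."""
    text = text.strip()
    m = _ALLELE_COMPACT.match(text)
    if m:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    else:
        m = _ALLELE_HGVS.match(text)
        if not m:
            raise CatalogError(f"unparseable allele string {text!r}")
        pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
    norm = lambda b: b.upper().replace("U", "T")
    return pos, norm(ref), norm(alt)


def load_pathogenic_catalog(
    path: str | Path,
    statuses: Optional[set[str]] = frozenset({"Cfrm"}),
    human_length: int = 16569,
) -> list[PathogenicCatalogEntry]:
    """Load a MITOMAP-style tab- or comma-separated catalog.

    Expects columns (case-insensitive, order-free) ``locus``, ``allele``
    and ``status``; ``statuses=None`` disables status filtering.  Malformed
    allele strings are reported with their line number.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            raise CatalogError(f"{path}: empty catalog")
        fields = {f.lower().strip(): f for f in reader.fieldnames}
        try:
            locus_col = fields["locus"]
            allele_col = fields["allele"]
            status_col = fields.get("status")
        except KeyError as exc:
            raise CatalogError(f"{path}: missing column {exc}") from exc
        entries = []
        for lineno, row in enumerate(reader, 2):
            status = (row[status_col] or "").strip() if status_col else ""
            if statuses is not None and status not in statuses:
                continue
            try:
                pos, ref, alt = parse_allele(row[allele_col])
            except CatalogError as exc:
                raise CatalogError(f"{path}:{lineno}: {exc}") from exc
            if not 1 <= pos <= human_length:
                raise CatalogError(
                    f"{path}:{lineno}: position {pos} outside 1..{human_length}"
                )
            entries.append(
                PathogenicCatalogEntry(
                    human_pos=pos, human_ref=ref, human_alt=alt,
                    locus_name=(row[locus_col] or "").strip(), status=status,
                )
            )
    return entries


@dataclass
class PathogenicHit:
    entry: PathogenicCatalogEntry
    mouse_pos: int
    mouse_ref: str
    mouse_alt: str
    variant: object  # the matched SiteVariant
    match_mode: str


def count_pathogenic(
    variants,
    catalog: list[PathogenicCatalogEntry],
    hmap: HomologyMap,
    threshold: float = 1.0,
    match_mode: Literal["position+allele", "position_only"] = "position+allele",
    include_ref_mismatch: bool = False,
) -> tuple[int, list[PathogenicHit]]:
    """Count variants homologous to catalog entries with frequency > threshold.

    A hit requires the variant position to be the mouse image of a catalog
    position.  With the default ``position+allele`` mode the variant's alt
    base must equal the catalog alt.  Sites where the mouse reference base
    differs from the human reference base are excluded unless
    ``include_ref_mismatch`` (a "homologous mutation" is ill-defined where
    the ancestral base already differs).  Hit variants get their
    ``pathogenic_human_pos`` field filled.
    """
    by_mouse_pos: dict[int, list[PathogenicCatalogEntry]] = {}
    for entry in catalog:
        mpos = hmap.lift(entry.human_pos, source="b")
        if mpos is not None:
            by_mouse_pos.setdefault(mpos, []).append(entry)

    hits: list[PathogenicHit] = []
    seen: set[tuple[int, str, int]] = set()
    for v in variants:
        if v.frequency <= threshold or v.pos not in by_mouse_pos:
            continue
        for entry in by_mouse_pos[v.pos]:
            if not include_ref_mismatch and v.ref != entry.human_ref:
                continue
            if match_mode == "position+allele" and v.alt != entry.human_alt:
                continue
            key = (v.pos, v.alt, entry.human_pos)
            if key in seen:
                continue
            seen.add(key)
            v.pathogenic_human_pos = entry.human_pos
            hits.append(
                PathogenicHit(entry=entry, mouse_pos=v.pos, mouse_ref=v.ref,
                              mouse_alt=v.alt, variant=v, match_mode=match_mode)
            )
    return len(hits), hits


# ---------------------------------------------------------------------------
# amino-acid-level cross-check
# ---------------------------------------------------------------------------

def align_region_protein(
    seq_a: str,
    seq_b: str,
    region_name: str = "region",
    **scoring,
) -> AlignedRegion:
    """Codon-resolution mapping from an amino-acid alignment (cross-check).

    Both sequences are translated under the vertebrate mitochondrial code,
    aligned as proteins, and the aligned residues back-projected to their
    codon bases.  Nucleotide alignment remains authoritative; this exists
    to confirm protein-level colinearity on ortholog pairs.
    """
    def _translate(seq: str) -> str:
        return "".join(
            translate_codon(seq[i:i + 3]) for i in range(0, len(seq) - 2, 3)
        )

    aa_a, aa_b = _translate(seq_a), _translate(seq_b)
    cols, identity, score = align_sequences(aa_a, aa_b, **scoring)
    pairs: list[tuple[Optional[int], Optional[int]]] = []
    for ia, ib in cols:
        for k in range(3):
            pa = (ia - 1) * 3 + k + 1 if ia is not None else None
            pb = (ib - 1) * 3 + k + 1 if ib is not None else None
            pairs.append((pa, pb))
    return AlignedRegion(region_name=region_name, pairs=pairs,
                         identity=identity, score=score)
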