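import numpy as np
import pandas as pd
import pytest

from mitomut.io import (AlleleCountTable, GeneAnnotation, GeneRecord, MtGenome,
                        SampleMeta)

TOY_GENE_SEQ = (
    "ATGACCGCTATTCTAGGATGAACCTCTGCCCATATTGACCTAGCCGAAATCGGCTGCTAA"
)  # 60 bp = 20 complete codons, starts ATG, ends TAA


@pytest.fixture
def meta():
    return SampleMeta(mouse_id="m1", organ="heart", polg_genotype="+/+",
                      generation="G1")


@pytest.fixture
def toy_genome():
    """60-bp genome fully covered by a single plus-strand protein gene."""
    return MtGenome(name="toy", sequence=TOY_GENE_SEQ)


@pytest.fixture
def toy_annotation(toy_genome):
    return GeneAnnotation(
        records=[GeneRecord(gene_name="g1", region_class="protein",
                            start=1, end=60, strand="+")],
        genome_length=toy_genome.length,
    )


def make_table(genome, meta, depths=None, alt_calls=(), ins=(), dels=()):
    """Build an AlleleCountTable: all-reference at the given depths, then
    move `n` reads from ref to `alt` for each (pos, alt, n) in alt_calls."""
    L = genome.length
    if depths is None:
        depths = np.full(L, 100, dtype=np.int64)
    depths = np.asarray(depths, dtype=np.int64)
    counts = {b: np.zeros(L, dtype=np.int64) for b in "ACGT"}
    for i, b in enumerate(genome.sequence):
        counts[b][i] = depths[i]
    for pos, alt, n in alt_calls:
        ref = genome.base(pos)
        counts[ref][pos - 1] -= n
        counts[alt][pos - 1] += n
    ins_arr = np.zeros(L, dtype=np.int64)
    for pos, n in ins:
        ins_arr[pos - 1] = n
    del_arr = np.zeros(L, dtype=np.int64)
    for pos, n in dels:
        del_arr[pos - 1] = n
    df = pd.DataFrame({
        "pos": np.arange(1, L + 1, dtype=np.int64), "depth": depths,
        "A": counts["A"], "C": counts["C"], "G": counts["G"], "T": counts["T"],
        "ins": ins_arr, "del": del_arr,
    })
    return AlleleCountTable(meta=meta, table=df, genome_name=genome.name)


@pytest.fixture
def make_count_table():
    return make_table


def random_genome(rng, length, name="rand"):
    return MtGenome(name=name,
                    sequence="".join(np.array(list("ACGT"))[
                        rng.integers(0, 4, size=length)]))


@pytest.fixture
def random_genome_factory():
    return random_genome
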