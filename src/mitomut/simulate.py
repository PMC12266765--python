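"""Forward simulator of the mutator-mouse mtDNA generative process.

The model has three layers:

1. **Maternal germline** (:func:`simulate_pedigree`): each of
   ``generation_count`` transmissions adds Poisson-distributed new point
   mutations (entering at heteroplasmy 1/N_b), applies purifying selection
   against non-synonymous variants, and resamples every heteroplasmy
   through an effective bottleneck of ``bottleneck_size`` segregating
   genome copies (binomial drift).  Variants lost at frequency 0 are
   dropped; variants fixed at 1 become lineage reference replacements and
   stop drifting.  A G1-like founder (``generation_count=0``) carries no
   inherited variants.

2. **Soma** (:func:`simulate_soma`): every organ inherits the germline set
   at identical heteroplasmies, then gains Poisson-distributed private
   somatic variants with truncated-exponential heteroplasmies.  A fraction
   of new mutations (germline and somatic) are 1-bp indels.

3. **Sequencing** (:func:`simulate_counts`): per-site read depths are
   Poisson; base calls are drawn from the site's true allele mixture and
   flipped with probability ``error_rate`` to one of the other three bases
   uniformly.  Indel-supporting reads are drawn binomially; deletion
   supporters are kept outside the base-call depth, matching the
   count-table convention.

All randomness flows from a single root seed through named substreams per
mouse and organ, so cohort outputs are reproducible regardless of the
order in which samples are generated.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .effects import classify_substitution
from .io import (AlleleCountTable, GeneAnnotation, MtGenome, MitomutError,
                 SampleMeta, write_counts)

DEFAULT_ORGANS = ("heart", "kidney", "soleus")


class ConfigError(MitomutError):
    pass


@dataclass
class SimulationConfig:
    """Study-condition parameters for one simulated mouse.

    Defaults emulate the mutator-mouse study design: three nuclear Polg
    genotypes, strains maintained through heterozygous mothers, a
    sequencing-error floor that alone puts wild-type total mutation
    frequency near 0.45%, a mut/mut somatic burden raising the total to
    roughly 1.7x wild type, and indels rarer than point mutations by more
    than a factor of 40.
    """

    genome_length: int = 16299
    polg_genotype: str = "+/+"
    generation_count: int = 0                # 0 = G1-like, >=9 = G>=10-like
    maternal_genotype: str = "+/mut"         # strain kept by het x het crosses
    mu_germline: dict = field(
        default_factory=lambda: {"+/+": 3.0, "+/mut": 3.0, "mut/mut": 8.0}
    )
    bottleneck_size: int = 32
    selection_s: float = 0.3
    mu_somatic: dict = field(
        default_factory=lambda: {"+/+": 3000.0, "+/mut": 3000.0,
                                 "mut/mut": 50000.0}
    )
    somatic_freq_mean: float = 0.001         # mean somatic heteroplasmy (fraction)
    indel_fraction: float = 1.0 / 60.0       # of new mutations that are 1-bp indels
    organs: Sequence[str] = DEFAULT_ORGANS
    depth_mean: float = 2000.0
    error_rate: float = 0.0045               # per-base-call error probability
    transition_bias: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ConfigError("genome_length must be positive")
        if self.generation_count < 0:
            raise ConfigError("generation_count must be non-negative")
        if self.bottleneck_size <= 0:
            raise ConfigError("bottleneck_size must be positive")
        if not 0.0 <= self.selection_s <= 1.0:
            raise ConfigError("selection_s must lie in [0, 1]")
        if not 0.0 < self.somatic_freq_mean < 1.0:
            raise ConfigError("somatic_freq_mean must lie in (0, 1)")
        if not 0.0 <= self.error_rate <= 0.01:
            raise ConfigError("error_rate must lie in [0, 0.01]")
        if not 0.0 <= self.indel_fraction <= 1.0:
            raise ConfigError("indel_fraction must lie in [0, 1]")
        for d in (self.mu_germline, self.mu_somatic):
            if any(v < 0 for v in d.values()):
                raise ConfigError("mutation rates must be non-negative")
        if self.depth_mean < 0:
            raise ConfigError("depth_mean must be non-negative")


@dataclass
class GroundTruthVariant:
    """One true variant with its origin and heteroplasmy."""

    pos: int
    ref: str
    alt: str          # base, "+N" insertion token, or "-" deletion
    origin: str       # germline | somatic
    organ: str        # "all" for germline, one organ name for somatic
    heteroplasmy: float
    effect_truth: str  # synonymous | nonsynonymous | noncoding | indel

    def __post_init__(self) -> None:
        if not 0.0 < self.heteroplasmy <= 1.0:
            raise ValueError("heteroplasmy must lie in (0, 1]")

    @property
    def is_indel(self) -> bool:
        return self.alt.startswith("+") or self.alt == "-"


def substream(seed: int, *names: str) -> np.random.Generator:
    """Named, order-independent child RNG of the root seed."""
    entropy = [int(seed)] + [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _truth_effect(genome: MtGenome, annotation: GeneAnnotation,
                  pos: int, alt: str) -> str:
    if alt.startswith("+") or alt == "-":
        return "indel"
    # somatic burdens run to tens of thousands of variants; memoize per-site
    # effect lookups on the annotation instance
    cache = annotation.__dict__.setdefault("_effect_cache", {})
    key = (hash(genome.sequence), pos, alt)
    if key not in cache:
        effect = classify_substitution(genome, annotation, pos, alt).effect
        if effect not in ("synonymous", "nonsynonymous"):
            effect = "noncoding"
        cache[key] = effect
    return cache[key]


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _draw_mutation(
    rng: np.random.Generator,
    genome: MtGenome,
    annotation: GeneAnnotation,
    config: SimulationConfig,
    heteroplasmy: float,
    origin: str,
    organ: str,
) -> GroundTruthVariant:
    pos = int(rng.integers(1, genome.length + 1))
    ref = genome.base(pos)
    if rng.random() < config.indel_fraction:
        if rng.random() < 0.5:
            alt = "+" + "ACGT"[rng.integers(0, 4)]
        else:
            alt = "-"
    elif config.transition_bias and rng.random() < 2.0 / 3.0:
        # crude 2:1 ts:tv skew when enabled; default is uniform
        alt = _TRANSITION[ref]
    else:
        choices = [b for b in "ACGT" if b != ref]
        alt = choices[rng.integers(0, 3)]
    return GroundTruthVariant(
        pos=pos, ref=ref, alt=alt, origin=origin, organ=organ,
        heteroplasmy=heteroplasmy,
        effect_truth=_truth_effect(genome, annotation, pos, alt),
    )


def simulate_pedigree(
    config: SimulationConfig,
    genome: MtGenome,
    annotation: GeneAnnotation,
    rng: Optional[np.random.Generator] = None,
) -> list[GroundTruthVariant]:
    """Germline variant set of the focal mouse after ``generation_count``
    maternal transmissions.

    Selection acts within each site: a non-synonymous variant's frequency
    h is reweighted to h(1-s) against a reference weight of (1-h) before
    the bottleneck draw.  Fixed variants are returned at heteroplasmy 1.0
    (they read as 100% mismatches against the reference) but no longer
    drift.
    """
    if rng is None:
        rng = substream(config.seed, "pedigree")
    mu = config.mu_germline[config.maternal_genotype]
    nb = config.bottleneck_size
    s = config.selection_s

    segregating: list[GroundTruthVariant] = []
    fixed: list[GroundTruthVariant] = []
    for _ in range(config.generation_count):
        for _ in range(rng.poisson(mu)):
            segregating.append(
                _draw_mutation(rng, genome, annotation, config,
                               heteroplasmy=1.0 / nb, origin="germline",
                               organ="all")
            )
        survivors: list[GroundTruthVariant] = []
        for v in segregating:
            h = v.heteroplasmy
            if v.effect_truth == "nonsynonymous" and s > 0:
                h = h * (1.0 - s) / (1.0 - s * h)
            k = int(rng.binomial(nb, h))
            if k == 0:
                continue
            v.heteroplasmy = k / nb
            if k == nb:
                fixed.append(v)
            else:
                survivors.append(v)
        segregating = survivors
    return segregating + fixed


def _truncated_exponential(rng: np.random.Generator, mean: float) -> float:
    while True:
        h = float(rng.exponential(mean))
        if 0.0 < h < 1.0:
            return h


def simulate_soma(
    germline: list[GroundTruthVariant],
    config: SimulationConfig,
    genome: MtGenome,
    annotation: GeneAnnotation,
    rng_factory=None,
) -> dict[str, list[GroundTruthVariant]]:
    """Per-organ variant sets: the shared germline plus private somatics."""
    if rng_factory is None:
        rng_factory = lambda organ: substream(config.seed, "soma", organ)
    mu = config.mu_somatic[config.polg_genotype]
    out: dict[str, list[GroundTruthVariant]] = {}
    for organ in config.organs:
        rng = rng_factory(organ)
        variants = list(germline)  # shared objects: identical heteroplasmies
        for _ in range(rng.poisson(mu)):
            h = _truncated_exponential(rng, config.somatic_freq_mean)
            variants.append(
                _draw_mutation(rng, genome, annotation, config,
                               heteroplasmy=h, origin="somatic", organ=organ)
            )
        out[organ] = variants
    return out


def simulate_counts(
    organ_variants: list[GroundTruthVariant],
    config: SimulationConfig,
    genome: MtGenome,
    meta: Optional[SampleMeta] = None,
    rng: Optional[np.random.Generator] = None,
) -> AlleleCountTable:
    """Sequencing layer: allele-count table for one organ sample."""
    if rng is None:
        rng = substream(config.seed, "counts")
    if meta is None:
        meta = SampleMeta(
            mouse_id="sim", organ="organ", polg_genotype=config.polg_genotype,
            generation="G1" if config.generation_count == 0 else "G10plus",
        )
    L = genome.length
    base_idx = {b: i for i, b in enumerate("ACGT")}
    ref_idx = np.array([base_idx[b] for b in genome.sequence])

    # true allele mixture per site (L x 4), reference mass reduced by sum(h)
    p = np.zeros((L, 4))
    p[np.arange(L), ref_idx] = 1.0
    for v in organ_variants:
        if v.is_indel:
            continue
        i = v.pos - 1
        p[i, base_idx[v.alt]] += v.heteroplasmy
        p[i, ref_idx[i]] -= v.heteroplasmy
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)

    # per-read error: called base = true base w.p. 1-e, else uniform other
    e = config.error_rate
    q = p * (1.0 - e) + (1.0 - p) * (e / 3.0)

    depth = rng.poisson(config.depth_mean, size=L)
    counts = np.zeros((L, 4), dtype=np.int64)
    remaining = depth.copy()
    prob_left = np.ones(L)
    for b in range(3):
        with np.errstate(divide="ignore", invalid="ignore"):
            pb = np.where(prob_left > 0, q[:, b] / prob_left, 0.0)
        counts[:, b] = rng.binomial(remaining, np.clip(pb, 0.0, 1.0))
        remaining -= counts[:, b]
        prob_left -= q[:, b]
    counts[:, 3] = remaining

    ins = np.zeros(L, dtype=np.int64)
    dele = np.zeros(L, dtype=np.int64)
    for v in organ_variants:
        i = v.pos - 1
        if v.alt.startswith("+"):
            ins[i] += rng.binomial(depth[i], v.heteroplasmy)
        elif v.alt == "-":
            span = rng.poisson(config.depth_mean)  # deletion reads live outside depth
            dele[i] += rng.binomial(span, v.heteroplasmy)

    df = pd.DataFrame({
        "pos": np.arange(1, L + 1, dtype=np.int64),
        "depth": depth.astype(np.int64),
        "A": counts[:, 0], "C": counts[:, 1],
        "G": counts[:, 2], "T": counts[:, 3],
        "ins": ins, "del": dele,
    })
    return AlleleCountTable(meta=meta, table=df, genome_name=genome.name)


def simulate_mouse(
    config: SimulationConfig,
    genome: MtGenome,
    annotation: GeneAnnotation,
    mouse_id: str = "sim",
) -> tuple[list[GroundTruthVariant], dict[str, AlleleCountTable]]:
    """Full generative pass for one mouse: germline, soma, sequencing."""
    generation = "G1" if config.generation_count == 0 else "G10plus"
    germ = simulate_pedigree(
        config, genome, annotation, rng=substream(config.seed, mouse_id, "pedigree")
    )
    organs = simulate_soma(
        germ, config, genome, annotation,
        rng_factory=lambda o: substream(config.seed, mouse_id, "soma", o),
    )
    tables = {}
    for organ, variants in organs.items():
        meta = SampleMeta(mouse_id=mouse_id, organ=organ,
                          polg_genotype=config.polg_genotype,
                          generation=generation)
        tables[organ] = simulate_counts(
            variants, config, genome, meta=meta,
            rng=substream(config.seed, mouse_id, "counts", organ),
        )
    return germ, tables


def preset_config(polg_genotype: str, generation: str, seed: int = 0,
                  **overrides) -> SimulationConfig:
    """Study-design preset: 'G1' founders or 'G10plus' late-generation mice."""
    if generation not in ("G1", "G10plus"):
        raise ConfigError("generation must be 'G1' or 'G10plus'")
    gc = 0 if generation == "G1" else 10
    return SimulationConfig(polg_genotype=polg_genotype, generation_count=gc,
                            seed=seed, **overrides)


TRUTH_COLUMNS = ["pos", "ref", "alt", "origin", "organ", "heteroplasmy",
                 "effect_truth"]


def write_truth(variants_by_organ: Mapping[str, list[GroundTruthVariant]],
                path: str | Path) -> None:
    rows = []
    seen = set()
    for organ in variants_by_organ:
        for v in variants_by_organ[organ]:
            key = (v.pos, v.alt, v.origin, v.organ)
            if key in seen:
                continue  # germline variants are shared across organs
            seen.add(key)
            rows.append({
                "pos": v.pos, "ref": v.ref, "alt": v.alt, "origin": v.origin,
                "organ": v.organ, "heteroplasmy": f"{v.heteroplasmy:.6g}",
                "effect_truth": v.effect_truth,
            })
    rows.sort(key=lambda r: (r["pos"], r["alt"], r["organ"]))
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def simulate_cohort(
    grid: Iterable[Mapping],
    genome: MtGenome,
    annotation: GeneAnnotation,
    out_dir: str | Path,
    base_config: Optional[SimulationConfig] = None,
) -> list[Path]:
    """Simulate a cohort and write one count TSV per mouse x organ plus a
    ground-truth TSV per mouse.

    ``grid`` rows are mappings with keys ``mouse_id``, ``polg_genotype``,
    ``generation`` ('G1' or 'G10plus').  Deterministic for a fixed root
    seed (taken from ``base_config``), independent of row order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = base_config if base_config is not None else SimulationConfig()
    written: list[Path] = []
    for row in grid:
        mouse_id = str(row["mouse_id"])
        gc = 0 if row["generation"] == "G1" else 10
        config = replace(base, polg_genotype=row["polg_genotype"],
                         generation_count=gc)
        germ = simulate_pedigree(
            config, genome, annotation,
            rng=substream(config.seed, mouse_id, "pedigree"),
        )
        organs = simulate_soma(
            germ, config, genome, annotation,
            rng_factory=lambda o, m=mouse_id: substream(config.seed, m, "soma", o),
        )
        for organ, variants in organs.items():
            meta = SampleMeta(mouse_id=mouse_id, organ=organ,
                              polg_genotype=config.polg_genotype,
                              generation=str(row["generation"]))
            acount = simulate_counts(
                variants, config, genome, meta=meta,
                rng=substream(config.seed, mouse_id, "counts", organ),
            )
            p = out_dir / f"counts_{mouse_id}_{organ}.tsv"
            write_counts(acount, p)
            written.append(p)
        p = out_dir / f"truth_{mouse_id}.tsv"
        write_truth(organs, p)
        written.append(p)
    return written
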