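# Methods

`mitomut` analyses mitochondrial DNA (mtDNA) heteroplasmy in
proofreading-deficient *Polg* ("mutator") mice from pileup-derived
allele-count tables, and ships a forward simulator of the full generative
process so that every analysis stage can be validated against ground truth
at desk scale. This note records the models, the parameter choices, and
their limits.

## The mutation-frequency statistic

For one sample the central readout is

```
mutation frequency (%) = 100 x (base calls differing from the reference)
                              / (total base calls)
```

summed over positions. Properties that the implementation guarantees and
the tests enforce:

* Positions with zero depth enter neither numerator nor denominator;
  coverage is reported separately (`QCMetrics.coverage_rate`). The formula
  counts *sequenced* bases, so unsequenced positions cannot dilute it.
* The numerator sums **all** non-reference base calls at a site; a
  tri-allelic site contributes every mismatching read, not just the major
  alternative allele.
* Indel-supporting reads are excluded from the substitution statistic and
  reported separately: insertions against the base-call depth, deletions
  against depth + deletion reads (deletion-supporting reads carry no base
  call at the site and are kept outside `depth` in the count-table format).
* Conservation: region-wise mismatch counts sum to the genome-wide count,
  and the depth-weighted mean of region frequencies over any partition of
  positions reproduces the total frequency to 1e-12 relative tolerance.
* No depth floor or quality filter is applied by default (`--min-depth` is
  opt-in): defaults must not silently filter.

Per-site variants (`SiteVariant`) are emitted for every (position, alt
base) with at least one supporting read; the 1% quantification threshold
for counting non-synonymous and pathogenic-homologous variants is strict
(`frequency > 1.0`), applied to the per-site alt-allele frequency, not to
the genome-wide statistic.

## Effect annotation

Protein-coding substitutions are translated under NCBI translation
table 2 (vertebrate mitochondrial code: ATA=Met, TGA=Trp, AGA/AGG=stop),
via Biopython's codon tables. Minus-strand genes are read on the reverse
complement; coordinates stay in reference-strand numbering. Stop gains
and losses are counted as non-synonymous (the readout is binary).
Variants under overlapping records (e.g. the ATP8/ATP6 overlap) are
classified within the first record in file order, with a warning.
Variants in the trailing partial codon of a length-incomplete protein
record cannot be translated and are flagged instead of guessed.

Frequency histograms use decile bins with a (1,10] first bin —
(1,10], (10,20], ..., (90,100] — matching the descriptive bands used for
high-heteroplasmy variants (e.g. "20%-30%", "60%-70%"); exact figure bin
edges are not standardized, so decile bins are a recorded design choice.

## Cross-species pathogenic liftover

Human pathogenic mtDNA variants (MITOMAP-style catalog; both `T8993G` and
`m.8993T>G` notations are parsed, default filter: confirmed status) are
projected onto the mouse genome by per-gene pairwise global alignment:
Needleman-Wunsch with affine gaps (Gotoh), scoring match +2, mismatch -1,
gap open -5, gap extend -1, deterministic traceback with tie order
diagonal > up > left. A multiple-alignment tool is unnecessary for
exactly two sequences per region, and at mammalian mtDNA ortholog
identities (~85-90%) the mapping is insensitive to the gap penalties
(tested by doubling/halving). Minus-strand regions are aligned as reverse
complements and re-indexed. Inter-genic positions are unmapped by design.

A catalog entry hits a sample variant when the variant sits at the mouse
image of the catalog position, exceeds the frequency threshold, and (by
default) carries the same alternative allele; sites where the mouse
reference base already differs from the human reference are excluded by
default because a "homologous mutation" is ill-defined there. A
position-only mode exists because allele-matching rules are not
standardized for cross-species homology claims. An amino-acid-level
alignment back-projected to codons is provided as a cross-check; the
nucleotide alignment is authoritative.

The classic anchor case: human m.8993 (ATP6, the T8993G/C NARP/Leigh
site) maps to mouse m.8393, which falls out of the per-gene alignment
because both ATP6 orthologs are 681 bp and colinear with the gene starts
at human 8527 / mouse 7927.

## Group comparison

Genotype groups are compared with the Tukey-Kramer procedure: one-way
ANOVA pooled error mean square MSE with df = N - k, pairwise
q = |m_i - m_j| / sqrt((MSE/2)(1/n_i + 1/n_j)), p-values from the
studentized-range distribution (scipy's implementation; numerically
verified in the tests against direct quadrature of the double-integral
representation to 1e-6, and against the exact q = sqrt(2)|t| identity at
k = 2 to 1e-9). Stars: * for p < 0.05, ** for p < 0.01. SD is the
sample standard deviation (n-1), the universal convention for
"mean +/- SD" at n = 4. No multiplicity correction is applied beyond
Tukey-Kramer within a panel; organs and metrics are tested per panel.
When all groups are internally constant, an identical-means contrast is
defined as p = 1 (null contrast) and a different-means contrast as p = 0.

## Clonal-expansion arithmetic

A variant confined to a fraction c of cells at within-cell heteroplasmy h
reads out in bulk sequencing at 100*c*h percent — e.g. 38% respiratory-
deficient (COX-/SDH+) cells carrying a variant at 50% heteroplasmy yield
an expected bulk frequency of 19%. `detectable_heteroplasmy` inverts the
identity and flags configurations where the implied within-cell
heteroplasmy exceeds 1 as infeasible.

## The simulator

Three layers, all driven by named substreams of one root seed (cohorts
are reproducible independent of sample order):

1. **Maternal germline.** The mouse strain is maintained through
   heterozygous mothers; each of `generation_count` transmissions draws
   Poisson(mu) new point mutations entering at heteroplasmy 1/N_b, applies
   within-site purifying selection against non-synonymous variants
   (h -> h(1-s)/(1-s*h)), and resamples every variant through an effective
   single-bottleneck of N_b segregating genome copies
   (h -> Binomial(N_b, h)/N_b). Variants hitting 0 are lost; variants
   hitting 1 become lineage reference replacements (reported at
   heteroplasmy 1, no longer drifting). `generation_count = 0` models a
   founder (G1-like) mouse with no inherited mutator variants. This is a
   deliberate reduction of intracellular mtDNA population dynamics to a
   single effective bottleneck: the analyses only need the qualitative
   founder-versus-late-generation frequency-spectrum contrast.
2. **Soma.** Every organ inherits the germline set at *identical*
   heteroplasmies (organ-shared maternal variants), then gains
   Poisson(mu_somatic) private variants with heteroplasmies from an
   exponential law truncated to (0,1). The one-parameter truncated
   exponential produces the many-low/few-high pattern of somatic
   heteroplasmy; no empirical somatic frequency law is established, so
   the simplest shape was chosen. A fraction `indel_fraction` of new
   mutations (germline and somatic) are 1-bp indels.
3. **Sequencing.** Depth ~ Poisson(depth_mean) per site; each base call
   is drawn from the site's true allele mixture and flipped with
   probability e to one of the other three bases uniformly, so with no
   true variants the expected total mutation frequency is exactly 100*e
   percent. Indel-supporting reads are binomial; deletion supporters are
   drawn outside the base-call depth per the count-table convention.

### Default parameters (the simulated study conditions)

| parameter | default | rationale |
|---|---|---|
| genome_length | 16299 bp | mouse mtDNA length |
| error_rate e | 0.0045 | wild-type error-floor total frequency ~0.45%, inside the 0.3-0.7% band of deep mtDNA sequencing of wild-type organs |
| depth_mean | 2000 | deep-coverage mtDNA enrichment sequencing |
| mu_germline (maternal +/mut) | 3 / transmission | modest germline input; over ~10 transmissions yields a handful of organ-shared inherited variants, some drifting above 10% heteroplasmy |
| bottleneck_size N_b | 32 | mouse germline effective-bottleneck estimates (tens of segregating units) |
| selection_s | 0.3 | moderate purifying selection against non-synonymous germline variants |
| mu_somatic | 3000 (+/+, +/mut) / 50000 (mut/mut) per organ | sized so the mut/mut total frequency lands at ~1.6-1.7x wild type; +/mut is deliberately wild-type-like (the empirical observation; the mechanism is open, so the rate is a parameter, not an assertion) |
| somatic_freq_mean | 0.001 | mean somatic heteroplasmy 0.1%: most somatic variants sit below the 1% quantification threshold, as in real mutator organs |
| indel_fraction | 1/60 | keeps measured indel frequencies far more than 40x below point-mutation frequencies |
| transition_bias | off | no spectrum is imposed by default; a crude 2:1 toggle exists |

Under these defaults (seed-dependent, heart, n = 4 per group) the
pipeline produces: wild-type total frequency ~0.47%, mut/mut ~0.75%
(ratio ~1.6), deletion/insertion frequencies of a few 0.001%, and a
strongly significant mut/mut vs +/+ Tukey-Kramer contrast — the numbers
printed by `scripts/acceptance.py`.

### What the simulator does not emulate

* **Real mouse/human sequences.** The bundled reference pair
  (`mitomut.synthref`) is random sequence in the real *layout*: real
  genome lengths, gene order, gene lengths and coordinates (ATP6 exactly
  at mouse 7927-8607 / human 8527-9207, including the ATP8/ATP6 overlap
  and a minus-strand ND6). The ortholog generator derives the human-like
  genome from the mouse-like one per gene (~10% divergence, one
  length-adjusting indel where species' gene lengths differ), so
  alignments behave like real orthologs — but no conclusion about real
  sequence content follows from passing tests.
* **The founder-vs-late-generation gap in *total* frequency.** In real
  mutator cohorts founder (G1) mut/mut organs show roughly half the total
  frequency of late-generation ones; in this model the germline
  contributes little total mass, so that gap is not reproduced. The
  generation contrast is expressed where the model does carry it: the
  count of >10%-heteroplasmy organ-shared variants.
* Mutational spectra, copy-number dynamics, large deletions, paternal
  leakage, NUMT contamination, read-level qualities, and alignment
  artifacts.

## Numerical choices and degenerate inputs

* Coordinates are 1-based inclusive everywhere internally ("m.8993"
  style); BED input (0-based half-open) is converted on read.
* All-zero-depth tables raise (`EmptyTableError`) rather than returning
  0/0; regions with zero sequenced bases report 0 within an otherwise
  valid table.
* Alignment traceback ties break diagonal > up > left, making maps
  byte-reproducible.
* Truncated-exponential heteroplasmies are drawn by rejection (the
  rejection mass at the defaults is ~e^-1000, so this is effectively a
  single draw).
* Seeds: one root integer; substreams are derived via
  `SeedSequence([seed, crc32(name), ...])` so cohort outputs do not
  depend on generation order.

## Known limitations

* Pileup generation (mapping/base-quality filtering) is upstream and out
  of scope; the count-table format deliberately abstracts it away, and no
  error-correction of the sequencing floor is attempted.
* Annotation records may not wrap past the origin; none of the packaged
  layouts span it (no mouse mtDNA gene does).
* The per-gene alignment is pairwise-global; rearranged or non-homologous
  region pairs would produce low-identity maps rather than a refusal —
  check `AlignedRegion.identity` before trusting a lift.
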