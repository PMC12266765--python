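import filecmp

import numpy as np
import pytest

from mitomut.io import read_counts, SampleMeta
from mitomut.mutfreq import total_mutation_frequency
from mitomut.simulate import (ConfigError, SimulationConfig, preset_config,
                              simulate_cohort, simulate_counts,
                              simulate_mouse, simulate_pedigree,
                              simulate_soma, substream)
from .conftest import random_genome


@pytest.fixture(scope="module")
def small_refs():
    """Small genome + single-gene annotation for fast generative tests."""
    from mitomut.io import GeneAnnotation, GeneRecord

    rng = np.random.default_rng(42)
    g = random_genome(rng, 600, name="small")
    ann = GeneAnnotation(records=[
        GeneRecord(gene_name="p1", region_class="protein", start=1, end=300),
        GeneRecord(gene_name="dl", region_class="dloop", start=451, end=600),
    ], genome_length=600)
    return g, ann


def config(**kw):
    defaults = dict(genome_length=600, depth_mean=200.0, error_rate=0.0,
                    organs=("heart", "kidney"), seed=0)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(selection_s=1.5),
        dict(error_rate=0.05),
        dict(somatic_freq_mean=0.0),
        dict(generation_count=-1),
        dict(bottleneck_size=0),
        dict(mu_somatic={"+/+": -1, "+/mut": 0, "mut/mut": 0}),
    ])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ConfigError):
            config(**kw)


class TestPedigree:
    def test_g1_founder_has_no_inherited_variants(self, small_refs):
        g, ann = small_refs
        assert simulate_pedigree(config(generation_count=0), g, ann) == []

    def test_zero_mutation_rate_gives_empty_set(self, small_refs):
        g, ann = small_refs
        cfg = config(generation_count=10,
                     mu_germline={"+/+": 0, "+/mut": 0, "mut/mut": 0})
        assert simulate_pedigree(cfg, g, ann) == []

    def test_drift_matches_independent_wright_fisher_oracle(self, small_refs):
        """Fraction of surviving germline variants above 10% heteroplasmy
        agrees with a bare-bones re-simulation of the same
        mutation/bottleneck process (no selection), over 200 replicates."""
        g, ann = small_refs
        nb, mu, gens, reps = 20, 30.0, 10, 200

        high = total = 0
        for r in range(reps):
            cfg = config(generation_count=gens, bottleneck_size=nb,
                         selection_s=0.0, maternal_genotype="mut/mut",
                         mu_germline={"+/+": 0, "+/mut": 0, "mut/mut": mu},
                         seed=r)
            for v in simulate_pedigree(cfg, g, ann):
                total += 1
                high += v.heteroplasmy > 0.10

        # independent oracle: frequencies only, binomial drift per generation
        rng = np.random.default_rng(987654)
        o_high = o_total = 0
        for _ in range(reps):
            hs: list[float] = []
            fixed: list[float] = []
            for _ in range(gens):
                hs.extend([1.0 / nb] * rng.poisson(mu))
                ks = rng.binomial(nb, hs) if hs else []
                hs = []
                for k in np.atleast_1d(ks):
                    if k == nb:
                        fixed.append(1.0)
                    elif k > 0:
                        hs.append(k / nb)
            survivors = hs + fixed
            o_total += len(survivors)
            o_high += sum(h > 0.10 for h in survivors)

        frac = high / total
        o_frac = o_high / o_total
        # Monte-Carlo tolerance: 3 x combined binomial SE
        se = np.sqrt(frac * (1 - frac) / total + o_frac * (1 - o_frac) / o_total)
        assert abs(frac - o_frac) <= 3 * se + 1e-9

    def test_selection_reduces_nonsynonymous_burden(self, small_refs):
        """Average surviving non-synonymous germline count is non-increasing
        in the selection coefficient (common random seeds)."""
        g, ann = small_refs
        means = []
        for s in (0.0, 0.5, 0.9):
            counts = []
            for seed in range(60):
                cfg = config(generation_count=8, selection_s=s,
                             mu_germline={"+/+": 10, "+/mut": 10, "mut/mut": 10},
                             bottleneck_size=20, seed=seed)
                germ = simulate_pedigree(cfg, g, ann)
                counts.append(
                    sum(v.effect_truth == "nonsynonymous" for v in germ))
            means.append(np.mean(counts))
        assert means[0] >= means[1] >= means[2]
        assert means[0] > means[2]  # selection must actually bite

    def test_generation_effect_on_high_heteroplasmy(self, small_refs):
        """Expected count of >10% variants grows with pedigree depth."""
        g, ann = small_refs
        means = []
        for gens in (0, 5, 15):
            counts = []
            for seed in range(60):
                cfg = config(generation_count=gens, bottleneck_size=20,
                             mu_germline={"+/+": 5, "+/mut": 5, "mut/mut": 5},
                             seed=seed)
                germ = simulate_pedigree(cfg, g, ann)
                counts.append(sum(v.heteroplasmy > 0.10 for v in germ))
            means.append(np.mean(counts))
        assert means[0] <= means[1] <= means[2]
        assert means[2] > 0


class TestSoma:
    def test_no_somatic_source_copies_germline(self, small_refs):
        g, ann = small_refs
        cfg = config(generation_count=5, mu_somatic={"+/+": 0, "+/mut": 0,
                                                     "mut/mut": 0})
        germ = simulate_pedigree(cfg, g, ann)
        organs = simulate_soma(germ, cfg, g, ann)
        for organ in cfg.organs:
            assert organs[organ] == germ

    def test_germline_shared_at_identical_heteroplasmy(self, small_refs):
        g, ann = small_refs
        cfg = config(generation_count=8, mu_somatic={"+/+": 5, "+/mut": 5,
                                                     "mut/mut": 5})
        germ = simulate_pedigree(cfg, g, ann)
        organs = simulate_soma(germ, cfg, g, ann)
        germ_set = {(v.pos, v.alt, v.heteroplasmy) for v in germ}
        for organ in cfg.organs:
            shared = {(v.pos, v.alt, v.heteroplasmy)
                      for v in organs[organ] if v.origin == "germline"}
            assert shared == germ_set

    def test_somatic_count_matches_poisson_mean(self, small_refs):
        g, ann = small_refs
        mu = 50.0
        counts = []
        for seed in range(100):
            cfg = config(polg_genotype="mut/mut", seed=seed,
                         mu_somatic={"+/+": 5, "+/mut": 5, "mut/mut": mu},
                         organs=("heart",))
            organs = simulate_soma([], cfg, g, ann)
            counts.append(sum(v.origin == "somatic" for v in organs["heart"]))
        se = np.sqrt(mu / len(counts))  # Poisson SE of the mean
        assert abs(np.mean(counts) - mu) <= 3 * se


class TestCounts:
    def test_noiseless_reference_has_no_alt_calls(self, small_refs, meta):
        g, ann = small_refs
        t = simulate_counts([], config(error_rate=0.0), g, meta=meta)
        assert total_mutation_frequency(t, g) == 0.0
        assert t.table[["ins", "del"]].to_numpy().sum() == 0

    def test_error_floor_recovered(self, small_refs, meta):
        """With no true variants the downstream statistic estimates 100*e."""
        g, ann = small_refs
        e = 0.003
        cfg = config(error_rate=e, depth_mean=2000.0)
        t = simulate_counts([], cfg, g, meta=meta)
        freq = total_mutation_frequency(t, g)
        n = t.table["depth"].sum()
        se_pct = 100 * np.sqrt(e * (1 - e) / n)
        assert abs(freq - 100 * e) <= 3 * se_pct

    def test_heterozygous_site_frequency(self, small_refs, meta):
        from mitomut.simulate import GroundTruthVariant

        g, ann = small_refs
        ref = g.base(100)
        alt = [b for b in "ACGT" if b != ref][0]
        v = GroundTruthVariant(pos=100, ref=ref, alt=alt, origin="somatic",
                               organ="heart", heteroplasmy=0.5,
                               effect_truth="noncoding")
        cfg = config(depth_mean=10000.0, error_rate=0.0)
        t = simulate_counts([v], cfg, g, meta=meta)
        row = t.table.iloc[99]
        freq = row[alt] / row["depth"]
        se = np.sqrt(0.25 / row["depth"])
        assert abs(freq - 0.5) <= 3 * se


class TestCohort:
    GRID = [
        {"mouse_id": "wt_1", "polg_genotype": "+/+", "generation": "G10plus"},
        {"mouse_id": "hom_1", "polg_genotype": "mut/mut", "generation": "G10plus"},
    ]

    def test_deterministic_and_file_count(self, small_refs, tmp_path):
        g, ann = small_refs
        base = config(seed=5)
        out1, out2 = tmp_path / "a", tmp_path / "b"
        simulate_cohort(self.GRID, g, ann, out1, base_config=base)
        simulate_cohort(list(reversed(self.GRID)), g, ann, out2,
                        base_config=base)
        names1 = sorted(p.name for p in out1.iterdir())
        # 2 mice x 2 organs counts + 2 truth files
        assert len(names1) == 6
        assert names1 == sorted(p.name for p in out2.iterdir())
        for name in names1:
            assert filecmp.cmp(out1 / name, out2 / name, shallow=False), name

    def test_count_tables_read_back(self, small_refs, tmp_path):
        g, ann = small_refs
        simulate_cohort(self.GRID, g, ann, tmp_path, base_config=config())
        meta = SampleMeta(mouse_id="wt_1", organ="heart",
                          polg_genotype="+/+", generation="G10plus")
        t = read_counts(tmp_path / "counts_wt_1_heart.tsv", g, meta)
        assert t.length == g.length


def test_substreams_are_order_independent():
    a = substream(3, "m1", "soma", "heart").integers(0, 1 << 30, 5)
    b = substream(3, "m1", "soma", "heart").integers(0, 1 << 30, 5)
    c = substream(3, "m1", "soma", "kidney").integers(0, 1 << 30, 5)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_presets_and_mutator_burden_contrast():
    """mut/mut presets give strictly higher mean total frequency than +/+
    under the default study conditions (paired seeds, full genome)."""
    from mitomut.synthref import mouse_like_annotation, mouse_like_genome

    g = mouse_like_genome(0)
    ann = mouse_like_annotation()
    wins = 0
    n_runs = 5
    for seed in range(n_runs):
        freqs = {}
        for gt in ("+/+", "mut/mut"):
            cfg = preset_config(gt, "G10plus", seed=seed, organs=("heart",))
            _, tables = simulate_mouse(cfg, g, ann, mouse_id=f"{gt}_{seed}")
            freqs[gt] = total_mutation_frequency(tables["heart"], g)
        wins += freqs["mut/mut"] > freqs["+/+"]
    assert wins == n_runs
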