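import json

import numpy as np
import pytest

from hgfscan.diversity import nucleotide_diversity
from hgfscan.genotypes import MISSING, GenomicWindow, write_vcf
from hgfscan.simulate import (
    BOTTLENECK_FOLD,
    CM_PER_MB_TO_PER_BP,
    DemographyConfig,
    SimulationError,
    TruthRecord,
    default_hgf_demography,
    inject_sweep,
    simulate_genotypes,
    simulate_tracks,
)


class TestDefaultDemography:
    def test_template_pulse_fractions(self):
        cfg = default_hgf_demography()
        assert {m for *_ , m in cfg.pulses} == {0.093, 0.054}

    def test_template_split_times(self):
        cfg = default_hgf_demography()
        times = {t for _, _, t in cfg.splits}
        assert {5452.0, 1261.0} <= times

    def test_bottleneck_ratio(self):
        cfg = default_hgf_demography(wild_ne=24_000)
        wild = cfg.populations["wild_nigeria"]["ne"]
        dom = cfg.populations["dom_nigeria"]["ne"]
        assert dom / wild == pytest.approx(1 / BOTTLENECK_FOLD)

    def test_recombination_conversion(self):
        cfg = default_hgf_demography()
        assert cfg.recombination_rate == pytest.approx(1.7e-8)
        assert CM_PER_MB_TO_PER_BP == 1e-8

    def test_generation_time_scales_mutation(self):
        cfg = default_hgf_demography()
        cfg.generation_time_years = 2.0
        assert cfg.mutation_rate_per_generation == pytest.approx(2 * 1.91e-9)

    def test_validation_rejects_bad_pulse(self):
        with pytest.raises(SimulationError):
            DemographyConfig(
                populations={"a": {"role": "wild", "ne": 100.0}},
                splits=[],
                pulses=[("a", "a", 10.0, 1.5)],
            )

    def test_validation_rejects_event_after_merge(self):
        with pytest.raises(SimulationError, match="merged"):
            DemographyConfig(
                populations={
                    "a": {"role": "wild", "ne": 100.0},
                    "b": {"role": "wild", "ne": 100.0},
                },
                splits=[("a", "b", 100.0)],
                pulses=[("a", "b", 500.0, 0.1)],
            )

    def test_short_contig_rejected(self):
        with pytest.raises(SimulationError, match="10 kb"):
            default_hgf_demography(contig_length=5000)


def _two_pop_config(split_ybp, seed=1, ne=5000.0, length=500_000, mu=5e-8):
    return DemographyConfig(
        populations={
            "a": {"role": "wild", "ne": ne},
            "b": {"role": "wild", "ne": ne},
        },
        splits=[("a", "b", split_ybp)],
        mutation_rate=mu,
        contig_length=length,
        samples_per_pop={"a": 8, "b": 8},
        seed=seed,
    )


class TestSimulateGenotypes:
    def test_determinism_byte_identical_vcf(self, tmp_path):
        cfg = _two_pop_config(1000.0, seed=9)
        paths = []
        for tag in ("x", "y"):
            gm, pm, truth = simulate_genotypes(cfg)
            p = tmp_path / f"{tag}.vcf"
            write_vcf(gm, p, {"contig1": cfg.contig_length})
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_deep_split_high_fst(self):
        from hgfscan.fstats import build_freq_table
        from hgfscan.sweepscan import hudson_fst

        cfg = _two_pop_config(40_000.0, seed=5)  # 4 x 2Ne generations
        gm, pm, _ = simulate_genotypes(cfg)
        ft = build_freq_table(gm, pm)
        w = GenomicWindow("contig1", 0, cfg.contig_length)
        rec = hudson_fst(ft, "a", "b", windows=[w])[0]
        assert rec.value > 0.2

    def test_panmictic_relabeling_d_near_zero(self):
        from hgfscan.fstats import build_freq_table, d_stat
        from hgfscan.genotypes import PopulationMap

        cfg = DemographyConfig(
            populations={"a": {"role": "wild", "ne": 10_000.0}},
            splits=[],
            mutation_rate=5e-8,
            contig_length=1_000_000,
            samples_per_pop={"a": 16},
            seed=3,
        )
        gm, pm, _ = simulate_genotypes(cfg)
        labels = ["p1", "p2", "p3", "p4"]
        assignments = {
            s: labels[i // 4] for i, s in enumerate(gm.sample_ids)
        }
        pm2 = PopulationMap(assignments=assignments, roles={})
        ft = build_freq_table(gm, pm2)
        res = d_stat(ft, "p1", "p2", "p3", "p4", block_size=200)
        assert abs(res.z) < 3

    def test_truth_round_trip(self):
        cfg = _two_pop_config(1000.0)
        _, _, truth = simulate_genotypes(cfg)
        again = TruthRecord.from_json(truth.to_json())
        assert again == truth

    def test_ref_is_ancestral_and_positions_valid(self):
        cfg = _two_pop_config(1000.0, seed=2)
        gm, _, _ = simulate_genotypes(cfg)
        assert gm.n_variants > 0
        assert gm.pos.min() >= 1 and gm.pos.max() <= cfg.contig_length
        assert (np.diff(gm.pos) > 0).all()


@pytest.fixture(scope="module")
def base():
    cfg = _two_pop_config(5000.0, seed=7, length=600_000)
    gm, pm, truth = simulate_genotypes(cfg)
    return cfg, gm, pm, truth


class TestInjectSweep:

    def test_full_intensity_wipes_diversity(self, base):
        cfg, gm, pm, truth = base
        center = cfg.contig_length // 2
        radius = 50_000
        swept, t2 = inject_sweep(
            gm, pm, "contig1", center, ["a"], 1.0, radius=radius, truth=truth
        )
        rows = swept.sample_indices(pm.samples_of("a"))
        core = np.abs(swept.pos - center) <= radius
        g = swept.gt[np.ix_(rows, np.flatnonzero(core))]
        assert set(np.unique(g)) <= {0, 2}
        assert all(len(set(g[:, j])) == 1 for j in range(g.shape[1]))
        w = GenomicWindow("contig1", center - radius, center + radius)
        pi = nucleotide_diversity(swept, pm.samples_of("a"), [w])[0].pi
        assert pi == 0.0
        assert len(t2.sweeps) == 1
        assert t2.sweeps[0]["position"] == center

    def test_zero_intensity_unchanged(self, base):
        _, gm, pm, truth = base
        swept, t2 = inject_sweep(gm, pm, "contig1", 100_000, ["a"], 0.0, truth=truth)
        np.testing.assert_array_equal(swept.gt, gm.gt)
        assert len(t2.sweeps) == 1  # still recorded in the truth

    def test_other_population_untouched(self, base):
        cfg, gm, pm, _ = base
        swept, _ = inject_sweep(gm, pm, "contig1", cfg.contig_length // 2, ["a"], 0.9)
        rows_b = gm.sample_indices(pm.samples_of("b"))
        np.testing.assert_array_equal(swept.gt[rows_b, :], gm.gt[rows_b, :])

    def test_position_outside_contig_errors(self, base):
        cfg, gm, pm, _ = base
        with pytest.raises(SimulationError, match="outside"):
            inject_sweep(gm, pm, "contig1", cfg.contig_length * 10, ["a"], 0.5)


@pytest.fixture(scope="module")
def sim():
    cfg = _two_pop_config(1000.0, seed=13, length=1_000_000)
    gm, pm, _ = simulate_genotypes(cfg)
    return cfg, gm


class TestSimulateTracks:

    def test_exon_fraction(self, sim):
        cfg, gm = sim
        exons, genes, gerp = simulate_tracks(
            gm, cfg.contig_length, exon_fraction=0.1, seed=3
        )
        total = sum(e - s for _, s, e in exons)
        assert abs(total - 0.1 * cfg.contig_length) <= 0.01 * cfg.contig_length
        # non-overlapping and sorted
        for (_, s1, e1), (_, s2, e2) in zip(exons, exons[1:]):
            assert e1 <= s2

    def test_gene_count_and_coordinates(self, sim):
        cfg, gm = sim
        _, genes, _ = simulate_tracks(gm, cfg.contig_length, gene_count=20, seed=3)
        assert len(genes) == 20
        for ctg, start, end, gid in genes:
            assert 1 <= start < end <= cfg.contig_length

    def test_exonic_gerp_fraction_binomial(self, sim):
        from scipy.stats import binom

        cfg, gm = sim
        p = 0.3
        exons, _, gerp = simulate_tracks(
            gm, cfg.contig_length, exon_fraction=0.3, p_high_gerp=p, seed=5
        )
        starts = np.array([s for _, s, _ in exons])
        ends = np.array([e for _, _, e in exons])
        high = 0
        n_exonic = 0
        for ctg, pos, score in gerp:
            k = np.searchsorted(starts, pos - 1, side="right") - 1
            if k >= 0 and pos - 1 < ends[k]:
                n_exonic += 1
                high += score > 2
        assert n_exonic > 50
        lo, hi = binom.ppf([0.005, 0.995], n_exonic, p)
        assert lo <= high <= hi

    def test_determinism(self, sim):
        cfg, gm = sim
        a = simulate_tracks(gm, cfg.contig_length, seed=11)
        b = simulate_tracks(gm, cfg.contig_length, seed=11)
        assert a == b


class TestPolarizationAccuracy:
    def test_outgroup_consensus_accuracy_on_polymorphic_sites(self):
        from hgfscan.polarize import ANC_REF, assign_ancestral

        cfg = default_hgf_demography(
            wild_ne=10_000,
            outgroup_split_ybp=250_000,
            wild_split_ybp=20_000,
            contig_length=1_000_000,
            seed=77,
        )
        gm, pm, _ = simulate_genotypes(cfg)
        out_samples = pm.samples_of("outgroup")
        anc = assign_ancestral(gm, out_samples)
        hgf_rows = gm.sample_indices(
            [s for s in gm.sample_ids if s not in out_samples]
        )
        alt, an = gm.allele_counts(hgf_rows)
        poly = (alt > 0) & (alt < an)
        sel = poly & anc.assigned
        assert sel.sum() > 200
        # simulated REF is the true ancestral allele everywhere
        accuracy = (anc.state[sel] == ANC_REF).mean()
        assert accuracy > 0.99


class TestNeutralExpectations:
    def test_constant_size_pi_matches_closed_form(self):
        # one constant-size population: E[pi] = 4 * Ne * mu_per_generation
        ne, mu = 5_000.0, 5e-8
        cfg = DemographyConfig(
            populations={"a": {"role": "wild", "ne": ne}},
            splits=[],
            mutation_rate=mu,
            contig_length=1_000_000,
            samples_per_pop={"a": 10},
            seed=41,
        )
        gm, pm, _ = simulate_genotypes(cfg)
        w = [GenomicWindow("contig1", 0, cfg.contig_length)]
        pi = nucleotide_diversity(gm, gm.sample_ids, w)[0].pi
        expected = 4 * ne * mu
        assert abs(pi - expected) / expected < 0.25

    def test_ld_decay_monotone_on_neutral_sim(self):
        from hgfscan.diversity import ld_decay
        from hgfscan.genotypes import filter_maf

        cfg = DemographyConfig(
            populations={"a": {"role": "wild", "ne": 10_000.0}},
            splits=[],
            mutation_rate=2e-8,
            contig_length=2_000_000,
            samples_per_pop={"a": 12},
            seed=43,
        )
        gm, _, _ = simulate_genotypes(cfg)
        gm = filter_maf(gm, 0.05)
        bins = ld_decay(gm, gm.sample_ids, max_dist=100_000, n_bins=5,
                        max_pairs=100_000, seed=1)
        vals = [b.r2_corrected for b in bins]
        assert len(vals) == 5
        # non-increasing within Monte-Carlo tolerance; last bin exempt
        for a, b in zip(vals[:-2], vals[1:-1]):
            assert b <= a + 0.01
        assert vals[-1] < vals[0]
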