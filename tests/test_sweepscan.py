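import math

import numpy as np
import pytest

from hgfscan.diversity import nucleotide_diversity
from hgfscan.fstats import FreqTable, build_freq_table
from hgfscan.genotypes import GenomicWindow, GenotypeError, PopulationMap, make_windows
from hgfscan.sweepscan import (
    ScanRecord,
    annotate_genes,
    apply_threshold,
    empirical_threshold,
    hudson_fst,
    ld_block_profile,
    overlap_calls,
    pbs,
    pca_outlier_scan,
    pi_ratio,
    read_gff3_genes,
)

from conftest import matrix_from_genotypes, random_matrix


def table(freqs, sizes=20):
    m = len(next(iter(freqs.values())))
    return FreqTable(
        contig=np.full(m, "chr1", dtype=object),
        pos=np.arange(1, m + 1, dtype=np.int64) * 100,
        freqs={k: np.asarray(v, dtype=float) for k, v in freqs.items()},
        sizes={k: np.full(m, sizes) for k in freqs},
    )


class TestHudsonFst:
    def test_fixed_difference(self):
        ft = table({"a": [1.0], "b": [0.0]})
        recs = hudson_fst(ft, "a", "b")
        assert recs[0].value == pytest.approx(1.0, abs=1e-9)

    def test_equal_freqs_hand_value(self):
        # p=0.5 both, 2n=10 each: N = -2*(0.25/9), D = 0.5 -> FST = -1/9
        ft = table({"a": [0.5], "b": [0.5]}, sizes=10)
        recs = hudson_fst(ft, "a", "b")
        assert recs[0].value == pytest.approx(-0.111111111, abs=1e-9)

    def test_same_fixed_allele_skipped(self):
        ft = table({"a": [1.0, 0.5], "b": [1.0, 0.4]})
        recs = hudson_fst(ft, "a", "b")
        assert len(recs) == 1 and recs[0].start == 200

    def test_windowed_is_ratio_of_sums(self):
        rng = np.random.default_rng(2)
        pa = rng.uniform(0.1, 0.9, size=10)
        pb = rng.uniform(0.1, 0.9, size=10)
        ft = table({"a": pa, "b": pb})
        w = GenomicWindow("chr1", 0, 2000)
        rec = hudson_fst(ft, "a", "b", windows=[w])[0]
        n = (pa - pb) ** 2 - pa * (1 - pa) / 19 - pb * (1 - pb) / 19
        d = pa * (1 - pb) + pb * (1 - pa)
        assert rec.value == pytest.approx(n.sum() / d.sum(), abs=1e-12)


class TestPbs:
    def test_equal_branch_identity(self):
        # all pairwise FST = 1 - exp(-t) -> PBS = t/2
        t = 0.4
        fst = 1 - math.exp(-t)
        p_t, p_c, p_b = 0.9, 0.1, 0.5  # engineered via direct formula below
        # bypass frequency computation: verify identity on branch lengths
        from hgfscan.sweepscan import _branch_length

        T = _branch_length(np.array([fst, fst, fst]))
        assert (T[0] + T[1] - T[2]) / 2 == pytest.approx(t / 2, abs=1e-12)

    def test_hand_value(self):
        from hgfscan.sweepscan import _branch_length

        T = _branch_length(np.array([0.3, 0.3, 0.1]))
        pbs_val = (T[0] + T[1] - T[2]) / 2
        assert pbs_val == pytest.approx(0.30399, abs=1e-5)
        assert pbs_val == pytest.approx(
            (-math.log(0.7) - math.log(0.7) + math.log(0.9)) / 2, abs=1e-12
        )

    def test_control_background_swap_symmetry(self):
        rng = np.random.default_rng(4)
        ft = table(
            {
                "t": rng.uniform(0.1, 0.9, 30),
                "c": rng.uniform(0.1, 0.9, 30),
                "b": rng.uniform(0.1, 0.9, 30),
            }
        )
        r1 = pbs(ft, "t", "c", "b")
        r2 = pbs(ft, "t", "b", "c")
        np.testing.assert_allclose(
            [r.value for r in r1], [r.value for r in r2], atol=1e-12
        )

    def test_pbs_pair_sum_identity(self):
        # PBS_t + PBS_c == T_tc (clamping off the degenerate cases)
        rng = np.random.default_rng(8)
        ft = table(
            {
                "t": rng.uniform(0.2, 0.8, 30),
                "c": rng.uniform(0.2, 0.8, 30),
                "b": rng.uniform(0.2, 0.8, 30),
            },
            sizes=200,
        )
        from hgfscan.sweepscan import _branch_length, _hudson_components

        pt = {r.start: r.value for r in pbs(ft, "t", "c", "b")}
        pc = {r.start: r.value for r in pbs(ft, "c", "t", "b")}
        num, den = _hudson_components(ft, "t", "c")
        with np.errstate(invalid="ignore"):
            fst_tc = num / den
        for j, pos in enumerate(ft.pos):
            if pos in pt and pos in pc and 0 <= fst_tc[j] < 1:
                t_tc = float(_branch_length(np.array([fst_tc[j]]))[0])
                assert pt[pos] + pc[pos] == pytest.approx(t_tc, abs=1e-9)

    def test_window_mode_single_snp_matches_snp_mode(self):
        ft = table({"t": [0.9], "c": [0.2], "b": [0.3]})
        snp = pbs(ft, "t", "c", "b")[0].value
        w = GenomicWindow("chr1", 0, 200)
        win = pbs(ft, "t", "c", "b", windows=[w])[0].value
        assert snp == pytest.approx(win, abs=1e-12)


class TestPiRatio:
    def _recs(self, pis, pop):
        from hgfscan.diversity import DiversityRecord

        return [
            DiversityRecord(pop, GenomicWindow("chr1", i * 10, (i + 1) * 10), p, 1)
            for i, p in enumerate(pis)
        ]

    def test_basic_ratios(self):
        out = pi_ratio(self._recs([0.004, 0.002], "b"), self._recs([0.001, 0.002], "t"))
        assert out[0].value == pytest.approx(4.0)
        assert out[1].value == pytest.approx(1.0)

    def test_infinite_sentinel_and_exclusion(self):
        out = pi_ratio(self._recs([0.004, 0.0], "b"), self._recs([0.0, 0.0], "t"))
        assert len(out) == 1 and math.isinf(out[0].value)

    def test_mismatched_tiling_errors(self):
        a = self._recs([0.1], "b")
        b = [
            __import__("hgfscan.diversity", fromlist=["DiversityRecord"]).DiversityRecord(
                "t", GenomicWindow("chr1", 5, 15), 0.1, 1
            )
        ]
        with pytest.raises(GenotypeError, match="tiling"):
            pi_ratio(a, b)


class TestPcaScan:
    def test_k_zero_errors(self):
        gm = random_matrix(10, 50, seed=1)
        with pytest.raises(GenotypeError):
            pca_outlier_scan(gm, 0)

    def test_planted_outlier_found_on_pc1(self):
        rng = np.random.default_rng(6)
        n, m = 30, 200
        p = rng.uniform(0.2, 0.8, size=m)
        gt = rng.binomial(2, np.broadcast_to(p, (n, m))).astype(np.int8)
        # plant one fixed-difference SNP between the two halves
        gt[: n // 2, 0] = 0
        gt[n // 2 :, 0] = 2
        # a few mildly differentiated SNPs so PC1 is the group axis
        for j in range(1, 6):
            gt[: n // 2, j] = rng.binomial(2, 0.2, size=n // 2)
            gt[n // 2 :, j] = rng.binomial(2, 0.8, size=n - n // 2)
        gm = matrix_from_genotypes(gt, pos=np.arange(1, m + 1) * 100)
        recs, pc = pca_outlier_scan(gm, k=1, maf_min=0.0)
        values = {r.start: r.value for r in recs}
        top = max(values, key=values.get)
        assert top == 100  # the planted SNP's position
        top_rec = [r for r in recs if r.start == top][0]
        assert top_rec.pc == 1

    def test_median_matches_chi2_after_rescaling(self):
        from scipy.stats import chi2

        gm = random_matrix(24, 400, seed=10)
        recs, _ = pca_outlier_scan(gm, k=2, maf_min=0.0)
        med = np.median([r.value for r in recs])
        assert med == pytest.approx(chi2.ppf(0.5, 2), rel=1e-6)


class TestEmpiricalThreshold:
    def test_known_sequence(self):
        scores = np.arange(1, 100_001, dtype=float)
        thr = empirical_threshold(scores, 100_000, 0.001, seed=0)
        assert thr.cutoff == 99_900
        assert int((scores > thr.cutoff).sum()) == 100

    def test_constant_scores_no_outliers(self):
        scores = np.full(1000, 5.0)
        thr = empirical_threshold(scores, 100, 0.01, seed=1)
        recs = [
            ScanRecord("c", i, i, "X", 5.0) for i in range(1000)
        ]
        flagged = apply_threshold(recs, thr)
        assert not any(r.outlier for r in flagged)

    def test_subsample_close_to_full(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=200_000)
        full = empirical_threshold(scores, len(scores), 0.01, seed=0)
        rel = []
        for seed in range(10):
            sub = empirical_threshold(scores, 20_000, 0.01, seed=seed)
            rel.append(abs(sub.cutoff - full.cutoff) / abs(full.cutoff))
        assert np.median(rel) < 0.05

    def test_determinism(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=5000)
        t1 = empirical_threshold(scores, 1000, 0.01, seed=9)
        t2 = empirical_threshold(scores, 1000, 0.01, seed=9)
        assert t1 == t2


class TestOverlap:
    def _site(self, pos, out=True):
        return ScanRecord("c", pos, pos, "X", 1.0, outlier=out)

    def _win(self, start, end, out=True):
        return ScanRecord("c", start, end, "Y", 1.0, outlier=out)

    def test_disjoint_empty(self):
        assert overlap_calls([self._site(1)], [self._site(2)]) == []

    def test_identical_sets(self):
        a = [self._site(5), self._site(9)]
        assert overlap_calls(a, a) == [("c", 5, 5), ("c", 9, 9)]

    def test_site_in_window(self):
        hits = overlap_calls([self._site(15)], [self._win(10, 20)])
        assert hits == [("c", 15, 15)]
        assert overlap_calls([self._site(5)], [self._win(10, 20)]) == []

    def test_non_outliers_ignored(self):
        assert overlap_calls([self._site(1, out=False)], [self._site(1)]) == []


class TestAnnotateGenes:
    def test_snp_in_gene(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c\tx\tgene\t100\t200\t.\t+\t.\tID=g1\n"
            "c\tx\tgene\t201\t300\t.\t+\t.\tID=g2\n"
        )
        genes = read_gff3_genes(gff)
        out = annotate_genes([("c", 150, 150)], genes)
        assert list(out) == ["g1"] and len(out["g1"]) == 1

    def test_window_spanning_two_genes(self, tmp_path):
        genes = [("c", 100, 200, "g1"), ("c", 201, 300, "g2")]
        out = annotate_genes([("c", 150, 250)], genes)
        assert set(out) == {"g1", "g2"}

    def test_malformed_gff_errors(self, tmp_path):
        gff = tmp_path / "bad.gff3"
        gff.write_text("c\tx\tgene\t100\n")
        with pytest.raises(GenotypeError, match="bad.gff3:1"):
            read_gff3_genes(gff)

    def test_bruteforce_interval_scan(self, tmp_path):
        rng = np.random.default_rng(11)
        genes = []
        for i in range(30):
            s = int(rng.integers(1, 10_000))
            genes.append(("c", s, s + int(rng.integers(50, 500)), f"g{i}"))
        loci = [("c", int(p), int(p)) for p in rng.integers(1, 11_000, size=200)]
        out = annotate_genes(loci, genes)
        for ctg, s, e, gid in genes:
            expected = [l for l in loci if s <= l[1] <= e]
            got = out.get(gid, [])
            assert sorted(got) == sorted(expected)


class TestLdBlockProfile:
    def test_duplicated_columns_all_one(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, size=12)
        while len(set(base)) < 2:
            base = rng.integers(0, 3, size=12)
        gt = np.column_stack([base] * 4)
        gm = matrix_from_genotypes(gt, pos=[10, 20, 30, 40])
        pos, mat, extent = ld_block_profile(gm, gm.sample_ids, "chr1", 0, 100)
        assert np.allclose(np.diag(mat), 1.0)
        assert np.allclose(mat, 1.0, atol=1e-9)
        assert extent == (10, 40, 4)

    def test_snp_cap(self):
        gm = random_matrix(6, 50, seed=2)
        with pytest.raises(GenotypeError, match="cap"):
            ld_block_profile(gm, gm.sample_ids, "chr1", 0, int(gm.pos.max()) + 1, max_snps=10)
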