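import numpy as np
import pytest

from hgfscan.genotypes import MISSING, GenotypeMatrix, PopulationMap


def random_matrix(
    n_samples: int,
    n_variants: int,
    seed: int = 0,
    missing_rate: float = 0.0,
    contig: str = "chr1",
) -> GenotypeMatrix:
    """Random biallelic genotype matrix with optional missingness."""
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, n_variants * 100), size=n_variants, replace=False))
    p = rng.uniform(0.05, 0.95, size=n_variants)
    gt = rng.binomial(1, p, size=(n_samples, n_variants)) + rng.binomial(
        1, p, size=(n_samples, n_variants)
    )
    if missing_rate > 0:
        mask = rng.random((n_samples, n_variants)) < missing_rate
        gt = np.where(mask, MISSING, gt)
    refs = rng.choice(list("ACGT"), size=n_variants)
    alts = np.array([{"A": "G", "C": "T", "G": "A", "T": "C"}[r] for r in refs])
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n_samples)],
        contig=np.full(n_variants, contig, dtype=object),
        pos=pos.astype(np.int64),
        ref=refs.astype(object),
        alt=alts.astype(object),
        gt=gt.astype(np.int8),
    )


def matrix_from_genotypes(gt, pos=None, contig="chr1"):
    """Build a matrix from an explicit (samples x variants) genotype array."""
    gt = np.asarray(gt, dtype=np.int8)
    n_samples, n_variants = gt.shape
    if pos is None:
        pos = np.arange(1, n_variants + 1) * 10
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n_samples)],
        contig=np.full(n_variants, contig, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.full(n_variants, "A", dtype=object),
        alt=np.full(n_variants, "G", dtype=object),
        gt=gt,
    )


@pytest.fixture
def small_popmap():
    return PopulationMap(
        assignments={"s0": "popA", "s1": "popA", "s2": "popB", "s3": "popB"},
        roles={"popA": "wild", "popB": "domestic"},
    )


@pytest.fixture(scope="session")
def template_sim():
    """One small template simulation shared across tests."""
    from hgfscan.simulate import default_hgf_demography, simulate_genotypes

    cfg = default_hgf_demography(
        wild_ne=10_000,
        outgroup_split_ybp=100_000,
        wild_split_ybp=20_000,
        contig_length=2_000_000,
        seed=1234,
    )
    gm, pm, truth = simulate_genotypes(cfg)
    return cfg, gm, pm, truth
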