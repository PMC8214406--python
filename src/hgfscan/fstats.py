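"""Allele-frequency admixture statistics: outgroup f3 and the four-population
D statistic, with weighted block-jackknife standard errors and Z-scores."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genotypes import GenotypeMatrix, GenotypeError, PopulationMap

__all__ = [
    "FreqTable",
    "FStatResult",
    "build_freq_table",
    "snp_blocks",
    "block_jackknife",
    "outgroup_f3",
    "d_stat",
]


@dataclass
class FreqTable:
    """Per-(population, site) alt-allele frequencies and allele sample sizes."""

    contig: np.ndarray
    pos: np.ndarray
    freqs: dict[str, np.ndarray]  # population -> alt frequency (NaN if uncalled)
    sizes: dict[str, np.ndarray]  # population -> called allele count 2n

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def populations(self) -> list[str]:
        return list(self.freqs)


@dataclass(frozen=True)
class FStatResult:
    statistic: str
    populations: tuple[str, ...]
    estimate: float
    se: float
    z: float
    n_blocks: int
    n_sites: int


def build_freq_table(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> FreqTable:
    """Alt-allele frequencies per population (or pooled group of populations).

    ``groups`` maps a label to the populations pooled under it (pooling is at
    the sample level, before frequency estimation); default is one group per
    population in the map.
    """
    pm.check_against(gm)
    if groups is None:
        groups = {p: [p] for p in pm.populations}
    freqs: dict[str, np.ndarray] = {}
    sizes: dict[str, np.ndarray] = {}
    for label, pops in groups.items():
        rows = gm.sample_indices(pm.samples_of(*pops))
        alt, an = gm.allele_counts(rows)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(an >= 2, alt / np.maximum(an, 1), np.nan)
        freqs[label] = p
        sizes[label] = an
    return FreqTable(contig=gm.contig, pos=gm.pos, freqs=freqs, sizes=sizes)


def snp_blocks(n_sites: int, block_size: int = 1000) -> np.ndarray:
    """Contiguous fixed-size SNP blocks (the last block may be short)."""
    if block_size <= 0:
        raise GenotypeError("block_size must be positive")
    return np.arange(n_sites) // block_size


def block_jackknife(
    per_site_num: np.ndarray,
    per_site_den: np.ndarray,
    block_assignment: np.ndarray,
) -> tuple[float, float]:
    """Weighted delete-one-block jackknife for a ratio estimator.

    Blocks must be contiguous in genome order; weights are block site
    counts.  Returns ``(pooled estimate, jackknife SE)`` following the
    weighted-jackknife variance for unequal block sizes.
    """
    num = np.asarray(per_site_num, dtype=float)
    den = np.asarray(per_site_den, dtype=float)
    blocks = np.asarray(block_assignment)
    uniq = np.unique(blocks)
    sizes = np.array([(blocks == b).sum() for b in uniq], dtype=float)
    uniq = uniq[sizes > 0]
    sizes = sizes[sizes > 0]
    m = len(uniq)
    if m < 2:
        raise GenotypeError("block jackknife requires >= 2 non-empty blocks")
    n_total = sizes.sum()
    if np.any(sizes == n_total):
        raise GenotypeError("a single block covers all sites")
    tot_num = num.sum()
    tot_den = den.sum()
    if tot_den == 0:
        raise GenotypeError("denominator is zero: no informative sites")
    theta = tot_num / tot_den

    theta_del = np.empty(m)
    for k, b in enumerate(uniq):
        sel = blocks == b
        d = tot_den - den[sel].sum()
        if d == 0:
            raise GenotypeError(f"denominator vanishes when deleting block {b}")
        theta_del[k] = (tot_num - num[sel].sum()) / d

    h = n_total / sizes
    tau = h * theta - (h - 1.0) * theta_del
    theta_dot = m * theta - np.sum((1.0 - sizes / n_total) * theta_del)
    var = np.sum((tau - theta_dot) ** 2 / (h - 1.0)) / m
    return float(theta), float(np.sqrt(max(var, 0.0)))


def _complete_case(ft: FreqTable, pops: Sequence[str]) -> np.ndarray:
    ok = np.ones(ft.n_sites, dtype=bool)
    for p in pops:
        if p not in ft.freqs:
            raise GenotypeError(f"population {p!r} not in frequency table")
        ok &= np.isfinite(ft.freqs[p])
    return ok


def outgroup_f3(
    ft: FreqTable,
    outgroup_pop: str,
    pop_a: str,
    pop_b: str,
    block_size: int = 1000,
) -> FStatResult:
    """Shared-drift statistic f3 = mean (p_O - p_A)(p_O - p_B).

    Larger values indicate more shared drift of A and B relative to the
    outgroup.  SE and Z come from a contiguous-SNP block jackknife.
    """
    sel = _complete_case(ft, (outgroup_pop, pop_a, pop_b))
    po = ft.freqs[outgroup_pop][sel]
    pa = ft.freqs[pop_a][sel]
    pb = ft.freqs[pop_b][sel]
    if len(po) == 0:
        raise GenotypeError("no shared sites for f3")
    num = (po - pa) * (po - pb)
    den = np.ones_like(num)
    blocks = snp_blocks(len(num), block_size)
    est, se = block_jackknife(num, den, blocks)
    z = est / se if se > 0 else float("inf") * np.sign(est) if est else 0.0
    return FStatResult(
        statistic="f3",
        populations=(outgroup_pop, pop_a, pop_b),
        estimate=est,
        se=se,
        z=float(z),
        n_blocks=int(blocks.max()) + 1,
        n_sites=len(num),
    )


def d_stat(
    ft: FreqTable,
    p1: str,
    p2: str,
    p3: str,
    outgroup: str,
    block_size: int = 1000,
) -> FStatResult:
    """ABBA-BABA D over population allele frequencies.

    ``D = sum(ABBA - BABA) / sum(ABBA + BABA)`` with
    ``ABBA = (1-p1) p2 p3 (1-p4)`` and ``BABA = p1 (1-p2) p3 (1-p4)``;
    positive D indicates excess sharing between ``p2`` and ``p3``.
    """
    sel = _complete_case(ft, (p1, p2, p3, outgroup))
    f1 = ft.freqs[p1][sel]
    f2 = ft.freqs[p2][sel]
    f3_ = ft.freqs[p3][sel]
    f4 = ft.freqs[outgroup][sel]
    abba = (1 - f1) * f2 * f3_ * (1 - f4)
    baba = f1 * (1 - f2) * f3_ * (1 - f4)
    num = abba - baba
    den = abba + baba
    if den.sum() == 0:
        raise GenotypeError("no ABBA/BABA-informative sites: denominator is zero")
    blocks = snp_blocks(len(num), block_size)
    est, se = block_jackknife(num, den, blocks)
    z = est / se if se > 0 else float("inf") * np.sign(est) if est else 0.0
    return FStatResult(
        statistic="D",
        populations=(p1, p2, p3, outgroup),
        estimate=est,
        se=se,
        z=float(z),
        n_blocks=int(blocks.max()) + 1,
        n_sites=len(num),
    )
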