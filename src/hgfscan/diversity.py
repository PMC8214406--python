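"""Within-population summaries: windowed nucleotide diversity, per-individual
singleton counts, bias-corrected LD decay, and runs of homozygosity."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotypes import (
    MISSING,
    GenomicWindow,
    GenotypeMatrix,
    GenotypeError,
    PopulationMap,
)

__all__ = [
    "DiversityRecord",
    "LDBinRecord",
    "ROHSegment",
    "nucleotide_diversity",
    "count_singletons",
    "ld_decay",
    "detect_roh",
    "summarize_roh",
    "corrected_r2",
]


@dataclass(frozen=True)
class DiversityRecord:
    population: str
    window: GenomicWindow
    pi: float
    n_sites: int


@dataclass(frozen=True)
class LDBinRecord:
    bin_lo: int
    bin_hi: int
    r2_naive: float
    r2_corrected: float
    n_pairs: int


@dataclass(frozen=True)
class ROHSegment:
    sample: str
    contig: str
    start: int  # 1-based position of first SNP in run
    end: int  # 1-based position of last SNP in run
    n_snps: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def snp_density(self) -> float:
        return self.n_snps / max(self.length, 1)


def _per_site_pi(alt: np.ndarray, an: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity 2c(2n-c) / (2n(2n-1))."""
    an = an.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * alt * (an - alt) / (an * (an - 1.0))
    pi[an < 2] = 0.0
    return pi


def nucleotide_diversity(
    gm: GenotypeMatrix,
    samples: Sequence[str],
    windows: Sequence[GenomicWindow],
    population: str = "",
    per_accessible_site: bool = False,
) -> list[DiversityRecord]:
    """Windowed nucleotide diversity for one population.

    Per-site diversity is ``2c(2n-c)/(2n(2n-1))`` with ``c`` the alt count
    and ``2n`` the non-missing allele count; window values divide the summed
    per-site terms by the full window width (or by the number of usable
    sites if ``per_accessible_site``).  Sites with fewer than two called
    alleles contribute nothing and are not counted in ``n_sites``.
    """
    rows = gm.sample_indices(samples)
    alt, an = gm.allele_counts(rows)
    site_pi = _per_site_pi(alt, an)
    usable = an >= 2
    out = []
    for w in windows:
        in_w = (gm.contig == w.contig) & (gm.pos > w.start) & (gm.pos <= w.end)
        sel = in_w & usable
        n_sites = int(sel.sum())
        total = float(site_pi[sel].sum())
        denom = n_sites if per_accessible_site else w.width
        pi = total / denom if denom > 0 else 0.0
        out.append(DiversityRecord(population, w, pi, n_sites))
    return out


def count_singletons(
    gm: GenotypeMatrix, samples: Sequence[str]
) -> dict[str, int]:
    """Per-individual singleton counts within the supplied sample scope.

    A site is a singleton when the minor allele appears exactly once among
    the scope's non-missing alleles; the count is credited to the carrier
    (necessarily heterozygous).
    """
    rows = gm.sample_indices(samples)
    g = gm.gt[rows, :]
    called = g != MISSING
    alt = np.where(called, g, 0).sum(axis=0)
    an = 2 * called.sum(axis=0)
    minor = np.minimum(alt, an - alt)
    singleton_sites = np.flatnonzero((minor == 1) & (an >= 2))
    counts = {s: 0 for s in samples}
    for j in singleton_sites:
        carriers = np.flatnonzero(g[:, j] == 1)
        # exactly one heterozygote carries the single minor-allele copy
        counts[samples[carriers[0]]] += 1
    return counts


def corrected_r2(r2: np.ndarray, n_diploids: np.ndarray | float) -> np.ndarray:
    """Small-sample corrected squared correlation.

    Subtracts the 1/(2n) expectation of r^2 for unlinked loci and rescales by
    2n/(2n-1), so the estimator is centred at ~0 for independent sites even
    at small n (it may go slightly negative).
    """
    two_n = 2.0 * np.asarray(n_diploids, dtype=float)
    return (r2 - 1.0 / two_n) * (two_n / (two_n - 1.0))


def ld_decay(
    gm: GenotypeMatrix,
    samples: Sequence[str],
    max_dist: int = 100_000,
    n_bins: int = 20,
    max_pairs: int | None = None,
    seed: int = 0,
) -> list[LDBinRecord]:
    """Distance-binned naive and corrected r^2 over intra-contig SNP pairs.

    ``r^2`` is the squared composite correlation of 0/1/2 dosages using
    pairwise-complete observations.  ``max_pairs``, if set, caps the number
    of evaluated pairs by deterministic subsampling.
    """
    rows = gm.sample_indices(samples)
    if len(rows) < 4:
        raise GenotypeError("ld_decay requires >= 4 diploids")
    # sites without dosage variance in this sample set carry no LD signal
    # (monomorphic sites, and the all-heterozygote corner case)
    g_all = gm.gt[rows, :].astype(float)
    g_all[g_all == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        informative = np.nanstd(g_all, axis=0) > 0
    gm = gm.take_variants(np.flatnonzero(informative))
    g = g_all[:, informative]

    pair_i, pair_j = [], []
    for ctg in dict.fromkeys(gm.contig):
        idx = np.flatnonzero(gm.contig == ctg)
        pos = gm.pos[idx]
        for a in range(len(idx)):
            hi = np.searchsorted(pos, pos[a] + max_dist, side="right")
            for b in range(a + 1, hi):
                pair_i.append(idx[a])
                pair_j.append(idx[b])
    if not pair_i:
        return []
    pair_i = np.array(pair_i)
    pair_j = np.array(pair_j)
    if max_pairs is not None and len(pair_i) > max_pairs:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(pair_i), size=max_pairs, replace=False)
        keep.sort()
        pair_i, pair_j = pair_i[keep], pair_j[keep]

    dist = gm.pos[pair_j] - gm.pos[pair_i]
    r2 = np.empty(len(pair_i))
    ncomp = np.empty(len(pair_i))
    has_missing = np.isnan(g).any()
    if not has_missing:
        mean = g.mean(axis=0)
        sd = g.std(axis=0)
        z = (g - mean) / np.where(sd == 0, np.nan, sd)
        prod = np.nanmean(z[:, pair_i] * z[:, pair_j], axis=0)
        r2[:] = np.square(prod)
        ncomp[:] = len(rows)
    else:
        for k in range(len(pair_i)):
            x = g[:, pair_i[k]]
            y = g[:, pair_j[k]]
            ok = ~(np.isnan(x) | np.isnan(y))
            n = int(ok.sum())
            ncomp[k] = n
            if n < 2 or x[ok].std() == 0 or y[ok].std() == 0:
                r2[k] = np.nan
                continue
            r = np.corrcoef(x[ok], y[ok])[0, 1]
            r2[k] = r * r
    valid = ~np.isnan(r2) & (ncomp >= 2)
    r2, ncomp, dist = r2[valid], ncomp[valid], dist[valid]
    r2c = corrected_r2(r2, ncomp)

    edges = np.linspace(0, max_dist, n_bins + 1)
    which = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    out = []
    for b in range(n_bins):
        sel = which == b
        n = int(sel.sum())
        if n == 0:
            continue
        out.append(
            LDBinRecord(
                bin_lo=int(edges[b]),
                bin_hi=int(edges[b + 1]),
                r2_naive=float(r2[sel].mean()),
                r2_corrected=float(r2c[sel].mean()),
                n_pairs=n,
            )
        )
    return out


def detect_roh(
    gm: GenotypeMatrix,
    sample: str,
    min_length: int = 1_000_000,
    min_snp: int = 15,
    max_het: int = 0,
    max_miss: int = 1,
    max_gap: int = 1_000_000,
) -> list[ROHSegment]:
    """Consecutive-runs ROH detection for one sample.

    A run is a maximal stretch of homozygous calls allowing up to
    ``max_het`` heterozygotes and ``max_miss`` missing calls, with adjacent
    SNPs no farther apart than ``max_gap``; emitted when its span is at
    least ``min_length`` and it holds at least ``min_snp`` SNPs.
    """
    row = gm.sample_indices([sample])[0]
    segments: list[ROHSegment] = []
    for ctg in dict.fromkeys(gm.contig):
        idx = np.flatnonzero(gm.contig == ctg)
        pos = gm.pos[idx]
        if np.any(np.diff(pos) <= 0):
            raise GenotypeError(f"positions unsorted on {ctg}")
        g = gm.gt[row, idx]
        candidates: list[tuple[int, int]] = []  # index ranges [s, e]
        s = 0
        hets: list[int] = []
        misses: list[int] = []

        def flush(s_: int, e_: int) -> None:
            # trim ends to homozygous calls
            while s_ <= e_ and g[s_] in (1, MISSING):
                s_ += 1
            while e_ >= s_ and g[e_] in (1, MISSING):
                e_ -= 1
            if e_ > s_:
                candidates.append((s_, e_))

        for i in range(len(idx)):
            if i > s and pos[i] - pos[i - 1] > max_gap:
                flush(s, i - 1)
                s, hets, misses = i, [], []
            if g[i] == 1:
                hets.append(i)
                if len(hets) > max_het:
                    flush(s, i - 1)
                    s = hets.pop(0) + 1
                    hets = [h for h in hets if h >= s]
                    misses = [m for m in misses if m >= s]
            elif g[i] == MISSING:
                misses.append(i)
                if len(misses) > max_miss:
                    flush(s, i - 1)
                    s = misses.pop(0) + 1
                    hets = [h for h in hets if h >= s]
                    misses = [m for m in misses if m >= s]
        flush(s, len(idx) - 1)

        # merge overlapping candidates (possible when max_het/max_miss > 0)
        merged: list[list[int]] = []
        for s_, e_ in candidates:
            if merged and s_ <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e_)
            else:
                merged.append([s_, e_])
        for s_, e_ in merged:
            span = int(pos[e_] - pos[s_])
            nsnp = e_ - s_ + 1
            if span >= min_length and nsnp >= min_snp:
                segments.append(
                    ROHSegment(
                        sample=sample,
                        contig=str(ctg),
                        start=int(pos[s_]),
                        end=int(pos[e_]),
                        n_snps=nsnp,
                    )
                )
    return segments


def summarize_roh(
    segments: Sequence[ROHSegment],
    pm: PopulationMap,
    samples: Sequence[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-population (mean segment count, mean total length) over individuals.

    ``samples`` defines the denominator (individuals with zero ROH count);
    defaults to every sample in the population map.
    """
    if samples is None:
        samples = list(pm.assignments)
    per_sample: dict[str, tuple[int, int]] = {s: (0, 0) for s in samples}
    for seg in segments:
        if seg.sample not in per_sample:
            continue
        c, tot = per_sample[seg.sample]
        per_sample[seg.sample] = (c + 1, tot + seg.length)
    out: dict[str, tuple[float, float]] = {}
    for pop in pm.populations:
        members = [s for s in samples if pm.assignments.get(s) == pop]
        if not members:
            continue
        counts = [per_sample[s][0] for s in members]
        totals = [per_sample[s][1] for s in members]
        out[pop] = (float(np.mean(counts)), float(np.mean(totals)))
    return out
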